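"""File input/output: FASTA sequences, PDB bead coordinates, topology
JSON, DCD trajectories, and tabular reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .topology import Topology

__all__ = ["read_fasta", "write_pdb", "read_pdb_coordinates",
           "save_topology", "load_topology", "write_dcd", "read_dcd"]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Sequences from a FASTA file as (id, sequence) pairs."""
    from Bio import SeqIO
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_pdb(path: str | Path, coords: np.ndarray, topology: Topology) -> None:
    """Write bead coordinates as a PDB with one pseudo-CA atom per residue."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = topology.n_beads
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32) * 10.0  # nm -> A
    arr.atom_name = np.array(["CA"] * n)
    arr.res_name = np.array(topology.resnames)
    arr.res_id = np.asarray(topology.residue_index) + 1
    arr.chain_id = np.array(
        [_chain_label(c) for c in topology.chain_index])
    arr.element = np.array(["C"] * n)
    arr.hetero = np.zeros(n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def _chain_label(idx: int) -> str:
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789abcdefghijklmnopqrstuvwxyz"
    return alphabet[idx % len(alphabet)]


def read_pdb_coordinates(path: str | Path) -> np.ndarray:
    """Cα (or single-bead) coordinates from a PDB, in nm, chain-major order."""
    from biotite.structure.io.pdb import PDBFile

    arr = PDBFile.read(str(path)).get_structure(model=1)
    mask = arr.atom_name == "CA"
    if not mask.any():
        mask = np.ones(len(arr), dtype=bool)
    return np.asarray(arr.coord[mask], dtype=np.float64) / 10.0


def save_topology(path: str | Path, topology: Topology) -> None:
    """Serialize a Topology to the documented JSON schema."""
    def arr(a):
        return np.asarray(a).tolist()

    doc = {
        "schema": "cocomo2-topology-1",
        "resnames": topology.resnames,
        "chain_index": arr(topology.chain_index),
        "residue_index": arr(topology.residue_index),
        "chain_kind": topology.chain_kind,
        "chain_label": topology.chain_label,
        "bonds": arr(topology.bonds),
        "bond_l0": arr(topology.bond_l0),
        "angles": arr(topology.angles),
        "angle_kind": topology.angle_kind,
        "enm_pairs": arr(topology.enm_pairs),
        "enm_r0": arr(topology.enm_r0),
        "xi": arr(topology.xi),
        "s_ratio": arr(np.nan_to_num(topology.s_ratio, nan=-1.0)),
        "folded": arr(topology.folded.astype(int)),
        "reference_coordinates": arr(
            np.nan_to_num(topology.reference_coordinates, nan=1e30)),
    }
    Path(path).write_text(json.dumps(doc))


def load_topology(path: str | Path) -> Topology:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != "cocomo2-topology-1":
        raise ValueError("not a cocomo2 topology file")
    s_ratio = np.asarray(doc["s_ratio"], dtype=np.float64)
    s_ratio[s_ratio < 0] = np.nan
    ref = np.asarray(doc["reference_coordinates"], dtype=np.float64).reshape(-1, 3)
    ref[ref > 1e29] = np.nan
    return Topology(
        resnames=list(doc["resnames"]),
        chain_index=np.asarray(doc["chain_index"], dtype=np.int64),
        residue_index=np.asarray(doc["residue_index"], dtype=np.int64),
        chain_kind=list(doc["chain_kind"]),
        chain_label=list(doc["chain_label"]),
        bonds=np.asarray(doc["bonds"], dtype=np.int64).reshape(-1, 2),
        bond_l0=np.asarray(doc["bond_l0"], dtype=np.float64),
        angles=np.asarray(doc["angles"], dtype=np.int64).reshape(-1, 3),
        angle_kind=list(doc["angle_kind"]),
        enm_pairs=np.asarray(doc["enm_pairs"], dtype=np.int64).reshape(-1, 2),
        enm_r0=np.asarray(doc["enm_r0"], dtype=np.float64),
        xi=np.asarray(doc["xi"], dtype=np.float64),
        s_ratio=s_ratio,
        folded=np.asarray(doc["folded"], dtype=bool),
        reference_coordinates=ref,
    )


def write_dcd(path: str | Path, trajectory) -> None:
    """Write trajectory frames to a DCD file (coordinates in Angstrom)."""
    from mdtraj.formats import DCDTrajectoryFile

    with DCDTrajectoryFile(str(path), "w") as fh:
        for frame in trajectory.frames:
            box = trajectory.box * 10.0
            fh.write(np.asarray(frame, dtype=np.float32) * 10.0,
                     cell_lengths=box.astype(np.float32),
                     cell_angles=np.array([90.0, 90.0, 90.0], dtype=np.float32))


def read_dcd(path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    """Frames (n_frames, N, 3) in nm plus box edges from a DCD file."""
    from mdtraj.formats import DCDTrajectoryFile

    with DCDTrajectoryFile(str(path)) as fh:
        xyz, cell_lengths, _ = fh.read()
    box = cell_lengths[0] / 10.0 if cell_lengths is not None else None
    return np.asarray(xyz, dtype=np.float64) / 10.0, box
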