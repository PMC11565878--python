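"""Coarse-grained topology construction.

Chains are declared by sequence plus optional folded-domain annotations
with reference coordinates.  The builder emits one bead per residue,
harmonic bonds between consecutive residues, angle terms on all
consecutive triples, elastic-network (ENM) restraints within each
folded domain, and the per-bead interaction scale xi derived from
surface exposure of the reference structure.  xi is computed once from
the reference structure and never updated during simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forcefield import ParameterSet, residue_table, resolve_residue
from .sasa import reference_surface_area, shrake_rupley

__all__ = [
    "ChainSpec",
    "Topology",
    "SurfaceReport",
    "build_topology",
    "compute_surface_ratio",
    "compute_interaction_scale",
]


@dataclass
class ChainSpec:
    """Declaration of one molecular species.

    folded_ranges are 1-based inclusive residue intervals; reference
    coordinates (nm) must be finite for every residue inside a folded
    range and may be NaN elsewhere.
    """

    chain_id: str
    sequence: str
    molecule_kind: str = "protein"  # protein | rna
    folded_ranges: list[tuple[int, int]] = field(default_factory=list)
    reference_coordinates: np.ndarray | None = None
    copies: int = 1

    def __post_init__(self):
        if self.molecule_kind not in ("protein", "rna"):
            raise ValueError(f"molecule_kind must be protein or rna")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        n = len(self.sequence)
        prev_end = 0
        for start, end in sorted(self.folded_ranges):
            if not (1 <= start <= end <= n):
                raise ValueError(f"folded range ({start},{end}) outside 1..{n}")
            if start <= prev_end:
                raise ValueError("folded ranges overlap")
            prev_end = end
        self.folded_ranges = sorted(tuple(r) for r in self.folded_ranges)
        if self.folded_ranges:
            if self.reference_coordinates is None:
                raise ValueError("folded ranges require reference coordinates")
            coords = np.asarray(self.reference_coordinates, dtype=np.float64)
            if coords.shape != (n, 3):
                raise ValueError("reference_coordinates must be (n_residues, 3)")
            for start, end in self.folded_ranges:
                if not np.all(np.isfinite(coords[start - 1:end])):
                    raise ValueError(
                        f"missing reference coordinates in folded range ({start},{end})")
            self.reference_coordinates = coords
        # residue codes must resolve
        for c in self.sequence:
            resolve_residue(c, self.molecule_kind)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def resnames(self) -> list[str]:
        return [resolve_residue(c, self.molecule_kind) for c in self.sequence]

    def folded_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_residues, dtype=bool)
        for start, end in self.folded_ranges:
            mask[start - 1:end] = True
        return mask


@dataclass
class SurfaceReport:
    """Per-residue surface-exposure report for the folded residues of a chain."""

    chain_id: str
    residue_index: np.ndarray  # 1-based
    resname: list[str]
    s_residue: np.ndarray  # nm^2
    s_ref: np.ndarray  # nm^2
    s_ratio: np.ndarray
    xi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chain": self.chain_id,
            "resid": self.residue_index,
            "resname": self.resname,
            "S_residue": self.s_residue,
            "S_ref": self.s_ref,
            "S_ratio": self.s_ratio,
            "xi": self.xi,
        })


@dataclass
class Topology:
    """Bead-resolution system topology (chain-major, residue-minor order)."""

    resnames: list[str]  # 3-letter code per bead
    chain_index: np.ndarray  # bead -> chain instance
    residue_index: np.ndarray  # bead -> 0-based residue within chain
    chain_kind: list[str]  # per chain instance: protein | rna
    chain_label: list[str]  # per chain instance: source ChainSpec id
    bonds: np.ndarray  # (M, 2) bead indices
    bond_l0: np.ndarray  # (M,)
    angles: np.ndarray  # (K, 3)
    angle_kind: list[str]  # per angle: protein | rna
    enm_pairs: np.ndarray  # (E, 2)
    enm_r0: np.ndarray  # (E,)
    xi: np.ndarray  # per-bead interaction scale in [0, 1]
    s_ratio: np.ndarray  # per-bead surface ratio; NaN outside folded ranges
    folded: np.ndarray  # per-bead bool
    reference_coordinates: np.ndarray  # (N, 3), NaN where undefined

    @property
    def n_beads(self) -> int:
        return len(self.resnames)

    @property
    def n_chains(self) -> int:
        return len(self.chain_kind)

    def chain_slices(self) -> list[slice]:
        out = []
        start = 0
        for c in range(self.n_chains):
            n = int(np.sum(self.chain_index == c))
            out.append(slice(start, start + n))
            start += n
        return out

    def exclusions(self) -> set[tuple[int, int]]:
        """Nonbonded-excluded pairs: exactly the one-bond-separated pairs."""
        return {(int(i), int(j)) for i, j in self.bonds}

    def masses(self) -> np.ndarray:
        table = residue_table()
        return np.array([table[r]["mass"] for r in self.resnames])

    def with_lambda(self, lambda_surface: float | None) -> "Topology":
        """Recompute xi for a different surface-scaling threshold.

        Uses the stored S_ratio values; no SASA recomputation needed.
        """
        xi = np.ones(self.n_beads)
        for b in range(self.n_beads):
            if self.folded[b]:
                xi[b] = compute_interaction_scale(
                    float(self.s_ratio[b]), lambda_surface, True)
        new = Topology(**{**self.__dict__})
        new.xi = xi
        return new


def compute_interaction_scale(s_ratio: float, lam: float | None,
                              is_folded: bool) -> float:
    """Surface-exposure interaction scale xi.

    Disordered residues always interact at full strength (xi = 1).  For
    folded residues xi = 1 when S_ratio >= lambda and S_ratio/lambda
    below the threshold, reaching 0 for fully buried residues.  A
    missing or zero lambda disables scaling.
    """
    if not is_folded or lam is None or lam == 0:
        return 1.0
    if not (0 < lam <= 1):
        raise ValueError("lambda must lie in (0, 1]")
    if s_ratio < 0:
        raise ValueError("S_ratio must be >= 0")
    return 1.0 if s_ratio >= lam else s_ratio / lam


def compute_surface_ratio(chain: ChainSpec,
                          coordinates: np.ndarray | None = None) -> SurfaceReport:
    """Per-residue S_ratio for the folded residues of a chain.

    SASA is evaluated on the coarse-grained reference beads with radii
    sigma_i/2; every residue with finite reference coordinates acts as
    an occluder.  S_ref is the residue-specific fully-exposed reference
    area.
    """
    coords = np.asarray(coordinates if coordinates is not None
                        else chain.reference_coordinates, dtype=np.float64)
    if coords is None or coords.ndim != 2 or coords.shape != (chain.n_residues, 3):
        raise ValueError("coordinates must be (n_residues, 3)")
    folded = chain.folded_mask()
    if not np.all(np.isfinite(coords[folded])):
        raise ValueError("folded residues lack coordinates")
    resnames = chain.resnames()
    table = residue_table()
    present = np.all(np.isfinite(coords), axis=1)
    idx = np.flatnonzero(present)
    radii = np.array([table[resnames[i]]["sigma"] / 2.0 for i in idx])
    areas = shrake_rupley(coords[idx], radii)
    area_by_res = dict(zip(idx.tolist(), areas))

    fold_idx = np.flatnonzero(folded)
    s_res = np.array([area_by_res[int(i)] for i in fold_idx])
    s_ref = np.array([reference_surface_area(resnames[i]) for i in fold_idx])
    s_ratio = s_res / s_ref
    return SurfaceReport(
        chain_id=chain.chain_id,
        residue_index=fold_idx + 1,
        resname=[resnames[i] for i in fold_idx],
        s_residue=s_res,
        s_ref=s_ref,
        s_ratio=s_ratio,
        xi=np.array([1.0] * len(fold_idx)),  # filled by build_topology per lambda
    )


def _enm_pairs_for_range(coords: np.ndarray, start0: int, end0: int,
                         cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """Restraint pairs within one folded range: |i-j| >= 2 and r0 <= cutoff."""
    pairs, r0s = [], []
    for i in range(start0, end0 + 1):
        for j in range(i + 2, end0 + 1):
            r0 = float(np.linalg.norm(coords[i] - coords[j]))
            if r0 <= cutoff:
                pairs.append((i, j))
                r0s.append(r0)
    return (np.array(pairs, dtype=np.int64).reshape(-1, 2),
            np.array(r0s, dtype=np.float64))


def build_topology(chains: list[ChainSpec], params: ParameterSet,
                   allow_cross_domain_enm: bool = False) -> Topology:
    """Assemble the full system topology from chain declarations.

    Each ChainSpec is replicated ``copies`` times with bead indices
    offset per copy; bonded terms never cross copies.  By default ENM
    restraints are restricted to pairs within one declared folded
    range; ``allow_cross_domain_enm`` extends them to any folded pair
    of the same chain within the distance cutoff.
    """
    resnames: list[str] = []
    chain_index: list[int] = []
    residue_index: list[int] = []
    chain_kind: list[str] = []
    chain_label: list[str] = []
    bonds, bond_l0 = [], []
    angles, angle_kind = [], []
    enm_pairs, enm_r0 = [], []
    xi_all, sratio_all, folded_all = [], [], []
    ref_all = []

    chain_counter = 0
    offset = 0
    for spec in chains:
        n = spec.n_residues
        names = spec.resnames()
        l0 = (params.bond_length_protein if spec.molecule_kind == "protein"
              else params.bond_length_rna)
        folded = spec.folded_mask()

        # surface exposure + xi, computed once per species on the reference
        xi_chain = np.ones(n)
        sratio_chain = np.full(n, np.nan)
        if spec.folded_ranges:
            report = compute_surface_ratio(spec)
            for k, resid in enumerate(report.residue_index):
                i = int(resid) - 1
                sratio_chain[i] = report.s_ratio[k]
                xi_chain[i] = compute_interaction_scale(
                    float(report.s_ratio[k]), params.lambda_surface, True)

        # per-species ENM pairs (local indices)
        enm_local: list[tuple[int, int]] = []
        enm_local_r0: list[float] = []
        if spec.folded_ranges:
            coords = spec.reference_coordinates
            if allow_cross_domain_enm:
                fold_idx = np.flatnonzero(folded)
                for a in range(len(fold_idx)):
                    for b in range(a + 1, len(fold_idx)):
                        i, j = int(fold_idx[a]), int(fold_idx[b])
                        if j - i < 2:
                            continue
                        r0 = float(np.linalg.norm(coords[i] - coords[j]))
                        if r0 <= params.enm_cutoff:
                            enm_local.append((i, j))
                            enm_local_r0.append(r0)
            else:
                for start, end in spec.folded_ranges:
                    p, r = _enm_pairs_for_range(coords, start - 1, end - 1,
                                                params.enm_cutoff)
                    enm_local.extend(map(tuple, p.tolist()))
                    enm_local_r0.extend(r.tolist())

        ref = (spec.reference_coordinates if spec.reference_coordinates is not None
               else np.full((n, 3), np.nan))

        for _copy in range(spec.copies):
            resnames.extend(names)
            chain_index.extend([chain_counter] * n)
            residue_index.extend(range(n))
            chain_kind.append(spec.molecule_kind)
            chain_label.append(spec.chain_id)
            for i in range(n - 1):
                bonds.append((offset + i, offset + i + 1))
                bond_l0.append(l0)
            for i in range(n - 2):
                angles.append((offset + i, offset + i + 1, offset + i + 2))
                angle_kind.append(spec.molecule_kind)
            for (i, j), r0 in zip(enm_local, enm_local_r0):
                enm_pairs.append((offset + i, offset + j))
                enm_r0.append(r0)
            xi_all.append(xi_chain)
            sratio_all.append(sratio_chain)
            folded_all.append(folded)
            ref_all.append(ref)
            chain_counter += 1
            offset += n

    return Topology(
        resnames=resnames,
        chain_index=np.array(chain_index, dtype=np.int64),
        residue_index=np.array(residue_index, dtype=np.int64),
        chain_kind=chain_kind,
        chain_label=chain_label,
        bonds=np.array(bonds, dtype=np.int64).reshape(-1, 2),
        bond_l0=np.array(bond_l0, dtype=np.float64),
        angles=np.array(angles, dtype=np.int64).reshape(-1, 3),
        angle_kind=angle_kind,
        enm_pairs=np.array(enm_pairs, dtype=np.int64).reshape(-1, 2),
        enm_r0=np.array(enm_r0, dtype=np.float64),
        xi=np.concatenate(xi_all) if xi_all else np.zeros(0),
        s_ratio=np.concatenate(sratio_all) if sratio_all else np.zeros(0),
        folded=np.concatenate(folded_all) if folded_all else np.zeros(0, dtype=bool),
        reference_coordinates=np.vstack(ref_all) if ref_all else np.zeros((0, 3)),
    )
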