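"""Mixed-phase start configurations and phase observables.

Condensation is detected through single-linkage chain clustering: two
chains are in contact when any inter-chain bead pair lies within the
contact cutoff (minimum image), and clusters are the connected
components of the contact graph.  Chains in clusters smaller than
``min_cluster_size`` count as the dilute phase; their number density
gives the dilute-phase concentration, and its trailing time average
under condensate/dilute coexistence is the saturation-concentration
(csat) estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .constants import AVOGADRO
from .energy import SystemState
from .topology import Topology

__all__ = ["StartConfig", "PhaseReport", "CsatEstimate", "build_start",
           "find_clusters", "dilute_concentration", "estimate_csat",
           "radius_of_gyration", "CONTACT_CUTOFF", "MIN_CLUSTER_SIZE"]

#: default chain-chain contact criterion (nm, any inter-chain bead pair)
CONTACT_CUTOFF = 1.0
#: clusters at least this large count as condensate, smaller ones as dilute
MIN_CLUSTER_SIZE = 5


@dataclass
class StartConfig:
    mode: str = "mixed"  # random | condensate | mixed
    n_chains_total: int = 10
    n_chains_condensed: int | None = None  # mixed mode
    box: float | np.ndarray = 30.0
    min_separation: float = 0.38  # nm, inter-chain bead distance at t=0
    seed: int = 0
    max_retries: int = 2000

    def __post_init__(self):
        if self.mode not in ("random", "condensate", "mixed"):
            raise ValueError("mode must be random, condensate or mixed")
        self.box = np.broadcast_to(np.asarray(self.box, dtype=np.float64),
                                   (3,)).copy()
        if self.mode == "condensate":
            self.n_chains_condensed = self.n_chains_total
        elif self.mode == "random":
            self.n_chains_condensed = 0
        if self.n_chains_condensed is None:
            raise ValueError("mixed mode requires n_chains_condensed")
        if not (0 <= self.n_chains_condensed <= self.n_chains_total):
            raise ValueError("n_chains_condensed must be <= n_chains_total")


@dataclass
class CsatEstimate:
    value: float  # uM; NaN when no coexistence
    spread: float  # block-average standard deviation, uM
    coexistence: bool
    flag: str  # "ok" | "no coexistence" | "fully condensed"
    n_frames: int


@dataclass
class PhaseReport:
    frame_steps: list[int]
    assignments: list[np.ndarray]  # per-frame cluster label per chain
    largest_cluster: np.ndarray
    monomer_count: np.ndarray
    dilute_uM: np.ndarray
    csat: CsatEstimate | None = None
    rg: np.ndarray | None = None  # (n_frames, n_chains)

    def to_frame(self):
        import pandas as pd
        n_clusters = [len(np.unique(a)) for a in self.assignments]
        return pd.DataFrame({
            "frame": range(len(self.assignments)),
            "step": self.frame_steps,
            "n_clusters": n_clusters,
            "largest": self.largest_cluster,
            "monomers": self.monomer_count,
            "c_dilute_uM": self.dilute_uM,
        })


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@njit(cache=True)
def _chain_contacts(coords, box, chain_index, cutoff, contacts):
    n = coords.shape[0]
    c2 = cutoff * cutoff
    for i in range(n):
        ci = chain_index[i]
        for j in range(i + 1, n):
            cj = chain_index[j]
            if ci == cj or contacts[ci, cj]:
                continue
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            dx -= box[0] * round(dx / box[0])
            dy -= box[1] * round(dy / box[1])
            dz -= box[2] * round(dz / box[2])
            if dx * dx + dy * dy + dz * dz < c2:
                contacts[ci, cj] = True
                contacts[cj, ci] = True


def find_clusters(coords: np.ndarray, box: np.ndarray, topology: Topology,
                  contact_cutoff: float = CONTACT_CUTOFF) -> np.ndarray:
    """Single-linkage cluster label per chain for one frame."""
    coords = np.ascontiguousarray(coords, dtype=np.float64)
    box = np.asarray(box, dtype=np.float64)
    nc = topology.n_chains
    contacts = np.zeros((nc, nc), dtype=np.bool_)
    _chain_contacts(coords, box, topology.chain_index, contact_cutoff, contacts)
    _, labels = connected_components(coo_matrix(contacts), directed=False)
    return labels


def dilute_concentration(assignment: np.ndarray, box: np.ndarray,
                         min_cluster_size: int = MIN_CLUSTER_SIZE) -> float:
    """Dilute-phase concentration in uM for one frame's cluster labels."""
    labels, counts = np.unique(assignment, return_counts=True)
    n_dilute = int(counts[counts < min_cluster_size].sum())
    box = np.broadcast_to(np.asarray(box, dtype=np.float64), (3,))
    volume_L = float(np.prod(box)) * 1e-24  # nm^3 -> L
    return n_dilute / (AVOGADRO * volume_L) * 1e6


def analyze_trajectory(traj, topology: Topology,
                       contact_cutoff: float = CONTACT_CUTOFF,
                       min_cluster_size: int = MIN_CLUSTER_SIZE,
                       window_fraction: float = 0.2,
                       with_rg: bool = False) -> PhaseReport:
    """Cluster every frame and attach a csat estimate over the trailing window."""
    assignments, largest, monomers, dilute = [], [], [], []
    box = traj.box
    for frame in traj.frames:
        labels = find_clusters(frame, box, topology, contact_cutoff)
        _, counts = np.unique(labels, return_counts=True)
        assignments.append(labels)
        largest.append(int(counts.max()))
        monomers.append(int((counts == 1).sum()))
        dilute.append(dilute_concentration(labels, box, min_cluster_size))
    report = PhaseReport(
        frame_steps=list(traj.steps),
        assignments=assignments,
        largest_cluster=np.array(largest),
        monomer_count=np.array(monomers),
        dilute_uM=np.array(dilute),
    )
    report.csat = estimate_csat(report, box, window_fraction=window_fraction,
                                min_cluster_size=min_cluster_size)
    if with_rg:
        masses = topology.masses()
        rg = np.array([
            [radius_of_gyration(frame[sl], masses[sl], box=box)
             for sl in topology.chain_slices()]
            for frame in traj.frames])
        report.rg = rg
    return report


def estimate_csat(report: PhaseReport, box,
                  window_fraction: float = 0.2,
                  min_cluster_size: int = MIN_CLUSTER_SIZE,
                  n_blocks: int = 5) -> CsatEstimate:
    """Trailing-window time average of the dilute-phase concentration.

    Requires coexistence within the window: a condensate (cluster of at
    least ``min_cluster_size`` chains) present in most frames, and a
    nonzero dilute phase on average.  Otherwise the estimate is flagged
    rather than reported as a number.
    """
    n = len(report.assignments)
    if n == 0:
        raise ValueError("empty report")
    n_win = max(1, int(math.ceil(window_fraction * n)))
    if n_win > n:
        raise ValueError("window exceeds trajectory")
    largest = report.largest_cluster[n - n_win:]
    dilute = report.dilute_uM[n - n_win:]
    has_condensate = np.median(largest) >= min_cluster_size
    mean = float(np.mean(dilute))
    if not has_condensate:
        return CsatEstimate(math.nan, math.nan, False, "no coexistence", n_win)
    if mean == 0.0:
        return CsatEstimate(math.nan, math.nan, False, "fully condensed", n_win)
    blocks = np.array_split(dilute, min(n_blocks, n_win))
    spread = float(np.std([np.mean(b) for b in blocks]))
    return CsatEstimate(mean, spread, True, "ok", n_win)


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray,
                       box: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration of one chain (nm).

    With a box, the chain is first unwrapped by walking its bonds and
    replacing each step by its minimum-image displacement, so chains
    split across periodic images are measured contiguously.
    """
    coords = np.asarray(coords, dtype=np.float64)
    masses = np.asarray(masses, dtype=np.float64)
    if coords.ndim != 2 or len(coords) == 0:
        raise ValueError("need at least one bead")
    if box is not None and len(coords) > 1:
        coords = _unwrap_chain(coords, np.asarray(box, dtype=np.float64))
    com = np.average(coords, axis=0, weights=masses)
    d2 = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt(np.average(d2, weights=masses)))


def _unwrap_chain(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    out = coords.copy()
    for i in range(1, len(coords)):
        step = coords[i] - coords[i - 1]
        step -= box * np.round(step / box)
        out[i] = out[i - 1] + step
    return out


# ---------------------------------------------------------------------------
# start configurations
# ---------------------------------------------------------------------------

def _chain_template(spec, rng, l0: float) -> np.ndarray:
    """Initial single-chain conformation: the reference structure when
    complete, else a biased random walk at the bond length."""
    if (spec.reference_coordinates is not None
            and np.all(np.isfinite(spec.reference_coordinates))):
        coords = spec.reference_coordinates.copy()
        return coords - coords.mean(axis=0)
    n = spec.n_residues
    coords = np.zeros((n, 3))
    direction = _random_unit(rng)
    for i in range(1, n):
        # persistent walk: new direction correlated with the previous one
        direction = direction + 0.7 * _random_unit(rng)
        direction /= np.linalg.norm(direction)
        coords[i] = coords[i - 1] + l0 * direction
    return coords - coords.mean(axis=0)


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _min_interchain_distance(new_beads, placed, box) -> float:
    if placed is None or len(placed) == 0:
        return np.inf
    d = new_beads[:, None, :] - placed[None, :, :]
    d -= box * np.round(d / box)
    return float(np.sqrt(np.min(np.sum(d * d, axis=-1))))


def build_start(chains, start: StartConfig, topology: Topology,
                params=None) -> SystemState:
    """Place chains into the box according to the start mode.

    mixed: ``n_chains_condensed`` chains drop into a compact droplet at
    the box center, the rest scatter uniformly; condensate/random are
    the pure cases.  Placement enforces the minimum inter-chain bead
    separation with bounded rejection sampling.
    """
    from .forcefield import PRESETS
    if params is None:
        params = PRESETS["COCOMO2"]
    rng = np.random.default_rng(start.seed)
    box = start.box
    slices = topology.chain_slices()
    if len(slices) != start.n_chains_total:
        raise ValueError("topology chain count does not match StartConfig")

    # droplet radius from total condensed bead count at ~loose liquid packing
    specs_per_chain = []
    for spec in chains:
        specs_per_chain.extend([spec] * spec.copies)
    n_cond = start.n_chains_condensed
    beads_cond = sum(s.n_residues for s in specs_per_chain[:n_cond])
    r_drop = max(1.5, 0.5 * (beads_cond ** (1 / 3)) * 0.8 + 1.0)

    coords = np.full((topology.n_beads, 3), np.nan)
    placed: list[np.ndarray] = []
    center = box / 2.0
    for ci, (spec, sl) in enumerate(zip(specs_per_chain, slices)):
        l0 = (params.bond_length_protein if spec.molecule_kind == "protein"
              else params.bond_length_rna)
        condensed = ci < n_cond
        ok = False
        r_try = r_drop
        for attempt in range(start.max_retries):
            template = _chain_template(spec, rng, l0)
            if condensed:
                # uniform point in a sphere around the box center
                u = rng.random() ** (1 / 3)
                pos = center + r_try * u * _random_unit(rng)
            else:
                pos = rng.random(3) * box
            candidate = template + pos
            prev = np.vstack(placed) if placed else None
            if _min_interchain_distance(candidate, prev, box) >= start.min_separation:
                coords[sl] = candidate
                placed.append(candidate)
                ok = True
                break
            if condensed and attempt % 50 == 49:
                r_try *= 1.1  # relax the droplet if packing is too tight
        if not ok:
            raise RuntimeError(
                f"failed to place chain {ci} after {start.max_retries} retries")
    return SystemState(coordinates=coords, box=box.copy(),
                       topology=topology, params=params)
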