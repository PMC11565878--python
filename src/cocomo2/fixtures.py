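"""Synthetic test systems: toy sequences, procedurally built folded
bundles with known burial, and rescoring fixtures with a known
generating parameter set.

Everything here is generated programmatically and deterministically
from a seed; no external structures or downloads are involved.  The
folded "domains" are ideal-helix bundles — geometrically compact
arrangements with a construction-guaranteed buried core — not real
protein folds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .forcefield import ParameterSet, PRESETS
from .phase import StartConfig, build_start
from .simulate import RunConfig, minimize_then_equilibrate, run_langevin
from .topology import ChainSpec, Topology, build_topology

__all__ = ["FixtureSpec", "make_idp_sequence", "make_folded_fixture",
           "make_rescore_fixture", "RescoreFixture", "COMPOSITION_POOLS"]

#: residue pools for the composition classes of toy disordered sequences
COMPOSITION_POOLS = {
    "charged": "DEKR",
    "aromatic": "FYW",
    "polar": "STNQHC",
    "hydrophobic": "AGILMPV",
}

# ideal helix geometry shared with the reference-surface construction
_RISE = 0.15
_RADIUS = 0.23
_TWIST = math.radians(100.0)


@dataclass
class FixtureSpec:
    kind: str  # idp_sequence | folded_helix_bundle | condensate_snapshot | rescore_set
    size: int = 20
    composition: dict = field(default_factory=lambda: {
        "charged": 0.2, "aromatic": 0.1, "polar": 0.4, "hydrophobic": 0.3})
    seed: int = 0


def make_idp_sequence(length: int, composition: dict | None = None,
                      seed: int = 0) -> str:
    """Random disordered sequence drawn from a class composition.

    ``composition`` maps class names (charged/aromatic/polar/
    hydrophobic) or single residue letters to weights summing to 1.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    if composition is None:
        composition = {"charged": 0.2, "aromatic": 0.1,
                       "polar": 0.4, "hydrophobic": 0.3}
    keys = list(composition)
    weights = np.array([composition[k] for k in keys], dtype=np.float64)
    if np.any(weights < 0) or not math.isclose(weights.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("composition weights must be non-negative and sum to 1")
    for k in keys:
        if k not in COMPOSITION_POOLS and not (len(k) == 1 and k.isalpha()):
            raise ValueError(f"unknown composition key {k!r}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(length):
        k = keys[rng.choice(len(keys), p=weights)]
        pool = COMPOSITION_POOLS.get(k, k)
        out.append(pool[rng.integers(len(pool))])
    return "".join(out)


def _helix(n: int, phase: float = 0.0) -> np.ndarray:
    i = np.arange(n, dtype=np.float64)
    ang = i * _TWIST + phase
    return np.column_stack((_RADIUS * np.cos(ang), _RADIUS * np.sin(ang),
                            i * _RISE))


def make_folded_fixture(n_residues: int, seed: int = 0,
                        axis_spacing: float = 0.75,
                        sequence: str | None = None) -> tuple[ChainSpec, dict]:
    """Compact helix-bundle chain with construction-known burial labels.

    For n >= 42 the chain folds into seven parallel ideal helices packed
    hexagonally (six on a ring, one central); the interior residues of
    the central helix are geometrically enclosed and labelled buried,
    while ring residues pointing radially outward are labelled exposed.
    Smaller chains build fewer helices and emit no buried labels.
    Returns the ChainSpec (whole chain declared as one folded domain)
    and a label dict {"buried": [...], "exposed": [...]} of 0-based
    residue indices.
    """
    if n_residues < 8:
        raise ValueError("need at least 8 residues")
    rng = np.random.default_rng(seed)
    if n_residues >= 42:
        n_seg = 7
    elif n_residues >= 30:
        n_seg = 5
    elif n_residues >= 12:
        n_seg = 3
    else:
        n_seg = 1
    m = n_residues // n_seg
    sizes = [m] * n_seg
    sizes[-1] += n_residues - m * n_seg

    # hexagonal axis positions: ring first, center last
    if n_seg == 7:
        angs = np.arange(6) * math.pi / 3.0
        axes = [(axis_spacing * math.cos(a), axis_spacing * math.sin(a))
                for a in angs] + [(0.0, 0.0)]
    elif n_seg == 1:
        axes = [(0.0, 0.0)]
    else:
        angs = np.arange(n_seg - 1) * 2.0 * math.pi / (n_seg - 1)
        axes = [(axis_spacing * math.cos(a), axis_spacing * math.sin(a))
                for a in angs] + [(0.0, 0.0)]

    coords = np.zeros((n_residues, 3))
    seg_of = np.zeros(n_residues, dtype=int)
    pos_in_seg = np.zeros(n_residues, dtype=int)
    start = 0
    for s, size in enumerate(sizes):
        h = _helix(size, phase=0.9 * s)
        if s % 2 == 1:
            h = h[::-1].copy()  # antiparallel for chain connectivity
        h[:, 0] += axes[s][0]
        h[:, 1] += axes[s][1]
        coords[start:start + size] = h
        seg_of[start:start + size] = s
        pos_in_seg[start:start + size] = np.arange(size)
        start += size
    coords += rng.normal(scale=0.005, size=coords.shape)  # break exact symmetry

    buried, exposed = [], []
    if n_seg >= 5:
        center_seg = n_seg - 1
        for i in range(n_residues):
            s, p = seg_of[i], pos_in_seg[i]
            if s == center_seg and 2 <= p <= sizes[s] - 3:
                buried.append(i)
            elif s != center_seg:
                radial = math.hypot(coords[i, 0], coords[i, 1])
                if radial > axis_spacing + 0.5 * _RADIUS:
                    exposed.append(i)

    if sequence is None:
        sequence = make_idp_sequence(n_residues, seed=seed + 1)
    elif len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    spec = ChainSpec(
        chain_id=f"bundle{n_residues}",
        sequence=sequence,
        molecule_kind="protein",
        folded_ranges=[(1, n_residues)],
        reference_coordinates=coords,
    )
    return spec, {"buried": buried, "exposed": exposed}


# ---------------------------------------------------------------------------
# rescoring fixture
# ---------------------------------------------------------------------------

@dataclass
class RescoreFixture:
    """Self-consistent synthetic inverse problem for the optimizer."""

    true_params: ParameterSet
    rescore_sets: list  # RescoreSet per system (csat assigned from the record)
    calibration: dict  # system_id -> list of (U, csat_mM) points
    record: dict  # true params, per-system (a, b), noise sigma, seed

    def save_record(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.record, indent=2, sort_keys=True))

    @staticmethod
    def load_record(path: str | Path) -> dict:
        return json.loads(Path(path).read_text())


def _default_systems(seed: int) -> list[dict]:
    """Composition-diverse toy systems covering all free parameters.

    Composition-pure systems isolate individual parameter classes;
    chain lengths differ so that paired systems probe different
    condensate contact statistics, which decorrelates the well-depth
    and solvation-repulsion directions of the inverse problem.
    """
    return [
        {"system_id": "polar_idp",
         "sequence": make_idp_sequence(20, {"polar": 1.0}, seed + 11)},
        {"system_id": "polar_idp_short",
         "sequence": make_idp_sequence(10, {"polar": 1.0}, seed + 15)},
        {"system_id": "hydrophobic_idp",
         "sequence": make_idp_sequence(20, {"hydrophobic": 0.7, "aromatic": 0.3},
                                       seed + 12)},
        {"system_id": "hydrophobic_idp_short",
         "sequence": make_idp_sequence(10, {"hydrophobic": 1.0}, seed + 16)},
        {"system_id": "mixed_idp",
         "sequence": make_idp_sequence(20, None, seed + 13)},
        {"system_id": "charged_idp",
         "sequence": make_idp_sequence(20, {"charged": 0.5, "polar": 0.25,
                                            "hydrophobic": 0.25}, seed + 14)},
        {"system_id": "bundle_a", "folded": 42},
        {"system_id": "bundle_b", "folded": 49},
    ]


def _condensate_snapshots(chains: list[ChainSpec], params: ParameterSet,
                          box: float, seed: int, n_conformations: int,
                          n_steps: int = 3000) -> tuple[Topology, list]:
    """Short condensed-phase run; evenly strided trailing conformations."""
    topology = build_topology(chains, params)
    n_total = sum(c.copies for c in chains)
    start = StartConfig(mode="condensate", n_chains_total=n_total,
                        box=box, seed=seed)
    state = build_start(chains, start, topology, params)
    run = RunConfig(n_equil_steps=1000, n_prod_steps=n_steps, seed=seed,
                    report_interval=max(1, n_steps // (2 * n_conformations)))
    state = minimize_then_equilibrate(state, run)
    traj, _ = run_langevin(state, run)
    frames = traj.frames
    stride_idx = np.linspace(len(frames) // 2, len(frames) - 1,
                             n_conformations).astype(int)
    return topology, [frames[i] for i in stride_idx]


def make_rescore_fixture(true_params: ParameterSet | None = None,
                         systems: list[dict] | None = None,
                         seed: int = 0,
                         n_chains: int = 8,
                         box: float = 12.0,
                         n_conformations: int = 10,
                         noise_sigma: float = 0.0) -> RescoreFixture:
    """Build the optimizer's synthetic inverse problem.

    Condensate snapshots are generated by short simulations under
    ``true_params``; each system is assigned a linear energy-to-csat
    relation log10(csat) = a U + b with random (a, b), calibration
    points are produced by rescoring the snapshots under scaled
    parameter variants, and the synthetic "experimental" csat is the
    relation evaluated at the true parameters, optionally perturbed by
    lognormal noise of width ``noise_sigma`` (decades).
    """
    from dataclasses import replace
    from .optimize import RescoreSet, rescore

    if true_params is None:
        # solvation-repulsion amplitudes are set large enough that they
        # leave a clear signature in the condensate energies; tiny A0
        # values are invisible to any energy-based fit
        true_params = replace(PRESETS["COCOMO2"],
                              name="fixture-truth",
                              eps_polar=0.20, eps_hydrophobic=0.30,
                              A0_polar=0.30, A0_hydrophobic=0.20,
                              lambda_surface=0.55)
    if systems is None:
        systems = _default_systems(seed)
    rng = np.random.default_rng(seed)

    # parameter variants for the calibration points: scale the class
    # well depths and repulsion terms, sweep lambda
    factors = [0.6, 0.8, 1.0, 1.25, 1.5, 1.8]
    lambdas = [0.35, 0.45, 0.55, 0.65, 0.7, 0.5]
    variants = []
    for f, lam in zip(factors, lambdas):
        variants.append(replace(
            true_params,
            eps_polar=true_params.eps_polar * f,
            eps_hydrophobic=true_params.eps_hydrophobic / f,
            A0_polar=true_params.A0_polar * f,
            A0_hydrophobic=true_params.A0_hydrophobic * (2.0 - f),
            lambda_surface=lam))

    rescore_sets, calibration = [], {}
    record = {"seed": seed, "noise_sigma": noise_sigma,
              "true_params": {k: v for k, v in true_params.to_dict().items()
                              if isinstance(v, (int, float, str, bool)) or v is None},
              "systems": {}}
    for k, sysdef in enumerate(systems):
        if "folded" in sysdef:
            spec, _ = make_folded_fixture(sysdef["folded"], seed=seed + 100 + k)
            spec = ChainSpec(chain_id=sysdef["system_id"], sequence=spec.sequence,
                             folded_ranges=spec.folded_ranges,
                             reference_coordinates=spec.reference_coordinates,
                             copies=n_chains)
        else:
            spec = ChainSpec(chain_id=sysdef["system_id"],
                             sequence=sysdef["sequence"], copies=n_chains)
        topology, confs = _condensate_snapshots(
            [spec], true_params, box, seed + 200 + k, n_conformations)
        a = float(rng.uniform(0.4, 0.8))
        b = float(rng.uniform(0.0, 1.5))
        rset = RescoreSet(system_id=sysdef["system_id"], topology=topology,
                          conformations=confs, box=np.full(3, box),
                          csat_exp_mM=1.0)  # placeholder until U(true) known
        U_true = rescore(rset, true_params)
        noise = float(rng.normal(0.0, noise_sigma)) if noise_sigma > 0 else 0.0
        csat_exp = 10.0 ** (a * U_true + b + noise)
        rset.csat_exp_mM = csat_exp
        points = []
        for variant in variants:
            U = rescore(rset, variant)
            pnoise = float(rng.normal(0.0, noise_sigma)) if noise_sigma > 0 else 0.0
            points.append((U, 10.0 ** (a * U + b + pnoise)))
        rescore_sets.append(rset)
        calibration[sysdef["system_id"]] = points
        record["systems"][sysdef["system_id"]] = {
            "a": a, "b": b, "csat_exp_mM": csat_exp, "U_true": U_true}
    return RescoreFixture(true_params=true_params, rescore_sets=rescore_sets,
                          calibration=calibration, record=record)
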