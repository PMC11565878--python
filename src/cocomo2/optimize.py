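"""Energy-based parameter optimization.

The saturation concentration of a condensate-forming system depends
exponentially on the mean interaction energy U of the condensed phase,
csat ~ exp(-U/kB T), so log10(csat) is linear in U.  This module
implements the resulting three-stage fitting protocol:

1. rescore stored condensate conformations under candidate parameters
   (no simulation),
2. fit robust (RANSAC) per-system lines log10(csat) = a U + b from
   calibration points, and
3. minimize the summed squared deviation between predicted and
   experimental log10(csat) over the free parameters — first a grid
   scan and bounded L-BFGS-B refinement on disordered systems only
   (the surface threshold lambda does not affect them), then a joint
   refinement over all systems with lambda included, capped at 0.7.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.linear_model import LinearRegression, RANSACRegressor

from .energy import EnergyModel
from .forcefield import ParameterSet
from .topology import Topology

__all__ = ["RescoreSet", "FitModel", "OptimizationProblem", "OptimizationResult",
           "rescore", "fit_energy_csat", "predict_csat", "optimize"]

#: upper bound on the surface-exposure threshold during optimization;
#: higher values change condensate morphology
LAMBDA_MAX = 0.7

FREE_PARAMS = ("eps_polar", "eps_hydrophobic", "A0_polar", "A0_hydrophobic",
               "lambda_surface")

DEFAULT_BOUNDS = {
    "eps_polar": (0.01, 2.0),
    "eps_hydrophobic": (0.01, 2.0),
    "A0_polar": (0.0, 1.0),
    "A0_hydrophobic": (0.0, 1.0),
    "lambda_surface": (0.05, LAMBDA_MAX),
}


@dataclass
class RescoreSet:
    """Stored condensate conformations of one system plus its experimental csat."""

    system_id: str
    topology: Topology
    conformations: list  # list of (N, 3) coordinate arrays, nm
    box: np.ndarray  # (3,) nm
    csat_exp_mM: float

    def __post_init__(self):
        if not self.conformations:
            raise ValueError("need at least one conformation")
        n = self.topology.n_beads
        for c in self.conformations:
            if np.asarray(c).shape != (n, 3):
                raise ValueError("conformation does not match topology")
        if self.csat_exp_mM <= 0:
            raise ValueError("experimental csat must be positive")
        self.box = np.broadcast_to(np.asarray(self.box, dtype=np.float64), (3,)).copy()
        self._pair_lists: list | None = None

    @property
    def n_beads(self) -> int:
        return self.topology.n_beads

    @property
    def is_idp(self) -> bool:
        return not bool(np.any(self.topology.folded))


@dataclass
class FitModel:
    """Per-system linear model log10(csat/mM) = a * U + b."""

    system_id: str
    slope: float
    intercept: float
    inlier_mask: np.ndarray
    r2_inliers: float

    def predict_log10(self, U: float) -> float:
        return self.slope * U + self.intercept


def rescore(rescore_set: RescoreSet, candidate: ParameterSet) -> float:
    """Mean per-residue potential energy (kJ/mol per bead) of the stored
    conformations under candidate parameters.

    The surface-exposure scales xi are recomputed for the candidate's
    lambda from the stored per-bead surface ratios; no simulation and
    no SASA recomputation is performed.  Pair lists are cached per
    conformation (the cutoff is not a free parameter).
    """
    top = rescore_set.topology.with_lambda(candidate.lambda_surface)
    model = EnergyModel(top, candidate)
    if rescore_set._pair_lists is None:
        rescore_set._pair_lists = [
            model.build_pair_list(np.asarray(c, dtype=np.float64), rescore_set.box)
            for c in rescore_set.conformations]
    total = 0.0
    for coords, pairs in zip(rescore_set.conformations, rescore_set._pair_lists):
        breakdown, _ = model.evaluate(np.asarray(coords, dtype=np.float64),
                                      rescore_set.box, pairs=pairs,
                                      want_forces=False)
        total += breakdown.total
    return total / (len(rescore_set.conformations) * rescore_set.n_beads)


def fit_energy_csat(points, seed: int = 0, min_samples: int = 2,
                    max_trials: int = 1000,
                    residual_threshold: float | None = None,
                    system_id: str = "") -> FitModel:
    """RANSAC-robust linear fit of log10(csat/mM) against per-residue energy.

    With no outliers the consensus set is every point and the result
    equals ordinary least squares.  The residual threshold defaults to
    the median absolute deviation of the responses (sklearn default).
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (U, csat) points")
    U = pts[:, 0:1]
    csat = pts[:, 1]
    if np.any(csat <= 0):
        raise ValueError("csat values must be positive")
    if np.ptp(U) == 0:
        raise ValueError("degenerate design: all energies identical")
    y = np.log10(csat)
    ransac = RANSACRegressor(estimator=LinearRegression(),
                             min_samples=min_samples,
                             max_trials=max_trials,
                             residual_threshold=residual_threshold,
                             random_state=seed)
    ransac.fit(U, y)
    mask = ransac.inlier_mask_
    a = float(ransac.estimator_.coef_[0])
    b = float(ransac.estimator_.intercept_)
    resid = y[mask] - (a * U[mask, 0] + b)
    ss_tot = float(np.sum((y[mask] - y[mask].mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return FitModel(system_id=system_id, slope=a, intercept=b,
                    inlier_mask=mask, r2_inliers=r2)


def predict_csat(model: FitModel, U: float) -> float:
    """Predicted saturation concentration in mM: 10^(a U + b)."""
    return 10.0 ** model.predict_log10(U)


@dataclass
class OptimizationProblem:
    base_params: ParameterSet
    systems: list  # list of (RescoreSet, FitModel)
    free_params: tuple = FREE_PARAMS
    bounds: dict = field(default_factory=dict)
    scan_grid: dict = field(default_factory=dict)  # param -> values for stage 1

    def __post_init__(self):
        for p in self.free_params:
            if p not in FREE_PARAMS:
                raise ValueError(f"unknown free parameter {p!r}")
        merged = {p: self.bounds.get(p, DEFAULT_BOUNDS[p]) for p in self.free_params}
        lo, hi = merged.get("lambda_surface", (0.05, LAMBDA_MAX))
        if "lambda_surface" in merged and hi > LAMBDA_MAX:
            merged["lambda_surface"] = (lo, LAMBDA_MAX)
        self.bounds = merged


@dataclass
class OptimizationResult:
    params: ParameterSet
    objective: float
    trace: list  # (stage, dict(theta), objective) accepted iterates
    active_bounds: list


def _objective(theta: dict, base: ParameterSet, systems) -> float:
    candidate = replace(base, **theta)
    total = 0.0
    for rset, fit in systems:
        U = rescore(rset, candidate)
        total += (fit.predict_log10(U) - math.log10(rset.csat_exp_mM)) ** 2
    return total


def optimize(problem: OptimizationProblem, stage: str = "joint",
             x0: ParameterSet | None = None) -> OptimizationResult:
    """Run one stage of the parameterization.

    scan: grid evaluation over disordered systems only, lambda
    excluded.  refine: bounded L-BFGS-B from the incoming parameters,
    disordered systems only, lambda excluded.  joint: bounded L-BFGS-B
    over all systems with lambda included (capped at 0.7; a lambda
    start above the cap is clamped and the bound reported active).
    """
    from scipy.optimize import minimize as sp_minimize

    if stage not in ("scan", "refine", "joint"):
        raise ValueError("stage must be scan, refine or joint")
    base = x0 if x0 is not None else problem.base_params
    if stage in ("scan", "refine"):
        names = [p for p in problem.free_params if p != "lambda_surface"]
        systems = [s for s in problem.systems if s[0].is_idp]
    else:
        names = list(problem.free_params)
        systems = list(problem.systems)
    if not systems:
        raise ValueError(f"no systems available for stage {stage!r}")

    trace: list = []
    active: list = []

    if stage == "scan":
        grids = []
        for p in names:
            if p in problem.scan_grid:
                grids.append(np.asarray(problem.scan_grid[p], dtype=np.float64))
            else:
                lo, hi = problem.bounds[p]
                grids.append(np.linspace(lo, hi, 5))
        best, best_obj = None, np.inf
        for values in itertools.product(*grids):
            theta = dict(zip(names, values))
            obj = _objective(theta, base, systems)
            if obj < best_obj:
                best, best_obj = theta, obj
                trace.append(("scan", dict(theta), obj))
        return OptimizationResult(replace(base, **best), best_obj, trace, active)

    # bounded quasi-Newton stages
    x_start = []
    for p in names:
        v = getattr(base, p)
        lo, hi = problem.bounds[p]
        if v is None:
            v = hi  # lambda disabled on the base set: start at the cap
        if v > hi:
            v = hi
            active.append(p)
        if v < lo:
            v = lo
            active.append(p)
        x_start.append(v)

    def fun(x):
        return _objective(dict(zip(names, x)), base, systems)

    def cb(xk):
        trace.append((stage, dict(zip(names, xk)), fun(xk)))

    res = sp_minimize(fun, np.asarray(x_start), method="L-BFGS-B",
                      bounds=[problem.bounds[p] for p in names],
                      callback=cb,
                      options={"maxiter": 500, "eps": 1e-5,
                               "ftol": 1e-14, "gtol": 1e-10})
    theta = dict(zip(names, res.x))
    for p, v in theta.items():
        lo, hi = problem.bounds[p]
        if math.isclose(v, hi, abs_tol=1e-9) or math.isclose(v, lo, abs_tol=1e-9):
            if p not in active:
                active.append(p)
    return OptimizationResult(replace(base, **theta), float(res.fun), trace, active)
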