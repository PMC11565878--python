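"""Potential-energy evaluation under periodic boundary conditions.

The total potential is the sum of harmonic bonds, elastic-network
restraints, harmonic angles (straight-chain reference), a 10-5
short-range pair potential scaled by the surface-exposure factors
xi_i*xi_j, and a screened Debye-Hueckel electrostatic term.  Nonbonded
interactions are truncated at the cutoff (plain truncation by default)
and one-bond-separated pairs are excluded.

Nonbonded evaluation runs over a Verlet pair list built by cell
binning with a safety skin; results are identical to a brute-force
double loop, which the test suite verifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .forcefield import AROMATIC, CATIONIC, ParameterSet, electro_attraction, residue_table
from .topology import Topology

__all__ = [
    "SystemState",
    "EnergyBreakdown",
    "EnergyModel",
    "bond_energy",
    "enm_energy",
    "angle_energy",
    "short_range_energy",
    "electrostatic_energy",
    "total_energy",
    "forces",
]

NEIGHBOR_SKIN = 0.3  # nm


class OverlappingBeadsError(ValueError):
    """Raised when an interacting pair sits at zero separation."""


class DegenerateAngleError(ValueError):
    """Raised when an angle triple contains a zero-length bond vector."""


@dataclass
class SystemState:
    """Coordinates plus everything needed to score them."""

    coordinates: np.ndarray  # (N, 3) nm
    box: np.ndarray  # (3,) orthorhombic edges, nm
    topology: Topology
    params: ParameterSet

    def __post_init__(self):
        self.coordinates = np.ascontiguousarray(self.coordinates, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64).reshape(3)
        if self.coordinates.shape != (self.topology.n_beads, 3):
            raise ValueError("coordinates do not match topology")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")
        if np.any(self.box <= 2.0 * self.params.cutoff):
            raise ValueError("box edges must exceed twice the nonbonded cutoff")

    def model(self) -> "EnergyModel":
        key = getattr(self, "_model_key", None)
        if key != (id(self.topology), self.params):
            self._model = EnergyModel(self.topology, self.params)
            self._model_key = (id(self.topology), self.params)
        return self._model


@dataclass(frozen=True)
class EnergyBreakdown:
    bond: float
    angle: float
    enm: float
    short_range: float
    electrostatic: float

    @property
    def total(self) -> float:
        return self.bond + self.angle + self.enm + self.short_range + self.electrostatic

    def as_dict(self) -> dict:
        return {"bond": self.bond, "angle": self.angle, "enm": self.enm,
                "short_range": self.short_range,
                "electrostatic": self.electrostatic, "total": self.total}


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _harmonic_pairs(coords, box, pairs, r0, k, f):
    e = 0.0
    for m in range(pairs.shape[0]):
        i, j = pairs[m, 0], pairs[m, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        dx -= box[0] * round(dx / box[0])
        dy -= box[1] * round(dy / box[1])
        dz -= box[2] * round(dz / box[2])
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0[m]
        e += 0.5 * k * dr * dr
        if r > 0.0:
            fac = -k * dr / r
            f[i, 0] += fac * dx
            f[i, 1] += fac * dy
            f[i, 2] += fac * dz
            f[j, 0] -= fac * dx
            f[j, 1] -= fac * dy
            f[j, 2] -= fac * dz
    return e


@njit(cache=True)
def _angles(coords, box, triples, kper, theta0, f):
    e = 0.0
    bad = -1
    for m in range(triples.shape[0]):
        i, j, kk = triples[m, 0], triples[m, 1], triples[m, 2]
        ux = coords[i, 0] - coords[j, 0]
        uy = coords[i, 1] - coords[j, 1]
        uz = coords[i, 2] - coords[j, 2]
        vx = coords[kk, 0] - coords[j, 0]
        vy = coords[kk, 1] - coords[j, 1]
        vz = coords[kk, 2] - coords[j, 2]
        ux -= box[0] * round(ux / box[0])
        uy -= box[1] * round(uy / box[1])
        uz -= box[2] * round(uz / box[2])
        vx -= box[0] * round(vx / box[0])
        vy -= box[1] * round(vy / box[1])
        vz -= box[2] * round(vz / box[2])
        nu = math.sqrt(ux * ux + uy * uy + uz * uz)
        nv = math.sqrt(vx * vx + vy * vy + vz * vz)
        if nu < 1e-12 or nv < 1e-12:
            bad = m
            continue
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = math.acos(c)
        dth = theta - theta0
        k = kper[m]
        e += 0.5 * k * dth * dth
        s = math.sqrt(1.0 - c * c)
        if s > 1e-8:
            # F = k (theta-theta0)/sin(theta) * dcos/dx
            pre = k * dth / s
            inu = 1.0 / nu
            inv = 1.0 / nv
            uhx, uhy, uhz = ux * inu, uy * inu, uz * inu
            vhx, vhy, vhz = vx * inv, vy * inv, vz * inv
            dix = (vhx - c * uhx) * inu
            diy = (vhy - c * uhy) * inu
            diz = (vhz - c * uhz) * inu
            dkx = (uhx - c * vhx) * inv
            dky = (uhy - c * vhy) * inv
            dkz = (uhz - c * vhz) * inv
            f[i, 0] += pre * dix
            f[i, 1] += pre * diy
            f[i, 2] += pre * diz
            f[kk, 0] += pre * dkx
            f[kk, 1] += pre * dky
            f[kk, 2] += pre * dkz
            f[j, 0] -= pre * (dix + dkx)
            f[j, 1] -= pre * (diy + dky)
            f[j, 2] -= pre * (diz + dkz)
    return e, bad


@njit(cache=True)
def _build_pairs_brute(coords, box, rlist, chain_index, residue_index, out, cap):
    n = coords.shape[0]
    cnt = 0
    r2 = rlist * rlist
    for i in range(n):
        for j in range(i + 1, n):
            if chain_index[i] == chain_index[j]:
                dres = residue_index[i] - residue_index[j]
                if dres == 1 or dres == -1:
                    continue
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            dx -= box[0] * round(dx / box[0])
            dy -= box[1] * round(dy / box[1])
            dz -= box[2] * round(dz / box[2])
            if dx * dx + dy * dy + dz * dz <= r2:
                if cnt < cap:
                    out[cnt, 0] = i
                    out[cnt, 1] = j
                cnt += 1
    return cnt


@njit(cache=True)
def _build_pairs_cells(coords, box, rlist, chain_index, residue_index, out, cap):
    n = coords.shape[0]
    ncx = max(1, int(box[0] // rlist))
    ncy = max(1, int(box[1] // rlist))
    ncz = max(1, int(box[2] // rlist))
    ncell = ncx * ncy * ncz
    head = np.full(ncell, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    cx = np.empty(n, dtype=np.int64)
    cy = np.empty(n, dtype=np.int64)
    cz = np.empty(n, dtype=np.int64)
    for i in range(n):
        x = coords[i, 0] % box[0]
        y = coords[i, 1] % box[1]
        z = coords[i, 2] % box[2]
        a = int(x / box[0] * ncx)
        b = int(y / box[1] * ncy)
        c = int(z / box[2] * ncz)
        if a >= ncx:
            a = ncx - 1
        if b >= ncy:
            b = ncy - 1
        if c >= ncz:
            c = ncz - 1
        cx[i], cy[i], cz[i] = a, b, c
        cell = (a * ncy + b) * ncz + c
        nxt[i] = head[cell]
        head[cell] = i
    cnt = 0
    r2 = rlist * rlist
    for a in range(ncx):
        for b in range(ncy):
            for c in range(ncz):
                cell = (a * ncy + b) * ncz + c
                i = head[cell]
                while i >= 0:
                    # same cell: j after i in the linked list
                    j = nxt[i]
                    while j >= 0:
                        cnt = _try_pair(coords, box, r2, chain_index,
                                        residue_index, i, j, out, cap, cnt)
                        j = nxt[j]
                    # half of the neighboring cells
                    for da in range(-1, 2):
                        for db in range(-1, 2):
                            for dc in range(-1, 2):
                                # half-shell: only positively-encoded offsets
                                if da * 9 + db * 3 + dc <= 0:
                                    continue
                                na = (a + da) % ncx
                                nb = (b + db) % ncy
                                nc = (c + dc) % ncz
                                ocell = (na * ncy + nb) * ncz + nc
                                if ocell == cell:
                                    continue
                                j = head[ocell]
                                while j >= 0:
                                    cnt = _try_pair(coords, box, r2, chain_index,
                                                    residue_index, i, j, out, cap, cnt)
                                    j = nxt[j]
                    i = nxt[i]
    return cnt


@njit(cache=True, inline="always")
def _try_pair(coords, box, r2, chain_index, residue_index, i, j, out, cap, cnt):
    if chain_index[i] == chain_index[j]:
        dres = residue_index[i] - residue_index[j]
        if dres == 1 or dres == -1:
            return cnt
    dx = coords[i, 0] - coords[j, 0]
    dy = coords[i, 1] - coords[j, 1]
    dz = coords[i, 2] - coords[j, 2]
    dx -= box[0] * round(dx / box[0])
    dy -= box[1] * round(dy / box[1])
    dz -= box[2] * round(dz / box[2])
    if dx * dx + dy * dy + dz * dz <= r2:
        if cnt < cap:
            out[cnt, 0] = i
            out[cnt, 1] = j
        cnt += 1
    return cnt


@njit(cache=True)
def _nonbonded(coords, box, pairs, sigma, eps, xi, A, A0,
               is_cat, is_aro, is_nuc,
               emod_ca, emod_cn, emod_aa,
               cutoff, kappa, pref, xi_elec, shift, f):
    e_sr = 0.0
    e_el = 0.0
    bad = -1
    cut2 = cutoff * cutoff
    for m in range(pairs.shape[0]):
        i, j = pairs[m, 0], pairs[m, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        dx -= box[0] * round(dx / box[0])
        dy -= box[1] * round(dy / box[1])
        dz -= box[2] * round(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= cut2:
            continue
        if r2 < 1e-20:
            bad = m
            continue
        r = math.sqrt(r2)

        emod = 0.0
        if (is_cat[i] and is_aro[j]) or (is_cat[j] and is_aro[i]):
            emod = emod_ca
        elif (is_cat[i] and is_nuc[j]) or (is_cat[j] and is_nuc[i]):
            emod = emod_cn
        elif is_aro[i] and is_aro[j]:
            emod = emod_aa

        sij = 0.5 * (sigma[i] + sigma[j])
        eij = math.sqrt(eps[i] * eps[j])
        xij = xi[i] * xi[j]
        s5 = (sij / r) ** 5
        s10 = s5 * s5
        amp = 4.0 * xij * (eij + emod)
        u_sr = amp * (s10 - s5)
        # dU/dr = amp * (-10 s10 + 5 s5)/r ; force magnitude = -dU/dr
        fmag = amp * (10.0 * s10 - 5.0 * s5) / r

        aij = A[i] * A[j] + A0[i] * A0[j]
        scale_el = xij if xi_elec else 1.0
        ex = math.exp(-r / kappa)
        u_el = scale_el * pref * aij * ex / r
        fmag += u_el * (1.0 / r + 1.0 / kappa)

        if shift:
            sc5 = (sij / cutoff) ** 5
            u_sr -= amp * (sc5 * sc5 - sc5)
            u_el -= scale_el * pref * aij * math.exp(-cutoff / kappa) / cutoff

        e_sr += u_sr
        e_el += u_el
        fr = fmag / r
        f[i, 0] += fr * dx
        f[i, 1] += fr * dy
        f[i, 2] += fr * dz
        f[j, 0] -= fr * dx
        f[j, 1] -= fr * dy
        f[j, 2] -= fr * dz
    return e_sr, e_el, bad


# ---------------------------------------------------------------------------
# model wrapper
# ---------------------------------------------------------------------------

class EnergyModel:
    """Precompiled per-bead parameter arrays for a (topology, params) pair."""

    def __init__(self, topology: Topology, params: ParameterSet):
        self.topology = topology
        self.params = params
        table = residue_table()
        n = topology.n_beads
        self.sigma = np.empty(n)
        self.eps = np.empty(n)
        self.A = np.empty(n)
        self.A0 = np.empty(n)
        self.is_cat = np.zeros(n, dtype=np.uint8)
        self.is_aro = np.zeros(n, dtype=np.uint8)
        self.is_nuc = np.zeros(n, dtype=np.uint8)
        for i, name in enumerate(topology.resnames):
            rec = table[name]
            self.sigma[i] = rec["sigma"]
            self.eps[i] = params.eps_for_class(rec["class"])
            self.A[i] = electro_attraction(rec["charge"], params)
            self.A0[i] = params.A0_for_class(rec["class"])
            self.is_cat[i] = name in CATIONIC
            self.is_aro[i] = name in AROMATIC
            self.is_nuc[i] = rec["class"] == "nucleotide"
        self.xi = np.ascontiguousarray(topology.xi, dtype=np.float64)
        self.mass = topology.masses()
        self.angle_k = np.array(
            [params.k_angle_protein if k == "protein" else params.k_angle_nucleic
             for k in topology.angle_kind])
        self._pair_cap = max(1024, 64 * n)

    # -- pair list ----------------------------------------------------------
    def build_pair_list(self, coords: np.ndarray, box: np.ndarray,
                        rlist: float | None = None) -> np.ndarray:
        """Candidate nonbonded pairs within cutoff + skin (exclusions removed)."""
        if rlist is None:
            rlist = self.params.cutoff + NEIGHBOR_SKIN
        coords = np.ascontiguousarray(coords, dtype=np.float64)
        box = np.asarray(box, dtype=np.float64)
        use_cells = np.all(box / rlist >= 3.0) and coords.shape[0] > 64
        build = _build_pairs_cells if use_cells else _build_pairs_brute
        cap = self._pair_cap
        while True:
            out = np.empty((cap, 2), dtype=np.int64)
            cnt = build(coords, box, rlist, self.topology.chain_index,
                        self.topology.residue_index, out, cap)
            if cnt <= cap:
                self._pair_cap = cap
                return out[:cnt]
            cap = int(cnt * 1.2) + 16

    # -- energy/forces ------------------------------------------------------
    def evaluate(self, coords: np.ndarray, box: np.ndarray,
                 pairs: np.ndarray | None = None,
                 want_forces: bool = True) -> tuple[EnergyBreakdown, np.ndarray]:
        coords = np.ascontiguousarray(coords, dtype=np.float64)
        box = np.asarray(box, dtype=np.float64)
        top = self.topology
        p = self.params
        f = np.zeros_like(coords)
        e_bond = _harmonic_pairs(coords, box, top.bonds, top.bond_l0, p.k_bond, f)
        e_enm = _harmonic_pairs(coords, box, top.enm_pairs, top.enm_r0, p.k_enm, f)
        e_ang, bad = _angles(coords, box, top.angles, self.angle_k, math.pi, f)
        if bad >= 0:
            raise DegenerateAngleError(
                f"zero-length bond vector in angle triple {bad}")
        if pairs is None:
            pairs = self.build_pair_list(coords, box)
        e_sr, e_el, badp = _nonbonded(
            coords, box, pairs, self.sigma, self.eps, self.xi, self.A, self.A0,
            self.is_cat, self.is_aro, self.is_nuc,
            p.eps_mod_cation_aromatic, p.eps_mod_cation_nucleic,
            p.eps_mod_aromatic_aromatic,
            p.cutoff, p.kappa, p.elec_prefactor,
            p.xi_scales_electrostatics, p.shift_cutoff, f)
        if badp >= 0:
            i, j = pairs[badp]
            raise OverlappingBeadsError(f"beads {i} and {j} overlap (r = 0)")
        return EnergyBreakdown(bond=e_bond, angle=e_ang, enm=e_enm,
                               short_range=e_sr, electrostatic=e_el), f


# ---------------------------------------------------------------------------
# functional API on SystemState
# ---------------------------------------------------------------------------

def _evaluate(state: SystemState) -> tuple[EnergyBreakdown, np.ndarray]:
    return state.model().evaluate(state.coordinates, state.box)


def bond_energy(state: SystemState) -> float:
    """Harmonic chain-connectivity energy (kJ/mol)."""
    f = np.zeros_like(state.coordinates)
    return _harmonic_pairs(state.coordinates, state.box, state.topology.bonds,
                           state.topology.bond_l0, state.params.k_bond, f)


def enm_energy(state: SystemState) -> float:
    """Elastic-network restraint energy (kJ/mol)."""
    f = np.zeros_like(state.coordinates)
    return _harmonic_pairs(state.coordinates, state.box, state.topology.enm_pairs,
                           state.topology.enm_r0, state.params.k_enm, f)


def angle_energy(state: SystemState) -> float:
    """Chain-stiffness angle energy about the straight-chain reference (kJ/mol)."""
    model = state.model()
    f = np.zeros_like(state.coordinates)
    e, bad = _angles(state.coordinates, state.box, state.topology.angles,
                     model.angle_k, math.pi, f)
    if bad >= 0:
        raise DegenerateAngleError(f"zero-length bond vector in angle triple {bad}")
    return e


def short_range_energy(state: SystemState) -> float:
    """10-5 pair potential energy with xi scaling (kJ/mol)."""
    return _evaluate(state)[0].short_range


def electrostatic_energy(state: SystemState) -> float:
    """Screened Debye-Hueckel electrostatic energy (kJ/mol)."""
    return _evaluate(state)[0].electrostatic


def total_energy(state: SystemState) -> EnergyBreakdown:
    """All energy components of a configuration."""
    return _evaluate(state)[0]


def forces(state: SystemState) -> np.ndarray:
    """Analytic forces, kJ/(mol nm), shape (N, 3)."""
    return _evaluate(state)[1]
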