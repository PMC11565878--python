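"""Solvent-accessible surface area for coarse-grained bead models.

Shrake-Rupley numerical SASA: each bead is inflated by the probe radius
and sampled with a fixed quasi-uniform point set (golden-section
spiral); points not buried inside any neighboring inflated sphere count
toward the accessible area.  Defaults: probe 0.14 nm, 960 points per
sphere.

The module also provides the amino-acid-specific fully-exposed
reference areas S_ref, computed once per residue type by embedding the
residue bead at the center of an ideal poly-alanine alpha-helix of
beads and measuring its SASA.  S_ratio = S_residue / S_ref is the
surface-exposure measure that drives the interaction-scale reduction
of buried residues.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from numba import njit

__all__ = ["shrake_rupley", "reference_surface_area", "PROBE_RADIUS", "N_SPHERE_POINTS"]

PROBE_RADIUS = 0.14  # nm, water probe
N_SPHERE_POINTS = 960

# ideal alpha-helix geometry for the reference-area construction
_HELIX_RISE = 0.15  # nm per residue
_HELIX_RADIUS = 0.23  # nm
_HELIX_TWIST = math.radians(100.0)


@lru_cache(maxsize=8)
def _unit_sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-section spiral)."""
    i = np.arange(n, dtype=np.float64)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    pts = np.column_stack((rho * np.cos(phi), rho * np.sin(phi), z))
    return np.ascontiguousarray(pts)


@njit(cache=True)
def _sasa_kernel(coords, radii, points, areas):
    n = coords.shape[0]
    npts = points.shape[0]
    for i in range(n):
        ri = radii[i]
        exposed = 0
        for k in range(npts):
            px = coords[i, 0] + ri * points[k, 0]
            py = coords[i, 1] + ri * points[k, 1]
            pz = coords[i, 2] + ri * points[k, 2]
            buried = False
            for j in range(n):
                if j == i:
                    continue
                dx = px - coords[j, 0]
                dy = py - coords[j, 1]
                dz = pz - coords[j, 2]
                if dx * dx + dy * dy + dz * dz < radii[j] * radii[j]:
                    buried = True
                    break
            if not buried:
                exposed += 1
        areas[i] = 4.0 * math.pi * ri * ri * exposed / npts


def shrake_rupley(coords: np.ndarray, radii: np.ndarray,
                  probe_radius: float = PROBE_RADIUS,
                  n_points: int = N_SPHERE_POINTS) -> np.ndarray:
    """Per-sphere solvent-accessible surface area (nm^2).

    Parameters
    ----------
    coords : (N, 3) array, nm
    radii : (N,) intrinsic sphere radii, nm (probe added internally)
    """
    coords = np.ascontiguousarray(coords, dtype=np.float64)
    radii = np.asarray(radii, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (N, 3)")
    if radii.shape != (coords.shape[0],):
        raise ValueError("radii must match coords")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    # duplicate positions make burial ill-defined
    if coords.shape[0] > 1:
        from scipy.spatial.distance import pdist
        if pdist(coords).min() < 1e-9:
            raise ValueError("degenerate structure: coincident beads")
    expanded = np.ascontiguousarray(radii + probe_radius)
    areas = np.empty(coords.shape[0])
    _sasa_kernel(coords, expanded, _unit_sphere_points(n_points), areas)
    return areas


def _ideal_helix(n: int) -> np.ndarray:
    i = np.arange(n, dtype=np.float64)
    ang = i * _HELIX_TWIST
    return np.column_stack((_HELIX_RADIUS * np.cos(ang),
                            _HELIX_RADIUS * np.sin(ang),
                            i * _HELIX_RISE))


_SREF_CACHE: dict[str, float] = {}


def reference_surface_area(resname: str) -> float:
    """Fully-exposed reference area S_ref (nm^2) of a residue type.

    Computed once by placing the residue bead at the center of an
    11-residue ideal poly-Ala helix of beads and measuring its SASA;
    cached for the process lifetime.  Nucleotide beads have no helix
    context and use the free-sphere area.
    """
    from .forcefield import residue_table, resolve_residue

    resname = resolve_residue(resname)
    if resname in _SREF_CACHE:
        return _SREF_CACHE[resname]
    table = residue_table()
    rec = table[resname]
    if rec["class"] == "nucleotide":
        r = rec["sigma"] / 2.0 + PROBE_RADIUS
        area = 4.0 * math.pi * r * r
    else:
        n = 11
        coords = _ideal_helix(n)
        radii = np.full(n, table["ALA"]["sigma"] / 2.0)
        center = n // 2
        radii[center] = rec["sigma"] / 2.0
        area = float(shrake_rupley(coords, radii)[center])
    _SREF_CACHE[resname] = area
    return area
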