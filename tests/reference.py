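"""Independent brute-force oracles used to validate the implementation.

Everything here is written directly from the model definitions with
plain numpy (no cell lists, no numba, no shared code with the package
internals beyond parameter values), so agreement is a genuine
cross-check.
"""

import math

import numpy as np

from cocomo2.forcefield import AROMATIC, CATIONIC, residue_table


def min_image(d, box):
    return d - box * np.round(d / box)


def brute_energies(coords, box, topology, params):
    """All five energy terms by direct summation (O(N^2) nonbonded)."""
    table = residue_table()
    names = topology.resnames
    n = len(names)
    sigma = np.array([table[r]["sigma"] for r in names])
    eps = np.array([params.eps_for_class(table[r]["class"]) for r in names])
    A0 = np.array([params.A0_for_class(table[r]["class"]) for r in names])
    q = np.array([table[r]["charge"] for r in names])
    A = np.where(q == 0, 0.0,
                 np.sign(q) * params.charge_amplitude *
                 np.abs(q) ** params.charge_exponent)
    cat = np.array([r in CATIONIC for r in names])
    aro = np.array([r in AROMATIC for r in names])
    nuc = np.array([table[r]["class"] == "nucleotide" for r in names])
    xi = topology.xi

    e_bond = 0.0
    for (i, j), l0 in zip(topology.bonds, topology.bond_l0):
        r = np.linalg.norm(min_image(coords[i] - coords[j], box))
        e_bond += 0.5 * params.k_bond * (r - l0) ** 2
    e_enm = 0.0
    for (i, j), r0 in zip(topology.enm_pairs, topology.enm_r0):
        r = np.linalg.norm(min_image(coords[i] - coords[j], box))
        e_enm += 0.5 * params.k_enm * (r - r0) ** 2
    e_ang = 0.0
    for (i, j, k), kind in zip(topology.angles, topology.angle_kind):
        u = min_image(coords[i] - coords[j], box)
        v = min_image(coords[k] - coords[j], box)
        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        theta = math.acos(max(-1.0, min(1.0, c)))
        ka = (params.k_angle_protein if kind == "protein"
              else params.k_angle_nucleic)
        e_ang += 0.5 * ka * (theta - math.pi) ** 2

    excluded = {tuple(sorted(b)) for b in topology.bonds.tolist()}
    e_sr = 0.0
    e_el = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excluded:
                continue
            r = np.linalg.norm(min_image(coords[i] - coords[j], box))
            if r >= params.cutoff:
                continue
            if (cat[i] and aro[j]) or (cat[j] and aro[i]):
                emod = params.eps_mod_cation_aromatic
            elif (cat[i] and nuc[j]) or (cat[j] and nuc[i]):
                emod = params.eps_mod_cation_nucleic
            elif aro[i] and aro[j]:
                emod = params.eps_mod_aromatic_aromatic
            else:
                emod = 0.0
            sij = 0.5 * (sigma[i] + sigma[j])
            eij = math.sqrt(eps[i] * eps[j])
            e_sr += (xi[i] * xi[j] * 4.0 * (eij + emod)
                     * ((sij / r) ** 10 - (sij / r) ** 5))
            scale = xi[i] * xi[j] if params.xi_scales_electrostatics else 1.0
            e_el += (scale * params.elec_prefactor
                     * (A[i] * A[j] + A0[i] * A0[j]) * math.exp(-r / params.kappa) / r)
    return {"bond": e_bond, "angle": e_ang, "enm": e_enm,
            "short_range": e_sr, "electrostatic": e_el}


def union_find_clusters(coords, box, topology, cutoff):
    """Chain clusters via union-find over the full contact matrix."""
    parent = list(range(topology.n_chains))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    chain = topology.chain_index
    n = len(chain)
    for i in range(n):
        for j in range(i + 1, n):
            if chain[i] == chain[j]:
                continue
            r = np.linalg.norm(min_image(coords[i] - coords[j], box))
            if r < cutoff:
                union(int(chain[i]), int(chain[j]))
    roots = [find(c) for c in range(topology.n_chains)]
    relabel = {r: k for k, r in enumerate(dict.fromkeys(roots))}
    return np.array([relabel[r] for r in roots])


def brute_rg(coords, masses):
    com = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    return math.sqrt(float((masses * ((coords - com) ** 2).sum(axis=1)).sum()
                           / masses.sum()))


def brute_enm_pairs(coords, folded_ranges_0based, cutoff):
    """All restraint pairs by scanning every residue pair of each range."""
    out = set()
    for lo, hi in folded_ranges_0based:
        for i in range(lo, hi + 1):
            for j in range(lo, hi + 1):
                if j - i >= 2 and np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                    out.add((i, j))
    return out


def sphere_cap_exposed_area(r1, r2, d):
    """Analytic accessible area of sphere 1 partially covered by sphere 2.

    Spheres of radii r1, r2 at center distance d; returns the area of
    sphere 1 outside sphere 2 (spherical-cap geometry).
    """
    if d >= r1 + r2:
        return 4.0 * math.pi * r1 * r1
    if d + r1 <= r2:
        return 0.0
    # polar angle of the intersection circle on sphere 1
    cos_t = (d * d + r1 * r1 - r2 * r2) / (2.0 * d * r1)
    cap = 2.0 * math.pi * r1 * r1 * (1.0 - cos_t)
    return 4.0 * math.pi * r1 * r1 - cap


def brute_nonbonded_matrix(coords, box, topology, params):
    """Vectorized O(N^2) nonbonded oracle (full distance matrix, no
    neighbor acceleration); independent of the kernel pair-list path."""
    table = residue_table()
    names = topology.resnames
    n = len(names)
    sigma = np.array([table[r]["sigma"] for r in names])
    eps = np.array([params.eps_for_class(table[r]["class"]) for r in names])
    A0 = np.array([params.A0_for_class(table[r]["class"]) for r in names])
    q = np.array([table[r]["charge"] for r in names])
    A = np.where(q == 0, 0.0,
                 np.sign(q) * params.charge_amplitude *
                 np.abs(q) ** params.charge_exponent)
    cat = np.array([r in CATIONIC for r in names])
    aro = np.array([r in AROMATIC for r in names])
    nuc = np.array([table[r]["class"] == "nucleotide" for r in names])
    xi = topology.xi

    d = coords[:, None, :] - coords[None, :, :]
    d -= box * np.round(d / box)
    r = np.sqrt((d ** 2).sum(axis=-1))
    include = np.triu(np.ones((n, n), dtype=bool), 1) & (r < params.cutoff)
    for i, j in topology.bonds:
        include[min(i, j), max(i, j)] = False
    r = np.where(include, r, 1.0)  # avoid div-by-zero outside the mask

    emod = np.zeros((n, n))
    emod[np.outer(cat, aro) | np.outer(aro, cat)] = params.eps_mod_cation_aromatic
    emod[np.outer(cat, nuc) | np.outer(nuc, cat)] = params.eps_mod_cation_nucleic
    emod[np.outer(aro, aro)] = params.eps_mod_aromatic_aromatic

    sij = 0.5 * (sigma[:, None] + sigma[None, :])
    eij = np.sqrt(np.outer(eps, eps))
    xij = np.outer(xi, xi)
    s5 = (sij / r) ** 5
    u_sr = 4.0 * xij * (eij + emod) * (s5 * s5 - s5)
    aij = np.outer(A, A) + np.outer(A0, A0)
    scale = xij if params.xi_scales_electrostatics else 1.0
    u_el = scale * params.elec_prefactor * aij * np.exp(-r / params.kappa) / r
    return float(u_sr[include].sum()), float(u_el[include].sum())
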