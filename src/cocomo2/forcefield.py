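"""Bead-level force-field parameters and pairwise combination rules.

The model represents each amino-acid or RNA residue as a single spherical
bead.  Residues are grouped into three interaction classes (polar,
hydrophobic, nucleotide); the class-level well depths and
solvation-repulsion terms, together with the surface-exposure scaling
threshold ``lambda_surface``, are the tunable parameters of the model.
Two presets are shipped: ``COCOMO`` (the original disordered-protein
parameterization, no surface scaling) and ``COCOMO2`` (re-optimized
against phase-separation and solubility data, with surface scaling).
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

__all__ = [
    "BeadType",
    "ParameterSet",
    "PairParams",
    "load_parameter_set",
    "combine_pair",
    "bead_type",
    "residue_table",
    "CATIONIC",
    "AROMATIC",
    "PRESETS",
]

#: residues carrying the cation-pi / cation-nucleotide enhanced attraction
CATIONIC = frozenset({"ARG", "LYS"})
#: aromatic residues (pi-stacking enhancement, new in the COCOMO2 preset)
AROMATIC = frozenset({"PHE", "TYR", "TRP"})

_PROTEIN_LETTERS = {}
_RNA_LETTERS = {}


def _load_residue_table() -> dict:
    path = importlib.resources.files("cocomo2") / "data" / "residues.yaml"
    with importlib.resources.as_file(path) as p:
        raw = yaml.safe_load(Path(p).read_text())
    table = {}
    for name, rec in raw["residues"].items():
        # sigma_i = 2 r_i 2^(-1/6), r_i the radius of the equal-volume sphere
        r_nm = (3.0 * rec["volume"] / (4.0 * math.pi)) ** (1.0 / 3.0) * 0.1
        sigma = 2.0 * r_nm * 2.0 ** (-1.0 / 6.0)
        table[name] = {
            "letter": rec["letter"],
            "sigma": sigma,
            "mass": float(rec["mass"]),
            "charge": float(rec["charge"]),
            "class": rec["class"],
        }
        if rec["class"] == "nucleotide":
            _RNA_LETTERS[rec["letter"]] = name
        else:
            _PROTEIN_LETTERS[rec["letter"]] = name
    return table


_RESIDUES = _load_residue_table()


def residue_table() -> dict:
    """Return the shipped per-residue property table (keyed by 3-letter code)."""
    return _RESIDUES


def resolve_residue(code: str, kind: str = "protein") -> str:
    """Map a 1- or 3-letter residue code to the canonical 3-letter key."""
    code = code.upper()
    if len(code) == 3 and code in _RESIDUES:
        return code
    if len(code) == 1:
        lookup = _RNA_LETTERS if kind == "rna" else _PROTEIN_LETTERS
        if code in lookup:
            return lookup[code]
    raise KeyError(f"unknown {kind} residue code: {code!r}")


@dataclass(frozen=True)
class ParameterSet:
    """Global force-field parameters.

    The class-level nonbonded parameters (``eps_*``, ``A0_*``,
    ``lambda_surface``) are the quantities adjusted during
    parameterization; everything else is part of the fixed functional
    form (bonded force constants, screening length, cutoff) or a
    documented numerical convention.
    """

    name: str = "custom"
    # class well depths, kJ/mol
    eps_polar: float = 0.176
    eps_hydrophobic: float = 0.295
    eps_nucleotide: float = 0.176
    # solvation repulsion amplitudes (dimensionless, enter as A0_i * A0_j)
    A0_polar: float = 0.0
    A0_hydrophobic: float = 0.002
    A0_nucleotide: float = 0.0
    # surface-exposure scaling threshold; None disables scaling entirely
    lambda_surface: float | None = 0.7
    # pair-class specific short-range enhancements, kJ/mol
    eps_mod_cation_aromatic: float = 0.3
    eps_mod_cation_nucleic: float = 0.2
    eps_mod_aromatic_aromatic: float = 0.1
    # electrostatics
    kappa: float = 1.0  # Debye screening length, nm (~100 mM)
    elec_prefactor: float = 138.935458 / 80.0  # kJ nm/mol, Coulomb const / eps_r
    charge_exponent: float = 0.5  # A_i = sign(q) 0.75 |q|^charge_exponent
    charge_amplitude: float = 0.75
    xi_scales_electrostatics: bool = False
    # bonded terms
    k_bond: float = 4184.0  # kJ/(mol nm^2)
    k_enm: float = 500.0  # kJ/(mol nm^2)
    k_angle_protein: float = 4.184  # kJ/(mol rad^2)
    k_angle_nucleic: float = 4.184
    bond_length_protein: float = 0.38  # nm, mean Ca-Ca distance
    bond_length_rna: float = 0.5  # nm, mean ssRNA backbone spacing
    enm_cutoff: float = 0.9  # nm
    # nonbonded truncation
    cutoff: float = 3.0  # nm, plain truncation
    shift_cutoff: bool = False

    def __post_init__(self):
        for f in ("eps_polar", "eps_hydrophobic", "eps_nucleotide",
                  "eps_mod_cation_aromatic", "eps_mod_cation_nucleic",
                  "eps_mod_aromatic_aromatic"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        for f in ("A0_polar", "A0_hydrophobic", "A0_nucleotide"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.kappa <= 0 or self.cutoff <= 0:
            raise ValueError("kappa and cutoff must be positive")
        if self.lambda_surface is not None and not (0.0 <= self.lambda_surface <= 1.0):
            raise ValueError("lambda_surface must lie in [0, 1]")

    def eps_for_class(self, hydro_class: str) -> float:
        return {"polar": self.eps_polar,
                "hydrophobic": self.eps_hydrophobic,
                "nucleotide": self.eps_nucleotide}[hydro_class]

    def A0_for_class(self, hydro_class: str) -> float:
        return {"polar": self.A0_polar,
                "hydrophobic": self.A0_hydrophobic,
                "nucleotide": self.A0_nucleotide}[hydro_class]

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: Shipped presets.  COCOMO is the original disordered-protein/RNA model
#: (no surface scaling, no aromatic-aromatic enhancement); COCOMO2 is the
#: re-optimized model for mixed disordered/folded systems.
PRESETS: dict[str, ParameterSet] = {
    "COCOMO": ParameterSet(
        name="COCOMO",
        eps_polar=0.40,
        eps_hydrophobic=0.41,
        eps_nucleotide=0.40,
        A0_polar=0.05,
        A0_hydrophobic=0.0,
        A0_nucleotide=0.05,
        lambda_surface=None,
        eps_mod_aromatic_aromatic=0.0,
    ),
    "COCOMO2": ParameterSet(
        name="COCOMO2",
        eps_polar=0.176,
        eps_hydrophobic=0.295,
        eps_nucleotide=0.176,
        A0_polar=0.0,
        A0_hydrophobic=0.002,
        A0_nucleotide=0.0,
        lambda_surface=0.7,
        eps_mod_aromatic_aromatic=0.1,
    ),
}


def load_parameter_set(preset: str | None = None,
                       file: str | Path | None = None,
                       **overrides) -> ParameterSet:
    """Load a shipped preset and/or a flat key-value YAML override file.

    A file may contain a ``preset:`` key naming the base parameter set;
    all other keys override individual fields.  Keyword overrides are
    applied last.
    """
    base = None
    file_overrides: dict = {}
    if file is not None:
        raw = yaml.safe_load(Path(file).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"malformed parameter file: {file}")
        file_overrides = dict(raw)
        preset = file_overrides.pop("preset", preset)
    if preset is not None:
        if preset not in PRESETS:
            raise KeyError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
        base = PRESETS[preset]
    if base is None:
        base = ParameterSet()
    merged = {**file_overrides, **overrides}
    valid = {f.name for f in fields(ParameterSet)}
    unknown = set(merged) - valid
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    if merged:
        base = replace(base, **merged)
    return base


@dataclass(frozen=True)
class BeadType:
    """Physical parameters of one residue bead under a given ParameterSet."""

    name: str
    sigma: float  # nm
    well_depth: float  # kJ/mol
    charge: float  # e
    electro_attraction: float  # signed, dimensionless
    electro_repulsion: float  # >= 0, dimensionless
    hydro_class: str
    ref_surface: float  # nm^2, fully-exposed reference area
    mass: float  # amu

    def __post_init__(self):
        if self.sigma <= 0 or self.well_depth < 0 or self.electro_repulsion < 0:
            raise ValueError("invalid bead parameters")
        if self.ref_surface <= 0:
            raise ValueError("ref_surface must be positive")
        if self.charge == 0 and self.electro_attraction != 0:
            raise ValueError("A_i must vanish for neutral beads")
        if self.charge != 0 and math.copysign(1, self.electro_attraction) != math.copysign(1, self.charge):
            raise ValueError("sign(A_i) must equal sign(q_i)")


def electro_attraction(charge: float, params: ParameterSet) -> float:
    """A_i = sign(q) * 0.75 * |q|^p with p = params.charge_exponent."""
    if charge == 0:
        return 0.0
    return math.copysign(params.charge_amplitude * abs(charge) ** params.charge_exponent,
                         charge)


def bead_type(resname: str, params: ParameterSet) -> BeadType:
    """Construct the BeadType of a residue under a parameter set."""
    resname = resolve_residue(resname)
    rec = _RESIDUES[resname]
    from .sasa import reference_surface_area  # lazy: sasa imports residue radii

    return BeadType(
        name=resname,
        sigma=rec["sigma"],
        well_depth=params.eps_for_class(rec["class"]),
        charge=rec["charge"],
        electro_attraction=electro_attraction(rec["charge"], params),
        electro_repulsion=params.A0_for_class(rec["class"]),
        hydro_class=rec["class"],
        ref_surface=reference_surface_area(resname),
        mass=rec["mass"],
    )


@dataclass(frozen=True)
class PairParams:
    """Combined nonbonded parameters for one bead pair."""

    sigma_ij: float
    eps_ij: float
    eps_mod_ij: float
    xi_ij: float
    A_ij: float
    A0_ij: float


def eps_mod(resname_i: str, resname_j: str, params: ParameterSet) -> float:
    """Short-range enhancement for the three disjoint special pair classes.

    cation-aromatic (Arg/Lys with Phe/Tyr/Trp), cation-nucleotide, and
    aromatic-aromatic; every other pair gets 0.
    """
    ci, cj = resname_i in CATIONIC, resname_j in CATIONIC
    ai, aj = resname_i in AROMATIC, resname_j in AROMATIC
    ni = _RESIDUES[resname_i]["class"] == "nucleotide"
    nj = _RESIDUES[resname_j]["class"] == "nucleotide"
    if (ci and aj) or (cj and ai):
        return params.eps_mod_cation_aromatic
    if (ci and nj) or (cj and ni):
        return params.eps_mod_cation_nucleic
    if ai and aj:
        return params.eps_mod_aromatic_aromatic
    return 0.0


def combine_pair(bead_i: BeadType, bead_j: BeadType,
                 xi_i: float = 1.0, xi_j: float = 1.0,
                 params: ParameterSet | None = None) -> PairParams:
    """Apply the combination rules to a bead pair.

    sigma: arithmetic mean; well depth: geometric mean; the interaction
    scale, electrostatic attraction and solvation repulsion all combine
    multiplicatively.
    """
    if params is None:
        params = PRESETS["COCOMO2"]
    return PairParams(
        sigma_ij=0.5 * (bead_i.sigma + bead_j.sigma),
        eps_ij=math.sqrt(bead_i.well_depth * bead_j.well_depth),
        eps_mod_ij=eps_mod(bead_i.name, bead_j.name, params),
        xi_ij=xi_i * xi_j,
        A_ij=bead_i.electro_attraction * bead_j.electro_attraction,
        A0_ij=bead_i.electro_repulsion * bead_j.electro_repulsion,
    )
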