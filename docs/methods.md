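# Methods

## Model

Each amino-acid or RNA residue is one spherical bead. The potential
energy of a configuration is

U_total = U_bond + U_angle + U_short-range + U_electrostatic,

with the elastic-network restraints of folded domains folded into the
bonded part.

**Bonds.** Harmonic, ½·k_bond·(l − l₀)² with k_bond = 4184 kJ/(mol nm²);
l₀ = 0.38 nm for proteins (mean Cα–Cα distance) and 0.5 nm for
single-stranded RNA. **Angles.** Harmonic about a straight-chain
reference, ½·k_angle·(θ − 180°)², k_angle = 4.184 kJ/(mol rad²) for both
proteins and nucleic acids (two separate config keys are exposed in case
users want to stiffen one of them). **Elastic network.** Within each
declared folded domain, every residue pair separated by at least two
bonds whose reference distance r₀ ≤ 0.9 nm is restrained by
½·k_ENM·(r − r₀)², k_ENM = 500 kJ/(mol nm²). By default restraints never
bridge two declared domains of the same chain (a flag enables
cross-domain restraints); one-bond neighbors are excluded because the
bond term already covers them.

**Short range.** A 10–5 pair potential
ξᵢξⱼ·4(εᵢⱼ + ε_mod)[(σᵢⱼ/r)¹⁰ − (σᵢⱼ/r)⁵] with σᵢⱼ the arithmetic and
εᵢⱼ the geometric combination. Bead diameters derive from published
residue volumes (Zamyatnin 1972 amino-acid partial volumes; Voss &
Gerstein 2005 nucleotide volumes; shipped in
`src/cocomo2/data/residues.yaml`) via σᵢ = 2rᵢ·2^(−1/6) with rᵢ the
equal-volume sphere radius. Well depths are grouped by class (polar /
hydrophobic / nucleotide); ε_mod adds fixed enhancements for
cation–aromatic (0.3 kJ/mol), cation–nucleotide (0.2) and — in the
COCOMO2 preset only — aromatic–aromatic (0.1) pairs; the three classes
are disjoint by construction. The nucleotide class is not covered by
the published class parameters, so both presets reuse their polar-class
ε and A₀ for nucleotides; this is a package assumption, documented here
because RNA systems are secondary scope.

**Electrostatics.** A screened Debye–Hückel form
C·(AᵢAⱼ + A₀ᵢA₀ⱼ)·exp(−r/κ)/r with κ = 1 nm (≈100 mM ionic strength).
Aᵢ = sign(qᵢ)·0.75·|qᵢ|^p encodes attraction/repulsion from the residue
charge (Asp/Glu −1, Lys/Arg +1, His neutral, one negative charge per
nucleotide); p defaults to ½ and is configurable — for unit charges
every choice of p coincides. A₀ᵢ ≥ 0 is a class-level solvation
repulsion. The prefactor C is housed as the configurable
`elec_prefactor`; its default is the Coulomb constant divided by the
relative permittivity of water, 138.935/80 ≈ 1.737 kJ·nm/mol, which is
the natural unit-bearing constant for this functional form. ξ scaling
is applied to the short-range term only; the config flag
`xi_scales_electrostatics` enables the alternative reading.

**Surface-exposure scaling.** For residues inside folded domains the
interaction scale is ξ = 1 if S_ratio ≥ λ and S_ratio/λ otherwise,
where S_ratio = S_residue/S_ref. Disordered residues always have
ξ = 1, and λ = 0 or a missing λ disables scaling (the COCOMO preset).
ξ is computed once from the reference structure and never updated
during a simulation — the elastic network keeps burial essentially
constant, which is what makes this a zero-cost solvation correction.

S_residue is computed by an in-package Shrake–Rupley algorithm (probe
0.14 nm, 960 golden-spiral points per sphere) on the coarse-grained
reference beads with radii σᵢ/2. S_ref is generated procedurally at
first use: each residue bead is embedded at the center of an
11-residue ideal poly-Ala α-helix of beads (rise 0.15 nm, radius
0.23 nm, 100° twist) and its SASA is cached. Computing both S_residue
and S_ref at the bead level keeps the ratio internally consistent;
all-atom reference SASA is not currently supported.

**Nonbonded bookkeeping.** Plain truncation at 3 nm (an optional
energy-shifted truncation exists for conservation studies), minimum
image in orthorhombic boxes, and exclusion of exactly the one-bond
pairs. Production evaluation runs over a Verlet pair list built by
cell binning with a 0.3 nm skin, rebuilt when any bead has moved more
than half the skin; the contract that this is bit-identical to a
brute-force double loop is enforced by the test suite against an
independently written O(N²) oracle.

## Parameter presets

| parameter | COCOMO | COCOMO2 |
|---|---|---|
| ε_polar (kJ/mol) | 0.40 | 0.176 |
| ε_hydrophobic (kJ/mol) | 0.41 | 0.295 |
| A₀,polar | 0.05 | 0 |
| A₀,hydrophobic | 0 | 0.002 |
| λ | — (no scaling) | 0.7 |
| ε aromatic–aromatic | 0 | 0.1 kJ/mol |

## Dynamics

Langevin NVT with the BAOAB splitting; defaults follow the model's
simulation protocol: 298 K, friction 0.01 ps⁻¹, 10 fs time step for
equilibration and 20 fs for production, 5000 equilibration steps.
Preparation is steepest-descent minimization followed by
equilibration; a run aborts with the offending step index when
coordinates become non-finite or an interacting pair collapses to zero
separation. All randomness flows from a single seed, and identical
seeds give bitwise-identical trajectories.

Two numerical caveats are documented rather than hidden. First, the
kinetic temperature read from full-step velocities carries an O((ωΔt)²)
bias for stiff bonds; at the 20 fs production step this can reach a few
percent on bond-rich systems, and the temperature-control test therefore
runs at the 10 fs step where the bias is below 1%. Second, at the
protocol friction of 0.01 ps⁻¹ the velocity autocorrelation time is
100 ps, so kinetic-energy statistics converge slowly; the equipartition
and bond-variance checks use friction 0.5–1 ps⁻¹ to obtain many
independent samples — the stationary distribution is friction-
independent, so this changes sampling efficiency, not the quantity
under test.

## Phase analysis

Chains are clustered by single linkage on the contact graph: two chains
touch when any inter-chain bead pair is within 1.0 nm (minimum image).
Chains in clusters smaller than 5 count as the dilute phase; dividing
by the box volume gives the dilute concentration in μM. Both numbers
are conventions, not measurements — the underlying publications rarely
state their criterion — so both are config keys, and csat shifts by
only a few percent when the cutoff is varied between 0.8 and 1.2 nm on
the toy systems used here. The csat estimate is the time average of
the dilute concentration over the trailing 20% of a trajectory
(echoing "averaged over the last microsecond" of a 5 μs run), with a
block-average spread, and is refused (flagged, not numeric) when the
window lacks coexistence: no condensate-sized cluster, or an empty
dilute phase.

Mixed-phase starts place a chosen number of chains in a compact
droplet at the box center and scatter the rest uniformly, enforcing a
minimum inter-chain bead separation with bounded rejection sampling.
Starting from both phases at once avoids the nucleation/melting
hysteresis that biases csat from pure random or pure condensate
starts; the hysteresis itself is reproduced qualitatively by the test
suite.

Radii of gyration are mass-weighted, after unwrapping each chain
across periodic images by walking its bonds (never by heuristics).

## Parameter optimization

csat ~ exp(−U/k_BT) motivates fitting log₁₀(csat) = a·U + b per system,
with U the mean per-residue potential energy of ~10 stored condensate
conformations rescored under candidate parameters (no re-simulation;
conformations are taken as evenly strided frames from the trailing half
of a condensed-phase run). Fits use RANSAC (scikit-learn; minimal
sample 2, 1000 trials, MAD-scaled residual threshold, seeded) so
outliers — more common for multi-domain systems — do not skew the
lines; with no outliers the result equals ordinary least squares.

The optimization objective is Σ_systems (log₁₀ csat_pred −
log₁₀ csat_exp)², minimized in three stages: a grid scan over the
disordered systems only (λ has no effect there), a bounded L-BFGS-B
refinement from the scan optimum, and a joint L-BFGS-B refinement over
all systems with λ included. λ is capped at 0.7 throughout, because
condensate morphology changes above that value; a start above the cap
is clamped and the active bound reported.

## Synthetic data

The fixture generator emulates three ingredients of real studies.
Toy disordered sequences are drawn from class compositions
(charged/aromatic/polar/hydrophobic pools); the default composition
(20/10/40/30%) mimics sticky low-complexity sequences. Folded
"domains" are ideal-helix bundles — seven parallel helices packed
hexagonally at 0.75 nm axis spacing, smaller chains build fewer — with
construction-guaranteed burial labels: interior residues of the
central helix are enclosed (S_ratio ≲ 0.1), outward-facing ring
residues are exposed (S_ratio ≳ 0.6). These bundles exercise the
elastic network and surface scaling with known answers but are not
real protein folds: they have idealized geometry, no side-chain
packing, and a sharper burial spectrum than crystal structures, so
passing tests demonstrate the machinery, not structural realism.

The optimizer fixture is a self-consistent inverse problem: snapshots
are generated by short condensed-phase simulations under known "true"
parameters, each system gets a random linear energy→log-csat relation,
calibration points are produced by rescoring under scaled parameter
variants, and the synthetic experimental csat is the relation evaluated
at the true parameters (plus optional lognormal noise in decades). The
true solvation-repulsion amplitudes are set at 0.2–0.3 rather than the
preset-scale 0.002–0.05: amplitudes that small leave essentially no
signature in condensate energies, making any energy-based recovery
ill-conditioned by construction; the larger values keep the inverse
problem honest while testing the same machinery. With zero noise the
three-stage optimizer recovers all five generating parameters to well
under 1%.

## Problem sizes

The shipped tests and the acceptance script run desk-scale versions of
the study conditions: chains of 10–42 residues, 24–30 chains per box
(≈500–1000 beads), boxes of 25 nm, and runs of 3,000–10,000 steps for
phase experiments (up to 10 ns-equivalent for thermostat statistics
on 1–100 beads). Published production systems (hundreds of chains of
100+ residues, microseconds) need GPU-scale resources; the desk-scale
systems are chosen so that every qualitative property — hysteresis,
λ-dependence of csat, proxy validity — is resolved with clear margins
under fixed seeds.

## Known limitations

- No all-atom SASA path; S_ratio is bead-level throughout.
- Nucleotide ε/A₀ reuse polar-class values (see above).
- Kinetic-temperature bias at the 20 fs step, documented above.
- The built-in integrator is CPU-bound; production-scale multi-chain
  runs at published sizes are out of reach without an external engine.
- csat from short runs is a kinetically biased estimate; the package
  reports coexistence flags and spreads so users can judge convergence.
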