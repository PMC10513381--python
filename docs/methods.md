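# Methods

This note documents the models, numerical conventions and design choices
behind `cgphase`, and what its tests do and do not demonstrate.

## Unit system

Everything internal is nm, ps, amu, kJ/mol, elementary charge and kelvin.
Parameter files quoted in kcal/mol are converted once, on load, with the
exact factor 4.184. Densities are reported as mass densities in mg/mL
(1 amu/nm³ = 1.66053906660 mg/mL, to 3 significant figures in tables).

## Interaction models

### Electrostatics

All charged beads interact through the Debye–Hückel potential
U(r) = k_e q_i q_j/(ε_r) · e^{−r/λ_D}/r with k_e = e²N_A/(4πε₀) =
138.935458 kJ·nm/mol. The screening length is the closed form for a 1:1
electrolyte; at 100 mM, 300 K, ε_r = 80 it evaluates to 0.974 nm.
Defaults: ε_r = 80, 100 mM salt, 3.5 nm cutoff — all configurable and
recorded in provenance logs. In the salt → 0 limit the term converges to
the (truncated) Coulomb potential, which is test-locked.

### HPS (hydropathy scale)

Ashbaugh–Hatch form built on a 12-6 Lennard-Jones U_LJ with ε = 0.8368
kJ/mol (0.2 kcal/mol) and arithmetic-mean σ:

* r ≤ 2^{1/6}σ: U = U_LJ + (1 − λ̄)ε
* r > 2^{1/6}σ: U = λ̄ U_LJ

with λ̄ = μ(λ_i + λ_j)/2 − Δ. Two normalized hydropathy scales are
shipped (Kapcha–Rossky and Urry); the shifted-Urry optimum μ = 1,
Δ = 0.08 is the default. Backbone bonds are harmonic, k = 8368
kJ/mol/nm², r₀ = 0.38 nm.

### Mpipi-style (Wang–Frenkel)

U(r) = ε α [(σ/r)^{2μ} − 1][(R/r)^{2μ} − 1]^{2ν} with ν = 1, μ = 2,
R = 3σ and α chosen so the well depth is exactly −ε; the potential
vanishes identically at r = R, which therefore doubles as its cutoff.
Per-pair (ε, σ) tables cover the 20 amino acids and 4 RNA nucleotides.
RNA beads carry charge −0.75 e (the reduced-phosphate convention of
residue-level protein/RNA models); DNA beads carry −1 e.

### MOFF-style contact model

U(r) = 4ε_rep(σ/r)^{12} − (ε_ij/2)[1 + tanh(η(r₀ − r))] with
ε_rep = 0.8368 kJ/mol, η = 10 nm⁻¹ and r₀ = σ_ij + 0.25 nm. ε_ij > 0 is
attractive. η and the r₀ offset are package conventions (the original
model's printed shape parameters were not available); they give a
smooth, short-ranged contact well with a width comparable to a residue
diameter.

### MRG-CG-style DNA

One bead per nucleotide. Bonds, angles and inter-strand fan bonds are
quartic polynomials U(x) = Σ_{n=2..4} K_n (x − x₀)ⁿ (angles tabulated per
degree). Fan bonds connect nucleotide i to the beads at offsets
Δ ∈ {−2..2} from its Watson–Crick partner, giving duplex cohesion and
stacking stiffness. The `rescaled` flag multiplies every bonded stiffness
by `bonded_rescale` (default 0.9) — the implicit-ion correction knob —
and touches nothing else, which is contract-tested. Nonbonded DNA–DNA
and protein–DNA interactions are r⁻¹² excluded volume plus
electrostatics.

### Synthetic parameter tables

The residue registry (masses, diameters, charges) and both hydropathy
scales are standard published constants. Three parameter sets could not
be transcribed from their sources and are shipped as deterministic
synthetic stand-ins, generated by `scripts/make_synthetic_tables.py` and
named `*_synthetic.csv`:

* the MOFF 20×20 contact matrix (built from hydropathy products and
  charge products, clipped to ±1.5 kJ/mol);
* the Mpipi 24×24 ε/σ tables (hydropathy products with aromatic–aromatic,
  cation–aromatic and nucleotide boosts mimicking the π-interaction
  hierarchy; σ from arithmetic mixing);
* the MRG-CG polynomial coefficients (equilibrium geometry measured from
  the ideal B-form helix builder — rise 0.34 nm/bp, twist 36°, radius
  0.9 nm, strand phase 154° — with stiffnesses giving a duplex
  persistence length of order tens of nm at 100 mM salt).

Consequences: all *structural* contracts (symmetry, coverage, units,
exclusions, energy conservation, force correctness) are fully meaningful;
*absolute* energies and phase boundaries computed with those three
families are illustrative, and published-value comparisons (e.g. specific
critical temperatures or the 200-bp DNA persistence length) are out of
reach until real tables are substituted — the file format makes that a
drop-in replacement. The histidine charge differs between the HPS
(+0.5 e) and MOFF (+0.25 e) families as a documented convention; only
the existence of the difference, not the two values, is fixed by the
sources available.

## Energetics

Two evaluation paths share one set of kernels: a brute-force O(N²)
minimum-image path (the oracle) and a Verlet neighbor list built on a
periodic k-d tree (skin 0.3 nm, rebuilt when any displacement exceeds
skin/2). Both paths agree to 1e-10 relative on every fixture, which is
the core validation currency of the artifact.

Numerical conventions:

* Energy-shifted truncation: each nonbonded form is shifted by its value
  at the cutoff (pair cutoff 2.0 nm, DH cutoff 3.5 nm), so the energy is
  continuous and exactly zero beyond the cutoff. Wang–Frenkel needs no
  shift. Forces are the exact analytic negative gradient of the
  *shifted* energy and are verified against central finite differences
  at 1e-6 relative, term by term.
* Orthorhombic boxes, minimum-image convention; bonded terms also use
  minimum image, so molecules may wrap.
* Divergence guard: any interacting pair below 1e-4 nm raises
  immediately rather than returning NaN.
* Nonbonded exclusions are the bond-graph 1-2 and 1-3 pairs; fan-bonded
  pairs are deliberately *not* excluded (configurable at the topology
  level by adding bonds).

## Dynamics

* **Langevin middle (BAOAB)**: half kick, half drift, exact
  Ornstein–Uhlenbeck friction step, half drift, half kick. At γ = 0 the
  scheme reduces exactly to velocity Verlet, which is how the NVE
  conservation contract (drift < 1e-4 relative over 10⁴ steps at 1 fs)
  is exercised. The kinetic-temperature estimator carries an O((ωΔt)²)
  discretization bias, so the equipartition test uses Δt = 2 fs on the
  harmonic dimer where the bias is far below the statistical error.
* **Nosé–Hoover**: single-chain thermostat, symmetric quarter-step
  updates around velocity Verlet. The protocol's "collision frequency"
  ν maps to the relaxation time τ = 1/ν through the chain mass
  Q = 3N k_B T τ².
* **MC barostat**: isotropic log-volume proposals every `move_interval`
  steps; molecule centers of mass are scaled, internal geometry kept
  rigid; acceptance on ΔU + PΔV − N k_B T ln(V'/V) with N the molecule
  count. With symmetric ln V proposals this samples V ~ Γ(N, βP) for an
  ideal gas, mean N k_B T/P, which the barostat test verifies against
  that closed form.
* **REMD**: neighbor exchanges alternate even (0-1, 2-3, …) and odd
  (1-2, …) pairs; acceptance min(1, exp[(β_i − β_j)(E_i − E_j)]) on
  potential energies; velocities rescale by √(T_new/T_old) on accepted
  swaps (rescale, not redraw). The two-temperature acceptance is
  validated within 2% against dense quadrature over the two Boltzmann
  energy densities of an isotropic harmonic well (Γ(3/2, k_B T)).
* **Minimization**: steepest descent with backtracking — energy is
  monotone non-increasing by construction; terminates at max |F| below
  tolerance.
* Seeds: every stochastic component takes an explicit integer seed; a
  master seed fans out by fixed offsets (CLI and acceptance script), and
  repeated runs are bit-identical.

## Analysis

* Molecules are made whole by bond-walking before any COM or Rg
  computation; cluster centering along z uses a circular (periodic-aware)
  mass-weighted mean so a slab crossing the boundary centers correctly
  and the operation is idempotent.
* Clustering: one molecule copy = one node (a pre-assembled dimer is one
  monomer); edge when COM minimum-image distance < cutoff (default 5
  nm); largest connected component, ties toward the lowest molecule
  index. Implementation uses a periodic k-d tree + graph components and
  is tested against exhaustive union-find.
* Density profiles: default bin width 1 nm (adjusted to divide the box
  exactly); mass conservation Σ ρ·V_bin = M_total holds to rounding.
* Coexistence windows: dense |z| < 5 nm (HPS protocol) or < 10 nm
  (MOFF protocol), dilute |z| > 50 nm; production averages use the
  second half of a trajectory by convention.
* Critical fit: nonlinear least squares in (A, T_c) with β = 0.325
  frozen, T_c bounded above max fitted T, initialized at max T + 20 K;
  only phase-separated points (ρ_H > ρ_L) enter. Noiseless data is
  recovered to 1e-8.
* Persistence length: C(n) averaged over bonds and frames; weighted
  linear fit of log C(n) over n ∈ [2, 20] (weights C(n)·√counts, the
  delta-method variance of log C), l_p = −b/slope; a rigid chain reports
  l_p = ∞; non-positive C(n) inside the range shrinks it with a warning.

## Fixtures and what the tests show

The synthetic fixtures (harmonic dimer, 30-residue toy IDP, 20-bp
dsDNA, constructed step-density slabs, LJ cluster, ideal gas) exercise
every code path deterministically at desk scale. They validate the
*mechanics* — energies, gradients, ensembles, estimators, bookkeeping —
against independent oracles. They do not emulate the slow collective
relaxation, finite-size effects, or interfacial fluctuations of real
condensate simulations, so passing tests certify the engine and the
analysis chain, not the thermodynamics of any particular protein. The
production-scale protocol (compress 100 copies at 1 bar/150 K from a 75
nm box, elongate to a slab, anneal, 2×10⁸-step production, six-replica
REMD at 300–400 K with exchanges every 1000 steps) is expressible in the
config schema and runs unmodified, but needs cluster-scale time.

Problem sizes used by `scripts/acceptance.py`: 120 random configurations
(6 force-field families × 20) for the energy oracle; four 30-bead
fixtures for force gradients; 10⁶ thermostat steps; 10⁴ NVE steps; 3000
exchange attempts; 7 noiseless coexistence points; a 728-bead constructed
slab; 10⁵ freely-rotating-chain configurations.

## Known limitations

* The three synthetic parameter sets above; drop-in replaceable.
* No Ewald/PME — Debye–Hückel only, as appropriate for implicit-ion
  condensate models.
* Orthorhombic boxes; isotropic barostat (cubic only).
* The engine is a reference implementation in vectorized NumPy: correct
  and deterministic, but orders of magnitude slower than GPU MD engines;
  production condensate studies should treat it as a validation tool.
* MOFF-style bonded structure is reduced to harmonic backbone bonds;
  structure-based angle/dihedral statistics are not included.
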