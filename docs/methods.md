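# Methods

This note records the models, numerical choices and their rationale, and
what the bundled fixtures do and do not demonstrate.

## Units

Internal units are amu, Å, fs throughout; the derived energy unit
amu·Å²·fs⁻² equals 9999.999997 kJ/mol (from the SI definitions of the
constants involved), so all reported kJ/mol values are conversions by
that factor.  Boltzmann's constant is 8.31446×10⁻⁷ amu·Å²·fs⁻²·K⁻¹.
Boundary stiffness k therefore carries units of fs⁻² — the harmonic
force constant of the wall is m_i·k.

## Boundary potential

U_i = ½ m_i k(t) (d_i − R(t))² outside the sphere, zero inside.  The ½
prefactor is a convention choice: it makes m_i·k exactly the Hooke
constant of the restoring force.  The (R, k) program is a rectangular
wave with no smoothing ramp; switch instants belong to the interval they
begin, and the cycle starts expanded because runs begin from an
energy-minimized packed configuration.  The center is fixed (default
origin).  The per-mass scaling makes boundary acceleration independent
of mass, which is the property the tests pin down.

## Dynamics

Langevin integration uses the BAOAB splitting: it has the best
configurational accuracy of the standard one-stage splittings at large
time steps, which matters at the 0.5 fs default, and collapses to
velocity-Verlet as the friction vanishes — the NVE mode is literally the
same code path with the O-step removed.  Friction is γ = 1/τ per degree
of freedom (τ = 300 fs default).  Initial velocities: whatever the
caller supplies; if none are supplied and the thermostat is on, a seeded
Maxwell–Boltzmann draw at the target temperature.  All noise comes from
one `numpy` generator seeded from the run seed, so trajectories are
bit-reproducible per platform.  Runs are budgeted by step count, not
wall time.

## Bond perception and events

Bonds use the covalent-radius criterion with form factor 1.3; the
optional break factor (> form) adds hysteresis so a vibrating bond near
threshold does not flicker.  "Settled" states are defined purely by
graph equality; an event is emitted when a *new* graph persists
unchanged for ≥ 25 snapshots (the persistence window), with onset at the
first frame that departed the previous settled graph.  Event scope is
the closure of the changed edges' endpoints under both graphs' component
partitions, so reactant and product fragments always partition the same
atoms.  Degenerate identity exchanges (graph changed, fragment-signature
multiset unchanged, e.g. H₂ + H′ → H + H′H among identical atoms)
advance the settled graph but are not reported as reactions.  The
original trajectory-analysis method this stage reimplements leaves its
distance criterion and persistence parameters unspecified; the values
here are declared defaults, all exposed in configuration.

Fragment signatures are exact canonical forms of the element-labeled
connectivity graph: iterative neighborhood (1-WL) color refinement,
followed by individualization–refinement when the coloring is not
discrete, taking the lexicographically smallest canonical string.  Two
fragments share a signature iff their labeled graphs are isomorphic (the
test suite checks this against networkx on exhaustive small-graph
families).  A single atom's signature is its element symbol.

## Screening

Records carry electronic energies of independently minimized fragments
(kJ/mol); ΔE = E_products − E_reactants in the discovered
(fragmentation) direction.  The bimolecularity filter passes exactly two
products; the exothermic-reverse filter is a strict sign test (ΔE > 0),
with |ΔE| < 5 kJ/mol flagged `marginal` for human review rather than
auto-decided, since the criterion is stated qualitatively.  Reversal
swaps sides, negates ΔE and toggles the direction flag; deduplication
merges records with identical unordered signature pairs and concatenates
provenance.  The "non-intuitive/novel" criterion is editorial and is
represented only as a free-text annotation field.  ZPVE-corrected ΔE is
available when frequencies have been computed, but records default to
electronic-only energies.

## Refinement

* **Minimization** — BFGS with the per-iteration displacement capped at
  a 0.015 Å per-atom norm and a backtracking line search, so accepted
  steps never raise the energy.  The initial inverse Hessian is scaled
  so the first step has full cap length; without this, van-der-Waals
  approaches with ~10⁻⁷ gradients would crawl.  Convergence: largest
  gradient component ≤ 10⁻⁴ internal units (10⁻⁵ in the pipeline).
* **NEB** — Cartesian linear interpolation, improved (energy-upwind)
  tangent, perpendicular true force + parallel spring force, FIRE
  relaxation, climbing image activated after a loose pre-relaxation.
  Defaults: 11 images, spring 1.0.  Endpoints are rigid-body aligned
  (Kabsch) before interpolation to strip spurious overall
  translation/rotation from the path.
* **TS refinement** — eigenvector following with finite-difference
  Hessians: uphill along the lowest mode, downhill along the rest,
  |λ|-regularized steps, cap 0.05 Å.  Convergence to a stationary point
  without exactly one imaginary mode is a flagged failure with the
  spectrum attached, never an exception.
* **Entrance-channel fallback** — discrete NEB images can step across a
  thin ridge without sampling it when the two complexes are far apart
  (their separation is set by where the trajectory left the fragments).
  When the NEB's highest image does not tighten to a first-order saddle,
  the pipeline falls back to the workflow's own constrained-scan step:
  a relaxed scan along the bond that forms between the two sides, with
  the profile maximum seeding a second TS search.
* **IRC** — displacement ±0.01 Å along the imaginary mode, then damped
  steepest descent in mass-weighted coordinates (step 0.02 amu^½·Å,
  halved whenever it would climb), endpoint polished by the minimizer.
* **Frequencies** — central finite-difference Hessian (0.005 Å),
  mass-weighted, translations and rotations projected out by an
  SVD-orthonormalized rigid-body basis (rank 5 for linear molecules);
  imaginary frequencies are reported as negative wavenumbers;
  ZPVE = ½Σhν over real modes.  Imaginary-mode counting uses a relative
  threshold (10⁻⁴ of the spectral radius) with an absolute floor
  (10⁻⁷ fs⁻²) so the all-noise spectrum of a fully dissociated plateau
  is classified as flat, not as a saddle.
* **Prereaction complexes** — rigid minimized fragments posed by Kabsch
  alignment onto a template intermediate, pushed apart along the
  centroid axis until every contact exceeds 5.00 Å, then jointly
  minimized with the capped-step optimizer.

## Bundled surfaces and the toy study

The Morse table carries rounded spectroscopic well depths, lengths and
widths for H–H, C–C, C–H, C–N, N–H, N–N and Lennard-Jones helium terms.
These are *fixtures with chemically plausible magnitudes*, not fitted
potentials.  All non-helium pairs interact (no bond list), so
connectivity can change freely.

The LEPS provider builds the classic exchange surface from the same
Morse parameters with Sato parameter 0.05; with fewer than three
reactive atoms it reduces exactly to the pair Morse curve.  A
sum-of-Morse-pairs surface binds a triatomic at every pair contact and
therefore has no exchange saddle; the LEPS form is the standard minimal
surface that does, which is why the end-to-end study runs on it.

The bundled study (`toy_abc.yaml`) is H₂ + C → CH + H: forward
endothermic by 19 kJ/mol with an 82.7 kJ/mol barrier, reverse (the
synthesis read-out) exothermic with a 63.7 kJ/mol entrance barrier and a
genuine collinear first-order saddle.  The H₂ dissociation channel lies
at 432 kJ/mol, far above the exchange barrier, so moderate piston
driving finds the exchange without shattering the molecule.  The study
conditions — 1500 K thermostat (within the method's usual 1000–3500 K
range), R₁ = 6 Å, R₂ = 2.5 Å, t₁ = 300 fs, t₂ = 200 fs, k₁ = 2×10⁻³,
k₂ = 4×10⁻³ fs⁻², six helium atoms, 10⁵ steps (50 ps) — were chosen the
way any nanoreactor study chooses them: strong enough compression to
cross the target barrier repeatedly, gentle enough not to atomize the
reactants.  Individual trajectories remain stochastic; most seeds (10 of the 12
examined while fixing the defaults) yield a verified exchange pathway
within 50 ps, and
the acceptance script, like the method itself, simply runs additional
independent simulations (bounded at five) when one does not.

## Synthetic trajectory fixtures

`make_scripted_trajectory` realizes planted connectivity timelines
geometrically: edited pairs ramp between 0.9× (clearly bonded) and 3.0×
(clearly separated) the covalent-radius sum over 5 frames, moving the
far-side group rigidly along the pair axis, plus Gaussian jitter
(σ ≤ 0.02 Å never crosses the 1.3× perception threshold).  The
randomized suite plants 1–3 edits per script on separated diatomics with
spacing that respects the persistence window, giving an exact ground
truth for precision/recall scoring.  These fixtures emulate the
*connectivity signal* of reactive trajectories, not their energetics or
kinetics: a perfect score on them shows the detector implements its
definition of a lasting change, not that the definition is optimal for
any particular level of theory.

## Scale and what the tests show

Everything here runs on toy surfaces at desk scale.  The workflow's
logic — boundary mechanics, thermostat statistics, event semantics,
filter algebra, and the agreement of minimize/NEB/TS/IRC with an
independent grid oracle on Müller–Brown — is verified exactly or to
stated tolerances.  Nothing here reproduces any published ab initio
energetics; coupling the same pipeline to a quantum-chemistry backend is
a matter of implementing one `ForceProvider`.

## Known limitations

* Bond perception is purely geometric; no bond orders, charges or spin.
* The canonical signature distinguishes labeled-graph isomorphism
  classes only — stereochemistry and geometry are invisible to it.
* The TS search assumes a start near the saddle (NEB image or scan
  maximum); it is not a global surface walker.
* LEPS handles at most three reactive atoms; larger reactive systems
  need an external provider.
* The packer is rejection sampling; very dense packings that Packmol's
  constrained optimizer could achieve will exhaust its retry budget.
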