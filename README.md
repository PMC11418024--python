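# nanoreactor

Reaction-discovery molecular dynamics with a piston boundary potential,
graph-based reaction-event detection, retrosynthetic screening, and
minimum-energy-path refinement — a complete three-stage workflow that
runs at desk scale on bundled toy reactive potentials.

## The problem

Finding which reactions a pool of molecules *can* undergo is hard to do
by guessing: interesting mechanisms are exactly the ones nobody proposes.
One systematic alternative is to slam molecules together inside a
simulated "nanoreactor": a molecular-dynamics run confined by a
time-dependent spherical boundary whose radius and stiffness breathe in a
rectangular wave.  Each compression stroke drives high-velocity
collisions that cross reaction barriers far faster than equilibrium
dynamics would; each expansion lets the products separate and be
identified.  Run retrosynthetically — start from a target molecule plus
a leaving group, watch it fragment, and read the discovered endothermic
fragmentations *backwards* — the method proposes exothermic two-body
formation routes of the kind relevant to low-temperature, low-density
environments such as interstellar clouds, where only bimolecular
reactions with low entrance barriers are viable.

This package implements that workflow end to end, with the
quantum-chemistry engine abstracted behind a small `ForceProvider`
interface (`evaluate(positions, elements) -> (energy, forces)`).  Bundled
providers — an all-pairs Morse potential with Lennard-Jones helium, a
LEPS exchange surface, and the Müller–Brown 2-D benchmark — make every
stage executable and verifiable without any external code.

## The model

**Discovery.** Atoms inside a sphere of radius R(t) move freely; outside
it each atom i feels the harmonic boundary

    U_i = ½ m_i k(t) (|r_i − c| − R(t))²,

whose force constant m_i·k(t) is proportional to the mass, so the
boundary accelerates every molecule uniformly.  (R, k) alternates between
an expanded phase (R₁, k₁) lasting t₁ fs and a compression stroke
(R₂ < R₁, k₂) lasting t₂ fs.  Dynamics is BAOAB Langevin (γ = 1/τ,
τ = 300 fs by default) at 0.5 fs time step; helium atoms serve as inert
collision partners.

**Selection.** Snapshots are converted to molecular graphs: atoms i, j
bond when d_ij ≤ 1.3·(r_cov,i + r_cov,j) (Cordero covalent radii), with
optional hysteresis (a bond persists until a larger break factor) to
absorb vibrational flicker.  A reaction event is a *lasting* change of
the graph — one that persists for at least 25 consecutive snapshots.
Event fragments are minimized independently, and two astrochemical
filters are applied: the fragmentation must yield exactly two products
(so the reverse is a two-body collision) and must be endothermic (so the
reverse synthesis is exothermic).  Surviving records are reversed and
deduplicated by canonical fragment signature.

**Refinement.** Each candidate pathway is verified on the potential
surface: capped-step (0.015 Å) BFGS minimization of the two complexes,
climbing-image NEB from linear interpolation, eigenvector-following
transition-state refinement, harmonic frequencies with ZPVE (one
imaginary mode confirms a first-order saddle), and mass-weighted IRC
descent to check that the saddle really connects the event's reactant
and product fragment sets.  Constrained distance scans locate entrance
barriers, and prereaction complexes are assembled at > 5.00 Å initial
separation.

## Worked example

The bundled study is the exchange reaction H₂ + C → CH + H on a LEPS
surface (one H₂, one carbon atom, six helium atoms in a breathing
sphere, 50 ps of Langevin dynamics at 1500 K):

```bash
$ nanoreactor pipeline --toy -o demo_out
events detected: 29; passed filters: 16; refined paths: 3
```

`demo_out/report.json` then contains, for the verified pathway (the
reversed record CH + H → H₂ + C):

| quantity | value | meaning |
|---|---|---|
| `delta_e_kj_per_mol` | −19.00 | the synthesis direction is exothermic by 19 kJ/mol |
| `barrier_forward_kj_per_mol` | 63.71 | entrance barrier of CH + H → H₂ + C |
| `barrier_reverse_kj_per_mol` | 82.71 | barrier of the discovered fragmentation direction |
| `imaginary_frequency_cm` | −2356.5 | the single imaginary mode of the saddle |
| `zpve_ts_kj_per_mol` | 12.27 | harmonic ZPVE at the transition state |
| `endpoints_match_event` | true | IRC ends reproduce {H₂, C} and {CH, H} |

The two barrier heights are the LEPS saddle measured from the two
minimized complexes; their difference equals the reaction energy.  The
same run writes the packed sphere, the full trajectory (extended XYZ
with the boundary state in every frame), the event list, the screening
report and the refined path images.

Every stage is also available separately (`pack`, `run`, `detect`,
`screen`, `refine-neb`, `refine-ts`, `irc`, `freq`, `scan`), reading and
writing plain XYZ/JSON, with a YAML configuration file documented in
`src/nanoreactor/data/toy_abc.yaml`.

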