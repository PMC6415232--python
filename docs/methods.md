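# Methods

## Model and assumptions

The chain is an infinite line of identical unit point charges joined by
zero-rest-length Hooke springs of constant `a` (nm⁻²), immersed in a
continuum solvent characterised by its Bjerrum length `lB` and carrying added
salt that screens with Debye constant `κ² = 4π lB Σ ci zi²`. Mean-field
assumptions apply throughout: the solvent is a structureless dielectric, the
particles have no excluded volume, the chain is long enough to neglect end
effects (per-bead free energies are used), and the chain's own counterions do
not enter the screening sum — only added salt does. At fixed molarity κ is
therefore recomputed whenever lB changes during a sweep.

Two closed-form free-energy branches (kBT per bead) are implemented:

* Debye–Hückel: `g_dh = ½ a b² − (lB/b) ln(1 − e^(−κb))`, physical for
  `b > z·lB`;
* counterion condensation:
  `g_cc = ½ a b² − (1/z)(2 − b/(z lB)) ln(1 − e^(−κb)) − 1/z + b/(z² lB)`,
  physical for `b < z·lB`.

Written this way the two branches are exactly continuous at the condensation
threshold `b = z·lB` (the logarithm coefficients both reduce to `1/z` and the
last two terms of `g_cc` cancel); continuity is enforced as a property test
over randomised parameters and is the criterion that fixes the grouping of
the condensation branch's terms, whose flat-text rendering is otherwise
ambiguous. Both electrostatic terms vanish as `κb → ∞`, leaving the pure
spring energy.

The condensed-layer geometry underlying the stiffening model: the local
concentration of condensed counterions per bead is `1/(8πe lB b²)` (e =
Euler's number), the subpopulation near enough to a bead to act on it fills a
cylinder `π lB² b`, giving `(1/8e)(lB/b)` active counterions per bead, and the
full layer has radius `sqrt(8e[(lB/b) − 1]) b`. Requiring that radius to
exceed lB restricts the construction to `1.05 < lB/b < 20.7`, the roots of
`x² − 8e x + 8e`; the package returns full-precision roots and treats the
two/three-figure values as roundings. Whether the "local concentration per
bead" is a number density or a count is immaterial downstream: only the
product `(1/8e)(lB/b)` enters the stiffening law, and the ambiguity is
quarantined inside `CondensedLayer`.

## Parameters

| parameter | meaning | units | default |
|---|---|---|---|
| `z` | unsigned counterion valence | — | 1 |
| `a0` | bare spring constant | nm⁻² | 0.1 (the transition-range scenarios) |
| `t` | stiffening per active condensed counterion | nm⁻² | 0 (off) |
| `temperature` | solvent temperature | K | 298.15 |
| `dielectric_constant` / `bjerrum_length_nm` | solvent quality (exactly one) | — / nm | — |
| `salt_species` | small-ion species, (mol/L, valence) each | — | none (must be set; κ = 0 is rejected because the unscreened lattice sum diverges) |

Physical constants are CODATA 2018 exact values; molarities convert to nm⁻³
via NA × 10⁻²⁴.

## Numerics

* **Equilibria.** Each branch free energy is scanned on a 4096-point
  geometric grid over the search bracket (default 10⁻³–10² nm, spanning all
  regimes of interest with margin); the bracketed minimum is then polished by
  Brent root-finding on the *analytic* derivative to 10⁻¹⁰ nm — far below the
  two-decimal precision of any reported quantity. A minimum on a bracket edge
  is reported as "no equilibrium on this branch" (or "collapsed to bound" in
  the stiffening solver) rather than silently clipped. A root landing on the
  wrong side of `z·lB` is returned flagged invalid with diagnostics, because
  branch termination is exactly the information the phase mapper needs.
  Equality with the threshold within 10⁻⁸ nm counts as valid (branch
  terminus). `a = 0` is rejected: without a restoring force the screened
  repulsion stretches the chain without bound.
* **Overlap edges.** The bistable interval of lB is bounded by the two points
  where a branch root crosses `beq = z·lB`: the condensation branch enters at
  the lower edge, the Debye–Hückel branch exits at the upper. Edges are found
  by a coarse sweep (step 0.05 nm, robust against narrow windows at large
  spring constants) for the sign change of `beq(lB) − z·lB`, then Brent
  bracketing to 10⁻⁴ nm. With `a = 0.1` nm⁻², 0.01 M 1:1 salt and `z = 1`
  this yields 1.6070 and 2.5380 nm.
* **Stiffening feedback.** With `a(b) = a0 + (1/8e) t (lB/b)` the elasticity
  is nonlinear. The default `composite` method substitutes `a(b)` into the
  spring term and minimises the resulting `g(b) = ½ a0 b² + t lB b/(16e) +
  (electrostatics)` directly. The optional `iterative` method instead solves
  the frozen-spring fixed point (solve `beq` at fixed `a`, update `a`,
  repeat). These are *different* stationary conditions — the b-dependence of
  the spring term contributes `t lB/(16e)` to the composite gradient but
  `t lB/(8e)` at the frozen-spring fixed point — so they converge to
  different spacings (e.g. 0.63 vs 0.38 nm at lB = 2 nm, t = 50 nm⁻²). Both
  produce the same three qualitative collapse regimes; `composite` is the
  default because minimising a single well-defined free energy keeps the
  result variational. Results record which lB/b values leave the validity
  window.
* **Stability of evaluation.** `ln(1 − e^(−κb))` is computed via `expm1` so
  it is accurate from `κb ~ 10⁻¹⁵` up to the regime where the electrostatics
  underflow harmlessly to zero; a genuinely unscreened evaluation (κb
  underflows) raises a domain error with guidance rather than returning ±inf.

## Verified model behaviour worth knowing

* Inside the bistable window the piecewise profile has exactly two minima and
  a maximum pinned at the junction `b = z·lB`; outside it, one minimum.
* The contracted-branch spacing is *not* monotone in lB: it rises from the
  threshold crossing (≈1.69 nm at lB = 2) to a single maximum (≈1.88 nm near
  lB ≈ 4.5) before declining gradually in ever-poorer solvents; the total
  passive contraction stays modest (well under 50% over lB ≤ 20 nm).
* The bistable window narrows monotonically and slides toward the origin as
  springs stiffen (the transition "funnel").

## Scope and limitations

The synthetic scenarios (figure presets) pin only physically meaningful
parameters — solvent, salt, spring constant, valence, stiffening — and use
package-chosen sweep grids; a 60-point geometric spring grid and 0.05–0.25 nm
lB steps resolve every feature tested while keeping any preset under a few
seconds. Being a closed-form mean-field model there is no sampling noise
anywhere, so passing tests demonstrate correctness of the formulas and
solvers, not agreement with real gels: no excluded volume, no inter-chain
interactions, no dielectric saturation, no dynamics (barrier-crossing rates
between the bistable states are out of scope), and no radius-of-gyration
mapping. Valences enter only through `z` and the screening sum; ion-specific
chemistry is deliberately absent.
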