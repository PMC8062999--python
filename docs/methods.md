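# Methods

## The titration circuit and its reduction

The core object is a mass-action network of one mRNA species `R` with
`n ∈ {1,2,3}` identical binding sites for one miRNA species `r`. Stepwise
binding forms 1:i complexes `C_i`; both free species are synthesized
(`s_R`, `s_r`) and degraded (`k_R`, `k_r`); the mRNA inside `C_i` degrades at
`a_i k_R` and each miRNA bound in `C_i` at `b_i k_r`. Degradation of a complex
is an elementary step that removes one partner and releases the survivor
intact (multiple turnover of both mRNA- and miRNA-directed degradation).
Concentrations are scaled by `s_R/k_R` and time by `1/k_R`, so the
dissociation constant enters only as `K_scaled = K·k_R/s_R` (default `1e-5`
for the circuit analyses).

Two conventions are explicit and configurable:

* **Binding multiplicity** (`binding_convention`). With `n` identical sites,
  stepwise binding carries the combinatorial factor of the number of
  free/occupied sites (`kon_i = (n−i+1)·kon`, `koff_i = i·K·kon`), so at
  equilibrium `C_i = C(n,i)·R·(r/K)^i`. The alternative `plain` convention
  drops the factors. The default is `statistical_factors`: in the
  10,000-set screens it reproduces the reference bistable fractions for
  **both** circuit sizes (33.3% two-site / 50.2% three-site at seed 1,
  against references 33.48% / 50.81%), whereas the plain convention matches
  only the two-site number (33.0% / 42.2%).
* **miRNA loss from higher complexes** (`mirna_loss_convention`). Default
  `per_molecule`: each bound miRNA decays independently, so `C_i` loses
  miRNA at total rate `i·b_i·k_r`. The `per_complex` alternative (total rate
  `b_i·k_r`) is retained for sensitivity analysis; it inflates the two-site
  bistable fraction to ~50% and is clearly not the convention behind the
  reference numbers.

Binding and unbinding are fast compared to synthesis and decay, so analysis
uses the total quasi-steady-state reduction: two ODEs in
`R_T = R + ΣC_i` and `r_T = r + Σ iC_i` with the binding equilibrium imposed
algebraically. The inner solve reduces to one polynomial of degree `n+1` in
free `r`; the unique root in `[0, r_T]` is taken (the conservation map is
strictly monotone), with a bracketed bisection fallback when polynomial
conditioning fails. Residuals of both conservation identities are audited at
`1e-12` relative (`1e-10` for the miRNA identity, which carries the
polynomial's cancellation error). Validity of the reduction is checked by
integrating the full model from reduced fixed points: the relative
discrepancy decays like `1/kon` and is below 1% for `kon ≥ 1e7` in scaled
units (at `kon = 1e6` the strong-binding branch still differs by ~4%, so the
tests use `1e7`).

## Fixed points, stability, bifurcation structure

At a fixed point the mRNA balance pins `R = (s_R/k_R)/phi_a(x)` with
`x = r/K` and `phi_a(x) = 1 + Σ a_i c_i x^i`, which turns the miRNA balance
into the scalar curve

    s_r(r) = k_r ( r + (s_R/k_R) · psi_b(x) / phi_a(x) ),
    psi_b(x) = Σ i·b_i·c_i·x^i.

All fixed points at a given control are real positive roots of a degree-`n+1`
polynomial (hence never more than `n+1` of them); saddle-node points are the
curve's interior extrema; bistability is non-monotonicity. Stability is
labelled from the Jacobian of the reduced two-variable system, obtained by
implicit differentiation through the binding algebra (`J = N M⁻¹` with `M`
differentiating the totals and `N` the rates with respect to the free
species). Near-multiple roots are clustered at relative tolerance `1e-8` and
flagged degenerate. Branches of bifurcation diagrams are swept in `r` — the
natural parameter along the S-curve — so folds are resolved exactly rather
than by continuation. Nullclines of the phase plane are computed in closed
form as curves parameterized by free miRNA; the separatrix is integrated
backward in time from the saddle along its stable eigendirections with a
bounding-box stopping event.

## The random-parameter screen

The screen draws each multiplier `a_i`, `b_i` independently from
U(0.125, 16) — per-record counter-based seeding `(seed, index)`, so records
are order-independent — with all other rates 1 and `K_scaled = 1e-5`, and
classifies by counting the positive real extrema of `s_r(r)`: at least two
extrema means some control interval with two stable outer branches and a
saddle between them. The default classification accepts a bistable window
anywhere on `s_r > 0`. Restricting the window to `[0, 10]` (folds outside
count as monostable) lowers the two-site fraction from 33.0% to 32.2%; the
unrestricted rule is the default because the reference protocol's window is
not stated and the unrestricted fraction matches the reference value.
Switch magnitudes are evaluated at the fold points: the free-mRNA drop
`log10 R(fold_upper)/R(fold_lower)` and the companion total-mRNA change.
A classification failure rate above 0.1% aborts the screen (none observed).

The closed-form two-site condition `a1/b1 < a2/(2 b2)` is exact for the
non-monotonicity of the `K → 0` limit curve (the quadratic coefficient of the
derivative numerator changes sign exactly there) and is verified
screen-wide as a necessary condition. The bisected onset of bistability in
`a2/b2` at `a1 = b1 = 1` depends on `K`: 2.086 at `K_scaled = 1e-5`, 2.008 at
`1e-8`, 2.004 at `1e-9`. `critical_ratio` defaults to `K_scaled = 1e-9` as a
practical stand-in for the strong-binding limit, where the threshold
`2·a1/b1` holds within a fraction of a percent.

## Reaction-network indices

`crnt` writes the canonical network with a single shared empty complex and
recycling degradation arcs (`C_i → i·r` when the mRNA decays, `C_i → C_{i−1}`
when a bound miRNA decays), and computes complexes, linkage classes
(connected components), stoichiometric rank over the integers (exact
arithmetic), deficiency `δ = n − l − s` and weak reversibility. Under this
bookkeeping the one-site circuit has `δ = 1` (5 complexes, 1 linkage class,
rank 3): the recycling products `r` and `R` tie the binding linkage class to
the synthesis/decay class. Other notations of the same chemistry (e.g.
lumping degradation products, or omitting recycling arcs) split the linkage
classes and can yield `δ = 0` for the one-site circuit; published deficiency
statements for these circuits therefore depend on the chosen bookkeeping, and
the module reports the canonical value rather than forcing agreement.

## Motif counting

Site tables are tab-separated with canonical columns (a configurable dialect
maps TargetScan release headers); malformed coordinate rows are rejected and
logged, duplicates dropped. miRNAs are grouped at family level; overlapping
sites are not merged. For `k ∈ {2,3}` the lower bound counts (gene, family)
groups with ≥ k conserved sites; the upper bound sums `C(m, k)` over groups
of all sites. The synthetic generator draws per-(gene, family) site counts
from a configurable distribution, thins conservation by a Bernoulli flag,
and tallies both bounds during generation, independently of the counting
path; under Poisson(λ) counts with conservation probability p the analytic
expectations `N·P(Pois(λp) ≥ 2)` and `N·λ²/2` are used as a further oracle.
Printed genome-wide counts from any specific external database release are
version-dependent reference points, not assertions of this package.

## The tissue model

A strip of spinal cord is a grid of 10 columns × 40 rostrocaudal positions of
*uncoupled* cells. RA and FGF are produced at the rostral and caudal ends and
degrade uniformly, giving exponential antiparallel gradients
`RA = A(t)·e^(−x/λ)`, `FGF = A(t)·e^(−(39−x)/λ)` with λ = 8 cell positions.
The shared amplitude `A(t)` ramps up (t < 5), holds (t ≤ 30), then recedes
exponentially (timescale 10) to a low plateau of 0.1 — the transient
differentiation signal; the plateau retains the spatial profile, so late
positional information is weak but nonzero. Each cell perceives each
morphogen through an independent multiplicative Ornstein–Uhlenbeck factor
`1 + η` (stationary s.d. σ = 0.15, correlation time 1), integrated by
Euler–Maruyama at `dt = 0.01` and clipped at zero, giving across-cell
variance `σ²·signal²` at fixed position and time.

Cell-model wiring is declarative (Hill edges with per-edge threshold and
exponent over transcription units, plus titration pairs or catalytic edges).
Defaults, in nondimensional units (rates relative to mRNA turnover):

* Morphogen sensing `θ = 0.04`, Hill `n = 2` (the unilateral-repression
  variant uses `n = 4`, very high cooperativity, to give the feedback-free
  model its best chance). The threshold sits deep in the gradient tail so the
  receded profiles still discriminate position.
* `mmi_S` (titration model): Hoxa5 transcription `0.25 + 3.2·H⁺(RA)`, the
  whole unit damped by Hoxc8 protein (`H⁻`, θ = 0.1, floor 0.25 — the
  repression is strong but leaky); Hoxc8 transcription `0.15 + 3.0·H⁺(FGF)`;
  miR-27 constitutive at 0.15; miR-196 `0.1 + 0.52·H⁺(FGF)` (constitutive
  with caudal enhancement, matching a broad caudal distribution). Both
  mRNA–miRNA pairs use two-site kinetics `a = (1, 1)`, `b = (1, 0.1)`,
  `K_scaled = 1e-4`: the 1:2 complex protects the miRNA, which creates the
  switch while leaving total mRNA equal to the transcription rate — the
  configuration in which protein patterns can segregate sharply over
  overlapping mRNA patterns. Proteins are translated from *free* mRNA with
  unit rates. The feedback-free control (`mmi_S_nofeedback`) balances the
  complex degradation (`b = (1, 1)`), removing bistability and nothing else.
* These numbers place the Hoxa5 arm's bistable window of transcriptional
  drive at (0.27, 0.64) and were chosen jointly so that: the pulse peak
  drives Hoxa5 on down to position ≈ 20 and Hoxc8 on from ≈ 20; the receded
  drives keep committed cells inside their windows (memory); the
  basal Hoxa5 drive lies *below* its window so naive caudal cells cannot
  switch on; and repressed drive falls below the window's lower fold so a
  Hoxc8-on cell always extinguishes Hoxa5 (no stable double-positive state).
* Cells start naive (zero mRNA and protein) with a resting miRNA pool of
  5× the basal free level, making the silenced state the from-zero attractor.

Fate calls for the titration family use absolute protein thresholds
(Hoxa5 on ≥ 0.05, Hoxc8 on ≥ 0.2, recorded with every call); the Hoxc8
threshold sits above the constitutive Hoxc8 leak so that knockout analyses
remain interpretable, and relative (10%-of-max) thresholds are the default
elsewhere. A cell is *equivocal* if double-positive, double-negative, or if
its Hoxa5:Hoxc8 protein ratio is within 10-fold of unity; the transition
width is the number of positions with ≥ 1 equivocal cell. The boundary
position is the midpoint between the caudal edge of the Hoxa5-majority
domain and the rostral edge of the Hoxc8-majority domain. The segregation
index is the ratio of protein-to-mRNA boundary steepness, steepness being
the maximum absolute discrete derivative of the column-averaged,
max-normalized rostrocaudal profile; these metric definitions are this
package's conventions, fixed here because no external definition is
available to it.

Per-position steady states (for positional bifurcation diagrams) are exact,
not sampled: the Hoxc8 arm never depends on Hoxa5 (except in the
cross-repression variant, solved by a scalar composition scan), so fixed
points factor into Hoxc8-arm states × Hoxa5-arm states given Hoxc8 protein.
Titration arms are enumerated through the steady-state polynomial;
self-referential transcription-only arms by dense scalar bracketing, with
the composite loop gain deciding stability.

The RA-pulse protocol compares a pulsed cell (high RA until `t_switch`, then
`ra_low = 0.005`, which places the drive just inside the bistable window)
against a never-pulsed control; *persistence* is a pulsed/unpulsed final
Hoxa5 ratio above 3. The "on" threshold is the geometric midpoint between
the two stable branches at `ra_low` when the RA response is bistable — the
natural separatrix scale — and a tenth of the maximal attainable level when
it is monostable (a monostable response has no branch structure to
separate); with the titration arm silenced, free mRNA equals total mRNA, so
any absolute threshold that is blind to the branch structure cannot
distinguish the two genotypes' final levels.

## Problem sizes

Screens use 10,000 parameter sets (seconds); tissue runs use the full
10 × 40 grid for 80 time units at `dt = 0.01` (a few seconds per run), and
the 20-seed median-width comparisons use `dt = 0.02`, which leaves the width
metric unchanged on spot checks. Oracle-based tests (ODE attractor censuses,
full-model integration) use 8–15 random parameter sets with a handful of
initial conditions each.

## What the synthetic data do and do not emulate

The generator reproduces the *statistical structure* the analyses need —
uniform kinetic multipliers over the reference interval, morphogen
time-courses with multiplicative noise, site catalogs with known multi-site
counts — not real measurements: no measurement noise on "protein" readouts,
no cell movement, growth or axis elongation, no transcriptional bursting, and
site catalogs with independent Poisson site counts rather than the clustered,
conservation-correlated structure of real 3′ UTRs. Passing tissue tests
therefore show that the mechanisms produce the claimed qualitative patterns
under the stated idealizations, not that the parameter values are those of
the embryo.

## Known limitations

* The exact kinetic parameter tables of the original tissue models are not
  available here; the defaults above are this package's own calibration to
  the qualitative claims, and the claims are tested as orderings and
  existence statements, never as numeric pattern matches.
* Deficiency values depend on network bookkeeping (see above).
* The critical-ratio threshold is exact only in the strong-binding limit;
  at `K_scaled = 1e-5` the onset is ≈ 4% above `2·a1/b1`.
* Stability labels for scalar-scan (non-titration) arms use the composite
  loop gain of the slaved map, which is a sufficient criterion for these
  monotone feedback loops rather than a full Jacobian analysis.
* Hopf bifurcations/limit cycles are not searched for (none arise in the
  reduced two-variable circuits analysed here).
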