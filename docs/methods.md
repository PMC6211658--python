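# Methods

## The model

`bindkin` treats receptor occupancy as a race between two clocks: the
intrinsic binding kinetics of a ligand (kon, koff) and the extrinsic
turnover of the binding site itself, which is produced/activated with
rate constant k_i and removed/deactivated with rate constant k_-i.
Classical pharmacology assumes the site is always there, so occupancy is
the Hill value L0/(L0 + Kd).  When the site builds and decays on a
timescale comparable to (or faster than) binding, occupancy becomes a
genuinely dynamic quantity and the equilibrium picture can fail by orders
of magnitude.

The bound complex C(t) obeys

    dC/dt = kon * (B_total(t) - C) * L0 - koff' * C,      C(0) = 0

with free ligand held at a constant concentration L0 and the free site
eliminated through the instantaneous conservation B_free = B_total - C.

**Site availability.**  B_total(t) rises toward an asymptote B_inf and,
once it has settled — by convention at 95% of B_inf, reached at the
settling time xi = -ln(0.05)/k_i ≈ 3/k_i — decays with rate k_-i.  Two
shapes are implemented:

* *Scenario 1* (species turnover): saturating-exponential buildup
  `1 - exp(-k_i t)`, then exponential decay.  In dimensionless time
  tau = k_i t the peak always sits at tau = 3.
* *Scenario 2* (conformational gating): logistic buildup pinned at 5% of
  maximum at t = 0 (midpoint tau01 = ln 19 ≈ 2.94), then logistic decay
  (midpoint tau02 = 3 + xi_bar); the peak sits at xi_bar = 3 + ln 19 ≈
  5.94.  For k_i ≠ k_-i the decay argument is gamma*(tau - xi_bar) - 3
  with gamma = k_-i/k_i, which preserves continuity at the switch and
  reduces to tau - tau02 at gamma = 1; results there are flagged
  `extrapolated`, since the equal-rates derivation does not cover them.

**koff hijacking.**  A complex cannot outlive its own binding site:
dissociation slower than site decay is irrelevant, so the effective
dissociation rate is koff' = max(koff, k_-i) and the effective affinity
Kd' = koff'/kon ≥ Kd.  This single rule is behind the package's central
design message: residence-time optimization below the site's own decay
rate buys nothing.

**Dimensionless groups.**  With alpha = kon·L0/k_i, beta = koff'/k_-i,
gamma = k_-i/k_i and c = C/B_max, the rate equation becomes
dc/dtau = alpha·b(tau) - (alpha+beta)·c.  The equilibrium fraction is
c_inf = alpha/(alpha+beta), which reduces to the Hill value.

## Closed forms and the numeric oracle

Scenario 1 admits an elementary solution: three exponentials with rates
-(alpha+beta), -1, 0 on the buildup branch, and
c = (c0 - K)·e^{-s·dtau} + K·e^{-gamma·dtau} with K = alpha/(s-gamma),
s = alpha+beta on the decay branch.  The decay initial condition c0 is
`continuous` (the buildup value at the settling time; default, matches
the ODE solution exactly) or `paper_literal` (restart from the truncated
plateau 0.95·c_inf, which can disagree with the buildup branch by a few
points).  Removable singularities at s = 1 and s = gamma are detected
within 1e-8 and delegated to the integrator rather than patched with
limits — the ODE is exact and cheap.

Scenario 2's solution lives in the Gauss hypergeometric family:
2F1(1, s+1; s+2; -e^{tau-tau01}) terms on the buildup branch (this was
re-derived via the incomplete-Beta representation and cross-checked
against adaptive integration to ~1e-9) and 2F1(1, s; s+1; ·) terms on
the decay branch.  Arguments are mapped into the unit disk with the
Pfaff transformation before evaluation; where the library routine
returns a non-finite value (very large s), a directly summed transformed
series — whose terms decay at least as fast as n!/(s+1)_n — takes over.
Values are cross-validated against arbitrary-precision evaluation in the
test suite.  The closed form requires gamma = 1; other gammas (e.g. the
hERG case) use the integrator.

The numeric path integrates the dimensionless equation with adaptive
LSODA at rtol 1e-9 / atol 1e-13, split into buildup and decay segments so
the switch kink is a segment boundary.  Closed form and integrator agree
to better than 1e-6 across the tested (alpha, beta, gamma) grids — each
serves as the oracle for the other.

One bookkeeping choice at the scenario-1 switch: the paper-form decay
forcing restarts from the full asymptote, a deliberate ~5% truncation
jump.  The reported B_total at the switch grid point is taken from the
buildup side, where the complex level still refers; otherwise the single
seam point would show a spurious 5% dip in fractional occupancy.

## Occupancy profiles and thresholds

Profiles are classified from the fractional occupancy c/b_total over the
site's functional window (the span where b_total ≥ 50% of its maximum,
measured on the trajectory):

* **SSO** — the fraction stays within `sso_deviation` (default 6%) of
  c_inf.  The default admits the boundary case of the on-rate rule
  itself: at kon = kon_ss (alpha = beta = 10) the inherent early-window
  lag of the exact solution is 1/19 ≈ 5.3%, and that case *defines*
  steady-state occupancy, so a 5% cutoff would be self-defeating.
* **qSSO** — not steady-state, but the peak fraction reaches
  `qsso_peak_fraction` (default 0.9) of c_inf with a saturating dose,
  n = L0/Kd' ≥ `qsso_multiple` (default 10).
* **nSSO** — occupancy lags the site and peaks below the equilibrium
  fraction.

The on-rate rule kon_ss = 10·k_i/L0 (prefactor exposed as
`KON_SS_PREFACTOR`) marks where bound-state buildup keeps pace with site
buildup.  All thresholds are plain config (`ClassificationThresholds`).

**Functional window.**  Scenario 1: Lambda = (3 - ln 2)/k_i + ln 2/k_-i,
exact for the ≥50%-of-plateau span of the site curve (referencing the
0.95-truncated peak instead would shift the buildup crossing from ln 2
to 0.644, a ~2% difference).  Scenario 2 with equal rates:
Lambda = 2·ln 2/k_i — a half-life-based rise-plus-fall convention, not
the literal half-maximum width of the logistic curve (~6.2/k_i); it is
kept because it is the convention under which the published window
values (e.g. 3.85 hr at k_i = 1e-4 s^-1) are stated.  Unequal-rate
scenario 2 reports ln 2/k_i + ln 2/k_-i, flagged `extrapolated`.

## Kinetic tuning

`tuning_report` encodes the optimization order as a fixed decision
table: below kon_ss, occupancy is on-rate limited and slowing koff is
futile → `speed_kon_first` (with the L0 multiple that would compensate);
if the required kon_ss exceeds the 1e9 M^-1 s^-1 diffusion limit, only
concentration can compensate → `concentration_compensation_needed`; at
or above kon_ss, koff faster than k_-i still pays → 
`slow_koff_within_k_minus_i`; once koff ≤ k_-i the pair is `tuned` and
further residence-time gains are hijacked away.

## Packaged tables

Four small CSVs ship with the package (checksummed; loading fails loudly
on any alteration): the turnover grid spanning k_i from 1e-8 to 10 s^-1;
measured PCSK9/LDL-R kinetics by variant and pH; hERG blocker
pro-arrhythmic concentration thresholds; and published kinetics of 32
marketed drugs.  The turnover grid is fully recomputable and is
validated cell by cell at the printed precision — its "~kon_ss" column
is quoted to the next power of ten (a conservative sufficient on-rate),
so the recomputed 10·k_i/L0 is decade-rounded up before comparison; the
equal-rate rows coincide exactly.  One row ("83") carries no printed
unit and is treated as hours, consistent with ln 2/k_i for its row.

The PCSK9 case study takes the effective koff' directly from the
measured table.  The table's own hijack floor (ln 2 / 5 min ≈ 2.3e-3
s^-1, applied to the D374Y mutant) sits below the nominal site decay
rate used for the turnover curve (1e-2 s^-1), and the wild-type koff' is
left at its measured koff although it is smaller than the mutant's
floor; these published inconsistencies are reproduced as-is rather than
"corrected", since the quoted occupancy results depend on them.

For the marketed-drug statistics the bin edges are applied exactly as
conventionally printed (kon ≥ 1e5; koff < 3.9e-4 strict; Kd < 1 nM
strict; kon-driven: koff > 3.9e-4 and kon > 1e5; koff-driven: koff <
3.9e-4 and kon < 1e5).  Under the strict rules the slow-koff bin counts
16/32 (50%) and the koff-driven bin 7/32 (22%); the commonly quoted ~47%
and ~19% correspond to excluding one borderline entry each (Amlodipine,
koff = 3.0e-4 s^-1, sits just inside the slow bin).  The headline 72%
fast-kon and 44% sub-nanomolar fractions are exact integer counts
(23/32, 14/32).

## Case-study peak reporting

For the PCSK9 cases two summary numbers are exposed: `c_at_site_peak`,
the occupancy at the moment site availability peaks (tau = 3) — the
quantity the published 82%/85% figures correspond to — and `c_peak`, the
true maximum of the continuous solution, which occurs slightly later
(tau ≈ 3.07-3.09) and is about one percentage point higher (83.0%/86.0%
at L0 = 40.5 nM).  Both are computed, not asserted; the acceptance
script reports the true maximum.

## Problem sizes and determinism

All computations are desk-scale: trajectories default to 1201 uniform
points on tau ∈ [0, 12] (the standard figure window; the acceptance
script uses 12001 points for peak finding), and every solve completes in
milliseconds.  The model contains no stochastic component — fixed inputs
give byte-identical outputs; the acceptance script accepts a seed only
for interface uniformity.

## Limitations

* Free ligand is fixed at L0; time-varying exposure, endogenous
  competitor dynamics and differential degradation of bound vs free site
  are out of scope (each would only raise the effective kon_ss).
* Buildup and decay are treated as sequential single-exponential /
  single-logistic phases; multiphasic kinetics and growth-dilution are
  not modeled.
* The scenario-2 unequal-rates decay and its window are labeled
  extrapolations; the hERG case study is qualitative by construction
  (its occupancy thresholds come from an upstream action-potential
  simulation and are carried as fixture data only).
* The SSO/qSSO/nSSO cutoffs are sharp renderings of qualitative
  definitions; they are exposed as configuration and results near the
  boundaries should be read accordingly.
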