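# Methods

## The estimand

For a patient observed at two measurement dates, the binary outcome is an
address-of-record change: the registration-system street address at the
endpoint date differs from the one at baseline. Deprivation persistence is
characterized conditionally on a change. With origin ADI quintile q:

* `A_q` — probability of an address-of-record change within one year;
* `B_q = 1 − T[q,q]` — probability the destination lies outside quintile q,
  given a change, where `T` is the mover origin→destination quintile
  transition matrix;
* `D_q = 1 − Σ_{j∈N(q)} T[q,j]` — probability the destination lies outside
  the same-or-neighboring set `N(q)`, given a change.

`N(q)` is {q−1, q, q+1} for q ∈ {2,3,4} and two inward steps at the edges
(`N(1)={1,2,3}`, `N(5)={3,4,5}`), so the complement of `N(q)` always has
exactly two quintiles and `D_q` is comparable across origins. The
unconditional leave probabilities are the products `A_q·B_q` and `A_q·D_q`,
and the headline scalars weight these across quintiles by the cohort's
quintile shares.

## ADI construction

Each of the 17 block-group indicators carries a direction flag (+1 when a
larger raw value means more deprivation). Indicators are z-scored with the
sample SD (ddof=1) — the convention under which the three-point column
(1, 2, 3) standardizes exactly to (−1, 0, 1) — multiplied by their direction
flag, and combined as `score = base + scale·Σ wⱼ zⱼ` (defaults: base 100,
scale 1). Constant columns standardize to zero rather than erroring, since
a region-wide constant carries no ranking information.

The shipped weight preset is `equal` (1/17 per indicator). Published
deprivation-index coefficient sets can be supplied as a YAML/CSV weights
file; we deliberately do not hard-code any externally estimated coefficient
vector we cannot source exactly, and all quintile-based statistics are
invariant to positive affine rescaling of the score in any case.

Quintile cut points are the 20/40/60/80th percentiles (inverted-CDF
convention) of the block-group score distribution — unweighted over block
groups by default, or population-weighted on request. A score exactly at a
cut point falls in the lower quintile (deterministic, conservative toward
less deprivation). With all scores identical the split is degenerate: every
block group is reported as quintile 1 with a warning. Urban/rural is a
majority rule on the block group's population split, ties classed urban.

## Cohort rules

Eligibility needs one encounter in the closed baseline window
[enrollment start, baseline date] and one in the half-open follow-up window
(baseline date, endpoint date]; an encounter exactly on the baseline date
counts only toward baseline (the windows abut, so a convention is required).
Exclusions are applied in the fixed order deceased → PO-box baseline address
→ missing geocode, each patient logged once under the first matching reason,
so the exclusion log is deterministic and sums to input − output.

Address equality is judged after normalization (uppercase, whitespace
collapsed, `.,#` stripped). This is deliberately conservative: it removes
trivial formatting churn but will still count a unit-number correction as a
move, a known limitation of registration-address data generally. PO-box
detection requires a digit after the box token ("PO BOX 44", "P O BOX 44",
"POST OFFICE BOX 44") to avoid substring false positives. When raw strings
are absent, geocoded block-group IDs are compared instead; a change of
residence within one block group is then invisible, which only understates
mobility and cannot bias the persistence measures toward optimism. Age bands
are half-open: <18, [18,30), [30,50), [50,70), ≥70.

## Annualization and rounding

Rates observed over a w-month window are annualized linearly (`×12/w`), the
convention under which 27.2% over 14 months gives 23.3% per year. We do not
use an exponential hazard conversion; at these magnitudes the difference is
small and the linear rule matches the published arithmetic this package
reproduces. Report tables round half-up to 2 d.p. and headline scalars to
the nearest percent; internal computation never rounds. The headline
weighted probabilities follow the published convention of weighting the
2-d.p.-rounded composite rows (full-precision variants are exposed as
`*_exact`). `compare_composites` flags table cells whose printed value
disagrees with the rounded product of the table's own rounded inputs — such
cells are flagged, never forced; with the published persistence table this
flags exactly one cell (quintile-2 A×B, printed 0.09 vs recomputed 0.08),
indicating unrounded inputs upstream of that table.

Transition-matrix rows with no movers are undefined (NaN), rendered as a
dash, and dropped from weighted summaries with a logged warning and share
renormalization.

## Logistic models

Categorical factors are dummy-coded against declared reference levels
(quintile 1, male, white, non-Hispanic, married, <18, urban by default).
Fitting is Newton/IRLS with a step-halving safeguard, so the Bernoulli
log-likelihood is non-decreasing at every iteration; convergence is a
log-likelihood change below 1e−8, capped at 100 iterations. Confidence
intervals are Wald, `exp(β ± 1.96·SE)` — closed-form, symmetric on the log
scale, and testable against the 2×2 algebraic oracle (`OR = ad/bc`,
`SE = √(1/a+1/b+1/c+1/d)`); the fitter agrees with that oracle to six
significant figures and with an independent maximum-likelihood
implementation (statsmodels) in the cross-check tests. Estimates diverging
past |β| > 30 raise a separation error naming the offending term rather than
returning unstable output. No family/household clustering adjustment is
offered: address data plausibly contain correlated household moves, but
modeling them requires family linkage information this pipeline does not
assume, so reported CIs are anti-conservative to an unknown degree on real
household-structured data.

## Synthetic cohort generator

The generator exists so every pipeline stage is testable end to end without
any external data, and its defaults are the study conditions the package is
validated against:

* quintile shares (0.266, 0.269, 0.187, 0.148, 0.130);
* 14-month per-quintile move probabilities (0.229, 0.241, 0.282, 0.309,
  0.366), increasing with deprivation;
* destination kernel per origin: same-quintile mass (0.55, 0.44, 0.37, 0.34,
  0.43), neighboring mass (0.31, 0.34, 0.36, 0.39, 0.37) split evenly over
  the two neighbors, remainder split evenly over the two outside quintiles —
  the simplest kernel consistent with the B and D rows it must reproduce;
* demographic marginals matching the published cohort mix, drawn
  independently of quintile (no built-in confounding; confounded data for
  the adjustment tests are constructed explicitly in those tests).

Block groups get a latent deprivation factor z ~ N(0,1) driving all 17
indicators (loading 1.0, noise SD 0.3, protective indicators sign-flipped),
populations lognormal around 1500 persons, and a 3.2% rural-majority share.
Patients draw at most one true move per window (the measurement design
cannot observe more), a move date uniform in the window, and encounters
1+Poisson(1) per study window, which guarantees eligibility by construction;
a dropout option removes follow-up encounters to exercise the eligibility
filter.

The observation layer reproduces the registration lag: the observed address
at a measurement date is the true address at the last encounter on or before
that date, so a move after the final encounter is a false negative (the
observed change rate can never exceed the true move rate). By default the
last follow-up encounter is placed on the endpoint measurement date —
emulating a design in which endpoint addresses are current as of measurement
— so that default runs recover the configured move probabilities; switching
`final_encounter_at_endpoint` off (or thinning encounters) exposes the lag,
and the tests verify that more frequent encounters monotonically shrink the
false-negative rate.

For odds-ratio recovery the generator switches to an explicit
log-odds-linear parametrization: logit P(move) = logit(0.15) + β_q, with
β_5 = log 1.75 for adults and log 2.13 for pediatric patients (intermediate
quintiles interpolated), making the adjusted logistic model correctly
specified and the configured OR the exact estimand.

Randomness: one root seed, split via `SeedSequence.spawn` into independent
per-stage streams (block groups / patients / mobility / encounters), so each
stage is reproducible in isolation and all outputs are pure functions of
(config, seed).

What the generator does **not** emulate: spatial contiguity of block groups,
realistic address-string variety (templates only), household-correlated
moves, secular trends in mobility, or differential loss to follow-up by
destination. Passing tests therefore demonstrate that the pipeline measures
what it claims on data with the study's marginal structure — not that the
study's substantive conclusions transfer to any particular real population.

## Problem sizes and tolerances

The persistence-share check simulates 50,000 patients (≈13,600 movers; ±2
percentage-point tolerance, several times the binomial SE). OR recovery uses
100 replicates of 12,000 patients and requires the 95% Wald interval to
cover the generating OR in at least 93 of 100 replicates, per stratum.
Quintile-share recovery uses 100,000 patients at ±0.5 points. The shipped
200-patient fixture is for I/O and pipeline wiring, regenerated bit-exactly
from its recorded seed; statistical checks always simulate at the sizes
above.
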