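# Methods

## The measurement model

PIR motion sensors are event sources, not presence sensors: a `1` is emitted
when motion begins in a room and a `0` when motion has not been seen for the
hardware lockout period; a person sitting still, or asleep, is invisible. In
a 2-person home the absence of motion in one room cannot be attributed to a
departure, because motion elsewhere may come from the co-resident. The
package therefore computes only quantities that are *certain* under these
semantics:

* **Room use.** The union of `[on, off)` intervals per room (multiple
  sensors mapped to one room are unioned). This bounds true dwell time from
  below; the gap is largest for rooms used while stationary (bedrooms at
  night, living rooms during television).
* **TOOH.** For the pooled egress-door channel, an episode runs from a door
  open through at least one close to the next open. If no motion occurs
  strictly inside the episode, nobody was home and the whole span counts.
  Motion exactly at a boundary (the resident tripping a hall sensor while
  stepping out) does not void the episode; this strict-interior rule is
  configurable, as is a minimum-episode floor (default 0 s) for door-ajar
  chatter. Episodes crossing midnight contribute to each day only the
  in-window part.
* **ILSA.** The measure of instants at which at least two distinct rooms
  are simultaneously in use, computed as a boundary sweep over the count of
  active rooms. Overlaps of three or more rooms count once: the
  measure-of-union is the only extension of "2 rooms used simultaneously"
  that does not double-count.
* **Percent rooms used.** Distinct motion sensors firing in the window over
  installed motion sensors (one sensor per room by deployment protocol).

Intervals are half-open `[start, end)` in integer seconds, so zero-length
events cannot occur and windows tile exactly. A trailing `on` with no `off`
is closed at the end of the home's covered data span; an `off` with no
preceding `on` is dropped with a warning; repeated identical states (PIR
retrigger chatter) collapse to the first occurrence. Timestamps are naive
local time; daylight-saving shifts are processed as-is, which perturbs at
most one hour on two days a year.

Because day- and hour-level metrics are window clips of one precomputed
interval set per home, the partition identity
`sum over hours of profile(h)/100 × 1 h = daily value` holds exactly; the
suite asserts it per home and outcome. Every metric also equals a 1-second
occupancy-grid recomputation exactly, asserted on 1000 randomized streams.

## Day exclusion and eligibility

A home-day is eligible only if none of: a reported overnight-visitor or
away-overnight week covers it (the report's `week_start` covers 7 days);
some installed motion sensor was silent that day while the home was
otherwise active (door contacts are exempt — a silent door day is a day
without outings, not a fault); the day falls after the pandemic restriction
date for the home's site (2020-03-20 Illinois, 2020-03-23 Oregon); the day
falls after a move or resident change; the day is within the first 14 days
of monitoring (observation-effect burn-in); or it is a weekend.

Daily and hourly analyses use each home's first 20 eligible weekdays (four
weeks of weekdays, interruptions ignored); homes with fewer than 20 eligible
days are dropped. Longitudinal analyses use all eligible days and require
more than 180 of them. Outlier homes beyond 5 SD from the cohort mean of an
outcome are removed in a single pass (mean and SD computed once — iterating
would silently change removal counts), with a strict inequality at the
threshold.

## Group-comparison models

Home-level summaries are regressed on household type, MCI-home status, their
interaction, and home-level covariates (mean age, counts of females, males,
White and other-ethnicity residents, rooms, mean education). Because
females+males and White+other each equal the resident count, the stated
design is structurally rank deficient; exactly collinear columns are dropped
greedily (keeping earlier terms) with a warning, which reproduces what R's
`lm` does by aliasing. If the interaction is significant at α = 0.05 the
analysis is stratified by household type (dropping household terms),
otherwise the interaction is removed and the pooled model refitted. The
rooms covariate is excluded for the percent-rooms-used outcome, whose
denominator already contains it. No multiplicity correction is applied by
default; a Benjamini–Hochberg helper is provided.

Trend analyses regress the per-home slope (OLS of daily value on calendar
day index from the first eligible day, so gaps advance time) or variability
(SD of raw daily values; a detrended option exists in spirit via the slope
output) on household type, MCI, interaction and age only. Reporting helpers
convert hours/day-per-day slopes to seconds/day (×3600) and minutes/year
(×3600×365/60).

Trajectory-class membership is tested by multinomial logistic regression on
the same covariates with the largest class as reference. Quasi-separation —
endemic when a class is nearly co-extensive with a covariate — is detected
via non-convergence, runaway coefficients, or exploded standard errors; the
reported fallback is a Newton fit with a tiny L2 penalty whose Wald errors
come from the penalized Hessian, and the result is flagged `unstable`.
Classes with ≤ 5 homes are fitted but flagged uninterpretable.

## Latent-class trajectory model

Hour-to-hour profiles (24 values per home per outcome, percent of hour) are
modeled as a finite mixture of polynomial curves with linear-mixed-model
within-class structure: `y_i | k ~ N(X b_k, Z G_k Z' + s²_k I)`. Clock time
is scaled to [0, 1] before polynomial expansion so quartic designs stay well
conditioned; coefficients can be mapped back to raw hours
(`b_j → b_j / 23^j`). The marginal is closed-form Gaussian, so no numerical
integration is needed anywhere. Nine families span the variance structures:
fixed-effects homoscedastic (A) and heteroscedastic (B); random intercept
(C), slope (D), quadratic (E) with covariance common across classes;
proportional covariance `G_k = τ_k G₀` with `τ₁ = 1` (F); unrestricted
class-specific covariance with quadratic (G), cubic (H) and quartic (I)
bases — in H and I both the fixed and random effect bases are raised.

Fitting is EM with the class label and random effects as missing data. The
E-step computes responsibilities from the marginal and posterior moments of
the random effects; the M-step updates mixing weights, fixed effects (GLS on
random-effect-corrected responses), `G` (per family: pooled, proportional
via one coordinate update each of `G₀` and `τ`, or free) and residual
variances, all in closed form from the same fixed posterior moments, so the
observed-data log-likelihood is non-decreasing — this is *asserted* on every
iteration, not assumed. Initialization is k-means++ on the raw 24-vectors
(20 restarts by default, all seeded); a restart collapsing a class or a
variance is discarded, and if all restarts collapse the fit is returned
non-converged. Convergence is a relative log-likelihood change below 1e-8 or
500 iterations.

Parameter counts are audited per family (e.g. family A with K classes:
`3K + (K−1) + 1`), and `BIC = −2 logL + p log(N homes)`. Model selection
takes the lowest BIC among converged fits over the family × class-count
grid; if the winner has a class with fewer than 2 modally assigned homes,
the class count is capped below the winner's and the selection repeated —
the search order across families and K is otherwise unspecified in the
underlying framework, so the grid-with-cap is this package's choice. Labels
are canonicalized by descending class size (ties by mean level), making all
outputs invariant to the initial labeling.

## The household simulator

The simulator exists because the cohort's raw streams are not public: it
provides ground truth for every certainty claim. Residents follow
semi-Markov daily routines — seeded wake/sleep times; a morning
bedroom→bathroom→kitchen chain; kitchen meals; scattered bathroom visits;
lognormal room-to-room wandering that visits every room daily; night
excursions (kitchen snack, bathroom trip); and home-level outings through
the door with open/close cycles. Visitors arrive only while a resident is
home, occupy a room of their own and are included in ground truth. Weekly
reports flag overnight-visitor and away weeks; sensor outages silently drop
one motion sensor's events for a day.

Three structural properties make the certainty bounds theorems rather than
tendencies on simulated data: motion bouts stay inside the generating dwell
and end at least one PIR timeout before it (so the delayed `0` lands inside
true occupancy); an awake resident at home is never motionless longer than
~10 minutes, while solo outings in 2-person homes last ≥ 20 minutes and
never overlap (so a no-motion door-to-door episode really means an empty
home); and joint outings share a single door cycle. Consequently measured
room use ≤ true dwell, measured ILSA ≤ true co-occupancy, and measured TOOH
≤ true all-out time on every sensor-intact day — days with an injected
outage are exempt, since deleting motion events can fabricate out-of-home
time, which is precisely why outage days are excluded from analysis.

Group structure follows the study conditions: couples have structurally
lower TOOH (both must leave) and higher ILSA (two movers); effect parameters
add fewer daytime visitors for 1-person MCI homes (lowering their ILSA),
more outings for 1-person MCI homes, fewer for couples with MCI, and more
co-activity and night kitchen use in 2-person MCI homes. `SimScenario.null()`
switches all MCI deltas off for calibration studies. Defaults (e.g. 1.2
outings/day of ~90 min, 0.35 visitors/day in 1-person homes, 10-s PIR
timeout, 0.003/sensor-day outage rate) were chosen once as plausible for
community-dwelling older adults and are all tunable. Pets are available as
optional noise agents and are off by default; a large stationary pet breaks
the TOOH bound in reality and would here too.

What the simulator does **not** emulate: real hardware jitter and missed
detections (detection is deterministic within bouts), multi-door homes
(one egress door), seasonal and weekday/weekend behavioral differences,
and the actual effect magnitudes of the cohort — only directions are
built in, with tunable sizes. Passing tests therefore demonstrate the
pipeline's correctness and calibration under faithful sensor semantics, not
the clinical effect sizes themselves.

## Numerical and calibration choices

Problem sizes in the test and acceptance runs are scaled to what the
properties need: 1000 random streams for grid equivalence, 50 homes × 8 days
for the physics bounds, a 100-home 10-SD two-class fixture for trajectory
recovery, 60 homes × 50 days for effect-direction recovery through the full
pipeline, and 200 simulated null cohorts (24 homes, 5-day summaries) for the
false-positive rate of the MCI and interaction terms, which lands at 5–6%
at α = 0.05. The household-type term is excluded from the null check because
couples genuinely differ in the generator — only the MCI labeling is
exchangeable under the null.
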