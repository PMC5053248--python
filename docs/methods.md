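# Methods

This note records the model as implemented, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, the
numerical choices, and the known limitations. Notation: `tau` is always a
precision (inverse variance); sexes are indexed F then M; age groups are
`1..A` five-year bins with the last open-ended; the rest-of-the-world
aggregate is unit 0.

## Model and assumptions

**Measurement.** Each observed report block — one (origin, destination,
year, reporter) — contributes independent Poisson counts whose log-means
scatter around the log true flow shifted by a block-level interaction
`alpha[o,d,t,k] ~ N(0, precision 0.01)`:

    z ~ Poisson(nu),   log nu ~ N(log m + alpha[o,d,t,k], tau_k).

The log-normal layer adds overdispersion with a reporter-side-specific
precision (`tau_S`, `tau_R`); the interaction absorbs level discrepancies
between reporters (definition and coverage differences) so only the
within-block composition informs the estimand. This makes the Poisson model
an exact respecification of a multinomial model for the block's age–sex
split: conditional on the block total, the counts are multinomial with
probabilities `nu / sum(nu)` (verified by enumeration in the test suite).
Sex-only blocks use the same equations with `m` summed over age *before*
the measurement model (so missing age profiles are inferred from the age
structure of other reporters, not from a reporter-specific aggregate) and
separate precisions `tau_S1`, `tau_R1`. Flows to the rest of the world are
observed only by the sending country, flows from it only by the receiving
country. A block never contributes both forms: sex-only counts are used only
where no full age–sex table exists.

**Level model.** `log m ~ N(da + ds + oa + os, tau_m)` with
destination-age, destination-sex, origin-age and origin-sex effects, each
shrunk towards global age/sex profiles with its own precision
(`da ~ N(a_glob, tau_1)`, `ds ~ N(s_glob, tau_2)`, `oa ~ N(a_glob, tau_3)`,
`os ~ N(s_glob, tau_4)`). Free global profile elements get standard-normal
priors; the youngest age group and the female effect are pinned to zero —
the only hard identifiability constraints. Country effects are left
unconstrained and identified softly through their hierarchical priors; the
rest-of-world unit carries ordinary effect rows. Hyperpriors are
Gamma(10⁻³, 10⁻³) (shape–rate) on `tau_m, tau_S, tau_R, tau_S1, tau_R1` and
Gamma(10⁻², 10⁻²) on `tau_1..tau_4`.

Note there is no global intercept: the overall level of `log m` lives in the
(unconstrained) country effects, and any level error is absorbed by the
block interactions at fit time. Consequently the model identifies
compositions `pi = m / sum m` well, but per-flow *totals* of `m` only weakly
(through the hierarchy). All level-dependent outputs are therefore defined
on the combined product `y[o,d,a,s,t] = pi * y[o,d,t]`, where the marginal
draws `y[o,d,t]` come from an upstream origin–destination model and are
consumed as a plain numeric table. The combination pairs draws by index, so
age–sex sums reproduce each marginal draw exactly.

## Posterior computation

A univariate slice sampler (stepping-out and shrinkage) embedded in a Gibbs
sweep. One sweep updates, in this order:

1. every observed `log nu` (age–sex, then sex-only cells) — cells are
   conditionally independent, so one vectorized slice call updates them all;
2. every `log m`, looping over age groups and vectorizing over
   (flow, year, sex) — within one age group the coordinates are
   conditionally independent even under the sex-only log-sum coupling,
   because that coupling only links different ages of the same block;
3. every block interaction `alpha[o,d,t,k]` (its conditional is quadratic);
4. the four country-effect families, then the free global profile elements
   (all normal conditionals; entries within a family are conditionally
   independent because no two entries of one family enter the same cell);
5. all nine precisions by exact conjugate Gamma draws.

A randomized-scan option permutes the order of these step groups. Slice
tuning: width 1.0, at most 50 step-outs, shared by all blocks — posterior
log-scale conditionals have spread well under 1, so step-outs are rare.

**Initialization** (data-driven, nothing in the estimand depends on it):
`log m` starts at smoothed log observed counts, averaged over the reporters
that saw the block, with sex-only counts split evenly over age and
unobserved cells at the mean of the initialized ones; `log nu` at smoothed
log counts; interactions and effects at 0; precisions at 1. Precisions are
updated *last* in the sweep so their first conjugate draw sees residuals
from already-perturbed states rather than the artificial zeros of the
starting point.

**Chain defaults.** 5,000 sweeps, burn-in half, thinning 10 (250 retained
draws) — the desk-scale defaults used by the tests and the acceptance
script, chosen as the smallest chain whose interval coverage is nominal on
the desk-scale scenario; production-length chains (hundreds of thousands of
sweeps) are a config choice, not a code change. Degenerate conjugate draws
that underflow to exactly zero (possible for a precision with no attached
data under the near-noninformative Gamma) are floored at the smallest
positive float to preserve positivity.

Diagnostics: autocorrelation at chosen lags and cumulative-mean sequences
per monitored scalar, as a table and optional plots.

## Goodness of fit

For every retained draw, reports are re-simulated through the full
measurement chain (log-normal means, then Poisson) for each observed block,
and within-block proportions `zeta_hat` formed; blocks whose simulated total
is zero are undefined for that draw and are dropped from that draw's mean
rather than imputed. The statistic is
`log10(zeta_observed) − log10(mean zeta_hat)` over observed non-zero cells
("common logarithm" read as base 10; a natural-log option exists). The RMS
of the differences estimates their spread, and cells beyond ±3·RMS are
flagged. Zero observed counts are excluded: their log is undefined and they
carry no composition information of their own.

## Summary products

Female-share tables aggregate combined-flow draws per country and direction
(emigration sums over destinations, immigration over origins) and report the
posterior mean with a central 95% interval; period aggregation sums flows
over the period's years before taking shares (flow-weighted) by default,
with a simple mean of annual percentages as an option, since either
convention is defensible. Given raw report tables instead of draws, the same
function returns point percentages from each country's own reports. Age
profiles are per-(flow, year, sex) quantiles of the combined draws, default
deciles and median.

## Synthetic-data generator

The generator is the study design for all testing: it draws hierarchical
effects, true flows, and corrupted double reports from exactly the model
above, so parameter recovery is a well-specified-model experiment. Defaults
(the desk-scale scenario): 6 countries plus rest of world, 18 age groups,
2 sexes, 2 years; hierarchy and level precisions 4 (country effects and
cell-level noise of sd 0.5 on the log scale); measurement precisions 10
(~30% overdispersion, a typical register-vs-survey disagreement scale);
reporter level shifts `alpha` drawn with sd 0.5 and zero mean per side —
shifts of factors up to ~e, matching the magnitude of discrepancies between
permissive ("no time limit") and restrictive ("permanent") national migrant
definitions; 40% of admissible reports missing per side and 20% of the
present reports sex-only, mirroring roughly half of the country-year tables
being unavailable; base flow 100 persons/year per cell before effects. The
shift sd deliberately does *not* reuse the fit-time prior scale (sd 10):
that prior is chosen to be weakly informative for estimation, and shifts of
factor e^±10 would be unphysical as a data-generating mechanism. Global
profiles default to standard-normal draws (matching their prior) and can be
pinned to user-supplied schedules, as the worked example does with a
labour-peak age profile.

One root seed per scenario; every stage (hyperparameters, flows, reports,
marginal draws) uses an independent substream spawned from it, so any stage
is reproducible in isolation and changing, say, the missingness pattern
never changes the truth.

What the generator does **not** emulate: instrument mechanics beyond the
measurement equations (no undercount/coverage machinery, no expert
judgement), duplicate registrations, year-to-year dependence of reporting
practice (shifts are drawn independently per year), or definitional breaks
within a series. Passing recovery tests therefore demonstrates correctness
of inference under the model's own assumptions, not robustness to real-world
misspecification.

## Preprocessing

Rows with unknown origin (or destination) are proportioned across the
observed patterns of the matching stratum — (reporter, year, known margin,
age group, sex) — falling back to the (reporter, year) marginal pattern with
a logged warning when no counterpart exists; rows with both margins unknown
use the joint pattern. Allocation uses largest-remainder rounding with ties
broken by level order, so counts stay integer (the Poisson likelihood
requires it) and per-(reporter, year) totals are conserved exactly. The
stratum choice keeps aggregate reported levels intact while respecting age-
and sex-specific destination patterns where they exist. Assembly then
enforces the single-use rule and rest-of-world sidedness with logged
notices. Age labels ("85+") are presentation-layer config; the model sees
codes `1..A`.

## Numerical choices

- `log z!` via log-gamma; Poisson terms evaluated from `log nu` with the
  exponential clipped at 700 to avoid overflow on extreme slice proposals.
- Block compositions from `log m` by max-subtracted softmax.
- `log(sum_a m)` in sex-only conditionals via logaddexp against the
  age-complement running sum, floored at the smallest positive float.
- Slice shrinkage treats a NaN proposal density as rejection; a non-finite
  conditional at the current point raises a diagnostic error naming the
  block.
- Retained compositions are recomputed per draw and sum to 1 to 1e-10;
  combined tables conserve marginals to machine precision by construction.

## Problem sizes used by the tests

The suite's recovery experiment fits the desk-scale scenario (3,024 latent
flow cells, ~90 observed blocks) with the 5,000-sweep default chain; the
distributional checks use 10⁵ replicates; enumeration checks are exact.
These sizes make the whole suite and the acceptance script each run in a
couple of minutes on one CPU while leaving Monte-Carlo error well below the
asserted tolerances.

## Known limitations

- Flow *levels* of `m` are deliberately only weakly identified; any output
  that needs levels must go through the combined product with marginal
  draws. Summaries computed directly from `m` would inherit essentially
  prior-driven weights across flows.
- Borrowing strength shrinks genuinely extreme countries towards the global
  profile: in simulation, a country whose true sex effect sits far in the
  tail of the hierarchy can miss its aggregate female share by a few
  percentage points even with data present.
- Single-chain inference; between-chain diagnostics are obtained by running
  the CLI repeatedly with different seeds.
- The sampler is univariate; strongly correlated posteriors (e.g. a block
  interaction against its block's mean log flow) mix by alternation, which
  is adequate at desk scale but is the first thing to revisit for much
  larger systems.
- No closed-form marginalization of `nu` (Poisson–log-normal has none); the
  Poisson means stay latent by design.
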