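# Methods

## Data model

A foraging dataset is two tables. The **trial table** has one row per patch
visit: session, subject, environment type (two valence-cued environments
and a social/nonsocial environment), environment index, choice order within
the environment (1–8), symbolic patch type (A/B), travel time (s),
patch-residence time (s, image onset to travel-bar selection or timeout),
and a flag separating by-choice leaves from 15-s timeouts. The **fixation
table** holds half-open `[start, end)` on-image looking intervals in
integer milliseconds from image onset, keyed to trials. Trial times are
seconds, fixation times milliseconds; the conversion lives in one pair of
helpers. Timeout trials are retained in the tables and excluded by the MVT
and patch-leaving analyses. Validation is total: readers raise on
malformed files with the offending column/row named, while
`validate_dataset` reports every cross-table inconsistency (orphan traces,
looking beyond residence) without raising.

## Preference statistics

The contrast ratio CR = (F_A − F_B)/(F_A + F_B) is computed per (session,
environment type). F_A counts **non-negative** selections in the valence
environments and **social** selections in the social/nonsocial
environment; because the symbolic patch type A denotes the negative patch
in valence environments, a preference for negative patches yields CR < 0
there and CR > 0 in the social/nonsocial environment. "Daily" grouping is
mapped to the session identifier. The daily CRs are tested against zero
with a two-tailed one-sample t-test; a zero-variance sample is reported as
infinite t with p = 0 (logged) rather than an error.

Choice-order curves give, per choice number k = 1..8, the cumulative
proportion of each patch type selected out of its four available patches,
averaged over environments; only environments in which all eight patches
were visited enter (a truncated environment's later choice numbers are
undefined). The first-choice test is a Pearson chi-squared
goodness-of-fit of first-choice type counts against 50/50, without
continuity correction. The choice-order distributions are compared with a
two-sample Kolmogorov–Smirnov test on the per-environment cumulative
proportions pooled over environments and choice numbers. Looking times are
compared with a Wilcoxon signed-rank test on per-session per-type means
(rank-sum on raw per-trial totals is available as an option); looking-time
distributions are skewed, so a rank test rather than a t-test is the
default.

## Gain function and the intake-rate surface

Time in patch is tiled by 100-ms bins; a bin is represented by its center.
The **looking-rate curve** is, per bin, the total on-image time across
trials divided by (number of contributing trials × bin width). A trial
contributes to a bin only if its residence covers the whole bin; looking
time in the trailing partially covered bin is dropped along with the bin,
so rates remain proportions of fully observed bins. The **gain function**
g(T) is the running sum of the per-bin mean looking time per contributing
trial, in seconds of looking. Averaging per contributing trial makes g
invariant under replication of the trial set; the value units are
arbitrary since any proportionality constant cancels in the argmax below.

The intake-rate surface is E_n(T, t) = g(T)/(t + T) for travel time t on
the bin grid, under the standard simplifications: zero search cost, zero
travel energy cost, a single effective patch type, constant handling time.
The constant 400-ms handling delay is **not** added to the denominator by
default (it is the same for every choice and does not move the argmax
ordering); a configuration flag can include it. The optimal residence
T*(t) is the grid argmax, smallest T on ties, searched over the full 15-s
window (not only the 0–5 s analysis window; with realistic declining
looking the optimum falls well inside 5 s anyway). For display against
behavior, a 250-ms saccade reaction/movement allowance is added to T*; the
juice-optimal baseline is the travel-independent constant 200 ms (minimum
travel-bar fixation) + 250 ms = 0.45 s.

The MVT prediction is tested by the association between residence and
travel time over by-choice leaves with residence within the 0–5 s analysis
window (looking behavior is essentially over by 5 s; later leaves are
dominated by disengagement). Kendall's tau-b is used because the discrete
travel-time schedule guarantees massive ties; the p-value is one-tailed
for positive association. The slope is ordinary least squares of residence
on travel time with its two-sided p.

## Patch-leaving models

The **leave profile** at one travel time is the proportion of by-choice
leaves falling in each 100-ms bin of the 0–5 s window; the denominator is
all by-choice leaves at that travel time, so the profile mass equals the
in-window share and is ≤ 1. The **value profile** r(t) is the on-image
looking time summed over all trials per bin (no per-bin denominator, hence
no bin-coverage clipping), normalized to a maximum of 1. Max-normalization
fixes the scale the linear models would otherwise absorb into b₁ and makes
the hyperbolic discount parameter identifiable within a travel-time
condition. The value profile is shared across travel times; the leave
profile is rebuilt per travel time.

Four models of the per-bin leave probability are fitted, with t the
bin-center time in seconds:

| model            | P_leave(bin)               | K |
|------------------|----------------------------|---|
| value and time   | b₀ + b₁r + b₂t + b₃t²      | 4 |
| time only        | b₀ + b₁t + b₂t²            | 3 |
| value only       | b₀ + b₁r                   | 2 |
| hyperbolic       | r/(1 + k·travel)           | 2 |

Linear models are ordinary least squares (predictions not clipped to
[0, 1]; no link function is imposed). The log-likelihood for every model is
the Gaussian density with maximum-likelihood variance,
LL = −(n/2)(ln(2π·σ̂²) + 1), σ̂² = RSS/n — with 50 bins and RMSE near 0.01
this puts LL in the 130–175 range. K counts the mean-structure
coefficients for the linear models (the residual variance is deliberately
not counted, which keeps AIC = −2·LL + 2·K consistent with the published
table this pipeline reproduces); the hyperbolic K = 2 counts the discount
parameter plus the residual scale. The hyperbolic fit is exact: with
travel fixed, r/(1 + k·travel) = c·r is linear in c = 1/(1 + k·travel), so
the RSS-minimizing c has a closed form and the bound k ≥ 0 corresponds to
clipping c to (0, 1]; a profile anti-correlated with r drives k to a
documented cap rather than an error. Models are ranked by AIC, Akaike
weights w_i ∝ exp(−ΔAIC_i/2), and pairwise relative likelihoods w_i/w_j
(infinite ratios from zero weights are flagged, not raised). A
rank-deficient design (e.g. a constant value profile) is a per-model fit
error; the remaining models are still fitted and compared, with the
failures annotated.

### A structural identity worth knowing

Within a single travel-time condition the hyperbolic model's mean
structure {c·r : c ∈ (0, 1]} is a strict subset of the value-only model's
{b₀ + b₁·r}, and both carry K = 2. Consequently LL(value-only) ≥
LL(hyperbolic) on *every* dataset, with equality only on a measure-zero
set, and the hyperbolic model can never attain the largest Akaike weight —
including on data generated by a hyperbolic-discounting agent, which the
comparison attributes to the value-only model instead. This is a property
of the model set as defined, not of any particular dataset; the
model-recovery experiment reports the hyperbolic condition's (necessarily
zero) recovery rate rather than hiding it, and policy separation is
instead established by the *difference* in winners between hazard-rule and
hyperbolic-rule data.

## Synthetic sessions

The generator emulates the task's structure: environments of four A and
four B patches visited sequentially, the next patch being of type A with
probability `preference_prob_A` (0.7 by default) while both types remain; a
travel time drawn uniformly from {1, 3, 5, 7} s per visit; a 70-s time
budget per environment (handling + residence + travel); a 15-s viewing
window. On-image looking is a per-ms Bernoulli process (mirroring 1-kHz
eye tracking) with probability p(t) = p₀·exp(−t/τ), p₀ = 0.9, τ = 1.3 s —
an exponential stand-in for the observed steep early decline of image
fixation, under which looking is essentially over by 5 s and the implied
gain p₀τ(1 − e^(−T/τ)) is concave, as MVT requires. Runs of 1s are
run-length encoded into intervals.

Residence times come from one of four policies. The **hazard** policy
walks the 100-ms bins and leaves at the first bin whose Bernoulli with
probability b₀ + b₁r(t) + b₂t + b₃t² (clamped to [0, 1]) fires, with r(t)
the analytic normalized value profile; the **hyperbolic** policy uses
r(t)/(1 + k·travel) the same way; if no bin fires within 15 s the trial is
a timeout. The **mvt_threshold** policy returns the grid argmax of
g(T)/(t + T) for the generator's own analytic gain plus Gaussian jitter
(SD 0.5 s, truncated to (0, 15] by rejection) — Gaussian jitter is a
stand-in, as the distribution of real residence noise is unknown. The
**juice_max** policy returns the constant 0.45 s. Leaves are placed
uniformly within the firing bin. Everything is reproducible from the seed.

The default hazard coefficients (0.012, 0.06, 0.005, 0.0005) were chosen
so that the share of by-choice leaves within 0–5 s (~0.87–0.9) falls in
the 78–89% range reported for this task, with genuine value and time
contributions.

What the generator does **not** emulate: the fine structure of real
looking-rate profiles (real profiles are not smoothly exponential, which
makes the value and time regressors *less* collinear in real data than
here — the synthetic setting is conservative for separating them);
serial dependence across visits; subject heterogeneity beyond per-run
parameter overrides; saccade kinematics and off-image gaze. Passing tests
therefore demonstrate correctness and calibration of the estimators and
the model-selection machinery, not that any particular biological
population obeys a given policy.

## Validation experiments and problem sizes

Because a specific subject pool's statistics require that pool's data, the
pipeline is validated on data with known generating processes
(`patchforage.experiments`, reused by `scripts/acceptance.py`):

* **Type-I error**: the one-tailed Kendall test (1000 null datasets of 200
  visits) and the first-choice chi-squared test (1000 datasets of 100
  environments) reject at the nominal 5% within Monte-Carlo tolerance.
* **MVT pipeline recovery**: 1000 visits from the mvt_threshold policy
  give τ > 0 at p < 0.05, and recomputing the intake-rate optima from the
  generator's own gain reproduces the generating T*(t) exactly (same grid,
  same tie-break — an end-to-end consistency check of the surface code).
* **Model recovery**: 100 replicates of ~800 visits per generating model;
  the winner is the model with the lowest AIC summed across the four
  travel-time fits (summing the independent per-travel comparisons is the
  joint ranking and is more stable than any single travel time). The
  generating coefficient sets keep per-bin leave probabilities in the
  mild-survival-decay regime where the generating bin-wise probability and
  the fitted bin-wise proportion nearly coincide (a leave *proportion*
  profile equals hazard × survival; large hazards would make every
  fitted model misspecified in a way that favours the most flexible one),
  while keeping each generating term identifiable at this sample size. The
  hyperbolic condition's recovery rate is structurally zero (see the
  identity above).
* **Hyperbolic k recovery**: on noiseless profiles constructed as
  r/(1 + k·travel) the closed-form fit returns k exactly (a faster value
  decay, τ = 0.6 s, keeps the constructed profile's mass ≤ 1).

These sizes (50 bins, 100–125 environments ≈ 800–1000 visits, 100–1000
replicates) are the package's chosen experiment scales; they put LL, AIC
and RMSE in the magnitude regime of the published comparison table.

## Numerical conventions and degenerate inputs

Half-open `[start, end)` intervals make bin assignment unambiguous;
adjacent intervals are merged on construction, overlaps rejected. Grid
argmaxes break ties toward the smallest residence. Akaike weights are
computed from ΔAIC, making them invariant to AIC shifts. The t-test on
zero-variance CRs, the KS test on identical samples (D = 0, p = 1), the
signed-rank test on all-zero differences (p = 1) and zero Akaike weights
in relative likelihoods (infinity, flagged) are handled as logged
conventions rather than errors. Exact interpolation (RSS = 0) reports
infinite LL; the AIC comparison then degenerates and is left to the
caller, as it only arises on constructed data. The flat key:value config
format rejects unknown keys so typos cannot silently change an analysis.

## Known limitations

The CSV dialect and column names are package conventions (no standard
serialization exists for this kind of data). The per-bin proportion, not a
conditional hazard, is what the leaving models fit — faithful to the
published analysis but statistically ad hoc; a binomial likelihood on bin
counts or a discrete-time survival model would be the principled
alternative and is out of scope. Emotional-expression subcategories
(threat vs. fear, coo vs. lipsmack) are not modelled; patch geometry is
metadata only. The value-profile normalization ("frequency of looks")
admits more than one reading; summed looking time per bin, max-normalized,
is the implemented one, and any monotone reweighting leaves the model
ranking machinery unchanged.
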