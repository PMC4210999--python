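# Methods

## Model and assumptions

Daily exposure is the time-weighted average over microenvironments (MEs),
`E = Σᵢ Cᵢ·Tᵢ`, with concentration `Cᵢ` in pt/cm³ and time fraction `Tᵢ`
of the 24-h day. The model assumes a homogeneous concentration within each
ME, and statistical independence of all inputs — between time and
concentration, and across MEs. No covariance structure is modelled because
none is available at the summary-moment level the inputs come in; note that
this ignores real constraints (a long work day shortens home time) beyond
what the moments themselves encode.

Input uncertainty is parametric:

* time fractions: `Beta(α, β)` with `ν = m(1−m)/s² − 1`, `α = mν`,
  `β = (1−m)ν`, valid when `s² < m(1−m)`. A zero SD or a boundary mean
  (0 or 1) yields a point mass. Infeasible printed pairs (rounded SDs can
  violate the bound) raise by default; an explicit `clamp` policy shrinks
  the SD to 0.95 of the bound and flags the fit — inputs are never altered
  silently.
* concentrations: `Lognormal(μ, σ)` with `σ² = ln(1 + (s/m)²)`,
  `μ = ln m − σ²/2`; every positive pair is feasible. The lognormal
  variance is evaluated with `expm1` so the fit/moments round trip holds to
  1e-9 relative even at coefficients of variation near 1e-6.

Both fits are exact in the first two moments, so `moments_of(fit(spec))`
returning `spec` is an identity the test suite asserts, not an
approximation.

## Sampling

Latin hypercube sampling, default 2000 iterations (configurable): each
parameter column receives exactly one uniform draw from each stratum
`[i/n, (i+1)/n)`, independently shuffled, then inverse-CDF transformed.
Column substreams derive from `SeedSequence([master_seed, column_index])`
with a fixed parameter order — the 11 time fractions first, then the 11
concentrations, MEs in the fixture row order — so results are reproducible
from one integer and independent of dict ordering. In a multi-scenario
study, per-scenario seeds derive from `SeedSequence([master, scenario
index])` truncated to 31 bits. Stratification removes the between-stratum
variance of every input's main effect; for the product `T·C` the residual
Monte Carlo error is dominated by the interaction term with standard
deviation `σ_T·σ_C`, roughly 1–2% of the in-transit means at n = 2000 and
much less for the indoor-dominated total.

Time fractions are **not** renormalised to a strict 24-h budget per
iteration by default: the published per-ME mean exposures sum exactly to
the published totals, which holds only without renormalisation (the printed
male fraction means sum to 1.01, the female to 0.98). A
`renormalize_time` flag divides each iteration's fractions by their sum for
users who want a hard budget; this changes means by O(1%).

## Summaries and conventions

Per ME and per cumulative category (in-transit, indoor, outdoor, total):
mean, SD with the n−1 denominator, min, max, and p5/median/p95 by linear
interpolation between order statistics (numpy's default). The percentage
contribution is `100·mean(column)/mean(total)`. The sources are silent on
both conventions; these are documented choices.

## Packaged study inputs

The fixtures transcribe the published Milan tables cell for cell: 11 MEs ×
2 seasons of concentration moments (the motorbike/scooter winter row equals
summer, as published — it was an indirect estimate), male and female
time-fraction moments, and cumulative-level published results for the age,
employment and education subgroups. Those subgroup records are reference
data only: their per-ME diaries were never published, so they cannot be
re-simulated — the engine works with any user-supplied per-ME profile CSV.
A `mean_subject` profile transcribes the population-level time-use column
of the concentration table (divided by 100 from daily percent, no SDs
printed so the entries are point masses). That column is internally
inconsistent with the per-gender diaries (e.g. work-indoor 0.5% vs 24–29%),
so it ships for completeness and is avoided by every reproduction target.

## Statistical comparisons

Mann-Whitney U (two-sided, tie-corrected; exact enumeration with
average-rank tie handling for pooled n ≤ 20, normal approximation with
continuity correction above — scipy's exact path does not correct for
ties, hence the in-house enumeration at small n), Kruskal-Wallis
(chi-square, k−1 df; all-tied data returns H = 0, p = 1), Spearman rank
correlation (t-approximation; constant vectors are an error), and factorial
ANOVA over scenario means with Helmert-coded contrasts and Tukey HSD
post-hoc (statsmodels; balanced designs only; a constant response returns
F = 0, p = 1). The default grouping unit is scenario-level means: with
thousands of iteration draws per scenario any contrast is "significant", so
draw-level reports are labelled as such.

## Nominal-range sensitivity

One input at a time — each ME's mean time fraction and mean concentration —
is moved to a low and a high probe (default: the p5/p95 of its fitted
distribution; overridable per input) while its SD, every other input and
the sampling plan stay at base; the report is the signed % change of the
mean total. Because the model is bilinear and the same LHS matrix is
reused, a zero-width probe reproduces the base run exactly and, with
degenerate inputs, the % change is exactly proportional to the
perturbation. Probe refits of time fractions use the clamp policy: an
extreme probe mean combined with the base SD can violate the beta variance
bound. Probed profiles skip the fractions-sum validation since probing a
large ME deliberately breaks the 24-h budget.

## Synthetic diaries

The generator emulates the structure of the real inputs: per subject-day,
beta time fractions renormalised to sum to exactly 1 (a real day has 24 h)
and lognormal concentrations i.i.d. across days, optionally averaged over
several records per day. It does **not** emulate temporal autocorrelation,
within-subject habit persistence, instrument noise, or indoor source
events; passing recovery tests therefore show the pipeline's statistical
machinery is correct, not that the parametric families fit real Milan
diaries. Per-row renormalisation deliberately differs from the engine's
default (see above); it leaves fraction means nearly unbiased when the
generating means sum to ≈1 (bias < 1% in the test spec) but inflates the
SD of large-share MEs — for the male home-indoor fraction the renormalised
SD is ≈0.091 against a generating beta SD of 0.08 — so SD-recovery checks
compare against a large reference cohort from the same generator rather
than the raw beta SD.

## Problem sizes and numerical choices

Defaults follow the study conditions: 2000 LHS iterations per scenario;
recovery tests use 2000 subject-days (200 subjects × 10 days) and a
20-cohort unbiasedness check at 300 subject-days each. Tolerances: 1e-9
relative for moment round trips and conservation identities; 3 Monte Carlo
standard errors for expectation-factorisation checks; 5% for reproduction
of published means. Fraction sums are validated to 1 ± 0.05 to absorb the
rounding of printed moments.

## Known limitations

Independence of all inputs is the strongest assumption; it matches the
information content of the inputs but not reality. The per-ME summaries for
the 26 published subpopulations are unavailable, so only the gender
profiles are re-simulable end to end. Concentrations are season-stationary
within a scenario (no diurnal structure), and dose (inhalation,
deposition) is out of scope: outputs are exposure concentrations, not
intake.
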