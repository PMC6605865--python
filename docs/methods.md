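# Methods

## Design being analyzed

A randomized, two-arm (after lot pooling), three-sub-cohort pediatric trial
of a second MMR dose. Children are randomized 6:1:1 to MMR-RIT, MMR II lot 1
or MMR II lot 2 in permuted blocks of 8; the two comparator lots are pooled,
giving a 3:1 analysis ratio. Sub-cohort 1 (USA only) co-administers DTaP-IPV
and varicella vaccine and carries the full 12-antigen assay panel; sub-cohort
2 (USA, South Korea, Taiwan) receives MMR alone with the three MMR assays;
sub-cohort 3 contributes safety follow-up only. Immunogenicity endpoints are
evaluated on the according-to-protocol (ATP) cohort — vaccinated, eligible,
protocol-compliant subjects with a Day-42 result for at least one MMR
component; safety is tabulated descriptively on the total vaccinated cohort.

Subjects with a post-vaccination result for some antigens but not others are
handled with per-endpoint complete-case denominators: a subject enters each
endpoint's numerator/denominator only when that endpoint's required
concentrations are present. Seroresponse needs only the post value; booster
and ANCOVA endpoints need the complete (pre, post) pair. This reproduces the
endpoint-to-endpoint variation in evaluable N seen in practice.

## Response rules

All rule comparisons are inclusive (`≥`), so boundary equality counts as a
response. Two readings of the tiered pertussis rule were possible and are
resolved as follows: "4 times above the assay cut-off" is read as `4·c`
(parallel to the seronegative tier's criterion), and a baseline concentration
exactly equal to `4·c` falls in the high-positive tier (the tier whose
definition is explicitly inclusive). Concentrations are classified as
provided — below-cutoff imputation applies only to geometric-mean analyses,
never to responder classification.

## Rate statistics

Single-group rates: Clopper–Pearson exact intervals by beta-quantile
inversion (`x = 0` pins the lower bound at 0, `x = n` the upper at 100%).

Between-group differences: the score interval with variance at the
constrained MLE. For a hypothesized difference δ the constrained MLE
(p̃₁, p̃₂) solves a cubic, computed in closed form by the trigonometric
method; the variance `p̃₁q̃₁/n₁ + p̃₂q̃₂/n₂` is multiplied by the
Miettinen–Nurminen factor `N/(N−1)` by default (the uncorrected Mee form is
available via `corrected=False`). Which variant the original SAS analysis
used is not documented; the corrected form is the default because it
reproduces the published boundary-case bounds to the printed 2 decimals —
including the case where the two variants differ (lower bound −0.72 vs
−0.71 for 698/698 against 250/250). Confidence bounds are located by Brent
root-finding on the monotone score statistic, brackets `[−1, p̂₁−p̂₂]` and
`[p̂₁−p̂₂, 1]`, tolerance 1e-10 on the proportion scale; degenerate
boundary cases (e.g. 0/N vs N/N) return the natural ±1 limits.

Rounding is a display concern only: rates to 1 decimal, differences and
bounds to 2, half-away-from-zero. Margin decisions always use unrounded
bounds.

## Geometric means and ANCOVA

Concentrations are modelled log10-normally. Log base is irrelevant to
ratios; base 10 follows titer convention. Values below the assay cut-off are
imputed at half the cut-off before log transform — a standard serology
convention that is essentially inert at this trial's near-ceiling titers.
The adjusted GM ratio comes from OLS of `log10(post)` on a group indicator,
`log10(pre)`, and (only where the endpoint specifies it, i.e. the
multi-country MMR-alone sub-cohort) a fixed-effect country categorical; the
CI is `10^(β ± t·SE)` with residual degrees of freedom from the full design.
Adjusted GMs are reported at the grand mean of the covariate columns; the
ratio is invariant to that evaluation point, the adjusted GMs are not.
Omitting the baseline covariate reduces the estimator exactly to the ratio
of unadjusted GMs, which the tests exploit as a closed-form limit.

## Objectives and gatekeeping

Four co-primary objectives (SRR difference and adjusted GMC ratio for the
MMR antigens, in each of sub-cohorts 1 and 2) are tested in parallel at
two-sided 97.5% — a Bonferroni split of 2.5% across the two sub-cohorts
implemented, as in the trial's tables, by fixed 97.5% CIs rather than
p-value splitting. Margins: −5 percentage points for MMR/VZV rate
differences, −10 for DTaP booster rates, 0.67 for GM ratios. An objective
node is met only if every listed antigen clears the margin.

Secondary objectives (VZV seroresponse + GMC, DTaP booster rates, polio GMT
ratios, pertussis GMC ratios) are formally assessed only when all primaries
succeed. The published objective list does not state an ordering among the
secondaries, so the default gate conditions each secondary on the primaries
only; a strict fixed-sequence mode (`gate_mode="sequential"`, ordered by
`order_index`, overridable in the objectives config) is provided. The
varicella objective jointly requires its rate and ratio criteria and is held
as two consecutive nodes, so the default tree has nine nodes representing
the eight objectives; overall success (every node evaluated and met) is
equivalent either way.

## Synthetic-data generator

What it emulates: arm sizes (1100/1099/1808 with 6:1:1 blocks), country mix,
bivariate log-normal (pre, post) per antigen with configurable correlation
(default 0.5), ATP attrition as independent Bernoulli non-compliance
(default 10%), small independent missingness in pre (1%) and post (0.5%)
results, and per-category Bernoulli adverse events at roughly the observed
incidences. Post-vaccination GMs default to the published Day-42 values of
the co-administration sub-cohort and pre-vaccination GMs to the middles of
the published ranges; both arms share one distribution, so the true ratio is
1 and true rate differences are 0. Near-ceiling response rates arise from
the log-normal tail rather than a responder mixture; the implied default
seroresponse probabilities are ≥ 99.99% (measles/mumps), ≈ 99.996%
(rubella), and the implied booster rates land near the published ones (e.g.
TT ≈ 94%, DT ≈ 99%) through the choice of unpublished pre-vaccination GMs
(TT 0.8, DT 0.35, PT 8, FHA 25, PRN 30 IU/mL) — conventions, stated here
once, not fitted quantities.

`response_rate_override` replaces a subject's post value with a
rule-failing one with probability 1 − target, per arm if a pair is given;
`rit_post_gm_ratio` scales the test arm's post GM. These exist to place the
generative truth exactly on or beyond a margin for operating-characteristic
studies and gate-failure tests.

What it does not emulate: lot-to-lot variation (lots were pooled), visit
scheduling, informative dropout, assay censoring/quantitation limits beyond
the log-normal support, within-subject correlation across antigens (draws
are independent across antigens), AE temporal profiles, and any
country-by-arm interaction. Passing end-to-end tests therefore demonstrates
the statistical machinery under the trial's stated design assumptions, not
robustness to violations of them.

## Numerical and testing choices

- Bivariate normals are drawn via an explicit 2×2 Cholesky construction,
  exact at correlation ±1 (the degenerate case is used as a test).
- Score-CI root-finding tolerance 1e-10; Clopper–Pearson via
  `scipy.stats.beta`; ANCOVA via `statsmodels` OLS.
- Independent oracles in the test suite: tail-probability bisection for the
  exact interval (all x, n ≤ 30); a constrained-likelihood grid search
  (delta in 1e-6 steps, golden-section likelihood maximization) for the
  score interval; explicit case enumeration for the booster tiers (10,000
  random pairs per family plus exact boundaries).
- Monte Carlo problem sizes: 500 replicates at n = 690/245 for ANCOVA
  calibration (bias, coverage, declaration rate at the 0.67 margin); 2,000
  binomial replicates at n = 700/250 for score-CI coverage and rate-margin
  type-I error; 100 full-trial replicates (≈ 4,000 subjects each) for
  end-to-end gatekeeping. These sizes put sampling error well inside the
  asserted tolerances.
- Power simulation spawns independent child seeds from a root
  `SeedSequence`, so results are reproducible given the seed and replicates
  are independent.

## Known limitations

- The trial's published global power figure (93%) rests on unpublished
  generative assumptions; `simulate_power` is validated only against
  analytically forced regimes (near-certain success, alternatives firmly
  outside the margin, truth pinned at the margin).
- Adjusted-GM point values depend on covariate evaluation; comparisons of
  adjusted GMs (not ratios) across software require matching that choice.
- The ANCOVA error degrees of freedom include all fitted country levels in
  pooled analyses; alternative df conventions would change bounds only in
  the third decimal at these sample sizes.
- Eligibility and protocol compliance are consumed as input flags; the
  clinical inclusion/exclusion logic that produces them is out of scope.
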