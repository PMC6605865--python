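# immunoninf

Non-inferiority analysis of vaccine immunogenicity trials, built around the
design of a phase III second-dose MMR trial (ClinicalTrials.gov NCT01621802)
comparing MMR-RIT against MMR II with and without DTaP-IPV and varicella
vaccine co-administration.

The package is for biostatisticians and trial methodologists who need the
full confirmatory pipeline as tested, reusable code: response classification,
interval estimation, margin decisions, multiplicity gatekeeping, and trial
simulation — rather than a one-off SAS program.

## What it computes

**Response classification.** Seroresponse is `post ≥ θ` for fixed antigen
thresholds (anti-measles 200 mIU/mL, anti-mumps 10 EU/mL, anti-rubella
10 IU/mL, anti-VZV 75 mIU/mL), ignoring baseline. Booster response for the
pertussis antigens is tiered on the assay cut-off *c*: `post ≥ 4c` when
`pre < c`, `post ≥ 4·pre` when `c ≤ pre < 4c`, and `post ≥ 2·pre` when
`pre ≥ 4c`; for DT/TT: `post ≥ 0.4 IU/mL` when `pre < 0.1 IU/mL`, else
`post ≥ 4·pre`. All comparisons are inclusive.

**Rate differences.** The "standardized asymptotic" CI for
Δ = p₁ − p₂ is the score interval: the set of δ with

    |p̂₁ − p̂₂ − δ| / √(Ṽ(δ)) ≤ z,   Ṽ(δ) = [p̃₁q̃₁/n₁ + p̃₂q̃₂/n₂]·N/(N−1)

where (p̃₁, p̃₂) are the MLEs constrained to p₁ − p₂ = δ
(Miettinen–Nurminen). It stays informative at observed rates of 0% or 100%,
where Wald intervals collapse. Non-inferiority: lower bound ≥ margin
(−5 or −10 percentage points).

**Geometric-mean ratios.** ANCOVA on log₁₀ concentration,
`log10(post) ~ group + log10(pre) [+ country]`; the exponentiated group
coefficient is the baseline-adjusted GMC/GMT ratio with a t-based CI.
Non-inferiority: lower bound ≥ 0.67.

**Multiplicity.** Bonferroni across the two immunogenicity sub-cohorts
(realized as fixed two-sided 97.5% CIs) and hierarchical gatekeeping: the
four secondary objectives are assessed only if all four co-primary
objectives succeed.

**Simulation.** A calibrated synthetic-trial generator (6:1:1 blocked
randomization pooled 3:1, correlated bivariate log-normal titers,
non-informative ATP attrition, Bernoulli adverse events) drives end-to-end
power and type-I-error estimation.

## Worked example

```python
from immunoninf import score_diff_ci, decide_noninferiority

# sub-cohort 1 anti-measles seroresponse: 697/697 vs 249/249 responders
ci = score_diff_ci(697, 697, 249, 249, level=0.975)
print(f"diff {ci.diff_pct:.2f} pp, 97.5% CI ({ci.lower_pct:.2f}, {ci.upper_pct:.2f})")
print("non-inferior at -5pp margin:", decide_noninferiority(ci, -5.0).met)
```

prints

```
diff 0.00 pp, 97.5% CI (-0.72, 1.98)
non-inferior at -5pp margin: True
```

Both observed rates are 100%, yet the score interval is non-degenerate: its
lower bound −0.72 clears the −5 point margin, so non-inferiority holds.

The whole pipeline from the command line:

```bash
immunoninf synth --seed 17 --out trial.csv        # 4007 synthetic subjects
immunoninf analyze --subjects trial.csv --out-dir run/
# -> overall non-inferiority success: True (9 of 9 nodes met)
immunoninf power --reps 100 --seed 1              # global success probability
```

`run/` contains per-endpoint response rates, score-CI rate differences,
ANCOVA ratios, the gatekeeping verdict, safety incidence tables with exact
95% CIs, and a manifest with input checksums.

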