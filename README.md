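# mateguard

Sexually experienced male *Drosophila melanogaster* copulate for a shorter
time than naive males ("shorter-mating-duration", SMD). This package
implements the computational core of that finding for behavioral
ecologists and fly neurogeneticists: a marginal-value-theorem (MVT)
cost–benefit model of post-ejaculatory mate guarding that makes the
shortening interpretable as adaptive time investment, the full statistical
battery used on mating-duration assays, fecundity/paternity accounting for
sperm-competition experiments, and seeded generators that emulate the
study's datasets so the whole pipeline is testable end to end.

## The model and the statistics

Guarding for time *t* secures eggs with diminishing returns while costs
accrue linearly:

    B(t) = (1/α)(1 − exp(−βt)),   C(t) = (γ/e)·t,   maximise N(t) = B(t) − C(t)

with α the inverse of the total securable clutch, β the benefit-accrual
rate and γ the cost parameter. The interior optimum is
t\* = (1/β)·ln(e·β/(α·γ)); guarding exceeds one benefit time constant for
γ ≤ β/α and ceases entirely at γ = e·β/α, so the regime classifier's
windows (below β/α, between β/α and e·β/α, above e·β/α) coincide with the
optimum's qualitative transitions. Shorter mating is predicted whenever a
naive→experienced parameter shift strictly lowers t\*.

The assay statistics mirror the study's battery: the one-hour inclusion
filter, percent-reduction effect sizes, pooled-variance Student's t with
star annotation, Lilliefors-corrected KS normality/lognormality checks,
Kruskal–Wallis with Dunn's Bonferroni-adjusted post hoc (hash marks),
bootstrap estimation statistics (mean difference with 95% CI from 5,000
resamples), courtship index, locomotion velocity, CaLexA GFP normalised to
autofluorescence, and egg/progeny ratios plus sepia-marker paternity shares
for two-sire crosses. See `docs/methods.md` for assumptions and defaults.

## Worked example

```python
from mateguard.guarding import GuardingParams, optimal_guarding_time, predict_smd, classify_regime
from mateguard.simulate import AssayDesign, generate_md_assay
from mateguard.stats import compare_experiment

naive = GuardingParams(alpha=1.0, beta=1.0, gamma=2.0)
print(classify_regime(naive), optimal_guarding_time(naive).t_star)
pred = predict_smd(naive, GuardingParams(alpha=1.0, beta=1.0, gamma=2.5))
print(pred.scenario, round(pred.delta_t_star, 3), pred.smd_predicted)

table = generate_md_assay(AssayDesign(percent_reduction=15.7, seed=1))
comparison, estimation = compare_experiment(table, reference="naive", seed=1)
print(f"{comparison.percent_reduction:.1f}% {comparison.stars} "
      f"CI [{estimation.ci_low:.0f}, {estimation.ci_high:.0f}] s")
```

prints

```
scenario_C_window 0.30685281944005466
C_gamma_larger -0.223 True
10.0% * CI [-237, -14] s
```

i.e. γ = 2 lies in the middle cost window with an optimal guarding time of
0.31 benefit time constants; raising γ to 2.5 shortens it by 0.22 (SMD
predicted); and one synthetic assay at the study's group size of 36
recovers a 10.0% reduction (the configured 15.7% ± realistic sampling
noise), significant at p < 0.05, with the bootstrap CI of the
experienced-minus-naive mean difference excluding zero. At n = 1000 per
group the recovered reduction lands within a fraction of a percentage point
of the configured truth (see `scripts/acceptance.py`).

The numbered scripts under `analysis/` run the study-style analyses in
order (simulate → per-strain comparisons → exposure-time Kruskal–Wallis →
fecundity/paternity → guarding model) and write their tables under
`results/`. A `mateguard` CLI exposes the same stages
(`simulate`, `analyze`, `analyze-fecundity`, `analyze-paternity`, `model`,
`run`, `demo`).

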