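# cutcost

Cost-aware selection of cut-offs on diagnostic markers.

## The problem

Clinical tests need a threshold *c*: subjects scoring ≥ *c* are called
positive. The most popular automatic rule maximizes **Youden's index**

    J_c = SE_c + SP_c − 1

over candidate cut-offs, and it is widely described as cost-neutral and
prevalence-free. Neither is true. In expected-cost decision theory one
summarizes the stakes of the four classification outcomes by a single
**cost ratio** r ∈ [0, 1] — the share of total stakes attached to
diseased subjects — and maximizes the rescaled expected cost

    EC′_c = P·SE_c·r + (1 − P)·SP_c·(1 − r),

equivalently operates where the ROC slope equals (1 − P)(1 − r)/(P·r).
Kraemer's weighted kappa κ(r) is the chance-corrected version of the
same criterion:

    κ(r)_c = (TN_c·TP_c − FN_c·FP_c) / (r·P·(1 − Q_c) + (1 − r)·(1 − P)·Q_c),

with cells as proportions, Q the fraction testing positive and P the
prevalence. The algebraic fact this package is built around:

    κ(1 − P)_c = J_c   for every 2×2 table,

so maximizing J *is* decision theory — with the implicit,
prevalence-dependent cost ratio **r = 1 − P**. At 25% prevalence a
J-optimal cut-off silently values one missed diseased subject as three
misclassified healthy ones; move the same test to a 75%-prevalence
clinic and the implied valuation inverts. `cutcost` computes J, EC,
EC′, κ(r) and the (prevalence-free, hence cost-blind) log odds ratio at
every cut-off, and always reports the cost ratio a chosen criterion
assumes, so the assumption can be audited instead of inherited.

Audience: biostatisticians and clinical-test developers choosing or
reviewing operating points on continuous markers.

## Worked example

The package bundles two 120-subject single-threshold tables sharing
SE = 0.8 and SP = 0.4 at prevalences 25% and 75%:

```sh
python -c "
from cutcost import scenario_profile, write_profile
write_profile(scenario_profile('prev25'), 'prev25.tsv')"
cutcost --input prev25.tsv --kind tables --cost-ratio 0.5 --out out --verbose
```

prints

```
prevalence P = 0.250000
cost ratio r used for kappa/EC' = 0.500000
implicit cost ratio of a Youden-J choice (1 - P) = 0.750000
WARNING: maximizing J assumes r = 0.750000, which differs from the requested r = 0.500000 by more than 0.05; a J-optimal cut-off is not optimal under your stated costs
max_j: chosen threshold c* = 1, optimum value = 0.200000
max_kappa at r = 0.500000: chosen threshold c* = 1, optimum value = 0.130435
max_ec_prime at r = 0.500000: chosen threshold c* = 1, optimum value = 0.250000
```

Reading: the table's J is 0.2 and its κ at the user's symmetric costs
(r = 0.5) is 0.130. The same (SE, SP) at 75% prevalence gives the same
J = 0.2 but κ(0.5) = 0.2 — J cannot see the difference because it
re-prices the errors as the prevalence moves, which is exactly what the
warning line surfaces. Per-threshold values land in `out/report.tsv`,
the selection summary in `out/summary.txt`, run metadata in
`out/run.log`.

The library surface mirrors the CLI: `profile_from_scores`,
`select_threshold`, `weighted_kappa`, `implicit_cost_ratio_of_j`,
`binormal_optimal_threshold`, `empirical_roc` / `auc`, and the
generators `binormal_sample` / `matched_prevalence_pair`.

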