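# Methods

## Model and conventions

A diagnostic marker is summarized, at each candidate cut-off *c*, by a
2×2 table of test outcome against disease state. Subjects with score
≥ *c* are positive; ties at the cut-off are positive. Counts are the
canonical representation and proportions a derived view, so repeated
re-weighting cannot accumulate rounding error. From each table we
derive SE (sensitivity), SP (specificity), P (prevalence) and Q (the
level, i.e. the fraction positive), linked by
Q = SE·P + (1 − SP)(1 − P).

Costs and benefits are stored as four non-negative magnitudes
(b_tp, b_tn, c_fp, c_fn); expected cost adds costs and subtracts
benefits on the proportion view. The scalar cost ratio is

    r = (b_tp + c_fn) / (b_tp + c_fn + b_tn + c_fp),

the diseased-subject share of the total stakes. This is the standard
ratio of cost *differences* evaluated with costs entered as negative
utilities; it is the unique reduction for which minimizing expected
cost and maximizing its rescaled form

    EC′ = P·SE·r + (1 − P)·SP·(1 − r) = TP·r + TN·(1 − r)

select the same cut-off — a property the test suite brute-forces over
1000 random profile/cost pairs rather than assumes.

## The central identity

Kraemer's weighted kappa

    κ(r) = (TN·TP − FN·FP) / (r·P·(1 − Q) + (1 − r)·(1 − P)·Q)

(cells as proportions) satisfies κ(1 − P) = J = SE + SP − 1 for every
table. Both the cell form and the equivalent SE/SP/Q rewriting
P(1 − P)(SE + SP − 1)/(r·P + Q·(1 − r − P)) are implemented and must
agree to 1e-12; the identity itself is property-tested to 1e-10 over
1000 randomized tables. κ(r) lies in [0, 1] whenever J ≥ 0 (also
property-tested); tables with J < 0 — markers oriented the wrong way —
are outside that guarantee and are surfaced as ordinary negative
values, not clipped.

Consequences worth stating plainly: J-selection is invariant to
re-weighting a profile's (SE, SP) rows to any other prevalence, whereas
κ at a *fixed* r is not — the package constructs integer-exact profile
pairs demonstrating that a κ(0.5) choice can flip between prevalences
25% and 75% while the J choice cannot. The log odds ratio
ln(TN·TP/(FN·FP)) depends only on (SE, SP), which is precisely why it
cannot encode any cost structure; zero cells raise an error rather than
receiving a continuity correction, since a silent +0.5 would change
rankings.

## Threshold selection

`select_threshold` evaluates one criterion (max J, max κ(r), min EC,
max EC′, max log OR) per cut-off and returns the optimum. Ties within
1e-12 of the optimum are all reported; the chosen value is the smallest
tied cut-off, favoring sensitivity — a deliberate tool choice, since no
convention exists. An index undefined at any cut-off (empty margin,
zero cell for the log OR, degenerate κ denominator) aborts the
selection with an error naming that cut-off; undefined values are never
silently ranked.

For a continuous marker the EC′ optimum sits where the ROC slope —
equivalently the diseased/healthy density ratio — equals
m = (1 − P)(1 − r)/(P·r). With J's implicit r = 1 − P this target is
exactly 1 at every prevalence. For the binormal model the log density
ratio is quadratic, so up to two crossings exist; the solver scans a
4001-point grid over [min mean − 10·max σ, max mean + 10·max σ],
refines each sign change by bisection to |f| < 1e-9 (xtol 1e-12), and
returns the crossing with the larger theoretical EC′. Equal variances
admit the closed form c = (μ_H + μ_D)/2 + σ²·ln m/(μ_D − μ_H), used as
an independent cross-check in tests, as is agreement with the argmax of
EC′ on a 10⁵-point grid. The solver requires μ_D > μ_H, matching the
≥ c positivity rule; inverted markers should be negated first.

## ROC and AUC

The empirical ROC uses one operating point per distinct observed score
(no interpolation thresholds), prepending (0, 0); the smallest score
classifies everyone positive and closes the curve at (1, 1).
Construction is a single descending sort with cumulative counts, so
10⁵-subject samples are immediate. AUC is the trapezoid area and must
equal the Mann–Whitney pairwise probability (ties one half) to 1e-12 on
every sample — the tests compute that oracle independently via rank
sums.

## Synthetic data

Two generators with different jobs:

* `binormal_sample` draws labels Bernoulli(P) and scores from
  class-conditional normals — the standard binormal marker model. It
  exercises the SE/SP trade-off and has a known AUC, Φ(d/√2) for equal
  unit variances with mean gap d, which the tests verify at n = 10⁵
  within 0.01. Defaults (means 0 and 1, unit variances, P = 0.5) give
  a moderately informative marker, AUC ≈ 0.76. Seeds are mandatory
  arguments; there is no global random state.
* `matched_prevalence_pair` realizes requested (SE, SP) rows as exact
  integer tables at two prevalences, raising rather than rounding when
  the cells are not integer-realizable. It exists for worked examples
  where every cell must be reproducible, and reconstructs the bundled
  120-subject scenarios from [(0.8, 0.4)] at prevalences 0.25/0.75 as
  the unique integer solution.

What the generators do not emulate: covariate-dependent thresholds,
verification bias, markers with non-normal or multimodal
class-conditional distributions, and sampling variability in SE/SP
estimates (no confidence intervals anywhere in the package — point
identities only). Passing tests therefore certify the algebra and the
selection machinery, not robustness of any particular clinical
threshold.

## Bundled scenarios

`scenario_profile("prev25")` / `("prev75")` are single-cut-off,
120-subject tables — (TN 36, FP 54, FN 6, TP 24) and (TN 12, FP 18,
FN 18, TP 72) — with identical SE = 0.8, SP = 0.4. They are the
minimal demonstration pair: identical J (0.2) and log OR (0.981),
different κ(0.5) (0.130 vs 0.2), hence different implicit costs behind
the same "prevalence-free" summary.

## CLI

The `cutcost` command is a thin layer over the library: it reads either
per-subject scores or pre-tabulated threshold tables (delimited text,
delimiter from the extension), writes a per-threshold report (6 decimal
places; ranking always uses full precision), a selection summary, and a
run log (timestamps confined to the log so report and summary are
byte-reproducible). When no cost information is given, r defaults to
0.5 — symmetric costs — and is stated in the output. The summary always
prints the implicit cost ratio 1 − P of a J choice and warns when it
differs from the working r by more than 0.05; the 0.05 margin is a
reporting choice, small enough that an unflagged discrepancy cannot
reorder error valuations materially.

## Known limitations

* No inference: no standard errors or confidence intervals for J, κ or
  AUC, and no comparison of correlated markers.
* Strictly binary disease state and dichotomous test outcome; no
  indeterminate results.
* The binormal solver assumes the diseased distribution lies above the
  healthy one.
* Costs enter only through per-outcome magnitudes or the scalar ratio;
  no utility elicitation support.
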