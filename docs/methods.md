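# Methods

This note records the assessment model implemented by `aquacpi`, the
numerical choices made where the published formulation leaves room, and
what the synthetic data generator does and does not establish.

## Compliance and the non-exceedance statistic

Every objective is direction-aware: an inclusive upper limit, an
inclusive lower limit, a closed range (pH, residual chlorine), or a
complete-absence target (fecal coliforms under the strictest reuse
scenarios).  Boundary equality is compliant throughout: a BOD₅ reading
of exactly 40 mg/L against a 40 mg/L limit passes.  For an absence
target, a left-censored non-detect ("<1 MPN/100 mL") or an exact
quantified zero complies; any positive quantified count fails.  We read
"quantified presence" literally — a laboratory zero is an observed
absence, not a presence.

The probability that a parameter meets its objective uses the Weibull
plotting position m/(n+1).  The rank m is the insertion rank of the
objective in the severity-sorted sample, i.e. m = 1 + (number of
violations): a parameter that never fails in n tests gets
P = 100·n/(n+1) (99.73 at n = 365), not 100, and a parameter that
always fails pins Pe at its maximum.  Computed probabilities are clamped
to [0.01, 99.99] percent — empirical rank statistics never justify
certainty, and the extremes of the reporting scale encode "essentially
always" / "essentially never".  One special case bypasses the rank
arithmetic: an absence target met by an entirely censored series reports
P = 99.99 directly, since no quantified value exists to rank.  Tables of
probabilities *loaded* from printed sources are accepted anywhere in
(0, 100): published tables themselves report values such as 0.005.

## Entropy weighting

Experts score the k parameters against n = 4 criteria on a 1–10 Likert
scale.  The share matrix normalizes each parameter's row across the
criteria, P_ij = s_ij / Σ_i s_ij, so the entropy
E_j = −(1/ln n) Σ_i P_ij ln P_ij ∈ [0, 1] measures how evenly a
parameter was scored; the 0·ln 0 limit contributes zero.  This row-wise
orientation is forced by α = 1/ln n with n the number of criteria; the
classical decision-matrix orientation (normalize within a criterion
column first) is available as `normalization="within_criterion"` since
the original worked example is not public, but it is not the default.
Multiple experts' matrices are combined by element-wise arithmetic mean
before the entropy step.

Final weights blend diversity with an a-priori rating from the odd
Likert scale {1,3,5,7,9}: W_j = ŵ_j w_j / Σ ŵ_k w_k with
w_j = d_j/Σd_j, d_j = 1 − E_j.  If every row is scored uniformly, all
d_j = 0 and the blend is 0/0; the implementation then falls back to
priori-proportional weights W_j = ŵ_j/Σŵ_k, which preserves ΣW = 1 and
respects the only information available.

## Grey relational index

Deviations Δ_ik = |100 − P_ik| are taken against the constant
perfect-compliance reference.  Δmin and Δmax pool over all facilities
and parameters of one scenario (the literal min-min/max-max reading);
per-parameter pooling is available via `comparison_scope` but changes
little on realistic tables.  The distinguishing coefficient defaults to
ξ = 0.5 (moderate contrast); larger ξ compresses coefficients toward 1
without reordering facilities.  The weighted grade Σ W_k ξ_ik lies in
(0, 1] and is reported ×100 so both indices share the 0–100 scale.  If
Δmax = 0 (every entry at the reference) all coefficients are defined
as 1.

The weight-sum precondition is enforced with a slack of ±0.05: published
weight tables rounded to two decimals sum to 0.97–0.99, and the package
deliberately accepts them verbatim rather than renormalizing, so index
values computed from printed tables are reproducible as printed.
Weights computed by `final_weights` satisfy ΣW = 1 to 1e−9.

## Modified CCME index

Scope F1 counts a parameter as failed if any test violates either side
of its objective; its denominator is the number of physico-chemical
parameters supplied (microbiology is excluded from F1–F3 entirely,
because an absence target admits no excursion).  Amplitude excursions
are value/objective − 1 against an exceeded maximum and
objective/value − 1 against an undershot minimum, dispatched per side
for range objectives; a failed value at or near zero under the
lower-side form is capped at 100 per excursion to keep nse finite.  nse
divides the excursion sum by the total number of tests, and
F3 = nse/(0.01·nse + 0.01) rises from 0 through 50 at nse = 1 toward
its asymptote 100.

CWQI_PC = 100 − √(F1²+F2²+F3²)/1.732 is floored at 0: at the factor
maximum (100,100,100) the norm is 173.205 and the −0.003 rounding
residue would otherwise leak below the scale.  The microbiological
sub-index is the plain pass rate, and the blend weights (W1, W2) per
scenario are (0.9,0.1), (0.8,0.2), (0.7,0.3), (0.7,0.3) for S1–S4,
shipped as overridable configuration.

Category bands are published as integer intervals with unit gaps
(…88 | 89…); real-valued indices use half-open intervals assigning each
gap to the lower category's upper edge: [0,45) Poor, [45,65) Marginal,
[65,80) Fair, [80,89) Good, [89,95) Very Good, [95,100] Excellent.

## Benchmarking

The benchmark is the unweighted arithmetic mean of the participating
facilities' index values for a scenario; gaps are mean-centered by
construction (they sum to zero).  Flow-weighted averaging was considered
and rejected as the default — plant flows differ by an order of
magnitude and would let the largest plant define the benchmark — but the
mean is computed per index (GWQI and modified CWQI separately).  A
"presumed" benchmark of 90, the bottom of the very-good zone, is carried
on every result as a reporting overlay only.  Recommendations attach the
scenario's improvement actions (chlorine control for the existing
scenarios; membrane-bioreactor nutrients polishing from cycle 1;
reverse osmosis for dissolved solids in cycle 2) plus gap-dependent
advice: below-benchmark facilities are flagged for major improvement,
above-benchmark ones for maintenance or minor improvement.  Where both
indices are computed, the benchmark/gap and category reported at the top
level follow the modified CWQI, the stricter of the two.

## Synthetic monitoring campaigns

The real one-year series are confidential; the generator emulates them
from the published per-facility summary rows (min, mean, max, SD).
Families: truncated normal for roughly symmetric parameters (pH, TDS,
nitrate); lognormal, matched by moments, for the right-skewed ones
(TSS, BOD₅, COD, ammonia, phosphate, chlorine — printed CVs reach
~360%); an all-censored "<1" stream for coliforms.  Draws are
rejection-clipped to the printed [min, max], with an error after 10⁴
consecutive empty batches.

Because the printed moments describe the *observed* (range-limited)
data, the proposal parameters are calibrated so that the clipped
distribution, not the proposal, reproduces them: a fixed-point iteration
on a pilot sample (8192 draws, its own deterministic stream derived from
the profile, so campaign seeds are unaffected) shifts the proposal mean
additively and scales its SD until both clipped moments land within 1%
of an SD of the targets.

Some printed rows are infeasible for any clipped unimodal family: a
mean within ~1.32 SD of a clip bound (the half-normal ratio
0.7979/0.6028) — several rows have mean equal to the minimum — cannot be
reached by a normal or lognormal proposal with an interior mode.  Those
rows switch to an exponential tail anchored at the near bound with its
scale calibrated to the mean, which reproduces the mean exactly but pins
the SD near the mean-to-bound distance.  This models what such rows
describe physically: values piled at a floor (e.g. TSS at the 1 mg/L
reporting floor) with occasional spikes.

Limitations: no temporal autocorrelation is injected (every index here
is order-free, so none is needed for validity, but the series are not
realistic day-to-day trajectories); boundary-regime SDs are not
recovered; and the surrogate cannot reproduce the exact published index
values, whose underlying data remain confidential.  Passing tests show
the pipeline's arithmetic and calibration are correct, not that the
synthetic campaigns are distributionally identical to the real plants.

## Problem sizes and determinism

Tests run the generator at 365 days where calibration is asserted and
45–60 days where only pipeline behaviour matters; property tests use
1000 randomized cases (seeded or derandomized).  Every stochastic
component takes an explicit seed and is reproducible byte-for-byte; all
index computations are deterministic given their inputs.
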