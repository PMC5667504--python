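# Methods

## The statistical problem

MeRIP-Seq (m6A-seq) quantifies transcriptome-wide RNA methylation through
paired sequencing libraries: an immunoprecipitated (IP) library enriched
for methylated fragments and an input control measuring basal expression.
After peak calling and read counting, each methylation site *i* in
replicate *j* is summarized by an IP count `t[i,j]` and an input count
`c[i,j]`. Differential methylation analysis asks whether the methylation
rate `p` of a site — the fraction of its molecules carrying the mark —
differs between two conditions A and B. Two features make this hard: read
coverage varies over orders of magnitude with expression (a naive rate
`t/(t+c)` is meaningless at low coverage), and experiments rarely have
more than 2–3 biological replicates, so per-site variability cannot be
estimated directly.

## The quad-negative-binomial model

Counts are modelled as negative binomial with means

    E t[i,j] = q_i · p_{i,ρ(j)} · e_{i,ρ(j)} · s_t[j]
    E c[i,j] = q_i · (1 − p_{i,ρ(j)}) · e_{i,ρ(j)} · s_c[j]

where `q_i` is the site's expected abundance in a standard library,
`e_{i,ρ}` a condition-specific expression factor, and `s_t`, `s_c` library
size factors (estimated separately for IP and input libraries, which have
intrinsically different count distributions — never pooled across types).
The variance decomposes into shot noise plus an over-dispersion term:

    Var t[i,j] = E t[i,j] + (e_{i,ρ(j)} s_t[j])² · v_t(p, q)

with the raw variance `v` assumed to be a smooth function of the
methylation rate and the abundance. Moment estimators:

* `q̂_i` — mean over **all** replicates of `t/s_t + c/s_c`. Using both
  libraries (not the input alone) keeps the background estimate usable for
  lowly expressed sites.
* `p̂_{i,ρ}` — summed normalized IP counts over summed normalized totals
  within the condition; the pooled variant `p̂_O` sums over both
  conditions and estimates the common rate under the null.
* `ê_{i,ρ}` — mean normalized total within the condition divided by `q̂_i`.
* `ŵ` — ddof-1 sample variance of `t[i,j]/(s_t[j] ê)` within a condition
  ("common-scale variance"), and the bias term
  `z = q̂ p̂ / |ρ| · Σ_j 1/(s_t[j] ê)`; `ŵ − z` is an unbiased estimate of
  the raw variance (verified by simulation in the test suite). The input
  analogue replaces `p̂` by `1 − p̂` and `s_t` by `s_c`.

## Variance smoothing

The scatter `(p̂_i, q̂_i) → ŵ_i` is smoothed by a local-linear gamma-family
regression with log link. Design choices, all open in principle:

* Covariates are `(p̂, log q̂)`, standardized; abundance spans orders of
  magnitude and the log keeps neighbourhoods meaningful.
* Neighbourhood: nearest-neighbour fraction (span), default 0.7, tricube
  weights; local fits use IRLS, which for the gamma/log-link pair reduces
  to iterated weighted least squares with the prior weights. If a local
  fit fails or diverges, the fitted value falls back to the weighted
  log-mean of the responses.
* Responses of zero (identical replicates) are floored at 1e−8 — a gamma
  response must be positive — and retained in the fit.
* The surface is evaluated on a 21×21 grid spanning the fitted scatter
  and queried by bilinear interpolation; query points outside the fitted
  range are clamped to the boundary instead of trusting smoother tails.
  Grid evaluation makes the smoother O(grid² · n) instead of
  O(n_query · n) with no measurable accuracy cost at the grid sizes used.
* Fits need at least 30 usable features per group.

Four fitting modes control how replicates are grouped: `per-condition`
(one surface per sample type and condition; needs ≥2 replicates in every
condition), `pooled` (one surface per sample type from the union of all
replicated conditions' scatters), `blind` (all samples of a type treated
as replicates of one pseudo-condition — the only option without biological
replicates, and necessarily anti-conservative since condition differences
inflate the variance), and `auto` (default: per-condition when every
condition is replicated, otherwise blind).

The raw variance used anywhere is `max(0, w_surface(rate, q̂) − z)` with
`z` recomputed at the same rate: the unbiased estimator can go negative,
but a count variance cannot sit below shot noise. In pooled mode the `z`
subtracted is the target condition's own bias term (that condition's
scatter carried that bias); in blind mode it is the blind group's.

## The exact conditional test

Under the null `p_A = p_B = p_O`, the four group sums `t_A, t_B, c_A, c_B`
(raw, unnormalized sums over replicates) are modelled as independent
negative binomials with

    μ̂_{t,A} = p̂_O q̂ ê_A Σ_{j∈A} s_t[j]
    σ̂²_{t,A} = μ̂_{t,A} + v_A(p̂_O, q̂) ê_A² Σ_{j∈A} s_t[j]²

and symmetrically for the other three groups (input groups use `1 − p̂_O`,
`s_c` and the input-type surface). The (mean, variance) pair maps to the
standard NB parameterization by `size = μ²/(σ² − μ)`, `prob = μ/σ²`; when
`σ² ≤ μ` the Poisson limit is used (the NB is undefined at or below the
shot-noise floor), and a zero mean degenerates to a point mass at zero.

Conditioning on the total IP count `t_i = t_A + t_B` and the condition
totals `n_A`, `n_B` fixes the support of the IP-in-A split to
`t ∈ [max(0, t_i − n_B), min(t_i, n_A)]` (all four group arguments must be
non-negative). The probability of a split is the product of the four
marginal masses, and the two-sided p-value is

    p = Σ_{t: P(t) ≤ P(t_obs)} P(t) / Σ_t P(t)

summed exactly over the finite support — no truncation. The comparison
uses a relative tolerance of 1e−8 (inclusion on ties), because exact
equality of floating-point masses is fragile; the tolerance errs
conservative. Features with `t_i = 0` or no reads at all are flagged
`skipped-zero` (no information); features whose support carries no
numerical mass get p = 1 and `skipped-degenerate`.

The vectorized path used by `run_qnb` enumerates all supports in flat
concatenated arrays and builds the log-mass profile by a per-step
recurrence (each unit step of `t` multiplies every marginal mass by a
rational factor), which agrees with the direct log-pmf evaluation to
~1e−11 and is an order of magnitude faster. The per-feature API
(`qnb_pvalue`) keeps the direct evaluation.

Effect sizes: risk ratio `RR = p̂_A/p̂_B` (B is the control; configurable)
and odds ratio `OR = [Σ_A(t/s_t)/Σ_A(c/s_c)] / [Σ_B(t/s_t)/Σ_B(c/s_c)]`,
both reported as missing (never ±inf) when a denominator is zero.
Benjamini–Hochberg adjusted p-values are reported alongside raw ones; the
test itself makes no multiplicity claim.

## Synthetic data

The simulator draws from exactly the model the test assumes, sharing the
same (mean, variance) → NB conversion:

| parameter | default | meaning |
|---|---|---|
| `n_features` | 20000 | methylation sites |
| `reps_per_condition` | 3 | balanced two-condition design |
| `d` | 1.0 | over-dispersion constant; `v = d/(e·s)` |
| `frac_differential` | 0.5 | sites with `p_A ≠ p_B` |
| `log_abundance_range` | (log 10, log 10⁴) | `log q` uniform |
| `sd_log_e`, `sd_log_s` | 0.25 | lognormal spread of expression/size factors |

`p_A ~ U(0,1)` per site; differential sites redraw `p_B ~ U(0,1)`
independently (redrawn on exact float collision), others copy `p_A`. The
raw variance `v = d/(e·s)` shrinks with expression and depth, so `d = 0`
recovers pure Poisson noise. The abundance range, the lognormal spreads
and the independent redraw of differential effects are this package's
choices — realistic for a transcriptome-wide site set, but choices; the
config exposes each so sweeps vary one knob.

What the simulator does **not** emulate: positional read structure within
peaks, isoform ambiguity, immunoprecipitation-efficiency differences
between antibody batches, and count correlation between IP and input of
the same replicate. Passing tests therefore demonstrate correctness of the
inference given the count model, not robustness to those real-data
artifacts.

## Evaluation protocols

* **ROC AUC** against simulator truth, ranking by ascending p-value;
  missing p-values rank last, ties use mid-rank.
* **Sample-swop**: with `k` replicates per condition, the `k` cyclic
  replicate pairings each produce a "mock" dataset in which one
  A-replicate and one B-replicate trade condition labels (a replicate's IP
  and input columns move together — a replicate is a paired library). The
  mock result is an empirical negative control: for each target mock call
  fraction `x`, the significance threshold is the mock p-value quantile
  realizing at least `x` (ties at the boundary included, so the realized
  fraction is also reported), and the curve reports the genuine call
  fraction at the same threshold, averaged over pairs, plus the implied
  empirical FDR `mock_fraction/genuine_fraction`.

## Numerical notes and limitations

* Geometric (median-of-ratios) size factors require at least one feature
  positive in every column of the sample type; below 50 such features a
  warning recommends `method="total"`. Factors are relative: only ratios
  between columns are identified.
* A global shift of methylation in one direction across *most* features is
  partially absorbed by the size factors (depth and global methylation
  change are confounded at the library level) — a limitation shared by any
  count normalization, worth remembering when a treatment is expected to
  move the whole methylome.
* Problem sizes in the test suite (1000–5000 features, 20-repeat AUC
  sweeps at 2000 features) were chosen so the full suite runs on a laptop
  in minutes while keeping Monte-Carlo error well below the asserted
  margins; trend comparisons across dispersion settings use common random
  numbers (paired seeds) for variance reduction.
* Per-site maximum-likelihood dispersion (instead of the smoothness
  assumption) becomes preferable as replicate numbers grow; it is out of
  scope here, as are read alignment, peak calling and BAM-level counting.
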