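# Methods

This note documents the statistical model, the optimization machinery,
the parameter defaults and why they were chosen, and the limits of what
the desk-scale test suite demonstrates.

## Stimulus model

A stimulus is a sparse nonnegative vector over `N` monomolecular
odorants, sampled in three stages.

**Frequencies.**  Per-odorant activation probabilities `μ_i` are drawn
once per environment from `Gamma(shape α, rate λ)` and clipped into
`(0, 1 − 10⁻⁶)`.  Defaults `α = 0.3`, `λ = 28.5` at `N = 1000`: a few
odorants are common, most are rare, and the expected active count
`N·α/λ ≈ 10.5` centers the per-sample *median* at ~10 active odorants
(the count distribution is right-skewed, so the mean sits slightly above
the median).  `EnvironmentSpec.default` scales the rate with `N` so that
reduced-size environments keep the same ~10-odorant regime.  A
`flat_frequency` switch replaces the Gamma draws with a constant `μ₀`.

**Presence.**  Binary presence is drawn through a Gaussian copula:
`c_bin = 1[Z > t]`, `Z ~ N(0, Σ)`, `t_i = Φ⁻¹(1 − μ_i)`.  `Σ` is
block-constant — `k` equal blocks (remainder odorants distributed one per
block from the first), `ρ` within blocks (default 0.5), zero across —
each block representing one odor source emitting correlated odorants.
The copula reproduces the marginals exactly; binary pairwise covariances
are monotone, nonlinear functions of `Σ_ij`.  For small `k` the desired
mean/covariance combination becomes infeasible in binary data, so a
thinning step independently zeroes active entries with probability `p_k`
(defaults 0.20/0.10/0.05 for k = 4/8/16, zero at k ≥ 32) and the default
Gamma rate is rescaled by `1/(1 − p_k)` to keep the post-thinning mean
count stable.  All-zero rows are redrawn: a sample represents an odor
encounter, so it carries at least one odorant.  This zero-truncation
touches ~0.1% of draws at defaults; a proportional-to-`μ` single-odorant
fallback guards pathologically sparse panels.

**Concentrations.**  Each active odorant receives an i.i.d. log-normal
concentration `exp(σ_c z)`, `z ~ N(0,1)`.  `σ_c` is the SD of the
*natural log* of concentration (default 3).  The log-median is pinned at
0 (median concentration 1): only relative values of sensitivity and
concentration matter to the circuit, so the concentration scale is a
gauge freedom absorbed into `W`.

One master seed feeds named child streams (frequencies, latents,
thinning, concentrations), so each stage is independently reproducible.

## Encoding model

Firing rates are `r = φ(E W c) + ξ` with the Hill function
`φ(x) = xⁿ/(1 + xⁿ)` (implemented in this overflow-safe form; `φ(0) = 0`
as the limit value).  `n = 1.46` by default, matching larval fly
dose-response fits.  The expression matrix sits *inside* the
nonlinearity: `φ` is used as an empirical description of neuron activity
under mixtures, not a mechanistic model of receptor cooperativity, and
the alternative placement is deliberately not implemented.  Noise is
Gaussian with `σ₀ = 0.1`, on the order of typical mean activity; a
Poisson noise model is out of scope.  Glomerular activity is
`g = G tanh(α r)`, a saturating transfer with adaptable gain; `G` rows
are on the simplex so `|g| < 1`.

Canonical expression allocates neurons to receptors in contiguous groups
of `⌊L/M⌋` (remainder one-per-receptor from receptor 0).  The ordering is
arbitrary; no downstream statistic depends on it.

## Information proxy

Mutual information between response and stimulus is the KL divergence
between joint and product of marginals; estimating it variationally in
high dimension is unstable, so the optimization proxy is the
Jensen–Shannon analogue.  Throughout the package "JSD" denotes the
f-divergence with generator `f(u) = u ln u − (u+1) ln((1+u)/2)`, i.e.
`KL(P‖M) + KL(Q‖M)` with `M` the even mixture — twice the symmetrized
textbook JSD, bounded by `2 ln 2`.  Its Fenchel conjugate is
`f*(t) = −log(2 − eᵗ)` with domain `t < ln 2`, and the bound is

    D_JS(P‖Q) ≥ E_P[T] − E_Q[f*(T)].

On weakly dependent pairs the trained bound stays below `ln 2`; on
strongly dependent circuit data it can legitimately exceed `ln 2` (up to
`2 ln 2`).  Absolute bound values are not comparable across different
models — only the ascent matters.

**Critic.**  `T(g, c) = squash(χ(g)ᵀψ(c))` with two separate
two-hidden-layer ReLU networks of width 128 and embedding dimension 128
(both configurable; the hidden width follows the reference architecture,
the embedding dimension and activation are implementation defaults).
`squash(v) = ln 2 − softplus(−v)` maps the raw inner product into the
conjugate's domain — the standard output activation for this bound in
the f-GAN construction — and is clamped one ulp-scale below `ln 2`
against float rounding.  Final layers initialize small so the bound
starts near 0.  A joint-concatenation critic is available as a
spot-check (`architecture="concat"`).  Product-of-marginals samples come
from shuffling responses against stimuli with a uniform permutation
(derangement not enforced; the `1/B` diagonal contamination is standard
and immaterial at the batch sizes used).

**Stimulus preprocessing.**  The critic's stimulus input is `log1p(c)`
by default: an invertible coordinate-wise map leaves mutual information
unchanged but removes the four-plus orders of magnitude of concentration
spread that would otherwise dominate the network's conditioning.  Raw
input is available via `stimulus_transform="raw"`.

All gradients — through both critic networks, the Hill stage, the
expression/pooling contractions, and the mirror maps — are hand-derived
and verified against central finite differences in the test suite.

## Constrained optimization

Mirror descent runs each layer in an unconstrained dual space:
`W = exp(U)` (positivity), `E` and `G` rows `= softmax(U)` (simplex),
`α = exp(u)`.  Feasibility is therefore exact at every step (unit row
sums to < 10⁻⁹, strict positivity).  Circuit duals and critic parameters
ascend the same bound simultaneously with Adam — both parties maximize,
so no adversarial alternation or schedule is needed.  Fresh stimulus
batches are drawn every step by default.  A fixed step budget (no early
stopping) keeps runs exactly reproducible from their seed; convergence
is judged post hoc from the recorded trace.

Defaults: batch 256, 2000 steps, step sizes 10⁻³ (desk profile; the
full-scale experiment configs use batches of 512 and 2·10⁴ steps).
Initializations: `W` is a scaled log-normal `exp(Z)/E[‖c‖]` (or the same
shape anchored at a configurable minimum sensitivity); `E` supports
random (flat Dirichlet), canonical, noncanonical (3–7 receptors per
neuron at roughly equal levels, small multiplicative jitter, default
jitter SD 0.05), and a block variant drawing a neuron's receptors from a
single receptor family to emulate coexpression by descent; `G` starts
random with `α = 1`.  `W_shuffle` for the glomerular stage permutes all
`M·N` entries by default (within-row shuffling preserves mean receptor
tuning and is provided as a second mode).

## Diagnostics

- **Sparsity / log-normal fit** of `W` above an effectively-zero cutoff
  (default `10⁻⁶ ×` the median entry, reported with every metric).
- **Specialists**: a receptor whose maximum sensitivity is ≥ 100× its
  own 99th-percentile sensitivity (linear-interpolated percentile);
  ratio-based, hence scale-invariant.  Counted per receptor.
- **Dynamic range** of an odorant: the log10-concentration measure of
  the union over receptors of the windows where `φ(W_ij c)` lies in
  `[0.1, 0.9]`; single-receptor width `(1/n) log10(81)` in closed form.
  The union-of-windows definition is a declared interpretation.
- **Canonical score**: `1 − mean_i H(E_i)/ln M`; one-hot rows score 1,
  uniform rows 0, `κ`-uniform rows `1 − ln κ/ln M`.  The `ln M`
  normalization is declared; for the 3–7-receptor noncanonical
  initialization at M=60 it evaluates to ≈ 0.62 (no base-consistent
  normalization of the row-entropy formula reproduces the reference
  value of 0.74 quoted for that initialization; the discrepancy is
  documented rather than absorbed into the definition).
- **PC variance spectrum**, **effective rank** (exponential of the
  entropy of the normalized singular values — a declared choice),
  **robust coexpression** (pairs expressed ≥ 0.1 of the budget in ≥ 3
  neurons; log-sensitivity covariances compared to never-coexpressed
  pairs by a two-sided Mann–Whitney U), **glomerular purity** (mean
  dominant-receptor weight fraction per glomerulus; ties break to the
  lowest index), and **histogram entropy** of pooled activity
  (equal-width bins over the support, nats).

## What the reduced scales do and do not show

The test suite and the bundled experiments run at deliberately small
sizes (typically `N = 120–200`, `M = 6–10`, `L = 24–30`, 10³–3·10³
steps) so every code path executes in minutes on one core.  At these
sizes:

- Expression optimization robustly recovers canonical coding from random
  or noncanonical initializations, under optimized, shuffled, and
  log-normal (i.i.d., block, Toeplitz) sensing models alike, and the
  activity PC spectrum flattens accordingly.  The *strict ordering*
  — surrogate-`W` runs canonicalizing further than optimized-`W` runs —
  is a large-`M` phenomenon: it requires the low-rank degeneracy of
  large optimized sensing matrices, and small-`M` optima are near full
  rank (desk-scale `W_opt` has effective rank ≈ 7 of 8), so all variants
  canonicalize about equally.
- The noise trend (more neural noise favoring canonical expression)
  holds between `σ₀ = 0.01` and `σ₀ = 0.1`.  At `σ₀ = 1.0` the
  desk-scale optimization stalls — with ≤ 30 bounded-activity neurons
  the bound's gradient signal drowns — so that end of the sweep is not
  meaningful at reduced size.
- Glomerular optimization produces strong convergence (purity far above
  the uniform `1/M` baseline).  Histogram equalization, however, does
  **not** survive the reduced convergence ratio: with `L/M = 3` neurons
  per glomerulus the residual pooled noise `σ₀/√3` is large, and the
  information-optimal gain is `α < 1` (compressing, entropy-reducing) at
  both `N = 200` and `N = 1000`.  At the realistic convergence ratio
  `L/M = 21` (e.g. `M = 21`, `L = 441`, `N = 1000`, shuffled optimized
  `W`, 64 sources, `σ_c = 3`) the phenomenon appears as expected:
  `α_opt ≈ 1.1–1.2 > 1` and pooled-activity entropy rises relative to
  the `α = 1` baseline.  High-gain equalization pays only when pooling
  has already averaged the noise down.
- Desk-scale optimized sensing matrices are denser and hotter (no
  effectively-zero entries, ~5 decades of sensitivity span, mean
  activity ~0.3–0.5) than full-scale optima; the ~40% sparsity and
  six-decade span are full-scale outcomes that the bundled short runs do
  not reproduce.

Synthetic environments emulate presence/absence statistics, source
correlations, and concentration spread; they do not emulate temporal
plume dynamics, hierarchical (nested) source structure, preserved
concentration ratios across samples, inhibitory/antagonistic receptor
interactions, or the geometric constraints that couple a real receptor's
affinities across odorants.  Conclusions from passing tests are
statements about this generative model, not about any measured circuit.

## Numerical notes

- `φ` and its derivative are computed in saturation-safe forms; float
  saturation reaches exactly 1.0 for extreme drives and is accepted.
- The copula covariance uses Cholesky with an eigenvalue-based PSD
  fallback (tolerance `10⁻⁸` relative) for edge cases like comonotone
  blocks.
- Dual initialization of simplex-constrained layers uses
  `log(E₀ + 10⁻⁸)`, so exactly-zero initial entries enter the softmax at
  a ~10⁻⁸ relative floor.
- Degenerate inputs: constant activity yields a `(1, 0, …)` PC spectrum
  with a warning; zero-support histograms have entropy 0; all-zero
  matrices are rejected where a statistic would be undefined.
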