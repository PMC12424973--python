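"""Diagnostic statistics of optimized olfactory circuits.

Covers the receptor-level statistics (sparsity, log-normal fit of nonzero
sensitivities, specialist receptors, per-odorant dynamic range), the
expression-level statistics (canonical score, PC variance spectrum, robust
coexpression, effective rank, null sensing-matrix surrogates), and the
glomerular-level statistics (purity, histogram entropy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .encoding import check_row_stochastic

__all__ = [
    "sparsity_fraction",
    "default_zero_threshold",
    "fit_lognormal_nonzero",
    "count_specialists",
    "odorant_dynamic_range",
    "canonical_score",
    "pc_variance_spectrum",
    "robust_coexpression_stats",
    "make_null_sensing",
    "glomerular_purity",
    "activity_histogram_entropy",
    "effective_rank",
]


def default_zero_threshold(w: np.ndarray) -> float:
    """Effectively-zero cutoff: 1e-6 times the median entry of ``W``.

    Optimized sensing matrices keep all entries strictly positive (the
    mirror map guarantees it), so "zero" entries are those that fell many
    orders of magnitude below the bulk.
    """
    w = np.asarray(w, dtype=float)
    med = float(np.median(w[w > 0]))
    return 1e-6 * med


def sparsity_fraction(w: np.ndarray, zero_threshold: float | None = None) -> float:
    """Fraction of entries below the effectively-zero threshold."""
    w = np.asarray(w, dtype=float)
    if zero_threshold is None:
        zero_threshold = default_zero_threshold(w)
    if zero_threshold <= 0:
        raise ValueError("zero_threshold must be positive")
    return float(np.mean(w < zero_threshold))


def fit_lognormal_nonzero(w: np.ndarray, zero_threshold: float | None = None):
    """ML normal fit to log of supra-threshold entries + KS statistic.

    Returns ``(log_mean, log_sd, ks_statistic)``.
    """
    w = np.asarray(w, dtype=float)
    if zero_threshold is None:
        zero_threshold = default_zero_threshold(w)
    vals = w[w >= zero_threshold]
    if vals.size < 10:
        raise ValueError("need at least 10 supra-threshold entries")
    logs = np.log(vals)
    mu, sd = float(logs.mean()), float(logs.std())
    if sd == 0.0:
        return mu, 0.0, 0.0
    ks = stats.kstest(logs, "norm", args=(mu, sd)).statistic
    return mu, sd, float(ks)


def count_specialists(w: np.ndarray):
    """Specialist receptors: max sensitivity >= 100x the row's 99th percentile.

    The criterion corresponds to probing a receptor with a 100-odorant
    panel and finding one odorant detected at 100-fold greater
    sensitivity than all others.  Ratio-based, so invariant to global
    rescaling of ``W``.  Returns ``(n_specialist_receptors, pairs)`` with
    ``pairs`` the (receptor, argmax odorant) list.
    """
    w = np.asarray(w, dtype=float)
    if w.shape[1] < 100:
        warnings.warn("fewer than 100 odorants: the 99th percentile is "
                      "interpolated over a short row", stacklevel=2)
    p99 = np.percentile(w, 99, axis=1)          # linear interpolation
    row_max = w.max(axis=1)
    is_spec = row_max >= 100.0 * p99
    pairs = [(int(i), int(np.argmax(w[i]))) for i in np.flatnonzero(is_spec)]
    return int(is_spec.sum()), pairs


def _hill_inverse(resp: float, n: float) -> float:
    """Drive x with phi(x) = resp for the Hill function with coefficient n."""
    return (resp / (1.0 - resp)) ** (1.0 / n)


def _union_length(intervals: np.ndarray) -> float:
    if len(intervals) == 0:
        return 0.0
    order = np.argsort(intervals[:, 0])
    total = 0.0
    cur_lo, cur_hi = intervals[order[0]]
    for lo, hi in intervals[order[1:]]:
        if lo > cur_hi:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    return total + (cur_hi - cur_lo)


def odorant_dynamic_range(w: np.ndarray, n: float, lo_resp: float = 0.1,
                          hi_resp: float = 0.9,
                          zero_threshold: float | None = None) -> np.ndarray:
    """Per-odorant dynamic range in log10 concentration decades.

    For odorant ``j``, the Lebesgue measure of the union over receptors of
    the log10-concentration intervals on which the receptor's Hill
    response lies in ``[lo_resp, hi_resp]``.  A single receptor with
    sensitivity ``W_ij`` responds on ``log10 c`` in
    ``[log10(x_lo / W_ij), log10(x_hi / W_ij)]`` where ``x`` is the Hill
    inverse, giving the closed-form width
    ``(1/n) log10(hi(1-lo) / (lo(1-hi)))`` independent of ``W_ij``.
    """
    if not 0.0 < lo_resp < hi_resp < 1.0:
        raise ValueError("need 0 < lo_resp < hi_resp < 1")
    w = np.asarray(w, dtype=float)
    if zero_threshold is None:
        zero_threshold = default_zero_threshold(w)
    x_lo = _hill_inverse(lo_resp, n)
    x_hi = _hill_inverse(hi_resp, n)
    out = np.zeros(w.shape[1])
    for j in range(w.shape[1]):
        col = w[:, j]
        col = col[col >= zero_threshold]
        if col.size == 0:
            continue
        lows = np.log10(x_lo / col)
        highs = np.log10(x_hi / col)
        out[j] = _union_length(np.column_stack([lows, highs]))
    return out


def canonical_score(e: np.ndarray) -> float:
    """One minus the mean normalized row entropy of the expression matrix.

    Each row of ``E`` is a probability distribution over the ``M``
    receptors; its Shannon entropy is normalized by ``ln M`` so a one-hot
    row contributes 1 to the score and a uniform row contributes 0.  A row
    uniform over ``kappa`` receptors scores ``1 - ln(kappa)/ln(M)``.
    """
    e = check_row_stochastic(np.asarray(e, dtype=float), "E")
    m = e.shape[1]
    if m < 2:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(e > 0, e * np.log(e), 0.0)
    row_entropy = -terms.sum(axis=1)
    return float(1.0 - np.mean(row_entropy) / np.log(m))


def pc_variance_spectrum(activity: np.ndarray) -> np.ndarray:
    """Fraction of activity variance along each principal component (descending)."""
    activity = np.asarray(activity, dtype=float)
    if activity.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    cov = np.cov(activity, rowvar=False)
    eigvals = np.clip(np.linalg.eigvalsh(np.atleast_2d(cov)), 0.0, None)[::-1]
    total = eigvals.sum()
    if total <= 0:
        warnings.warn("constant activity: degenerate spectrum", stacklevel=2)
        out = np.zeros(activity.shape[1])
        out[0] = 1.0
        return out
    return eigvals / total


def robust_coexpression_stats(e: np.ndarray, w: np.ndarray,
                              expr_threshold: float = 0.1,
                              min_neurons: int = 3):
    """Covariance of log sensitivities for robustly coexpressed receptor pairs.

    A neuron "expresses" receptor ``i`` when ``E_{li} >= expr_threshold``
    (10% of its expression budget by default).  A receptor pair is
    *robustly coexpressed* when at least ``min_neurons`` neurons express
    both; pairs never coexpressed form the comparison group.  For every
    pair the covariance of the two receptors' log-sensitivity rows of
    ``W`` is reported, and the two groups are compared with a two-sided
    Mann-Whitney U test.
    """
    e = check_row_stochastic(np.asarray(e, dtype=float), "E")
    w = np.asarray(w, dtype=float)
    m = e.shape[1]
    expressed = e >= expr_threshold
    co_counts = expressed.T.astype(int) @ expressed.astype(int)
    logw = np.log(np.clip(w, np.finfo(float).tiny, None))
    cov = np.cov(logw)
    iu = np.triu_indices(m, k=1)
    robust_mask = co_counts[iu] >= min_neurons
    single_mask = co_counts[iu] == 0
    robust_pairs = [(int(a), int(b)) for a, b in
                    zip(iu[0][robust_mask], iu[1][robust_mask])]
    result = {
        "robust_pairs": robust_pairs,
        "robust_cov": np.atleast_2d(cov)[iu][robust_mask],
        "single_cov": np.atleast_2d(cov)[iu][single_mask],
        "p_value": None,
    }
    if robust_mask.sum() > 0 and single_mask.sum() > 0:
        test = stats.mannwhitneyu(result["robust_cov"], result["single_cov"],
                                  alternative="two-sided")
        result["p_value"] = float(test.pvalue)
    return result


def make_null_sensing(w: np.ndarray, mode: str,
                      seed: int | np.random.Generator = 0,
                      n_families: int = 4, family_corr: float = 0.8,
                      toeplitz_decay: float = 0.5,
                      zero_threshold: float | None = None) -> np.ndarray:
    """Null/control surrogates for an optimized sensing matrix.

    shuffleGlobal
        Permute all ``M x N`` entries (preserves the entry multiset while
        destroying all row/column structure).
    shuffleRows
        Permute within each row independently (preserves mean receptor
        tuning).
    lognormalFit
        I.i.d. draws from the log-normal fitted to the supra-threshold
        entries.
    lognormalBlock / lognormalToeplitz
        Log-sensitivities drawn column-wise with inter-receptor
        correlation (contiguous receptor families at ``family_corr``, or
        Toeplitz ``toeplitz_decay**|i-j|``), marginals matched to the fit
        — surrogates for families of related receptors.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = np.asarray(w, dtype=float)
    m, n = w.shape
    if mode == "shuffleGlobal":
        return rng.permutation(w.ravel()).reshape(m, n)
    if mode == "shuffleRows":
        return np.apply_along_axis(rng.permutation, 1, w)
    mu, sd, _ = fit_lognormal_nonzero(w, zero_threshold)
    if mode == "lognormalFit":
        return np.exp(mu + sd * rng.standard_normal((m, n)))
    if mode == "lognormalBlock":
        from .environment import build_block_covariance
        corr = build_block_covariance(m, n_families, family_corr)
    elif mode == "lognormalToeplitz":
        corr = linalg.toeplitz(toeplitz_decay ** np.arange(m))
    else:
        raise ValueError(f"unknown null sensing mode {mode!r}")
    chol = np.linalg.cholesky(corr)
    z = chol @ rng.standard_normal((m, n))
    return np.exp(mu + sd * z)


def glomerular_purity(g: np.ndarray, e: np.ndarray) -> float:
    """Mean fraction of glomerular input weight from the dominant receptor type.

    Each neuron is labeled by its argmax receptor in ``E``; each
    glomerulus's dominant receptor is the one whose neurons carry the most
    summed ``G`` weight.  Purity 1 means every glomerulus draws all of its
    weight from neurons of a single receptor type.  Argmax ties break to
    the lowest index.
    """
    g = check_row_stochastic(np.asarray(g, dtype=float), "G")
    e = check_row_stochastic(np.asarray(e, dtype=float), "E")
    if g.shape[1] != e.shape[0]:
        raise ValueError("G pools a different number of neurons than E has rows")
    m = e.shape[1]
    neuron_type = np.argmax(e, axis=1)
    weight_by_type = np.zeros((g.shape[0], m))
    for t in range(m):
        weight_by_type[:, t] = g[:, neuron_type == t].sum(axis=1)
    return float(np.mean(weight_by_type.max(axis=1)))


def activity_histogram_entropy(values: np.ndarray, n_bins: int = 30) -> float:
    """Shannon entropy (nats) of the equal-width histogram over the support."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 100:
        raise ValueError("need at least 100 values for a stable histogram")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if np.ptp(values) == 0.0:
        return 0.0
    counts, _ = np.histogram(values, bins=n_bins)
    p = counts[counts > 0] / values.size
    return float(-(p * np.log(p)).sum())


def effective_rank(w: np.ndarray) -> float:
    """exp of the entropy of the normalized singular-value distribution.

    1 for a rank-one matrix, ``M`` for an ``M x M`` identity; a smooth
    proxy for how many directions the matrix meaningfully spans.
    """
    w = np.asarray(w, dtype=float)
    sv = np.linalg.svd(w, compute_uv=False)
    total = sv.sum()
    if total <= 0:
        raise ValueError("effective rank is undefined for an all-zero matrix")
    p = sv[sv > 0] / total
    return float(np.exp(-(p * np.log(p)).sum()))
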