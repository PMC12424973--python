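"""Receptor -> neuron -> glomerulus encoding of odor stimuli.

Neural firing rates follow a Hill-type dose-response applied to the
receptor drive routed through expression:

    r = phi(E W c) + xi,      phi(x) = x^n / (1 + x^n),

with ``W`` the (M x N) strictly positive receptor-by-odorant sensitivity
matrix, ``E`` the (L x M) row-stochastic neuron-by-receptor expression
matrix, and ``xi`` i.i.d. Gaussian neural noise with SD ``sigma0``.  The
expression matrix sits inside the nonlinearity: the Hill curve is an
empirical fit to neuron activity under mixtures, not a mechanistic model
of receptor cooperativity.  Glomerular activity pools neurons through a
row-stochastic map with a saturating transfer function of gain ``alpha``:

    g = G tanh(alpha r).

The Hill coefficient default (1.46) matches dose-response fits in the
Drosophila larva; ``sigma0 = 0.1`` puts noise on the order of the mean
activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environment import StimulusBatch

__all__ = [
    "EncodingParams",
    "hill_activation",
    "hill_derivative",
    "neural_response",
    "glomerular_response",
    "make_canonical_expression",
    "check_sensing",
    "check_row_stochastic",
]

ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class EncodingParams:
    """Hill coefficient ``n`` and neural noise SD ``sigma0``."""

    hill_coeff: float = 1.46
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.hill_coeff <= 0:
            raise ValueError("hill_coeff must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def hill_activation(x, n: float):
    """Hill function ``phi(x) = x^n / (1 + x^n)`` with ``phi(0) = 0``.

    Implemented in the overflow-safe form ``x^n / (x^n + 1)`` so that the
    limit value at zero is exact rather than ``0^-n``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("hill_activation requires nonnegative input")
    with np.errstate(over="ignore"):
        xn = np.power(x, n)
    out = np.where(np.isinf(xn), 1.0, xn / (1.0 + xn))
    return out if out.ndim else float(out)


def hill_derivative(x, n: float):
    """d phi / dx, stable at 0 (zero for n > 1, handled as a limit)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        xn = np.power(x, n)
        d = n * np.power(x, n - 1.0) / np.square(1.0 + xn)
    return np.where(np.isfinite(d), d, 0.0)


def check_sensing(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2:
        raise ValueError("W must be a matrix")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("W entries must be strictly positive and finite")
    return w


def check_row_stochastic(mat: np.ndarray, name: str = "matrix") -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2:
        raise ValueError(f"{name} must be a matrix")
    if np.any(mat < 0):
        raise ValueError(f"{name} entries must be nonnegative")
    if np.max(np.abs(mat.sum(axis=1) - 1.0)) > ROW_SUM_TOL:
        raise ValueError(f"{name} rows must sum to 1 within {ROW_SUM_TOL}")
    return mat


def neural_response(w: np.ndarray, e: np.ndarray, batch: StimulusBatch | np.ndarray,
                    params: EncodingParams = EncodingParams(),
                    seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Firing rates ``r = phi(E W c) + xi`` for a batch of stimuli.

    With ``noise_sd == 0`` (or ``seed=None`` and zero SD) the response is
    deterministic.  Returns an (n_samples, L) array.
    """
    w = check_sensing(w)
    e = check_row_stochastic(e, "E")
    conc = batch.conc if isinstance(batch, StimulusBatch) else np.asarray(batch, float)
    if conc.ndim == 1:
        conc = conc[None, :]
    if e.shape[1] != w.shape[0]:
        raise ValueError(f"E has {e.shape[1]} receptor columns but W has "
                         f"{w.shape[0]} receptor rows")
    if w.shape[1] != conc.shape[1]:
        raise ValueError(f"W covers {w.shape[1]} odorants but stimuli have "
                         f"{conc.shape[1]}")
    drive = conc @ w.T @ e.T
    if not np.all(np.isfinite(drive)):
        raise FloatingPointError("non-finite receptor drive (layer E W c)")
    r = hill_activation(drive, params.hill_coeff)
    if params.noise_sd > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        r = r + params.noise_sd * rng.standard_normal(r.shape)
    return r


def glomerular_response(g: np.ndarray, r: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Glomerular activity ``G tanh(alpha r)`` (bounded in (-1, 1))."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    g = check_row_stochastic(g, "G")
    r = np.asarray(r, dtype=float)
    if r.ndim == 1:
        r = r[None, :]
    if g.shape[1] != r.shape[1]:
        raise ValueError(f"G pools {g.shape[1]} neurons but activity has "
                         f"{r.shape[1]}")
    return np.tanh(alpha * r) @ g.T


def make_canonical_expression(m: int, l: int) -> np.ndarray:
    """One-hot expression: neurons allocated to receptors in contiguous groups.

    Each receptor gets ``floor(L/M)`` neurons, with the remainder handed
    out one per receptor starting from receptor 0, so every receptor is
    expressed by at least one neuron.
    """
    if not 1 <= m <= l:
        raise ValueError("need 1 <= M <= L (each receptor needs a neuron)")
    counts = np.full(m, l // m, dtype=int)
    counts[: l - (l // m) * m] += 1
    e = np.zeros((l, m))
    e[np.arange(l), np.repeat(np.arange(m), counts)] = 1.0
    return e
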