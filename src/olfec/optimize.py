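"""Layer-wise maximization of the variational JSD bound.

The circuit is optimized one layer at a time, mirroring the different
evolutionary/developmental timescales of each stage:

1. sensing ``W`` given canonical one-neuron-one-receptor expression,
2. expression ``E`` given a fixed (optimized or surrogate) ``W``,
3. glomerular map ``G`` and gain ``alpha`` given fixed ``W`` and ``E``.

Constraints are enforced with mirror descent: optimization runs in an
unconstrained dual space and maps back to the primal through ``exp`` for
positivity (``W``, ``alpha``) or a row-wise ``softmax`` for simplex rows
(``E``, ``G``), so positivity and unit row sums hold exactly at every
step.  The circuit duals and the critic parameters are ascended jointly
with a single adaptive first-order method (Adam) on the same bound — both
parties maximize it, so no adversarial alternation is needed.

The critic's stimulus input is passed through ``log1p`` by default: an
invertible coordinate-wise map leaves mutual information unchanged but
tames the orders-of-magnitude spread of log-normal concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .encoding import (EncodingParams, hill_activation, hill_derivative,
                       make_canonical_expression)
from .environment import EnvironmentSpec, StimulusSampler, block_labels
from .mi import AdamState, CriticParams, critic_backward, init_critic

__all__ = [
    "OptimizerConfig",
    "OptimizationTrace",
    "init_sensing",
    "init_expression",
    "mirror_step_positive",
    "mirror_step_simplex",
    "optimize_sensing",
    "optimize_expression",
    "optimize_glomerular",
]


@dataclass(frozen=True)
class OptimizerConfig:
    """Hyperparameters of one layer optimization.

    ``n_steps``/``batch_size`` default to a desk-scale profile; full-scale
    runs of the kind shown in the experiment configs use 2e4 steps and
    batches of 512.
    """

    circuit_step_size: float = 1e-3
    critic_step_size: float = 1e-3
    batch_size: int = 256
    n_steps: int = 2000
    seed: int = 0
    fresh_batch_per_step: bool = True
    w_init: str = "scaledLogNormal"          # or "minSensitivityLogNormal"
    min_sensitivity: float = 1e-5
    e_init: str = "random"                   # random | canonical | noncanonical | noncanonicalBlock
    e_init_k: tuple[int, int] = (3, 7)
    critic_hidden: int = 128
    critic_embed: int = 128
    stimulus_transform: str = "log1p"        # or "raw"
    record_every: int = 1

    def __post_init__(self) -> None:
        if self.circuit_step_size <= 0 or self.critic_step_size <= 0:
            raise ValueError("step sizes must be positive")
        if self.n_steps < 1 or self.batch_size < 2:
            raise ValueError("need n_steps >= 1 and batch_size >= 2")
        if self.stimulus_transform not in ("log1p", "raw"):
            raise ValueError("stimulus_transform must be 'log1p' or 'raw'")


@dataclass
class OptimizationTrace:
    """Bound values and constraint residuals recorded during training."""

    bound_values: np.ndarray
    max_row_sum_dev: np.ndarray
    min_entry: np.ndarray

    def moving_average(self, window: int = 100) -> np.ndarray:
        v = np.asarray(self.bound_values, dtype=float)
        if window >= v.size:
            return np.array([v.mean()])
        kernel = np.ones(window) / window
        return np.convolve(v, kernel, mode="valid")


# ---------------------------------------------------------------------------
# initializations


def init_sensing(m: int, n: int, mode: str = "scaledLogNormal",
                 batch_for_scale=None, seed: int | np.random.Generator = 0,
                 min_sensitivity: float = 1e-5) -> np.ndarray:
    """Log-normal initial sensing matrix.

    ``scaledLogNormal``: ``W = exp(Z) / E[||c||]`` with standard-normal
    ``Z`` and the empirical mean stimulus norm from ``batch_for_scale``,
    so typical receptor drive starts at order one.
    ``minSensitivityLogNormal``: the same log-normal shape anchored at a
    configurable minimum-sensitivity constant instead.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal((m, n))
    if mode == "scaledLogNormal":
        if batch_for_scale is None:
            raise ValueError("scaledLogNormal init needs a batch to set the scale")
        conc = getattr(batch_for_scale, "conc", batch_for_scale)
        conc = np.asarray(conc, dtype=float)
        if conc.size == 0:
            raise ValueError("scale batch is empty")
        mean_norm = float(np.mean(np.linalg.norm(conc, axis=1)))
        if mean_norm <= 0:
            raise ValueError("scale batch has zero mean norm")
        return np.exp(z) / mean_norm
    if mode == "minSensitivityLogNormal":
        if min_sensitivity <= 0:
            raise ValueError("min_sensitivity must be positive")
        return min_sensitivity * np.exp(z)
    raise ValueError(f"unknown sensing init mode {mode!r}")


def init_expression(m: int, l: int, mode: str = "random",
                    k_min: int = 3, k_max: int = 7, jitter: float = 0.05,
                    n_families: int | None = None,
                    seed: int | np.random.Generator = 0) -> np.ndarray:
    """Initial expression matrix (rows on the simplex).

    random
        Rows drawn from a flat Dirichlet over the ``M`` receptors.
    canonical
        One-hot rows via :func:`make_canonical_expression`.
    noncanonical
        Each neuron expresses ``kappa ~ Uniform{k_min..k_max}`` receptors
        chosen without replacement, at roughly equal levels (small
        multiplicative jitter), then renormalized.
    noncanonicalBlock
        As above, but the ``kappa`` receptors come from one randomly
        chosen receptor family (``n_families`` contiguous groups; default
        ``max(2, M // k_max)``), emulating coexpression by descent of
        related receptors.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mode == "canonical":
        return make_canonical_expression(m, l)
    if mode == "random":
        e = rng.dirichlet(np.ones(m), size=l)
        return e / e.sum(axis=1, keepdims=True)
    if mode not in ("noncanonical", "noncanonicalBlock"):
        raise ValueError(f"unknown expression init mode {mode!r}")
    if not 1 <= k_min <= k_max <= m:
        raise ValueError("need 1 <= k_min <= k_max <= M")
    if mode == "noncanonicalBlock":
        fam = n_families if n_families is not None else max(2, m // k_max)
        labels = block_labels(m, fam)
        pools = [np.flatnonzero(labels == f) for f in range(fam)]
        if min(len(p) for p in pools) < k_max:
            raise ValueError("receptor families are smaller than k_max")
    e = np.zeros((l, m))
    for row in range(l):
        kappa = int(rng.integers(k_min, k_max + 1))
        if mode == "noncanonicalBlock":
            pool = pools[int(rng.integers(len(pools)))]
        else:
            pool = np.arange(m)
        chosen = rng.choice(pool, size=kappa, replace=False)
        weights = np.exp(jitter * rng.standard_normal(kappa))
        e[row, chosen] = weights / weights.sum()
    return e


# ---------------------------------------------------------------------------
# mirror maps


def _softmax_rows(u: np.ndarray) -> np.ndarray:
    shifted = u - u.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def _softmax_row_backward(primal: np.ndarray, grad_primal: np.ndarray) -> np.ndarray:
    inner = (grad_primal * primal).sum(axis=-1, keepdims=True)
    return primal * (grad_primal - inner)


def mirror_step_positive(dual_u: np.ndarray, gradient: np.ndarray,
                         step_size: float):
    """One ascent step in the dual of the positive orthant (``W = exp(u)``).

    The gradient is with respect to the *primal*; the chain rule through
    ``exp`` is applied here.  Returns ``(dual, primal)``.
    """
    if not np.all(np.isfinite(gradient)):
        raise FloatingPointError("non-finite gradient in mirror step")
    primal = np.exp(dual_u)
    dual = dual_u + step_size * gradient * primal
    return dual, np.exp(dual)


def mirror_step_simplex(dual_u: np.ndarray, gradient: np.ndarray,
                        step_size: float):
    """One ascent step in the dual of the row simplex (``rows = softmax(u)``)."""
    if not np.all(np.isfinite(gradient)):
        raise FloatingPointError("non-finite gradient in mirror step")
    primal = _softmax_rows(dual_u)
    dual = dual_u + step_size * _softmax_row_backward(primal, gradient)
    return dual, _softmax_rows(dual)


# ---------------------------------------------------------------------------
# shared training loop


def _transform_stimulus(conc: np.ndarray, mode: str) -> np.ndarray:
    return np.log1p(conc) if mode == "log1p" else conc


def _run_ascent(sampler: StimulusSampler, cfg: OptimizerConfig,
                dim_act: int, circuit):
    """Joint ascent of circuit duals and critic on the JSD bound.

    ``circuit`` provides ``forward(conc, rng) -> (activity, cache)`` and
    ``backward(cache, grad_activity) -> dual_grads`` plus a ``duals`` dict
    and ``primal_report()`` for constraint residuals.
    """
    ss = np.random.SeedSequence(cfg.seed)
    s_critic, s_batchperm, s_noise = ss.spawn(3)
    rng_perm = np.random.default_rng(s_batchperm)
    rng_noise = np.random.default_rng(s_noise)

    critic = init_critic(dim_act, sampler.spec.n_odorants,
                         hidden=cfg.critic_hidden, embed_dim=cfg.critic_embed,
                         seed=np.random.default_rng(s_critic))
    critic_flat = critic.as_flat()
    adam_critic = AdamState(cfg.critic_step_size)
    adam_circuit = AdamState(cfg.circuit_step_size)

    fixed_batch = None if cfg.fresh_batch_per_step else sampler.draw(cfg.batch_size)

    bounds = np.empty(cfg.n_steps)
    row_dev = np.empty(cfg.n_steps)
    min_entry = np.empty(cfg.n_steps)
    for step in range(cfg.n_steps):
        batch = sampler.draw(cfg.batch_size) if cfg.fresh_batch_per_step else fixed_batch
        activity, cache = circuit.forward(batch.conc, rng_noise)
        stim = _transform_stimulus(batch.conc, cfg.stimulus_transform)
        perm = rng_perm.permutation(cfg.batch_size)
        value, critic_grads, grad_act = critic_backward(critic, activity, stim, perm)
        dual_grads = circuit.backward(cache, grad_act)
        adam_critic.update(critic_flat, critic_grads)
        adam_circuit.update(circuit.duals, dual_grads)
        circuit.refresh()
        bounds[step] = value
        dev, low = circuit.primal_report()
        row_dev[step] = dev
        min_entry[step] = low
    trace = OptimizationTrace(bound_values=bounds, max_row_sum_dev=row_dev,
                              min_entry=min_entry)
    return trace, critic


class _SensingCircuit:
    """W-layer forward/backward with canonical expression baked in."""

    def __init__(self, w_init: np.ndarray, e_can: np.ndarray,
                 params: EncodingParams):
        self.duals = {"U": np.log(w_init)}
        self.e = e_can
        self.params = params
        self.refresh()

    def refresh(self):
        self.w = np.exp(self.duals["U"])

    def forward(self, conc, rng_noise):
        drive_m = conc @ self.w.T                       # (B, M)
        drive_l = drive_m @ self.e.T                    # (B, L)
        r = hill_activation(drive_l, self.params.hill_coeff)
        if self.params.noise_sd > 0:
            r = r + self.params.noise_sd * rng_noise.standard_normal(r.shape)
        return r, (conc, drive_l)

    def backward(self, cache, grad_r):
        conc, drive_l = cache
        delta = grad_r * hill_derivative(drive_l, self.params.hill_coeff)
        grad_w = (delta @ self.e).T @ conc              # (M, N)
        return {"U": grad_w * self.w}

    def primal_report(self):
        return 0.0, float(self.w.min())


class _ExpressionCircuit:
    """E-layer forward/backward with fixed sensing matrix."""

    def __init__(self, e_init: np.ndarray, w: np.ndarray,
                 params: EncodingParams, dual_floor: float = 1e-8):
        self.duals = {"U": np.log(e_init + dual_floor)}
        self.w = w
        self.params = params
        self.refresh()

    def refresh(self):
        self.e = _softmax_rows(self.duals["U"])

    def forward(self, conc, rng_noise):
        x = conc @ self.w.T                             # (B, M)
        drive_l = x @ self.e.T                          # (B, L)
        r = hill_activation(drive_l, self.params.hill_coeff)
        if self.params.noise_sd > 0:
            r = r + self.params.noise_sd * rng_noise.standard_normal(r.shape)
        return r, (x, drive_l)

    def backward(self, cache, grad_r):
        x, drive_l = cache
        delta = grad_r * hill_derivative(drive_l, self.params.hill_coeff)
        grad_e = delta.T @ x                            # (L, M)
        return {"U": _softmax_row_backward(self.e, grad_e)}

    def primal_report(self):
        return float(np.abs(self.e.sum(axis=1) - 1.0).max()), float(self.e.min())


class _GlomerularCircuit:
    """G/alpha-layer forward/backward with fixed W and E."""

    def __init__(self, g_init: np.ndarray, w: np.ndarray, e: np.ndarray,
                 params: EncodingParams, alpha_init: float = 1.0,
                 dual_floor: float = 1e-8):
        self.duals = {"U": np.log(g_init + dual_floor),
                      "ua": np.array([np.log(alpha_init)])}
        self.w = w
        self.e = e
        self.params = params
        self.refresh()

    def refresh(self):
        self.g = _softmax_rows(self.duals["U"])
        self.alpha = float(np.exp(self.duals["ua"][0]))

    def forward(self, conc, rng_noise):
        drive = conc @ self.w.T @ self.e.T
        r = hill_activation(drive, self.params.hill_coeff)
        if self.params.noise_sd > 0:
            r = r + self.params.noise_sd * rng_noise.standard_normal(r.shape)
        h = np.tanh(self.alpha * r)
        g_act = h @ self.g.T                            # (B, M)
        return g_act, (r, h)

    def backward(self, cache, grad_g):
        r, h = cache
        grad_gmat = grad_g.T @ h                        # (M, L)
        delta_h = grad_g @ self.g                       # (B, L)
        sech2 = 1.0 - h * h
        grad_alpha = float(np.sum(delta_h * r * sech2))
        return {"U": _softmax_row_backward(self.g, grad_gmat),
                "ua": np.array([grad_alpha * self.alpha])}

    def primal_report(self):
        return float(np.abs(self.g.sum(axis=1) - 1.0).max()), float(self.g.min())


# ---------------------------------------------------------------------------
# layer drivers


def optimize_sensing(env: EnvironmentSpec, m: int, l: int,
                     encoding: EncodingParams = EncodingParams(),
                     cfg: OptimizerConfig = OptimizerConfig()):
    """Maximize the bound over ``W`` with canonical expression plugged in."""
    ss = np.random.SeedSequence(cfg.seed).spawn(2)
    sampler = StimulusSampler(env, seed=int(ss[0].generate_state(1)[0] % 2**31))
    rng_init = np.random.default_rng(ss[1])
    scale_batch = sampler.draw(max(cfg.batch_size, 256))
    w0 = init_sensing(m, env.n_odorants, mode=cfg.w_init,
                      batch_for_scale=scale_batch, seed=rng_init,
                      min_sensitivity=cfg.min_sensitivity)
    circuit = _SensingCircuit(w0, make_canonical_expression(m, l), encoding)
    trace, _ = _run_ascent(sampler, cfg, dim_act=l, circuit=circuit)
    return circuit.w, trace


def optimize_expression(env: EnvironmentSpec, w: np.ndarray, l: int,
                        encoding: EncodingParams = EncodingParams(),
                        cfg: OptimizerConfig = OptimizerConfig()):
    """Maximize the bound over row-stochastic ``E`` with fixed ``W``."""
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("W must be fixed, finite, and positive")
    m = w.shape[0]
    ss = np.random.SeedSequence(cfg.seed).spawn(2)
    sampler = StimulusSampler(env, seed=int(ss[0].generate_state(1)[0] % 2**31))
    rng_init = np.random.default_rng(ss[1])
    k_min, k_max = cfg.e_init_k
    e0 = init_expression(m, l, mode=cfg.e_init, k_min=k_min, k_max=k_max,
                         seed=rng_init)
    circuit = _ExpressionCircuit(e0, w, encoding)
    trace, _ = _run_ascent(sampler, cfg, dim_act=l, circuit=circuit)
    return circuit.e, trace, e0


def optimize_glomerular(env: EnvironmentSpec, w: np.ndarray, e: np.ndarray,
                        encoding: EncodingParams = EncodingParams(),
                        cfg: OptimizerConfig = OptimizerConfig()):
    """Maximize the bound over ``(G, alpha)`` with fixed ``W`` and ``E``.

    ``G`` starts from random row-stochastic connectivity and ``alpha`` at
    1; both stay feasible through their mirror maps.  Returns
    ``(G_opt, alpha_opt, trace)``.
    """
    m = w.shape[0]
    l = e.shape[0]
    ss = np.random.SeedSequence(cfg.seed).spawn(2)
    sampler = StimulusSampler(env, seed=int(ss[0].generate_state(1)[0] % 2**31))
    rng_init = np.random.default_rng(ss[1])
    g0 = rng_init.dirichlet(np.ones(l), size=m)
    circuit = _GlomerularCircuit(g0, w, e, encoding, alpha_init=1.0)
    trace, _ = _run_ascent(sampler, cfg, dim_act=m, circuit=circuit)
    return circuit.g, circuit.alpha, trace
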