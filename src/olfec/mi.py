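"""Variational Jensen-Shannon lower bound on mutual information.

Mutual information between stimulus ``c`` and response ``g`` is the KL
divergence between the joint ``p(g, c)`` and the product of marginals
``p(g) p(c)``.  KL-based variational estimators are sample-hungry, so the
optimization proxy used throughout this package is the f-divergence lower
bound for the Jensen-Shannon divergence between those same two
distributions:

    D_JS(P || Q) >= sup_T  E_P[T(x)] - E_Q[f*(T(x))],
    f*(t) = -log(2 - exp(t)),   dom f* = (-inf, ln 2).

Here ``D_JS`` denotes the f-divergence with generator
``f(u) = u ln u - (u + 1) ln((1+u)/2)``, i.e. ``KL(P||M) + KL(Q||M)`` with
``M`` the even mixture (twice the symmetrized "textbook" JSD; each KL term
is at most ln 2).  Samples from the product of marginals come from
shuffling responses against stimuli within a batch.

The critic uses an inner-product architecture ``T(g, c) = chi(g)^T psi(c)``
with two separate two-hidden-layer ReLU networks of width 128, and the raw
inner product ``v`` is squashed to ``ln 2 - softplus(-v)`` so the conjugate
domain constraint ``T < ln 2`` holds by construction (the standard output
activation for the JSD bound in the f-GAN construction).  Everything is
plain NumPy with hand-derived gradients; ``critic_backward`` returns both
parameter gradients and the gradient with respect to the response input so
circuit layers upstream can be trained against the same objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LN2",
    "CriticParams",
    "ConcatCritic",
    "BoundEstimate",
    "init_critic",
    "init_concat_critic",
    "fit_critic",
    "jsd_conjugate",
    "jsd_conjugate_deriv",
    "squash_score",
    "critic_score",
    "shuffle_pairs",
    "jsd_lower_bound",
    "critic_backward",
    "AdamState",
]

LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# scalar pieces


def jsd_conjugate(t):
    """Fenchel conjugate of the JS generator: ``f*(t) = -log(2 - exp(t))``."""
    t = np.asarray(t, dtype=float)
    if np.any(t >= LN2):
        raise ValueError("jsd_conjugate requires t < ln 2")
    out = -np.log(2.0 - np.exp(t))
    return out if out.ndim else float(out)


def jsd_conjugate_deriv(t):
    """d f*/dt = exp(t) / (2 - exp(t))."""
    et = np.exp(np.asarray(t, dtype=float))
    return et / (2.0 - et)


def _softplus(x):
    x = np.asarray(x, dtype=float)
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


def squash_score(v):
    """Map a raw critic value to ``(-inf, ln 2)``: ``ln 2 - softplus(-v)``.

    Clamped a hair below ln 2 so the conjugate's domain survives float
    rounding for very large raw scores.
    """
    out = LN2 - np.maximum(_softplus(-np.asarray(v, dtype=float)), 1e-12)
    return out if out.ndim else float(out)


def squash_deriv(v):
    """d squash / dv = sigmoid(-v)."""
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp(v))


# ---------------------------------------------------------------------------
# critic


@dataclass
class CriticParams:
    """Weights of the two embedding networks chi (responses) and psi (stimuli).

    Each network is input -> hidden -> hidden -> embed with ReLU hidden
    units; ``params[name]`` holds ``W0, b0, W1, b1, W2, b2``.
    """

    chi: dict = field(default_factory=dict)
    psi: dict = field(default_factory=dict)
    embed_dim: int = 128

    def as_flat(self) -> dict:
        flat = {f"chi_{k}": v for k, v in self.chi.items()}
        flat.update({f"psi_{k}": v for k, v in self.psi.items()})
        return flat


def _init_mlp(rng: np.random.Generator, dims: list[int],
              final_scale: float) -> dict:
    params = {}
    for i, (din, dout) in enumerate(zip(dims[:-1], dims[1:])):
        scale = np.sqrt(2.0 / din)
        if i == len(dims) - 2:
            scale *= final_scale
        params[f"W{i}"] = scale * rng.standard_normal((din, dout))
        params[f"b{i}"] = np.zeros(dout)
    return params


def init_critic(dim_g: int, dim_c: int, hidden: int = 128,
                embed_dim: int = 128, seed: int | np.random.Generator = 0,
                final_scale: float = 0.01) -> CriticParams:
    """He-initialized critic; the final layers start small so the raw
    inner product (and hence the bound) starts near zero."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chi = _init_mlp(rng, [dim_g, hidden, hidden, embed_dim], final_scale)
    psi = _init_mlp(rng, [dim_c, hidden, hidden, embed_dim], final_scale)
    return CriticParams(chi=chi, psi=psi, embed_dim=embed_dim)


def _mlp_forward(params: dict, x: np.ndarray):
    """Forward pass with cache for backprop."""
    h0 = x @ params["W0"] + params["b0"]
    a0 = np.maximum(h0, 0.0)
    h1 = a0 @ params["W1"] + params["b1"]
    a1 = np.maximum(h1, 0.0)
    out = a1 @ params["W2"] + params["b2"]
    return out, (x, h0, a0, h1, a1)


def _mlp_backward(params: dict, cache, grad_out: np.ndarray):
    """Returns (param grads, grad wrt input)."""
    x, h0, a0, h1, a1 = cache
    grads = {}
    grads["W2"] = a1.T @ grad_out
    grads["b2"] = grad_out.sum(axis=0)
    da1 = grad_out @ params["W2"].T
    dh1 = da1 * (h1 > 0)
    grads["W1"] = a0.T @ dh1
    grads["b1"] = dh1.sum(axis=0)
    da0 = dh1 @ params["W1"].T
    dh0 = da0 * (h0 > 0)
    grads["W0"] = x.T @ dh0
    grads["b0"] = dh0.sum(axis=0)
    dx = dh0 @ params["W0"].T
    return grads, dx


def critic_score(params, g: np.ndarray, c: np.ndarray):
    """Squashed critic value per paired row: ``squash(chi(g)^T psi(c))``
    for the inner-product architecture, ``squash(MLP([g, c]))`` for the
    concatenation spot-check.  Always strictly below ln 2.
    """
    g = np.atleast_2d(np.asarray(g, dtype=float))
    c = np.atleast_2d(np.asarray(c, dtype=float))
    if g.shape[0] != c.shape[0]:
        raise ValueError("g and c must pair row-for-row")
    if isinstance(params, ConcatCritic):
        v = _mlp_forward(params.net, np.concatenate([g, c], axis=1))[0][:, 0]
    else:
        eg, _ = _mlp_forward(params.chi, g)
        ec, _ = _mlp_forward(params.psi, c)
        v = np.einsum("bd,bd->b", eg, ec)
    if not np.all(np.isfinite(v)):
        raise FloatingPointError("non-finite critic score")
    s = squash_score(v)
    return float(s[0]) if s.size == 1 and np.asarray(g).ndim == 1 else s


def shuffle_pairs(g: np.ndarray, c: np.ndarray,
                  seed: int | np.random.Generator = 0):
    """Product-of-marginals sample: ``(g[perm], c)`` for a uniform permutation."""
    g = np.asarray(g)
    c = np.asarray(c)
    if g.shape[0] != c.shape[0]:
        raise ValueError("batch sizes must match")
    if g.shape[0] < 2:
        raise ValueError("need at least 2 samples to shuffle")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(g.shape[0])
    return g[perm], c, perm


@dataclass(frozen=True)
class BoundEstimate:
    """Scalar JSD lower-bound value (nats) with batch bookkeeping."""

    value: float
    n_joint: int
    n_marginal: int
    step_index: int = 0


def jsd_lower_bound(params: CriticParams, joint: tuple, shuffled: tuple,
                    step_index: int = 0) -> BoundEstimate:
    """Evaluate ``mean T(joint) - mean f*(T(shuffled))``.

    ``joint`` and ``shuffled`` are ``(g, c)`` pairs; the latter should come
    from :func:`shuffle_pairs` (or any product-of-marginals sample).
    """
    gj, cj = joint
    gm, cm = shuffled
    if len(gj) == 0 or len(gm) == 0:
        raise ValueError("batches must be non-empty")
    tj = np.atleast_1d(critic_score(params, gj, cj))
    tm = np.atleast_1d(critic_score(params, gm, cm))
    value = float(np.mean(tj) - np.mean(jsd_conjugate(tm)))
    if not np.isfinite(value):
        raise FloatingPointError("non-finite bound estimate")
    return BoundEstimate(value=value, n_joint=len(tj), n_marginal=len(tm),
                         step_index=step_index)


def critic_backward(params: CriticParams, g: np.ndarray, c: np.ndarray,
                    perm: np.ndarray):
    """Bound value and gradients for one batch.

    Joint pairs are ``(g_i, c_i)``; marginal pairs are ``(g_perm[i], c_i)``.
    Returns ``(value, param_grads, grad_g)`` where ``param_grads`` mirrors
    ``CriticParams.as_flat()`` and ``grad_g`` is d(bound)/d(g) — the hook
    through which circuit layers receive their learning signal.  chi and
    psi each run exactly once over the batch.
    """
    if isinstance(params, ConcatCritic):
        return _concat_score_backward(params, g, c, perm)
    g = np.asarray(g, dtype=float)
    c = np.asarray(c, dtype=float)
    b = g.shape[0]
    eg, cache_g = _mlp_forward(params.chi, g)
    ec, cache_c = _mlp_forward(params.psi, c)

    v_joint = np.einsum("bd,bd->b", eg, ec)
    v_marg = np.einsum("bd,bd->b", eg[perm], ec)
    t_joint = squash_score(v_joint)
    t_marg = squash_score(v_marg)
    value = float(np.mean(t_joint) - np.mean(jsd_conjugate(t_marg)))

    # d(bound)/d(raw inner product) for each pairing
    coef_joint = squash_deriv(v_joint) / b
    coef_marg = -jsd_conjugate_deriv(t_marg) * squash_deriv(v_marg) / b

    # gradients wrt the embeddings; the marginal term pairs eg[perm] with ec
    grad_eg = coef_joint[:, None] * ec
    np.add.at(grad_eg, perm, coef_marg[:, None] * ec)
    grad_ec = coef_joint[:, None] * eg + coef_marg[:, None] * eg[perm]

    grads_chi, grad_g = _mlp_backward(params.chi, cache_g, grad_eg)
    grads_psi, _ = _mlp_backward(params.psi, cache_c, grad_ec)
    param_grads = {f"chi_{k}": v for k, v in grads_chi.items()}
    param_grads.update({f"psi_{k}": v for k, v in grads_psi.items()})
    return value, param_grads, grad_g


@dataclass
class ConcatCritic:
    """Spot-check critic: one MLP on the concatenated pair ``[g, c]``.

    An alternative to the inner-product architecture used to confirm that
    results do not hinge on the critic family.  Same squashed output.
    """

    net: dict = field(default_factory=dict)

    def as_flat(self) -> dict:
        return {f"net_{k}": v for k, v in self.net.items()}


def init_concat_critic(dim_g: int, dim_c: int, hidden: int = 128,
                       seed: int | np.random.Generator = 0,
                       final_scale: float = 0.01) -> ConcatCritic:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return ConcatCritic(net=_init_mlp(rng, [dim_g + dim_c, hidden, hidden, 1],
                                      final_scale))


def _concat_score_backward(params: ConcatCritic, g, c, perm):
    g = np.asarray(g, dtype=float)
    c = np.asarray(c, dtype=float)
    b = g.shape[0]
    x_joint = np.concatenate([g, c], axis=1)
    x_marg = np.concatenate([g[perm], c], axis=1)
    vj, cache_j = _mlp_forward(params.net, x_joint)
    vm, cache_m = _mlp_forward(params.net, x_marg)
    vj, vm = vj[:, 0], vm[:, 0]
    tj, tm = squash_score(vj), squash_score(vm)
    value = float(np.mean(tj) - np.mean(jsd_conjugate(tm)))
    coef_j = (squash_deriv(vj) / b)[:, None]
    coef_m = (-jsd_conjugate_deriv(tm) * squash_deriv(vm) / b)[:, None]
    grads_j, dx_j = _mlp_backward(params.net, cache_j, coef_j)
    grads_m, dx_m = _mlp_backward(params.net, cache_m, coef_m)
    grads = {f"net_{k}": grads_j[k] + grads_m[k] for k in grads_j}
    grad_g = dx_j[:, :g.shape[1]].copy()
    np.add.at(grad_g, perm, dx_m[:, :g.shape[1]])
    return value, grads, grad_g


def fit_critic(pair_sampler, dim_g: int, dim_c: int, n_steps: int = 500,
               batch_size: int = 256, step_size: float = 1e-3,
               hidden: int = 64, embed_dim: int = 64,
               seed: int = 0, eval_samples: int = 4096,
               architecture: str = "inner_product"):
    """Train a critic on paired samples and evaluate the bound held-out.

    ``pair_sampler(batch_size, rng) -> (g, c)`` draws fresh joint samples.
    Returns ``(critic, BoundEstimate)`` where the estimate is computed on
    a fresh evaluation batch (so it is not inflated by critic overfit).
    ``architecture`` switches to the ``concat`` spot-check critic.
    """
    ss = np.random.SeedSequence(seed)
    s_init, s_data, s_perm, s_eval = ss.spawn(4)
    rng_data = np.random.default_rng(s_data)
    rng_perm = np.random.default_rng(s_perm)
    if architecture == "concat":
        critic = init_concat_critic(dim_g, dim_c, hidden=hidden,
                                    seed=np.random.default_rng(s_init))
    else:
        critic = init_critic(dim_g, dim_c, hidden=hidden, embed_dim=embed_dim,
                             seed=np.random.default_rng(s_init))
    flat = critic.as_flat()
    adam = AdamState(step_size)
    for _ in range(n_steps):
        g, c = pair_sampler(batch_size, rng_data)
        perm = rng_perm.permutation(len(g))
        _, grads, _ = critic_backward(critic, np.asarray(g, float),
                                      np.asarray(c, float), perm)
        adam.update(flat, grads)
    rng_eval = np.random.default_rng(s_eval)
    g, c = pair_sampler(eval_samples, rng_eval)
    g, c = np.asarray(g, float), np.asarray(c, float)
    gs, cs, _ = shuffle_pairs(g, c, rng_eval)
    estimate = jsd_lower_bound(critic, (g, c), (gs, cs), step_index=n_steps)
    return critic, estimate


# ---------------------------------------------------------------------------
# optimizer state (shared by critic and circuit duals)


class AdamState:
    """Minimal Adam accumulator over a dict of arrays (ascent convention)."""

    def __init__(self, step_size: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.step_size = step_size
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def update(self, params: dict, grads: dict) -> None:
        """In-place ascent step ``params += step``."""
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for key, grad in grads.items():
            if key not in self.m:
                self.m[key] = np.zeros_like(grad)
                self.v[key] = np.zeros_like(grad)
            self.m[key] = b1 * self.m[key] + (1 - b1) * grad
            self.v[key] = b2 * self.v[key] + (1 - b2) * grad * grad
            mhat = self.m[key] / corr1
            vhat = self.v[key] / corr2
            params[key] += self.step_size * mhat / (np.sqrt(vhat) + self.eps)
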