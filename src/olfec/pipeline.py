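"""Experiment orchestration: single runs, phase sweeps, consolidated reports.

A run directory contains ``params.h5`` (circuit matrices), ``trace.tsv``
(bound and constraint residuals per step), ``metrics.json`` (the metrics
report), ``events.jsonl`` (coarse training log), and ``manifest.json``
(config digest + seeds), so any run can be regenerated exactly from its
manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import metrics as cm
from .encoding import (EncodingParams, glomerular_response,
                       make_canonical_expression, neural_response)
from .environment import EnvironmentSpec, StimulusSampler, generate_stimuli
from .io import save_circuit, save_trace_tsv
from .optimize import (OptimizerConfig, init_sensing, optimize_expression,
                       optimize_glomerular, optimize_sensing)

__all__ = ["ExperimentConfig", "SweepGrid", "run_experiment",
           "run_phase_sweep", "write_report"]

_NULL_MODES = ("shuffleGlobal", "shuffleRows", "lognormalFit",
               "lognormalBlock", "lognormalToeplitz")
REPORT_SCHEMA = 1


@dataclass(frozen=True)
class ExperimentConfig:
    """One named experiment: environment + circuit sizes + optimizer settings.

    ``experiment`` is one of ``sensing``, ``expression``, ``glomerular``.
    ``w_source`` controls where the fixed ``W`` of the expression and
    glomerular stages comes from: ``optimize`` (run the sensing stage
    first), ``init`` (scaled log-normal, no optimization), or one of the
    null-surrogate modes applied to the optimized ``W``.
    """

    experiment: str
    env: EnvironmentSpec
    n_receptors: int
    n_neurons: int
    encoding: EncodingParams = EncodingParams()
    optimizer: OptimizerConfig = OptimizerConfig()
    w_source: str = "optimize"
    e_source: str = "canonical"          # glomerular stage: canonical | optimize
    w_steps: int | None = None           # step budget for the auxiliary W stage
    eval_samples: int = 2000

    def __post_init__(self) -> None:
        if self.experiment not in ("sensing", "expression", "glomerular"):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.encoding.hill_coeff <= 0:
            raise ValueError("hill_coeff must be positive")
        if self.w_source not in ("optimize", "init") + _NULL_MODES:
            raise ValueError(f"unknown w_source {self.w_source!r}")
        if not 1 <= self.n_receptors <= self.n_neurons:
            raise ValueError("need 1 <= M <= L")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        d["env"] = EnvironmentSpec(**d["env"])
        d["encoding"] = EncodingParams(**d.get("encoding", {}))
        opt = d.get("optimizer", {})
        if "e_init_k" in opt:
            opt["e_init_k"] = tuple(opt["e_init_k"])
        d["optimizer"] = OptimizerConfig(**opt)
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass(frozen=True)
class SweepGrid:
    """Phase-diagram grid over source count k and log-noise sigma_c."""

    k_values: tuple[int, ...] = (4, 8, 16, 32, 64)
    sigma_c_values: tuple[float, ...] = (1.0, 2.0, 3.0)
    seeds_per_cell: int = 1
    w_mode: str = "shuffleGlobal"

    def __post_init__(self) -> None:
        if not self.k_values or not self.sigma_c_values:
            raise ValueError("sweep grid must be non-empty")
        if self.seeds_per_cell < 1:
            raise ValueError("need at least one seed per cell")


def _resolve_w(config: ExperimentConfig):
    """Produce the fixed W for downstream stages per ``w_source``."""
    opt = config.optimizer
    w_cfg = opt if config.w_steps is None else replace(opt, n_steps=config.w_steps)
    if config.w_source == "init":
        sampler = StimulusSampler(config.env, seed=opt.seed + 1)
        batch = sampler.draw(max(opt.batch_size, 256))
        return init_sensing(config.n_receptors, config.env.n_odorants,
                            mode=opt.w_init, batch_for_scale=batch,
                            seed=opt.seed, min_sensitivity=opt.min_sensitivity)
    w_opt, _ = optimize_sensing(config.env, config.n_receptors,
                                config.n_neurons, config.encoding, w_cfg)
    if config.w_source == "optimize":
        return w_opt
    return cm.make_null_sensing(w_opt, config.w_source, seed=opt.seed)


def _metrics_for_sensing(w, config) -> dict:
    mu, sd, ks = cm.fit_lognormal_nonzero(w)
    n_spec, pairs = cm.count_specialists(w)
    dr = cm.odorant_dynamic_range(w, config.encoding.hill_coeff)
    batch = generate_stimuli(config.env, config.eval_samples)
    freq = np.asarray(batch.cbin).mean(axis=0)
    rho = _spearman(freq, dr)
    return {
        "sparsity_fraction": cm.sparsity_fraction(w),
        "lognormal_log_mean": mu, "lognormal_log_sd": sd, "lognormal_ks": ks,
        "specialist_count": n_spec, "specialist_pairs": pairs,
        "effective_rank": cm.effective_rank(w),
        "frequency_dynamic_range_spearman": rho,
        "zero_threshold": cm.default_zero_threshold(w),
    }


def _spearman(x, y) -> float:
    from scipy import stats
    res = stats.spearmanr(x, y)
    return float(res.statistic)


def _metrics_for_expression(e, e0, w, config) -> dict:
    batch = generate_stimuli(config.env, config.eval_samples)
    r_opt = neural_response(w, e, batch, config.encoding, seed=7)
    r_init = neural_response(w, e0, batch, config.encoding, seed=7)
    coex = cm.robust_coexpression_stats(e, w)
    return {
        "canonical_score_init": cm.canonical_score(e0),
        "canonical_score": cm.canonical_score(e),
        "top_pc_fraction": float(cm.pc_variance_spectrum(r_opt)[0]),
        "top_pc_fraction_init": float(cm.pc_variance_spectrum(r_init)[0]),
        "n_robust_coexpressed_pairs": len(coex["robust_pairs"]),
        "coexpression_p_value": coex["p_value"],
        "effective_rank_W": cm.effective_rank(w),
    }


def _metrics_for_glomerular(g, alpha, w, e, config) -> dict:
    batch = generate_stimuli(config.env, config.eval_samples)
    r = neural_response(w, e, batch, config.encoding, seed=7)
    act_base = glomerular_response(g, r, alpha=1.0)
    act_opt = glomerular_response(g, r, alpha=alpha)
    return {
        "glomerular_purity": cm.glomerular_purity(g, e),
        "alpha_opt": float(alpha),
        "activity_entropy_alpha1": cm.activity_histogram_entropy(act_base),
        "activity_entropy_opt": cm.activity_histogram_entropy(act_opt),
        "uniform_purity_baseline": 1.0 / config.n_receptors,
    }


def run_experiment(config: ExperimentConfig, out_dir) -> Path:
    """Execute generate -> optimize -> metrics for one experiment.

    Returns the run directory.  Idempotent given identical config + seed
    (timestamps in the manifest aside).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    enc, opt = config.encoding, config.optimizer

    if config.experiment == "sensing":
        w, trace = optimize_sensing(config.env, config.n_receptors,
                                    config.n_neurons, enc, opt)
        report = _metrics_for_sensing(w, config)
        save_circuit(out / "params.h5", w=w, hill_coeff=enc.hill_coeff,
                     noise_sd=enc.noise_sd)
    elif config.experiment == "expression":
        w = _resolve_w(config)
        e, trace, e0 = optimize_expression(config.env, w, config.n_neurons,
                                           enc, opt)
        report = _metrics_for_expression(e, e0, w, config)
        save_circuit(out / "params.h5", w=w, e=e, hill_coeff=enc.hill_coeff,
                     noise_sd=enc.noise_sd)
    else:
        w = _resolve_w(config)
        if config.e_source == "canonical":
            e = make_canonical_expression(config.n_receptors, config.n_neurons)
        else:
            e, _, _ = optimize_expression(config.env, w, config.n_neurons,
                                          enc, opt)
        g, alpha, trace = optimize_glomerular(config.env, w, e, enc, opt)
        report = _metrics_for_glomerular(g, alpha, w, e, config)
        save_circuit(out / "params.h5", w=w, e=e, g=g, alpha=alpha,
                     hill_coeff=enc.hill_coeff, noise_sd=enc.noise_sd)

    report["provenance"] = {
        "config_digest": config.digest(),
        "env_digest": config.env.digest(),
        "experiment": config.experiment,
        "seed": opt.seed,
        "schema_version": REPORT_SCHEMA,
    }
    save_trace_tsv(out / "trace.tsv", trace)
    (out / "metrics.json").write_text(json.dumps(report, indent=2,
                                                 default=_jsonify))
    with open(out / "events.jsonl", "w") as fh:
        stride = max(1, len(trace.bound_values) // 50)
        for step in range(0, len(trace.bound_values), stride):
            fh.write(json.dumps({
                "step": step,
                "bound": float(trace.bound_values[step]),
                "max_row_sum_dev": float(trace.max_row_sum_dev[step]),
            }) + "\n")
    manifest = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": opt.seed,
        "wall_time_s": time.time() - t_start,
        "schema_version": REPORT_SCHEMA,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=_jsonify))
    return out


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return str(obj)


def _cell_seed(master_seed: int, k: int, sigma_c: float, index: int) -> int:
    payload = f"{master_seed}:{k}:{sigma_c}:{index}".encode()
    return int.from_bytes(hashlib.sha256(payload).digest()[:4], "little") % 2**31


def run_phase_sweep(grid: SweepGrid, base: ExperimentConfig,
                    out_dir=None) -> list[dict]:
    """Canonical-score phase diagram over (k, sigma_c).

    For each cell: rebuild the environment, obtain ``W`` per the grid's
    ``w_mode``, optimize expression from the configured init, and record
    the final canonical score.  Per-cell seeds derive from
    ``(master seed, k, sigma_c, cell index)`` so cells are independent and
    individually rerunnable.  Failures are recorded and the sweep
    continues.
    """
    rows = []
    for k in grid.k_values:
        for sigma_c in grid.sigma_c_values:
            scores = []
            for idx in range(grid.seeds_per_cell):
                seed = _cell_seed(base.optimizer.seed, k, sigma_c, idx)
                env = EnvironmentSpec.default(
                    n_odorants=base.env.n_odorants, n_blocks=k,
                    conc_log_sd=sigma_c, seed=seed)
                cfg = replace(base, experiment="expression", env=env,
                              w_source=grid.w_mode,
                              optimizer=replace(base.optimizer, seed=seed))
                try:
                    w = _resolve_w(cfg)
                    e, _, e0 = optimize_expression(env, w, cfg.n_neurons,
                                                   cfg.encoding, cfg.optimizer)
                    scores.append({"seed": seed,
                                   "score_init": cm.canonical_score(e0),
                                   "score": cm.canonical_score(e)})
                except Exception as exc:   # noqa: BLE001 - sweep must continue
                    scores.append({"seed": seed, "error": str(exc)})
            ok = [s["score"] for s in scores if "score" in s]
            rows.append({"k": k, "sigma_c": sigma_c,
                         "mean_score": float(np.mean(ok)) if ok else None,
                         "per_seed": scores})
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "sweep.json").write_text(json.dumps(rows, indent=2))
        with open(out / "sweep.tsv", "w") as fh:
            fh.write("k\tsigma_c\tmean_score\n")
            for row in rows:
                fh.write(f"{row['k']}\t{row['sigma_c']}\t{row['mean_score']}\n")
    return rows


def write_report(run_dirs, out_path=None) -> dict:
    """Merge per-run metrics into one comparison document.

    Adds trend summaries where the inputs support them: specialist count
    vs number of receptors, and canonical score vs neural noise.
    """
    run_dirs = list(run_dirs)
    if not run_dirs:
        raise ValueError("need at least one completed run")
    runs = []
    for d in run_dirs:
        d = Path(d)
        report = json.loads((d / "metrics.json").read_text())
        manifest = json.loads((d / "manifest.json").read_text())
        if manifest.get("schema_version") != REPORT_SCHEMA:
            raise ValueError(f"run {d} has schema version "
                             f"{manifest.get('schema_version')}, expected "
                             f"{REPORT_SCHEMA}")
        runs.append({"run_dir": str(d), "metrics": report,
                     "config": manifest["config"]})
    merged: dict = {"schema_version": REPORT_SCHEMA, "n_runs": len(runs),
                    "runs": runs, "trends": {}}
    spec_runs = [(r["config"]["n_receptors"], r["metrics"]["specialist_count"])
                 for r in runs if "specialist_count" in r["metrics"]]
    if len(spec_runs) >= 2:
        spec_runs.sort()
        counts = [c for _, c in spec_runs]
        merged["trends"]["specialists_vs_M"] = {
            "M": [m for m, _ in spec_runs], "count": counts,
            "non_decreasing": all(a <= b for a, b in zip(counts, counts[1:]))}
    noise_runs = [(r["config"]["encoding"]["noise_sd"],
                   r["metrics"]["canonical_score"])
                  for r in runs if "canonical_score" in r["metrics"]]
    if len(noise_runs) >= 2:
        noise_runs.sort()
        scores = [s for _, s in noise_runs]
        merged["trends"]["canonical_score_vs_noise"] = {
            "noise_sd": [n for n, _ in noise_runs], "score": scores,
            "non_decreasing": all(a <= b + 1e-12
                                  for a, b in zip(scores, scores[1:]))}
    if out_path is not None:
        Path(out_path).write_text(json.dumps(merged, indent=2,
                                             default=_jsonify))
    return merged
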