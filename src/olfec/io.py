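"""HDF5 persistence for stimuli and circuit parameters, TSV traces."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .environment import EnvironmentSpec, StimulusBatch
from .optimize import OptimizationTrace

__all__ = [
    "save_stimulus_batch",
    "load_stimulus_batch",
    "save_circuit",
    "load_circuit",
    "save_trace_tsv",
]


def save_stimulus_batch(path, batch: StimulusBatch,
                        spec: EnvironmentSpec | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("cbin", data=np.asarray(batch.cbin, dtype=np.uint8),
                         compression="gzip")
        f.create_dataset("conc", data=np.asarray(batch.conc, dtype=np.float64),
                         compression="gzip")
        f.attrs["seed"] = batch.seed
        f.attrs["spec_digest"] = batch.spec_digest
        if spec is not None:
            f.attrs["spec_json"] = spec.to_json()


def load_stimulus_batch(path) -> StimulusBatch:
    with h5py.File(path, "r") as f:
        return StimulusBatch(cbin=f["cbin"][:], conc=f["conc"][:],
                             seed=int(f.attrs["seed"]),
                             spec_digest=str(f.attrs.get("spec_digest", "")))


def save_circuit(path, *, w=None, e=None, g=None, alpha=None,
                 hill_coeff=None, noise_sd=None, extra: dict | None = None) -> None:
    """Persist any subset of circuit parameters with shape metadata."""
    with h5py.File(path, "w") as f:
        for name, mat in (("W", w), ("E", e), ("G", g)):
            if mat is not None:
                f.create_dataset(name, data=np.asarray(mat, dtype=np.float64),
                                 compression="gzip")
        for name, val in (("alpha", alpha), ("hill_coeff", hill_coeff),
                          ("noise_sd", noise_sd)):
            if val is not None:
                f.attrs[name] = float(val)
        if extra:
            f.attrs["extra_json"] = json.dumps(extra, sort_keys=True)


def load_circuit(path) -> dict:
    out: dict = {}
    with h5py.File(path, "r") as f:
        for name in ("W", "E", "G"):
            if name in f:
                out[name.lower()] = f[name][:]
        for name in ("alpha", "hill_coeff", "noise_sd"):
            if name in f.attrs:
                out[name] = float(f.attrs[name])
        if "extra_json" in f.attrs:
            out["extra"] = json.loads(f.attrs["extra_json"])
    return out


def save_trace_tsv(path, trace: OptimizationTrace) -> None:
    arr = np.column_stack([np.arange(len(trace.bound_values)),
                           trace.bound_values,
                           trace.max_row_sum_dev,
                           trace.min_entry])
    header = "step\tbound\tmax_row_sum_dev\tmin_entry"
    np.savetxt(Path(path), arr, delimiter="\t", header=header, comments="",
               fmt=("%d", "%.8g", "%.3e", "%.3e"))
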