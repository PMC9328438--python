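"""Trace, curve and table I/O.

Traces are stored as HDF5 (dataset ``/counts`` as uint32, attributes
``bin_time`` and ``duration``, metadata as a JSON attribute string) with
a CSV export for interoperability; correlation curves and dose-response
tables are plain CSV; fit results serialize to JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .correlator import CorrelationCurve
from .simkit import DoseResponseDataset, PhotonTrace

__all__ = ["save_trace", "load_trace", "trace_to_csv", "curve_to_csv",
           "curve_from_csv", "histogram_to_csv", "dose_response_to_csv",
           "dose_response_from_csv", "fit_report_json"]


def save_trace(trace: PhotonTrace, path) -> None:
    meta = {k: v for k, v in trace.metadata.items()
            if not isinstance(v, np.ndarray)}
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=trace.counts.astype(np.uint32),
                         compression="gzip")
        f.attrs["bin_time"] = trace.bin_time
        f.attrs["duration"] = trace.duration
        f.attrs["metadata"] = json.dumps(meta)


def load_trace(path) -> PhotonTrace:
    with h5py.File(path, "r") as f:
        counts = f["counts"][:].astype(np.int64)
        bin_time = float(f.attrs["bin_time"])
        duration = float(f.attrs["duration"])
        meta = json.loads(f.attrs.get("metadata", "{}"))
    return PhotonTrace(counts, bin_time, duration, meta)


def trace_to_csv(trace: PhotonTrace, path) -> None:
    pd.DataFrame({"bin_index": np.arange(trace.n_bins),
                  "count": trace.counts}).to_csv(path, index=False)


def curve_to_csv(curve: CorrelationCurve, path) -> None:
    pd.DataFrame({"lag_s": curve.lags, "G": curve.G,
                  "npts": curve.npts}).to_csv(path, index=False)


def curve_from_csv(path, mean_rate: float = float("nan"),
                   bin_time: float = 0.0) -> CorrelationCurve:
    df = pd.read_csv(path)
    return CorrelationCurve(df["lag_s"].to_numpy(), df["G"].to_numpy(),
                            df["npts"].to_numpy(), mean_rate, bin_time)


def histogram_to_csv(hist, path) -> None:
    pd.DataFrame({"k": hist.k, "frequency": hist.frequency}).to_csv(
        path, index=False)


def dose_response_to_csv(data: DoseResponseDataset, path) -> None:
    rows = [(c, data.responses[i, r], r)
            for i, c in enumerate(data.concentrations)
            for r in range(data.replicates)]
    pd.DataFrame(rows, columns=["concentration_M", "response",
                                "replicate"]).to_csv(path, index=False)


def dose_response_from_csv(path) -> DoseResponseDataset:
    df = pd.read_csv(path)
    if "replicate" not in df.columns:
        df["replicate"] = 0
    wide = df.pivot_table(index="concentration_M", columns="replicate",
                          values="response").sort_index()
    return DoseResponseDataset(wide.index.to_numpy(), wide.to_numpy(),
                               wide.shape[1])


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def fit_report_json(result, path=None) -> str:
    """Serialize any fit-result dataclass to JSON (optionally to a file)."""
    text = json.dumps(_to_jsonable(result), indent=2, allow_nan=True)
    if path is not None:
        Path(path).write_text(text)
    return text
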