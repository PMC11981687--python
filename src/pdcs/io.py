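"""Shared file formats of the pipeline.

FrameStreams travel as HDF5 (binary counts plus timing attributes, with a
JSON sidecar holding the full simulation config and an optional ground-truth
BFI CSV); correlation records, BFI traces, markers and trial tables are plain
CSV; summary metrics are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .correlator import CorrelationRecord
from .pulse_markers import PulseMarkerSet, PulseMetrics
from .speckle_sim import FrameStream
from .traces import BfiTrace

__all__ = [
    "write_frame_stream",
    "read_frame_stream",
    "records_to_csv",
    "read_records_csv",
    "trace_to_csv",
    "read_trace_csv",
    "markers_to_csv",
    "metrics_to_json",
]


def write_frame_stream(path: str | Path, stream: FrameStream) -> Path:
    """Write a FrameStream container (HDF5 + JSON sidecar + truth CSV)."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("counts", data=stream.counts.astype(np.uint8),
                          compression="gzip", compression_opts=1)
        h5.attrs["exposure_s"] = stream.exposure_s
        h5.attrs["frame_period_s"] = stream.frame_period_s
        h5.attrs["sds_cm"] = stream.sds_cm
        h5.attrs["wavelength_nm"] = stream.wavelength_nm
        h5.attrs["n_rows"] = -1 if stream.n_rows is None else stream.n_rows
        h5.attrs["seed"] = -1 if stream.seed is None else stream.seed
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(stream.config, indent=2, sort_keys=True))
    if stream.ground_truth is not None:
        truth = path.with_name(path.stem + "_truth.csv")
        pd.DataFrame({
            "time_s": stream.ground_truth.times,
            "bfi_cm2_per_s": stream.ground_truth.bfi,
        }).to_csv(truth, index=False)
    return path


def read_frame_stream(path: str | Path) -> FrameStream:
    path = Path(path)
    with h5py.File(path, "r") as h5:
        counts = h5["counts"][...]
        attrs = dict(h5.attrs)
    sidecar = path.with_suffix(".json")
    config = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    truth_path = path.with_name(path.stem + "_truth.csv")
    truth = None
    if truth_path.exists():
        df = pd.read_csv(truth_path)
        truth = BfiTrace(times=df["time_s"].to_numpy(),
                         bfi=df["bfi_cm2_per_s"].to_numpy())
    n_rows = int(attrs.get("n_rows", -1))
    seed = int(attrs.get("seed", -1))
    return FrameStream(
        counts=counts,
        exposure_s=float(attrs["exposure_s"]),
        frame_period_s=float(attrs["frame_period_s"]),
        sds_cm=float(attrs["sds_cm"]),
        wavelength_nm=float(attrs["wavelength_nm"]),
        n_rows=None if n_rows < 0 else n_rows,
        seed=None if seed < 0 else seed,
        config=config,
        ground_truth=truth,
    )


def records_to_csv(records: Sequence[CorrelationRecord], path: str | Path) -> Path:
    """Long-format CSV: one row per (window, delay)."""
    rows = []
    for r in records:
        for tau, g2 in zip(r.delays, r.g2):
            rows.append({
                "window_start_s": r.window_start,
                "window_length_s": r.window_length,
                "tau_s": tau,
                "g2": g2,
                "n_pixels": r.n_pixels_averaged,
                "n_curves": r.n_curves_averaged,
                "mean_rate": r.mean_rate,
                "valid": r.valid,
            })
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_records_csv(path: str | Path) -> list[CorrelationRecord]:
    df = pd.read_csv(path)
    records = []
    for start, grp in df.groupby("window_start_s", sort=True):
        grp = grp.sort_values("tau_s")
        records.append(CorrelationRecord(
            window_start=float(start),
            window_length=float(grp["window_length_s"].iloc[0]),
            delays=grp["tau_s"].to_numpy(),
            g2=grp["g2"].to_numpy(),
            n_pixels_averaged=int(grp["n_pixels"].iloc[0]),
            n_curves_averaged=int(grp["n_curves"].iloc[0]),
            mean_rate=float(grp["mean_rate"].iloc[0]),
            valid=bool(grp["valid"].iloc[0]),
        ))
    return records


def trace_to_csv(trace: BfiTrace, path: str | Path) -> Path:
    path = Path(path)
    n = len(trace)
    pd.DataFrame({
        "time_s": trace.times,
        "bfi_cm2_per_s": trace.bfi,
        "beta": trace.beta if trace.beta is not None else np.full(n, np.nan),
        "residual": trace.residual if trace.residual is not None else np.full(n, np.nan),
        "valid": trace.valid,
        "segment": [trace.segment_label or ""] * n,
    }).to_csv(path, index=False)
    return path


def read_trace_csv(path: str | Path) -> BfiTrace:
    df = pd.read_csv(path)
    label = str(df["segment"].iloc[0]) if "segment" in df and len(df) else None
    return BfiTrace(
        times=df["time_s"].to_numpy(),
        bfi=df["bfi_cm2_per_s"].to_numpy(),
        beta=df["beta"].to_numpy() if "beta" in df else None,
        residual=df["residual"].to_numpy() if "residual" in df else None,
        valid=df["valid"].to_numpy(dtype=bool) if "valid" in df else None,
        segment_label=label or None,
    )


def markers_to_csv(markers: PulseMarkerSet, path: str | Path) -> Path:
    rows = []
    for kind in ("sp", "de", "dn", "dp"):
        times = getattr(markers, f"{kind}_times")
        values = getattr(markers, f"{kind}_values")
        for t, v in zip(times, values):
            rows.append({"kind": kind.upper(), "time_s": t, "bfi": v})
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def metrics_to_json(metrics: PulseMetrics, markers: PulseMarkerSet,
                    path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "pulse_rate_hz": markers.pulse_rate,
        "pi": metrics.pi,
        "mean_bfi": metrics.mean_bfi,
        "mean_sp": metrics.mean_sp,
        "mean_de": metrics.mean_de,
        "counts": {
            "sp": int(markers.sp_idx.size),
            "de": int(markers.de_idx.size),
            "dn": int(markers.dn_idx.size),
            "dp": int(markers.dp_idx.size),
            "discarded_dn_dp": markers.discarded_dn_dp,
        },
    }
    path.write_text(json.dumps(payload, indent=2))
    return path
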