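"""Marker-conditioned g2 noise and the multi-speckle noise-scaling law.

The noise of an in vivo PDCS measurement is estimated as the standard
deviation of each g2(tau) value across repeated windows taken under similar
blood-flow conditions — all systolic peaks of a trial, or all diastolic
endpoints — averaged over delays:

    N_bar = < std_n(g2(tau)) >_tau

Because every SPAD pixel performs an independent measurement, averaging M
pixels reduces this noise by sqrt(M); a 32x32 array therefore buys a 32-fold
noise reduction over a single pixel.  ``noise_vs_pixels`` measures that
scaling on a stream, and ``parallel_noise_ratio`` runs the full
simulate-correlate-measure recipe for the single-pixel versus full-array
noise ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.random import default_rng

from . import speckle_sim
from .correlator import CorrelationRecord, per_pixel_window_g2
from .speckle_sim import (
    DetectorSimParams,
    FrameStream,
    OpticalProperties,
    ProbeGeometry,
)

__all__ = [
    "NoiseSummary",
    "g2_noise_at_markers",
    "noise_vs_pixels",
    "parallel_noise_ratio",
]


@dataclass
class NoiseSummary:
    """Marker-conditioned g2 noise of one trial.

    ``per_delay_noise`` maps each condition ('sp', 'de') to N(tau) over the
    evaluated delays; ``n_bar_*`` are the delay averages; ``n_markers_used``
    counts the windows entering each standard deviation.
    """

    n_bar_sp: float
    n_bar_de: float | None
    n_markers_used: dict
    per_delay_noise: dict
    delays: np.ndarray


def _records_matrix(records: Sequence[CorrelationRecord]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    delays = records[0].delays
    for r in records[1:]:
        if not np.allclose(r.delays, delays):
            raise ValueError("all records must share one delay grid")
    g2 = np.vstack([r.g2 for r in records])
    starts = np.array([r.window_start for r in records])
    return g2, starts, delays


def _nearest_windows(starts: np.ndarray, times: np.ndarray) -> np.ndarray:
    # nearest window_start per marker; collisions intentionally keep both
    # draws so the count n is preserved
    idx = np.searchsorted(starts, times)
    idx = np.clip(idx, 1, starts.size - 1)
    left = idx - 1
    choose_left = np.abs(times - starts[left]) <= np.abs(starts[idx] - times)
    return np.where(choose_left, left, idx)


def g2_noise_at_markers(
    records: Sequence[CorrelationRecord],
    sp_times: np.ndarray,
    de_times: np.ndarray | None = None,
    include_zero_delay: bool = False,
) -> NoiseSummary:
    """Standard deviation of g2 across marker-selected windows, per delay.

    Each marker time is mapped to the record with the nearest window start;
    N(tau) is the n-1-denominator sample standard deviation across those
    records, and N_bar its mean over delays (all nonzero delays by default).
    Computed separately for the systolic-peak and diastolic-end marker sets.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    g2, starts, delays = _records_matrix(records)
    mask = slice(None) if include_zero_delay else delays > 0
    eval_delays = delays[mask]

    per_delay: dict = {}
    counts: dict = {}

    def one(times: np.ndarray, label: str) -> float:
        times = np.asarray(times, dtype=float)
        if times.size < 2:
            raise ValueError(f"need >= 2 {label.upper()} markers for a standard deviation")
        sel = g2[_nearest_windows(starts, times)][:, mask]
        n_tau = sel.std(axis=0, ddof=1)
        per_delay[label] = n_tau
        counts[label] = times.size
        return float(n_tau.mean())

    n_bar_sp = one(sp_times, "sp")
    n_bar_de = one(de_times, "de") if de_times is not None else None
    return NoiseSummary(
        n_bar_sp=n_bar_sp,
        n_bar_de=n_bar_de,
        n_markers_used=counts,
        per_delay_noise=per_delay,
        delays=eval_delays,
    )


def noise_vs_pixels(
    stream: FrameStream | np.ndarray,
    pixel_counts: Sequence[int],
    n_delays: int = 16,
    window_frames: int = 512,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Across-window g2 noise as a function of the number of averaged pixels.

    For each M in ``pixel_counts`` a random M-pixel subset (drawn without
    replacement with the given seed) is averaged per window; N_bar is the
    delay-averaged across-window standard deviation.  Returns the table of
    N_bar(M) and the log-log slope, which is -1/2 for independent pixels.
    """
    counts = stream.counts if isinstance(stream, FrameStream) else np.asarray(stream)
    total_pixels = counts.shape[1]
    pixel_counts = sorted(int(m) for m in pixel_counts)
    if pixel_counts[0] < 1:
        raise ValueError("pixel counts must be >= 1")
    if pixel_counts[-1] > total_pixels:
        raise ValueError(
            f"requested {pixel_counts[-1]} pixels but the stream has {total_pixels}"
        )
    g2, valid = per_pixel_window_g2(counts, n_delays, window_frames, dtype=np.float32)
    rng = default_rng(seed)
    rows = []
    for m in pixel_counts:
        subset = rng.choice(total_pixels, size=m, replace=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            avg = np.nanmean(g2[:, subset, :], axis=1)  # (W, K)
            n_tau = np.nanstd(avg[:, 1:], axis=0, ddof=1)
        rows.append({"n_pixels": m, "n_bar": float(n_tau.mean())})
    table = pd.DataFrame(rows)
    slope = float(np.polyfit(np.log(table["n_pixels"]), np.log(table["n_bar"]), 1)[0])
    return table, slope


def parallel_noise_ratio(
    n_pixels: int = 1024,
    n_windows: int = 200,
    window_frames: int = 512,
    bfi: float = 6e-9,
    sds_cm: float = 1.5,
    exposure: float = 10e-6,
    mean_rate: float = 0.05,
    coherent_fraction: float = 0.5,
    n_delays: int = 16,
    seed: int = 1,
) -> dict:
    """Single-pixel vs full-array g2 noise ratio on a stationary simulation.

    Simulates ``n_pixels`` independent speckle streams at a fixed BFI
    (semi-infinite g1, Siegert beta = coherent_fraction^2), computes one g2
    curve per pixel per window, and compares the across-window standard
    deviation of a single pixel's estimate with that of the all-pixel
    average, each averaged over the nonzero delays.  For independent pixels
    the expected ratio is sqrt(n_pixels).
    """
    props = OpticalProperties()
    geom = ProbeGeometry(sds_cm=sds_cm)
    det = DetectorSimParams(
        n_pixels=n_pixels,
        exposure=exposure,
        n_frames=n_windows * window_frames,
        coherent_fraction=coherent_fraction,
        mean_rate=mean_rate,
        seed=seed,
    )
    stream = speckle_sim.simulate_speckle_photons(props, geom, bfi, det)
    g2, _ = per_pixel_window_g2(stream.counts, n_delays, window_frames,
                                dtype=np.float32)
    single = g2[:, 0, :]  # (W, K)
    averaged = np.nanmean(g2, axis=1)
    n_bar_single = float(np.nanstd(single[:, 1:], axis=0, ddof=1).mean())
    n_bar_avg = float(np.nanstd(averaged[:, 1:], axis=0, ddof=1).mean())
    return {
        "ratio": n_bar_single / n_bar_avg,
        "n_bar_single": n_bar_single,
        "n_bar_averaged": n_bar_avg,
        "n_pixels": n_pixels,
        "n_windows": n_windows,
        "expected_ratio": float(np.sqrt(n_pixels)),
    }
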