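"""Multi-pixel intensity autocorrelation (g2) estimation.

Implements the linear software correlator used throughout the pipeline: the
per-pixel normalized intensity autocorrelation

    g2(tau_k) = <I(t) I(t+tau_k)> / <I(t)>^2

with time averages over all frame pairs that fit inside the averaging span
(lag-shrinking denominator), plus pixel/sub-window averaging and an emulation
of the on-board 16-delay FPGA correlator mode.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .speckle_sim import FrameStream

__all__ = [
    "DelayGrid",
    "SensorTiming",
    "CorrelationRecord",
    "ROW_TIME_S",
    "exposure_time",
    "frame_rate",
    "curves_per_window",
    "g2_curves",
    "per_pixel_window_g2",
    "compute_g2_pixel",
    "average_g2",
    "correlate_stream",
    "onboard16_g2",
]

logger = logging.getLogger(__name__)

#: Row readout time of the rolling-shutter 500x500 array, seconds.
ROW_TIME_S = 40e-9

#: Number of delay points produced by the on-board FPGA correlator
#: (tau = 0, dt, ..., 15*dt).
ONBOARD_N_DELAYS = 16


@dataclass(frozen=True)
class DelayGrid:
    """Uniform delay grid tau_k = k * dt, k = 0 .. n_delays-1."""

    dt: float  # delay spacing = frame period, s
    n_delays: int  # number of delays including tau = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_delays < 2:
            raise ValueError("n_delays must be >= 2")

    @classmethod
    def from_nonzero(cls, n_nonzero: int, dt: float) -> "DelayGrid":
        """Grid with ``n_nonzero`` nonzero delays plus the tau = 0 point.

        Matches the convention of quoting "delays per curve" as the nonzero
        count, so tau_max = n_nonzero * dt.
        """
        return cls(dt=dt, n_delays=n_nonzero + 1)

    @property
    def delays(self) -> np.ndarray:
        return np.arange(self.n_delays) * self.dt

    @property
    def tau_max(self) -> float:
        return (self.n_delays - 1) * self.dt


@dataclass(frozen=True)
class SensorTiming:
    """Frame timing of a SPAD array.

    ``nominal_exposure`` is the shutter-defined exposure; the effective frame
    period adds readout/wait overhead (e.g. the on-board mode runs 250 rows at
    a nominal 10 us but an effective 10.81 us period).  The overhead is a free
    configuration parameter because it is device-state dependent.
    """

    nominal_exposure: float  # s
    overhead: float = 0.0  # extra wait per frame, s
    n_rows: int | None = None
    n_halves: int = 1
    mode: str = "raw_stream"  # or "onboard16"

    def __post_init__(self) -> None:
        if self.nominal_exposure <= 0:
            raise ValueError("nominal_exposure must be positive")
        if self.overhead < 0:
            raise ValueError("overhead must be non-negative")
        if self.n_halves not in (1, 2):
            raise ValueError("n_halves must be 1 or 2")
        if self.mode not in ("raw_stream", "onboard16"):
            raise ValueError("mode must be 'raw_stream' or 'onboard16'")

    @classmethod
    def from_rows(cls, n_rows: int, n_halves: int = 1, overhead: float = 0.0,
                  mode: str = "raw_stream") -> "SensorTiming":
        return cls(
            nominal_exposure=exposure_time(n_rows, n_halves),
            overhead=overhead, n_rows=n_rows, n_halves=n_halves, mode=mode,
        )

    @property
    def effective_frame_period(self) -> float:
        return self.nominal_exposure + self.overhead


def exposure_time(n_rows: int, n_halves: int = 1) -> float:
    """Nominal exposure (s) of the rolling-shutter array: n_rows x 40 ns.

    Both sensor halves are read concurrently, so ``n_halves`` doubles the
    pixel count but does not change the exposure.
    """
    if not 1 <= n_rows <= 250:
        raise ValueError("n_rows must lie in [1, 250]")
    if n_halves not in (1, 2):
        raise ValueError("n_halves must be 1 or 2")
    return n_rows * ROW_TIME_S


def frame_rate(effective_frame_period: float) -> int:
    """Frame rate in whole frames per second (truncated)."""
    if effective_frame_period <= 0:
        raise ValueError("frame period must be positive")
    return int(math.floor(1.0 / effective_frame_period + 1e-9))


def curves_per_window(window_length: float, grid: DelayGrid,
                      timing: SensorTiming) -> int:
    """Number of g2 sub-curves per averaging window.

    The window is partitioned into consecutive non-overlapping spans of
    ``grid.n_delays`` frames, one curve per span:
    floor(window / (n_delays * effective_frame_period)).
    """
    span = grid.n_delays * timing.effective_frame_period
    n = math.floor(window_length / span)
    if n < 1:
        warnings.warn(
            f"window of {window_length} s is shorter than one curve span "
            f"({span:.3g} s); no complete curve fits", stacklevel=2,
        )
        return 0
    return n


@dataclass
class CorrelationRecord:
    """An averaged g2(tau) curve with its averaging provenance."""

    window_start: float  # s
    window_length: float  # s
    delays: np.ndarray  # s
    g2: np.ndarray
    n_pixels_averaged: int
    n_curves_averaged: int
    mean_rate: float  # mean events per frame within the window
    valid: bool = True

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        if self.delays.shape != self.g2.shape:
            raise ValueError("delays and g2 must have matching shapes")

    def nonzero_delay_indices(self) -> np.ndarray:
        return np.flatnonzero(self.delays > 0)


def g2_curves(
    counts: np.ndarray,
    n_delays: int,
    span_frames: int,
    dtype=np.float64,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-span, per-pixel g2 curves of a (frames, pixels) count array.

    The stream is partitioned into consecutive spans of ``span_frames``
    frames; within each span the estimator uses every frame pair that fits
    entirely inside the span and normalizes by the squared span mean.

    Returns ``(curves, valid, means)`` with shapes (S, M, K), (S, M), (S, M).
    Curves from spans with zero mean intensity are flagged invalid and set to
    NaN rather than propagating a division by zero.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise ValueError("counts must be (frames, pixels)")
    t_frames, m = counts.shape
    if span_frames < n_delays:
        raise ValueError("span_frames must be >= n_delays")
    s = t_frames // span_frames
    if s == 0:
        raise ValueError("stream shorter than one span")

    curves = np.empty((s, m, n_delays), dtype=dtype)
    means = np.empty((s, m), dtype=dtype)
    block = max(1, int(3.2e7 // max(1, span_frames * m)))
    for b0 in range(0, s, block):
        b1 = min(s, b0 + block)
        c = (
            counts[b0 * span_frames : b1 * span_frames]
            .reshape(b1 - b0, span_frames, m)
            .astype(dtype)
        )
        mu = c.mean(axis=1)
        means[b0:b1] = mu
        den = mu * mu
        with np.errstate(divide="ignore", invalid="ignore"):
            for k in range(n_delays):
                if k == 0:
                    num = np.mean(c * c, axis=1)
                else:
                    num = np.mean(c[:, :-k, :] * c[:, k:, :], axis=1)
                curves[b0:b1, :, k] = num / den
    valid = means > 0
    curves[~valid] = np.nan
    return curves, valid, means


def per_pixel_window_g2(
    counts: np.ndarray, n_delays: int, window_frames: int, dtype=np.float64
) -> tuple[np.ndarray, np.ndarray]:
    """One g2 curve per (window, pixel), using the whole window as the span.

    Returns ``(g2, valid)`` with shapes (W, M, K) and (W, M).
    """
    curves, valid, _ = g2_curves(counts, n_delays, window_frames, dtype=dtype)
    return curves, valid


def compute_g2_pixel(
    stream: FrameStream,
    pixel: int,
    grid: DelayGrid,
    window: tuple[float, float] | None = None,
) -> CorrelationRecord:
    """g2 of a single pixel over one averaging window.

    ``window`` is (start, length) in seconds; None means the full stream.
    A window with zero mean intensity yields a record flagged invalid.
    """
    period = stream.frame_period_s
    if window is None:
        window = (0.0, stream.duration)
    start_s, length_s = window
    f0 = int(round(start_s / period))
    n = int(round(length_s / period))
    if f0 < 0 or f0 + n > stream.n_frames:
        raise ValueError("window extends outside the stream")
    if n < grid.n_delays:
        raise ValueError("window shorter than the delay grid")
    segment = stream.counts[f0 : f0 + n, pixel : pixel + 1]
    curves, valid, means = g2_curves(segment, grid.n_delays, n)
    ok = bool(valid[0, 0])
    g2 = curves[0, 0] if ok else np.full(grid.n_delays, np.nan)
    return CorrelationRecord(
        window_start=start_s,
        window_length=length_s,
        delays=grid.delays,
        g2=g2,
        n_pixels_averaged=1,
        n_curves_averaged=1,
        mean_rate=float(means[0, 0]),
        valid=ok,
    )


def average_g2(
    curves: np.ndarray | Iterable[np.ndarray],
    delays: np.ndarray,
    window_start: float = 0.0,
    window_length: float = float("nan"),
    n_pixels_averaged: int | None = None,
    n_curves_averaged: int | None = None,
    mean_rate: float = float("nan"),
) -> CorrelationRecord:
    """Unweighted mean of valid g2 curves sharing one delay grid.

    ``curves`` is an (N, K) array or an iterable of K-vectors; rows containing
    NaN (invalid sub-curves) are dropped from the mean but the provenance
    counts record how many curves contributed.
    """
    arr = np.atleast_2d(np.asarray(list(curves) if not isinstance(curves, np.ndarray) else curves, dtype=float))
    if arr.size == 0:
        raise ValueError("no curves to average")
    keep = ~np.any(np.isnan(arr), axis=1)
    if not np.any(keep):
        raise ValueError("all curves are invalid")
    mean_curve = arr[keep].mean(axis=0)
    return CorrelationRecord(
        window_start=window_start,
        window_length=window_length,
        delays=np.asarray(delays, dtype=float),
        g2=mean_curve,
        n_pixels_averaged=n_pixels_averaged if n_pixels_averaged is not None else int(keep.sum()),
        n_curves_averaged=n_curves_averaged if n_curves_averaged is not None else int(keep.sum()),
        mean_rate=mean_rate,
    )


def correlate_stream(
    stream: FrameStream,
    grid: DelayGrid,
    window_length: float,
    span_frames: int | None = None,
    pixel_limit: int | None = None,
    dtype=np.float64,
) -> list[CorrelationRecord]:
    """Average g2 over pixels and sub-windows for consecutive windows.

    Each window of ``window_length`` seconds is partitioned into spans of
    ``span_frames`` frames (default: ``grid.n_delays``, the on-board
    convention); one curve per span per pixel is computed and the grand mean
    over all valid curves becomes the window's CorrelationRecord.  Pixels with
    zero counts in a span are dropped from the mean and reflected in the
    provenance counts.
    """
    period = stream.frame_period_s
    counts = stream.counts
    if pixel_limit is not None:
        counts = counts[:, :pixel_limit]
    span = span_frames if span_frames is not None else grid.n_delays
    window_frames = int(round(window_length / period))
    spans_per_window = window_frames // span
    if spans_per_window < 1:
        raise ValueError("window shorter than one curve span")
    n_windows = counts.shape[0] // (spans_per_window * span)
    if n_windows == 0:
        raise ValueError("stream shorter than one window")

    records: list[CorrelationRecord] = []
    frames_per_window = spans_per_window * span
    for w in range(n_windows):
        seg = counts[w * frames_per_window : (w + 1) * frames_per_window]
        curves, valid, means = g2_curves(seg, grid.n_delays, span, dtype=dtype)
        flat = curves.reshape(-1, grid.n_delays)
        keep = ~np.any(np.isnan(flat), axis=1)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.debug("window %d: dropped %d zero-count sub-curves", w, n_dropped)
        if not np.any(keep):
            records.append(
                CorrelationRecord(
                    window_start=w * window_length,
                    window_length=window_length,
                    delays=grid.delays,
                    g2=np.full(grid.n_delays, np.nan),
                    n_pixels_averaged=0,
                    n_curves_averaged=0,
                    mean_rate=float(means.mean()),
                    valid=False,
                )
            )
            continue
        records.append(
            CorrelationRecord(
                window_start=w * window_length,
                window_length=window_length,
                delays=grid.delays,
                g2=flat[keep].mean(axis=0),
                n_pixels_averaged=int(valid.any(axis=0).sum()),
                n_curves_averaged=spans_per_window,
                mean_rate=float(means.mean()),
            )
        )
    return records


def onboard16_g2(
    stream: FrameStream,
    timing: SensorTiming,
    window_length: float,
    pixel_limit: int | None = None,
) -> list[CorrelationRecord]:
    """Emulate the on-board FPGA correlator: 16 delays, tau_max = 15 * dt.

    Sub-curves span exactly 16 frames; when the averaging window equals a
    single span the result is numerically identical to ``compute_g2_pixel``
    restricted to the 16-delay grid.
    """
    if timing.mode != "onboard16":
        raise ValueError("SensorTiming.mode must be 'onboard16'")
    grid = DelayGrid(dt=stream.frame_period_s, n_delays=ONBOARD_N_DELAYS)
    return correlate_stream(
        stream, grid, window_length, span_frames=ONBOARD_N_DELAYS,
        pixel_limit=pixel_limit,
    )
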