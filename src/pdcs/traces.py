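"""Blood-flow-index (BFI) time series containers shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

__all__ = ["BfiSample", "BfiTrace"]


@dataclass(frozen=True)
class BfiSample:
    """One BFI estimate for a single averaging window.

    Attributes
    ----------
    time : float
        Window start time in seconds.
    bfi : float
        Blood flow index in cm^2/s.
    beta : float
        Fitted correlation amplitude (g2(0) - 1), dimensionless.
    residual : float
        Scalar fit residual (RMS over the fitted delay subset).
    valid : bool
        False when the fit failed or the window was degenerate.
    """

    time: float
    bfi: float
    beta: float = float("nan")
    residual: float = float("nan")
    valid: bool = True


@dataclass
class BfiTrace:
    """A uniformly sampled BFI time series.

    ``times`` are window-start times in seconds, ``bfi`` in cm^2/s.  ``beta``,
    ``residual`` and ``valid`` are optional per-sample annotations filled in by
    the model fit; a ground-truth trace from the simulator carries only times
    and values.
    """

    times: np.ndarray
    bfi: np.ndarray
    beta: np.ndarray | None = None
    residual: np.ndarray | None = None
    valid: np.ndarray | None = None
    sample_rate: float | None = None
    segment_label: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.bfi = np.asarray(self.bfi, dtype=float)
        if self.times.shape != self.bfi.shape:
            raise ValueError("times and bfi must have the same shape")
        if self.valid is None:
            self.valid = np.ones(self.times.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.beta is not None:
            self.beta = np.asarray(self.beta, dtype=float)
        if self.residual is not None:
            self.residual = np.asarray(self.residual, dtype=float)
        if self.sample_rate is None and self.times.size >= 2:
            dt = np.diff(self.times)
            if dt.size and np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12) and dt[0] > 0:
                self.sample_rate = 1.0 / dt[0]

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        if self.times.size == 0:
            return 0.0
        step = 1.0 / self.sample_rate if self.sample_rate else 0.0
        return float(self.times[-1] - self.times[0] + step)

    def valid_bfi(self) -> np.ndarray:
        """BFI values of valid samples only."""
        return self.bfi[self.valid]

    def samples(self) -> Iterator[BfiSample]:
        beta = self.beta if self.beta is not None else np.full(len(self), np.nan)
        resid = self.residual if self.residual is not None else np.full(len(self), np.nan)
        for t, b, be, r, v in zip(self.times, self.bfi, beta, resid, self.valid):
            yield BfiSample(float(t), float(b), float(be), float(r), bool(v))

    def scaled(self, factor: float) -> "BfiTrace":
        """Return a copy with BFI multiplied by ``factor`` (annotations kept)."""
        return replace(self, bfi=self.bfi * factor)
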