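"""Instantaneous head-body correlation and its per-target summaries.

The second stage of Correlation Map Analysis: slide a moving filter over
two motion time series and correlate them frame-by-frame, producing an
instantaneous coordination trace r(t) in [-1, 1].  Two filters are offered:

* ``boxcar`` — the Pearson correlation over a centered window of odd width
  (the default; exactly reproducible with a brute-force per-window oracle);
* ``exponential`` — exponentially weighted running means, variances and
  covariance with smoothing weight ``eta``, the causal filter used in
  published correlation-map variants.

A target's intrapersonal behavioral coordination (IBC) is summarized by the
*level* (mean of r(t)) and the *variability* (sample SD of r(t), ddof=1)
over all frames where the correlation is defined.  Negative instantaneous
correlations are retained as computed; summaries operate on the signed
trace.  Frames without a full centered window, or whose window variance in
either signal falls below ``min_variance``, are flagged invalid and
excluded from every summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .motion import MotionSeries

__all__ = [
    "CMAConfig",
    "CoordinationSeries",
    "IBCSummary",
    "instantaneous_correlation",
    "summarize_ibc",
    "cohort_descriptives",
]


@dataclass(frozen=True)
class CMAConfig:
    """Moving-filter settings for the instantaneous correlation."""

    kernel: str = "boxcar"
    window_frames: int = 31  # boxcar width; ~1 s at 30 fps
    eta: float = 0.06  # exponential smoothing weight
    min_variance: float = 1e-12

    def __post_init__(self) -> None:
        if self.kernel not in ("boxcar", "exponential"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.kernel == "boxcar":
            if self.window_frames < 3 or self.window_frames % 2 == 0:
                raise ValueError("window_frames must be an odd integer >= 3")
        else:
            if not (0.0 < self.eta < 1.0):
                raise ValueError("eta must lie in (0, 1)")
        if self.min_variance <= 0:
            raise ValueError("min_variance must be positive")


@dataclass
class CoordinationSeries:
    """Instantaneous correlation trace with validity flags."""

    r: np.ndarray
    valid_mask: np.ndarray
    config: CMAConfig

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.r.shape != self.valid_mask.shape:
            raise ValueError("r and valid_mask must have matching shapes")
        valid = self.r[self.valid_mask]
        if valid.size and (np.any(valid < -1) or np.any(valid > 1)):
            raise ValueError("valid correlations must lie in [-1, 1]")

    @property
    def valid_r(self) -> np.ndarray:
        return self.r[self.valid_mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame_index": np.arange(len(self.r)), "r": self.r, "valid": self.valid_mask}
        )


@dataclass(frozen=True)
class IBCSummary:
    """Per-target IBC level (mean r) and variability (sample SD of r)."""

    target_id: str
    level: float
    variability: float
    n_valid: int


def _windowed_moments(v: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered-window running mean of v and of v**2 via cumulative sums."""
    c = np.concatenate([[0.0], np.cumsum(v)])
    c2 = np.concatenate([[0.0], np.cumsum(v * v)])
    n = len(v)
    h = w // 2
    t = np.arange(h, n - h)
    mean = (c[t + h + 1] - c[t - h]) / w
    mean2 = (c2[t + h + 1] - c2[t - h]) / w
    return mean, mean2


def instantaneous_correlation(
    x: MotionSeries | np.ndarray,
    y: MotionSeries | np.ndarray,
    config: CMAConfig | None = None,
) -> CoordinationSeries:
    """Correlate two motion series with a moving filter at zero time offset.

    Returns one r value per frame of the input series; frames where the
    filter is undefined (window hanging off an edge, exponential burn-in,
    or near-zero window variance in either signal) are flagged invalid.
    """
    config = config or CMAConfig()
    xv = np.asarray(x.values if isinstance(x, MotionSeries) else x, dtype=float)
    yv = np.asarray(y.values if isinstance(y, MotionSeries) else y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1-D series of identical length")
    if isinstance(x, MotionSeries) and isinstance(y, MotionSeries):
        if x.frame_rate != y.frame_rate:
            raise ValueError("x and y must share a frame rate")
    n = len(xv)

    if config.kernel == "boxcar":
        w = config.window_frames
        if n < w:
            raise ValueError(f"series of length {n} shorter than window {w}")
        h = w // 2
        mx, mx2 = _windowed_moments(xv, w)
        my, my2 = _windowed_moments(yv, w)
        cxy = np.concatenate([[0.0], np.cumsum(xv * yv)])
        t = np.arange(h, n - h)
        mxy = (cxy[t + h + 1] - cxy[t - h]) / w
        vx = mx2 - mx * mx
        vy = my2 - my * my
        cov = mxy - mx * my
        r = np.full(n, np.nan)
        valid = np.zeros(n, dtype=bool)
        ok = (vx > config.min_variance) & (vy > config.min_variance)
        denom = np.sqrt(np.where(ok, vx * vy, 1.0))
        rr = np.where(ok, cov / denom, np.nan)
        r[t] = rr
        valid[t] = ok
    else:  # exponential
        eta = config.eta
        burn_in = int(np.ceil(1.0 / eta))
        if n <= burn_in:
            raise ValueError(f"series of length {n} shorter than burn-in {burn_in}")
        mx = my = mx2 = my2 = mxy = 0.0
        r = np.full(n, np.nan)
        valid = np.zeros(n, dtype=bool)
        # debiased EW moments (divide by 1 - (1-eta)^(t+1)), as in EW variance
        wsum = 0.0
        for t in range(n):
            mx = (1 - eta) * mx + eta * xv[t]
            my = (1 - eta) * my + eta * yv[t]
            mx2 = (1 - eta) * mx2 + eta * xv[t] ** 2
            my2 = (1 - eta) * my2 + eta * yv[t] ** 2
            mxy = (1 - eta) * mxy + eta * xv[t] * yv[t]
            wsum = (1 - eta) * wsum + eta
            if t < burn_in:
                continue
            emx, emy = mx / wsum, my / wsum
            vx = mx2 / wsum - emx * emx
            vy = my2 / wsum - emy * emy
            cov = mxy / wsum - emx * emy
            if vx > config.min_variance and vy > config.min_variance:
                r[t] = cov / np.sqrt(vx * vy)
                valid[t] = True

    overshoot = valid & (np.abs(r) > 1.0 + 1e-12)
    if np.any(overshoot):
        raise FloatingPointError("correlation overshoot beyond round-off tolerance")
    r[valid] = np.clip(r[valid], -1.0, 1.0)
    return CoordinationSeries(r=r, valid_mask=valid, config=config)


def summarize_ibc(series: CoordinationSeries, target_id: str) -> IBCSummary:
    """Level = mean of valid r; variability = sample SD (ddof=1) of valid r."""
    valid = series.valid_r
    if valid.size < 2:
        raise ValueError(
            f"target {target_id!r}: only {valid.size} valid frames; need >= 2"
        )
    return IBCSummary(
        target_id=str(target_id),
        level=float(np.mean(valid)),
        variability=float(np.std(valid, ddof=1)),
        n_valid=int(valid.size),
    )


def cohort_descriptives(summaries: Sequence[IBCSummary]) -> dict:
    """Cohort means/SDs of IBC level and variability and their correlation.

    The level-variability Pearson correlation is reported as NaN (undefined,
    never 0) when either summary has zero spread across targets.
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 targets for cohort descriptives")
    levels = np.array([s.level for s in summaries])
    variabilities = np.array([s.variability for s in summaries])
    out = {
        "n_targets": len(summaries),
        "level_mean": float(np.mean(levels)),
        "level_sd": float(np.std(levels, ddof=1)),
        "variability_mean": float(np.mean(variabilities)),
        "variability_sd": float(np.std(variabilities, ddof=1)),
    }
    if out["level_sd"] == 0.0 or out["variability_sd"] == 0.0:
        out["level_variability_r"] = float("nan")
    else:
        out["level_variability_r"] = float(np.corrcoef(levels, variabilities)[0, 1])
    return out


def write_ibc_csv(summaries: Sequence[IBCSummary], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "target_id": s.target_id,
                "level": s.level,
                "variability": s.variability,
                "n_valid": s.n_valid,
            }
            for s in summaries
        ]
    ).to_csv(path, index=False)
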