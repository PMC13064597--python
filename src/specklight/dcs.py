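"""Conventional DCS post-processing: pixel-wise intensity autocorrelation
and decorrelation-time read-out.

The normalized intensity autocorrelation of a single-pixel series is

    g2(tau) = <I(t) I(t + tau)> / <I(t)>^2,

with time averages over the record and, by default, the full-series mean in
the denominator. The decorrelation time is read off the curve as the lag
where ``g2 - 1`` has fallen to 1/e of its zero-lag value,

    tau_c = argmin_tau | g2(tau) - [1 + (g2(0) - 1)/e] |,

evaluated on the discrete lag grid (ties break toward the smallest lag; an
optional linear interpolation of the crossing is available but off by
default). Pixels whose zero-lag contrast ``g2(0) - 1`` falls below a
configurable dynamic-range floor are flagged invalid rather than estimated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import scipy.fft

from .stack import SpeckleStack

__all__ = [
    "G2Curve",
    "TauCMap",
    "TauCEstimate",
    "REASONS",
    "compute_g2",
    "extract_tau_c",
    "dcs_map",
]

#: Per-pixel validity reason codes carried by :class:`TauCMap`.
REASONS = {
    0: "ok",
    1: "constant_series",
    2: "low_dynamic_range",
    3: "no_threshold_crossing",
}
_OK, _CONSTANT, _LOW_DR, _NO_CROSSING = 0, 1, 2, 3


@dataclass
class G2Curve:
    """A normalized intensity autocorrelation over discrete lags.

    ``lags`` are in seconds, strictly increasing and starting at 0;
    ``values`` are the dimensionless g2 estimates at those lags.
    """

    lags: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape or self.lags.ndim != 1:
            raise ValueError("lags and values must be 1-D arrays of equal length")
        if self.lags.size < 1 or self.lags[0] != 0:
            raise ValueError("lag grid must start at 0")
        if self.lags.size > 1 and not (np.diff(self.lags) > 0).all():
            raise ValueError("lags must be strictly increasing")
        if not np.isfinite(self.values).all():
            raise ValueError("g2 values must be finite")


class TauCEstimate(NamedTuple):
    """Result of the 1/e read-out for one curve."""

    tau_c: float  # seconds; NaN when invalid
    valid: bool
    reason: str  # one of REASONS.values()


@dataclass
class TauCMap:
    """Per-pixel decorrelation-time map with validity bookkeeping.

    ``tau_c`` holds seconds (NaN at invalid pixels), ``valid`` is boolean,
    ``reason`` carries the integer code from :data:`REASONS` and
    ``method_tag`` records which pipeline produced the map (``"dcs"`` or
    ``"mldcs"``).
    """

    tau_c: np.ndarray
    valid: np.ndarray
    reason: np.ndarray
    method_tag: str = "dcs"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.tau_c.shape == self.valid.shape == self.reason.shape):
            raise ValueError("tau_c, valid and reason must share one shape")
        bad = self.valid & ~(np.nan_to_num(self.tau_c, nan=-1.0) > 0)
        if bad.any():
            raise ValueError("valid pixels must carry tau_c > 0")

    @property
    def shape(self):
        return self.tau_c.shape


def _default_max_lag(duration: float) -> float:
    """min(2 s, duration / 3): covers the 0-2 s operating range of the
    estimators while bounding the variance of long-lag correlations."""
    return min(2.0, duration / 3.0)


def compute_g2(
    series: np.ndarray,
    fps: float,
    max_lag: float | None = None,
    normalization: str = "full",
) -> G2Curve:
    """Normalized intensity autocorrelation of one pixel series.

    Parameters
    ----------
    series
        1-D non-negative intensity series, length >= 2. An all-zero series
        is rejected (the normalization would divide by zero); a constant
        non-zero series yields ``g2 == 1`` at every lag.
    fps
        Frame rate; the lag grid is ``0, 1/fps, 2/fps, ...``.
    max_lag
        Largest lag in seconds (must be smaller than the series duration).
        Defaults to ``min(2, duration / 3)``.
    normalization
        ``"full"`` divides every lag by the squared full-series mean (the
        literal definition); ``"symmetric"`` divides lag ``k`` by the product
        of the means of the two overlapping segments, which reduces the
        finite-record bias at long lags.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("series must be 1-D with at least 2 samples")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    if not (x > 0).any():
        raise ValueError("all-zero series: g2 normalization is undefined")
    if normalization not in ("full", "symmetric"):
        raise ValueError("normalization must be 'full' or 'symmetric'")
    T = x.size
    duration = T / fps
    if max_lag is None:
        max_lag = _default_max_lag(duration)
    if max_lag >= duration:
        raise ValueError(f"max_lag={max_lag} must be < series duration {duration}")
    n_lags = int(math.floor(max_lag * fps))
    n_lags = min(n_lags, T - 1)
    vals = np.empty(n_lags + 1)
    mean_full = x.mean()
    for k in range(n_lags + 1):
        head, tail = x[: T - k], x[k:]
        num = (head * tail).mean()
        if normalization == "full":
            vals[k] = num / mean_full**2
        else:
            vals[k] = num / (head.mean() * tail.mean())
    return G2Curve(lags=np.arange(n_lags + 1) / fps, values=vals)


def extract_tau_c(
    curve: G2Curve,
    dynamic_range_floor: float = 0.01,
    interpolate: bool = False,
) -> TauCEstimate:
    """Read the decorrelation time off a g2 curve via the 1/e criterion.

    The threshold is ``theta = 1 + (g2(0) - 1)/e``. By default tau_c is the
    grid lag (tau > 0) minimizing ``|g2(tau) - theta|`` with ties broken
    toward the smallest lag; with ``interpolate=True`` the first downward
    crossing of ``theta`` is refined linearly between the bracketing lags.

    Invalid outcomes (returned, never raised):

    - ``constant_series`` — the curve is exactly flat at 1;
    - ``low_dynamic_range`` — ``g2(0) - 1`` below ``dynamic_range_floor``;
    - ``no_threshold_crossing`` — the curve has not decayed to the
      threshold within the lag range (the argmin lands on the last lag).
    """
    v = curve.values
    if v.size < 2:
        raise ValueError("curve needs at least one non-zero lag")
    contrast = v[0] - 1.0
    if np.all(v == v[0]) and abs(contrast) < 1e-12:
        return TauCEstimate(math.nan, False, REASONS[_CONSTANT])
    if contrast < dynamic_range_floor:
        return TauCEstimate(math.nan, False, REASONS[_LOW_DR])
    theta = 1.0 + contrast / math.e
    if interpolate:
        below = np.nonzero(v[1:] <= theta)[0]
        if below.size == 0:
            return TauCEstimate(math.nan, False, REASONS[_NO_CROSSING])
        k = below[0] + 1
        v0, v1 = v[k - 1], v[k]
        frac = 0.0 if v0 == v1 else (v0 - theta) / (v0 - v1)
        tau = (k - 1 + min(max(frac, 0.0), 1.0)) * (curve.lags[1] - curve.lags[0])
        return TauCEstimate(float(tau), True, REASONS[_OK])
    k = int(np.argmin(np.abs(v[1:] - theta))) + 1  # argmin -> smallest lag on ties
    if k == v.size - 1:
        return TauCEstimate(math.nan, False, REASONS[_NO_CROSSING])
    return TauCEstimate(float(curve.lags[k]), True, REASONS[_OK])


# ---------------------------------------------------------------------------
# batched map
# ---------------------------------------------------------------------------


def _g2_values_batch(pix: np.ndarray, n_lags: int, normalization: str) -> np.ndarray:
    """g2 estimates for an (n_pix, T) block, lags 0..n_lags, FFT-accelerated.

    Mathematically identical to :func:`compute_g2` per row (the FFT computes
    the same lagged sums); rows with zero mean are returned as NaN.
    """
    n_pix, T = pix.shape
    nfft = scipy.fft.next_fast_len(2 * T)
    F = scipy.fft.rfft(pix, nfft, axis=1)
    raw = scipy.fft.irfft(F * np.conj(F), nfft, axis=1)[:, : n_lags + 1]
    counts = T - np.arange(n_lags + 1)
    num = raw / counts
    mean = pix.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if normalization == "full":
            vals = num / mean[:, None] ** 2
        else:
            csum = np.concatenate(
                [np.zeros((n_pix, 1)), np.cumsum(pix, axis=1)], axis=1
            )
            total = csum[:, -1][:, None]
            k = np.arange(n_lags + 1)
            head_means = (csum[:, T - k] - csum[:, [0]]) / counts
            tail_means = (total - csum[:, k]) / counts
            vals = num / (head_means * tail_means)
    vals[mean == 0] = np.nan
    return vals


def dcs_map(
    stack: SpeckleStack,
    max_lag: float | None = None,
    dynamic_range_floor: float = 0.01,
    normalization: str = "full",
    interpolate: bool = False,
    chunk: int = 1024,
) -> TauCMap:
    """Apply the g2 / 1/e pipeline independently to every pixel of a stack.

    Per-pixel failures (constant series, low dynamic range, no crossing)
    are flagged in the returned map, never raised. The batched implementation
    is numerically equivalent to the scalar ``extract_tau_c(compute_g2(...))``
    path.
    """
    if normalization not in ("full", "symmetric"):
        raise ValueError("normalization must be 'full' or 'symmetric'")
    T = stack.n_frames
    duration = stack.duration
    if max_lag is None:
        max_lag = _default_max_lag(duration)
    if max_lag >= duration:
        raise ValueError(f"max_lag={max_lag} must be < stack duration {duration}")
    n_lags = min(int(math.floor(max_lag * stack.fps)), T - 1)
    if n_lags < 1:
        raise ValueError("max_lag shorter than one frame period")
    n_pix = stack.height * stack.width
    flat = stack.frames.reshape(T, n_pix)
    tau = np.full(n_pix, np.nan)
    reason = np.zeros(n_pix, dtype=np.uint8)
    dt = 1.0 / stack.fps
    for i0 in range(0, n_pix, chunk):
        blk = np.ascontiguousarray(flat[:, i0 : i0 + chunk].T)
        vals = _g2_values_batch(blk, n_lags, normalization)
        v0 = vals[:, 0]
        contrast = v0 - 1.0
        constant = blk.std(axis=1) == 0
        zero_mean = blk.mean(axis=1) == 0
        low_dr = contrast < dynamic_range_floor
        with np.errstate(invalid="ignore"):
            theta = 1.0 + contrast / math.e
            if interpolate:
                below = vals[:, 1:] <= theta[:, None]
                has = below.any(axis=1)
                k = np.argmax(below, axis=1) + 1
                kk = np.clip(k, 1, n_lags)
                vprev = np.take_along_axis(vals, (kk - 1)[:, None], axis=1)[:, 0]
                vcur = np.take_along_axis(vals, kk[:, None], axis=1)[:, 0]
                denom = vprev - vcur
                frac = np.where(denom != 0, (vprev - theta) / denom, 0.0)
                t_est = (kk - 1 + np.clip(frac, 0.0, 1.0)) * dt
                crossed = has
            else:
                k = np.argmin(
                    np.abs(np.nan_to_num(vals[:, 1:], nan=np.inf) - theta[:, None]),
                    axis=1,
                ) + 1
                t_est = k * dt
                crossed = k < n_lags
        bad_const = constant | zero_mean
        bad_dr = low_dr & ~bad_const
        bad_cross = ~crossed & ~bad_const & ~bad_dr
        ok = ~(bad_const | bad_dr | bad_cross)
        sl = slice(i0, i0 + blk.shape[0])
        tau[sl] = np.where(ok, t_est, np.nan)
        reason[sl] = np.select(
            [bad_const, bad_dr, bad_cross], [_CONSTANT, _LOW_DR, _NO_CROSSING], _OK
        )
    shape = (stack.height, stack.width)
    return TauCMap(
        tau_c=tau.reshape(shape),
        valid=(reason == _OK).reshape(shape),
        reason=reason.reshape(shape),
        method_tag="dcs",
        meta={
            "max_lag": max_lag,
            "fps": stack.fps,
            "normalization": normalization,
            "dynamic_range_floor": dynamic_range_floor,
        },
    )
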