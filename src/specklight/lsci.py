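"""Temporal laser speckle contrast imaging.

Per pixel, the speckle contrast of a short temporal window is

    K = sigma / <I>,

where sigma is the (population, by default) standard deviation of the
window and <I> its mean. A window of ``window_len`` frames (default 7) is
slid along the time axis with a configurable stride (default 1, i.e. every
position), and the final image averages K over all window positions.

At short exposure, slower dynamics (stiffer tissue, larger tau_c) vary less
within a window, so temporal K *decreases* with tau_c — the sign convention
opposite to the decorrelation-time maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stack import SpeckleStack

__all__ = [
    "ContrastMap",
    "temporal_contrast_window",
    "lsci_map",
    "window_sweep",
    "DEFAULT_SWEEP_LENGTHS",
]

#: The window-length sweep used to justify the 7-frame default: odd lengths 3..51.
DEFAULT_SWEEP_LENGTHS = tuple(range(3, 52, 2))


@dataclass
class ContrastMap:
    """Per-pixel temporal speckle contrast (dimensionless, >= 0)."""

    K: np.ndarray
    window_len: int
    stride: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.K < 0).any():
            raise ValueError("speckle contrast must be non-negative")

    @property
    def shape(self):
        return self.K.shape


def temporal_contrast_window(window: np.ndarray, ddof: int = 0) -> float:
    """Speckle contrast ``K = sigma / mean`` of one temporal window.

    ``ddof=0`` (population standard deviation) is the default; pass
    ``ddof=1`` for the sample convention. A window with zero mean (all-zero
    intensities) is rejected.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("window must be 1-D with at least 2 samples")
    m = w.mean()
    if m == 0:
        raise ValueError("zero-mean window: speckle contrast is undefined")
    return float(w.std(ddof=ddof) / m)


def _window_contrast_block(
    blk: np.ndarray, window_len: int, stride: int, ddof: int
) -> np.ndarray:
    """Mean-over-positions temporal K for an (n_pix, T) block.

    Variances are accumulated on the offset-removed series (each pixel minus
    its first sample) so that a temporally constant pixel yields exactly
    K = 0 with no floating-point residue.
    """
    n_pix, T = blk.shape
    n_pos = T - window_len + 1
    offset = blk[:, :1]
    d = blk - offset
    S = np.zeros((n_pix, n_pos))
    for j in range(window_len):
        S += d[:, j : j + n_pos]
    S /= window_len
    SS = np.zeros((n_pix, n_pos))
    for j in range(window_len):
        SS += (d[:, j : j + n_pos] - S) ** 2
    SS /= window_len - ddof
    mean = S + offset
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.sqrt(SS) / mean
    K[np.broadcast_to(mean == 0, K.shape) & (SS == 0)] = 0.0
    return K[:, ::stride].mean(axis=1)


def lsci_map(
    stack: SpeckleStack,
    window_len: int = 7,
    stride: int = 1,
    ddof: int = 0,
    chunk: int = 512,
) -> ContrastMap:
    """Temporal speckle contrast image of a stack.

    Per pixel, K is computed on every window position (subject to
    ``stride``) over the last full windows only (no partial windows:
    positions ``0 .. T - window_len``), then averaged across positions.
    """
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    if window_len > stack.n_frames:
        raise ValueError(
            f"window_len={window_len} exceeds the stack's {stack.n_frames} frames"
        )
    if stride < 1:
        raise ValueError("stride must be >= 1")
    T = stack.n_frames
    n_pix = stack.height * stack.width
    flat = stack.frames.reshape(T, n_pix)
    out = np.empty(n_pix)
    for i0 in range(0, n_pix, chunk):
        blk = np.ascontiguousarray(flat[:, i0 : i0 + chunk].T)
        out[i0 : i0 + blk.shape[0]] = _window_contrast_block(
            blk, window_len, stride, ddof
        )
    return ContrastMap(
        K=out.reshape(stack.height, stack.width),
        window_len=window_len,
        stride=stride,
        meta={"fps": stack.fps, "exposure_us": stack.exposure_us, "ddof": ddof},
    )


def window_sweep(
    stack: SpeckleStack,
    tumour_mask: np.ndarray,
    control_mask: np.ndarray,
    lengths=DEFAULT_SWEEP_LENGTHS,
    stride: int = 1,
    ddof: int = 0,
) -> pd.DataFrame:
    """Sweep the temporal window length and tabulate ROI separation.

    For each requested length, computes one contrast map and reports the
    tumour- and control-ROI mean K together with the Welch t statistic and
    two-sided p-value between the two pixel populations. Degenerate cases
    (zero variance in both ROIs, e.g. a temporally constant stack) are
    flagged with ``separation_defined == False`` and NaN statistics.
    """
    from .roi import ROIMask, roi_summary, welch_t_test

    lengths = [int(w) for w in lengths]
    if max(lengths) > stack.n_frames:
        raise ValueError("largest window length exceeds the stack duration")
    rows = []
    t_roi = ROIMask(mask=np.asarray(tumour_mask, bool), label="tumour")
    c_roi = ROIMask(mask=np.asarray(control_mask, bool), label="control")
    for w in lengths:
        cmap = lsci_map(stack, window_len=w, stride=stride, ddof=ddof)
        sT = roi_summary(cmap, t_roi)
        sC = roi_summary(cmap, c_roi)
        if sT.std == 0 and sC.std == 0:
            rows.append(
                dict(
                    window_len=w,
                    k_tumour_mean=sT.mean,
                    k_control_mean=sC.mean,
                    t_stat=np.nan,
                    p_value=np.nan,
                    separation_defined=False,
                )
            )
            continue
        res = welch_t_test(sT, sC)
        rows.append(
            dict(
                window_len=w,
                k_tumour_mean=sT.mean,
                k_control_mean=sC.mean,
                t_stat=res.t_statistic,
                p_value=res.p_value,
                separation_defined=True,
            )
        )
    return pd.DataFrame(rows)
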