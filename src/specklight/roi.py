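"""ROI statistics for modality comparison.

A tumour region of interest is drawn (as a polygon or mask) on a reference
image; its control counterpart is obtained by mirroring it across the
image's horizontal midline into the contralateral hemisphere. Pixel values
inside each ROI form the two populations compared by

    SNR_T = mu_T / sigma_T          (single-image detectability)
    t     = (mu_T - mu_C) / sqrt(sigma_T^2 / n + sigma_C^2 / m)

with Welch-Satterthwaite degrees of freedom and a two-sided p-value.
Summaries use the sample (n - 1) standard deviation; invalid pixels are
excluded and never silently filled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

from .dcs import TauCMap
from .lsci import ContrastMap

__all__ = [
    "ROIMask",
    "ROISummary",
    "ComparisonResult",
    "ROIOverlapWarning",
    "mirror_roi",
    "polygon_to_mask",
    "roi_summary",
    "compute_snr",
    "welch_t_test",
    "difference_map",
    "compare_rois",
]


class ROIOverlapWarning(UserWarning):
    """Mirrored control ROI overlaps the original tumour ROI."""


@dataclass
class ROIMask:
    """A boolean region of interest with provenance."""

    mask: np.ndarray
    label: str = "tumour"
    provenance: str = ""

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not self.mask.any():
            raise ValueError("ROI mask must contain at least one pixel")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class ROISummary:
    """Population summary of the valid pixels under one ROI."""

    mean: float
    std: float  # sample standard deviation (ddof=1); 0 when n == 1
    n: int
    units: str = ""

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("summary needs at least one pixel")
        if not (np.isfinite(self.mean) and np.isfinite(self.std)):
            raise ValueError("summary statistics must be finite")
        if self.std < 0:
            raise ValueError("standard deviation must be >= 0")


@dataclass(frozen=True)
class ComparisonResult:
    """Tumour-vs-control comparison: SNR_T, Welch t, df and p."""

    snr_t: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float


def mirror_roi(roi: ROIMask, axis: str = "horizontal-midline") -> ROIMask:
    """Mirror a tumour ROI into the contralateral hemisphere.

    Reflection is about the image's horizontal midline: row ``r`` maps to
    row ``H - 1 - r`` in the same column, preserving the pixel count. If the
    mirrored mask overlaps the original, a :class:`ROIOverlapWarning` is
    issued (the mirror is still returned).
    """
    if axis != "horizontal-midline":
        raise ValueError(f"unsupported mirror axis {axis!r}")
    mirrored = np.flip(roi.mask, axis=0)
    overlap = int((mirrored & roi.mask).sum())
    if overlap:
        warnings.warn(
            f"mirrored control ROI overlaps the tumour ROI on {overlap} pixels",
            ROIOverlapWarning,
            stacklevel=2,
        )
    return ROIMask(mask=mirrored, label="control", provenance=f"mirrored({roi.label})")


def polygon_to_mask(
    vertices, shape: tuple[int, int], label: str = "tumour"
) -> ROIMask:
    """Rasterize a polygon ROI given as ``[(row, col), ...]`` vertices
    (0-based pixel coordinates, row-major)."""
    from skimage.draw import polygon2mask

    mask = polygon2mask(shape, np.asarray(vertices, dtype=float))
    return ROIMask(mask=mask, label=label, provenance="polygon")


def _map_values(map_obj) -> tuple[np.ndarray, np.ndarray]:
    """Extract (values, valid) from a TauCMap, ContrastMap or plain array."""
    if isinstance(map_obj, TauCMap):
        return map_obj.tau_c, map_obj.valid
    if isinstance(map_obj, ContrastMap):
        return map_obj.K, np.isfinite(map_obj.K)
    arr = np.asarray(map_obj, dtype=float)
    return arr, np.isfinite(arr)


_UNITS = {"dcs": "s", "mldcs": "s"}


def roi_summary(map_obj, roi: ROIMask, units: str | None = None) -> ROISummary:
    """Mean, sample standard deviation and count of the valid pixels of a
    map under an ROI. Invalid pixels are excluded (and reduce ``n``); an ROI
    with no valid pixel is an error."""
    values, valid = _map_values(map_obj)
    if values.shape != roi.mask.shape:
        raise ValueError(
            f"map shape {values.shape} does not match ROI shape {roi.mask.shape}"
        )
    sel = values[roi.mask & valid]
    if sel.size == 0:
        raise ValueError(f"ROI {roi.label!r} contains no valid pixels")
    if units is None:
        if isinstance(map_obj, TauCMap):
            units = _UNITS.get(map_obj.method_tag, "s")
        elif isinstance(map_obj, ContrastMap):
            units = ""
        else:
            units = ""
    std = float(sel.std(ddof=1)) if sel.size > 1 else 0.0
    return ROISummary(mean=float(sel.mean()), std=std, n=int(sel.size), units=units)


def compute_snr(summary: ROISummary) -> float:
    """Single-image signal-to-noise ratio ``mu / sigma`` of one ROI."""
    if summary.std == 0:
        raise ValueError("SNR undefined: ROI standard deviation is zero")
    return summary.mean / summary.std


def welch_t_test(summary_t: ROISummary, summary_c: ROISummary) -> ComparisonResult:
    """Welch's unequal-variance two-sample t-test from ROI summaries.

    Returns the t statistic, Welch-Satterthwaite degrees of freedom, the
    two-sided p-value from Student's t distribution, and the tumour-ROI
    SNR (NaN if the tumour sigma is zero).
    """
    if summary_t.n < 2 or summary_c.n < 2:
        raise ValueError("Welch's t needs at least 2 pixels per ROI")
    vt, vc = summary_t.std**2, summary_c.std**2
    if vt == 0 and vc == 0:
        raise ValueError("both ROI variances are zero: t undefined")
    se2_t, se2_c = vt / summary_t.n, vc / summary_c.n
    se2 = se2_t + se2_c
    t = (summary_t.mean - summary_c.mean) / np.sqrt(se2)
    df = se2**2 / (
        (se2_t**2 / (summary_t.n - 1)) + (se2_c**2 / (summary_c.n - 1))
    )
    p = float(2.0 * _st.t.sf(abs(t), df))
    snr = summary_t.mean / summary_t.std if summary_t.std > 0 else np.nan
    return ComparisonResult(
        snr_t=float(snr),
        t_statistic=float(t),
        degrees_of_freedom=float(df),
        p_value=p,
    )


def compare_rois(map_obj, tumour: ROIMask, control: ROIMask) -> dict:
    """One row of the modality-comparison table: mu/sigma for both ROIs,
    SNR_T, Welch t and p. Keys mirror the conventional table layout."""
    sT = roi_summary(map_obj, tumour)
    sC = roi_summary(map_obj, control)
    res = welch_t_test(sT, sC)
    return {
        "mu_C": sC.mean,
        "sigma_C": sC.std,
        "mu_T": sT.mean,
        "sigma_T": sT.std,
        "n_T": sT.n,
        "n_C": sC.n,
        "SNR_T": res.snr_t,
        "t": res.t_statistic,
        "p": res.p_value,
        "units": sT.units,
    }


def difference_map(post_map, pre_map) -> np.ndarray:
    """Element-wise post-minus-pre difference of two co-registered maps.

    Accepts decorrelation-time maps, contrast maps or plain arrays of equal
    shape; no registration is performed (the caller asserts alignment).
    Pixels invalid in either input are NaN in the output.
    """
    post_v, post_ok = _map_values(post_map)
    pre_v, pre_ok = _map_values(pre_map)
    if post_v.shape != pre_v.shape:
        raise ValueError(
            f"map shapes differ: {post_v.shape} vs {pre_v.shape}"
        )
    out = np.where(post_ok & pre_ok, post_v - pre_v, np.nan)
    return out
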