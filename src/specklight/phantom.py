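"""Synthetic dynamic-speckle phantoms with known per-pixel decorrelation time.

The simulator produces single-pixel speckle intensity time series whose
normalized intensity autocorrelation follows, in expectation,

    g2(tau) - 1 = beta * exp(-tau / tau_c),

i.e. it is *calibrated* so that the 1/e read-out of the DCS pipeline recovers
exactly the requested decorrelation time ``tau_c``. The underlying dynamics
model is the simplest one consistent with Brownian scatterer motion and a
closed-form g2: each pixel carries an independent complex Gaussian field
E(t), evolved as a stationary Ornstein-Uhlenbeck process with field
correlation ``g1(tau) = exp(-tau / tau_f)``; the intensity is ``I = |E|^2``
and the Siegert relation gives ``g2 - 1 = beta * |g1|^2``. Because that
decays as ``exp(-2 tau / tau_f)``, the simulator sets ``tau_f = 2 * tau_c``.

Pixels are statistically independent in space (the downstream processing is
strictly pixel-wise), each driven by its own deterministic random stream
derived from ``(seed, pixel_index)``, so stacks are reproducible bit-for-bit
and a pixel's series does not depend on the stack shape.

"Static" (infinitely stiff) pixels are represented by the sentinel
:data:`STATIC` (``math.inf``): such a pixel holds one random speckle value,
drawn from the exponential intensity distribution, at every frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .stack import SpeckleStack

__all__ = [
    "STATIC",
    "Lesion",
    "PhantomSpec",
    "NoiseSpec",
    "GroundTruth",
    "make_phantom_tau_map",
    "simulate_pixel_intensity",
    "simulate_stack",
    "add_camera_noise",
    "standard_lesion_phantom",
]

#: Sentinel for an infinitely slow ("static") pixel. ``"static"`` is accepted
#: anywhere a tau_c is accepted and normalized to this value.
STATIC = math.inf

_ALLOWED_BIT_DEPTHS = (8, 10, 12, 16)


def _normalize_tau(tau_c) -> float:
    """Map the user-facing tau_c (number or ``"static"``) to a float."""
    if isinstance(tau_c, str):
        if tau_c.lower() == "static":
            return STATIC
        raise ValueError(f"unrecognized tau_c sentinel {tau_c!r}")
    tau = float(tau_c)
    if math.isinf(tau) and tau > 0:
        return STATIC
    if not (tau > 0 and math.isfinite(tau)):
        raise ValueError(f"tau_c must be > 0 and finite (or 'static'), got {tau_c}")
    return tau


@dataclass(frozen=True)
class Lesion:
    """An elliptical region of distinct decorrelation time.

    Center and semi-axes are in pixel coordinates, ``(row, col)`` 0-based.
    The ellipse must lie entirely within the image bounds.
    """

    center_row: float
    center_col: float
    semi_axis_row: float
    semi_axis_col: float
    tau_c: float  # seconds, or STATIC

    def mask(self, height: int, width: int) -> np.ndarray:
        rr, cc = np.mgrid[0:height, 0:width]
        return (
            ((rr - self.center_row) / self.semi_axis_row) ** 2
            + ((cc - self.center_col) / self.semi_axis_col) ** 2
        ) <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic acquisition.

    Defaults follow the acquisition regime the estimators are designed for:
    100 fps with a 9500 us exposure, and decorrelation times in the
    0.39-0.67 s range typical of soft-tissue surface speckle.
    """

    height: int
    width: int
    n_frames: int
    fps: float = 100.0
    exposure_us: float = 9500.0
    background_tau_c: float = 0.39
    lesions: tuple[Lesion, ...] = ()
    beta: float = 1.0  # Siegert coherence factor
    mean_intensity: float = 100.0  # photoelectrons / pixel / frame
    seed: int = 0
    oversample: int = 1  # sub-exposure temporal oversampling factor (1 = off)

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise ValueError("image dimensions must be >= 1")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not self.fps > 0:
            raise ValueError("fps must be > 0")
        if self.exposure_us < 0 or self.exposure_us > 1e6 / self.fps + 1e-9:
            raise ValueError(
                f"exposure_us must lie in [0, {1e6 / self.fps:.1f}] at fps={self.fps}"
            )
        if not (0 < self.beta <= 1):
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")
        if not self.mean_intensity > 0:
            raise ValueError("mean_intensity must be > 0")
        if self.oversample < 1:
            raise ValueError("oversample must be >= 1")
        object.__setattr__(self, "lesions", tuple(self.lesions))
        _normalize_tau(self.background_tau_c)
        for les in self.lesions:
            _normalize_tau(les.tau_c)
            if not (les.semi_axis_row > 0 and les.semi_axis_col > 0):
                raise ValueError("lesion semi-axes must be > 0")
            if (
                les.center_row - les.semi_axis_row < 0
                or les.center_row + les.semi_axis_row > self.height - 1
                or les.center_col - les.semi_axis_col < 0
                or les.center_col + les.semi_axis_col > self.width - 1
            ):
                raise ValueError(
                    f"lesion at ({les.center_row}, {les.center_col}) with semi-axes "
                    f"({les.semi_axis_row}, {les.semi_axis_col}) extends outside the "
                    f"{self.height}x{self.width} image"
                )


@dataclass(frozen=True)
class NoiseSpec:
    """Camera noise model: Poisson shot noise, Gaussian read noise,
    optional clipping + quantization to a given bit depth."""

    shot_noise: bool = False
    read_noise_sigma: float = 0.0  # photoelectrons
    bit_depth: int | None = None

    def __post_init__(self):
        if self.read_noise_sigma < 0:
            raise ValueError("read_noise_sigma must be >= 0")
        if self.bit_depth is not None and self.bit_depth not in _ALLOWED_BIT_DEPTHS:
            raise ValueError(f"bit_depth must be one of {_ALLOWED_BIT_DEPTHS} or None")

    @property
    def is_noiseless(self) -> bool:
        return (
            not self.shot_noise
            and self.read_noise_sigma == 0
            and self.bit_depth is None
        )


@dataclass
class GroundTruth:
    """Per-pixel ground truth of a simulated stack: the tau_c field (seconds;
    ``inf`` marks static pixels) and the boolean lesion mask."""

    tau_c_map: np.ndarray
    lesion_mask: np.ndarray


def make_phantom_tau_map(spec: PhantomSpec) -> GroundTruth:
    """Rasterize the ground-truth tau_c field of a phantom.

    The map equals ``spec.background_tau_c`` everywhere except inside
    lesions; overlapping lesions resolve last-listed-wins. The mask is true
    exactly where a lesion tau_c was assigned.
    """
    tau = np.full(
        (spec.height, spec.width), _normalize_tau(spec.background_tau_c), dtype=float
    )
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    for les in spec.lesions:
        m = les.mask(spec.height, spec.width)
        tau[m] = _normalize_tau(les.tau_c)
        mask |= m
    return GroundTruth(tau_c_map=tau, lesion_mask=mask)


# ---------------------------------------------------------------------------
# core speckle series generator
# ---------------------------------------------------------------------------


def _ou_complex_field(tau_f: float, n: int, dt: float, rng: np.random.Generator):
    """Stationary complex OU field, unit total variance, g1 = exp(-tau/tau_f)."""
    a = math.exp(-dt / tau_f)
    s = math.sqrt((1.0 - a * a) / 2.0)
    w = rng.standard_normal(n) + 1j * rng.standard_normal(n)
    x0 = w[0] / math.sqrt(2.0)  # stationary initial draw, component var 1/2
    if n == 1:
        return np.array([x0])
    y, _ = lfilter([1.0], [1.0, -a], s * w[1:], zi=np.array([a * x0]))
    return np.concatenate(([x0], y))


def _speckle_series(
    tau_c: float,
    n_frames: int,
    fps: float,
    beta: float,
    mean_intensity: float,
    rng: np.random.Generator,
    exposure_us: float = 0.0,
    oversample: int = 1,
) -> np.ndarray:
    """One pixel's intensity series under the calibrated OU-field model.

    Partial coherence: the fully developed speckle intensity is mixed with a
    constant pedestal, ``I = sqrt(beta) * I_speckle + (1 - sqrt(beta)) * m``,
    which yields exactly ``g2 - 1 = beta * |g1|^2`` while keeping the mean at
    ``m`` and intensities non-negative.

    When ``oversample > 1`` the field is simulated on a finer time grid and
    each frame integrates the sub-samples falling within the exposure window
    at the start of the frame period (instantaneous sampling otherwise).
    """
    if math.isinf(tau_c):
        i_speckle = np.full(n_frames, rng.exponential(1.0))
    else:
        tau_f = 2.0 * tau_c
        if oversample > 1:
            n_sub = n_frames * oversample
            E = _ou_complex_field(tau_f, n_sub, 1.0 / (fps * oversample), rng)
            I_fine = np.abs(E) ** 2
            n_int = max(1, round(oversample * exposure_us * 1e-6 * fps))
            I_fine = I_fine.reshape(n_frames, oversample)
            i_speckle = I_fine[:, :n_int].mean(axis=1)
        else:
            E = _ou_complex_field(tau_f, n_frames, 1.0 / fps, rng)
            i_speckle = np.abs(E) ** 2
    alpha = math.sqrt(beta)
    return mean_intensity * (alpha * i_speckle + (1.0 - alpha))


def simulate_pixel_intensity(
    tau_c,
    n_frames: int,
    fps: float,
    beta: float = 1.0,
    mean_intensity: float = 1.0,
    seed=0,
) -> np.ndarray:
    """Simulate one pixel's speckle intensity time series.

    Parameters
    ----------
    tau_c
        Speckle decorrelation time in seconds (> 0), or :data:`STATIC` /
        ``"static"`` for a frozen pixel.
    n_frames, fps
        Number of frames (>= 2) and frame rate.
    beta
        Siegert coherence factor in (0, 1]; ``g2(0) - 1 = beta``.
    mean_intensity
        Mean intensity of the series (arbitrary linear units).
    seed
        Integer or sequence seeding this pixel's private random stream.

    Returns
    -------
    numpy.ndarray
        Non-negative stationary series of length ``n_frames`` whose expected
        normalized autocorrelation is ``1 + beta * exp(-tau / tau_c)``.
    """
    tau = _normalize_tau(tau_c)
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if not fps > 0:
        raise ValueError("fps must be > 0")
    if not (0 < beta <= 1):
        raise ValueError("beta must be in (0, 1]")
    rng = np.random.default_rng(seed)
    return _speckle_series(tau, n_frames, fps, beta, mean_intensity, rng)


def simulate_stack(
    spec: PhantomSpec,
    noise: NoiseSpec | None = None,
    memory_budget_bytes: int = 4 << 30,
) -> tuple[SpeckleStack, GroundTruth]:
    """Simulate a full speckle stack from a phantom description.

    Every pixel is an independent realization of the single-pixel model with
    its own random stream ``(spec.seed, flat_pixel_index)``; the noise stage
    draws from a separate stream. Refuses to run if the estimated working
    memory (stack plus transposition workspace) exceeds ``memory_budget_bytes``.

    Returns
    -------
    (SpeckleStack, GroundTruth)
    """
    noise = noise or NoiseSpec()
    est_bytes = spec.n_frames * spec.height * spec.width * 8 * 2 * max(1, spec.oversample)
    if est_bytes > memory_budget_bytes:
        raise MemoryError(
            f"simulating {spec.n_frames}x{spec.height}x{spec.width} needs about "
            f"{est_bytes / 2**30:.1f} GiB, over the budget of "
            f"{memory_budget_bytes / 2**30:.1f} GiB"
        )
    gt = make_phantom_tau_map(spec)
    tau_flat = gt.tau_c_map.ravel()
    n_pix = tau_flat.size
    pix = np.empty((n_pix, spec.n_frames))
    for idx in range(n_pix):
        rng = np.random.default_rng([spec.seed, idx])
        pix[idx] = _speckle_series(
            tau_flat[idx],
            spec.n_frames,
            spec.fps,
            spec.beta,
            spec.mean_intensity,
            rng,
            exposure_us=spec.exposure_us,
            oversample=spec.oversample,
        )
    frames = pix.T.reshape(spec.n_frames, spec.height, spec.width).copy()
    stack = SpeckleStack(
        frames=frames,
        fps=spec.fps,
        exposure_us=spec.exposure_us,
        meta={"seed": spec.seed, "phantom": True},
    )
    if not noise.is_noiseless:
        stack = add_camera_noise(stack, noise, seed=[spec.seed, n_pix + 1])
    return stack, gt


def add_camera_noise(stack: SpeckleStack, noise: NoiseSpec, seed=0) -> SpeckleStack:
    """Apply the camera noise model to a (photoelectron-count) stack.

    Poisson shot noise replaces each intensity by a Poisson draw with that
    mean; Gaussian read noise is added; if a bit depth is set, values are
    clipped to ``[0, 2**bits - 1]`` and rounded to integers. A fully
    noiseless :class:`NoiseSpec` returns the input stack unchanged.
    """
    if noise.is_noiseless:
        return stack
    rng = np.random.default_rng(seed)
    frames = stack.frames.astype(float)
    if noise.shot_noise:
        frames = rng.poisson(frames).astype(float)
    if noise.read_noise_sigma > 0:
        frames = frames + rng.normal(0.0, noise.read_noise_sigma, frames.shape)
    if noise.bit_depth is not None:
        frames = np.clip(np.rint(frames), 0, 2**noise.bit_depth - 1)
    else:
        frames = np.clip(frames, 0.0, None)
    meta = dict(stack.meta)
    meta["noise"] = {
        "shot_noise": noise.shot_noise,
        "read_noise_sigma": noise.read_noise_sigma,
        "bit_depth": noise.bit_depth,
    }
    return SpeckleStack(
        frames=frames, fps=stack.fps, exposure_us=stack.exposure_us, meta=meta
    )


def standard_lesion_phantom(
    height: int = 64,
    width: int = 64,
    n_frames: int = 6000,
    fps: float = 100.0,
    background_tau_c: float = 0.39,
    lesion_tau_c: float = 0.67,
    seed: int = 0,
    **kwargs,
) -> PhantomSpec:
    """The stock validation phantom: a slow elliptical lesion in the upper
    hemisphere on a faster background, sized so lesion and mirrored-control
    ROIs each hold >= 1000 pixels at the default 64x64 geometry.

    The tau_c levels (0.67 s lesion on 0.39 s background) match the contrast
    regime of a locally stiffened soft-tissue surface.
    """
    lesion = Lesion(
        center_row=height * 0.25,
        center_col=width * 0.5,
        semi_axis_row=min(height * 0.19, height * 0.25),
        semi_axis_col=min(width * 0.42, width * 0.5 - 1),  # fits small images too
        tau_c=lesion_tau_c,
    )
    return PhantomSpec(
        height=height,
        width=width,
        n_frames=n_frames,
        fps=fps,
        background_tau_c=background_tau_c,
        lesions=(lesion,),
        seed=seed,
        **kwargs,
    )
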