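"""The universal in-memory container for speckle movies.

A :class:`SpeckleStack` is a ``(T, H, W)`` array of non-negative pixel
intensities together with the two pieces of acquisition metadata every
downstream estimator needs: the frame rate and the camera exposure time.
Axis 0 is always time; pixel coordinates are 0-based ``(row, col)``,
row-major.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpeckleStack"]


@dataclass
class SpeckleStack:
    """A time series of wide-field speckle images.

    Parameters
    ----------
    frames
        Intensity movie of shape ``(T, H, W)`` with ``T >= 2``. All values
        must be finite and non-negative (photoelectron counts or arbitrary
        linear camera units).
    fps
        Frame rate in frames per second. Strictly positive.
    exposure_us
        Camera exposure time per frame in microseconds. Cannot exceed the
        frame period ``1e6 / fps``.
    meta
        Free-form provenance dictionary (simulation seed, noise settings,
        source file, ...). Never interpreted by the estimators.
    """

    frames: np.ndarray
    fps: float
    exposure_us: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must have shape (T, H, W); got ndim={self.frames.ndim}"
            )
        if self.frames.shape[0] < 2:
            raise ValueError("a speckle stack needs at least 2 frames")
        if not np.isfinite(self.frames).all():
            raise ValueError("frames contain non-finite values")
        if (self.frames < 0).any():
            raise ValueError("intensities must be non-negative")
        if not self.fps > 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if self.exposure_us < 0:
            raise ValueError("exposure_us must be >= 0")
        if self.exposure_us > 1e6 / self.fps + 1e-9:
            raise ValueError(
                f"exposure_us={self.exposure_us} exceeds the frame period "
                f"{1e6 / self.fps:.1f} us at fps={self.fps}"
            )

    # -- convenience accessors -------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def duration(self) -> float:
        """Acquisition length in seconds (``T / fps``)."""
        return self.n_frames / self.fps

    def pixel_series(self, row: int, col: int) -> np.ndarray:
        """Return one pixel's intensity time series (a length-``T`` copy)."""
        return np.ascontiguousarray(self.frames[:, row, col], dtype=float)

    def as_pixel_matrix(self) -> np.ndarray:
        """Return the stack as an ``(H*W, T)`` matrix (row-major pixel order).

        This is a copy; mutating it does not touch :attr:`frames`.
        """
        return np.ascontiguousarray(
            self.frames.reshape(self.n_frames, -1).T, dtype=float
        )
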