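"""Time-density curves: the universal signal type of quantitative angiography.

A time-density curve (TDC) is the mean contrast density inside a region of
interest (ROI) of a digital-subtraction-angiography (DSA) sequence, sampled
uniformly in time.  Every downstream stage — deconvolution, biomarker
extraction, cohort modelling — consumes and produces this one type.

Conventions
-----------
* Times are in seconds; sample ``i`` sits at ``t0 + i * dt`` (no mid-frame
  offset).
* The ROI statistic is the arithmetic mean over mask pixels, so curves are
  invariant to ROI size.
* Contrast density is physically non-negative; baseline correction therefore
  clamps negative residuals to zero.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


class DegenerateCurveError(ValueError):
    """Raised when a curve is too degenerate for the requested quantity
    (e.g. an all-zero curve has no bolus arrival time)."""


def _as_float_vector(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return arr


@dataclasses.dataclass(frozen=True)
class TimeDensityCurve:
    """Uniformly sampled contrast-density series.

    Parameters
    ----------
    values : array-like of float
        Contrast density in arbitrary units, length >= 3.
    dt : float
        Frame interval in seconds, strictly positive.
    t0 : float, default 0.0
        Time of the first sample in seconds.
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self):
        arr = _as_float_vector(self.values, "values")
        if arr.size < 3:
            raise InvalidInputError(f"curve needs >= 3 samples, got {arr.size}")
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise InvalidInputError(f"dt must be strictly positive, got {self.dt}")
        if not np.isfinite(self.t0):
            raise InvalidInputError("t0 must be finite")
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "dt", float(self.dt))
        object.__setattr__(self, "t0", float(self.t0))

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times ``t0 + i*dt`` in seconds."""
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        """Span from first to last sample in seconds."""
        return self.dt * (self.values.size - 1)

    def with_values(self, values) -> "TimeDensityCurve":
        """Same grid, new samples."""
        return TimeDensityCurve(values, dt=self.dt, t0=self.t0)


@dataclasses.dataclass(frozen=True)
class ImageStack:
    """A DSA sequence: time x rows x cols of non-negative intensities."""

    frames: np.ndarray
    dt: float

    def __post_init__(self):
        arr = np.asarray(self.frames, dtype=float)
        if arr.ndim != 3:
            raise InvalidInputError(f"frames must be 3-D (time, rows, cols), got {arr.ndim}-D")
        if arr.shape[0] < 3:
            raise InvalidInputError("stack needs >= 3 frames")
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("frames contain non-finite values")
        if np.any(arr < 0):
            raise InvalidInputError("frames must be non-negative")
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise InvalidInputError(f"dt must be strictly positive, got {self.dt}")
        arr.setflags(write=False)
        object.__setattr__(self, "frames", arr)
        object.__setattr__(self, "dt", float(self.dt))

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclasses.dataclass(frozen=True)
class RoiMask:
    """Binary region-of-interest mask over one frame."""

    mask: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.mask)
        if arr.ndim != 2:
            raise InvalidInputError(f"mask must be 2-D, got {arr.ndim}-D")
        arr = arr.astype(bool)
        if not arr.any():
            raise InvalidInputError("mask has no true pixels")
        arr.setflags(write=False)
        object.__setattr__(self, "mask", arr)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def extract_tdc(stack: ImageStack, roi: RoiMask) -> TimeDensityCurve:
    """Average each frame over the ROI to produce a time-density curve.

    The curve value at frame ``i`` is the arithmetic mean of that frame over
    the true pixels of the mask; ``dt`` is copied from the stack.
    """
    if roi.mask.shape != stack.frame_shape:
        raise InvalidInputError(
            f"mask shape {roi.mask.shape} does not match frame shape {stack.frame_shape}"
        )
    values = stack.frames[:, roi.mask].mean(axis=1)
    return TimeDensityCurve(values, dt=stack.dt)


def baseline_correct(tdc: TimeDensityCurve, n_baseline: int) -> TimeDensityCurve:
    """Subtract the pre-bolus pedestal estimated from the first samples.

    DSA curves carry an offset before contrast arrives; relative thresholds
    (the 1 %-of-peak arrival rule) are only meaningful once it is removed.
    The mean of the first ``n_baseline`` samples is subtracted and negative
    residuals are clamped to zero.
    """
    n_baseline = int(n_baseline)
    if not 1 <= n_baseline < len(tdc):
        raise InvalidInputError(
            f"n_baseline must be in [1, {len(tdc) - 1}], got {n_baseline}"
        )
    pedestal = tdc.values[:n_baseline].mean()
    return tdc.with_values(np.maximum(tdc.values - pedestal, 0.0))


def resample(tdc: TimeDensityCurve, dt_new: float) -> TimeDensityCurve:
    """Linearly interpolate the curve onto a new uniform grid.

    The new grid starts at ``t0`` with step ``dt_new`` and covers the original
    span (the last original sample time is always included); endpoints are
    preserved exactly.
    """
    if not (np.isfinite(dt_new) and dt_new > 0):
        raise InvalidInputError(f"dt_new must be strictly positive, got {dt_new}")
    if dt_new == tdc.dt:
        return tdc
    span = tdc.duration
    n_new = int(np.floor(span / dt_new + 1e-9)) + 1
    t_new = tdc.t0 + dt_new * np.arange(n_new)
    values = np.interp(t_new, tdc.times, tdc.values)
    if n_new < 3:
        raise InvalidInputError("resampled curve would have fewer than 3 samples")
    return TimeDensityCurve(values, dt=dt_new, t0=tdc.t0)


# ---------------------------------------------------------------------------
# I/O: two-column text, wide CSV, TIFF / NPZ stacks and masks
# ---------------------------------------------------------------------------

def write_tdc(path, tdc: TimeDensityCurve, delimiter: str = "\t") -> None:
    """Write a curve as two-column (time, value) delimited text."""
    data = np.column_stack([tdc.times, tdc.values])
    np.savetxt(path, data, delimiter=delimiter, header="time_s\tvalue", comments="# ")


def read_tdc(path) -> TimeDensityCurve:
    """Read a two-column (time, value) text file; the grid must be uniform."""
    data = np.loadtxt(path, delimiter=None)
    if data.ndim != 2 or data.shape[1] < 2:
        raise InvalidInputError(f"{path}: expected two columns (time, value)")
    t, v = data[:, 0], data[:, 1]
    steps = np.diff(t)
    if steps.size == 0 or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise InvalidInputError(f"{path}: time column is not uniformly sampled")
    return TimeDensityCurve(v, dt=float(steps[0]), t0=float(t[0]))


def write_tdc_table(path, curves: dict[str, TimeDensityCurve]) -> None:
    """Write several curves sharing one grid as a wide CSV (time + one column each)."""
    import pandas as pd

    first = next(iter(curves.values()))
    for name, c in curves.items():
        if len(c) != len(first) or c.dt != first.dt or c.t0 != first.t0:
            raise InvalidInputError(f"curve {name!r} is not on the shared grid")
    df = pd.DataFrame({"time_s": first.times})
    for name, c in curves.items():
        df[name] = c.values
    df.to_csv(path, index=False)


def read_tdc_table(path) -> dict[str, TimeDensityCurve]:
    """Read a wide CSV written by :func:`write_tdc_table`."""
    import pandas as pd

    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise InvalidInputError(f"{path}: missing 'time_s' column")
    t = df["time_s"].to_numpy(float)
    steps = np.diff(t)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise InvalidInputError(f"{path}: time column is not uniformly sampled")
    dt, t0 = float(steps[0]), float(t[0])
    return {
        str(col): TimeDensityCurve(df[col].to_numpy(float), dt=dt, t0=t0)
        for col in df.columns
        if col != "time_s"
    }


def read_stack(path, dt: float) -> ImageStack:
    """Read an image stack from multi-page TIFF or NPZ (key ``frames``)."""
    path = Path(path)
    if path.suffix.lower() == ".npz":
        frames = np.load(path)["frames"]
    else:
        import tifffile

        frames = tifffile.imread(path)
    return ImageStack(np.asarray(frames, dtype=float), dt=dt)


def read_mask(path) -> RoiMask:
    """Read a binary mask from single-page TIFF or NPZ (key ``mask``)."""
    path = Path(path)
    if path.suffix.lower() == ".npz":
        mask = np.load(path)["mask"]
    else:
        import tifffile

        mask = tifffile.imread(path)
    return RoiMask(np.asarray(mask) != 0)


def write_stack(path, stack: ImageStack) -> None:
    path = Path(path)
    if path.suffix.lower() == ".npz":
        np.savez(path, frames=stack.frames)
    else:
        import tifffile

        tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")


def write_mask(path, roi: RoiMask) -> None:
    path = Path(path)
    if path.suffix.lower() == ".npz":
        np.savez(path, mask=roi.mask)
    else:
        import tifffile

        tifffile.imwrite(path, roi.mask.astype(np.uint8))
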