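"""First-order gray-level histogram features of a ROI.

Three parameters summarize the gray-level distribution inside a region of
interest:

    MGL  — mean gray level,
    SDGL — standard deviation of gray level (sample, n-1 denominator),
    CVGL — percent coefficient of variation, (SDGL / MGL) * 100.

Features are computed from the pixel values directly; the histogram is a
reporting artifact (re-binning only adds quantization error).  On filtered,
real-valued ROIs the histogram bins values into equal-width bins for
display while the features use the unquantized values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import ImageGrid

__all__ = ["GrayHistogram", "GrayLevelFeatures", "UndefinedCVError", "gray_histogram", "compute_gray_features"]


class UndefinedCVError(ZeroDivisionError):
    """CVGL requested for a ROI whose mean gray level is zero."""


@dataclass(frozen=True)
class GrayHistogram:
    """Gray-level histogram: equal-width bins spanning [0, 2**bit_depth - 1]."""

    counts: np.ndarray
    bin_edges: np.ndarray
    n_bins: int
    total: int


@dataclass(frozen=True)
class GrayLevelFeatures:
    mgl: float
    sdgl: float
    cvgl: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.mgl, self.sdgl, self.cvgl)


def _values(roi) -> np.ndarray:
    arr = roi.pixels if isinstance(roi, ImageGrid) else np.asarray(roi)
    return np.asarray(arr, dtype=float)


def gray_histogram(roi, n_bins: int = 4096, bit_depth: int = 12) -> GrayHistogram:
    """Histogram ROI values into `n_bins` equal-width bins over the full range.

    At full resolution (n_bins = 2**bit_depth) on integer inputs each bin
    holds exactly one gray level, so bin index == gray level.
    """
    v = _values(roi).ravel()
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    vmax = float((1 << bit_depth) - 1)
    if v.size and (v.min() < 0 or v.max() > vmax):
        raise ValueError(f"values outside [0, {vmax:g}] for bit_depth={bit_depth}")
    counts, edges = np.histogram(v, bins=n_bins, range=(0.0, vmax))
    return GrayHistogram(counts=counts, bin_edges=edges, n_bins=n_bins, total=int(v.size))


def compute_gray_features(roi, ddof: int = 1) -> GrayLevelFeatures:
    """Compute (MGL, SDGL, CVGL) for a ROI of raw or filtered values.

    Parameters
    ----------
    roi
        ImageGrid or real-valued 2D array; must be non-empty.
    ddof
        Denominator convention for SDGL: 1 (sample, default) or 0
        (population).  With a 40x50 ROI the difference is < 0.03%.

    Raises
    ------
    UndefinedCVError
        If MGL == 0 (CVGL is a ratio to the mean).
    """
    v = _values(roi).ravel()
    if v.size == 0:
        raise ValueError("empty ROI")
    mgl = float(np.mean(v))
    sdgl = float(np.std(v, ddof=ddof)) if v.size > ddof else 0.0
    if mgl == 0.0:
        raise UndefinedCVError("CVGL undefined: mean gray level is zero")
    cvgl = sdgl / mgl * 100.0
    return GrayLevelFeatures(mgl=mgl, sdgl=sdgl, cvgl=cvgl)
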