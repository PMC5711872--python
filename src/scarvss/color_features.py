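"""Color descriptors for RGB scar patches.

Two kinds of color information are extracted:

* the first four central moments (mean, variance, skewness, kurtosis) of
  each RGB channel — population moments (divide by N), non-excess kurtosis
  (a Gaussian channel gives 3), with skewness and kurtosis defined as 0 for
  a constant channel;
* 4-bin normalized histograms of each channel after conversion to HSV and
  to CIELAB.  Bin edges are fixed by the nominal channel ranges (H, S, V in
  [0, 1]; L* in [0, 100]; a*, b* in [-128, 127]) so that features are
  comparable across images; values are clipped into range and the last bin
  is right-closed.

Color-space conversions follow the sRGB standard with a D65 white point
(camera calibration data are not assumed available).  Hue is binned as a
linear quantity; its circular topology is deliberately ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as _skcolor

from .dataset_io import _validate_rgb


@dataclass(frozen=True)
class ChannelMoments:
    mean: float
    variance: float
    skewness: float
    kurtosis: float

    def as_array(self) -> np.ndarray:
        return np.array([self.mean, self.variance, self.skewness, self.kurtosis])


def channel_moments(values: np.ndarray) -> ChannelMoments:
    """First four central moments of a sample of channel values."""
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("cannot compute moments of an empty sample")
    m1 = float(x.mean())
    d = x - m1
    m2 = float((d**2).mean())
    if m2 == 0.0:
        return ChannelMoments(m1, 0.0, 0.0, 0.0)
    m3 = float((d**3).mean())
    m4 = float((d**4).mean())
    return ChannelMoments(m1, m2, m3 / m2**1.5, m4 / m2**2)


def rgb_moments(img: np.ndarray) -> np.ndarray:
    """12-value vector: moment quadruples of the R, G, B channels in order."""
    img = _validate_rgb(img)
    return np.concatenate(
        [channel_moments(img[..., ch]).as_array() for ch in range(3)]
    )


def rgb_to_hsv(img: np.ndarray) -> np.ndarray:
    """Standard hexcone RGB -> HSV conversion; H, S, V all in [0, 1]
    (hue is degrees/360)."""
    img = _validate_rgb(img)
    return _skcolor.rgb2hsv(img)


def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """sRGB -> CIELAB under the D65 white point.

    L* spans [0, 100]; a* and b* are roughly within [-128, 127].
    """
    img = _validate_rgb(img)
    return _skcolor.rgb2lab(img)


def histogram4(values: np.ndarray, value_range: tuple[float, float]) -> np.ndarray:
    """Normalized 4-bin histogram with equal-width bins over ``value_range``.

    Values are clipped into the range; the last bin is right-closed, so a
    value exactly at the upper edge lands in bin 4.
    """
    lo, hi = value_range
    if hi <= lo:
        raise ValueError(f"invalid range ({lo}, {hi})")
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("cannot histogram an empty sample")
    x = np.clip(x, lo, hi)
    counts, _ = np.histogram(x, bins=4, range=(lo, hi))
    return counts / x.size


#: Nominal per-channel ranges used for histogram binning.
HSV_RANGES = (((0.0, 1.0),) * 3)
LAB_RANGES = ((0.0, 100.0), (-128.0, 127.0), (-128.0, 127.0))


def hsv_histogram_features(img: np.ndarray) -> np.ndarray:
    """12 values: 4-bin histograms of H, S, V concatenated."""
    hsv = rgb_to_hsv(img)
    return np.concatenate(
        [histogram4(hsv[..., ch], HSV_RANGES[ch]) for ch in range(3)]
    )


def lab_histogram_features(img: np.ndarray) -> np.ndarray:
    """12 values: 4-bin histograms of L*, a*, b* concatenated."""
    lab = rgb_to_lab(img)
    return np.concatenate(
        [histogram4(lab[..., ch], LAB_RANGES[ch]) for ch in range(3)]
    )
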