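"""Colocalisation metrics, viscosity maps and per-object statistics.

Pearson and Manders coefficients quantify co-staining of two fluorescence
channels; lifetime maps become viscosity maps through a rotor calibration
curve; simple intensity segmentation supports per-cell summaries in which
each object contributes one observation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .calibration import CalibrationCurve
from .tcspc import LifetimeMap

__all__ = [
    "ChannelPair",
    "ColocResult",
    "pearson",
    "manders",
    "ViscosityMap",
    "apply_calibration",
    "segment_objects",
    "per_object_stats",
    "read_tiff",
    "write_tiff",
]


def read_tiff(path: str | Path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)


def write_tiff(path: str | Path, image: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


@dataclass(frozen=True)
class ChannelPair:
    """Two co-registered, non-negative intensity images."""

    ch1: np.ndarray
    ch2: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.ch1, dtype=float)
        b = np.asarray(self.ch2, dtype=float)
        if a.shape != b.shape:
            raise ValueError("channels must share the same shape")
        if np.any(a < 0) or np.any(b < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "ch1", a)
        object.__setattr__(self, "ch2", b)


@dataclass(frozen=True)
class ColocResult:
    pearson_r: float
    m1: float
    m2: float
    thresholds: tuple[float, float]
    n_pixels: int

    def summary(self) -> str:
        return (
            f"Colocalisation over {self.n_pixels} pixels "
            f"(thresholds {self.thresholds}):\n"
            f"  Pearson r = {self.pearson_r:.4f}\n"
            f"  Manders M1 (ch1 in ch2) = {self.m1:.4f}\n"
            f"  Manders M2 (ch2 in ch1) = {self.m2:.4f}"
        )


def pearson(pair: ChannelPair, mask: np.ndarray | None = None) -> float:
    """Product-moment correlation between the channels over masked pixels."""
    a, b = pair.ch1, pair.ch2
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        a, b = a[mask], b[mask]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size < 2:
        raise ValueError("need at least 2 pixels for a correlation")
    va, vb = a.std(), b.std()
    if va == 0 or vb == 0:
        raise ValueError("zero variance in a channel: correlation undefined")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (va * vb))


def manders(
    pair: ChannelPair, thresholds: tuple[float, float] = (0.0, 0.0)
) -> tuple[float, float]:
    """Manders colocalisation coefficients (M1, M2).

    M1 is the fraction of channel-1 intensity found in pixels where
    channel 2 exceeds its threshold; M2 symmetrically.  Thresholds default
    to zero (the classic coefficients).
    """
    t1, t2 = thresholds
    if t1 < 0 or t2 < 0:
        raise ValueError("thresholds must be non-negative")
    s1, s2 = pair.ch1.sum(), pair.ch2.sum()
    if s1 == 0 or s2 == 0:
        raise ValueError("zero total intensity in a channel")
    m1 = float(pair.ch1[pair.ch2 > t2].sum() / s1)
    m2 = float(pair.ch2[pair.ch1 > t1].sum() / s2)
    return m1, m2


def colocalise(
    pair: ChannelPair,
    thresholds: tuple[float, float] = (0.0, 0.0),
    mask: np.ndarray | None = None,
) -> ColocResult:
    """Pearson r over the union of above-threshold pixels, plus Manders."""
    t1, t2 = thresholds
    union = (pair.ch1 > t1) | (pair.ch2 > t2)
    if mask is not None:
        union &= np.asarray(mask, dtype=bool)
    r = pearson(pair, union)
    m1, m2 = manders(pair, thresholds)
    return ColocResult(r, m1, m2, (float(t1), float(t2)), int(union.sum()))


# ---------------------------------------------------------------------------
# Viscosity maps
# ---------------------------------------------------------------------------


@dataclass
class ViscosityMap:
    """Per-pixel viscosity (cP) converted from a lifetime map.

    ``extrapolated`` marks pixels whose lifetime fell outside the
    calibration's validity range; they hold finite values but should be
    interpreted with care.
    """

    viscosity_cp: np.ndarray
    mask: np.ndarray
    extrapolated: np.ndarray
    curve: CalibrationCurve

    def masked_values(self) -> np.ndarray:
        return self.viscosity_cp[self.mask]


def apply_calibration(
    lifetime: LifetimeMap | np.ndarray,
    curve: CalibrationCurve,
    mask: np.ndarray | None = None,
) -> ViscosityMap:
    """Convert a lifetime map (ps) to viscosity (cP) pixel by pixel."""
    if isinstance(lifetime, LifetimeMap):
        arr = lifetime.mean_lifetime_map()
        if mask is None:
            mask = lifetime.mask
    else:
        arr = np.asarray(lifetime, dtype=float)
    if mask is None:
        mask = np.isfinite(arr)
    mask = np.asarray(mask, dtype=bool) & np.isfinite(arr)
    out = np.full(arr.shape, np.nan)
    flags = np.zeros(arr.shape, dtype=bool)
    if mask.any():
        eta, ext = curve.lifetime_to_viscosity(arr[mask], with_flags=True)
        out[mask] = eta
        flags[mask] = ext
    return ViscosityMap(out, mask, flags, curve)


# ---------------------------------------------------------------------------
# Segmentation and per-object statistics
# ---------------------------------------------------------------------------


def segment_objects(
    image: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    min_size: int = 1,
) -> np.ndarray:
    """Label connected bright objects in an intensity image.

    ``otsu`` picks the threshold automatically; ``fixed`` uses the given
    value.  Components smaller than ``min_size`` pixels are discarded and
    labels are compacted to 1..n.
    """
    image = np.asarray(image, dtype=float)
    if np.any(image < 0):
        raise ValueError("intensity image must be non-negative")
    if method == "otsu":
        from skimage.filters import threshold_otsu

        if np.ptp(image) == 0:
            raise ValueError("flat image: cannot derive an Otsu threshold")
        thr = threshold_otsu(image)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        thr = threshold
    else:
        raise ValueError(f"unknown method {method!r}")
    binary = image > thr
    labels, n = ndimage.label(binary)
    if n and min_size > 1:
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_size
        keep[0] = False
        remap = np.zeros_like(sizes)
        remap[keep] = np.arange(1, keep.sum() + 1)
        labels = remap[labels]
    return labels


def per_object_stats(labels: np.ndarray, values: np.ndarray) -> pd.DataFrame:
    """Mean, SD and pixel count of ``values`` within each labelled object.

    NaN pixels (e.g. unfitted FLIM pixels) are excluded from an object's
    statistics; SD is the population standard deviation and NaN for
    single-pixel objects.
    """
    labels = np.asarray(labels)
    values = np.asarray(values, dtype=float)
    if labels.shape != values.shape:
        raise ValueError("labels and value map must be co-registered")
    rows = []
    for obj in np.unique(labels):
        if obj == 0:
            continue
        v = values[(labels == obj) & np.isfinite(values)]
        rows.append(
            {
                "object_id": int(obj),
                "mean": float(v.mean()) if v.size else float("nan"),
                "sd": float(v.std()) if v.size > 1 else float("nan"),
                "n_pixels": int(v.size),
            }
        )
    return pd.DataFrame(rows, columns=["object_id", "mean", "sd", "n_pixels"])
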