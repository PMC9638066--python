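"""Soil-background removal by thresholding the VARI raster.

Soil and canopy separate well in the visible atmospherically resistant index
VARI = (G - R) / (G + R - B): bare soil sits below zero, green canopy well
above.  The canopy mask keeps pixels whose VARI exceeds a threshold chosen
automatically by Otsu's method (256-bin histogram) or fixed by the user; the
mask then restricts every zonal extraction so soil pixels never dilute
plot-level index values (critical for early stages and unfertilized plots).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateFitError, GeometryError, UnitsError
from .geo import UNITS_REFLECTANCE, BandStack, GridTransform

logger = logging.getLogger(__name__)

#: reflectance-unit guard against vanishing VARI denominators
DENOM_EPS = 1e-6


@dataclass
class CanopyMask:
    """Binary canopy raster aligned to a band stack."""

    mask: np.ndarray  # bool (rows, cols); True = canopy
    transform: GridTransform
    threshold: float | None = None
    method: str = "fixed"
    fraction_retained: float = field(default=None)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.fraction_retained is None:
            self.fraction_retained = float(self.mask.mean()) if self.mask.size else 0.0


def vari_raster(stack: BandStack) -> np.ndarray:
    """Per-pixel VARI; NaN where the denominator vanishes or inputs are invalid."""
    if stack.units != UNITS_REFLECTANCE:
        raise UnitsError("VARI requires a reflectance stack; calibrate first")
    g = stack.band("green").astype(np.float64)
    r = stack.band("red").astype(np.float64)
    b = stack.band("blue").astype(np.float64)
    denom = g + r - b
    out = np.full(stack.shape, np.nan)
    ok = stack.valid_mask() & (np.abs(denom) >= DENOM_EPS)
    out[ok] = (g[ok] - r[ok]) / denom[ok]
    return out


def otsu_threshold(values) -> float:
    """Otsu's between-class-variance-maximizing split over a 256-bin histogram."""
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2 or np.unique(v).size < 2:
        raise DegenerateFitError("Otsu threshold undefined for constant input")
    return float(threshold_otsu(v, nbins=256))


def segment_soil(vari: np.ndarray, threshold, transform: GridTransform) -> CanopyMask:
    """Canopy mask = (VARI > threshold); ``threshold='auto'`` uses Otsu."""
    method = "fixed"
    if isinstance(threshold, str):
        if threshold != "auto":
            raise DegenerateFitError(f"unknown threshold mode {threshold!r}")
        threshold = otsu_threshold(vari)
        method = "otsu"
    threshold = float(threshold)
    valid = np.isfinite(vari)
    n_valid = int(valid.sum())
    if n_valid:
        vmin, vmax = float(np.nanmin(vari)), float(np.nanmax(vari))
        if threshold < vmin or threshold > vmax:
            logger.warning(
                "threshold %.4g outside observed VARI range [%.4g, %.4g]; "
                "mask will be full or empty",
                threshold, vmin, vmax,
            )
    mask = valid & (vari > threshold)
    frac = float(mask.sum() / n_valid) if n_valid else 0.0
    return CanopyMask(
        mask=mask, transform=transform, threshold=threshold, method=method,
        fraction_retained=frac,
    )


def mask_accuracy(mask: CanopyMask, truth: CanopyMask) -> dict:
    """Confusion-matrix summaries of a mask against a reference mask."""
    if mask.mask.shape != truth.mask.shape:
        raise GeometryError("mask grids are not aligned")
    m, t = mask.mask, truth.mask
    tp = int(np.count_nonzero(m & t))
    fp = int(np.count_nonzero(m & ~t))
    fn = int(np.count_nonzero(~m & t))
    tn = int(np.count_nonzero(~m & ~t))
    total = tp + fp + fn + tn
    union = tp + fp + fn
    return {
        "accuracy": (tp + tn) / total if total else float("nan"),
        "iou": tp / union if union else 1.0,
        "precision": tp / (tp + fp) if (tp + fp) else float("nan"),
        "recall": tp / (tp + fn) if (tp + fn) else float("nan"),
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
    }


class VariOtsuMasker(BaseEstimator, TransformerMixin):
    """Sklearn-style soil masker: fit learns the VARI threshold, transform masks.

    Parameters
    ----------
    method : "otsu" or "fixed"
    threshold : float, required when method="fixed"

    Attributes: ``threshold_`` (the value actually applied).
    """

    def __init__(self, method: str = "otsu", threshold: float | None = None):
        self.method = method
        self.threshold = threshold

    def fit(self, stack: BandStack, y=None):
        vari = vari_raster(stack)
        if self.method == "otsu":
            self.threshold_ = otsu_threshold(vari)
        elif self.method == "fixed":
            if self.threshold is None:
                raise DegenerateFitError("fixed method requires an explicit threshold")
            self.threshold_ = float(self.threshold)
        else:
            raise DegenerateFitError(f"unknown masking method {self.method!r}")
        return self

    def transform(self, stack: BandStack) -> CanopyMask:
        if not hasattr(self, "threshold_"):
            raise DegenerateFitError("VariOtsuMasker is not fitted")
        vari = vari_raster(stack)
        out = segment_soil(vari, self.threshold_, stack.transform)
        out.method = self.method
        return out
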