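"""Empirical line method (ELM) radiometric calibration.

The camera's digital numbers (DN) are converted to surface reflectance with a
zero-intercept per-band linear model,

    R_band = a_band * DN_band,

whose slope ``a_band`` is estimated by least squares over reference panels of
known reflectance.  Panel DN values are the arithmetic mean over a small
square at the panel center, avoiding boundary-mixing pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import box
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    DegenerateFitError,
    ExtractionError,
    GeometryError,
    InvalidConfigError,
    UnitsError,
)
from .geo import BAND_NAMES, UNITS_DN, UNITS_REFLECTANCE, BandStack, pixel_center_mask

logger = logging.getLogger(__name__)


@dataclass
class PanelSet:
    """Reference panels: footprint polygons and known per-band reflectances."""

    polygons: list
    reflectances: np.ndarray  # (n_panels, 5) in [0, 1]
    panel_ids: list

    def __post_init__(self):
        self.reflectances = np.asarray(self.reflectances, dtype=float)
        if len(self.polygons) < 1:
            raise InvalidConfigError("need at least one reference panel")
        if self.reflectances.shape != (len(self.polygons), len(BAND_NAMES)):
            raise InvalidConfigError(
                f"reflectances must be (n_panels, 5), got {self.reflectances.shape}"
            )
        if np.any(self.reflectances < 0) or np.any(self.reflectances > 1):
            raise InvalidConfigError("panel reflectances must lie in [0, 1]")

    def __len__(self):
        return len(self.polygons)

    def reflectance_frame(self) -> pd.DataFrame:
        """Long (panel_id, band, reflectance) table, the CSV interchange format."""
        rows = [
            {"panel_id": pid, "band": band, "reflectance": self.reflectances[i, b]}
            for i, pid in enumerate(self.panel_ids)
            for b, band in enumerate(BAND_NAMES)
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, polygons, panel_ids, frame: pd.DataFrame) -> "PanelSet":
        wide = frame.pivot(index="panel_id", columns="band", values="reflectance")
        refl = wide.loc[panel_ids, list(BAND_NAMES)].to_numpy()
        return cls(polygons=list(polygons), reflectances=refl, panel_ids=list(panel_ids))


def extract_panel_dn(stack: BandStack, panels: PanelSet, inner_side: float = 0.2) -> np.ndarray:
    """Mean DN per panel per band over the centered ``inner_side`` square.

    Only pixels whose centers fall inside the inner square are used (the
    standard way to avoid panel boundary-mixing effects).
    """
    if stack.units != UNITS_DN:
        raise UnitsError("panel extraction expects a DN stack")
    minx = stack.transform.origin_x
    maxy = stack.transform.origin_y
    maxx = minx + stack.shape[1] * stack.transform.pixel_size
    miny = maxy - stack.shape[0] * stack.transform.pixel_size
    extent = box(minx, miny, maxx, maxy)

    out = np.empty((len(panels), len(BAND_NAMES)), dtype=float)
    for i, poly in enumerate(panels.polygons):
        if not extent.intersects(poly):
            raise GeometryError(f"panel {panels.panel_ids[i]} lies outside the raster extent")
        cx, cy = poly.centroid.x, poly.centroid.y
        inner = box(cx - inner_side / 2, cy - inner_side / 2, cx + inner_side / 2, cy + inner_side / 2)
        if not poly.contains(inner):
            raise ExtractionError(
                f"panel {panels.panel_ids[i]} is smaller than the {inner_side} m inner square"
            )
        sel = pixel_center_mask(stack.transform, stack.shape, inner)
        if not sel.any():
            raise ExtractionError(
                f"no pixel centers inside the inner square of panel {panels.panel_ids[i]}"
            )
        for b in range(len(BAND_NAMES)):
            out[i, b] = float(stack.data[b][sel].mean())
    return out


@dataclass
class ElmCoefficients:
    """Fitted per-band DN -> reflectance slopes with fit diagnostics."""

    slopes: np.ndarray  # (5,) reflectance per DN
    residual_rms: np.ndarray  # (5,) RMS of panel reflectance residuals
    n_panels: int

    def __post_init__(self):
        self.slopes = np.asarray(self.slopes, dtype=float)
        self.residual_rms = np.asarray(self.residual_rms, dtype=float)
        if not np.all(np.isfinite(self.slopes)) or np.any(self.slopes <= 0):
            raise DegenerateFitError("ELM slopes must be strictly positive and finite")


def fit_elm(panel_dns, panel_refls) -> ElmCoefficients:
    """Zero-intercept least squares per band: a = sum(R*DN) / sum(DN^2)."""
    D = np.atleast_2d(np.asarray(panel_dns, dtype=float))
    R = np.atleast_2d(np.asarray(panel_refls, dtype=float))
    if D.shape != R.shape or D.shape[1] != len(BAND_NAMES):
        raise InvalidConfigError(f"panel DN/reflectance shapes differ: {D.shape} vs {R.shape}")
    if D.shape[0] < 1:
        raise InvalidConfigError("need at least one panel")
    denom = np.sum(D * D, axis=0)
    if np.any(denom <= 0):
        raise DegenerateFitError("all-zero DN in at least one band; slope not identifiable")
    slopes = np.sum(R * D, axis=0) / denom
    resid = R - slopes[None, :] * D
    rms = np.sqrt(np.mean(resid**2, axis=0))
    return ElmCoefficients(slopes=slopes, residual_rms=rms, n_panels=D.shape[0])


def apply_elm(stack: BandStack, coeffs: ElmCoefficients, clip_max: float = 1.0) -> BandStack:
    """Convert a DN stack to reflectance: R = DN * a_band, clipped at clip_max."""
    if stack.units != UNITS_DN:
        raise UnitsError("stack is already in reflectance units")
    data = stack.data.astype(np.float64)
    nodata_mask = None
    if stack.nodata is not None:
        nodata_mask = stack.data == stack.nodata
    refl = data * np.asarray(coeffs.slopes)[:, None, None]
    n_clipped = int(np.count_nonzero(refl > clip_max))
    if n_clipped:
        logger.warning("clipped %d reflectance values above %.3g", n_clipped, clip_max)
        np.clip(refl, None, clip_max, out=refl)
    if nodata_mask is not None:
        refl[nodata_mask] = np.nan
    return stack.with_data(refl.astype(np.float32), units=UNITS_REFLECTANCE, nodata=None)


class ElmCalibrator(BaseEstimator, TransformerMixin):
    """Sklearn-style empirical-line calibrator.

    ``fit`` takes per-panel mean DN (n_panels, 5) as X and the matching known
    reflectances as y; ``transform`` converts a DN :class:`BandStack` to
    reflectance.  :meth:`fit_from_stack` runs panel extraction first.

    Attributes set by fit: ``slopes_``, ``residual_rms_``, ``n_panels_``.
    """

    def __init__(self, inner_side: float = 0.2, clip_max: float = 1.0):
        self.inner_side = inner_side
        self.clip_max = clip_max

    def fit(self, X, y):
        coeffs = fit_elm(X, y)
        self.slopes_ = coeffs.slopes
        self.residual_rms_ = coeffs.residual_rms
        self.n_panels_ = coeffs.n_panels
        return self

    def fit_from_stack(self, stack: BandStack, panels: PanelSet):
        dns = extract_panel_dn(stack, panels, inner_side=self.inner_side)
        return self.fit(dns, panels.reflectances)

    def transform(self, stack: BandStack) -> BandStack:
        if not hasattr(self, "slopes_"):
            raise DegenerateFitError("ElmCalibrator is not fitted")
        return apply_elm(stack, self.coefficients_, clip_max=self.clip_max)

    @property
    def coefficients_(self) -> ElmCoefficients:
        return ElmCoefficients(
            slopes=self.slopes_, residual_rms=self.residual_rms_, n_panels=self.n_panels_
        )


def percent_error(measured, reference) -> float:
    """Mean absolute percent error, 100 * mean(|m - r| / |r|).

    Used to compare camera-derived band reflectance or indices against an
    independent reference (e.g., a field spectrometer).
    """
    m = np.asarray(measured, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.shape != r.shape:
        raise InvalidConfigError("measured and reference must have equal length")
    if np.any(r == 0):
        raise ZeroDivisionError("reference contains zero entries; percent error undefined")
    return float(100.0 * np.mean(np.abs(m - r) / np.abs(r)))
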