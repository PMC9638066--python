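"""The nine vegetation indices and masked plot-level (zonal) extraction.

All indices are per-pixel band algebra on reflectance:

====================  =============================================
VARI                  (G - R) / (G + R - B)
NGBDI                 (G - B) / (G + B)
NDVI                  (NIR - R) / (NIR + R)
NDRE                  (NIR - RE) / (NIR + RE)
GNDVI                 (NIR - G) / (NIR + G)
CIrededge             NIR / RE - 1
MTCI                  (NIR - RE) / (RE - R)
mNDblue               (B - RE) / (NIR + B)
repRVI                R / NIR   (reciprocal of the ratio index NIR/R)
====================  =============================================

Plot-level values are the mean of per-pixel index values over canopy-mask
pixels inside the inward-buffered plot polygon (mean-of-index, not
index-of-mean-reflectance; the two differ because the formulas are nonlinear,
and this package pins the former).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import EmptyZoneError, GeometryError, InvalidConfigError, UnitsError
from .geo import UNITS_REFLECTANCE, BandStack, pixel_center_mask
from .masking import DENOM_EPS, CanopyMask

logger = logging.getLogger(__name__)

# name -> (numerator, denominator) as functions of (blue, green, red, red_edge, nir)
_FORMULAS = {
    "VARI": (lambda b, g, r, re, n: g - r, lambda b, g, r, re, n: g + r - b),
    "NGBDI": (lambda b, g, r, re, n: g - b, lambda b, g, r, re, n: g + b),
    "NDVI": (lambda b, g, r, re, n: n - r, lambda b, g, r, re, n: n + r),
    "NDRE": (lambda b, g, r, re, n: n - re, lambda b, g, r, re, n: n + re),
    "GNDVI": (lambda b, g, r, re, n: n - g, lambda b, g, r, re, n: n + g),
    "CIrededge": (lambda b, g, r, re, n: n - re, lambda b, g, r, re, n: re),
    "MTCI": (lambda b, g, r, re, n: n - re, lambda b, g, r, re, n: re - r),
    "mNDblue": (lambda b, g, r, re, n: b - re, lambda b, g, r, re, n: n + b),
    "repRVI": (lambda b, g, r, re, n: r, lambda b, g, r, re, n: n),
}

INDEX_NAMES = tuple(_FORMULAS)


def compute_index(stack: BandStack, name: str) -> np.ndarray:
    """Per-pixel index raster; NaN where the denominator is within eps of zero."""
    if name not in _FORMULAS:
        raise KeyError(f"unknown index {name!r}; choose from {INDEX_NAMES}")
    if stack.units != UNITS_REFLECTANCE:
        raise UnitsError("vegetation indices require reflectance units")
    bands = [stack.data[i].astype(np.float64) for i in range(5)]
    num_f, den_f = _FORMULAS[name]
    num, den = num_f(*bands), den_f(*bands)
    out = np.full(stack.shape, np.nan)
    ok = stack.valid_mask() & (np.abs(den) >= DENOM_EPS)
    out[ok] = num[ok] / den[ok]
    return out


def zonal_mean(raster, polygon, mask: CanopyMask, edge_buffer: float = 0.25):
    """Mean of `raster` over canopy pixels inside the inward-buffered polygon.

    Returns ``(value, n_pixels)``; raises :class:`EmptyZoneError` when no pixel
    qualifies (soil-only plots must be flagged, never silently NaN).
    """
    raster = np.asarray(raster)
    if raster.shape != mask.mask.shape:
        raise GeometryError("raster and mask grids are not aligned")
    zone = polygon.buffer(-edge_buffer) if edge_buffer > 0 else polygon
    if zone.is_empty:
        raise EmptyZoneError("inward buffer consumed the whole polygon")
    sel = pixel_center_mask(mask.transform, raster.shape, zone)
    sel &= mask.mask & np.isfinite(raster)
    n = int(sel.sum())
    if n == 0:
        raise EmptyZoneError("no canopy pixels inside the buffered polygon")
    return float(raster[sel].mean()), n


def build_vi_table(
    stacks: dict,
    layout,
    masks: dict,
    index_names="all",
    edge_buffer: float = 0.25,
) -> pd.DataFrame:
    """Long (plot_id, stage, index, value, n_pixels) table over all stages.

    Plots that are fully soil-masked at a stage are recorded in
    ``result.attrs['empty_zones']`` and omitted from the table, leaving every
    reported value backed by at least one pixel.
    """
    if index_names == "all":
        index_names = list(INDEX_NAMES)
    unknown = [n for n in index_names if n not in _FORMULAS]
    if unknown:
        raise KeyError(f"unknown indices {unknown}")
    missing = [s for s in stacks if s not in masks] + [s for s in masks if s not in stacks]
    if missing:
        raise InvalidConfigError(f"stages missing a stack or a mask: {sorted(set(missing))}")

    records, empty = [], []
    for stage, stack in stacks.items():
        mask = masks[stage]
        if mask.mask.shape != stack.shape:
            raise GeometryError(f"mask/stack shapes differ at stage {stage}")
        # per-plot pixel selections are index-independent; compute them once
        zones = {}
        for row in layout:
            zone = row.geometry.buffer(-edge_buffer) if edge_buffer > 0 else row.geometry
            if zone.is_empty:
                raise EmptyZoneError(f"buffer consumed plot {row.plot_id}")
            zones[row.plot_id] = pixel_center_mask(mask.transform, stack.shape, zone) & mask.mask
        for name in index_names:
            raster = compute_index(stack, name)
            finite = np.isfinite(raster)
            for plot_id, sel in zones.items():
                use = sel & finite
                n = int(use.sum())
                if n == 0:
                    empty.append((plot_id, stage, name))
                    logger.warning("empty zone: plot %s stage %s index %s", plot_id, stage, name)
                    continue
                records.append(
                    {
                        "plot_id": plot_id,
                        "stage": stage,
                        "index": name,
                        "value": float(raster[use].mean()),
                        "n_pixels": n,
                    }
                )
    out = pd.DataFrame(records, columns=["plot_id", "stage", "index", "value", "n_pixels"])
    _check_reciprocal_identity(out)
    out.attrs["empty_zones"] = empty
    return out


def _check_reciprocal_identity(table: pd.DataFrame) -> None:
    # internal consistency spot-check: plot-level repRVI must be the mean of
    # Red/NIR, i.e. strictly positive wherever reported for a reflective canopy
    rep = table[table["index"] == "repRVI"]["value"]
    if len(rep) and (rep <= 0).any():
        logger.warning("repRVI non-positive for %d plot records", int((rep <= 0).sum()))


def vi_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long VI table to plot_id x 'index@stage' feature columns."""
    wide = table.pivot_table(
        index="plot_id", columns=["index", "stage"], values="value", aggfunc="first"
    )
    wide.columns = [f"{idx}@{stage}" for idx, stage in wide.columns]
    return wide
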