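"""Per-plot agronomic targets: grain yield and the two NUE traits.

For a plot fertilized at rate Ni (kg N/ha, Ni > 0) with grain yield GY_Ni
(kg/ha) and an unfertilized control yielding GY_N0:

    NPFP = GY_Ni / Ni                 (N partial factor productivity)
    aNUE = (GY_Ni - GY_N0) / Ni       (agronomic N use efficiency)

both in kg yield per kg N.  Neither is defined at Ni = 0, and the exact
identity aNUE = NPFP - GY_N0 / Ni ties the two together.  aNUE may be
negative when a fertilized plot yields below its control.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, PairingError, UndefinedTraitError

PAIRING_RULES = ("replicate", "variety-mean")


def yield_to_kg_ha(sample_mass_g: float, sample_area_m2: float) -> float:
    """Convert a harvested sample (grams over m^2) to kg/ha.

    (g / m^2) * (10000 m^2/ha) / (1000 g/kg) = 10 * g/m^2.
    """
    if sample_area_m2 <= 0:
        raise InvalidConfigError("sample area must be positive")
    if sample_mass_g < 0:
        raise InvalidConfigError("sample mass must be non-negative")
    return 10.0 * sample_mass_g / sample_area_m2


def compute_npfp(gy: float, ni: float) -> float:
    if ni <= 0:
        raise UndefinedTraitError("NPFP is undefined at N rate 0")
    if gy < 0:
        raise InvalidConfigError("yield must be non-negative")
    return gy / ni


def compute_anue(gy: float, gy_n0: float, ni: float) -> float:
    if ni <= 0:
        raise UndefinedTraitError("aNUE is undefined at N rate 0")
    return (gy - gy_n0) / ni


def build_trait_table(yields, layout, pairing: str = "replicate") -> pd.DataFrame:
    """Assemble the per-plot trait table.

    Parameters
    ----------
    yields : mapping or DataFrame
        plot_id -> yield (kg/ha), or a frame with plot_id / yield_kg_ha columns.
    layout : PlotLayout
        supplies n_level, variety, replicate per plot.
    pairing : "replicate" or "variety-mean"
        how each fertilized plot finds its GY_N0 control: the N0 plot of the
        same variety and replicate, or the mean over the variety's N0 plots.

    NPFP/aNUE columns are NaN (absent, not zero) for N0 plots.
    """
    if pairing not in PAIRING_RULES:
        raise InvalidConfigError(f"pairing must be one of {PAIRING_RULES}")
    if isinstance(yields, pd.DataFrame):
        ymap = dict(zip(yields["plot_id"], yields["yield_kg_ha"]))
    else:
        ymap = dict(yields)

    frame = layout.frame[["plot_id", "n_level", "variety", "replicate"]].copy()
    missing = [p for p in frame["plot_id"] if p not in ymap]
    if missing:
        raise InvalidConfigError(f"yields missing for plots {missing}")
    frame["yield_kg_ha"] = [float(ymap[p]) for p in frame["plot_id"]]

    n0 = frame[frame["n_level"] == 0]
    rows = []
    unmatched = []
    for _, row in frame.iterrows():
        rec = row.to_dict()
        if row.n_level > 0:
            if pairing == "replicate":
                ctrl = n0[(n0["variety"] == row.variety) & (n0["replicate"] == row.replicate)]
                if len(ctrl) != 1:
                    unmatched.append(row.plot_id)
                    continue
                gy_n0 = float(ctrl["yield_kg_ha"].iloc[0])
                rec["paired_n0_plot_id"] = ctrl["plot_id"].iloc[0]
            else:
                ctrl = n0[n0["variety"] == row.variety]
                if len(ctrl) == 0:
                    unmatched.append(row.plot_id)
                    continue
                gy_n0 = float(ctrl["yield_kg_ha"].mean())
                rec["paired_n0_plot_id"] = "|".join(ctrl["plot_id"])
            rec["npfp"] = compute_npfp(row.yield_kg_ha, row.n_level)
            rec["anue"] = compute_anue(row.yield_kg_ha, gy_n0, row.n_level)
            rec["gy_n0"] = gy_n0
        else:
            rec["paired_n0_plot_id"] = None
            rec["npfp"] = np.nan
            rec["anue"] = np.nan
            rec["gy_n0"] = np.nan
        rows.append(rec)
    if unmatched:
        raise PairingError(unmatched)
    return pd.DataFrame(rows)
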