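"""Synthetic winter-wheat trial scenes.

Emulates a 4 N-level x 3 variety x 3 replicate split-plot trial (36 plots of
2 m x 8 m, ~1.5 cm ground sample distance) imaged by a 5-band multispectral
camera across six growth stages, together with reflectance reference panels
and per-plot yield ground truth.  The generative chain is

    N rate (+ small variety offset)  ->  latent vigor
    vigor                            ->  canopy endmember spectrum
                                         (red/blue darken, red-edge/NIR brighten)
    vigor, stage                     ->  fractional canopy cover
    per-pixel Bernoulli(cover) + sub-pixel mixing  ->  canopy fraction field
    linear canopy/soil mixture (+ noise)           ->  reflectance
    reflectance / a_band (+ DN noise, quantization) -> digital numbers

so soil contamination, its N dependence, and the DN->reflectance calibration
problem all arise exactly as the downstream modules assume.  Yields are
linear in vigor plus Gaussian noise, which couples canopy signal to yield and
lets vegetation-index/trait correlations of realistic magnitude emerge.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from .calibration import PanelSet
from .errors import InvalidConfigError, StageError
from .geo import (
    BAND_NAMES,
    UNITS_DN,
    UNITS_REFLECTANCE,
    BandStack,
    GridTransform,
    pixel_center_mask,
    read_band_stack,
    read_feature_collection,
    write_band_stack,
    write_feature_collection,
    write_single_band,
    read_single_band,
)
from .masking import CanopyMask

DEFAULT_STAGES = ("J", "B", "H", "LF", "IGF", "LGF")


@dataclass(frozen=True)
class SceneConfig:
    """All free parameters of the synthetic trial.

    Spectra are band-ordered (blue, green, red, red_edge, nir) reflectances in
    [0, 1].  ``canopy_spectrum_params`` maps latent vigor v in [0, 1] to the
    canopy endmember via base + slope * v per band.  ``cover_params`` maps
    (stage, vigor) to fractional canopy cover via base_s + gain_s * v, clipped
    to [0, cover_max].  ``elm_true_slopes`` are the true per-band DN ->
    reflectance slopes a_i; DN noise is additive Gaussian before (optional)
    16-bit quantization.
    """

    n_levels: tuple = (0.0, 100.0, 200.0, 300.0)  # kg N/ha
    varieties: int = 3
    replicates: int = 3
    plot_size: tuple = (2.0, 8.0)  # width x length, m
    gsd: float = 0.015  # m/pixel
    stages: tuple = DEFAULT_STAGES
    soil_spectrum: tuple = (0.10, 0.16, 0.22, 0.26, 0.30)
    canopy_spectrum_params: tuple = (
        (0.055, -0.025),  # blue
        (0.110, -0.030),  # green
        (0.080, -0.050),  # red
        (0.180, 0.100),  # red edge
        (0.320, 0.200),  # nir
    )
    cover_params: dict = field(
        default_factory=lambda: {
            "J": (0.15, 0.55),
            "B": (0.35, 0.55),
            "H": (0.45, 0.55),
            "LF": (0.50, 0.52),
            "IGF": (0.50, 0.50),
            "LGF": (0.45, 0.48),
        }
    )
    cover_max: float = 0.98
    vigor_params: dict = field(
        default_factory=lambda: {
            "intercept": 0.15,
            "span": 0.65,
            "gamma": 0.8,
            "variety_offsets": (0.02, 0.0, -0.02),
            "noise_sd": 0.04,
        }
    )
    yield_model: dict = field(
        default_factory=lambda: {"intercept": 2800.0, "slope": 7000.0, "noise_sd": 250.0}
    )
    elm_true_slopes: tuple = (1.8e-5, 2.0e-5, 2.2e-5, 2.4e-5, 2.6e-5)
    dn_noise_sd: float = 15.0
    refl_noise_sd: float = 0.004
    mixing_sd: float = 0.06
    quantize_dn: bool = True
    panel_reflectances: tuple = (
        (0.06,) * 5,
        (0.22,) * 5,
        (0.44,) * 5,
        (0.64,) * 5,
    )
    panel_size: float = 0.5  # m
    margin: float = 1.0  # m around the field
    plot_spacing: float = 0.5  # m between plots
    panel_strip: float = 1.0  # m strip holding the panels
    seed: int = 0

    def __post_init__(self):
        if self.varieties < 1 or self.replicates < 1 or len(self.n_levels) < 1:
            raise InvalidConfigError("n_levels, varieties, replicates must be >= 1")
        w, l = self.plot_size
        if w <= 0 or l <= 0 or self.gsd <= 0:
            raise InvalidConfigError("plot dimensions and gsd must be positive")
        for sd_name in ("dn_noise_sd", "refl_noise_sd", "mixing_sd"):
            if getattr(self, sd_name) < 0:
                raise InvalidConfigError(f"{sd_name} must be non-negative")
        if self.yield_model["noise_sd"] < 0:
            raise InvalidConfigError("yield noise sd must be non-negative")
        if not all(a > 0 for a in self.elm_true_slopes):
            raise InvalidConfigError("elm_true_slopes must be strictly positive")
        spectra = np.concatenate(
            [np.ravel(self.soil_spectrum), np.ravel(self.panel_reflectances)]
        )
        if np.any(spectra < 0) or np.any(spectra > 1):
            raise InvalidConfigError("reflectances must lie in [0, 1]")
        missing = [s for s in self.stages if s not in self.cover_params]
        if missing:
            raise InvalidConfigError(f"cover_params missing stages {missing}")

    @property
    def n_plots(self) -> int:
        return len(self.n_levels) * self.varieties * self.replicates

    # -- field geometry --------------------------------------------------
    @property
    def grid_cols(self) -> int:
        return self.varieties * self.replicates

    @property
    def grid_rows(self) -> int:
        return len(self.n_levels)

    @property
    def field_size(self) -> tuple[float, float]:
        """(width, height) of the scene in meters."""
        w, l = self.plot_size
        width = 2 * self.margin + self.grid_cols * w + (self.grid_cols - 1) * self.plot_spacing
        height = (
            2 * self.margin
            + self.panel_strip
            + self.plot_spacing
            + self.grid_rows * l
            + (self.grid_rows - 1) * self.plot_spacing
        )
        return width, height

    @property
    def raster_shape(self) -> tuple[int, int]:
        width, height = self.field_size
        return int(round(height / self.gsd)), int(round(width / self.gsd))

    @property
    def transform(self) -> GridTransform:
        _, height = self.field_size
        return GridTransform(origin_x=0.0, origin_y=height, pixel_size=self.gsd)

    def canopy_spectrum(self, vigor):
        """Canopy endmember reflectance per band for latent vigor (vectorized)."""
        v = np.asarray(vigor, dtype=float)[..., None]
        params = np.asarray(self.canopy_spectrum_params)
        return np.clip(params[:, 0] + params[:, 1] * v, 0.0, 1.0)

    def cover(self, stage, vigor):
        if stage not in self.cover_params:
            raise StageError(stage)
        base, gain = self.cover_params[stage]
        return np.clip(base + gain * np.asarray(vigor, dtype=float), 0.0, self.cover_max)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cover_params"] = {k: list(v) for k, v in self.cover_params.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        for key in (
            "n_levels",
            "plot_size",
            "stages",
            "soil_spectrum",
            "elm_true_slopes",
        ):
            if key in d:
                d[key] = tuple(d[key])
        if "canopy_spectrum_params" in d:
            d["canopy_spectrum_params"] = tuple(tuple(p) for p in d["canopy_spectrum_params"])
        if "panel_reflectances" in d:
            d["panel_reflectances"] = tuple(tuple(p) for p in d["panel_reflectances"])
        if "cover_params" in d:
            d["cover_params"] = {k: tuple(v) for k, v in d["cover_params"].items()}
        if "vigor_params" in d and "variety_offsets" in d["vigor_params"]:
            d["vigor_params"] = dict(d["vigor_params"])
            d["vigor_params"]["variety_offsets"] = tuple(d["vigor_params"]["variety_offsets"])
        return cls(**d)


@dataclass
class PlotLayout:
    """Plot polygons with treatment attributes (world coordinates, meters)."""

    frame: pd.DataFrame  # columns: plot_id, n_level, variety, replicate, geometry

    def __post_init__(self):
        required = {"plot_id", "n_level", "variety", "replicate", "geometry"}
        missing = required - set(self.frame.columns)
        if missing:
            raise InvalidConfigError(f"layout missing columns {sorted(missing)}")

    def __len__(self):
        return len(self.frame)

    def __iter__(self):
        return (row for _, row in self.frame.iterrows())

    def to_features(self):
        return [
            (
                row.geometry,
                {
                    "plot_id": row.plot_id,
                    "n_level": float(row.n_level),
                    "variety": row.variety,
                    "replicate": int(row.replicate),
                },
            )
            for _, row in self.frame.iterrows()
        ]

    @classmethod
    def from_features(cls, features) -> "PlotLayout":
        rows = [
            {
                "plot_id": props["plot_id"],
                "n_level": float(props["n_level"]),
                "variety": props["variety"],
                "replicate": int(props["replicate"]),
                "geometry": geom,
            }
            for geom, props in features
        ]
        return cls(pd.DataFrame(rows))


def build_design(config: SceneConfig) -> PlotLayout:
    """Lay out the split-plot design on a regular grid.

    N levels occupy full rows (primary plots); within each row the
    replicate blocks run left to right, each holding one column per variety.
    Deterministic in the config alone.
    """
    w, l = config.plot_size
    _, height = config.field_size
    rows = []
    k = 0
    for i_n, n_level in enumerate(config.n_levels):
        y_top = (
            config.margin
            + config.panel_strip
            + config.plot_spacing
            + i_n * (l + config.plot_spacing)
        )
        for rep in range(config.replicates):
            for var in range(config.varieties):
                col = rep * config.varieties + var
                x0 = config.margin + col * (w + config.plot_spacing)
                # GeoJSON-style world frame: y up, so flip from top-based offsets
                geom = box(x0, height - y_top - l, x0 + w, height - y_top)
                rows.append(
                    {
                        "plot_id": f"P{k:02d}",
                        "n_level": float(n_level),
                        "variety": f"V{var + 1}",
                        "replicate": rep + 1,
                        "geometry": geom,
                    }
                )
                k += 1
    return PlotLayout(pd.DataFrame(rows))


def panel_set(config: SceneConfig) -> PanelSet:
    """Reference panels in the calibration strip at the top of the scene."""
    _, height = config.field_size
    refls = np.asarray(config.panel_reflectances, dtype=float)
    s = config.panel_size
    y_top = config.margin + (config.panel_strip - s) / 2.0
    polys = []
    for j in range(len(refls)):
        x0 = config.margin + j * (s + 1.0)
        polys.append(box(x0, height - y_top - s, x0 + s, height - y_top))
    ids = [f"panel{j + 1}" for j in range(len(refls))]
    return PanelSet(polygons=polys, reflectances=refls, panel_ids=ids)


@dataclass
class GroundTruth:
    """Latent state of one simulated trial (what the pipeline tries to recover)."""

    plots: pd.DataFrame  # plot_id, n_level, variety, replicate, vigor, yield_kg_ha
    canopy_reflectance: pd.DataFrame  # plot_id x band: canopy endmember
    cover: pd.DataFrame  # plot_id x stage: fractional canopy cover
    elm_slopes: np.ndarray  # true a_i per band

    def plot_mean_reflectance(self, stage: str, soil_spectrum) -> pd.DataFrame:
        """Expected (noise-free) plot-mean reflectance per band at a stage."""
        c = self.cover[stage].to_numpy()[:, None]
        soil = np.asarray(soil_spectrum)[None, :]
        mix = c * self.canopy_reflectance.to_numpy() + (1 - c) * soil
        return pd.DataFrame(mix, index=self.cover.index, columns=list(BAND_NAMES))


def simulate_ground_truth(layout: PlotLayout, config: SceneConfig, seed: int) -> GroundTruth:
    """Draw per-plot latent vigor, canopy endmembers, stage covers and yields.

    Vigor rises monotonically (in expectation) with N rate via a saturating
    power law, with small variety offsets and Gaussian plot noise; yield is
    linear in vigor plus noise, floored at zero.
    """
    vp = config.vigor_params
    if vp["noise_sd"] < 0:
        raise InvalidConfigError("vigor noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n = np.asarray(layout.frame["n_level"], dtype=float)
    n_max = max(float(np.max(n)), 1.0)
    var_idx = layout.frame["variety"].str.replace("V", "").astype(int) - 1
    offsets = np.asarray(vp["variety_offsets"])[var_idx]
    vigor = (
        vp["intercept"]
        + vp["span"] * (n / n_max) ** vp["gamma"]
        + offsets
        + rng.normal(0.0, vp["noise_sd"], size=len(n))
    )
    vigor = np.clip(vigor, 0.02, 1.0)

    ym = config.yield_model
    gy = ym["intercept"] + ym["slope"] * vigor
    if ym["noise_sd"] > 0:
        gy = gy + rng.normal(0.0, ym["noise_sd"], size=len(n))
    gy = np.maximum(gy, 0.0)

    plots = layout.frame[["plot_id", "n_level", "variety", "replicate"]].copy()
    plots["vigor"] = vigor
    plots["yield_kg_ha"] = gy

    idx = pd.Index(plots["plot_id"], name="plot_id")
    canopy = pd.DataFrame(config.canopy_spectrum(vigor), index=idx, columns=list(BAND_NAMES))
    cover = pd.DataFrame(
        {stage: config.cover(stage, vigor) for stage in config.stages}, index=idx
    )
    return GroundTruth(
        plots=plots,
        canopy_reflectance=canopy,
        cover=cover,
        elm_slopes=np.asarray(config.elm_true_slopes, dtype=float),
    )


@dataclass
class StageRender:
    """One stage's rendered imagery plus its latent truth."""

    dn: BandStack
    true_mask: CanopyMask
    panels: PanelSet
    true_reflectance: BandStack | None = None


def render_scene(
    truth: GroundTruth,
    stage: str,
    config: SceneConfig,
    seed: int,
    keep_true_reflectance: bool = False,
) -> StageRender:
    """Render one growth stage to a DN band stack.

    Per-pixel canopy fraction: Bernoulli(plot cover) pixels pushed to ~0 or ~1
    with half-Gaussian sub-pixel mixing (at 1.5 cm GSD most pixels are nearly
    pure canopy or soil).  Reflectance is the linear canopy/soil mixture plus
    Gaussian noise, clipped to [0, 1]; panels overwrite their footprint with
    their exact known reflectance; DN = reflectance / a_i + DN noise, then
    (optionally) rounded into uint16.
    """
    if stage not in config.stages:
        raise StageError(stage)
    rng = np.random.default_rng(seed)
    shape = config.raster_shape
    transform = config.transform
    soil = np.asarray(config.soil_spectrum, dtype=float)

    frac = np.zeros(shape, dtype=np.float64)
    refl = np.empty((len(BAND_NAMES),) + shape, dtype=np.float64)
    for b in range(len(BAND_NAMES)):
        refl[b].fill(soil[b])

    layout = truth.plots
    covers = truth.cover[stage].to_numpy()
    canopy = truth.canopy_reflectance.to_numpy()
    geoms = _plot_geometries(truth, config)
    for i in range(len(layout)):
        inside = pixel_center_mask(transform, shape, geoms[i])
        m = int(inside.sum())
        if m == 0:
            continue
        u = rng.random(m)
        is_canopy = u < covers[i]
        if config.mixing_sd > 0:
            e = np.clip(np.abs(rng.normal(0.0, config.mixing_sd, m)), 0.0, 1.0)
        else:
            e = np.zeros(m)
        f = np.where(is_canopy, 1.0 - e, e)
        frac[inside] = f
        for b in range(len(BAND_NAMES)):
            refl[b][inside] = f * canopy[i, b] + (1.0 - f) * soil[b]

    if config.refl_noise_sd > 0:
        for b in range(len(BAND_NAMES)):
            refl[b] += rng.normal(0.0, config.refl_noise_sd, size=shape)
    np.clip(refl, 0.0, 1.0, out=refl)

    panels = panel_set(config)
    for poly, prefl in zip(panels.polygons, panels.reflectances):
        inside = pixel_center_mask(transform, shape, poly)
        for b in range(len(BAND_NAMES)):
            refl[b][inside] = prefl[b]

    slopes = np.asarray(config.elm_true_slopes, dtype=float)
    dn = np.empty((len(BAND_NAMES),) + shape, dtype=np.float64)
    for b in range(len(BAND_NAMES)):
        dn[b] = refl[b] / slopes[b]
        if config.dn_noise_sd > 0:
            dn[b] += rng.normal(0.0, config.dn_noise_sd, size=shape)
    if config.quantize_dn:
        dn = np.clip(np.rint(dn), 0, 65535).astype(np.uint16)

    dn_stack = BandStack(data=dn, units=UNITS_DN, transform=transform)
    true_mask = CanopyMask(
        mask=frac > 0.5, transform=transform, threshold=0.5, method="truth"
    )
    refl_stack = (
        BandStack(data=refl, units=UNITS_REFLECTANCE, transform=transform)
        if keep_true_reflectance
        else None
    )
    return StageRender(dn=dn_stack, true_mask=true_mask, panels=panels, true_reflectance=refl_stack)


def _plot_geometries(truth: GroundTruth, config: SceneConfig):
    # geometries live on the layout; regenerate deterministically from config
    layout = build_design(config)
    order = {pid: i for i, pid in enumerate(layout.frame["plot_id"])}
    idx = [order[pid] for pid in truth.plots["plot_id"]]
    return list(layout.frame["geometry"].iloc[idx])


@dataclass
class SceneBundle:
    """A fully simulated trial: design, latent truth, and per-stage imagery."""

    config: SceneConfig
    layout: PlotLayout
    truth: GroundTruth
    stages: dict  # stage -> StageRender


def simulate_scene(config: SceneConfig, keep_true_reflectance: bool = False) -> SceneBundle:
    """Simulate the whole trial; all randomness derives from ``config.seed``."""
    layout = build_design(config)
    truth = simulate_ground_truth(layout, config, seed=config.seed)
    stages = {
        stage: render_scene(
            truth,
            stage,
            config,
            seed=config.seed + 1000 * (k + 1),
            keep_true_reflectance=keep_true_reflectance,
        )
        for k, stage in enumerate(config.stages)
    }
    return SceneBundle(config=config, layout=layout, truth=truth, stages=stages)


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

def write_scene(bundle: SceneBundle, directory) -> dict:
    """Persist a simulated scene; returns the manifest of written paths."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    with open(out / "scene_config.json", "w") as fh:
        json.dump(bundle.config.to_dict(), fh, indent=1)
    paths["config"] = out / "scene_config.json"

    write_feature_collection(out / "layout.geojson", bundle.layout.to_features())
    paths["layout"] = out / "layout.geojson"

    first = next(iter(bundle.stages.values()))
    panels = first.panels
    write_feature_collection(
        out / "panels.geojson",
        [(p, {"panel_id": pid}) for p, pid in zip(panels.polygons, panels.panel_ids)],
    )
    paths["panels"] = out / "panels.geojson"
    panels.reflectance_frame().to_csv(out / "panel_reflectance.csv", index=False)
    paths["panel_reflectance"] = out / "panel_reflectance.csv"

    truth = bundle.truth
    truth.plots.to_csv(out / "ground_truth_plots.csv", index=False)
    truth.canopy_reflectance.to_csv(out / "ground_truth_canopy_reflectance.csv")
    truth.cover.to_csv(out / "ground_truth_cover.csv")
    pd.DataFrame({"band": BAND_NAMES, "slope": truth.elm_slopes}).to_csv(
        out / "ground_truth_elm_slopes.csv", index=False
    )

    for stage, render in bundle.stages.items():
        p = out / f"dn_{stage}.tif"
        write_band_stack(p, render.dn)
        paths[f"dn_{stage}"] = p
        mp = out / f"true_mask_{stage}.tif"
        write_single_band(
            mp,
            render.true_mask.mask.astype(np.uint8),
            render.true_mask.transform,
            meta={"method": "truth", "nodata": 255},
        )
        paths[f"true_mask_{stage}"] = mp
    return paths


def read_scene(directory) -> SceneBundle:
    """Load a scene written by :func:`write_scene`."""
    src = Path(directory)
    with open(src / "scene_config.json") as fh:
        config = SceneConfig.from_dict(json.load(fh))
    layout = PlotLayout.from_features(read_feature_collection(src / "layout.geojson"))

    panel_feats = read_feature_collection(src / "panels.geojson")
    refl_df = pd.read_csv(src / "panel_reflectance.csv")
    panels = PanelSet.from_frame([g for g, _ in panel_feats],
                                 [p["panel_id"] for _, p in panel_feats], refl_df)

    plots = pd.read_csv(src / "ground_truth_plots.csv")
    canopy = pd.read_csv(src / "ground_truth_canopy_reflectance.csv", index_col="plot_id")
    cover = pd.read_csv(src / "ground_truth_cover.csv", index_col="plot_id")
    slopes = pd.read_csv(src / "ground_truth_elm_slopes.csv")["slope"].to_numpy()
    truth = GroundTruth(plots=plots, canopy_reflectance=canopy, cover=cover, elm_slopes=slopes)

    stages = {}
    for stage in config.stages:
        dn = read_band_stack(src / f"dn_{stage}.tif")
        mask_arr, mtransform, _ = read_single_band(src / f"true_mask_{stage}.tif")
        stages[stage] = StageRender(
            dn=dn,
            true_mask=CanopyMask(
                mask=mask_arr.astype(bool), transform=mtransform, threshold=0.5, method="truth"
            ),
            panels=panels,
        )
    return SceneBundle(config=config, layout=layout, truth=truth, stages=stages)


# ---------------------------------------------------------------------------
# desk-scale trial generator for model evaluation studies
# ---------------------------------------------------------------------------

def simulate_vi_yield_trial(
    seed: int,
    population_r2: float = 0.85,
    n_levels=(0.0, 100.0, 200.0, 300.0),
    varieties: int = 3,
    replicates: int = 3,
    stage: str = "LGF",
    index_name: str = "repRVI",
    vi_by_level=(0.50, -0.38),  # intercept, slope on N/N_max
    vi_noise_sd: float = 0.03,
    yield_coef=(11500.0, -15000.0),  # intercept, slope on the VI
):
    """Plot table with a single VI exactly linear in yield at known signal-to-noise.

    The yield noise standard deviation is solved from the requested population
    R-squared given the analytic variance of the VI over the design (uniform N
    levels plus Gaussian plot noise), so the attainable test R-squared of a
    univariate linear model is known by construction.  Returns
    ``(vi_table, trait_frame, sigma_eps)`` ready for the modeling module.
    """
    if not 0 < population_r2 < 1:
        raise InvalidConfigError("population_r2 must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    levels = np.repeat(np.asarray(n_levels, dtype=float), varieties * replicates)
    n_max = max(float(np.max(levels)), 1.0)
    mu = vi_by_level[0] + vi_by_level[1] * levels / n_max
    x = mu + rng.normal(0.0, vi_noise_sd, size=len(levels))

    mu_all = vi_by_level[0] + vi_by_level[1] * np.asarray(n_levels) / n_max
    var_x = float(np.var(mu_all)) + vi_noise_sd**2
    c0, c1 = yield_coef
    sigma_eps = abs(c1) * np.sqrt(var_x) * np.sqrt((1 - population_r2) / population_r2)
    y = c0 + c1 * x + rng.normal(0.0, sigma_eps, size=len(levels))

    plot_ids = [f"P{i:02d}" for i in range(len(levels))]
    vi = pd.DataFrame(
        {
            "plot_id": plot_ids,
            "stage": stage,
            "index": index_name,
            "value": x,
            "n_pixels": 1,
        }
    )
    traits = pd.DataFrame(
        {
            "plot_id": plot_ids,
            "n_level": levels,
            "variety": [f"V{(i % (varieties * replicates)) % varieties + 1}" for i in range(len(levels))],
            "replicate": [(i % (varieties * replicates)) // varieties + 1 for i in range(len(levels))],
            "yield_kg_ha": y,
        }
    )
    return vi, traits, sigma_eps
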