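"""End-to-end orchestration: simulate -> calibrate -> mask -> extract -> traits
-> screen -> model, with every intermediate persisted and a seed/hash manifest
so a run can be reproduced or restarted from any stage."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import ElmCalibrator
from .errors import PlotspecError
from .indices import build_vi_table
from .masking import VariOtsuMasker
from .modeling import ModelSpec, repeated_evaluation
from .scene import SceneBundle, SceneConfig, read_scene, simulate_scene, write_scene
from .screening import correlation_screen, generality_score
from .traits import build_trait_table

logger = logging.getLogger(__name__)


def default_model_specs() -> list:
    """The standard demo model set: the four regression families on the
    stage-robust indices (repRVI for yield over the reproductive stages, MTCI
    and mNDblue for the NUE traits)."""
    rep_repro = ["repRVI@LF", "repRVI@IGF", "repRVI@LGF"]
    return [
        ModelSpec(family="lr", features=["repRVI@LGF"], target="yield", name="lr_yield"),
        ModelSpec(family="mlr", features=rep_repro, target="yield", name="mlr_yield"),
        ModelSpec(family="smlr", features=rep_repro, target="yield", name="smlr_yield"),
        ModelSpec(family="plsr", features=rep_repro, target="yield", name="plsr_yield"),
        ModelSpec(family="mlr", features=["MTCI@J", "MTCI@B", "MTCI@H"], target="npfp",
                  name="mlr_npfp"),
        ModelSpec(family="plsr", features=["mNDblue@LF", "mNDblue@IGF", "mNDblue@LGF"],
                  target="anue", name="plsr_anue"),
    ]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    scene: object = None  # SceneConfig, an existing scene directory, or None -> defaults
    out_dir: str = "plotspec_run"
    seed: int = 0
    inner_side: float = 0.2
    clip_max: float = 1.0
    mask_method: str = "otsu"
    mask_threshold: float | None = None
    index_names: object = "all"
    edge_buffer: float = 0.25
    pairing: str = "replicate"
    screening_traits: tuple = ("yield", "npfp", "anue")
    model_specs: list = field(default_factory=list)
    generality_weight: float = 0.5
    save_rasters: bool = True
    write_heatmaps: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("scene"), dict):
            d["scene"] = SceneConfig.from_dict(d["scene"])
        if "model_specs" in d:
            d["model_specs"] = [
                m if isinstance(m, ModelSpec) else ModelSpec(**m) for m in d["model_specs"]
            ]
        if "screening_traits" in d:
            d["screening_traits"] = tuple(d["screening_traits"])
        return cls(**d)


@dataclass
class RunReport:
    """Everything a finished (or failed) run produced."""

    config: RunConfig
    out_dir: Path
    stages_completed: list = field(default_factory=list)
    failed_stage: str | None = None
    error: str | None = None
    vi_table: pd.DataFrame | None = None
    trait_table: pd.DataFrame | None = None
    screens: dict = field(default_factory=dict)
    generality: dict = field(default_factory=dict)
    model_summaries: list = field(default_factory=list)
    mask_stats: dict = field(default_factory=dict)
    elm: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.failed_stage is None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full pipeline; on a stage failure, downstream stages are
    skipped and the report records the failure."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config, out_dir=out)
    manifest = {"plotspec_version": __version__, "seed": config.seed, "seeds": {}, "hashes": {}}
    report.manifest = manifest

    def _finish_fail(stage, exc):
        logger.exception("stage %s failed", stage)
        report.failed_stage = stage
        report.error = f"{type(exc).__name__}: {exc}"
        _write_report(report)
        return report

    # -- scene ----------------------------------------------------------
    try:
        if isinstance(config.scene, (str, Path)):
            bundle = read_scene(config.scene)
        else:
            scfg = config.scene or SceneConfig(seed=config.seed)
            if config.scene is None:
                logger.info("no scene supplied; simulating defaults with seed %d", config.seed)
            bundle = simulate_scene(scfg)
            if config.save_rasters:
                write_scene(bundle, out / "scene")
        manifest["seeds"]["scene"] = bundle.config.seed
        manifest["seeds"]["stage_render"] = {
            s: bundle.config.seed + 1000 * (k + 1) for k, s in enumerate(bundle.config.stages)
        }
        report.stages_completed.append("scene")
    except Exception as exc:
        return _finish_fail("scene", exc)

    # -- calibrate + mask ----------------------------------------------
    try:
        refl, masks = {}, {}
        for stage, render in bundle.stages.items():
            cal = ElmCalibrator(inner_side=config.inner_side, clip_max=config.clip_max)
            cal.fit_from_stack(render.dn, render.panels)
            stack = cal.transform(render.dn)
            refl[stage] = stack
            report.elm[stage] = {
                "slopes": cal.slopes_.tolist(),
                "residual_rms": cal.residual_rms_.tolist(),
                "n_panels": cal.n_panels_,
            }
            masker = VariOtsuMasker(method=config.mask_method, threshold=config.mask_threshold)
            mask = masker.fit(stack).transform(stack)
            masks[stage] = mask
            report.mask_stats[stage] = {
                "threshold": mask.threshold,
                "fraction_retained": mask.fraction_retained,
            }
        pd.DataFrame(report.elm).T.to_csv(out / "elm_coefficients.csv")
        pd.DataFrame(report.mask_stats).T.to_csv(out / "mask_stats.csv")
        report.stages_completed += ["calibrate", "mask"]
    except Exception as exc:
        return _finish_fail("calibrate/mask", exc)

    # -- extract + traits ----------------------------------------------
    try:
        vi = build_vi_table(refl, bundle.layout, masks,
                            index_names=config.index_names, edge_buffer=config.edge_buffer)
        vi.to_csv(out / "vi_table.csv", index=False)
        report.vi_table = vi
        traits = build_trait_table(
            bundle.truth.plots[["plot_id", "yield_kg_ha"]], bundle.layout, pairing=config.pairing
        )
        traits.to_csv(out / "trait_table.csv", index=False)
        report.trait_table = traits
        report.stages_completed += ["extract", "traits"]
    except Exception as exc:
        return _finish_fail("extract/traits", exc)

    # -- screening ------------------------------------------------------
    try:
        for trait in config.screening_traits:
            screen = correlation_screen(vi, traits, trait)
            report.screens[trait] = screen
            screen.r.to_csv(out / f"screen_{trait}_r.csv")
            screen.p.to_csv(out / f"screen_{trait}_p.csv")
            screen.significance.to_csv(out / f"screen_{trait}_sig.csv")
            if screen.r.shape[0] >= 2 and screen.r.shape[1] >= 2:
                scores = generality_score(screen, w=config.generality_weight)
                report.generality[trait] = scores
                scores.to_csv(out / f"generality_{trait}.csv")
            if config.write_heatmaps:
                _heatmap(screen, out / f"screen_{trait}.png")
        report.stages_completed.append("screen")
    except Exception as exc:
        return _finish_fail("screen", exc)

    # -- modeling -------------------------------------------------------
    try:
        rows = []
        for spec in config.model_specs:
            summary = repeated_evaluation(spec, vi, traits, base_seed=config.seed)
            report.model_summaries.append(summary)
            summary.per_repeat.to_csv(out / f"model_{spec.name}_repeats.csv", index=False)
            agg = summary.aggregate()
            agg.to_csv(out / f"model_{spec.name}_summary.csv")
            row = {"model": spec.name, "family": spec.family, "target": spec.target,
                   "n_repeats": summary.n_repeats, "n_failures": len(summary.failures)}
            row.update({f"{m}_{s}": agg.loc[m, s] for m in agg.index for s in ("mean", "std")})
            rows.append(row)
        if rows:
            pd.DataFrame(rows).to_csv(out / "model_overview.csv", index=False)
        manifest["seeds"]["model_base_seed"] = config.seed
        report.stages_completed.append("model")
    except Exception as exc:
        return _finish_fail("model", exc)

    for p in sorted(out.rglob("*.csv")):
        manifest["hashes"][str(p.relative_to(out))] = _sha256(p)
    _write_report(report)
    return report


def _heatmap(screen, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    data = screen.r.to_numpy(dtype=float)
    im = ax.imshow(data, cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(screen.r.shape[1]), screen.r.columns)
    ax.set_yticks(range(screen.r.shape[0]), screen.r.index)
    for i in range(screen.r.shape[0]):
        for j in range(screen.r.shape[1]):
            if np.isfinite(data[i, j]):
                ax.text(j, i, f"{data[i, j]:.2f}{screen.significance.iloc[i, j].strip('NS')}",
                        ha="center", va="center", fontsize=7)
    ax.set_title(f"Pearson r: vegetation indices vs {screen.trait}")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)


def _write_report(report: RunReport) -> None:
    out = report.out_dir
    lines = [
        "# plotspec run report", "",
        f"- plotspec version: {__version__}",
        f"- seed: {report.config.seed}",
        f"- stages completed: {', '.join(report.stages_completed) or 'none'}",
    ]
    if report.failed_stage:
        lines.append(f"- FAILED at stage `{report.failed_stage}`: {report.error}")
    if report.vi_table is not None:
        lines.append(f"- VI records: {len(report.vi_table)}")
    if report.trait_table is not None:
        n_nue = int(report.trait_table["npfp"].notna().sum())
        lines.append(f"- plots: {len(report.trait_table)} ({n_nue} with NUE traits)")
    for trait, scores in report.generality.items():
        best = scores.index[0]
        lines.append(f"- most stage-robust index for {trait}: {best} "
                     f"(score {scores['score'].iloc[0]:.2f})")
    for s in report.model_summaries:
        agg = s.aggregate()
        lines.append(
            f"- {s.spec.name}: test R2 {agg.loc['test_r2', 'mean']:.3f} "
            f"+/- {agg.loc['test_r2', 'std']:.3f}, "
            f"test RMSE {agg.loc['test_rmse', 'mean']:.1f}"
        )
    (out / "report.md").write_text("\n".join(lines) + "\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=1, default=str)
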