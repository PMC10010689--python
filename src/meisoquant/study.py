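"""Reproducible end-to-end synthetic studies.

`run_study` ties the stages together: simulate a baseline and a fragmented
group of scenes, segment every image with the same parameters, compare the
three morphometric readouts between groups, and (optionally) run a
co-localisation study and an AFM modulus-recovery study. Every run writes
its resolved configuration and seeds next to the results so a rerun with
the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import afm, coloc, stats, synthetic
from .blobs import SegmentationParams, run_pipeline
from .images import RoiMask

__all__ = ["RunConfig", "StudyResult", "run_study", "config_from_dict"]


@dataclass
class RunConfig:
    """Fully serialisable configuration of a synthetic study."""

    seed: int = 0
    n_images: int = 5
    scene: synthetic.SceneSpec = field(default_factory=synthetic.SceneSpec)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    k_fragments: int = 3
    gap_um: float = 0.15
    do_coloc: bool = False
    coloc_n_a: int = 20
    coloc_n_b: int = 24
    coloc_fraction: float = 0.3
    do_afm: bool = False
    afm_n_curves: int = 10
    hertz: synthetic.HertzCurveSpec = field(default_factory=synthetic.HertzCurveSpec)
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def config_from_dict(d: dict) -> RunConfig:
    """Build a validated RunConfig from a plain (e.g. YAML-loaded) mapping.

    Unknown keys are rejected so typos fail before any compute; nested
    sections validate through their own dataclasses. Tuple-valued fields
    arriving as lists are coerced.
    """
    d = dict(d)
    kwargs: dict = {}
    if "scene" in d:
        sc = dict(d.pop("scene"))
        for key in ("area_range_um2", "elongation_range"):
            if key in sc:
                sc[key] = tuple(sc[key])
        kwargs["scene"] = synthetic.SceneSpec(**sc)
    if "segmentation" in d:
        kwargs["segmentation"] = SegmentationParams(**d.pop("segmentation"))
    if "hertz" in d:
        kwargs["hertz"] = synthetic.HertzCurveSpec(**d.pop("hertz"))
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(d) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs.update(d)
    return RunConfig(**kwargs)


@dataclass
class StudyResult:
    """Tables and comparisons produced by one study run."""

    morphometry: pd.DataFrame
    comparisons: dict[str, stats.GroupComparison]
    coloc: coloc.ColocSummary | None
    afm_fits: pd.DataFrame | None
    config: RunConfig


def _segment_group(cfg: RunConfig, group: str) -> pd.DataFrame:
    rows = []
    for i in range(cfg.n_images):
        spec = dataclasses.replace(cfg.scene, seed=cfg.seed + 1000 * (i + 1))
        img, gt = synthetic.generate_reticulated_image(spec)
        if group == "fragmented":
            img, gt = synthetic.fragment_scene(
                gt, cfg.k_fragments, cfg.gap_um, seed=spec.seed + 1
            )
        roi = RoiMask.full(img.shape, img.pixel_size_um)
        res = run_pipeline(img, roi, cfg.segmentation)
        rows.append(
            {
                "group": group,
                "image": i,
                "seed": spec.seed,
                "n_objects": res.summary.n_objects,
                "mean_area_um2": res.summary.mean_area_um2,
                "mean_feret_um": res.summary.mean_feret_um,
                "density_per_um2": res.summary.density_per_um2,
                "n_planted": gt.n_objects,
                "threshold": res.threshold,
            }
        )
    return pd.DataFrame(rows)


def run_study(config: RunConfig, outdir: str | Path | None = None) -> StudyResult:
    """Execute the configured study; optionally write results to ``outdir``."""
    base = _segment_group(config, "baseline")
    frag = _segment_group(config, "fragmented")
    morpho = pd.concat([base, frag], ignore_index=True)

    comparisons = {}
    for metric in ("mean_area_um2", "mean_feret_um", "density_per_um2"):
        a = base[metric].to_numpy()
        b = frag[metric].to_numpy()
        if len(a) >= 3 and len(b) >= 3:
            comparisons[metric] = stats.compare_groups(a, b, config.alpha)

    coloc_res = None
    if config.do_coloc:
        per_image = []
        for i in range(config.n_images):
            la, lb, _ = synthetic.generate_coloc_pair(
                config.coloc_n_a,
                config.coloc_n_b,
                config.coloc_fraction,
                spec=config.scene,
                seed=config.seed + 5000 + i,
            )
            per_image.append(coloc.centroid_in_mask_pct(la, lb))
        coloc_res = coloc.coloc_summary(per_image)

    afm_df = None
    if config.do_afm:
        fits = []
        for i in range(config.afm_n_curves):
            spec = dataclasses.replace(config.hertz, seed=config.seed + 9000 + i)
            curve = synthetic.generate_force_curve(spec)
            fit = afm.process_curve(curve)
            fits.append(
                {
                    "curve": i,
                    "E_pa": fit.E_pa,
                    "true_E_pa": spec.E_pa,
                    "z0_nm": fit.z0_nm,
                    "rms_residual_nN": fit.rms_residual_nN,
                    "converged": fit.converged,
                }
            )
        afm_df = pd.DataFrame(fits)

    result = StudyResult(morpho, comparisons, coloc_res, afm_df, config)
    if outdir is not None:
        _write_study(result, Path(outdir))
    return result


def _write_study(result: StudyResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.json", "w") as fh:
        json.dump(result.config.to_dict(), fh, indent=2, default=str)
    result.morphometry.to_csv(outdir / "morphometry.csv", index=False)
    report = {
        name: {
            "chosen_test": cmp.selection.chosen_test,
            "statistic": cmp.statistic,
            "p_value": cmp.p_value,
            "stars": cmp.stars,
            "shapiro_p_a": cmp.selection.shapiro_p_a,
            "shapiro_p_b": cmp.selection.shapiro_p_b,
            "variance_p": cmp.selection.variance_p,
        }
        for name, cmp in result.comparisons.items()
    }
    base = result.morphometry[result.morphometry["group"] == "baseline"]
    frag = result.morphometry[result.morphometry["group"] == "fragmented"]
    report["density_percent_change"] = stats.percent_change(
        base["density_per_um2"].mean(), frag["density_per_um2"].mean()
    )
    if result.coloc is not None:
        report["coloc"] = dataclasses.asdict(result.coloc)
    with open(outdir / "comparisons.json", "w") as fh:
        json.dump(report, fh, indent=2)
    if result.afm_fits is not None:
        result.afm_fits.to_csv(outdir / "afm_fits.csv", index=False)
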