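"""End-to-end orchestration: generate -> segment -> detect -> measure ->
statistics, with counter-based sub-seeding so specimen k of a cohort is
identical regardless of cohort size, and full provenance in every report."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .config import RunConfig
from .detect import (NerveObject, ROIMeasurement, assign_and_measure, detect_candidates,
                     optimize_objects, refine_candidates, restrict_to_rois)
from .stats import ComparisonResult, run_comparison
from .synthetic import GroundTruth, generate_slide, get_profile
from .tissue import TissueMask, segment_tissue, white_exclusion_mask

logger = logging.getLogger(__name__)


def specimen_seed(base_seed: int, index: int) -> int:
    """Counter-based sub-seed: stable per (base seed, specimen index)."""
    ss = np.random.SeedSequence(entropy=[int(base_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclasses.dataclass
class SlideResult:
    measurements: list[ROIMeasurement]
    objects: list[NerveObject]
    tissue: TissueMask

    def measurement_rows(self, specimen_id: str) -> list[dict]:
        return [
            {"specimen_id": specimen_id, "roi": m.roi, "count": m.count,
             "object_area_px2": m.object_area_px2, "other_tissue_area_px2": m.other_tissue_area_px2}
            for m in self.measurements
        ]


def measure_slide(slide: nio.Slide, annotation: nio.ROIAnnotation, config: RunConfig | None = None) -> SlideResult:
    """Run the full measurement pipeline on one slide."""
    config = config or RunConfig()
    t, d = config.tissue, config.detection
    tissue = segment_tissue(
        slide.pixels,
        downscale_factor=t.downscale_factor,
        homogeneity_sd=t.homogeneity_sd,
        min_block_side=t.min_block_side,
        enclosed_max_fraction=t.enclosed_max_fraction,
        grow_iterations=t.grow_iterations,
        grow_radius=t.grow_radius,
    )
    roi_masks = restrict_to_rois(tissue.full, annotation)
    processing = np.zeros(slide.shape, bool)
    for m in roi_masks.values():
        processing |= m
    candidates = detect_candidates(slide.pixels, processing, d.blue_threshold, d.min_class_separation)
    refined = refine_candidates(slide.pixels, candidates, tissue.full, d.expand_radius, d.rb_diff_threshold)
    objects = optimize_objects(refined, slide.pixels, tissue.full, d.min_size, d.max_size,
                               d.close_radius, d.open_radius, d.merge_gap)
    exclusion = white_exclusion_mask(slide.pixels, tissue.full, t.white_cutoff)
    measurements = assign_and_measure(objects, annotation, tissue.full, exclusion)
    return SlideResult(measurements=measurements, objects=objects, tissue=tissue)


def objects_to_frame(objects: list[NerveObject]) -> pd.DataFrame:
    rows = [
        {"object_id": i, "roi": o.roi, "centroid_row": o.centroid[0],
         "centroid_col": o.centroid[1], "area_px2": o.area, "mean_rb": o.mean_rb}
        for i, o in enumerate(objects)
    ]
    return pd.DataFrame(rows, columns=["object_id", "roi", "centroid_row", "centroid_col",
                                       "area_px2", "mean_rb"])


def overlay_objects(slide: nio.Slide, objects: list[NerveObject]) -> np.ndarray:
    """Paint detected objects red over the slide, for visual inspection."""
    out = slide.pixels.copy()
    for o in objects:
        out[o.pixels[:, 0], o.pixels[:, 1]] = (255, 0, 0)
    return out


@dataclasses.dataclass
class ExperimentReport:
    cohort: pd.DataFrame
    truth: pd.DataFrame
    raw_result: ComparisonResult | None
    normalized_result: ComparisonResult | None
    config: RunConfig
    seed: int
    specimen_seeds: list[int]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "specimen_seeds": self.specimen_seeds,
            "config": self.config.to_dict(),
            "raw_comparison": self.raw_result.to_dict() if self.raw_result else None,
            "normalized_comparison": self.normalized_result.to_dict() if self.normalized_result else None,
            "cohort": self.cohort.to_dict(orient="records"),
            "ground_truth_counts": self.truth.to_dict(orient="records"),
        }


def run_experiment(
    config: RunConfig | None = None,
    n_specimens: int = 10,
    seed: int = 0,
    outdir: str | Path | None = None,
    save_overlays: bool = False,
) -> ExperimentReport:
    """Simulate a cohort of specimens, measure every slide, and run the raw
    and ROI-I-normalized group comparisons.

    Fully reproducible per seed; any stage failure aborts with the specimen
    index in the exception chain.
    """
    config = config or RunConfig()
    profile = get_profile(config.simulation.profile)
    rows, truth_rows, sub_seeds = [], [], []
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    for k in range(n_specimens):
        sub = specimen_seed(seed, k)
        sub_seeds.append(sub)
        sid = f"S{k + 1:03d}"
        try:
            slide, annotation, truth = generate_slide(
                profile, config.simulation.width, config.simulation.height, sub, specimen_id=sid
            )
            result = measure_slide(slide, annotation, config)
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(f"pipeline failed at specimen {sid} (seed {sub})") from exc
        rows.extend(result.measurement_rows(sid))
        truth_rows.extend(
            {"specimen_id": sid, "roi": roi, "count": truth.count(roi)} for roi in nio.ROI_LABELS
        )
        if outdir is not None and save_overlays:
            nio.write_mask_png(result.tissue.full, outdir / f"{sid}_tissue.png")
            nio.write_slide(nio.Slide(overlay_objects(slide, result.objects), slide.metadata),
                            outdir / f"{sid}_overlay.png", sidecar=False)
    cohort = pd.DataFrame(rows, columns=list(nio.COHORT_COLUMNS))
    truth_table = pd.DataFrame(truth_rows)
    if n_specimens >= 4:  # the normality gate needs at least 4 values per group
        raw = run_comparison(cohort, normalize=False, alpha=config.stats.alpha,
                             adjust=config.stats.adjust)
        normalized = run_comparison(cohort, normalize=True, reference=config.stats.reference_roi,
                                    alpha=config.stats.alpha, adjust=config.stats.adjust)
    else:
        logger.warning("cohort of %d specimens too small for group statistics; skipping",
                       n_specimens)
        raw = normalized = None
    report = ExperimentReport(cohort=cohort, truth=truth_table, raw_result=raw,
                              normalized_result=normalized, config=config, seed=seed,
                              specimen_seeds=sub_seeds)
    if outdir is not None:
        nio.write_cohort_table(cohort, outdir / "cohort.csv")
        truth_table.to_csv(outdir / "ground_truth.csv", index=False)
        (outdir / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
        config.dump(outdir / "config.toml")
    return report
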