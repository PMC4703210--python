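"""End-to-end glue: analyze images to per-stain tables, score cohorts.

These functions tie the modules together the way a screening run does:
render or load sheets, detect stains, compute indices, match against ground
truth, fit cutoffs and report screening metrics.  They are used both by the
command-line interface and by the validation/acceptance checks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classify as _classify
from . import evaluate as _evaluate
from .errors import DomainError
from .genotypes import Genotype
from .imaging import (
    DetectionConfig,
    IntensityMap,
    StainImage,
    compute_indices,
    detect_stains,
    to_intensity,
)
from .synthetic import (
    CohortSpec,
    GroundTruthRecord,
    SheetLayout,
    draw_cohort_params,
    generate_sheet,
)

RESULT_COLUMNS = [
    "source_id",
    "stain_id",
    "center_x_px",
    "center_y_px",
    "r_center_mm",
    "r_outer_mm",
    "s_index",
    "c_index",
]


def analyze_image(
    image: StainImage, config: DetectionConfig = DetectionConfig()
) -> pd.DataFrame:
    """Detect all stains in one image and compute both indices per stain.

    Returns one row per detected stain with the columns of
    ``RESULT_COLUMNS``; stains are numbered row-major within the image.
    """
    intensity = to_intensity(image)
    geometries = detect_stains(intensity, config)
    rows = []
    for i, geom in enumerate(geometries):
        idx = compute_indices(intensity, geom)
        rows.append(
            {
                "source_id": image.source_id,
                "stain_id": f"{image.source_id}:{i:03d}",
                "center_x_px": geom.center_xy[0],
                "center_y_px": geom.center_xy[1],
                "r_center_mm": geom.r_center,
                "r_outer_mm": geom.r_outer,
                "s_index": idx.s_index,
                "c_index": idx.c_index,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def analyze_images(
    images: list[StainImage], config: DetectionConfig = DetectionConfig()
) -> pd.DataFrame:
    """Analyze several images into one concatenated per-stain table."""
    frames = [analyze_image(img, config) for img in images]
    if not frames:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def truth_to_frame(records: list[GroundTruthRecord]) -> pd.DataFrame:
    """Ground-truth records as the canonical truth CSV table."""
    return pd.DataFrame(
        [
            {
                "stain_id": r.stain_id,
                "genotype": str(r.genotype_label) if r.genotype_label else "",
                "percent_hbs": r.percent_hbs,
                "hb_conc": r.hb_conc,
                "center_x_px": r.center_xy[0],
                "center_y_px": r.center_xy[1],
                "seed": r.params.seed,
            }
            for r in records
        ],
        columns=[
            "stain_id",
            "genotype",
            "percent_hbs",
            "hb_conc",
            "center_x_px",
            "center_y_px",
            "seed",
        ],
    )


def match_to_truth(
    results: pd.DataFrame, truth: pd.DataFrame, max_dist_px: float = 5.0
) -> pd.DataFrame:
    """Greedy nearest-center match of detected stains to ground truth.

    Joins detections to truth rows whose centers lie within ``max_dist_px``;
    each truth row is used at most once.  Unmatched detections are dropped.
    """
    if results.empty or truth.empty:
        return pd.DataFrame()
    det = results.reset_index(drop=True)
    tru = truth.reset_index(drop=True)
    d = np.hypot(
        det["center_x_px"].to_numpy()[:, None] - tru["center_x_px"].to_numpy()[None, :],
        det["center_y_px"].to_numpy()[:, None] - tru["center_y_px"].to_numpy()[None, :],
    )
    taken: set[int] = set()
    rows = []
    for i in range(len(det)):
        j = int(np.argmin(d[i]))
        if d[i, j] <= max_dist_px and j not in taken:
            taken.add(j)
            row = det.iloc[i].to_dict()
            row.update(
                {
                    "truth_id": tru.at[j, "stain_id"],
                    "genotype": tru.at[j, "genotype"],
                    "percent_hbs": tru.at[j, "percent_hbs"],
                    "hb_conc": tru.at[j, "hb_conc"],
                    "center_err_px": float(d[i, j]),
                }
            )
            rows.append(row)
    return pd.DataFrame(rows)


def pack_cohort_sheets(
    spec: CohortSpec, seed: int, layout: SheetLayout | None = None
) -> tuple[list[StainImage], list[GroundTruthRecord]]:
    """Draw a cohort and render it onto as few sheets as fit the layout."""
    params, labels = draw_cohort_params(spec, seed)
    layout = layout or SheetLayout(rows=7, cols=8)
    per_sheet = layout.rows * layout.cols
    images: list[StainImage] = []
    records: list[GroundTruthRecord] = []
    for k, start in enumerate(range(0, len(params), per_sheet)):
        chunk = params[start : start + per_sheet]
        chunk_labels = list(labels[start : start + per_sheet])
        img, recs = generate_sheet(
            chunk,
            layout,
            seed=seed + 1 + k,
            genotype_labels=chunk_labels,
            source_id=f"sheet_{k:02d}",
        )
        images.append(img)
        records.extend(recs)
    return images, records


@dataclass(frozen=True)
class RoundTripResult:
    """Summary of a simulate-analyze-classify round trip on one cohort."""

    matched: pd.DataFrame
    n_truth: int
    detection_rate: float
    max_center_err_px: float
    thresholds: _classify.Thresholds
    any_s: _evaluate.BinaryMetrics
    ss_vs_rest: _evaluate.BinaryMetrics
    auc_aa_vs_rest: float
    auc_ss_vs_rest: float
    auc_as_vs_ss: float
    n_correct: int


def cohort_round_trip(
    seed: int,
    spec: CohortSpec | None = None,
    noise_sd: float = 0.0,
    config: DetectionConfig = DetectionConfig(),
    ci_convention: _evaluate.CIConvention = "total_n",
) -> RoundTripResult:
    """Simulate a cohort on sheets, analyze, fit thresholds, classify, score.

    Thresholds are fitted on the analyzed S-indices against ground-truth
    genotypes and applied back to the same data (resubstitution), mirroring
    how a validation study reports its operating point.
    """
    spec = spec or CohortSpec()
    spec = dataclasses.replace(
        spec, template=dataclasses.replace(spec.template, noise_sd=noise_sd)
    )
    images, records = pack_cohort_sheets(spec, seed)
    results = analyze_images(images, config)
    truth = truth_to_frame(records)
    matched = match_to_truth(results, truth)
    if matched.empty:
        raise DomainError("no detected stain matched the ground truth")

    detection_rate = len(matched) / len(truth)
    max_err = float(matched["center_err_px"].max())
    scores = matched["s_index"].to_numpy()
    genos = [Genotype(g) for g in matched["genotype"]]
    thresholds = _classify.fit_thresholds(scores, genos)
    calls = [_classify.classify_s_index(s, thresholds).label for s in scores]
    cm = _evaluate.confusion_matrix(
        [str(g) for g in genos], [str(c) for c in calls], ("AA", "AS", "SS")
    )
    any_s = _evaluate.binary_metrics(
        _evaluate.binarize(cm, {"AS", "SS"}), ci_convention=ci_convention
    )
    ss_vs_rest = _evaluate.binary_metrics(
        _evaluate.binarize(cm, {"SS"}), ci_convention=ci_convention
    )
    y_any = np.array([g is not Genotype.AA for g in genos])
    y_ss = np.array([g is Genotype.SS for g in genos])
    as_ss = np.array([g in (Genotype.AS, Genotype.SS) for g in genos])
    return RoundTripResult(
        matched=matched,
        n_truth=len(truth),
        detection_rate=detection_rate,
        max_center_err_px=max_err,
        thresholds=thresholds,
        any_s=any_s,
        ss_vs_rest=ss_vs_rest,
        auc_aa_vs_rest=_evaluate.roc_auc(scores, y_any).auc,
        auc_ss_vs_rest=_evaluate.roc_auc(scores, y_ss).auc,
        auc_as_vs_ss=_evaluate.roc_auc(scores[as_ss], y_ss[as_ss]).auc,
        n_correct=int(sum(c is g for c, g in zip(calls, genos))),
    )


__all__ = [
    "RESULT_COLUMNS",
    "analyze_image",
    "analyze_images",
    "truth_to_frame",
    "match_to_truth",
    "pack_cohort_sheets",
    "RoundTripResult",
    "cohort_round_trip",
]
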