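"""End-to-end orchestration: synthetic cohort -> normative atlas ->
feature maps -> variable-size superpixels -> 68 features -> LogitBoost CV
-> ROC evaluation against the circumpapillary (cpRNFL) baseline.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import atlas as atl
from . import featuremap as fmap
from . import features as feat
from . import superpixel as spx
from .boost import cross_validate
from .grid import GridSpec, sample_map
from .roc import auc_compare, roc_auc, sensitivity_at_specificity
from .synthetic import SyntheticEye, generate_cohort, generate_eye, EyePhenotype

log = logging.getLogger("octsp")

QUADRANTS = ("temporal", "superior", "nasal", "inferior")
TASKS = {
    # healthy (label 0) vs disease group(s) (label 1)
    "HvGS": ("healthy", ("suspect",)),
    "HvG": ("healthy", ("glaucoma",)),
    "HvGGS": ("healthy", ("suspect", "glaucoma")),
}


def cp_rnfl_baseline(
    thickness_map: np.ndarray, grid: GridSpec, n_points: int = 256
) -> dict[str, float]:
    """Conventional circumpapillary measurement on the 3.4 mm circle.

    Returns the overall mean and the four 90-deg quadrant means (temporal
    centred at 0 deg, superior at 90, nasal at 180, inferior at 270).
    """
    r_px = grid.mm_to_px(feat.CP_CIRCLE_DIAMETER_MM / 2.0)
    cy, cx = grid.center
    if min(cy, cx, grid.n - 1 - cy, grid.n - 1 - cx) < r_px:
        raise ValueError("3.4 mm circle exits the scan grid")
    angles = np.arange(n_points) * (360.0 / n_points)
    rows, cols = grid.circle_points(r_px, angles)
    prof = sample_map(thickness_map, rows, cols)
    out = {"mean": float(prof.mean())}
    # half-open 90-deg bins so boundary angles belong to exactly one quadrant
    q_idx = (((angles + 45.0) % 360.0) // 90.0).astype(int)
    for i, q in enumerate(QUADRANTS):
        out[q] = float(prof[q_idx == i].mean())
    return out


@dataclass
class PipelineConfig:
    n_per_group: tuple[int, int, int] = (44, 59, 89)
    n_normative: int = 46
    grid_n: int = 200
    seed: int = 0
    n_folds: int = 10
    boost_iter: int = 100
    shrinkage: float = 0.1
    w_r: float = fmap.DEFAULT_W_R
    tasks: tuple[str, ...] = ("HvGS", "HvG", "HvGGS")
    spec_target: float = 0.85
    cohort_config: dict | None = None


def process_eye(
    eye: SyntheticEye,
    atlas: atl.NormativeAtlas,
    params: spx.SegmentationParams,
    th: feat.SizeThresholds,
    w_r: float = fmap.DEFAULT_W_R,
) -> dict:
    """Single-eye flow: inpaint -> normalize -> deviate -> compose ->
    segment -> refine -> features + cpRNFL baseline."""
    grid = eye.maps.grid
    t0 = time.perf_counter()
    inpainted = fmap.inpaint_vessels(
        eye.maps.thickness, eye.maps.vessel_mask, eye.maps.disc_mask
    )
    paths = atl.detect_bundle_paths(inpainted, grid, atlas.reference_paths.radii_px)
    normed = atl.normalize_map(inpainted, paths, atlas.reference_paths, grid)
    refl = atl.normalize_map(
        eye.maps.reflectivity, paths, atlas.reference_paths, grid
    )
    dev = atl.deviation_map(normed, atlas)
    ref_t = atlas.mean_map[~eye.maps.disc_mask]
    fm = fmap.compose_feature_map(
        normed, refl, dev.deficit, eye.maps.disc_mask, grid, w_r,
        reference_stats=(float(ref_t.mean()), float(ref_t.std()), float(ref_t.max())),
    )
    spm = spx.segment_feature_map(fm, params)
    vec = feat.extract_all(spm, normed, eye.maps.disc_mask, th)
    cp = cp_rnfl_baseline(inpainted, grid)
    log.info(
        "eye group=%s segments=%d t=%.2fs",
        eye.truth.group,
        spm.n_segments,
        time.perf_counter() - t0,
    )
    return {
        "features": vec,
        "cp": cp,
        "n_segments": spm.n_segments,
        "superpixel_map": spm,
        "feature_map": fm,
    }


def build_normative_atlas_from_eyes(eyes: list[SyntheticEye]) -> atl.NormativeAtlas:
    grid = eyes[0].maps.grid
    maps = [
        fmap.inpaint_vessels(e.maps.thickness, e.maps.vessel_mask, e.maps.disc_mask)
        for e in eyes
    ]
    atlas, _ = atl.build_atlas_from_cohort(maps, grid)
    return atlas


def evaluate_task(
    scores: np.ndarray,
    cp_means: np.ndarray,
    cp_quadrants: np.ndarray,
    y: np.ndarray,
    spec_target: float = 0.85,
) -> dict:
    """ROC summary for the machine classifier and the cpRNFL baseline."""
    r_sp = roc_auc(scores, y)
    r_cp = roc_auc(-cp_means, y)  # thin RNFL -> disease
    quad = {
        q: roc_auc(-cp_quadrants[:, i], y).auc for i, q in enumerate(QUADRANTS)
    }
    best_q = max(quad, key=quad.get)
    cmp_mean = auc_compare(scores, -cp_means, y)
    return {
        "auc_superpixel": r_sp.auc,
        "se_superpixel": float(np.sqrt(r_sp.variance)),
        "sens85_superpixel": sensitivity_at_specificity(r_sp, spec_target),
        "auc_cp_mean": r_cp.auc,
        "sens85_cp_mean": sensitivity_at_specificity(r_cp, spec_target),
        "auc_cp_quadrants": quad,
        "auc_cp_best_quadrant": quad[best_q],
        "best_quadrant": best_q,
        "delong_p_vs_cp_mean": cmp_mean.p_value,
        "auc_difference": cmp_mean.difference,
        "ci95": cmp_mean.ci95,
        "n": int(len(y)),
    }


def run_pipeline(config: PipelineConfig | None = None, outdir=None) -> dict:
    """Full study on a synthetic cohort; returns the evaluation report."""
    cfg = config or PipelineConfig()
    grid = GridSpec.for_size(cfg.grid_n)
    params = spx.SegmentationParams.for_grid(cfg.grid_n, seed=cfg.seed)
    th = feat.SizeThresholds.for_grid(cfg.grid_n)
    rng = np.random.default_rng(cfg.seed)

    log.info("generating normative cohort (n=%d)", cfg.n_normative)
    from .synthetic import sample_phenotype

    norm_rng = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
    normative = [
        generate_eye(
            sample_phenotype("healthy", norm_rng, cfg.cohort_config),
            grid,
            rng_seed=int(norm_rng.integers(0, 2**31 - 1)),
        )
        for _ in range(cfg.n_normative)
    ]
    atlas = build_normative_atlas_from_eyes(normative)

    log.info("generating study cohort %s", cfg.n_per_group)
    cohort = generate_cohort(
        cfg.n_per_group, grid, cfg.cohort_config,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )

    X, groups, cp_means, cp_quads, n_segs = [], [], [], [], []
    for eye in cohort:
        res = process_eye(eye, atlas, params, th, cfg.w_r)
        X.append(res["features"])
        groups.append(eye.truth.group)
        cp_means.append(res["cp"]["mean"])
        cp_quads.append([res["cp"][q] for q in QUADRANTS])
        n_segs.append(res["n_segments"])
    X = np.asarray(X)
    groups = np.asarray(groups)
    cp_means = np.asarray(cp_means)
    cp_quads = np.asarray(cp_quads)

    report = {
        "config": {**asdict(cfg), "n_per_group": list(cfg.n_per_group),
                   "tasks": list(cfg.tasks)},
        "n_eyes": int(len(cohort)),
        "mean_segments_per_group": {
            g: float(np.mean([s for s, gg in zip(n_segs, groups) if gg == g]))
            for g in ("healthy", "suspect", "glaucoma")
        },
        "tasks": {},
    }
    for task in cfg.tasks:
        neg, pos = TASKS[task]
        sel = (groups == neg) | np.isin(groups, pos)
        y = np.isin(groups[sel], pos).astype(int)
        scores = cross_validate(
            X[sel], y, cfg.n_folds, cfg.boost_iter, cfg.shrinkage, seed=cfg.seed
        )
        report["tasks"][task] = evaluate_task(
            scores, cp_means[sel], cp_quads[sel], y, cfg.spec_target
        )

    if outdir is not None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(X, columns=feat.FEATURE_NAMES)
        df.insert(0, "group", groups)
        df.insert(0, "eye_id", [f"eye{i:04d}" for i in range(len(cohort))])
        df.to_csv(out / "features.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
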