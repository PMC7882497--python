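"""End-to-end orchestration: subject-level morphometry and cohort-level
statistics as single reproducible runs with machine-readable reports.

Everything that affects outputs lives in the config, which is echoed
verbatim into the report; reports carry a ``report_version`` so their
schema can be pinned.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import accessory, csf, imaging, optic_nerve, stats

log = logging.getLogger(__name__)

REPORT_VERSION = 1

CLUSTER_FEATURES = ["fsas_mean_mm", "ihf_mean_mm", "on_width_mm",
                    "on_length_mm", "on_tortuosity_index"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def dump_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_jsonable, sort_keys=True))


# ---------------------------------------------------------------------------
# Subject-level run


def analyze_subject(
    image: imaging.VoxelVolume,
    csf_mask: imaging.VoxelVolume,
    total_mask: imaging.VoxelVolume,
    roi_frontal: np.ndarray,
    roi_ihf: np.ndarray,
    roi_on_left: np.ndarray | None = None,
    roi_on_right: np.ndarray | None = None,
    vessel_mask: imaging.VoxelVolume | None = None,
    lv_mask: imaging.VoxelVolume | None = None,
    meckel_seeds=None,
    depth_threshold_mm: float = csf.DEFAULT_DEPTH_THRESHOLD_MM,
    on_intensity_low: float | None = None,
    on_intensity_high: float | None = None,
    region_grow_tolerance: float = 20.0,
) -> dict:
    """Run the full subject-level morphometry battery on in-memory volumes.

    Stages: vessel subtraction -> CSF EDT -> skeletonization -> SAS/sulcal
    subdivision at the depth threshold -> regional width statistics ->
    optic-nerve segmentation and metrics -> accessory volumetry.
    """
    results: dict = {"report_version": REPORT_VERSION, "parameters": {
        "depth_threshold_mm": depth_threshold_mm,
        "on_intensity_low": on_intensity_low,
        "on_intensity_high": on_intensity_high,
        "region_grow_tolerance": region_grow_tolerance,
        "width_statistic": "skeleton-voxel mean/max of 2*(edt - spacing/2)",
        "on_width_statistic": "mean caliber along trimmed centerline",
    }}

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

    working_csf = csf_mask
    if vessel_mask is not None:
        working_csf = _stage("subtract_vessels", csf.subtract_vessels,
                             csf_mask, vessel_mask)
    csf_edt = _stage("edt", imaging.edt, working_csf)
    skeleton = _stage("skeletonize", imaging.skeletonize, working_csf)
    outer = _stage("outer_surface_distance", imaging.outer_surface_distance,
                   total_mask)
    sas_sk, sulcal_sk = _stage("subdivide_skeleton", csf.subdivide_skeleton,
                               skeleton, outer, depth_threshold_mm)
    sas_sk = _stage("width_map", csf.width_map, sas_sk, csf_edt)
    if len(sulcal_sk):
        sulcal_sk = _stage("width_map", csf.width_map, sulcal_sk, csf_edt)
    for region, roi in (("frontal_sas", roi_frontal), ("ihf", roi_ihf)):
        st = _stage("region_width_stats", csf.region_width_stats,
                    sas_sk if region == "frontal_sas" else _combined(sas_sk, sulcal_sk),
                    roi, region)
        results[region] = asdict(st)
    results["skeleton_voxels"] = {"sas": len(sas_sk), "sulcal": len(sulcal_sk)}

    on_results = {}
    for side, roi in (("left", roi_on_left), ("right", roi_on_right)):
        if roi is None:
            continue
        mask = _stage("segment_on", optic_nerve.segment_on, image, roi,
                      on_intensity_low, on_intensity_high)
        on_results[side] = _stage("on_metrics", optic_nerve.on_metrics, mask, side)
    if on_results:
        both = _stage("bilateral_average", optic_nerve.bilateral_average,
                      on_results.get("left"), on_results.get("right"))
        results["optic_nerve"] = {
            **{s: asdict(m) for s, m in on_results.items()},
            "mean": asdict(both),
        }

    if lv_mask is not None:
        ant, post = _stage("split_lv", accessory.split_lv, lv_mask)
        results["lateral_ventricle"] = {
            "anterior_mm3": ant, "posterior_mm3": post, "total_mm3": ant + post,
        }
    if meckel_seeds is not None:
        grown = _stage("region_grow", accessory.region_grow, image,
                       meckel_seeds, region_grow_tolerance)
        results["meckel_volume_mm3"] = accessory.mask_volume(grown)
    return results


def _combined(sas_sk, sulcal_sk):
    """IHF widths are read from the whole CSF skeleton: the fissure spans
    shallow and deep voxels."""
    if len(sulcal_sk) == 0:
        return sas_sk
    import numpy as _np
    from .imaging import Skeleton
    return Skeleton(
        _np.vstack([sas_sk.coords, sulcal_sk.coords]),
        sas_sk.spacing_mm, sas_sk.shape,
        width_mm=_np.concatenate([sas_sk.width_mm, sulcal_sk.width_mm]),
    )


def run_subject(config: dict, out_path: str | Path | None = None) -> dict:
    """File-based subject run: config maps stage inputs to NIfTI paths."""
    required = ["image", "csf", "total", "roi_frontal", "roi_ihf"]
    for key in required:
        if key not in config:
            raise PipelineError("config", f"missing required input {key!r}")
    vols = {k: imaging.read_volume(config[k]) for k in required if k in config}
    opt = {k: imaging.read_volume(config[k])
           for k in ("vessels", "lv", "roi_on_left", "roi_on_right")
           if k in config}
    report = analyze_subject(
        image=vols["image"],
        csf_mask=vols["csf"].astype_mask(),
        total_mask=vols["total"].astype_mask(),
        roi_frontal=vols["roi_frontal"].values,
        roi_ihf=vols["roi_ihf"].values,
        roi_on_left=opt["roi_on_left"].values if "roi_on_left" in opt else None,
        roi_on_right=opt["roi_on_right"].values if "roi_on_right" in opt else None,
        vessel_mask=opt.get("vessels"),
        lv_mask=opt.get("lv"),
        meckel_seeds=config.get("meckel_seeds"),
        depth_threshold_mm=config.get("depth_threshold_mm",
                                      csf.DEFAULT_DEPTH_THRESHOLD_MM),
        on_intensity_low=config.get("on_intensity_low"),
        on_intensity_high=config.get("on_intensity_high"),
        region_grow_tolerance=config.get("region_grow_tolerance", 20.0),
    )
    report["config"] = {k: str(v) for k, v in config.items()}
    if out_path is not None:
        dump_report(report, out_path)
    return report


# ---------------------------------------------------------------------------
# Cohort-level run


def run_cohort(cohort: pd.DataFrame, normative: stats.NormativeTable,
               max_k: int = 4) -> tuple[dict, pd.DataFrame]:
    """Cohort statistics battery on a subject table.

    Adds the derived columns (tortuosity index, Z-scores, enlargement
    flags, abnormality score, quantified group, cluster label), then runs
    group comparisons, diagnostic ROC models, the logistic odds ratio for
    complications, and two-step clustering with risk stratification.
    Returns (results dict, augmented table).
    """
    df = cohort.copy()
    df["on_tortuosity_index"] = optic_nerve.tortuosity_index(
        df["on_tortuosity_ratio"].to_numpy())
    df = stats.zscore_classify(df, normative)
    df = stats.abnormality_score(df)

    results: dict = {"report_version": REPORT_VERSION,
                     "n_subjects": int(len(df)),
                     "parameters": {"z_threshold": stats.Z_THRESHOLD,
                                    "max_k": max_k,
                                    "cluster_features": CLUSTER_FEATURES,
                                    "tortuosity_index_cohort_n": int(len(df))}}

    enlarged = df["quantified_group"] == "enlarged"
    results["group_sizes"] = {"enlarged": int(enlarged.sum()),
                              "normal": int((~enlarged).sum())}
    comparisons = {}
    if 0 < enlarged.sum() < len(df):
        for var in ("on_width_mm", "on_length_mm", "on_tortuosity_index"):
            stat, p = stats.compare_groups(df.loc[enlarged, var],
                                           df.loc[~enlarged, var],
                                           method="mannwhitney")
            comparisons[var] = {
                "enlarged_mean": float(df.loc[enlarged, var].mean()),
                "normal_mean": float(df.loc[~enlarged, var].mean()),
                "statistic": stat, "pvalue": p, "method": "mannwhitney",
            }
        results["group_comparisons"] = comparisons

        roc = {}
        for target, feats in (
            ("enlarged_fsas", ["on_width_mm", "on_length_mm", "on_tortuosity_index"]),
            ("enlarged_ihf", ["on_width_mm", "on_tortuosity_index"]),
        ):
            y = df[target].to_numpy()
            if 0 < y.sum() < len(y):
                try:
                    scores = stats.logistic_scores(df, feats, y)
                    auc, p = stats.roc_auc(scores, y)
                    roc[target] = {"features": feats, "auc": auc, "pvalue": p}
                except ValueError as exc:
                    roc[target] = {"features": feats, "skipped": str(exc)}
        results["roc"] = roc

        try:
            orres = stats.logistic_or(df["complication"], enlarged.astype(int))
            results["enlargement_odds_ratio"] = asdict(orres)
        except ValueError as exc:
            results["enlargement_odds_ratio"] = {"skipped": str(exc)}
    else:
        results["group_comparisons"] = {
            "skipped": "only one quantified group present"}
        log.warning("cohort has a single quantified group; comparisons skipped")

    cl = stats.twostep_cluster(df, CLUSTER_FEATURES, max_k=max_k)
    df["cluster_label"] = cl.labels
    results["cluster"] = {"n_clusters": cl.n_clusters,
                          "bic_by_k": {str(k): float(v) for k, v in cl.bic_by_k.items()},
                          "sizes": {str(k): int(v) for k, v in
                                    pd.Series(cl.labels).value_counts().items()}}
    strat = stats.risk_stratify(df, cl.labels, "complication",
                                features=CLUSTER_FEATURES)
    if strat.table is not None:
        results["risk_stratification"] = {
            "high_risk_cluster": strat.high_risk_cluster,
            "table": asdict(strat.table),
            "risk_ratio": asdict(strat.rr),
            "feature_pvalues": strat.feature_pvalues,
        }
    else:
        results["risk_stratification"] = {"skipped": strat.message}
    return results, df
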