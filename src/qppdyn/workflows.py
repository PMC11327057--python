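"""The two study-shaped pipelines: within-scan drift and cross-condition contrast.

Workflow A ("within_scan", the drowsiness analogue): preprocess every
subject, concatenate along time, decompose with complex PCA + varimax,
assign per-timepoint states, summarize incidence and first/last-segment
magnitudes, test last-vs-first per component, and cluster subjects on
magnitude mean/SD features.

Workflow B ("condition_contrast", the anesthesia analogue): preprocess each
subject x condition recording, concatenate everything so all conditions
share one pattern definition, decompose, split scores back per cell, build
the subject x condition x component summary, and run repeated-measures
ANOVA plus Bonferroni-corrected paired tests between two named conditions.

Concatenation happens after per-dataset standardization, and the analytic
signal is computed per dataset before stacking so the frequency-domain
Hilbert construction never wraps across recording boundaries.
"""

from __future__ import annotations

import logging
import time
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .cpca import (
    AnalyticDataset,
    CpcaResult,
    analytic_signal,
    complex_pca,
    component_magnitude_phase,
    select_elbow,
    varimax_complex,
)
from .io import RunConfig, read_bold, write_outputs
from .preprocess import (
    BoldDataset,
    get_projection_basis,
    project_and_filter,
    spatial_smooth,
    zscore_timecourses,
)
from .states import (
    assign_dominant_state,
    condition_summary,
    incidence_table,
    paired_segment_differences,
    segment_magnitude_summary,
)
from .stats import bonferroni, kmeans_cluster, paired_ttest, rm_anova, subject_features
from .synthetic import GroundTruth

__all__ = [
    "preprocess_dataset",
    "concatenate_analytic",
    "decompose",
    "split_rows",
    "match_components",
    "run_within_scan",
    "run_condition_contrast",
    "run_workflow",
]

log = logging.getLogger("qppdyn")


def preprocess_dataset(
    dataset: BoldDataset,
    passband: tuple[float, float] = (0.01, 0.1),
    polort: int = 2,
    motion: np.ndarray | None = None,
    smooth_fwhm: float = 0.0,
    geometry: Sequence[int] | None = None,
    standardize: bool = True,
) -> BoldDataset:
    """One-step nuisance regression + bandpass, optional smoothing, z-scoring."""
    out = dataset
    if smooth_fwhm > 0:
        out = spatial_smooth(out, smooth_fwhm, geometry)
    basis = get_projection_basis(
        out.n_timepoints, out.tr, passband, polort=polort, motion=motion
    )
    out = project_and_filter(out, basis)
    if standardize:
        out = zscore_timecourses(out)
    return out


def concatenate_analytic(
    datasets: Sequence[BoldDataset], per_dataset_analytic: bool = True
) -> AnalyticDataset:
    """Stack datasets along time in the complex analytic domain.

    The analytic signal is computed per dataset (default) so Hilbert
    edge effects never leak across recording boundaries; ``boundaries``
    records the cumulative row splits for mapping scores back.
    """
    if len(datasets) == 0:
        raise ValueError("need at least one dataset")
    trs = {round(d.tr, 9) for d in datasets}
    if len(trs) > 1:
        raise ValueError(f"cannot concatenate datasets with differing TRs: {sorted(trs)}")
    if per_dataset_analytic:
        blocks = [analytic_signal(d).data for d in datasets]
    else:
        stacked = np.vstack([d.data for d in datasets])
        merged = BoldDataset(data=stacked, tr=datasets[0].tr)
        blocks = [analytic_signal(merged).data]
    data = np.vstack(blocks)
    ends = np.cumsum([d.n_timepoints for d in datasets])
    return AnalyticDataset(
        data=data, tr=datasets[0].tr, boundaries=tuple(int(e) for e in ends)
    )


def decompose(
    analytic: AnalyticDataset, n_components: int = 10, rotate: bool = True
) -> CpcaResult:
    """Complex PCA, optionally varimax-rotated."""
    result = complex_pca(analytic, n_components)
    if rotate and n_components >= 2:
        result = varimax_complex(result)
    return result


def split_rows(matrix: np.ndarray, boundaries: Sequence[int]) -> list[np.ndarray]:
    """Split a concatenated timepoints x K matrix back into per-dataset blocks."""
    ends = list(boundaries)
    if ends[-1] != matrix.shape[0]:
        raise ValueError(
            f"boundaries end at {ends[-1]} but matrix has {matrix.shape[0]} rows"
        )
    starts = [0] + ends[:-1]
    return [matrix[lo:hi] for lo, hi in zip(starts, ends)]


def match_components(
    result: CpcaResult,
    truth: GroundTruth,
    location_scale: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Match extracted components to planted patterns by loading-map correlation.

    Returns ``(component_index_per_pattern, correlation_per_pattern)`` via
    an optimal one-to-one assignment over absolute Pearson correlations
    between planted magnitude maps and |loading| columns.  When the
    decomposition ran on standardized data, pass the per-location SD that
    was divided out as ``location_scale``: the pattern the decomposition
    can see is the planted map in those rescaled units.
    """
    K_true = truth.n_patterns
    mags = np.abs(result.loadings)
    corr = np.zeros((K_true, result.n_components))
    for i, p in enumerate(truth.patterns):
        ref = p.magnitude_map if location_scale is None else p.magnitude_map / location_scale
        for j in range(result.n_components):
            c = np.corrcoef(ref, mags[:, j])[0, 1]
            corr[i, j] = 0.0 if np.isnan(c) else abs(c)
    rows, cols = linear_sum_assignment(-corr)
    order = np.argsort(rows)
    return cols[order], corr[rows[order], cols[order]]


def _timed(label: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    out = fn(*args, **kwargs)
    log.info("%s finished in %.2f s", label, time.perf_counter() - t0)
    return out


def run_within_scan(
    datasets: Sequence[BoldDataset], config: RunConfig
) -> dict:
    """Workflow A: drift of pattern expression over the scan, across subjects."""
    if len(datasets) == 0:
        raise ValueError("no input datasets")
    pre = [
        _timed(
            f"preprocess {d.subject_id}",
            preprocess_dataset,
            d,
            passband=config.passband,
            polort=config.polort,
            smooth_fwhm=config.smooth_fwhm,
            standardize=config.standardize,
        )
        for d in datasets
    ]
    analytic = concatenate_analytic(pre)
    result = _timed("decompose", decompose, analytic, config.n_components, config.rotate)
    k_retain = select_elbow(result.explained_variance_ratio, k_override=config.k_retain)
    mags = component_magnitude_phase(result).magnitudes
    per_subject = dict(
        zip(
            [d.subject_id or f"sub-{i:03d}" for i, d in enumerate(datasets)],
            split_rows(mags, analytic.boundaries),
        )
    )
    sequences = {
        sub: assign_dominant_state(m, k_retain, config.dominance_pool)
        for sub, m in per_subject.items()
    }
    inc = incidence_table(sequences, include_other=config.dominance_pool == "all")
    seg = segment_magnitude_summary(per_subject, config.first_n, config.last_n)
    diffs = paired_segment_differences(seg)

    tests = []
    for k in range(1, k_retain + 1):
        sub = diffs[diffs["component"] == k]
        res = paired_ttest(sub["last"].to_numpy(), sub["first"].to_numpy())
        tests.append(
            {
                "component": k,
                "t": res.statistic,
                "df": res.df,
                "p": res.p_value,
                "mean_difference": res.effect,
            }
        )
    ttests = pd.DataFrame(tests)

    feats = subject_features(per_subject, k_retain)
    cluster = kmeans_cluster(
        feats,
        k_candidates=config.cluster_k_candidates,
        n_restarts=config.cluster_restarts,
        seed=config.seed,
    )
    return {
        "result": result,
        "k_retain": k_retain,
        "explained_variance_ratio": result.explained_variance_ratio,
        "magnitudes_per_subject": per_subject,
        "state_sequences": sequences,
        "incidence": inc,
        "segment_summary": seg,
        "segment_ttests": ttests,
        "features": feats,
        "cluster": cluster,
    }


def run_condition_contrast(
    datasets: Sequence[BoldDataset], config: RunConfig
) -> dict:
    """Workflow B: pattern incidence/magnitude across conditions, RM-ANOVA + paired tests."""
    if len(datasets) == 0:
        raise ValueError("no input datasets")
    keys = [(d.subject_id, d.condition_id) for d in datasets]
    if any(k[0] is None or k[1] is None for k in keys):
        raise ValueError("every dataset needs subject_id and condition_id")
    pre = [
        preprocess_dataset(
            d,
            passband=config.passband,
            polort=config.polort,
            smooth_fwhm=config.smooth_fwhm,
            standardize=config.standardize,
        )
        for d in datasets
    ]
    analytic = concatenate_analytic(pre)
    result = _timed("decompose", decompose, analytic, config.n_components, config.rotate)
    k_retain = select_elbow(result.explained_variance_ratio, k_override=config.k_retain)
    mags = component_magnitude_phase(result).magnitudes
    blocks = split_rows(mags, analytic.boundaries)
    per_cell = dict(zip(keys, blocks))
    sequences = {
        key: assign_dominant_state(m, k_retain, config.dominance_pool)
        for key, m in per_cell.items()
    }
    summary = condition_summary(sequences, per_cell)

    anovas, ttests = [], []
    contrast = config.contrast_conditions
    for k in range(1, k_retain + 1):
        sub = summary[summary["component"] == k]
        for measure in ("incidence", "mean_magnitude"):
            res = rm_anova(sub, value=measure)
            anovas.append(
                {
                    "component": k,
                    "measure": measure,
                    "F_condition": res.condition.statistic,
                    "df": str(res.condition.df),
                    "p_condition": res.condition.p_value,
                    "F_subject": res.subject.statistic,
                    "p_subject": res.subject.p_value,
                }
            )
        if contrast is not None:
            a = sub[sub["condition"] == contrast[0]].sort_values("subject")
            b = sub[sub["condition"] == contrast[1]].sort_values("subject")
            res = paired_ttest(a["incidence"].to_numpy(), b["incidence"].to_numpy())
            ttests.append(
                {
                    "component": k,
                    "t": res.statistic,
                    "df": res.df,
                    "p": res.p_value,
                    "mean_difference": res.effect,
                }
            )
    anova_table = pd.DataFrame(anovas)
    ttest_table = pd.DataFrame(ttests)
    if len(ttest_table):
        m = config.bonferroni_m or k_retain
        ttest_table["p_bonferroni"] = bonferroni(ttest_table["p"].to_numpy(), m)

    return {
        "result": result,
        "k_retain": k_retain,
        "explained_variance_ratio": result.explained_variance_ratio,
        "magnitudes_per_cell": per_cell,
        "state_sequences": sequences,
        "condition_summary": summary,
        "rm_anova": anova_table,
        "contrast_ttests": ttest_table,
    }


def run_workflow(
    config: RunConfig, datasets: Sequence[BoldDataset] | None = None
) -> tuple[int, dict]:
    """Run a named workflow end to end and write outputs + manifest.

    ``datasets`` may be passed in memory; otherwise ``config.inputs`` is a
    list of ``{"path": ..., "tr": ..., "subject_id": ..., "condition_id":
    ...}`` records read from disk.  Returns (exit status, manifest).
    """
    t0 = time.perf_counter()
    if datasets is None:
        loaded = []
        for rec in config.inputs:
            ds = read_bold(rec["path"], tr=rec.get("tr"))
            if rec.get("subject_id"):
                ds.subject_id = rec["subject_id"]
            if rec.get("condition_id"):
                ds.condition_id = rec["condition_id"]
            loaded.append(ds)
        datasets = loaded

    if config.workflow == "within_scan":
        res = run_within_scan(datasets, config)
        tables = {
            "explained_variance": pd.DataFrame(
                {"component": np.arange(1, len(res["explained_variance_ratio"]) + 1),
                 "evr": res["explained_variance_ratio"]}
            ).set_index("component"),
            "incidence": res["incidence"],
            "segment_summary": res["segment_summary"].set_index("subject"),
            "segment_ttests": res["segment_ttests"].set_index("component"),
            "features": res["features"],
            "cluster_assignments": res["cluster"].assignments.to_frame(),
            "cluster_info": {
                "chosen_k": res["cluster"].chosen_k,
                "silhouette_by_k": res["cluster"].silhouette_by_k,
                "k_retain": res["k_retain"],
            },
        }
    elif config.workflow == "condition_contrast":
        res = run_condition_contrast(datasets, config)
        tables = {
            "explained_variance": pd.DataFrame(
                {"component": np.arange(1, len(res["explained_variance_ratio"]) + 1),
                 "evr": res["explained_variance_ratio"]}
            ).set_index("component"),
            "condition_summary": res["condition_summary"].set_index("subject"),
            "rm_anova": res["rm_anova"].set_index("component"),
            "contrast_ttests": res["contrast_ttests"].set_index("component")
            if len(res["contrast_ttests"])
            else res["contrast_ttests"],
            "run_info": {"k_retain": res["k_retain"]},
        }
    else:
        raise ValueError(f"unknown workflow {config.workflow!r}")

    manifest = write_outputs(tables, config.out_dir, config=config)
    log.info("workflow %s finished in %.2f s", config.workflow, time.perf_counter() - t0)
    return 0, manifest
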