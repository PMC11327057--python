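"""Group-level inference: subject clustering, paired tests, repeated-measures ANOVA.

Subjects are summarized by the mean and standard deviation of each retained
component's score magnitude over the scan (2*K features), clustered with
k-means (silhouette-selected k), and compared with paired t-tests (optionally
Bonferroni-corrected) and one-way within-subject repeated-measures ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "SubjectFeatures",
    "ClusterResult",
    "TestResult",
    "RmAnovaResult",
    "subject_features",
    "kmeans_cluster",
    "paired_ttest",
    "bonferroni",
    "rm_anova",
]


@dataclass
class TestResult:
    """A single hypothesis test outcome."""

    name: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    effect: float | dict | None = None
    adjusted_p: float | None = None


@dataclass
class RmAnovaResult:
    """One-way within-subject ANOVA: condition and subject effects."""

    condition: TestResult
    subject: TestResult
    ss_conditions: float
    ss_subjects: float
    ss_error: float
    condition_means: pd.Series


@dataclass
class ClusterResult:
    """k-means clustering of subject feature vectors."""

    assignments: pd.Series  # subject -> cluster id
    centroids: np.ndarray
    chosen_k: int
    silhouette_by_k: dict[int, float]
    n_restarts: int
    seed: int
    standardized: bool


def subject_features(
    magnitudes_per_subject: Mapping[str, np.ndarray], k_retain: int
) -> pd.DataFrame:
    """2*K features per subject: per-component magnitude mean then SD.

    Column order is ``mean_1..mean_K, sd_1..sd_K`` (documented, fixed).
    """
    rows = {}
    for sub, mags in magnitudes_per_subject.items():
        mags = np.asarray(mags)[:, :k_retain]
        if mags.shape[0] < 2:
            raise ValueError(f"subject {sub!r}: need >= 2 timepoints for an SD")
        rows[sub] = np.concatenate([mags.mean(axis=0), mags.std(axis=0, ddof=1)])
    cols = [f"mean_{k}" for k in range(1, k_retain + 1)] + [
        f"sd_{k}" for k in range(1, k_retain + 1)
    ]
    out = pd.DataFrame(rows, index=cols).T
    out.index.name = "subject"
    return out


def kmeans_cluster(
    features: pd.DataFrame | np.ndarray,
    k_candidates: Sequence[int] = (2, 3, 4),
    n_restarts: int = 50,
    seed: int = 0,
    standardize: bool = True,
) -> ClusterResult:
    """Euclidean k-means over candidate k, best restart, silhouette-selected k.

    For each candidate k the best of ``n_restarts`` seeded runs (lowest
    within-cluster sum of squares) is kept; the chosen k maximizes the mean
    silhouette.  Deterministic given the seed.
    """
    if isinstance(features, pd.DataFrame):
        X = features.to_numpy(dtype=float)
        index = features.index
    else:
        X = np.asarray(features, dtype=float)
        index = pd.RangeIndex(X.shape[0])
    n = X.shape[0]
    k_candidates = [int(k) for k in k_candidates]
    if max(k_candidates) >= n:
        raise ValueError(f"largest candidate k {max(k_candidates)} needs > k subjects (have {n})")
    sds = X.std(axis=0)
    if np.all(sds == 0):
        raise ValueError("feature matrix is degenerate (zero variance everywhere)")
    if standardize:
        X = (X - X.mean(axis=0)) / np.where(sds > 0, sds, 1.0)

    silhouettes: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for k in k_candidates:
        km = KMeans(
            n_clusters=k,
            n_init=n_restarts,
            random_state=seed,
            algorithm="lloyd",
        ).fit(X)
        fits[k] = km
        silhouettes[k] = float(silhouette_score(X, km.labels_, metric="euclidean"))
    chosen_k = max(k_candidates, key=lambda k: (silhouettes[k], -k))
    km = fits[chosen_k]
    return ClusterResult(
        assignments=pd.Series(km.labels_, index=index, name="cluster"),
        centroids=km.cluster_centers_,
        chosen_k=chosen_k,
        silhouette_by_k=silhouettes,
        n_restarts=n_restarts,
        seed=seed,
        standardized=standardize,
    )


def paired_ttest(
    values_a: Sequence[float], values_b: Sequence[float], side: str = "two-sided"
) -> TestResult:
    """Paired t-test: t = mean(d) / (SD(d)/sqrt(n)), df = n - 1."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences; t is undefined")
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    if side == "two-sided":
        p = 2.0 * sps.t.sf(abs(t), df)
    elif side == "greater":
        p = sps.t.sf(t, df)
    elif side == "less":
        p = sps.t.cdf(t, df)
    else:
        raise ValueError(f"unknown side {side!r}")
    return TestResult(
        name=f"paired t ({side})",
        statistic=float(t),
        df=df,
        p_value=float(min(p, 1.0)),
        effect=float(d.mean()),
    )


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < 1:
        raise ValueError("m must be >= 1")
    if m < len(p):
        raise ValueError(f"m = {m} is smaller than the number of tests ({len(p)})")
    return np.minimum(1.0, p * m)


def rm_anova(
    table: pd.DataFrame,
    value: str = "value",
    subject: str = "subject",
    condition: str = "condition",
) -> RmAnovaResult:
    """One-way repeated-measures ANOVA by explicit sums of squares.

    ``SS_total = SS_subjects + SS_conditions + SS_error``;
    ``F_cond = MS_cond / MS_error`` on ``(c-1, (c-1)(s-1))`` degrees of
    freedom, the subject effect analogously.  No sphericity correction is
    applied.  Requires a complete balanced design with one value per cell.
    """
    for col in (value, subject, condition):
        if col not in table.columns:
            raise ValueError(f"table lacks column {col!r}")
    wide = table.pivot_table(index=subject, columns=condition, values=value)
    counts = table.groupby([subject, condition]).size()
    if np.any(counts != 1):
        dup = counts[counts != 1].index.tolist()
        raise ValueError(f"need exactly one value per subject x condition cell; got {dup}")
    if wide.isna().any().any():
        gaps = [
            (s, c) for s in wide.index for c in wide.columns if pd.isna(wide.loc[s, c])
        ]
        raise ValueError(f"incomplete design; missing cells: {gaps}")
    s, c = wide.shape
    if s < 2 or c < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    Y = wide.to_numpy(dtype=float)
    grand = Y.mean()
    ss_total = float(np.sum((Y - grand) ** 2))
    ss_subj = float(c * np.sum((Y.mean(axis=1) - grand) ** 2))
    ss_cond = float(s * np.sum((Y.mean(axis=0) - grand) ** 2))
    ss_err = ss_total - ss_subj - ss_cond
    df_cond = c - 1
    df_subj = s - 1
    df_err = (c - 1) * (s - 1)
    ms_err = ss_err / df_err

    def _ftest(ss_eff: float, df_eff: int, label: str) -> TestResult:
        if ss_eff <= 1e-300 or ms_err == 0 and ss_eff == 0:
            return TestResult(label, 0.0, (df_eff, df_err), 1.0)
        if ms_err == 0:
            return TestResult(label, float("inf"), (df_eff, df_err), 0.0)
        F = (ss_eff / df_eff) / ms_err
        return TestResult(
            label, float(F), (df_eff, df_err), float(sps.f.sf(F, df_eff, df_err))
        )

    cond_res = _ftest(ss_cond, df_cond, "RM-ANOVA condition")
    subj_res = _ftest(ss_subj, df_subj, "RM-ANOVA subject")
    cond_res.effect = wide.mean(axis=0).to_dict()
    return RmAnovaResult(
        condition=cond_res,
        subject=subj_res,
        ss_conditions=ss_cond,
        ss_subjects=ss_subj,
        ss_error=ss_err,
        condition_means=wide.mean(axis=0),
    )
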