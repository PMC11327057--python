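"""Seeded validation experiments over the full pipeline.

These drivers run the two study-shaped workflows on synthetic cohorts with
planted ground truth and measure how well the pipeline recovers what was
planted: loading-map and envelope correlations, state-assignment accuracy,
drift-detection power, subject-clustering agreement, condition-contrast
power and type-I error, and the motion/respiration QC contrast.  They are
shared by the test suite and the acceptance script so both measure the
same quantities the same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .cpca import component_magnitude_phase
from .preprocess import (
    framewise_displacement,
    temporal_snr,
    zscore_timecourses,
)
from .states import assign_dominant_state
from .stats import bonferroni, kmeans_cluster, paired_ttest, rm_anova, subject_features
from .states import condition_summary, paired_segment_differences, segment_magnitude_summary
from .synthetic import (
    EnvelopeSpec,
    MotionTrace,
    add_nuisance,
    make_pattern_library,
    simulate_cohort,
    simulate_conditions,
    simulate_subject,
)
from .workflows import (
    concatenate_analytic,
    decompose,
    match_components,
    preprocess_dataset,
    split_rows,
)

__all__ = [
    "CohortRecovery",
    "DriftOutcome",
    "ConditionOutcome",
    "run_cohort_recovery",
    "run_noise_free_recovery",
    "run_drift_replicate",
    "run_condition_replicate",
    "qc_contrast_pair",
    "ALT_CONDITION_SPECS",
    "NULL_CONDITION_SPECS",
    "ALT_DURATIONS",
    "NULL_DURATIONS",
]

#: per-condition pattern mixture weights for the planted condition contrast
#: (component-2 incidence differs by 0.25 between the first two conditions)
ALT_CONDITION_SPECS = (
    {"condition_id": "iso", "weights": (0.50, 0.20, 0.30)},
    {"condition_id": "dmed", "weights": (0.25, 0.45, 0.30)},
    {"condition_id": "both", "weights": (0.40, 0.30, 0.30)},
)
#: equal mixtures everywhere — the no-effect configuration
NULL_CONDITION_SPECS = (
    {"condition_id": "iso", "weights": (1 / 3, 1 / 3, 1 / 3)},
    {"condition_id": "dmed", "weights": (1 / 3, 1 / 3, 1 / 3)},
    {"condition_id": "both", "weights": (1 / 3, 1 / 3, 1 / 3)},
)
#: per-condition scan lengths (frames); unequal, like real acquisition periods
ALT_DURATIONS = (240, 320, 280)
#: equal lengths for the null, so condition variances are exchangeable
NULL_DURATIONS = (280, 280, 280)


@dataclass
class CohortRecovery:
    """How well a cohort decomposition recovered the planted patterns."""

    loading_correlations: np.ndarray  # per planted pattern
    envelope_correlations: np.ndarray  # per subject x varying pattern
    matched_components: np.ndarray


@dataclass
class DriftOutcome:
    """One drift-detection replicate: test on the ramped component + clustering."""

    p_value: float
    mean_difference: float
    chosen_k: int
    ari: float


@dataclass
class ConditionOutcome:
    """One condition-contrast replicate: RM-ANOVA and paired test on component 2."""

    anova_p: float
    paired_p_bonferroni: float


def _decompose_cohort(datasets, standardize: bool, n_components: int, passband, polort: int = 2):
    """Preprocess, concatenate and decompose; returns (result, analytic, scale)."""
    filtered = [
        preprocess_dataset(d, passband=passband, polort=polort, standardize=False)
        for d in datasets
    ]
    scale = np.sqrt(np.mean([f.data.var(axis=0) for f in filtered], axis=0))
    pre = [zscore_timecourses(f) for f in filtered] if standardize else filtered
    analytic = concatenate_analytic(pre)
    result = decompose(analytic, n_components=n_components, rotate=True)
    return result, analytic, (scale if standardize else None)


def run_cohort_recovery(
    seed: int,
    n_per_group: int = 10,
    n_timepoints: int = 600,
    n_locations: int = 90,
    n_components: int = 10,
    k_retain: int = 3,
) -> tuple[CohortRecovery, dict, list]:
    """Decompose the default two-group cohort and measure pattern recovery.

    Returns the recovery summary, the per-subject magnitude matrices
    (columns reordered so column k is the component matched to planted
    pattern k+1), and the cohort itself.
    """
    cohort = simulate_cohort(
        n_per_group, seed=seed, n_timepoints=n_timepoints, n_locations=n_locations
    )
    result, analytic, scale = _decompose_cohort(
        [d for d, _ in cohort], True, n_components, (0.01, 0.1)
    )
    idx, corr = match_components(result, cohort[0][1], location_scale=scale)
    mags = component_magnitude_phase(result).magnitudes
    blocks = split_rows(mags, analytic.boundaries)
    env_corrs = []
    for b, (_, truth) in zip(blocks, cohort):
        for k in range(k_retain):
            env = truth.envelopes[:, k]
            if env.std() > 1e-9:
                env_corrs.append(abs(np.corrcoef(b[:, idx[k]], env)[0, 1]))
    per_subject = {
        d.subject_id: b[:, idx] for (d, _), b in zip(cohort, blocks)
    }
    recovery = CohortRecovery(
        loading_correlations=corr,
        envelope_correlations=np.array(env_corrs),
        matched_components=idx,
    )
    return recovery, per_subject, cohort


def run_noise_free_recovery(
    seed: int = 5,
    n_timepoints: int = 600,
    tr: float = 0.72,
    n_locations: int = 90,
) -> float:
    """Noise-free variant: fraction of timepoints whose assigned state equals the truth.

    Six subjects, each dominated by a fixed planted pattern (allocation
    3/2/1 so pattern energies are distinct), carriers on the DFT grid
    inside the passband so the stopband projection is exactly orthogonal to
    the planted signal, no standardization (raw amplitudes carry the
    dominance structure).
    """
    duration = n_timepoints * tr
    # carriers on the scan's DFT grid, inside the 0.01-0.1 Hz passband
    bins = [max(2, round(f * duration)) for f in (0.030, 0.051, 0.069)]
    carriers = tuple(j / duration for j in bins)
    patterns = make_pattern_library(n_locations, 3, seed=seed, carrier_freqs=carriers)
    datasets, truths = [], []
    for s, dom in enumerate([0, 0, 0, 1, 1, 2]):
        amps = [0.5, 0.55, 0.6]
        amps[dom] = 1.5
        specs = [EnvelopeSpec("constant", a) for a in amps]
        d, g = simulate_subject(
            patterns, specs, n_timepoints, tr, noise_sd=0.0,
            seed=1000 * seed + s, subject_id=f"s{s}",
        )
        datasets.append(d)
        truths.append(g)
    # polort=0: noise-free data has no drift, and the constant column is exactly
    # orthogonal to integer-cycle carriers, so the projection leaves the planted
    # signal untouched (higher-order polynomials would add edge transients)
    result, analytic, _ = _decompose_cohort(datasets, False, 3, (0.01, 0.1), polort=0)
    idx, _ = match_components(result, truths[0])
    inv = np.empty(3, dtype=int)
    inv[idx] = np.arange(3)
    blocks = split_rows(component_magnitude_phase(result).magnitudes, analytic.boundaries)
    correct = total = 0
    for b, truth in zip(blocks, truths):
        predicted = inv[assign_dominant_state(b, 3).labels - 1] + 1
        correct += int((predicted == truth.true_dominant).sum())
        total += len(predicted)
    return correct / total


def run_drift_replicate(
    seed: int,
    n_per_group: int = 10,
    n_timepoints: int = 400,
    n_locations: int = 60,
    segment_fraction: float = 1 / 3,
) -> DriftOutcome:
    """One replicate of the within-scan drift study on a reduced cohort.

    Paired t-test of last-vs-first segment mean magnitude for the component
    matched to the planted ramping pattern, plus silhouette-selected
    k-means on the subject features compared to the planted groups.
    """
    recovery, per_subject, cohort = run_cohort_recovery(
        seed, n_per_group=n_per_group, n_timepoints=n_timepoints,
        n_locations=n_locations,
    )
    n_seg = int(n_timepoints * segment_fraction)
    seg = segment_magnitude_summary(per_subject, n_seg, n_seg)
    diffs = paired_segment_differences(seg)
    ramp = diffs[diffs["component"] == 1]  # column 1 = matched planted pattern 1
    test = paired_ttest(ramp["last"].to_numpy(), ramp["first"].to_numpy())
    features = subject_features(per_subject, 3)
    cluster = kmeans_cluster(features, seed=seed)
    truth_groups = [g.group_id for _, g in cohort]
    ari = adjusted_rand_score(truth_groups, cluster.assignments.to_numpy())
    return DriftOutcome(
        p_value=test.p_value,
        mean_difference=float(test.effect),
        chosen_k=cluster.chosen_k,
        ari=float(ari),
    )


def run_condition_replicate(
    seed: int,
    null: bool = False,
    n_subjects: int = 8,
    n_locations: int = 50,
    contrast: tuple[str, str] = ("iso", "dmed"),
) -> ConditionOutcome:
    """One replicate of the cross-condition study (anesthesia analogue).

    RM-ANOVA condition effect on component-2 incidence, and the
    Bonferroni-adjusted paired test between the two most distinct
    conditions.  ``null=True`` plants equal mixtures (no condition effect).
    """
    specs = list(NULL_CONDITION_SPECS if null else ALT_CONDITION_SPECS)
    durations = list(NULL_DURATIONS if null else ALT_DURATIONS)
    sims = simulate_conditions(
        n_subjects, specs, durations, seed=seed, n_locations=n_locations, snr=1.0
    )
    result, analytic, _ = _decompose_cohort(
        [d for d, _ in sims], False, 10, (0.01, 0.25)
    )
    idx, _ = match_components(result, sims[0][1])
    mags = component_magnitude_phase(result).magnitudes
    blocks = split_rows(mags, analytic.boundaries)
    sequences, cell_mags = {}, {}
    for (d, _), b in zip(sims, blocks):
        key = (d.subject_id, d.condition_id)
        matched = b[:, idx]
        sequences[key] = assign_dominant_state(matched, 3)
        cell_mags[key] = matched
    summary = condition_summary(sequences, cell_mags)
    comp2 = summary[summary["component"] == 2]
    anova = rm_anova(comp2, value="incidence")
    a = comp2[comp2["condition"] == contrast[0]].sort_values("subject")
    b = comp2[comp2["condition"] == contrast[1]].sort_values("subject")
    test = paired_ttest(a["incidence"].to_numpy(), b["incidence"].to_numpy())
    adj = float(bonferroni([test.p_value], 3)[0])
    return ConditionOutcome(anova_p=anova.condition.p_value, paired_p_bonferroni=adj)


def qc_contrast_pair(seed: int, n_timepoints: int = 300, n_locations: int = 60) -> dict:
    """Free-breathing vs mechanically-ventilated twin from one seed family.

    The "ventilated" dataset is the clean simulation; the "free-breathing"
    twin adds motion-coupled signal and a respiration-like oscillation.
    Returns mean framewise displacement and global-signal temporal SNR for
    both members.
    """
    patterns = make_pattern_library(n_locations, 3, seed=seed)
    specs = [EnvelopeSpec("constant", 1.0) for _ in range(3)]
    clean, _ = simulate_subject(
        patterns, specs, n_timepoints, 2.0, seed=seed, snr=1.0, baseline=100.0
    )
    noisy, trace = add_nuisance(
        clean,
        motion_spec={"amplitude_mm": 0.15, "coupling": 0.3},
        respiration_spec={"freq_hz": 0.45, "amplitude": 0.3},
        seed=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, gs_tsnr_clean = temporal_snr(clean)
        _, gs_tsnr_noisy = temporal_snr(noisy)
    fd_noisy = framewise_displacement(trace.params, head_radius_mm=5.0)
    fd_clean = framewise_displacement(
        MotionTrace.zeros(n_timepoints).params, head_radius_mm=5.0
    )
    return {
        "mean_fd_free_breathing": float(fd_noisy.mean()),
        "mean_fd_ventilated": float(fd_clean.mean()),
        "gs_tsnr_free_breathing": float(gs_tsnr_noisy),
        "gs_tsnr_ventilated": float(gs_tsnr_clean),
    }
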