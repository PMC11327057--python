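"""Synthetic BOLD datasets with planted quasiperiodic propagating patterns.

The generator emulates the structure that complex PCA is designed to
recover: each planted pattern is an amplitude-modulated travelling wave

    y(v, t) = sum_k a_k(t) * m_k(v) * cos(2*pi*f_k*t + phi_k(v)) + noise,

where ``m_k`` is a nonnegative spatial magnitude map, ``phi_k`` a spatial
phase-lag map (propagation), ``f_k`` a slow carrier frequency inside the
BOLD band and ``a_k(t)`` a slowly varying envelope.  The per-timepoint
"true dominant pattern" is the argmax of the envelopes, which is exactly
the quantity the state-assignment stage estimates from data.

Cohorts (subject groups with different envelope drifts) and multi-condition
recordings (per-condition pattern mixture weights) plant the two study
designs downstream statistics are tested on: within-scan drift of the
global pattern, and anesthesia-like shifts of pattern incidence across
conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .preprocess import BoldDataset

__all__ = [
    "PlantedPattern",
    "EnvelopeSpec",
    "GroundTruth",
    "MotionTrace",
    "make_pattern_library",
    "simulate_subject",
    "simulate_cohort",
    "simulate_conditions",
    "add_nuisance",
    "default_group_specs",
    "DEFAULT_CARRIERS",
]

#: default carrier frequencies (Hz), inside the human infraslow band and distinct
DEFAULT_CARRIERS = (0.03, 0.05, 0.08)

#: envelope amplitude of the dominant / non-dominant pattern within a block
BLOCK_AMP_HIGH = 1.5
BLOCK_AMP_LOW = 0.5

#: default length (frames) of one dominance block in condition simulations
BLOCK_LEN = 20


@dataclass
class PlantedPattern:
    """One planted propagating pattern: magnitude map, phase-lag map, carrier."""

    magnitude_map: np.ndarray
    phase_map: np.ndarray
    carrier_freq: float
    name: str = ""

    def __post_init__(self) -> None:
        self.magnitude_map = np.asarray(self.magnitude_map, dtype=float)
        self.phase_map = np.asarray(self.phase_map, dtype=float)
        if self.magnitude_map.shape != self.phase_map.shape:
            raise ValueError("magnitude and phase maps must have equal shape")
        if not np.any(self.magnitude_map > 0):
            raise ValueError("magnitude map needs at least one positive entry")
        if np.any(self.magnitude_map < 0):
            raise ValueError("magnitude map must be nonnegative")
        if np.any(self.phase_map < -np.pi - 1e-12) or np.any(self.phase_map > np.pi + 1e-12):
            raise ValueError("phase map entries must lie in [-pi, pi]")
        if self.carrier_freq <= 0:
            raise ValueError("carrier frequency must be positive")

    @property
    def complex_map(self) -> np.ndarray:
        """Spatial pattern as a complex vector, magnitude * exp(i*phase)."""
        return self.magnitude_map * np.exp(1j * self.phase_map)


@dataclass
class EnvelopeSpec:
    """Temporal amplitude envelope of one planted pattern.

    ``constant`` holds ``start_amp``; ``linear_ramp`` interpolates
    ``start_amp`` to ``end_amp``; ``piecewise`` is piecewise-constant with
    ``levels`` (one more level than breakpoints).
    """

    kind: str = "constant"
    start_amp: float = 1.0
    end_amp: float | None = None
    breakpoints: Sequence[int] = ()
    levels: Sequence[float] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "linear_ramp", "piecewise"):
            raise ValueError(f"unknown envelope kind {self.kind!r}")
        if self.start_amp < 0 or (self.end_amp is not None and self.end_amp < 0):
            raise ValueError("amplitudes must be >= 0")
        bp = list(self.breakpoints)
        if bp != sorted(set(bp)):
            raise ValueError("breakpoints must be strictly increasing")
        if self.kind == "piecewise":
            if len(self.levels) != len(bp) + 1:
                raise ValueError("piecewise needs len(levels) == len(breakpoints) + 1")
            if any(a < 0 for a in self.levels):
                raise ValueError("amplitudes must be >= 0")

    def render(self, n_timepoints: int) -> np.ndarray:
        """Evaluate the envelope on ``n_timepoints`` frames."""
        T = int(n_timepoints)
        if self.kind == "constant":
            return np.full(T, self.start_amp)
        if self.kind == "linear_ramp":
            end = self.start_amp if self.end_amp is None else self.end_amp
            return np.linspace(self.start_amp, end, T)
        bp = [b for b in self.breakpoints]
        if any(b <= 0 or b >= T for b in bp):
            raise ValueError("breakpoints must lie strictly inside the scan")
        out = np.empty(T)
        edges = [0, *bp, T]
        for lvl, lo, hi in zip(self.levels, edges[:-1], edges[1:]):
            out[lo:hi] = lvl
        return out


@dataclass
class GroundTruth:
    """Planted truth for one simulated dataset."""

    patterns: list[PlantedPattern]
    envelopes: np.ndarray  # timepoints x patterns
    group_id: str | None = None
    condition_id: str | None = None
    noise_sd: float = 0.0
    seed: int | None = None
    true_dominant: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.envelopes = np.asarray(self.envelopes, dtype=float)
        if self.envelopes.ndim != 2 or self.envelopes.shape[1] != len(self.patterns):
            raise ValueError("envelopes must be timepoints x n_patterns")
        # ties break toward the lower pattern index, as in state assignment
        self.true_dominant = np.argmax(self.envelopes, axis=1) + 1

    @property
    def n_patterns(self) -> int:
        return len(self.patterns)

    def true_incidence(self) -> np.ndarray:
        """Fraction of timepoints each pattern truly dominates."""
        k = self.n_patterns
        counts = np.bincount(self.true_dominant - 1, minlength=k)
        return counts / self.envelopes.shape[0]


@dataclass
class MotionTrace:
    """Six rigid-body motion parameters per frame: 3 translations (mm), 3 rotations (rad)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(f"motion trace must be (T, 6), got {self.params.shape}")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion trace must be finite")

    @classmethod
    def zeros(cls, n_timepoints: int) -> "MotionTrace":
        return cls(np.zeros((n_timepoints, 6)))


def _block_magnitude(n_locations: int, centers: Sequence[float], width: int) -> np.ndarray:
    m = np.zeros(n_locations)
    for c in centers:
        lo = int(round(c * n_locations)) - width // 2
        lo = min(max(lo, 0), n_locations - width)
        m[lo : lo + width] = 1.0
    return m


def _block_phase(magnitude: np.ndarray, offsets: Sequence[float], gradient_span: float = 0.6) -> np.ndarray:
    """Linear phase gradient inside each contiguous block, blocks offset against each other."""
    phase = np.zeros_like(magnitude)
    on = magnitude > 0
    # find contiguous runs
    edges = np.flatnonzero(np.diff(np.concatenate([[0], on.view(np.int8), [0]])))
    runs = list(zip(edges[0::2], edges[1::2]))
    for i, (lo, hi) in enumerate(runs):
        off = offsets[i % len(offsets)]
        grad = np.linspace(0.0, gradient_span, hi - lo)
        phase[lo:hi] = np.angle(np.exp(1j * (off + grad)))
    return phase


def make_pattern_library(
    n_locations: int,
    n_patterns: int = 3,
    geometry_spec=None,
    seed: int = 0,
    carrier_freqs: Sequence[float] | None = None,
) -> list[PlantedPattern]:
    """Build mutually near-orthogonal planted patterns.

    Pattern 1 is a near-uniform positive map with a shallow phase gradient
    (global-signal analogue).  Patterns 2..K are pairs of narrow anti-phase
    blocks on mutually disjoint supports, each block carrying a linear phase
    gradient (propagation).  Magnitude maps are unit L2-norm and pairwise
    near-orthogonal (|cosine| <= 0.2 by construction).
    """
    if n_patterns < 1:
        raise ValueError("need at least one pattern")
    if n_patterns > n_locations:
        raise ValueError(
            f"cannot plant {n_patterns} patterns in {n_locations} locations"
        )
    rng = np.random.default_rng(seed)
    if carrier_freqs is None:
        carrier_freqs = list(DEFAULT_CARRIERS) + [
            0.08 + 0.03 * (k - 2) for k in range(3, n_patterns)
        ]
    if len(set(np.round(carrier_freqs, 12))) < n_patterns:
        raise ValueError("carrier frequencies must be distinct")

    V = int(n_locations)
    patterns: list[PlantedPattern] = []

    # pattern 1: near-uniform positive with smooth +-25% variation
    bump = gaussian_filter1d(rng.standard_normal(V), sigma=max(V / 10.0, 1.0), mode="wrap")
    if bump.std() > 0:
        bump = bump / bump.std()
    m1 = 1.0 + 0.25 * np.clip(bump, -1.0, 1.0)
    m1 /= np.linalg.norm(m1)
    phase1 = np.linspace(0.0, 0.8 * np.pi, V)  # shallow global propagation, span <= pi
    phase1 = np.angle(np.exp(1j * (phase1 - phase1.mean())))
    patterns.append(
        PlantedPattern(m1, phase1, float(carrier_freqs[0]), name="global")
    )

    width = max(1, int(0.012 * V))
    n_slots = max(2 * (n_patterns - 1), 1)
    for k in range(1, n_patterns):
        c_a = (2 * (k - 1) + 0.5) / n_slots
        c_b = (2 * (k - 1) + 1.5) / n_slots
        m = _block_magnitude(V, (c_a, c_b), width)
        if not np.any(m > 0):  # degenerate tiny grids
            m = np.zeros(V)
            m[min(2 * (k - 1), V - 1)] = 1.0
        phase = _block_phase(m, offsets=(0.0, np.pi - 0.61))
        m = m / np.linalg.norm(m)
        patterns.append(
            PlantedPattern(m, phase, float(carrier_freqs[k]), name=f"blocks_{k + 1}")
        )
    return patterns


def _render_envelopes(
    envelope_specs: Sequence[EnvelopeSpec], n_timepoints: int
) -> np.ndarray:
    return np.column_stack([spec.render(n_timepoints) for spec in envelope_specs])


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """1/f-shaped noise via spectral filtering of white noise, unit variance."""
    T, V = shape
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=0)
    f = np.fft.rfftfreq(T)
    scale = np.where(f > 0, 1.0 / np.sqrt(f), 0.0)
    pink = np.fft.irfft(spec * scale[:, None], n=T, axis=0)
    sd = pink.std()
    return pink / sd if sd > 0 else pink


def simulate_subject(
    patterns: Sequence[PlantedPattern],
    envelope_specs: Sequence[EnvelopeSpec],
    n_timepoints: int,
    tr: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    snr: float | None = None,
    baseline: float = 0.0,
    noise_kind: str = "white",
    subject_id: str | None = None,
    condition_id: str | None = None,
    group_id: str | None = None,
) -> tuple[BoldDataset, GroundTruth]:
    """Simulate one recording from planted patterns and envelopes.

    If ``snr`` is given, ``noise_sd`` is set so that the planted-signal
    variance divided by the noise variance equals ``snr``.
    """
    if n_timepoints <= 0 or tr <= 0:
        raise ValueError("n_timepoints and tr must be positive")
    if len(envelope_specs) != len(patterns):
        raise ValueError("need one envelope spec per pattern")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    freqs = [p.carrier_freq for p in patterns]
    if len(set(np.round(freqs, 12))) < len(freqs):
        raise ValueError("carrier frequencies must be distinct")
    nyq = 1.0 / (2.0 * tr)
    if any(f >= nyq for f in freqs):
        raise ValueError(f"carrier frequency at or above Nyquist {nyq} Hz")

    rng = np.random.default_rng(seed)
    T = int(n_timepoints)
    t = np.arange(T) * tr
    env = _render_envelopes(envelope_specs, T)

    signal = np.zeros((T, len(patterns[0].magnitude_map)))
    for k, p in enumerate(patterns):
        carrier = np.cos(
            2.0 * np.pi * p.carrier_freq * t[:, None] + p.phase_map[None, :]
        )
        signal += env[:, k, None] * p.magnitude_map[None, :] * carrier

    if snr is not None:
        if snr <= 0:
            raise ValueError("snr must be positive")
        noise_sd = float(np.sqrt(signal.var() / snr))

    if noise_sd > 0:
        if noise_kind == "white":
            noise = noise_sd * rng.standard_normal(signal.shape)
        elif noise_kind == "pink":
            noise = noise_sd * _pink_noise(rng, signal.shape)
        else:
            raise ValueError(f"unknown noise kind {noise_kind!r}")
    else:
        noise = 0.0

    data = baseline + signal + noise
    dataset = BoldDataset(
        data=data, tr=tr, subject_id=subject_id, condition_id=condition_id
    )
    truth = GroundTruth(
        patterns=list(patterns),
        envelopes=env,
        group_id=group_id,
        condition_id=condition_id,
        noise_sd=noise_sd,
        seed=seed,
    )
    return dataset, truth


def default_group_specs(n_patterns: int = 3) -> list[dict]:
    """Default two-group design: drifting mixture vs stable mixture.

    Group "ramp" plants a rising global-pattern envelope at the expense of
    pattern 2 (the within-scan drowsiness analogue); group "constant" keeps
    a fixed, slightly graded mixture.
    """
    ramp = [
        EnvelopeSpec("linear_ramp", 0.5, 1.5),
        EnvelopeSpec("linear_ramp", 1.5, 0.5),
    ] + [EnvelopeSpec("constant", 0.9) for _ in range(n_patterns - 2)]
    const = [EnvelopeSpec("constant", 1.2 - 0.2 * k) for k in range(n_patterns)]
    return [
        {"group_id": "ramp", "envelope_specs": ramp},
        {"group_id": "constant", "envelope_specs": const},
    ]


def simulate_cohort(
    n_subjects_per_group: int,
    group_specs: Sequence[dict] | None = None,
    seed: int = 0,
    n_timepoints: int = 600,
    tr: float = 0.72,
    n_locations: int = 90,
    n_patterns: int = 3,
    snr: float | None = 1.0,
    noise_sd: float | None = None,
    amp_jitter: float = 0.05,
    patterns: Sequence[PlantedPattern] | None = None,
) -> list[tuple[BoldDataset, GroundTruth]]:
    """Simulate a multi-subject cohort with planted group structure.

    Every subject shares the pattern library; groups differ in their
    envelope specs.  Per-subject seeds are spawned deterministically from
    the master seed, and a small multiplicative amplitude jitter creates
    between-subject variability within each group.
    """
    if group_specs is None:
        group_specs = default_group_specs(n_patterns)
    if len(group_specs) == 0:
        raise ValueError("group_specs must be nonempty")
    if n_subjects_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    if patterns is None:
        patterns = make_pattern_library(n_locations, n_patterns, seed=seed)

    master = np.random.default_rng(seed)
    out: list[tuple[BoldDataset, GroundTruth]] = []
    idx = 0
    for spec in group_specs:
        gid = spec["group_id"]
        env_specs = spec["envelope_specs"]
        if len(env_specs) != len(patterns):
            raise ValueError(f"group {gid!r} needs one envelope per pattern")
        for s in range(n_subjects_per_group):
            sub_seed = int(master.integers(0, 2**31 - 1))
            jit_rng = np.random.default_rng(sub_seed + 1)
            jittered = []
            for e in env_specs:
                fac = float(1.0 + amp_jitter * jit_rng.standard_normal())
                fac = max(fac, 0.1)
                jittered.append(
                    EnvelopeSpec(
                        e.kind,
                        e.start_amp * fac,
                        None if e.end_amp is None else e.end_amp * fac,
                        e.breakpoints,
                        tuple(l * fac for l in e.levels),
                    )
                )
            ds, gt = simulate_subject(
                patterns,
                jittered,
                n_timepoints,
                tr,
                noise_sd=0.0 if noise_sd is None else noise_sd,
                snr=snr if noise_sd is None else None,
                seed=sub_seed,
                subject_id=f"sub-{idx:03d}",
                group_id=gid,
            )
            out.append((ds, gt))
            idx += 1
    return out


def _weights_to_envelopes(
    weights: np.ndarray,
    n_timepoints: int,
    rng: np.random.Generator,
    block_len: int = BLOCK_LEN,
    amp_high: float = BLOCK_AMP_HIGH,
    amp_low: float = BLOCK_AMP_LOW,
) -> np.ndarray:
    """Piecewise-constant envelopes whose dominance fractions match ``weights``.

    The scan is cut into blocks; each block is assigned one dominant pattern.
    Block counts follow largest-remainder rounding of the weights, so the
    realized dominance fraction is within one block of the request; the
    assignment order is shuffled.
    """
    K = len(weights)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    w = w / w.sum()
    n_blocks = max(1, int(np.ceil(n_timepoints / block_len)))
    ideal = w * n_blocks
    counts = np.floor(ideal).astype(int)
    rem = ideal - counts
    # largest-remainder rounding with randomized tie-breaking: a deterministic
    # tie rule would plant a systematic pattern bias under equal weights
    perm = rng.permutation(K)
    for i in perm[np.argsort(-rem[perm], kind="stable")][: n_blocks - counts.sum()]:
        counts[i] += 1
    labels = np.repeat(np.arange(K), counts)
    rng.shuffle(labels)
    env = np.full((n_timepoints, K), amp_low)
    # patterns with zero requested weight stay quiet everywhere
    env[:, w == 0] = amp_low * 0.5
    for b, lab in enumerate(labels):
        lo = b * block_len
        hi = min((b + 1) * block_len, n_timepoints)
        env[lo:hi, lab] = amp_high
    return env


def simulate_conditions(
    n_subjects: int,
    condition_specs: Sequence[dict],
    durations: Sequence[int],
    seed: int = 0,
    tr: float = 2.0,
    n_locations: int = 90,
    n_patterns: int = 3,
    snr: float | None = 1.0,
    noise_sd: float | None = None,
    carrier_freqs: Sequence[float] | None = None,
    block_len: int = BLOCK_LEN,
    patterns: Sequence[PlantedPattern] | None = None,
) -> list[tuple[BoldDataset, GroundTruth]]:
    """Simulate ``n_subjects`` x conditions recordings with planted mixtures.

    ``condition_specs`` is a list of ``{"condition_id": str, "weights":
    (K,)}``: the weights set the fraction of scan time each pattern
    dominates under that condition.  ``durations`` gives the scan length
    (frames) per condition; a nested sequence gives per-subject durations.
    """
    if len(condition_specs) == 0:
        raise ValueError("need at least one condition spec")
    if len(durations) != len(condition_specs):
        raise ValueError("need one duration (or per-subject list) per condition")
    if carrier_freqs is None and tr >= 2.0:
        # keep defaults below the low-TR Nyquist with separation
        carrier_freqs = [0.03, 0.07, 0.11][:n_patterns] + [
            0.11 + 0.04 * (k - 2) for k in range(3, n_patterns)
        ]
    if patterns is None:
        patterns = make_pattern_library(
            n_locations, n_patterns, seed=seed, carrier_freqs=carrier_freqs
        )
    master = np.random.default_rng(seed)
    out: list[tuple[BoldDataset, GroundTruth]] = []
    for s in range(n_subjects):
        for c, spec in enumerate(condition_specs):
            cid = spec["condition_id"]
            w = np.asarray(spec["weights"], dtype=float)
            if len(w) != len(patterns):
                raise ValueError(
                    f"condition {cid!r}: need one weight per pattern"
                )
            dur = durations[c]
            T = int(dur[s]) if np.ndim(dur) else int(dur)
            sub_seed = int(master.integers(0, 2**31 - 1))
            env_rng = np.random.default_rng(sub_seed + 7)
            env = _weights_to_envelopes(w, T, env_rng, block_len=block_len)
            # route through simulate_subject via explicit piecewise envelopes:
            # build the dataset directly from the rendered envelope array
            t = np.arange(T) * tr
            signal = np.zeros((T, len(patterns[0].magnitude_map)))
            for k, p in enumerate(patterns):
                carrier = np.cos(
                    2.0 * np.pi * p.carrier_freq * t[:, None] + p.phase_map[None, :]
                )
                signal += env[:, k, None] * p.magnitude_map[None, :] * carrier
            if noise_sd is None:
                sd = float(np.sqrt(signal.var() / snr)) if snr else 0.0
            else:
                sd = float(noise_sd)
            rng = np.random.default_rng(sub_seed)
            data = signal + (sd * rng.standard_normal(signal.shape) if sd > 0 else 0.0)
            ds = BoldDataset(
                data=data, tr=tr, subject_id=f"sub-{s:03d}", condition_id=cid
            )
            gt = GroundTruth(
                patterns=list(patterns),
                envelopes=env,
                condition_id=cid,
                noise_sd=sd,
                seed=sub_seed,
            )
            out.append((ds, gt))
    return out


def add_nuisance(
    dataset: BoldDataset,
    motion_spec: dict | None = None,
    drift_spec: dict | None = None,
    respiration_spec: dict | None = None,
    seed: int = 0,
) -> tuple[BoldDataset, MotionTrace]:
    """Add removable nuisance components and return the motion trace.

    ``motion_spec``: ``{"amplitude_mm": float, "rot_amplitude_rad": float,
    "coupling": float}`` — a smoothed random-walk 6-parameter trace plus a
    motion-coupled signal with random spatial weights.
    ``drift_spec``: ``{"order": int, "coeffs": sequence}`` — a shared
    polynomial in scan time (seconds), coefficient per order 1..order.
    ``respiration_spec``: ``{"freq_hz": float, "amplitude": float,
    "passband": (low, high)}`` — a global oscillation; a warning is raised
    when its frequency falls inside the stated analysis passband (it would
    then not be removable by the bandpass).
    """
    rng = np.random.default_rng(seed)
    T, V = dataset.data.shape
    t = np.arange(T) * dataset.tr
    data = dataset.data.copy()

    if drift_spec:
        order = int(drift_spec.get("order", 1))
        coeffs = drift_spec.get("coeffs")
        if coeffs is None:
            coeffs = [drift_spec.get("scale", 1.0)] * order
        if len(coeffs) != order:
            raise ValueError("drift_spec needs one coefficient per order 1..order")
        drift = np.zeros(T)
        for j, c in enumerate(coeffs, start=1):
            drift += c * t**j
        data += drift[:, None]

    if respiration_spec:
        f = float(respiration_spec["freq_hz"])
        amp = float(respiration_spec.get("amplitude", 1.0))
        band = respiration_spec.get("passband")
        if band is not None and band[0] <= f <= band[1]:
            warnings.warn(
                f"respiration frequency {f} Hz lies inside the analysis passband "
                f"{band}; it will not be removable by the bandpass"
            )
        phase = rng.uniform(0, 2 * np.pi)
        weights = rng.uniform(0.5, 1.0, size=V)
        data += amp * np.cos(2 * np.pi * f * t + phase)[:, None] * weights[None, :]

    if motion_spec:
        amp_mm = float(motion_spec.get("amplitude_mm", 0.1))
        amp_rad = float(motion_spec.get("rot_amplitude_rad", 0.002))
        coupling = float(motion_spec.get("coupling", 1.0))
        steps = rng.standard_normal((T, 6))
        walk = np.cumsum(steps, axis=0)
        walk = gaussian_filter1d(walk, sigma=3.0, axis=0)
        walk -= walk[0]
        sd = walk.std(axis=0)
        sd[sd == 0] = 1.0
        walk = walk / sd
        walk[:, :3] *= amp_mm
        walk[:, 3:] *= amp_rad
        trace = MotionTrace(walk)
        # motion-coupled signal: unit-scale parameters times random spatial weights
        W = rng.standard_normal((6, V))
        unit = walk / np.concatenate([np.full(3, amp_mm), np.full(3, amp_rad)])[None, :]
        data += coupling * (unit @ W) / np.sqrt(6)
    else:
        trace = MotionTrace.zeros(T)

    return dataset.with_data(data), trace
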