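"""Complex PCA of the analytic BOLD signal.

Each location's demeaned time series is lifted to its analytic
representation ``a(t) = x(t) + i H[x](t)`` (Hilbert transform in the
imaginary part).  A singular value decomposition of the resulting complex
timepoints x locations matrix yields components whose spatial loadings
carry a magnitude map (where the pattern is expressed) and a phase map
(relative timing, i.e. propagation), and whose temporal scores carry a
per-timepoint magnitude (instantaneous pattern strength) and phase
(position in the pattern's cycle).  A varimax rotation toward simple
structure, an elbow rule on the explained-variance scree, and a phase-binned
"pattern movie" reconstruction complete the decomposition stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import hilbert

from .preprocess import BoldDataset

__all__ = [
    "AnalyticDataset",
    "CpcaResult",
    "StateMagnitudes",
    "analytic_signal",
    "complex_pca",
    "varimax_complex",
    "component_magnitude_phase",
    "select_elbow",
    "reconstruct_phase_movie",
    "varimax_criterion",
]


@dataclass
class AnalyticDataset:
    """Complex analytic representation of a (demeaned) BOLD dataset."""

    data: np.ndarray  # timepoints x locations, complex
    tr: float
    source: BoldDataset | None = None
    boundaries: tuple[int, ...] = ()  # cumulative split points when concatenated

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 2:
            raise ValueError("analytic data must be 2-D")


@dataclass
class CpcaResult:
    """Complex PCA decomposition, optionally varimax-rotated.

    ``loadings`` (locations x K) have orthonormal columns before rotation;
    ``scores`` (timepoints x K) are U*S so that score magnitudes carry
    amplitude; ``scores @ loadings.conj().T`` reconstructs the analytic data
    at full rank.  ``rotation`` records the orthogonal rotation applied
    (identity if unrotated) and ``phase_convention`` the per-component
    global phase fix (zero phase at the largest-magnitude loading entry).
    """

    loadings: np.ndarray
    scores: np.ndarray
    singular_values: np.ndarray
    explained_variance_ratio: np.ndarray
    total_variance: float
    rotation: np.ndarray
    phase_convention: list[dict] = field(default_factory=list)
    rotated: bool = False
    criterion_before: float | None = None
    criterion_after: float | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class StateMagnitudes:
    """Per-timepoint magnitude and phase of every component score."""

    magnitudes: np.ndarray  # timepoints x K, nonnegative
    phases: np.ndarray  # timepoints x K, in (-pi, pi]


def analytic_signal(dataset: BoldDataset, demean: bool = True) -> AnalyticDataset:
    """Lift each location's series to its analytic (complex) representation.

    Uses the frequency-domain construction: zero the negative-frequency
    bins, double the positive ones, keep DC and Nyquist unmodified.  The
    real part of the output equals the demeaned input.
    """
    if dataset.n_timepoints < 4:
        raise ValueError("analytic signal needs at least 4 timepoints")
    x = dataset.data
    if demean:
        x = x - x.mean(axis=0, keepdims=True)
    a = hilbert(x, axis=0)
    return AnalyticDataset(data=a, tr=dataset.tr, source=dataset)


def _fix_phase(loadings: np.ndarray, scores: np.ndarray) -> list[dict]:
    """Rotate each component's global phase so its largest-magnitude loading is real positive."""
    record = []
    for k in range(loadings.shape[1]):
        idx = int(np.argmax(np.abs(loadings[:, k])))
        ang = float(np.angle(loadings[idx, k]))
        c = np.exp(-1j * ang)
        loadings[:, k] *= c
        scores[:, k] *= c
        record.append({"anchor_location": idx, "phase_removed": ang})
    return record


def complex_pca(analytic: AnalyticDataset, n_components: int) -> CpcaResult:
    """SVD-based PCA of the complex analytic matrix.

    ``X = U S V^H``; loadings are the first ``n_components`` columns of V,
    scores the corresponding columns of ``U S``, and explained-variance
    ratios ``s_k^2 / sum(s^2)`` over the full spectrum.  Components are
    ordered by nonincreasing singular value.
    """
    X = analytic.data
    max_rank = min(X.shape)
    if not (1 <= n_components <= max_rank):
        raise ValueError(
            f"n_components must be in [1, {max_rank}] for a {X.shape} matrix"
        )
    U, s, Vh = np.linalg.svd(X, full_matrices=False)
    tol = s[0] * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    if n_components > rank:
        raise ValueError(
            f"requested {n_components} components but matrix has numerical rank {rank}"
        )
    total = float(np.sum(s**2))
    loadings = Vh.conj().T[:, :n_components].copy()
    scores = (U[:, :n_components] * s[:n_components]).copy()
    record = _fix_phase(loadings, scores)
    return CpcaResult(
        loadings=loadings,
        scores=scores,
        singular_values=s[:n_components].copy(),
        explained_variance_ratio=s[:n_components] ** 2 / total,
        total_variance=total,
        rotation=np.eye(n_components),
        phase_convention=record,
    )


def varimax_criterion(loadings: np.ndarray) -> float:
    """Varimax simplicity: sum over components of the variance of squared loading magnitudes."""
    m = np.abs(loadings) ** 2
    return float(np.sum(m.var(axis=0)))


def _pair_criterion(a: np.ndarray, b: np.ndarray) -> float:
    ma = np.abs(a) ** 2
    mb = np.abs(b) ** 2
    return float(ma.var() + mb.var())


#: candidate relative phases for the unitary pair rotation (includes 0, so the
#: real-rotation optimum is always reachable exactly via Kaiser's formula)
_DELTA_GRID = np.linspace(-np.pi, np.pi, 37)[:-1]


def _best_pair_rotation(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Optimal planar unitary rotation of a complex column pair.

    The pair transforms as ``(a, b) -> (a, e^{i delta} b)`` followed by a real
    rotation by ``theta``.  For any fixed ``delta`` the squared magnitudes
    depend on ``theta`` exactly as in classical real varimax with
    ``u = |a|^2 - |b|^2`` and ``v = 2 Re(a conj(b) e^{-i delta})``, so
    Kaiser's closed-form angle applies; ``delta`` is searched on a grid
    (0 included, recovering the purely real rotation).  Returns
    ``(theta, delta, criterion)`` of the best candidate.
    """
    V = len(a)
    u = np.abs(a) ** 2 - np.abs(b) ** 2
    z = a * np.conj(b)
    A = u.sum()
    usq = float(np.sum(u**2))
    best = (0.0, 0.0, _pair_criterion(a, b))

    def evaluate(deltas):
        nonlocal best
        # vectorized over the phase candidates: v is V x D
        v = 2.0 * np.real(z[:, None] * np.exp(-1j * deltas)[None, :])
        B = v.sum(axis=0)
        C = usq - np.sum(v**2, axis=0)
        D = np.sum(2.0 * u[:, None] * v, axis=0)
        num = D - 2.0 * A * B / V
        den = C - (A**2 - B**2) / V
        theta = 0.25 * np.arctan2(num, den)
        ct, st = np.cos(theta), np.sin(theta)
        bp = b[:, None] * np.exp(1j * deltas)[None, :]
        new_a = ct[None, :] * a[:, None] + st[None, :] * bp
        new_b = -st[None, :] * a[:, None] + ct[None, :] * bp
        crit = (np.abs(new_a) ** 2).var(axis=0) + (np.abs(new_b) ** 2).var(axis=0)
        k = int(np.argmax(crit))
        if crit[k] > best[2] and not (num[k] == 0.0 and den[k] == 0.0):
            best = (float(theta[k]), float(deltas[k]), float(crit[k]))

    evaluate(_DELTA_GRID)
    # refine the phase locally: two zoom passes around the coarse optimum
    step = float(_DELTA_GRID[1] - _DELTA_GRID[0])
    for _ in range(2):
        center = best[1]
        evaluate(np.linspace(center - step, center + step, 9))
        step /= 4.0
    return best


def _varimax_rotation(
    L: np.ndarray, tolerance: float, max_iter: int
) -> tuple[np.ndarray, float, float, list[float]]:
    """Pairwise (Kaiser-style) sweeps maximizing the varimax criterion.

    Pairs of components are rotated by planar *unitary* rotations (a real
    rotation angle plus a relative phase): components that are mixed with a
    complex phase — as happens between near-degenerate singular values of
    complex data — cannot be separated by a real rotation alone.  For real
    loadings the optimal phase is 0 and the procedure reduces to the
    textbook pairwise varimax.  A pair rotation is applied only when it
    improves the criterion, so the result never falls below the unrotated
    criterion.
    """
    V, K = L.shape
    R = np.eye(K, dtype=complex)
    Lam = np.asarray(L, dtype=complex).copy()
    c0 = varimax_criterion(Lam)
    trajectory = [c0]
    prev_total = c0
    converged = False
    for _ in range(max_iter):
        for i in range(K - 1):
            for j in range(i + 1, K):
                a, b = Lam[:, i], Lam[:, j]
                theta, delta, crit = _best_pair_rotation(a, b)
                if crit > _pair_criterion(a, b) + 1e-15:
                    ct, st = np.cos(theta), np.sin(theta)
                    ph = np.exp(1j * delta)
                    new_a = ct * a + st * ph * b
                    new_b = -st * a + ct * ph * b
                    Lam[:, i], Lam[:, j] = new_a, new_b
                    G = np.eye(K, dtype=complex)
                    G[i, i] = ct
                    G[j, i] = st * ph
                    G[i, j] = -st
                    G[j, j] = ct * ph
                    R = R @ G
        total = varimax_criterion(Lam)
        trajectory.append(total)
        if total - prev_total < tolerance * max(1.0, abs(total)):
            converged = True
            break
        prev_total = total
    if not converged:
        raise RuntimeError(
            f"varimax did not converge in {max_iter} sweeps; "
            f"criterion trajectory tail {trajectory[-5:]}"
        )
    return R, c0, trajectory[-1], trajectory


def varimax_complex(
    result: CpcaResult,
    tolerance: float = 1e-10,
    max_iter: int = 1000,
    weight_by_variance: bool = True,
) -> CpcaResult:
    """Varimax-rotate a complex PCA solution toward simple structure.

    The rotation is a real orthogonal matrix maximizing the variance of
    squared loading magnitudes.  With ``weight_by_variance`` (default) the
    criterion is evaluated on variance-weighted loadings (columns scaled by
    their singular values, the factor-analytic convention), so that
    low-variance components cannot absorb high-variance structure; the
    rotation is then applied to the orthonormal loadings and the scores
    consistently (``scores @ loadings^H`` is unchanged).  Components are
    re-sorted by rotated-score variance and the per-component global phase
    convention is re-applied.
    """
    if result.rotated:
        raise ValueError("result is already rotated")
    K = result.n_components
    if K < 2:
        raise ValueError("varimax needs at least 2 components")
    result.loadings = np.asarray(result.loadings, dtype=complex)
    result.scores = np.asarray(result.scores, dtype=complex)
    L = result.loadings
    if weight_by_variance:
        L = L * result.singular_values[None, :] ** 2
    R, c_before, c_after, _ = _varimax_rotation(L, tolerance, max_iter)

    loadings = result.loadings @ R
    scores = result.scores @ R
    # re-sort by rotated score variance (descending, stable)
    var = np.sum(np.abs(scores) ** 2, axis=0)
    order = np.argsort(-var, kind="stable")
    loadings = loadings[:, order]
    scores = scores[:, order]
    var = var[order]
    record = _fix_phase(loadings, scores)
    perm = np.eye(K)[:, order]
    return CpcaResult(
        loadings=loadings,
        scores=scores,
        singular_values=np.sqrt(var),
        explained_variance_ratio=var / result.total_variance,
        total_variance=result.total_variance,
        rotation=R @ perm,
        phase_convention=record,
        rotated=True,
        criterion_before=c_before,
        criterion_after=c_after,
    )


def component_magnitude_phase(result: CpcaResult) -> StateMagnitudes:
    """Elementwise modulus and argument of the temporal scores."""
    mags = np.abs(result.scores)
    phases = np.angle(result.scores)
    phases[mags == 0] = 0.0  # phase of a zero score is 0 by convention
    return StateMagnitudes(magnitudes=mags, phases=phases)


def select_elbow(
    explained_variance_ratio: Sequence[float],
    method: str = "max_distance",
    k_override: int | None = None,
) -> int:
    """Pick the number of components to retain from the scree curve.

    ``k_override`` short-circuits the rule (the human analysis fixes 3).
    Otherwise the elbow is the point of maximum perpendicular distance from
    the chord joining the first and last scree points; ties break toward
    the smallest k.
    """
    r = np.asarray(explained_variance_ratio, dtype=float)
    n = len(r)
    if k_override is not None:
        if not (1 <= k_override <= n):
            raise ValueError(f"override {k_override} outside [1, {n}]")
        return int(k_override)
    if method != "max_distance":
        raise ValueError(f"unknown elbow method {method!r}")
    if np.any(np.diff(r) > 1e-12):
        raise ValueError("explained-variance ratios must be nonincreasing")
    if n == 1:
        return 1
    # perpendicular distance from each scree point to the first-last chord
    p1 = np.array([1.0, r[0]])
    p2 = np.array([float(n), r[-1]])
    chord = p2 - p1
    norm = np.linalg.norm(chord)
    ks = np.arange(1, n + 1, dtype=float)
    d = np.abs(chord[0] * (p1[1] - r) - (p1[0] - ks) * chord[1]) / norm
    best = float(np.max(d))
    # smallest k within numerical tie of the maximum
    k = int(np.flatnonzero(d >= best - 1e-12)[0]) + 1
    return k


def reconstruct_phase_movie(
    result: CpcaResult, component_index: int, n_bins: int = 16
) -> np.ndarray:
    """Reconstruct one pattern's cycle as ``n_bins`` frames (locations x bins).

    ``frame_b(v) = Re[loading_k(v) * exp(i * theta_b)]`` with
    ``theta_b = 2*pi*b/n_bins``; for a spatially linear phase map the peak
    advances across frames, visualizing propagation.
    """
    if not (0 <= component_index < result.n_components):
        raise ValueError(
            f"component index {component_index} outside [0, {result.n_components})"
        )
    if n_bins < 4:
        raise ValueError("need at least 4 phase bins")
    theta = 2.0 * np.pi * np.arange(n_bins) / n_bins
    l = result.loadings[:, component_index]
    return np.real(l[:, None] * np.exp(1j * theta)[None, :])
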