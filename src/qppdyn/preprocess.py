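"""Nuisance regression, bandpass projection, smoothing and QC measures.

The central preprocessing step mirrors the one-step "regress and filter"
semantics of AFNI's ``3dTProject``: polynomial trends, motion parameters and
every DFT frequency outside the passband are assembled into a single
regressor basis, and the data are replaced by the residual of a least-squares
projection onto that basis.  Doing the bandpass as frequency regressors (as
opposed to an IIR filter) makes the operation idempotent and leaves residuals
exactly orthogonal to everything removed, which is the property the
downstream complex-PCA decomposition relies on.

Quality-control measures (temporal SNR, framewise displacement, global
signal) follow the conventional definitions used to compare free-breathing
and mechanically-ventilated acquisitions.
"""

from __future__ import annotations

import warnings
from functools import lru_cache
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "BoldDataset",
    "ProjectionBasis",
    "build_projection_basis",
    "get_projection_basis",
    "project_and_filter",
    "spatial_smooth",
    "zscore_timecourses",
    "temporal_snr",
    "framewise_displacement",
    "global_signal",
]

#: full width at half maximum of a unit-variance Gaussian
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class BoldDataset:
    """A BOLD recording as a real timepoints x locations matrix.

    Parameters
    ----------
    data:
        Array of shape ``(n_timepoints, n_locations)``, arbitrary units.
    tr:
        Repetition time in seconds (sampling interval of the rows).
    mask:
        Boolean array over locations; ``None`` means all locations are
        in-brain.
    subject_id, condition_id:
        Free-form labels carried through the pipeline.
    """

    data: np.ndarray
    tr: float
    mask: np.ndarray | None = None
    subject_id: str | None = None
    condition_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (timepoints x locations)")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 timepoints")
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))
            raise ValueError(f"non-finite values at (t, v) indices {bad[:5].tolist()} ...")
        if not (self.tr > 0):
            raise ValueError("tr must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.data.shape[1],):
                raise ValueError("mask length must equal number of locations")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_locations(self) -> int:
        return self.data.shape[1]

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.tr)

    def effective_mask(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.n_locations, dtype=bool)
        return self.mask

    def with_data(self, data: np.ndarray) -> "BoldDataset":
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class ProjectionBasis:
    """Orthonormalized nuisance/stopband regressors for one dataset length.

    ``regressors`` has orthonormal columns spanning polynomial trends of
    order 0..``polort``, sine/cosine pairs for every DFT frequency strictly
    outside ``passband`` (cosine only at Nyquist), and any motion columns.
    ``removed_freqs`` / ``retained_freqs`` record the DFT frequency grid
    split for reproducibility.
    """

    regressors: np.ndarray
    passband: tuple[float, float]
    polort: int
    n_timepoints: int
    tr: float
    removed_freqs: np.ndarray
    retained_freqs: np.ndarray
    n_motion: int = 0
    raw_rank: int = field(default=0)


@lru_cache(maxsize=32)
def _cached_basis(
    n_timepoints: int, tr: float, passband: tuple[float, float], polort: int
) -> ProjectionBasis:
    return build_projection_basis(n_timepoints, tr, passband, polort, motion=None)


def get_projection_basis(
    n_timepoints: int,
    tr: float,
    passband: tuple[float, float],
    polort: int = 2,
    motion: np.ndarray | None = None,
) -> ProjectionBasis:
    """Like :func:`build_projection_basis` but memoized for motion-free bases.

    Cohort pipelines rebuild the identical basis for every subject; the
    orthonormalization is the expensive step, so motion-free bases are cached
    by (length, tr, passband, polort).
    """
    if motion is not None:
        return build_projection_basis(n_timepoints, tr, passband, polort, motion)
    return _cached_basis(int(n_timepoints), float(tr), (float(passband[0]), float(passband[1])), int(polort))


def build_projection_basis(
    n_timepoints: int,
    tr: float,
    passband: tuple[float, float],
    polort: int = 2,
    motion: np.ndarray | None = None,
) -> ProjectionBasis:
    """Assemble the one-step regression+bandpass basis.

    Frequencies on the DFT grid ``f_j = j / (n_timepoints * tr)`` with
    ``f_j < low`` or ``f_j > high`` are removed; the band is inclusive at
    both edges.  Polynomials are Legendre polynomials evaluated on a
    symmetric grid, matching the de-trending convention of AFNI's polort.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    if tr <= 0:
        raise ValueError("tr must be positive")
    low, high = float(passband[0]), float(passband[1])
    nyq = 1.0 / (2.0 * tr)
    if not (0 <= low < high):
        raise ValueError(f"passband must satisfy 0 <= low < high, got {passband}")
    if high > nyq + 1e-12:
        raise ValueError(f"passband high {high} exceeds Nyquist {nyq}")
    if polort < 0:
        raise ValueError("polort must be >= 0")

    T = int(n_timepoints)
    x = np.linspace(-1.0, 1.0, T)
    cols: list[np.ndarray] = [np.polynomial.legendre.Legendre.basis(p)(x) for p in range(polort + 1)]

    n = np.arange(T)
    j_max = T // 2
    js = np.arange(1, j_max + 1)
    freqs = js / (T * tr)
    outside = (freqs < low - 1e-12) | (freqs > high + 1e-12)
    removed = freqs[outside]
    retained = freqs[~outside]
    for j, f in zip(js[outside], removed):
        cols.append(np.cos(2.0 * np.pi * j * n / T))
        if not (T % 2 == 0 and j == T // 2):  # sine at Nyquist is identically 0
            cols.append(np.sin(2.0 * np.pi * j * n / T))

    n_motion = 0
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.ndim != 2 or motion.shape[0] != T:
            raise ValueError(
                f"motion trace must be ({T}, n_params), got {motion.shape}"
            )
        n_motion = motion.shape[1]
        cols.extend(motion[:, i] for i in range(n_motion))

    A = np.column_stack(cols)
    if A.shape[1] >= T:
        raise ValueError(
            f"basis has {A.shape[1]} columns for {T} timepoints; nothing would remain"
        )
    # SVD-based orthonormalization with rank truncation
    U, s, _ = np.linalg.svd(A, full_matrices=False)
    tol = s[0] * max(A.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    Q = U[:, :rank]
    return ProjectionBasis(
        regressors=Q,
        passband=(low, high),
        polort=polort,
        n_timepoints=T,
        tr=tr,
        removed_freqs=removed,
        retained_freqs=retained,
        n_motion=n_motion,
        raw_rank=rank,
    )


def project_and_filter(dataset: BoldDataset, basis: ProjectionBasis) -> BoldDataset:
    """Residualize each location's series against the projection basis.

    The output is orthogonal to every regressor and the operation is
    idempotent: applying it twice equals applying it once.
    """
    if basis.n_timepoints != dataset.n_timepoints:
        raise ValueError(
            f"basis built for T={basis.n_timepoints}, dataset has T={dataset.n_timepoints}"
        )
    if abs(basis.tr - dataset.tr) > 1e-9:
        raise ValueError(f"basis tr {basis.tr} != dataset tr {dataset.tr}")
    Q = basis.regressors
    if Q.shape[1] == 0:
        return dataset.with_data(dataset.data.copy())
    resid = dataset.data - Q @ (Q.T @ dataset.data)
    return dataset.with_data(resid)


def spatial_smooth(
    dataset: BoldDataset,
    fwhm: float,
    geometry_spec: Sequence[int] | None,
    spacing: float = 1.0,
) -> BoldDataset:
    """Gaussian-smooth each frame on its rectangular grid embedding.

    ``fwhm`` is in the same units as ``spacing`` (grid units by default).
    Symmetric ("reflect") boundary handling preserves the per-frame spatial
    mean.  ``fwhm=0`` is the identity.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm == 0:
        return dataset.with_data(dataset.data.copy())
    if geometry_spec is None:
        raise ValueError("spatial smoothing requires a grid geometry")
    shape = tuple(int(s) for s in geometry_spec)
    if int(np.prod(shape)) != dataset.n_locations:
        raise ValueError(
            f"geometry {shape} does not tile {dataset.n_locations} locations"
        )
    sigma = fwhm / _FWHM_PER_SIGMA / spacing
    out = np.empty_like(dataset.data)
    for t in range(dataset.n_timepoints):
        frame = dataset.data[t].reshape(shape)
        out[t] = ndimage.gaussian_filter(frame, sigma=sigma, mode="reflect").ravel()
    return dataset.with_data(out)


def zscore_timecourses(dataset: BoldDataset, ddof: int = 0) -> BoldDataset:
    """Standardize every location's time series to mean 0, variance 1."""
    mask = dataset.effective_mask()
    mean = dataset.data.mean(axis=0)
    sd = dataset.data.std(axis=0, ddof=ddof)
    degenerate = np.flatnonzero((sd <= 0) & mask)
    if degenerate.size:
        raise ValueError(
            f"zero temporal variance inside mask at locations {degenerate.tolist()}"
        )
    safe_sd = np.where(sd > 0, sd, 1.0)
    return dataset.with_data((dataset.data - mean) / safe_sd)


def temporal_snr(dataset: BoldDataset) -> tuple[np.ndarray, float]:
    """Per-location tSNR (temporal mean / temporal SD) and global-signal tSNR.

    Meaningful only on un-demeaned data; a warning is emitted when the input
    looks demeaned.  Zero-SD locations get an infinite sentinel.
    """
    mean = dataset.data.mean(axis=0)
    sd = dataset.data.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tsnr = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.inf)
    if np.any(sd <= 0):
        warnings.warn("zero temporal SD at some locations; tSNR reported as inf")
    nonzero_sd = sd[sd > 0]
    if nonzero_sd.size and np.median(np.abs(mean[sd > 0]) / nonzero_sd) < 1e-2:
        warnings.warn(
            "input appears demeaned; temporal SNR is not interpretable on demeaned data"
        )
    gs = global_signal(dataset)
    gs_sd = gs.std()
    gs_tsnr = float(gs.mean() / gs_sd) if gs_sd > 0 else float("inf")
    return tsnr, gs_tsnr


def framewise_displacement(motion: np.ndarray, head_radius_mm: float = 50.0) -> np.ndarray:
    """Power-style framewise displacement from a 6-column motion trace.

    FD(t) = sum |delta translation_i| + radius * sum |delta rotation_i|,
    translations in mm, rotations in radians; FD(0) = 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion trace must have 6 columns, got shape {motion.shape}")
    if head_radius_mm <= 0:
        raise ValueError("head radius must be positive")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def global_signal(dataset: BoldDataset, mask: np.ndarray | None = None) -> np.ndarray:
    """Frame-wise mean over masked locations."""
    if mask is None:
        mask = dataset.effective_mask()
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("mask selects no locations")
    return dataset.data[:, mask].mean(axis=1)
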