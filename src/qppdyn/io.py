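"""File I/O: datasets, motion traces, ground truth, result tables, manifests.

Datasets travel either as 4D NIfTI (locations embedded on a rectangular
grid) or as timepoints x locations TSV with a header row of location ids
and the repetition time in a JSON sidecar (``<file>.json`` with ``"tr"``).
All tables are written as TSV; the run manifest is written last and
atomically, so a manifest's presence certifies a complete run.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .preprocess import BoldDataset
from .synthetic import GroundTruth, MotionTrace

__all__ = [
    "RunConfig",
    "read_bold",
    "write_bold",
    "read_motion",
    "write_motion",
    "write_ground_truth",
    "write_outputs",
]


@dataclass
class RunConfig:
    """All stage parameters for one workflow run; round-trips through JSON/YAML."""

    workflow: str = "within_scan"
    seed: int = 0
    passband: tuple[float, float] = (0.01, 0.1)
    polort: int = 2
    smooth_fwhm: float = 0.0
    standardize: bool = True
    n_components: int = 10
    rotate: bool = True
    k_retain: int | None = 3
    dominance_pool: str = "retained"
    first_n: int = 200
    last_n: int = 200
    cluster_k_candidates: tuple[int, ...] = (2, 3, 4)
    cluster_restarts: int = 50
    bonferroni_m: int | None = None
    contrast_conditions: tuple[str, str] | None = None
    inputs: list = field(default_factory=list)
    out_dir: str = "qppdyn_out"
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["passband"] = list(self.passband)
        d["cluster_k_candidates"] = list(self.cluster_k_candidates)
        if self.contrast_conditions is not None:
            d["contrast_conditions"] = list(self.contrast_conditions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "passband" in d:
            d["passband"] = tuple(d["passband"])
        if "cluster_k_candidates" in d:
            d["cluster_k_candidates"] = tuple(d["cluster_k_candidates"])
        if d.get("contrast_conditions") is not None:
            d["contrast_conditions"] = tuple(d["contrast_conditions"])
        return cls(**d)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            yaml.safe_dump(self.to_dict(), sort_keys=True)
            if path.suffix in (".yml", ".yaml")
            else json.dumps(self.to_dict(), indent=2, sort_keys=True)
        )
        path.write_text(text)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(d)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _read_tr_sidecar(path: Path) -> float | None:
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        for key in ("tr", "RepetitionTime"):
            if key in meta:
                return float(meta[key])
    return None


def read_bold(
    path: str | Path,
    format_hint: str | None = None,
    tr: float | None = None,
    mask_path: str | Path | None = None,
) -> BoldDataset:
    """Read a dataset from 4D NIfTI or TSV (timepoints x locations)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint
    if fmt is None:
        fmt = "nifti" if "".join(path.suffixes).endswith((".nii", ".nii.gz")) else "tsv"

    if fmt == "nifti":
        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj)
        if arr.ndim != 4:
            raise ValueError(
                f"{path}: expected a 4D image (time dimension required), got {arr.ndim}D"
            )
        data = arr.reshape(-1, arr.shape[3]).T.astype(float)
        if tr is None:
            hdr_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
            tr = hdr_tr if hdr_tr > 0 else None
    else:
        try:
            frame = pd.read_csv(path, sep="\t", header=0)
        except pd.errors.ParserError as err:
            raise ValueError(f"{path}: malformed TSV ({err})") from err
        data = frame.to_numpy(dtype=float)
        if tr is None:
            tr = _read_tr_sidecar(path)

    if tr is None:
        raise ValueError(
            f"{path}: repetition time unknown; pass tr= or provide a JSON sidecar "
            "(the bandpass is meaningless without it)"
        )
    if np.isnan(data).any():
        bad = np.argwhere(np.isnan(data))
        raise ValueError(f"{path}: NaNs at (t, v) indices {bad[:5].tolist()} ...")

    mask = None
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        mask = np.asanyarray(mimg.dataobj).reshape(-1).astype(bool)
    return BoldDataset(data=data, tr=float(tr), mask=mask, subject_id=path.stem)


def write_bold(
    dataset: BoldDataset,
    path: str | Path,
    geometry: tuple[int, ...] | None = None,
) -> None:
    """Write a dataset as TSV (+ tr sidecar) or 4D NIfTI on a grid embedding."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if "".join(path.suffixes).endswith((".nii", ".nii.gz")):
        V = dataset.n_locations
        if geometry is None:
            geometry = (V, 1, 1)
        if int(np.prod(geometry)) != V:
            raise ValueError(f"geometry {geometry} does not tile {V} locations")
        vol = dataset.data.T.reshape(*geometry, dataset.n_timepoints)
        img = nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4))
        img.header.set_zooms((1.0, 1.0, 1.0, dataset.tr))
        nib.save(img, str(path))
    else:
        cols = [f"v{j:04d}" for j in range(dataset.n_locations)]
        pd.DataFrame(dataset.data, columns=cols).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps({"tr": dataset.tr})
        )


def read_motion(path: str | Path) -> MotionTrace:
    """Read a 6-column whitespace-delimited motion trace."""
    arr = np.loadtxt(path, ndmin=2)
    return MotionTrace(arr)


def write_motion(trace: MotionTrace, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, trace.params, fmt="%.8g")


def write_ground_truth(truth: GroundTruth, out_prefix: str | Path) -> None:
    """Ground truth as JSON (patterns, labels) + TSV envelope table."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "group_id": truth.group_id,
        "condition_id": truth.condition_id,
        "noise_sd": truth.noise_sd,
        "seed": truth.seed,
        "true_dominant": truth.true_dominant.tolist(),
        "patterns": [
            {
                "name": p.name,
                "carrier_freq": p.carrier_freq,
                "magnitude_map": p.magnitude_map.tolist(),
                "phase_map": p.phase_map.tolist(),
            }
            for p in truth.patterns
        ],
    }
    Path(str(out_prefix) + "_truth.json").write_text(json.dumps(meta, indent=1))
    env = pd.DataFrame(
        truth.envelopes, columns=[f"pattern_{k + 1}" for k in range(truth.n_patterns)]
    )
    env.to_csv(str(out_prefix) + "_envelopes.tsv", sep="\t", index=False)


def _file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(results: dict, out_dir: str | Path, config: RunConfig | None = None) -> dict:
    """Write result tables/arrays to ``out_dir``; manifest written last, atomically.

    ``results`` maps names to DataFrames (written as ``<name>.tsv``),
    arrays (TSV) or JSON-serializable objects (``<name>.json``).  Returns
    the manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            p = out_dir / f"{name}.tsv"
            obj.to_csv(p, sep="\t", float_format="%.10g")
        elif isinstance(obj, pd.Series):
            p = out_dir / f"{name}.tsv"
            obj.to_frame().to_csv(p, sep="\t", float_format="%.10g")
        elif isinstance(obj, np.ndarray):
            p = out_dir / f"{name}.tsv"
            np.savetxt(p, obj, fmt="%.10g", delimiter="\t")
        else:
            p = out_dir / f"{name}.json"
            p.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))
        written.append(p.name)

    manifest = {
        "files": {name: _file_sha256(out_dir / name) for name in sorted(written)},
        "config_hash": config.content_hash() if config is not None else None,
        "seed": config.seed if config is not None else None,
    }
    tmp = out_dir / ".manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    os.replace(tmp, out_dir / "manifest.json")
    return manifest
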