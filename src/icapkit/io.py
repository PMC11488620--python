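"""File I/O, motion handling, and run configuration.

Volumes travel as NIfTI-1 (via nibabel) with an identity-scaled affine,
motion as TSV with columns ``tx,ty,tz,rx,ry,rz`` (mm / radians), tables as
CSV, configuration as YAML.  Framewise displacement follows the standard
backwards-difference summary: absolute translation steps plus rotation
steps converted to arc length on a sphere of the given head radius.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .datatypes import BoldSession, MotionRecord

__all__ = [
    "framewise_displacement",
    "scrub",
    "read_motion_tsv",
    "write_motion_tsv",
    "save_session",
    "load_session",
    "save_mask",
    "load_mask",
    "RunConfig",
]

MOTION_COLUMNS = ["tx", "ty", "tz", "rx", "ry", "rz"]


def framewise_displacement(
    params: np.ndarray, head_radius: float = 50.0
) -> tuple[np.ndarray, float]:
    """FD_t = sum |delta translations| + head_radius * sum |delta rotations|.

    ``params`` is (T, 6): three translations in mm then three rotations in
    radians.  FD[0] is defined as 0; the returned mean is over t >= 1.
    """
    params = np.asarray(params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("motion parameters must have 6 columns (tx,ty,tz,rx,ry,rz)")
    if params.shape[0] < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    d = np.abs(np.diff(params, axis=0))
    fd = np.concatenate([[0.0], d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)])
    return fd, float(fd[1:].mean())


def scrub(
    session: BoldSession,
    fd: np.ndarray | None = None,
    fd_thresh: float = 0.5,
    drop_initial: int = 5,
) -> BoldSession:
    """Drop the initial volumes and mask (not delete) high-motion volumes.

    The first ``drop_initial`` volumes are removed outright (scanner
    equilibration); volumes with FD above ``fd_thresh`` are kept in place
    but flagged False in the scrub mask so downstream denominators exclude
    them without breaking the time axis.
    """
    if fd_thresh <= 0:
        raise ValueError("fd_thresh must be positive")
    if drop_initial < 0:
        raise ValueError("drop_initial must be non-negative")
    if session.n_volumes <= drop_initial:
        raise ValueError(
            f"session has {session.n_volumes} volumes, cannot drop {drop_initial}"
        )
    if fd is None:
        if session.motion is None:
            raise ValueError("no FD series available: pass fd or attach motion")
        fd = session.motion.fd
    fd = np.asarray(fd, dtype=float)[drop_initial:]
    data = session.data[..., drop_initial:]
    keep = fd <= fd_thresh
    motion = None
    if session.motion is not None:
        motion = MotionRecord(
            params=session.motion.params[drop_initial:],
            fd=fd,
            scrub_mask=keep,
        )
    else:
        motion = MotionRecord(
            params=np.zeros((data.shape[-1], 6)), fd=fd, scrub_mask=keep
        )
    return BoldSession(
        data=data,
        mask=session.mask,
        tr=session.tr,
        subject=session.subject,
        session=session.session,
        motion=motion,
    )


def read_motion_tsv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"motion TSV missing columns: {missing}")
    return df[MOTION_COLUMNS].to_numpy(dtype=float)


def write_motion_tsv(params: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(np.asarray(params, dtype=float), columns=MOTION_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def _identity_affine() -> np.ndarray:
    return np.eye(4)


def save_session(session: BoldSession, path: str | Path) -> None:
    nib.save(
        nib.Nifti1Image(session.data.astype(np.float32), _identity_affine()), str(path)
    )


def load_session(
    path: str | Path,
    mask: np.ndarray,
    tr: float,
    subject: str = "",
    session: str = "",
    motion: MotionRecord | None = None,
) -> BoldSession:
    img = nib.load(str(path))
    return BoldSession(
        data=np.asarray(img.dataobj, dtype=np.float32).astype(float),
        mask=mask,
        tr=tr,
        subject=subject,
        session=session,
        motion=motion,
    )


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), _identity_affine()), str(path))


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


@dataclass
class RunConfig:
    """All pipeline parameters; every stochastic stage has an explicit seed."""

    out_dir: str = "icapkit_out"
    seed: int = 0
    # cohort simulation
    n_subjects: int = 32
    n_networks: int = 8
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    n_volumes: int = 105
    tr: float = 2.0
    noise_sd: float = 0.5
    effect_networks: tuple[int, ...] = (0, 1, 2, 3)
    delta_mean_pct: float = 10.0
    delta_sd_pct: float = 3.0
    clinical_effect: float = -0.8
    clinical_noise_sd: float = 2.0
    # motion / scrubbing
    fd_thresh: float = 0.5
    head_radius: float = 50.0
    drop_initial: int = 5
    # deconvolution
    lam_scale: float = 0.5
    max_iter: int = 500
    tol: float = 1e-5
    # transient selection & clustering
    percentile: float = 95.0
    min_active_frac: float = 0.01
    n_clusters: int = 8
    k_range: tuple[int, int] = (5, 15)
    n_replicates: int = 20
    n_resamples: int = 30
    subsample_frac: float = 0.8
    run_consensus: bool = False
    # temporal metrics
    z_thresh: float = 1.0
    # PLSC
    n_perm: int = 1000
    n_boot: int = 500

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for key in ("grid_shape", "effect_networks", "k_range"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("grid_shape", "effect_networks", "k_range"):
            if key in d:
                d[key] = tuple(d[key])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.seed is None:
            raise ValueError("config must set a seed")
        return cfg

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for key in ("grid_shape", "effect_networks", "k_range"):
            d[key] = list(d[key])
        return json.dumps(d, indent=2, sort_keys=True)
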