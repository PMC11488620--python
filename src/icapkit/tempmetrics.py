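"""Per-subject iCAP time courses and their temporal properties.

Each iCAP's time course is recovered by regressing, at every time point,
the subject's activity-inducing map on the K spatial z-maps (both
mean-centred over the mask) — a per-timepoint back-projection of the
networks into the deconvolved signals.  Thresholding the z-normalised
course yields a signed activation train from which four families of
properties follow: total duration (percent of non-scrubbed time active),
occurrences (number of activation blocks), and coupling / anticoupling
(Jaccard fraction of time two iCAPs are jointly active with the same or
opposite sign).  A static inter-iCAP Pearson correlation over non-scrubbed
volumes is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ICAPTimeCourses",
    "TemporalMetrics",
    "transient_informed_regression",
    "binarize_blocks",
    "total_duration",
    "occurrences",
    "coupling_jaccard",
    "static_correlation",
    "compute_metrics",
    "metrics_frame",
    "pair_index",
]


@dataclass
class ICAPTimeCourses:
    """K x T activation amplitudes for one subject-session."""

    raw: np.ndarray  # (K, T) regression coefficients
    z: np.ndarray  # per-iCAP z-normalised over time
    blocks: np.ndarray | None = None  # signed train after thresholding
    scrub_mask: np.ndarray | None = None
    subject: str = ""
    session: str = ""


@dataclass
class TemporalMetrics:
    """Temporal properties of one subject-session.

    duration : per iCAP, % of non-scrubbed volumes active.
    occurrences : per iCAP, count of maximal same-sign activation blocks.
    coupling / anticoupling : (K, K) symmetric Jaccard matrices.
    """

    duration: np.ndarray
    occurrences: np.ndarray
    coupling: np.ndarray
    anticoupling: np.ndarray
    subject: str = ""
    session: str = ""


def transient_informed_regression(
    zmaps: np.ndarray,
    activity: np.ndarray,
    cond_limit: float = 1e8,
    norm_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Back-project spatial maps into activity signals, one OLS per time point.

    ``zmaps`` is (K, V), ``activity`` (V, T); both are mean-centred over
    voxels before the fit.  Returns ``(raw, z)`` time courses of shape
    (K, T); ``z`` is each course standardised over time, with the mean/SD
    taken over ``norm_mask`` volumes when given (so scrubbed or boundary
    volumes cannot distort the activation threshold).  A near-collinear
    map pair raises a conditioning error naming the offending pair.
    """
    zmaps = np.asarray(zmaps, dtype=float)
    activity = np.asarray(activity, dtype=float)
    if zmaps.shape[1] != activity.shape[0]:
        raise ValueError("zmaps and activity must share the voxel axis")
    x = zmaps.T - zmaps.T.mean(axis=0, keepdims=True)  # (V, K)
    y = activity - activity.mean(axis=0, keepdims=True)  # (V, T)
    gram = x.T @ x
    if np.linalg.cond(gram) > cond_limit:
        corr = np.corrcoef(zmaps)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"zmaps are rank deficient: maps {min(i, j)} and {max(i, j)} "
            f"are collinear (|r| = {abs(corr[i, j]):.3f})"
        )
    raw = np.linalg.solve(gram, x.T @ y)  # (K, T)
    stat = raw if norm_mask is None else raw[:, np.asarray(norm_mask, dtype=bool)]
    sd = stat.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (raw - stat.mean(axis=1, keepdims=True)) / sd
    return raw, z


def binarize_blocks(
    z_courses: np.ndarray,
    z_thresh: float = 1.0,
    scrub_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Signed activation train: +1 where z > thresh, -1 where z < -thresh.

    Scrubbed volumes are forced to zero (and are excluded from duration
    denominators downstream).
    """
    if z_thresh <= 0:
        raise ValueError("z_thresh must be positive")
    z_courses = np.atleast_2d(np.asarray(z_courses, dtype=float))
    blocks = np.zeros_like(z_courses, dtype=int)
    blocks[z_courses > z_thresh] = 1
    blocks[z_courses < -z_thresh] = -1
    if scrub_mask is not None:
        blocks[:, ~np.asarray(scrub_mask, dtype=bool)] = 0
    return blocks


def total_duration(blocks: np.ndarray, scrub_mask: np.ndarray | None = None) -> np.ndarray:
    """Percent of non-scrubbed volumes with a nonzero train."""
    blocks = np.atleast_2d(np.asarray(blocks))
    if scrub_mask is None:
        scrub_mask = np.ones(blocks.shape[1], dtype=bool)
    scrub_mask = np.asarray(scrub_mask, dtype=bool)
    denom = int(scrub_mask.sum())
    if denom == 0:
        raise ZeroDivisionError("all volumes scrubbed: duration undefined")
    active = (blocks[:, scrub_mask] != 0).sum(axis=1)
    return 100.0 * active / denom


def occurrences(blocks: np.ndarray) -> np.ndarray:
    """Number of maximal runs of same-sign nonzero values per train.

    A sign change without an intervening zero starts a new block.
    """
    blocks = np.atleast_2d(np.asarray(blocks))
    prev = np.concatenate([np.zeros((blocks.shape[0], 1), dtype=blocks.dtype), blocks[:, :-1]], axis=1)
    starts = (blocks != 0) & (blocks != prev)
    return starts.sum(axis=1)


def coupling_jaccard(blocks_i: np.ndarray, blocks_j: np.ndarray) -> tuple[float, float]:
    """Jaccard fractions of same-signed and opposite-signed joint activation.

    Denominator is the union of active time of the two trains; both
    fractions are 0 when the union is empty.
    """
    a = np.asarray(blocks_i).ravel()
    b = np.asarray(blocks_j).ravel()
    if a.shape != b.shape:
        raise ValueError("trains must have equal length")
    union = int(((a != 0) | (b != 0)).sum())
    if union == 0:
        return 0.0, 0.0
    both = (a != 0) & (b != 0)
    same = int((both & (a == b)).sum())
    opp = int((both & (a == -b)).sum())
    return same / union, opp / union


def static_correlation(raw_courses: np.ndarray, scrub_mask: np.ndarray | None = None) -> np.ndarray:
    """Pearson correlation of raw courses over non-scrubbed volumes.

    Zero-variance courses yield NaN rows/columns (flagged, not raised);
    the diagonal is 1 wherever defined.
    """
    raw = np.atleast_2d(np.asarray(raw_courses, dtype=float))
    if scrub_mask is not None:
        raw = raw[:, np.asarray(scrub_mask, dtype=bool)]
    if raw.shape[1] < 3:
        raise ValueError("need at least 3 volumes for a correlation")
    sd = raw.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(raw)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, np.where(sd == 0, np.nan, 1.0))
    return corr


def compute_metrics(
    blocks: np.ndarray,
    scrub_mask: np.ndarray | None = None,
    subject: str = "",
    session: str = "",
) -> TemporalMetrics:
    """All temporal properties of one subject-session's signed trains."""
    blocks = np.atleast_2d(np.asarray(blocks))
    k = blocks.shape[0]
    coup = np.zeros((k, k))
    anti = np.zeros((k, k))
    for i in range(k):
        ci, _ = coupling_jaccard(blocks[i], blocks[i])
        coup[i, i] = ci
        for j in range(i + 1, k):
            c, a = coupling_jaccard(blocks[i], blocks[j])
            coup[i, j] = coup[j, i] = c
            anti[i, j] = anti[j, i] = a
    return TemporalMetrics(
        duration=total_duration(blocks, scrub_mask),
        occurrences=occurrences(blocks),
        coupling=coup,
        anticoupling=anti,
        subject=subject,
        session=session,
    )


def pair_index(k: int) -> list[tuple[int, int]]:
    """Upper-triangle pair ordering (i < j, row-major): K*(K-1)/2 entries."""
    return [(i, j) for i in range(k) for j in range(i + 1, k)]


def metrics_frame(metrics: list[TemporalMetrics]) -> pd.DataFrame:
    """Tidy CSV layout: subject,session,icap_i,icap_j,metric,value.

    ``icap_j`` is empty (NA) for the unary metrics; pairs are ordered
    upper-triangle row-major.
    """
    rows = []
    for m in metrics:
        k = len(m.duration)
        for i in range(k):
            rows.append((m.subject, m.session, i, pd.NA, "duration", m.duration[i]))
            rows.append((m.subject, m.session, i, pd.NA, "occurrences", int(m.occurrences[i])))
        for i, j in pair_index(k):
            rows.append((m.subject, m.session, i, j, "coupling", m.coupling[i, j]))
            rows.append((m.subject, m.session, i, j, "anticoupling", m.anticoupling[i, j]))
    return pd.DataFrame(
        rows, columns=["subject", "session", "icap_i", "icap_j", "metric", "value"]
    )
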