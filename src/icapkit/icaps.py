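"""Transient selection and clustering into innovation-driven coactivation patterns.

Volumes whose innovation map shows enough suprathreshold voxels are kept as
*transient frames*; frames are pooled across subjects and sessions and fed
to a k-means variant operating on cosine distance that treats a frame and
its negation as the same pattern (a deactivation transient of a network is
the same network).  The number of clusters is chosen by consensus
clustering: repeated clustering of random frame subsamples, scored by how
consistently pairs of frames land in the same cluster.  Cluster means of
sign-aligned frames, z-scored over the mask, are the spatial iCAP maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import InnovationSet

__all__ = [
    "TransientFrameSet",
    "ICAPSet",
    "ConsensusResult",
    "select_transients",
    "kmeans_transients",
    "partition_objective",
    "consensus_select_K",
    "build_zmaps",
    "region_report",
]


@dataclass
class TransientFrameSet:
    """Signed innovation snapshots that passed the significance rule.

    frames : (F, V) matrix; provenance: one (subject, session, volume)
    triple per frame; threshold_used: per-subject |innovation| threshold.
    """

    frames: np.ndarray
    provenance: list[tuple[str, str, int]]
    threshold_used: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.provenance) != len(self.frames):
            raise ValueError("one provenance triple per frame required")
        if len(set(self.provenance)) != len(self.provenance):
            raise ValueError("provenance entries must be unique")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class ICAPSet:
    """K spatial z-maps with per-frame cluster labels and sign flips."""

    zmaps: np.ndarray  # (K, V), z-scored over the mask
    labels: np.ndarray  # cluster id per frame, 0..K-1
    signs: np.ndarray  # +1 / -1 alignment applied to each frame
    centroid_norms: np.ndarray
    mask: np.ndarray | None = None

    @property
    def K(self) -> int:
        return self.zmaps.shape[0]


@dataclass
class ConsensusResult:
    """Consensus-clustering diagnostics over a range of K."""

    k_range: list[int]
    consensus: dict[int, np.ndarray]  # (F, F), NaN where never co-sampled
    cluster_mean_consensus: dict[int, np.ndarray]  # per-cluster means
    mean_consensus: dict[int, float]  # mean over clusters
    selected_K: int


def select_transients(
    innovation_sets: list[InnovationSet] | InnovationSet,
    percentile: float = 95.0,
    min_active_voxels: int | None = None,
    pooled: bool = False,
) -> TransientFrameSet:
    """Keep volumes with enough significant innovation activity.

    The |innovation| threshold is the given percentile of each subject's
    pooled innovation values (or pooled over all subjects when
    ``pooled=True``).  A volume survives if at least ``min_active_voxels``
    voxels exceed the threshold (default: 1% of the voxel count) and it is
    not motion-scrubbed.  Surviving frames keep their signs.
    """
    if isinstance(innovation_sets, InnovationSet):
        innovation_sets = [innovation_sets]
    if not 50.0 < percentile < 100.0:
        raise ValueError("percentile must lie in (50, 100)")

    by_subject: dict[str, list[InnovationSet]] = {}
    for inn in innovation_sets:
        by_subject.setdefault(inn.subject, []).append(inn)

    pooled_thr: float | None = None
    if pooled:
        allv = np.concatenate(
            [np.abs(i.innovations[:, 1:]).ravel() for i in innovation_sets]
        )
        pooled_thr = float(np.percentile(allv, percentile))

    frames: list[np.ndarray] = []
    prov: list[tuple[str, str, int]] = []
    thr_used: dict[str, float] = {}
    for subject, sets in by_subject.items():
        if pooled_thr is None:
            vals = np.concatenate([np.abs(i.innovations[:, 1:]).ravel() for i in sets])
            thr = float(np.percentile(vals, percentile))
        else:
            thr = pooled_thr
        thr_used[subject] = thr
        for inn in sets:
            min_act = min_active_voxels
            if min_act is None:
                min_act = max(1, int(round(0.01 * inn.n_voxels)))
            keep = inn.scrub_mask
            if keep is None:
                keep = np.ones(inn.n_volumes, dtype=bool)
            counts = (np.abs(inn.innovations) > thr).sum(axis=0)
            for t in range(1, inn.n_volumes):
                if keep[t] and counts[t] >= min_act:
                    frames.append(inn.innovations[:, t].copy())
                    prov.append((subject, inn.session, t))
    if not frames:
        warnings.warn("no transient frame passed the significance rule", stacklevel=2)
        n_vox = innovation_sets[0].n_voxels
        return TransientFrameSet(
            frames=np.empty((0, n_vox)), provenance=[], threshold_used=thr_used
        )
    return TransientFrameSet(
        frames=np.array(frames), provenance=prov, threshold_used=thr_used
    )


def _normalise(frames: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(frames, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-norm frame cannot be clustered")
    return frames / norms


def _assign(fn: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Sign-invariant cosine assignment; lowest index wins exact ties."""
    sims = fn @ centroids.T
    a = np.abs(sims)
    labels = np.argmax(a, axis=1)  # argmax returns the first (lowest) maximiser
    chosen = a[np.arange(len(fn)), labels]
    signs = np.sign(sims[np.arange(len(fn)), labels])
    signs[signs == 0] = 1.0
    return labels, signs, float(np.sum(1.0 - chosen))


def _kmeans_once(
    fn: np.ndarray, k: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    n = len(fn)
    # k-means++ seeding under d = 1 - |cos|
    centroids = [fn[rng.integers(n)]]
    for _ in range(k - 1):
        d = np.clip(np.min(1.0 - np.abs(fn @ np.array(centroids).T), axis=1), 0.0, None)
        probs = d / d.sum() if d.sum() > 0 else np.full(n, 1.0 / n)
        centroids.append(fn[rng.choice(n, p=probs)])
    cents = np.array(centroids)

    labels = np.full(n, -1)
    for _ in range(max_iter):
        new_labels, signs, obj = _assign(fn, cents)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            mem = labels == j
            if not mem.any():
                # re-seed an empty cluster at the worst-fit frame
                worst = np.argmin(np.abs(fn @ cents.T).max(axis=1))
                cents[j] = fn[worst]
                continue
            c = (signs[mem, None] * fn[mem]).sum(axis=0)
            nrm = np.linalg.norm(c)
            cents[j] = c / nrm if nrm > 0 else fn[np.flatnonzero(mem)[0]]
    labels, signs, obj = _assign(fn, cents)
    return labels, signs, cents, obj


def kmeans_transients(
    frames: np.ndarray,
    k: int,
    n_replicates: int = 20,
    seed: int | None = None,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sign-invariant cosine k-means; best of ``n_replicates`` by dispersion.

    Returns ``(labels, signs, centroids)``: cluster id per frame, the sign
    flip aligning each frame to its centroid, and unit-norm centroids.
    Deterministic given ``seed``.
    """
    frames = np.asarray(frames, dtype=float)
    if len(frames) < k:
        raise ValueError(f"{len(frames)} frames cannot support K={k}")
    fn = _normalise(frames)
    if k ** len(frames) <= 2048:
        # tiny instance: enumerate every partition for the global optimum
        from itertools import product

        best_obj = np.inf
        labels = None
        for assignment in product(range(k), repeat=len(frames)):
            if len(set(assignment)) < k:
                continue
            obj = partition_objective(frames, np.array(assignment), k)
            if obj < best_obj - 1e-12:
                best_obj, labels = obj, np.array(assignment)
    else:
        rng = np.random.default_rng(seed)
        best: tuple | None = None
        for _ in range(max(1, n_replicates)):
            lab, sgn, cents, obj = _kmeans_once(fn, k, rng, max_iter)
            if best is None or obj < best[3] - 1e-12:
                best = (lab, sgn, cents, obj)
        labels = best[0]
    # final centroids and member signs for the chosen partition
    cents = np.zeros((k, fn.shape[1]))
    signs = np.ones(len(fn))
    for j in range(k):
        mem_idx = np.flatnonzero(labels == j)
        cents[j] = _aligned_centroid(fn[mem_idx])
        s = np.sign(fn[mem_idx] @ cents[j])
        s[s == 0] = 1.0
        signs[mem_idx] = s
    return labels, signs.astype(int), cents


def _aligned_centroid(mem: np.ndarray) -> np.ndarray:
    """Sign-aligned centroid: alternate sign flips and the normalised
    signed mean to a fixed point (the k-means centroid update rule)."""
    if len(mem) == 0:
        raise ValueError("empty cluster has no centroid")
    signs = np.ones(len(mem))
    c = mem[0]
    for _ in range(100):
        c = (signs[:, None] * mem).sum(axis=0)
        nrm = np.linalg.norm(c)
        c = c / nrm if nrm > 0 else mem[0]
        new_signs = np.sign(mem @ c)
        new_signs[new_signs == 0] = 1.0
        if np.array_equal(new_signs, signs):
            break
        signs = new_signs
    return c


def partition_objective(frames: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Dispersion sum(1 - |cos(frame, centroid)|) for a fixed partition.

    Per cluster, the sign-aligned centroid is the same fixed point the
    k-means update converges to, so objectives are comparable across any
    labelling of the same frames.
    """
    fn = _normalise(np.asarray(frames, dtype=float))
    total = 0.0
    for j in range(k):
        mem = fn[labels == j]
        if len(mem) == 0:
            continue
        c = _aligned_centroid(mem)
        total += float(np.sum(1.0 - np.abs(mem @ c)))
    return total


def consensus_select_K(
    frames: np.ndarray,
    k_range: list[int] | range,
    n_resamples: int = 30,
    subsample_frac: float = 0.8,
    seed: int | None = None,
    n_replicates: int = 5,
) -> ConsensusResult:
    """Choose K by consensus over repeated clustering of frame subsamples.

    consensus[i, j] = (#times i and j co-clustered) / (#times co-sampled);
    pairs never co-sampled are NaN and excluded from means.  The selected K
    maximises the mean over clusters (from a full-data clustering at that
    K) of the within-cluster mean consensus.
    """
    frames = np.asarray(frames, dtype=float)
    n = len(frames)
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty K range")
    if max(k_range) > n // 2 or min(k_range) < 2:
        raise ValueError("K range must lie within [2, n_frames/2]")
    rng = np.random.default_rng(seed)

    consensus: dict[int, np.ndarray] = {}
    cluster_means: dict[int, np.ndarray] = {}
    mean_cons: dict[int, float] = {}
    for k in k_range:
        together = np.zeros((n, n))
        cosampled = np.zeros((n, n))
        for _ in range(n_resamples):
            m = max(k, int(round(subsample_frac * n)))
            idx = rng.choice(n, size=m, replace=False)
            labels, _, _ = kmeans_transients(
                frames[idx], k, n_replicates=n_replicates,
                seed=int(rng.integers(2**31)),
            )
            cosampled[np.ix_(idx, idx)] += 1
            for j in range(k):
                mem = idx[labels == j]
                together[np.ix_(mem, mem)] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            cons = np.where(cosampled > 0, together / np.maximum(cosampled, 1), np.nan)
        consensus[k] = cons

        full_labels, _, _ = kmeans_transients(
            frames, k, n_replicates=n_replicates, seed=int(rng.integers(2**31))
        )
        per_cluster = []
        for j in range(k):
            mem = np.flatnonzero(full_labels == j)
            vals = [
                cons[a, b]
                for a, b in combinations(mem, 2)
                if np.isfinite(cons[a, b])
            ]
            per_cluster.append(float(np.mean(vals)) if vals else np.nan)
        cluster_means[k] = np.array(per_cluster)
        mean_cons[k] = float(np.nanmean(cluster_means[k]))

    selected = max(k_range, key=lambda k: (mean_cons[k], -k))
    return ConsensusResult(
        k_range=k_range,
        consensus=consensus,
        cluster_mean_consensus=cluster_means,
        mean_consensus=mean_cons,
        selected_K=selected,
    )


def build_zmaps(
    frames: np.ndarray,
    labels: np.ndarray,
    signs: np.ndarray,
    mask: np.ndarray | None = None,
) -> ICAPSet:
    """Average sign-aligned member frames per cluster and z-score over the mask."""
    frames = np.asarray(frames, dtype=float)
    labels = np.asarray(labels)
    signs = np.asarray(signs, dtype=float)
    k = int(labels.max()) + 1
    zmaps = np.zeros((k, frames.shape[1]))
    norms = np.zeros(k)
    for j in range(k):
        mem = labels == j
        if not mem.any():
            raise RuntimeError(f"cluster {j} is empty (invariant breach)")
        m = (signs[mem, None] * frames[mem]).mean(axis=0)
        norms[j] = np.linalg.norm(m)
        sd = m.std()
        if sd == 0:
            raise RuntimeError(f"cluster {j} mean map has zero variance")
        zmaps[j] = (m - m.mean()) / sd
    return ICAPSet(zmaps=zmaps, labels=labels, signs=signs.astype(int),
                   centroid_norms=norms, mask=mask)


def region_report(
    icapset: ICAPSet,
    region_labels: np.ndarray,
    z_thresh: float = 2.0,
    min_frac: float = 0.20,
) -> pd.DataFrame:
    """Regions covered by each iCAP at |z| > ``z_thresh``.

    ``region_labels`` assigns an integer region id to each in-mask voxel
    (0 = unlabelled).  A region is listed for an iCAP when more than
    ``min_frac`` of its voxels exceed the threshold.
    """
    region_labels = np.asarray(region_labels).ravel()
    if len(region_labels) != icapset.zmaps.shape[1]:
        raise ValueError("region labelling must cover the in-mask voxels")
    rows = []
    for k in range(icapset.K):
        hot = np.abs(icapset.zmaps[k]) > z_thresh
        for reg in np.unique(region_labels):
            if reg == 0:
                continue
            in_reg = region_labels == reg
            frac = float(hot[in_reg].mean())
            if frac > min_frac:
                rows.append({"icap": k, "region": int(reg), "fraction": frac})
    return pd.DataFrame(rows, columns=["icap", "region", "fraction"])
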