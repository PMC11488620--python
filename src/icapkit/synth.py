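"""Synthetic paired-session fMRI cohorts with planted ground truth.

The generator emulates the statistical structure of a pre/post
mindfulness-intervention resting-state study: each subject contributes two
sessions; large-scale networks switch on and off in blocks; the BOLD signal
is the haemodynamic convolution of those block trains plus Gaussian noise;
head motion occasionally spikes and the affected volumes are scrubbed; a
subset of "effect" networks has its activation duration shifted upward in
the second session by a per-subject amount delta_s; and a subset of
clinical change scores is linearly coupled to that shift.  All planted
quantities are recorded so downstream recovery can be scored exactly.

Defaults mirror the emulated study design: 32 subjects, 8 networks,
105 volumes at TR 2 s (of which the first 5 are dropped downstream),
4 effect networks, and 5 clinical scores of which 3 carry the planted
coupling (negatively signed: symptom scores fall as network engagement
rises) alongside gestational age and age at assessment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import BoldSession, MotionRecord, NetworkAtlas, PlantedTruth
from .deconv import hrf_kernel
from .io import framewise_displacement

__all__ = [
    "make_network_atlas",
    "simulate_block_activity",
    "simulate_bold",
    "simulate_motion",
    "simulate_cohort",
    "Cohort",
    "CLINICAL_SCORES",
    "PLANTED_SCORES",
]

#: clinical change scores carried in the cohort table; the first three are
#: coupled to the planted duration shift (negative sign: difficulty scores
#: decrease when network engagement increases), the last two are null.
CLINICAL_SCORES = ("brief_gec", "brief_mi", "brief_bri", "sdq_total", "self_compassion")
PLANTED_SCORES = ("brief_gec", "brief_mi", "brief_bri")

_NEIGHBOURS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def make_network_atlas(
    n_networks: int,
    grid_shape: tuple[int, int, int],
    overlap_frac: float = 0.0,
    seed: int | None = None,
    target_size: int | None = None,
) -> NetworkAtlas:
    """Place ``n_networks`` contiguous blobs on a 3D lattice.

    Blobs are grown by seeded breadth-first search from well-separated
    seed voxels; a voxel already claimed by another network may be shared
    only while the pairwise shared fraction (relative to the smaller blob)
    stays at or below ``overlap_frac``.
    """
    if n_networks < 2:
        raise ValueError("need at least 2 networks")
    grid_shape = tuple(int(g) for g in grid_shape)
    volume = int(np.prod(grid_shape))
    if volume < 10 * n_networks:
        raise ValueError(
            f"grid of {volume} voxels too small for {n_networks} networks "
            f"(need >= {10 * n_networks})"
        )
    rng = np.random.default_rng(seed)
    if target_size is None:
        target_size = max(10, volume // (3 * n_networks))
    coords = np.argwhere(np.ones(grid_shape, dtype=bool))

    # seeds: greedy farthest-point sampling from a random start
    seeds = [coords[rng.integers(len(coords))]]
    for _ in range(n_networks - 1):
        d = np.min(
            [np.abs(coords - s).sum(axis=1) for s in seeds], axis=0
        )
        best = np.flatnonzero(d == d.max())
        seeds.append(coords[rng.choice(best)])

    members: list[set[tuple[int, int, int]]] = [
        {tuple(int(c) for c in s)} for s in seeds
    ]
    frontiers = [[tuple(int(c) for c in s)] for s in seeds]
    shared = np.zeros((n_networks, n_networks), dtype=int)

    def can_share(k: int, vox: tuple[int, int, int]) -> bool:
        for j in range(n_networks):
            if j != k and vox in members[j]:
                if overlap_frac <= 0:
                    return False
                if (shared[k, j] + 1) > overlap_frac * target_size:
                    return False
        return True

    active = True
    while active:
        active = False
        order = rng.permutation(n_networks)
        for k in order:
            if len(members[k]) >= target_size or not frontiers[k]:
                continue
            idx = rng.integers(len(frontiers[k]))
            base = frontiers[k].pop(idx)
            for off in rng.permutation(6):
                vox = tuple(np.array(base) + _NEIGHBOURS[off])
                if any(v < 0 or v >= g for v, g in zip(vox, grid_shape)):
                    continue
                if vox in members[k] or not can_share(k, vox):
                    continue
                members[k].add(vox)
                frontiers[k].append(vox)
                for j in range(n_networks):
                    if j != k and vox in members[j]:
                        shared[k, j] += 1
                        shared[j, k] += 1
                break
            else:
                continue
            frontiers[k].append(base)
            active = True

    maps = np.zeros((n_networks,) + grid_shape)
    for k, mem in enumerate(members):
        for vox in mem:
            maps[k][vox] = 1.0
    return NetworkAtlas(maps=maps)


def simulate_block_activity(
    n_volumes: int,
    rate: float,
    block_len_range: tuple[int, int],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    target_duration_pct: float | None = None,
    n_blocks: int | None = None,
    min_gap: int = 3,
) -> PlantedTruth:
    """Draw one network's binary block train.

    ``rate`` is the expected number of activation blocks per 100 volumes;
    block lengths are uniform over ``block_len_range`` (inclusive).  If
    ``target_duration_pct`` is given, block lengths are adjusted so the
    active fraction hits the target exactly (to the nearest volume),
    overriding ``rate``; with ``n_blocks`` also given the block *count* is
    held fixed and only lengths absorb the target — which is how a paired
    cohort plants a duration change without touching occurrence counts.
    Blocks are separated by at least ``min_gap`` silent volumes (default 3,
    about one HRF rise time at TR 2 s, so that distinct activations stay
    resolvable after haemodynamic blurring); infeasible demands raise a
    placement error.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    lo, hi = int(block_len_range[0]), int(block_len_range[1])
    if lo < 1 or hi < lo:
        raise ValueError("invalid block length range")
    if n_volumes <= hi:
        raise ValueError("n_volumes must exceed the maximum block length")

    if target_duration_pct is not None:
        target = int(round(target_duration_pct / 100.0 * n_volumes))
        if n_blocks is not None:
            if n_blocks < 1 or target < n_blocks * lo:
                raise ValueError("block count infeasible for the target duration")
            base, rem = divmod(target, n_blocks)
            lengths = [base + (1 if i < rem else 0) for i in range(n_blocks)]
            # jitter lengths while conserving the total and the minimum
            for _ in range(2 * n_blocks):
                i, j = rng.integers(0, n_blocks, size=2)
                if lengths[i] > lo:
                    lengths[i] -= 1
                    lengths[j] += 1
        else:
            lengths = []
            while sum(lengths) < target:
                lengths.append(int(rng.integers(lo, hi + 1)))
            if lengths and sum(lengths) > target:
                excess = sum(lengths) - target
                if lengths[-1] > excess:
                    lengths[-1] -= excess
                else:
                    lengths.pop()
    else:
        n_blocks = int(round(rate * n_volumes / 100.0))
        lengths = [int(rng.integers(lo, hi + 1)) for _ in range(n_blocks)]

    total = sum(lengths) + min_gap * max(0, len(lengths) - 1)
    if total > n_volumes:
        raise ValueError(
            f"cannot place {len(lengths)} blocks totalling {sum(lengths)} "
            f"active volumes in {n_volumes} volumes"
        )

    train = np.zeros(n_volumes, dtype=float)
    onsets: list[int] = []
    offsets: list[int] = []
    if lengths:
        slack = n_volumes - total
        # distribute slack among the n_blocks+1 gaps (before, between, after)
        cuts = np.sort(rng.integers(0, slack + 1, size=len(lengths)))
        pos = 0
        prev_cut = 0
        for i, ln in enumerate(lengths):
            pos += int(cuts[i]) - prev_cut + (min_gap if i > 0 else 0)
            prev_cut = int(cuts[i])
            onsets.append(pos)
            offsets.append(pos + ln)
            train[pos : pos + ln] = 1.0
            pos += ln
    duration_pct = 100.0 * train.sum() / n_volumes
    return PlantedTruth(
        trains=train[None, :],
        block_onsets=[np.array(onsets, dtype=int)],
        block_offsets=[np.array(offsets, dtype=int)],
        planted_duration_pct=np.array([duration_pct]),
        seed=-1 if seed is None else seed,
    )


def _stack_truths(truths: list[PlantedTruth], seed: int) -> PlantedTruth:
    return PlantedTruth(
        trains=np.vstack([t.trains for t in truths]),
        block_onsets=[t.block_onsets[0] for t in truths],
        block_offsets=[t.block_offsets[0] for t in truths],
        planted_duration_pct=np.concatenate([t.planted_duration_pct for t in truths]),
        seed=seed,
    )


def simulate_bold(
    atlas: NetworkAtlas,
    trains: np.ndarray,
    tr: float = 2.0,
    noise_sd: float = 0.5,
    hrf_params: dict | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    subject: str = "",
    session: str = "",
) -> BoldSession:
    """Forward model: voxel series = sum_k weight_k * (train_k * HRF) + noise.

    The session mask is the whole lattice — background voxels carry pure
    noise, as out-of-network brain does.  With ``noise_sd=0`` the output is
    exactly the noiseless superposition, which the deconvolution stage
    should invert up to the solver tolerance.
    """
    trains = np.atleast_2d(np.asarray(trains, dtype=float))
    if trains.shape[0] != atlas.n_networks:
        raise ValueError("one train per network required")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_vol = trains.shape[1]
    kernel = hrf_kernel(tr, **(hrf_params or {}))
    conv = np.array([np.convolve(t, kernel)[:n_vol] for t in trains])
    flat_maps = atlas.maps.reshape(atlas.n_networks, -1)
    data = (flat_maps.T @ conv).reshape(atlas.grid_shape + (n_vol,))
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return BoldSession(
        data=data,
        mask=np.ones(atlas.grid_shape, dtype=bool),
        tr=tr,
        subject=subject,
        session=session,
    )


def simulate_motion(
    n_volumes: int,
    spike_prob: float = 0.02,
    spike_mm: float = 1.0,
    base_sd_mm: float = 0.02,
    fd_thresh: float = 0.5,
    head_radius: float = 50.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> MotionRecord:
    """Random-walk rigid-body motion with occasional displacement spikes."""
    if rng is None:
        rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, base_sd_mm, size=(n_volumes, 6))
    steps[:, 3:] /= head_radius  # comparable angular scale
    spikes = rng.random(n_volumes) < spike_prob
    spikes[0] = False
    steps[spikes, 0] += spike_mm * rng.choice([-1.0, 1.0], size=spikes.sum())
    params = np.cumsum(steps, axis=0)
    fd, _ = framewise_displacement(params, head_radius=head_radius)
    return MotionRecord(params=params, fd=fd, scrub_mask=fd <= fd_thresh)


@dataclass
class Cohort:
    """A paired-session synthetic cohort plus its planted ground truth."""

    atlas: NetworkAtlas
    subjects: list[str]
    sessions: dict[tuple[str, str], BoldSession]
    truths: dict[tuple[str, str], PlantedTruth]
    delta: pd.DataFrame  # per subject x network planted duration change (pct points)
    clinical: pd.DataFrame  # tidy: subject, score, before, after, ga, age
    effect_networks: tuple[int, ...]
    seed: int

    @property
    def delta_mean(self) -> pd.Series:
        """Per-subject mean planted duration shift over effect networks."""
        sub = self.delta[self.delta.network.isin(self.effect_networks)]
        return sub.groupby("subject").delta.mean()

    def clinical_table(self) -> pd.DataFrame:
        """ClinicalTable in the canonical column order."""
        return self.clinical[
            ["subject", "score", "before", "after", "gestational_age", "age_months"]
        ].copy()


def simulate_cohort(
    n_subjects: int = 32,
    atlas: NetworkAtlas | None = None,
    n_networks: int = 8,
    grid_shape: tuple[int, int, int] = (12, 12, 12),
    n_volumes: int = 105,
    tr: float = 2.0,
    noise_sd: float = 0.5,
    base_duration_pct: tuple[float, float] = (10.0, 25.0),
    block_len_range: tuple[int, int] = (4, 10),
    effect_networks: tuple[int, ...] = (0, 1, 2, 3),
    delta_mean_pct: float = 10.0,
    delta_sd_pct: float = 3.0,
    clinical_effect: float = -0.8,
    clinical_noise_sd: float = 2.0,
    motion_spike_prob: float = 0.02,
    seed: int | None = None,
) -> Cohort:
    """Simulate a paired pre/post cohort with a planted duration increase.

    Session-2 activation duration of each effect network is shifted by a
    per-subject draw delta_s ~ Normal(delta_mean_pct, delta_sd_pct), floored
    at zero.  The planted clinical change for coupled scores is
    ``clinical_effect * mean(delta_s over effect networks) + noise``; the
    remaining scores change by noise alone.  All randomness flows from
    ``seed``; the recorded durations are exact recounts of emitted trains.
    """
    if n_subjects < 4:
        raise ValueError("need at least 4 subjects")
    rng = np.random.default_rng(seed)
    if atlas is None:
        atlas = make_network_atlas(
            n_networks, grid_shape, overlap_frac=0.0, seed=int(rng.integers(2**31))
        )
    n_networks = atlas.n_networks
    if not all(0 <= k < n_networks for k in effect_networks):
        raise ValueError("effect_networks out of range")

    subjects = [f"sub{idx + 1:02d}" for idx in range(n_subjects)]
    sessions: dict[tuple[str, str], BoldSession] = {}
    truths: dict[tuple[str, str], PlantedTruth] = {}
    mean_len = 0.5 * (block_len_range[0] + block_len_range[1])
    delta_rows = []
    for subj in subjects:
        base = rng.uniform(*base_duration_pct, size=n_networks)
        shift = max(0.0, rng.normal(delta_mean_pct, delta_sd_pct))
        # block counts are fixed per subject-network across the two sessions,
        # so the planted shift changes durations only, not occurrences
        counts = [
            max(1, int(round(base[k] / 100.0 * n_volumes / mean_len)))
            for k in range(n_networks)
        ]
        for ses in ("pre", "post"):
            per_net = []
            for k in range(n_networks):
                tgt = base[k] + (shift if ses == "post" and k in effect_networks else 0.0)
                per_net.append(
                    simulate_block_activity(
                        n_volumes, rate=0.0, block_len_range=block_len_range,
                        rng=rng, target_duration_pct=min(tgt, 60.0),
                        n_blocks=counts[k],
                    )
                )
            truth = _stack_truths(per_net, seed=-1)
            truths[(subj, ses)] = truth
            bold = simulate_bold(
                atlas, truth.trains, tr=tr, noise_sd=noise_sd, rng=rng,
                subject=subj, session=ses,
            )
            bold.motion = simulate_motion(
                n_volumes, spike_prob=motion_spike_prob, rng=rng
            )
            sessions[(subj, ses)] = bold
        for k in range(n_networks):
            delta_rows.append(
                {
                    "subject": subj,
                    "network": k,
                    "delta": truths[(subj, "post")].planted_duration_pct[k]
                    - truths[(subj, "pre")].planted_duration_pct[k],
                }
            )
    delta = pd.DataFrame(delta_rows)

    dmean = (
        delta[delta.network.isin(effect_networks)].groupby("subject").delta.mean()
    )
    clin_rows = []
    for subj in subjects:
        ga = float(np.clip(rng.normal(29.07, 1.99), 24.0, 31.9))
        age = float(rng.normal(145.8, 14.8))
        for score in CLINICAL_SCORES:
            before = float(rng.normal(60.0, 10.0))
            change = float(rng.normal(0.0, clinical_noise_sd))
            if score in PLANTED_SCORES:
                change += clinical_effect * float(dmean[subj])
            clin_rows.append(
                {
                    "subject": subj,
                    "score": score,
                    "before": before,
                    "after": before + change,
                    "gestational_age": ga,
                    "age_months": age,
                }
            )
    clinical = pd.DataFrame(clin_rows)
    return Cohort(
        atlas=atlas,
        subjects=subjects,
        sessions=sessions,
        truths=truths,
        delta=delta,
        clinical=clinical,
        effect_networks=tuple(effect_networks),
        seed=-1 if seed is None else int(seed),
    )
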