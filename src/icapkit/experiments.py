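"""End-to-end synthetic-cohort experiments with planted-truth scoring.

Runs the full chain — simulate a paired pre/post cohort, scrub, deconvolve,
select and cluster transients, recover iCAP time courses and temporal
metrics, form reliable-change indices, and fit the four PLSC analyses
(duration, occurrences, coupling, anticoupling against the clinical
block) — then scores recovery against the planted ground truth: cluster
maps are matched to planted networks by Hungarian assignment on map
correlations, recovered durations are correlated with exact recounts of
the planted trains, and the PLSC significance pattern is compared with the
planted design (only the duration analysis has planted structure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import change_stats, icaps, synth, tempmetrics
from .deconv import deconvolve_session
from .io import RunConfig, scrub
from .plsc import PLSC

__all__ = ["EndToEndResult", "run_cohort_analysis", "small_config"]


def small_config(seed: int = 0, **overrides) -> RunConfig:
    """Study-sized cohort on a lattice small enough for repeated runs."""
    base = dict(
        seed=seed,
        n_subjects=32,
        n_networks=8,
        grid_shape=(9, 9, 9),
        n_volumes=105,
        max_iter=250,
        tol=1e-6,
        n_perm=200,
        n_boot=200,
    )
    base.update(overrides)
    return RunConfig(**base)


@dataclass
class EndToEndResult:
    cohort: synth.Cohort
    icapset: icaps.ICAPSet
    matching: np.ndarray  # cluster index assigned to each planted network
    map_dice: np.ndarray  # per planted network, Dice of |z|>2 vs support
    duration_r: np.ndarray  # per planted network, recovery correlation
    metrics: dict  # (subject, session) -> TemporalMetrics
    clinical_x: pd.DataFrame
    brain_y: dict  # analysis name -> DataFrame
    plsc_results: dict  # analysis name -> PLSCResults
    n_frames: int

    @property
    def lc1_p(self) -> dict:
        return {name: float(res.perm_p[0]) for name, res in self.plsc_results.items()}


def _match_clusters(zmaps: np.ndarray, atlas_flat: np.ndarray) -> np.ndarray:
    """Assign one cluster to each planted network, maximising map correlation."""
    k_true = atlas_flat.shape[0]
    k_est = zmaps.shape[0]
    cost = np.zeros((k_true, k_est))
    for i in range(k_true):
        for j in range(k_est):
            cost[i, j] = -abs(np.corrcoef(atlas_flat[i], zmaps[j])[0, 1])
    rows, cols = linear_sum_assignment(cost)
    out = np.zeros(k_true, dtype=int)
    out[rows] = cols
    return out


def run_cohort_analysis(
    config: RunConfig | None = None,
    seed: int | None = None,
    run_bootstrap: bool = False,
) -> EndToEndResult:
    """Execute the full pipeline on one synthetic cohort and score it."""
    if config is None:
        config = small_config(seed if seed is not None else 0)
    if seed is not None:
        config.seed = seed
    rng = np.random.default_rng(config.seed)

    cohort = synth.simulate_cohort(
        n_subjects=config.n_subjects,
        n_networks=config.n_networks,
        grid_shape=config.grid_shape,
        n_volumes=config.n_volumes,
        tr=config.tr,
        noise_sd=config.noise_sd,
        effect_networks=config.effect_networks,
        delta_mean_pct=config.delta_mean_pct,
        delta_sd_pct=config.delta_sd_pct,
        clinical_effect=config.clinical_effect,
        clinical_noise_sd=config.clinical_noise_sd,
        seed=int(rng.integers(2**31)),
    )

    # scrub + deconvolve every session
    innovation_sets = []
    for key, sess in cohort.sessions.items():
        s = scrub(sess, fd_thresh=config.fd_thresh, drop_initial=config.drop_initial)
        innovation_sets.append(
            deconvolve_session(
                s, lam_scale=config.lam_scale,
                max_iter=config.max_iter, tol=config.tol,
            )
        )

    frames = icaps.select_transients(
        innovation_sets, percentile=config.percentile,
        min_active_voxels=max(1, int(round(config.min_active_frac
                                           * innovation_sets[0].n_voxels))),
    )
    labels, signs, _ = icaps.kmeans_transients(
        frames.frames, config.n_clusters,
        n_replicates=config.n_replicates, seed=int(rng.integers(2**31)),
    )
    mask = next(iter(cohort.sessions.values())).mask
    icapset = icaps.build_zmaps(frames.frames, labels, signs, mask=mask)

    # score spatial recovery against the planted atlas
    atlas_flat = cohort.atlas.maps[:, mask]
    matching = _match_clusters(icapset.zmaps, atlas_flat)
    dice = np.zeros(cohort.atlas.n_networks)
    for i, j in enumerate(matching):
        hot = np.abs(icapset.zmaps[j]) > 2.0
        sup = atlas_flat[i] > 0
        denom = hot.sum() + sup.sum()
        dice[i] = 2.0 * (hot & sup).sum() / denom if denom else 0.0

    # per-session time courses and temporal metrics
    metrics: dict = {}
    by_key = {(i.subject, i.session): i for i in innovation_sets}
    for key, inn in by_key.items():
        raw, z = tempmetrics.transient_informed_regression(
            icapset.zmaps, inn.activity, norm_mask=inn.scrub_mask
        )
        blocks = tempmetrics.binarize_blocks(z, config.z_thresh, inn.scrub_mask)
        metrics[key] = tempmetrics.compute_metrics(
            blocks, inn.scrub_mask, subject=key[0], session=key[1]
        )

    # duration recovery: recovered (matched iCAP) vs exact recount of trains
    n_net = cohort.atlas.n_networks
    duration_r = np.zeros(n_net)
    rec = {k: [] for k in range(n_net)}
    planted = {k: [] for k in range(n_net)}
    for key, m in metrics.items():
        truth = cohort.truths[key]
        keep = by_key[key].scrub_mask
        trains = truth.trains[:, config.drop_initial :]
        for k in range(n_net):
            rec[k].append(m.duration[matching[k]])
            planted[k].append(100.0 * trains[k, keep].sum() / keep.sum())
    for k in range(n_net):
        duration_r[k] = np.corrcoef(rec[k], planted[k])[0, 1]

    # reliable change per feature, then the four PLSC analyses
    subjects = cohort.subjects
    feat = {"duration": {}, "occurrences": {}, "coupling": {}, "anticoupling": {}}
    pairs = tempmetrics.pair_index(config.n_clusters)
    for ses in ("pre", "post"):
        for name in feat:
            cols = {}
            for subj in subjects:
                m = metrics[(subj, ses)]
                if name == "duration":
                    vals = m.duration
                elif name == "occurrences":
                    vals = m.occurrences.astype(float)
                elif name == "coupling":
                    vals = np.array([m.coupling[i, j] for i, j in pairs])
                else:
                    vals = np.array([m.anticoupling[i, j] for i, j in pairs])
                cols[subj] = vals
            feat[name][ses] = pd.DataFrame(cols).T  # subjects x features

    import warnings as _warnings

    brain_y = {}
    for name, tables in feat.items():
        before, after = tables["pre"], tables["post"]
        out = {}
        for col in before.columns:
            b, a = before[col].to_numpy(), after[col].to_numpy()
            if np.std(b) == 0 or np.std(a - b) == 0:
                out[f"{name}_{col}"] = a - b  # degenerate: raw change
            else:
                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore", UserWarning)
                    out[f"{name}_{col}"] = change_stats.rci_frame(
                        b, a, measure=f"{name}_{col}"
                    )["rci"].to_numpy()
        brain_y[name] = pd.DataFrame(out, index=subjects)

    clin = cohort.clinical
    xcols = {}
    for score in synth.CLINICAL_SCORES:
        sub = clin[clin.score == score].set_index("subject").loc[subjects]
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", UserWarning)
            xcols[f"rci_{score}"] = change_stats.rci_frame(
                sub.before, sub.after, measure=score
            )["rci"].to_numpy()
    meta = clin.drop_duplicates("subject").set_index("subject").loc[subjects]
    xcols["gestational_age"] = meta.gestational_age.to_numpy()
    xcols["age_months"] = meta.age_months.to_numpy()
    clinical_x = pd.DataFrame(xcols, index=subjects)

    plsc_results = {}
    for name, y in brain_y.items():
        y_use = y.loc[:, y.std() > 0]
        res = PLSC(clinical_x, y_use).fit(
            n_perm=config.n_perm,
            n_boot=config.n_boot if run_bootstrap else 0,
            seed=int(rng.integers(2**31)),
        )
        plsc_results[name] = res

    return EndToEndResult(
        cohort=cohort,
        icapset=icapset,
        matching=matching,
        map_dice=dice,
        duration_r=duration_r,
        metrics=metrics,
        clinical_x=clinical_x,
        brain_y=brain_y,
        plsc_results=plsc_results,
        n_frames=frames.n_frames,
    )
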