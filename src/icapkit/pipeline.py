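"""Stage-chaining pipeline with on-disk artifacts and a run manifest.

Each stage reads its inputs from the artifact directory written by the
previous stage and writes its own outputs there, so stages can be run
separately (the CLI subcommands) or end to end (``run_pipeline``).  A
manifest records the configuration, seeds, package version, and a SHA-256
hash of every written file; rerunning with the same configuration
reproduces identical tabular outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__, change_stats, icaps, synth, tempmetrics
from .datatypes import BoldSession, MotionRecord
from .deconv import deconvolve_session
from .io import RunConfig, framewise_displacement, load_mask, read_motion_tsv, save_mask, save_session, scrub, write_motion_tsv
from .plsc import PLSC

__all__ = ["run_pipeline", "Pipeline"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class Pipeline:
    """Executes the synthetic-cohort analysis stage by stage.

    Stages: simulate -> deconvolve -> icaps -> metrics -> rci -> plsc.
    Each ``run_*`` method is restartable: it loads whatever the previous
    stage left in ``config.out_dir``.
    """

    def __init__(self, config: RunConfig):
        if config.seed is None:
            raise ValueError("config must set a seed")
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._written: dict[str, str] = {}

    # ---------------------------------------------------------------- utils
    def _note(self, path: Path) -> None:
        self._written[str(path.relative_to(self.out))] = _sha256(path)

    def _sessions(self) -> list[tuple[str, str]]:
        subs = [f"sub{i + 1:02d}" for i in range(self.config.n_subjects)]
        return [(s, ses) for s in subs for ses in ("pre", "post")]

    def _load_session(self, subject: str, ses: str) -> BoldSession:
        mask = load_mask(self.out / "mask.nii.gz")
        params = read_motion_tsv(self.out / f"{subject}_{ses}_motion.tsv")
        fd, _ = framewise_displacement(params, self.config.head_radius)
        img = nib.load(str(self.out / f"{subject}_{ses}_bold.nii.gz"))
        data = np.asarray(img.dataobj, dtype=np.float32).astype(float)
        motion = MotionRecord(params=params, fd=fd, scrub_mask=fd <= self.config.fd_thresh)
        return BoldSession(data=data, mask=mask, tr=self.config.tr,
                           subject=subject, session=ses, motion=motion)

    # --------------------------------------------------------------- stages
    def run_simulate(self) -> None:
        cfg = self.config
        cohort = synth.simulate_cohort(
            n_subjects=cfg.n_subjects,
            n_networks=cfg.n_networks,
            grid_shape=cfg.grid_shape,
            n_volumes=cfg.n_volumes,
            tr=cfg.tr,
            noise_sd=cfg.noise_sd,
            effect_networks=cfg.effect_networks,
            delta_mean_pct=cfg.delta_mean_pct,
            delta_sd_pct=cfg.delta_sd_pct,
            clinical_effect=cfg.clinical_effect,
            clinical_noise_sd=cfg.clinical_noise_sd,
            motion_spike_prob=0.02,
            seed=cfg.seed,
        )
        atlas_img = nib.Nifti1Image(
            np.moveaxis(cohort.atlas.maps, 0, -1).astype(np.float32), np.eye(4)
        )
        nib.save(atlas_img, str(self.out / "atlas.nii.gz"))
        self._note(self.out / "atlas.nii.gz")
        save_mask(next(iter(cohort.sessions.values())).mask, self.out / "mask.nii.gz")
        self._note(self.out / "mask.nii.gz")

        truth_rows = []
        for (subj, ses), bold in cohort.sessions.items():
            save_session(bold, self.out / f"{subj}_{ses}_bold.nii.gz")
            self._note(self.out / f"{subj}_{ses}_bold.nii.gz")
            write_motion_tsv(bold.motion.params, self.out / f"{subj}_{ses}_motion.tsv")
            self._note(self.out / f"{subj}_{ses}_motion.tsv")
            truth = cohort.truths[(subj, ses)]
            for k in range(truth.trains.shape[0]):
                truth_rows.append(
                    {
                        "subject": subj,
                        "session": ses,
                        "network": k,
                        "duration_pct": truth.planted_duration_pct[k],
                        "train": "".join(str(int(v)) for v in truth.trains[k]),
                    }
                )
        pd.DataFrame(truth_rows).to_csv(self.out / "truth.tsv", sep="\t", index=False)
        self._note(self.out / "truth.tsv")
        cohort.clinical_table().to_csv(self.out / "clinical.csv", index=False)
        self._note(self.out / "clinical.csv")

    def run_deconvolve(self) -> None:
        cfg = self.config
        mask = load_mask(self.out / "mask.nii.gz")
        for subj, ses in self._sessions():
            sess = scrub(
                self._load_session(subj, ses),
                fd_thresh=cfg.fd_thresh,
                drop_initial=cfg.drop_initial,
            )
            inn = deconvolve_session(
                sess, lam_scale=cfg.lam_scale, max_iter=cfg.max_iter, tol=cfg.tol
            )
            for name, arr in (("activity", inn.activity), ("innovations", inn.innovations)):
                vol = np.zeros(mask.shape + (inn.n_volumes,), dtype=np.float32)
                vol[mask] = arr
                nib.save(nib.Nifti1Image(vol, np.eye(4)),
                         str(self.out / f"{subj}_{ses}_{name}.nii.gz"))
                self._note(self.out / f"{subj}_{ses}_{name}.nii.gz")
            sidecar = {
                "subject": subj,
                "session": ses,
                "lam_scale": cfg.lam_scale,
                "lambda_median": float(np.median(inn.lambda_used)),
                "max_iter": cfg.max_iter,
                "tol": cfg.tol,
                "scrub_mask": inn.scrub_mask.astype(int).tolist(),
            }
            (self.out / f"{subj}_{ses}_deconv.json").write_text(
                json.dumps(sidecar, indent=1)
            )
            self._note(self.out / f"{subj}_{ses}_deconv.json")

    def _load_innovations(self):
        from .datatypes import InnovationSet

        mask = load_mask(self.out / "mask.nii.gz")
        sets = []
        for subj, ses in self._sessions():
            act = np.asarray(
                nib.load(str(self.out / f"{subj}_{ses}_activity.nii.gz")).dataobj
            ).astype(float)
            innov = np.asarray(
                nib.load(str(self.out / f"{subj}_{ses}_innovations.nii.gz")).dataobj
            ).astype(float)
            meta = json.loads((self.out / f"{subj}_{ses}_deconv.json").read_text())
            sets.append(
                InnovationSet(
                    activity=act[mask],
                    innovations=innov[mask],
                    lambda_used=np.array([]),
                    objective_trace=np.empty((0, 0)),
                    mask=mask,
                    tr=self.config.tr,
                    subject=subj,
                    session=ses,
                    scrub_mask=np.array(meta["scrub_mask"], dtype=bool),
                )
            )
        return sets, mask

    def run_icaps(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        sets, mask = self._load_innovations()
        frames = icaps.select_transients(
            sets,
            percentile=cfg.percentile,
            min_active_voxels=max(1, int(round(cfg.min_active_frac * sets[0].n_voxels))),
        )
        if cfg.run_consensus:
            cons = icaps.consensus_select_K(
                frames.frames,
                range(cfg.k_range[0], cfg.k_range[1] + 1),
                n_resamples=cfg.n_resamples,
                subsample_frac=cfg.subsample_frac,
                seed=int(rng.integers(2**31)),
            )
            k = cons.selected_K
            pd.DataFrame(
                {
                    "K": cons.k_range,
                    "mean_consensus": [cons.mean_consensus[kk] for kk in cons.k_range],
                }
            ).to_csv(self.out / "consensus.csv", index=False)
            self._note(self.out / "consensus.csv")
        else:
            k = cfg.n_clusters
        labels, signs, _ = icaps.kmeans_transients(
            frames.frames, k, n_replicates=cfg.n_replicates,
            seed=int(rng.integers(2**31)),
        )
        icapset = icaps.build_zmaps(frames.frames, labels, signs, mask=mask)
        vol = np.zeros(mask.shape + (k,), dtype=np.float32)
        vol[mask] = icapset.zmaps.T
        nib.save(nib.Nifti1Image(vol, np.eye(4)), str(self.out / "icaps_zmaps.nii.gz"))
        self._note(self.out / "icaps_zmaps.nii.gz")
        for j in range(k):
            nib.save(
                nib.Nifti1Image(vol[..., j], np.eye(4)),
                str(self.out / f"icap_{j + 1:02d}.nii.gz"),
            )
            self._note(self.out / f"icap_{j + 1:02d}.nii.gz")
        prov = pd.DataFrame(frames.provenance, columns=["subject", "session", "volume"])
        prov["label"] = labels
        prov["sign"] = signs
        prov.to_csv(self.out / "icaps_labels.tsv", sep="\t", index=False)
        self._note(self.out / "icaps_labels.tsv")

    def run_metrics(self) -> None:
        cfg = self.config
        sets, mask = self._load_innovations()
        vol = np.asarray(nib.load(str(self.out / "icaps_zmaps.nii.gz")).dataobj)
        zmaps = vol[mask].T.astype(float)
        all_metrics = []
        for inn in sets:
            _, z = tempmetrics.transient_informed_regression(
                zmaps, inn.activity, norm_mask=inn.scrub_mask
            )
            blocks = tempmetrics.binarize_blocks(z, cfg.z_thresh, inn.scrub_mask)
            all_metrics.append(
                tempmetrics.compute_metrics(
                    blocks, inn.scrub_mask, subject=inn.subject, session=inn.session
                )
            )
        tempmetrics.metrics_frame(all_metrics).to_csv(
            self.out / "metrics.csv", index=False
        )
        self._note(self.out / "metrics.csv")

    def run_rci(self) -> None:
        metrics = pd.read_csv(self.out / "metrics.csv")
        clinical = pd.read_csv(self.out / "clinical.csv")
        rows = []
        # brain metrics
        metrics["feature"] = metrics.apply(
            lambda r: f"{r.metric}_{int(r.icap_i)}"
            if pd.isna(r.icap_j)
            else f"{r.metric}_{int(r.icap_i)}_{int(r.icap_j)}",
            axis=1,
        )
        wide = metrics.pivot_table(
            index=["subject", "session"], columns="feature", values="value"
        )
        pre = wide.xs("pre", level="session")
        post = wide.xs("post", level="session").loc[pre.index]
        import warnings

        for col in wide.columns:
            b, a = pre[col].to_numpy(), post[col].to_numpy()
            if np.std(b) == 0 or np.std(a - b) == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                f = change_stats.rci_frame(b, a, measure=col)
            for subj, rci in zip(pre.index, f["rci"]):
                rows.append({"subject": subj, "measure": col, "rci": rci, "block": "brain"})
        # clinical scores
        for score in sorted(clinical.score.unique()):
            sub = clinical[clinical.score == score].set_index("subject")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                f = change_stats.rci_frame(sub.before, sub.after, measure=score)
            for subj, rci in zip(sub.index, f["rci"]):
                rows.append({"subject": subj, "measure": f"rci_{score}", "rci": rci,
                             "block": "clinical"})
        pd.DataFrame(rows).to_csv(self.out / "rci.csv", index=False)
        self._note(self.out / "rci.csv")

    def run_stats(self) -> None:
        """Pre/post comparison of each temporal metric with BH-FDR flags."""
        metrics = pd.read_csv(self.out / "metrics.csv")
        metrics["feature"] = metrics.apply(
            lambda r: f"{r.metric}_{int(r.icap_i)}"
            if pd.isna(r.icap_j)
            else f"{r.metric}_{int(r.icap_i)}_{int(r.icap_j)}",
            axis=1,
        )
        wide = metrics.pivot_table(
            index=["subject", "session"], columns="feature", values="value"
        )
        pre = wide.xs("pre", level="session")
        post = wide.xs("post", level="session").loc[pre.index]
        rows = []
        for col in wide.columns:
            b, a = pre[col].to_numpy(), post[col].to_numpy()
            if np.std(a - b) == 0:
                continue
            t = change_stats.prepost_model(b, a)
            rows.append(
                {
                    "measure": col, "term": "time", "estimate": t.estimate,
                    "se": t.se, "statistic": t.statistic, "df": t.df, "p": t.p,
                }
            )
        res = pd.DataFrame(rows)
        res["q"], res["flag"] = change_stats.bh_fdr(res["p"].to_numpy())
        res.to_csv(self.out / "group_stats.csv", index=False)
        self._note(self.out / "group_stats.csv")

    def run_plsc(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 2)
        rci = pd.read_csv(self.out / "rci.csv")
        clinical = pd.read_csv(self.out / "clinical.csv")
        x = rci[rci.block == "clinical"].pivot_table(
            index="subject", columns="measure", values="rci"
        )
        meta = clinical.drop_duplicates("subject").set_index("subject").loc[x.index]
        x["gestational_age"] = meta.gestational_age
        x["age_months"] = meta.age_months
        brain = rci[rci.block == "brain"].pivot_table(
            index="subject", columns="measure", values="rci"
        ).loc[x.index]
        summary = {}
        loadings = []
        for name in ("duration", "occurrences", "coupling", "anticoupling"):
            y = brain[[c for c in brain.columns if c.startswith(name)]]
            y = y.loc[:, y.std() > 0]
            res = PLSC(x, y).fit(
                n_perm=cfg.n_perm, n_boot=cfg.n_boot, seed=int(rng.integers(2**31))
            )
            summary[name] = {
                "singular_values": res.singular_values.tolist(),
                "perm_p": res.perm_p.tolist(),
            }
            lf = res.loadings_frame()
            lf.insert(0, "analysis", name)
            loadings.append(lf)
        (self.out / "plsc.json").write_text(json.dumps(summary, indent=1))
        self._note(self.out / "plsc.json")
        pd.concat(loadings).to_csv(self.out / "plsc_loadings.csv", index=False)
        self._note(self.out / "plsc_loadings.csv")

    def write_manifest(self, failed: str | None = None) -> None:
        manifest = {
            "version": __version__,
            "config": json.loads(self.config.to_json()),
            "failed_stage": failed,
            "files": self._written,
        }
        (self.out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    def run_all(self) -> Path:
        stages = [
            ("simulate", self.run_simulate),
            ("deconvolve", self.run_deconvolve),
            ("icaps", self.run_icaps),
            ("metrics", self.run_metrics),
            ("rci", self.run_rci),
            ("stats", self.run_stats),
            ("plsc", self.run_plsc),
        ]
        for name, fn in stages:
            try:
                fn()
            except Exception:
                self.write_manifest(failed=name)
                raise
        self.write_manifest()
        return self.out


def run_pipeline(config: RunConfig) -> Path:
    """Simulate-through-PLSC in one call; returns the artifact directory."""
    return Pipeline(config).run_all()
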