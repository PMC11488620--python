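"""Partial least-squares correlation (PLSC) between two data blocks.

Both blocks are column z-scored; the cross-correlation matrix
R = X'Y/(n-1) is decomposed as R = U S V', giving latent components (LCs):
paired weight vectors (saliences) U_k, V_k and subject scores X U_k, Y V_k
whose covariance is maximal.  LC significance is assessed by permuting the
rows of X relative to Y and comparing each rank's singular value with its
permutation distribution; loading stability is assessed by bootstrap
resampling of subjects, reporting the mean and SD of each variable's
loading (its correlation with the LC subject scores) and flagging a
loading as robust when |mean| / SD >= 2.

The interface follows the statsmodels convention: build a :class:`PLSC`
model from the two matrices (or data frames), call :meth:`PLSC.fit`, and
inspect the returned :class:`PLSCResults` (``summary()``, ``loadings_frame()``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PLSC", "PLSCResults", "plsc_fit", "plsc_permute", "plsc_bootstrap"]


def _zscore(a: np.ndarray, name: str) -> np.ndarray:
    sd = a.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"{name} column(s) {bad.tolist()} have zero variance")
    return (a - a.mean(axis=0)) / sd


class PLSC:
    """PLSC model of the cross-correlation between blocks X and Y.

    Parameters
    ----------
    x : (n, p) array or DataFrame — e.g. clinical change measures.
    y : (n, q) array or DataFrame — e.g. brain-dynamics change measures.
    Rows are subjects and must align; columns are z-scored internally.
    """

    def __init__(self, x, y, x_names=None, y_names=None):
        if isinstance(x, pd.DataFrame):
            x_names = list(x.columns) if x_names is None else x_names
            x = x.to_numpy(dtype=float)
        if isinstance(y, pd.DataFrame):
            y_names = list(y.columns) if y_names is None else y_names
            y = y.to_numpy(dtype=float)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 2 or y.ndim != 2 or x.shape[0] != y.shape[0]:
            raise ValueError("X and Y must be 2-D with equal row counts")
        if x.shape[0] < 4:
            raise ValueError("need at least 4 subjects")
        if np.isnan(x).any() or np.isnan(y).any():
            raise ValueError("missing entries are not allowed")
        self.x = x
        self.y = y
        self.x_names = x_names or [f"x{i}" for i in range(x.shape[1])]
        self.y_names = y_names or [f"y{i}" for i in range(y.shape[1])]

    @classmethod
    def from_frames(cls, x: pd.DataFrame, y: pd.DataFrame) -> "PLSC":
        """Build from two subject-indexed data frames (rows aligned on index)."""
        if not x.index.equals(y.index):
            y = y.loc[x.index]
        return cls(x, y)

    # -- core decomposition -------------------------------------------------
    def _decompose(self, x: np.ndarray, y: np.ndarray):
        xz = _zscore(x, "X")
        yz = _zscore(y, "Y")
        r = xz.T @ yz / (x.shape[0] - 1)
        u, s, vt = np.linalg.svd(r, full_matrices=False)
        return xz, yz, r, u, s, vt.T

    def fit(
        self,
        n_perm: int = 1000,
        n_boot: int = 500,
        seed: int | None = None,
        robust_ratio: float = 2.0,
    ) -> "PLSCResults":
        """Fit, then run the permutation and bootstrap procedures."""
        rng = np.random.default_rng(seed)
        xz, yz, r, u, s, v = self._decompose(self.x, self.y)
        res = PLSCResults(
            model=self,
            singular_values=s,
            x_saliences=u,
            y_saliences=v,
            x_scores=xz @ u,
            y_scores=yz @ v,
            cross_correlation=r,
        )
        if n_perm:
            res.perm_p = self.permutation_test(n_perm, rng=rng)
        if n_boot:
            boot = self.bootstrap(n_boot, rng=rng, robust_ratio=robust_ratio,
                                  ref=(u, v, s))
            (res.x_loading_mean, res.x_loading_sd, res.x_robust,
             res.y_loading_mean, res.y_loading_sd, res.y_robust,
             res.n_redrawn) = boot
        return res

    # -- permutation --------------------------------------------------------
    def permutation_test(
        self,
        n_perm: int = 1000,
        seed: int | None = None,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """p(LC k) = (1 + #{perm s_k >= observed s_k}) / (n_perm + 1).

        Rows of X are permuted relative to Y; singular values are compared
        rank by rank (no Procrustes alignment).
        """
        if n_perm < 1:
            raise ValueError("n_perm must be at least 1")
        if rng is None:
            rng = np.random.default_rng(seed)
        _, _, _, _, s_obs, _ = self._decompose(self.x, self.y)
        exceed = np.zeros_like(s_obs)
        for _ in range(n_perm):
            perm = rng.permutation(self.x.shape[0])
            _, _, _, _, s_perm, _ = self._decompose(self.x[perm], self.y)
            exceed += s_perm >= s_obs
        return (1.0 + exceed) / (n_perm + 1.0)

    # -- bootstrap ----------------------------------------------------------
    def bootstrap(
        self,
        n_boot: int = 500,
        seed: int | None = None,
        rng: np.random.Generator | None = None,
        robust_ratio: float = 2.0,
        ref: tuple | None = None,
        max_redraw: int = 1000,
    ):
        """Bootstrap loading means/SDs with sign alignment to the original.

        Loadings are correlations of each original variable with the LC
        subject scores.  Each bootstrap LC is sign-aligned to the original
        via the salience dot product.  Resamples with a zero-variance
        column are redrawn (counted).
        """
        if n_boot < 1:
            raise ValueError("n_boot must be at least 1")
        if rng is None:
            rng = np.random.default_rng(seed)
        if ref is None:
            _, _, _, u0, s0, v0 = self._decompose(self.x, self.y)
        else:
            u0, v0, s0 = ref
        n, p = self.x.shape
        q = self.y.shape[1]
        n_lc = len(s0)
        xl = np.zeros((n_boot, p, n_lc))
        yl = np.zeros((n_boot, q, n_lc))
        n_redrawn = 0
        b = 0
        while b < n_boot:
            idx = rng.integers(0, n, size=n)
            xb, yb = self.x[idx], self.y[idx]
            try:
                xz, yz, _, ub, sb, vb = self._decompose(xb, yb)
            except ValueError:
                n_redrawn += 1
                if n_redrawn > max_redraw:
                    raise RuntimeError("too many degenerate bootstrap resamples")
                continue
            # align bootstrap LCs to the originals (order and sign)
            flip = np.sign(np.sum(u0 * ub, axis=0) + np.sum(v0 * vb, axis=0))
            flip[flip == 0] = 1.0
            ub = ub * flip
            vb = vb * flip
            xs = xz @ ub
            ys = yz @ vb
            xl[b] = _safe_corr(xb, xs[:, :n_lc])
            yl[b] = _safe_corr(yb, ys[:, :n_lc])
            b += 1
        xm, xs_ = xl.mean(axis=0), xl.std(axis=0, ddof=1)
        ym, ys_ = yl.mean(axis=0), yl.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            xrob = np.abs(xm) / xs_ >= robust_ratio
            yrob = np.abs(ym) / ys_ >= robust_ratio
        return xm, xs_, xrob, ym, ys_, yrob, n_redrawn


def _safe_corr(block: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Correlation of each block column with each score column (NaN-safe)."""
    bz = block - block.mean(axis=0)
    sz = scores - scores.mean(axis=0)
    bs = bz.std(axis=0)
    ss = sz.std(axis=0)
    denom = np.outer(bs, ss)
    denom[denom == 0] = np.nan
    out = (bz.T @ sz) / block.shape[0] / denom
    return np.nan_to_num(out)


@dataclass
class PLSCResults:
    """Latent components, permutation p-values, and bootstrap stability."""

    model: PLSC
    singular_values: np.ndarray
    x_saliences: np.ndarray
    y_saliences: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    cross_correlation: np.ndarray
    perm_p: np.ndarray | None = None
    x_loading_mean: np.ndarray | None = None
    x_loading_sd: np.ndarray | None = None
    x_robust: np.ndarray | None = None
    y_loading_mean: np.ndarray | None = None
    y_loading_sd: np.ndarray | None = None
    y_robust: np.ndarray | None = None
    n_redrawn: int = 0

    @property
    def n_components(self) -> int:
        return len(self.singular_values)

    @property
    def explained_covariance(self) -> np.ndarray:
        s2 = self.singular_values**2
        return s2 / s2.sum()

    def loadings_frame(self) -> pd.DataFrame:
        """Tidy loadings: lc, side, variable, boot_mean, boot_sd, robust."""
        if self.x_loading_mean is None:
            raise ValueError("bootstrap was not run")
        rows = []
        for lc in range(self.n_components):
            for side, names, m, s, rob in (
                ("x", self.model.x_names, self.x_loading_mean,
                 self.x_loading_sd, self.x_robust),
                ("y", self.model.y_names, self.y_loading_mean,
                 self.y_loading_sd, self.y_robust),
            ):
                for vi, name in enumerate(names):
                    rows.append(
                        {
                            "lc": lc + 1,
                            "side": side,
                            "variable": name,
                            "boot_mean": m[vi, lc],
                            "boot_sd": s[vi, lc],
                            "robust": bool(rob[vi, lc]),
                        }
                    )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Partial least-squares correlation",
            f"  n subjects: {self.model.x.shape[0]}   "
            f"X: {self.model.x.shape[1]} cols   Y: {self.model.y.shape[1]} cols",
            "  LC   singular   %cov     perm p",
        ]
        for k in range(self.n_components):
            p = f"{self.perm_p[k]:.4f}" if self.perm_p is not None else "   --"
            lines.append(
                f"  {k + 1:>2}   {self.singular_values[k]:8.4f}   "
                f"{100 * self.explained_covariance[k]:5.1f}   {p}"
            )
        if self.x_robust is not None:
            rx = [self.model.x_names[i] for i in np.flatnonzero(self.x_robust[:, 0])]
            ry = [self.model.y_names[i] for i in np.flatnonzero(self.y_robust[:, 0])]
            lines.append(f"  LC1 robust X loadings: {', '.join(rx) or 'none'}")
            lines.append(f"  LC1 robust Y loadings: {', '.join(ry) or 'none'}")
        return "\n".join(lines)


# -- functional wrappers ----------------------------------------------------

def plsc_fit(x, y) -> PLSCResults:
    """Decomposition only (no permutation or bootstrap)."""
    return PLSC(x, y).fit(n_perm=0, n_boot=0)


def plsc_permute(x, y, n_perm: int = 1000, seed: int | None = None) -> np.ndarray:
    return PLSC(x, y).permutation_test(n_perm=n_perm, seed=seed)


def plsc_bootstrap(x, y, n_boot: int = 500, seed: int | None = None):
    m = PLSC(x, y)
    xm, xs, xr, ym, ys, yr, nre = m.bootstrap(n_boot=n_boot, seed=seed)
    return xm, xs, xr, ym, ys, yr, nre
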