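"""Trial-level coordination of hippocampal context and entorhinal object
codes: leave-one-trial-out representation strength, cross-trial and lagged
correlations between regions, and the median-split linear mixed-effects
model linking representation strength to the drop error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sstats

from .rsa import SimilarityTensor, _KIND_COLUMN
from .stats import clip_rho


@dataclass
class StrengthMatrix:
    """Leave-one-trial-out representation strength, trials x windows.

    For each epoch the strength is its mean Fisher-z similarity with
    same-label epochs minus its mean similarity with different-label
    epochs, computed within session.  NaN where an epoch has no same-label
    partner.
    """

    values: np.ndarray
    kind: str  # "context" | "object"
    epochs: pd.DataFrame

    @property
    def trial_ids(self) -> np.ndarray:
        return self.epochs["trial_id"].to_numpy()


def loto_strength(sim: SimilarityTensor, kind: str) -> StrengthMatrix:
    col = _KIND_COLUMN[kind]
    li, lj = sim.pair_labels(col)
    same = li == lj
    n_ep = len(sim.epochs)
    n_win = sim.z.shape[1]
    sums = np.zeros((2, n_ep, n_win))
    counts = np.zeros((2, n_ep, n_win))
    zfill = np.nan_to_num(sim.z, nan=0.0)
    ok = np.isfinite(sim.z)
    for bucket, sel in ((0, same), (1, ~same)):
        for ep_idx in (sim.pair_i, sim.pair_j):
            np.add.at(sums[bucket], ep_idx[sel], zfill[sel])
            np.add.at(counts[bucket], ep_idx[sel], ok[sel].astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_same = sums[0] / counts[0]
        mean_diff = sums[1] / counts[1]
    return StrengthMatrix(values=mean_same - mean_diff, kind=kind,
                          epochs=sim.epochs)


def _match_trials(hc: StrengthMatrix, ec: StrengthMatrix,
                  good_only: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Row indices aligning the two strength matrices on shared trial ids."""
    df_h = hc.epochs.reset_index()
    df_e = ec.epochs.reset_index()
    if good_only:
        df_h = df_h[df_h["is_good"]]
        df_e = df_e[df_e["is_good"]]
    merged = df_h.merge(df_e, on="trial_id", suffixes=("_h", "_e"))
    return merged["index_h"].to_numpy(), merged["index_e"].to_numpy()


def cross_trial_correlation(hc: StrengthMatrix, ec: StrengthMatrix,
                            good_only: bool = True,
                            min_trials: int = 3) -> np.ndarray | None:
    """Per-window Fisher-z Spearman correlation between HC context and EC
    object strength across matched trials; None when too few trials."""
    ih, ie = _match_trials(hc, ec, good_only)
    if len(ih) < min_trials:
        warnings.warn(f"only {len(ih)} matched trials; subject skipped")
        return None
    a, b = hc.values[ih], ec.values[ie]
    n_win = a.shape[1]
    out = np.empty(n_win)
    for w in range(n_win):
        rho = sstats.spearmanr(a[:, w], b[:, w]).statistic
        out[w] = np.arctanh(clip_rho(rho)) if np.isfinite(rho) else np.nan
    return out


def lagged_correlation(hc: StrengthMatrix, ec: StrengthMatrix,
                       good_only: bool = True,
                       min_trials: int = 3) -> np.ndarray | None:
    """Window x window Fisher-z Spearman matrix rho(HC window i, EC window j)
    across matched trials (one subject)."""
    ih, ie = _match_trials(hc, ec, good_only)
    if len(ih) < min_trials:
        warnings.warn(f"only {len(ih)} matched trials; subject skipped")
        return None
    a, b = hc.values[ih], ec.values[ie]
    ra = sstats.rankdata(a, axis=0)
    rb = sstats.rankdata(b, axis=0)
    ra = (ra - ra.mean(axis=0)) / np.maximum(ra.std(axis=0), 1e-12)
    rb = (rb - rb.mean(axis=0)) / np.maximum(rb.std(axis=0), 1e-12)
    rho = ra.T @ rb / len(ih)
    return np.arctanh(clip_rho(rho))


def lead_lag_summary(matrices: list[np.ndarray]) -> dict:
    """Compare mean Fisher-z over HC-leads (i < j) vs EC-leads (i > j) cells
    by a paired t-test across subjects."""
    n_win = matrices[0].shape[0]
    iu = np.triu_indices(n_win, k=1)
    il = np.tril_indices(n_win, k=-1)
    hc_leads = np.array([m[iu].mean() for m in matrices])
    ec_leads = np.array([m[il].mean() for m in matrices])
    t, p = sstats.ttest_rel(hc_leads, ec_leads)
    return dict(t=float(t), p=float(p), hc_leads_mean=float(hc_leads.mean()),
                ec_leads_mean=float(ec_leads.mean()), n=len(matrices))


# ---------------------------------------------------------------------------
# random-intercept linear mixed model with Satterthwaite dfs
# ---------------------------------------------------------------------------


class RandomInterceptLMM:
    """REML fit of y = X beta + b_subject + e with b ~ N(0, tau2),
    e ~ N(0, sigma2).

    The single-random-intercept structure admits closed-form per-group
    algebra (Woodbury), so the REML criterion is optimized directly over
    (log sigma2, log tau2).  Satterthwaite degrees of freedom for a contrast
    c use df = 2 phi^2 / (g' Vtheta g) with phi = c' (X'V^-1 X)^-1 c, g its
    gradient in (sigma2, tau2) and Vtheta the inverse observed REML
    information.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.groups = np.asarray(groups)
        self._idx = [np.flatnonzero(self.groups == g)
                     for g in pd.unique(self.groups)]
        self.n, self.p = self.X.shape
        self.singular_ = False

    def _reml(self, sigma2: float, tau2: float, want_beta: bool = False):
        XtViX = np.zeros((self.p, self.p))
        XtViy = np.zeros(self.p)
        yViy = 0.0
        logdetV = 0.0
        lam = tau2 / sigma2
        for idx in self._idx:
            Xi, yi = self.X[idx], self.y[idx]
            ni = len(idx)
            w = lam / (1.0 + ni * lam)
            sx, sy = Xi.sum(axis=0), yi.sum()
            XtViX += (Xi.T @ Xi - w * np.outer(sx, sx)) / sigma2
            XtViy += (Xi.T @ yi - w * sx * sy) / sigma2
            yViy += (yi @ yi - w * sy * sy) / sigma2
            logdetV += ni * np.log(sigma2) + np.log(1.0 + ni * lam)
        beta = np.linalg.solve(XtViX, XtViy)
        ypy = yViy - XtViy @ beta
        sign, logdetXtViX = np.linalg.slogdet(XtViX)
        ll = -0.5 * (logdetV + logdetXtViX + ypy)
        if want_beta:
            return ll, beta, XtViX
        return ll

    def fit(self) -> "RandomInterceptResult":
        ols_res = self.y - self.X @ np.linalg.lstsq(self.X, self.y, rcond=None)[0]
        s2 = max(ols_res.var(), 1e-8)

        def neg(theta):
            return -self._reml(np.exp(theta[0]), np.exp(theta[1]))

        best = None
        for t0 in (np.log([s2 * 0.8, s2 * 0.2]), np.log([s2, s2 * 0.01])):
            res = optimize.minimize(neg, t0, method="Nelder-Mead",
                                    options=dict(xatol=1e-8, fatol=1e-10,
                                                 maxiter=2000))
            if best is None or res.fun < best.fun:
                best = res
        sigma2, tau2 = np.exp(best.x)
        if tau2 < 1e-8 * sigma2:
            self.singular_ = True
        _, beta, XtViX = self._reml(sigma2, tau2, want_beta=True)
        cov_beta = np.linalg.inv(XtViX)
        vtheta = self._vcov_theta(sigma2, tau2)
        return RandomInterceptResult(self, beta, cov_beta, sigma2, tau2, vtheta,
                                     singular=self.singular_)

    def _vcov_theta(self, sigma2: float, tau2: float) -> np.ndarray:
        """Inverse observed information of the REML criterion in
        (sigma2, tau2)."""
        h = np.array([max(sigma2, 1e-6) * 1e-4, max(tau2, 1e-6) * 1e-4])

        def f(v):
            return self._reml(max(v[0], 1e-12), max(v[1], 0.0))

        x0 = np.array([sigma2, tau2])
        H = np.zeros((2, 2))
        for a in range(2):
            for b in range(2):
                ea = np.eye(2)[a] * h[a]
                eb = np.eye(2)[b] * h[b]
                H[a, b] = (f(x0 + ea + eb) - f(x0 + ea - eb)
                           - f(x0 - ea + eb) + f(x0 - ea - eb)) / (4 * h[a] * h[b])
        try:
            return np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            return np.full((2, 2), np.nan)


@dataclass
class RandomInterceptResult:
    model: RandomInterceptLMM
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    tau2: float
    vcov_theta: np.ndarray
    singular: bool = False

    def contrast(self, c: np.ndarray) -> dict:
        """Estimate, Satterthwaite df, t and p for a fixed-effect contrast."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.beta)
        phi = float(c @ self.cov_beta @ c)
        if self.singular or not np.all(np.isfinite(self.vcov_theta)):
            df = self.model.n - self.model.p
        else:
            h = np.array([max(self.sigma2, 1e-6) * 1e-4,
                          max(self.tau2, 1e-6) * 1e-4])

            def phi_of(v):
                _, _, XtViX = self.model._reml(max(v[0], 1e-12), max(v[1], 0.0),
                                               want_beta=True)
                return float(c @ np.linalg.inv(XtViX) @ c)

            x0 = np.array([self.sigma2, self.tau2])
            g = np.array([(phi_of(x0 + np.eye(2)[a] * h[a])
                           - phi_of(x0 - np.eye(2)[a] * h[a])) / (2 * h[a])
                          for a in range(2)])
            denom = float(g @ self.vcov_theta @ g)
            df = 2.0 * phi**2 / denom if denom > 0 else self.model.n - self.model.p
            df = float(np.clip(df, 1.0, self.model.n))
        t = est / np.sqrt(phi)
        p = 2.0 * sstats.t.sf(abs(t), df)
        return dict(estimate=est, se=float(np.sqrt(phi)), t=float(t),
                    df=float(df), p=float(p), F=float(t**2))


def median_split(df: pd.DataFrame, strength_col: str,
                 by: str = "subject_id") -> np.ndarray:
    """High/low split against the within-subject median (ties -> low)."""
    med = df.groupby(by)[strength_col].transform("median")
    return (df[strength_col] > med).to_numpy()


def median_split_lme(trials: pd.DataFrame,
                     context_col: str = "strength_context",
                     object_col: str = "strength_object",
                     error_col: str = "drop_error",
                     subject_col: str = "subject_id") -> dict:
    """Fit drop_error ~ 1 + X1*X2 + (1 | subject) with X1/X2 the
    within-subject median splits of context/object strength.

    Factors use centered (+-0.5) coding, so with two levels each the main
    effects and interaction are single-df contrasts (F = t^2).  Simple
    effects report the object-representation effect (high - low) within
    each context level.
    """
    df = trials.dropna(subset=[context_col, object_col, error_col]).copy()
    x1 = median_split(df, context_col, subject_col).astype(float) - 0.5
    x2 = median_split(df, object_col, subject_col).astype(float) - 0.5
    y = df[error_col].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), x1, x2, x1 * x2])
    groups = df[subject_col].to_numpy()
    if len(pd.unique(groups)) < 2:
        raise ValueError("need at least two subjects")

    model = RandomInterceptLMM(y, X, groups)
    fit = model.fit()
    if fit.singular:
        warnings.warn("singular fit (tau2 ~ 0); degrees of freedom fall back "
                      "to the fixed-effects residual df")
    out = dict(
        context=fit.contrast([0, 1, 0, 0]),
        object=fit.contrast([0, 0, 1, 0]),
        interaction=fit.contrast([0, 0, 0, 1]),
        simple_object_within_high_context=fit.contrast([0, 0, 1, 0.5]),
        simple_object_within_low_context=fit.contrast([0, 0, 1, -0.5]),
        sigma2=fit.sigma2, tau2=fit.tau2, singular=fit.singular,
        n_trials=len(df), beta=fit.beta.tolist(),
    )
    return out
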