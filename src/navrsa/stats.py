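"""Shared statistical machinery: Fisher z, cluster-based permutation tests,
Benjamini-Hochberg FDR.

Two permutation variants control the family-wise error over time windows:

* label shuffle — each subject's two condition values are swapped
  independently with probability 0.5 (equivalently, the paired difference is
  sign-flipped), the per-window group t is recomputed, and the maximal
  cluster mass is collected;
* sign flip — each subject's whole series (e.g., Fisher-z correlations) is
  multiplied by a random sign.

For paired data the two nulls coincide; both are provided to mirror the two
analysis branches they serve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

RHO_CLIP = 1.0 - 1e-10


def fisher_z(rho) -> np.ndarray | float:
    """atanh with the input required to lie strictly inside (-1, 1)."""
    r = np.asarray(rho, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|rho| >= 1; clip before transforming")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def fisher_z_inv(z) -> np.ndarray | float:
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def clip_rho(rho) -> np.ndarray:
    return np.clip(rho, -RHO_CLIP, RHO_CLIP)


@dataclass
class ClusterTestResult:
    clusters: list = field(default_factory=list)  # dicts: start, stop, mass, p
    n_permutations: int = 1000
    variant: str = "sign_flip"
    cluster_forming_alpha: float = 0.05
    tail: str = "greater"
    t_obs: np.ndarray | None = None
    null_quantiles: dict = field(default_factory=dict)

    @property
    def min_p(self) -> float:
        return min((c["p"] for c in self.clusters), default=1.0)

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c["p"] <= alpha]


def _window_t(d: np.ndarray) -> np.ndarray:
    """Per-window one-sample t across subjects of (subjects, windows) data."""
    n = d.shape[0]
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, m / (sd / np.sqrt(n)), np.where(m == 0, 0.0, np.inf))
    return t


def _find_clusters(t: np.ndarray, thr: float, tail: str) -> list[tuple[int, int, float]]:
    if tail == "greater":
        supra = t > thr
        vals = t
    elif tail == "less":
        supra = t < -thr
        vals = -t
    else:  # two-sided: clusters of same-signed exceedances
        supra = np.abs(t) > thr
        vals = np.abs(t)
    clusters = []
    i = 0
    n = len(t)
    while i < n:
        if supra[i]:
            j = i
            while j + 1 < n and supra[j + 1] and (
                    tail != "two-sided" or np.sign(t[j + 1]) == np.sign(t[i])):
                j += 1
            clusters.append((i, j + 1, float(vals[i:j + 1].sum())))
            i = j + 1
        else:
            i += 1
    return clusters


def _cluster_perm_core(d: np.ndarray, n_perm: int, alpha: float, tail: str,
                       rng: np.random.Generator, variant: str) -> ClusterTestResult:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] < 2:
        raise ValueError("need a (subjects >= 2, windows) array")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations; p-values are coarse")
    n_sub, n_win = d.shape
    df = n_sub - 1
    thr = sstats.t.ppf(1.0 - alpha if tail != "two-sided" else 1.0 - alpha / 2.0, df)

    t_obs = _window_t(d)
    clusters = _find_clusters(t_obs, thr, tail)

    # null: random sign per subject applied to the whole series; per-window t
    # recomputed in closed form from the flipped column sums
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    sums = signs @ d                       # (n_perm, n_win)
    q = (d**2).sum(axis=0)                 # invariant under sign flips
    mean_p = sums / n_sub
    var_p = np.maximum(q / n_sub - mean_p**2, 0.0) * n_sub / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = np.where(var_p > 0, mean_p / np.sqrt(var_p / n_sub), 0.0)
    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        cl = _find_clusters(t_null[p], thr, tail)
        if cl:
            null_max[p] = max(c[2] for c in cl)

    out = []
    for (i, j, mass) in sorted(clusters, key=lambda c: (-c[2], c[0])):
        pval = (1.0 + np.sum(null_max >= mass)) / (n_perm + 1.0)
        out.append(dict(start=i, stop=j, mass=mass, p=float(pval)))
    return ClusterTestResult(
        clusters=out, n_permutations=n_perm, variant=variant,
        cluster_forming_alpha=alpha, tail=tail, t_obs=t_obs,
        null_quantiles={"q95": float(np.quantile(null_max, 0.95)) if n_perm else np.nan})


def cluster_perm_label(cond_a: np.ndarray, cond_b: np.ndarray,
                       n_perm: int = 1000, alpha: float = 0.05,
                       tail: str = "greater",
                       rng: np.random.Generator | int | None = None
                       ) -> ClusterTestResult:
    """Cluster permutation test of condition A > B (paired, per subject).

    The null swaps each subject's two condition values independently with
    probability 0.5, which for the paired difference equals a sign flip.
    """
    rng = np.random.default_rng(rng)
    cond_a = np.asarray(cond_a, dtype=float)
    cond_b = np.asarray(cond_b, dtype=float)
    if cond_a.shape != cond_b.shape:
        raise ValueError("condition arrays must have the same shape")
    return _cluster_perm_core(cond_a - cond_b, n_perm, alpha, tail, rng,
                              variant="label_shuffle")


def cluster_perm_signflip(series: np.ndarray, n_perm: int = 1000,
                          alpha: float = 0.05, tail: str = "greater",
                          rng: np.random.Generator | int | None = None
                          ) -> ClusterTestResult:
    """Cluster permutation test of a subject x window series against zero,
    with whole-series random sign flips as the null."""
    rng = np.random.default_rng(rng)
    return _cluster_perm_core(np.asarray(series, dtype=float), n_perm, alpha,
                              tail, rng, variant="sign_flip")


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, monotone adjusted p)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj
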