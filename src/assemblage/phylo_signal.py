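"""Phylogenetic signal in organismal niches.

Niche optima are abundance-weighted means of the environmental axis; signal
is quantified two ways — Pagel's λ by maximum likelihood with a likelihood
ratio test against λ = 0, and a Mantel correlogram relating Euclidean niche
distances to patristic distance classes of width 0.02 on the standardized
(÷ max) phylogenetic distance.

The correlogram sign convention follows the autocorrelation reading:
``r = −cor(niche distance, within-class indicator)``, so a *positive* value
in a short distance class means close relatives have similar niches
(phylogenetic signal), and values typically turn negative or vanish at deep
classes. p-values are two-tailed permutation tests with a progressive
Bonferroni-style correction applied in order of increasing distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_io import PhyloTree

logger = logging.getLogger("assemblage")


def niche_optima(cm: pd.DataFrame, axis: pd.Series) -> pd.DataFrame:
    """Abundance-weighted niche optimum per taxon.

    optimum_i = Σ_s x_is·axis_s / Σ_s x_is, using only samples with a
    defined axis value. Taxa with zero total abundance are excluded (logged).
    """
    axis = axis.reindex(cm.index)
    ok = axis.notna()
    if not ok.all():
        logger.info("dropping %d samples without axis values", int((~ok).sum()))
    X = cm.loc[ok].values.astype(float)
    a = axis[ok].values.astype(float)
    totals = X.sum(axis=0)
    keep = totals > 0
    if (~keep).any():
        logger.info("excluding %d taxa with zero total abundance", int((~keep).sum()))
    opt = (X[:, keep] * a[:, None]).sum(axis=0) / totals[keep]
    return pd.DataFrame(
        {"optimum": opt, "weight": totals[keep]},
        index=cm.columns[keep].rename("taxon"),
    )


@dataclass
class PagelsLambdaResult:
    lambda_hat: float
    sigma2: float
    root_state: float
    loglik: float
    loglik_lambda0: float
    lr_statistic: float
    p_value: float
    identifiable: bool = True

    def to_dict(self) -> dict:
        return {
            "lambda": self.lambda_hat,
            "sigma2": self.sigma2,
            "root_state": self.root_state,
            "loglik": self.loglik,
            "loglik_lambda0": self.loglik_lambda0,
            "LR": self.lr_statistic,
            "p": self.p_value,
            "identifiable": self.identifiable,
        }


def _profile_loglik(lam: float, C: np.ndarray, d: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """GLS profile log-likelihood at λ: σ² and the root state are profiled
    out analytically."""
    n = len(y)
    V = lam * C + (1.0 - lam) * np.diag(d)
    try:
        cf = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf, np.nan, np.nan
    logdet = 2.0 * np.log(np.diag(cf)).sum()
    ones = np.ones(n)
    Vi_y = np.linalg.solve(V, y)
    Vi_1 = np.linalg.solve(V, ones)
    a_hat = (ones @ Vi_y) / (ones @ Vi_1)
    r = y - a_hat
    q = r @ np.linalg.solve(V, r)
    if q <= 0:
        return -np.inf, np.nan, a_hat
    sigma2 = q / n
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return ll, sigma2, a_hat


def pagels_lambda(tree: PhyloTree, trait: pd.Series) -> PagelsLambdaResult:
    """ML estimate of Pagel's λ with a boundary-aware likelihood ratio test.

    λ scales the off-diagonal entries of the Brownian covariance (tip depths
    unchanged) and is searched over [0, 1]. The LR statistic against λ = 0
    is referred to the ½χ²₀ + ½χ²₁ boundary mixture.
    """
    trait = trait.dropna()
    taxa = [t for t in tree.tip_labels if t in trait.index]
    if len(taxa) < 3:
        raise ValueError("need trait values for at least 3 tips")
    sub = tree.prune_to(taxa) if len(taxa) < tree.n_tips else tree
    C = sub.shared_path_matrix().loc[taxa, taxa].values
    d = np.diag(C).copy()
    y = trait.loc[taxa].values.astype(float)

    off = C - np.diag(d)
    identifiable = bool(np.abs(off).max() > 1e-12)
    if not identifiable:
        logger.warning("star tree: Pagel's λ is unidentifiable")

    ll0, s2_0, a0 = _profile_loglik(0.0, C, d, y)
    if not identifiable:
        return PagelsLambdaResult(0.0, s2_0, a0, ll0, ll0, 0.0, 1.0, False)

    res = optimize.minimize_scalar(
        lambda lam: -_profile_loglik(lam, C, d, y)[0],
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    candidates = [0.0, 1.0, float(res.x)]
    evals = [(_profile_loglik(lam, C, d, y), lam) for lam in candidates]
    (ll, s2, a), lam_hat = max(evals, key=lambda e: e[0][0])
    lr = max(0.0, 2.0 * (ll - ll0))
    p = 0.5 * stats.chi2.sf(lr, df=1) if lr > 0 else 1.0
    return PagelsLambdaResult(lam_hat, s2, a, ll, ll0, lr, p, True)


@dataclass
class CorrelogramResult:
    """Per-class Mantel correlations on the standardized patristic axis."""

    table: pd.DataFrame   # lower, upper, n_pairs, r, p, p_corrected, significant, tested
    class_width: float
    n_perm: int
    rng_seed: int
    min_pairs: int


def _condensed(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def mantel_correlogram(
    niche_dist: pd.DataFrame,
    phylo_dist: pd.DataFrame,
    class_width: float = 0.02,
    n_perm: int = 1000,
    rng_seed: int = 0,
    min_pairs: int = 10,
) -> CorrelogramResult:
    """Mantel correlogram of niche distances over patristic distance classes.

    Phylogenetic distances are standardized by their maximum (axis in
    [0, 1]); classes are half-open [lower, upper) of width ``class_width``,
    the last class closed. Classes with fewer than ``min_pairs`` pairs are
    reported but untested.
    """
    if list(niche_dist.index) != list(phylo_dist.index):
        raise ValueError("matrices must index identical taxa in the same order")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    n = niche_dist.shape[0]
    ND = niche_dist.values.astype(float)
    PDm = phylo_dist.values.astype(float)
    mx = PDm.max()
    if mx <= 0:
        raise ValueError("degenerate phylogenetic distances (all zero)")
    std = PDm / mx
    n_class = int(np.ceil(1.0 / class_width - 1e-9))

    iu = np.triu_indices(n, k=1)
    pvec = std[iu]
    nvec = ND[iu]
    if np.allclose(nvec, nvec[0]):
        raise ValueError("degenerate niche distances (all equal); r undefined")
    bins = np.minimum((pvec / class_width).astype(int), n_class - 1)

    ind = np.zeros((n_class, len(pvec)))
    for c in range(n_class):
        ind[c] = bins == c
    n_pairs = ind.sum(axis=1).astype(int)

    def class_r(dvec: np.ndarray) -> np.ndarray:
        """−cor(distance vector, class indicator) per class; NaN when the
        indicator is constant."""
        d0 = dvec - dvec.mean()
        dn = np.linalg.norm(d0)
        i0 = ind - ind.mean(axis=1, keepdims=True)
        inorm = np.linalg.norm(i0, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = -(i0 @ d0) / (inorm * dn)
        return r

    r_obs = class_r(nvec)
    rng = np.random.default_rng(rng_seed)
    exceed = np.zeros(n_class)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        nd_p = ND[np.ix_(perm, perm)][iu]
        r_p = class_r(nd_p)
        exceed += np.abs(r_p) >= np.abs(r_obs) - 1e-12
    p = (exceed + 1.0) / (n_perm + 1.0)

    tested = (n_pairs >= min_pairs) & np.isfinite(r_obs)
    p = np.where(tested, p, np.nan)
    # progressive correction in order of increasing distance
    p_corr = np.full(n_class, np.nan)
    k = 0
    for c in range(n_class):
        if tested[c]:
            k += 1
            p_corr[c] = min(1.0, p[c] * k)
    lower = np.arange(n_class) * class_width
    table = pd.DataFrame(
        {
            "lower": lower,
            "upper": lower + class_width,
            "n_pairs": n_pairs,
            "r": r_obs,
            "p": p,
            "p_corrected": p_corr,
            "significant": p_corr < 0.05,
            "tested": tested,
        }
    )
    return CorrelogramResult(table, class_width, n_perm, rng_seed, min_pairs)
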