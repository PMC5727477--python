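"""Group-level inference: Mantel tests, Monte-Carlo mean tests, PERMDISP
dispersion comparisons and fixed-breakpoint segmented regressions.

All permutation machinery is seeded explicitly; permutation p-values use
the (count + 1)/(n_perm + 1) convention so they are never exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("assemblage")


def normal_critical_value(alpha: float = 0.05, two_sided: bool = True) -> float:
    """Standard-normal critical value; the two-sided 5% value (≈1.96) is the
    anchor for the ±2 deviation thresholds."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    q = 1.0 - alpha / 2.0 if two_sided else 1.0 - alpha
    return float(stats.norm.ppf(q))


def ln_transform_differences(values: np.ndarray) -> np.ndarray:
    """Natural log of pairwise absolute differences; zero differences (pairs
    at the same level) are replaced by half the smallest positive difference
    before the log, with a warning."""
    v = np.asarray(values, dtype=float)
    pos = v[v > 0]
    if len(pos) == 0:
        raise ValueError("all differences are zero; ln-transform undefined")
    out = v.copy()
    if (v == 0).any():
        repl = 0.5 * pos.min()
        logger.warning(
            "ln-transform: %d zero differences replaced by %g",
            int((v == 0).sum()), repl,
        )
        out[v == 0] = repl
    return np.log(out)


# --------------------------------------------------------------------- #
# Mantel test
# --------------------------------------------------------------------- #
@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    tail: str


def mantel_test(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    n_perm: int = 10000,
    tail: str = "greater",
    rng_seed: int = 0,
) -> MantelResult:
    """Mantel correlation between two square symmetric matrices.

    Pearson r over the off-diagonal upper triangles; p by jointly permuting
    the rows/columns of the second matrix. ``tail`` is 'greater' (default),
    'less' or 'two-sided'.
    """
    if list(d1.index) != list(d2.index):
        raise ValueError("matrices must share IDs in identical order")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if tail not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    n = d1.shape[0]
    iu = np.triu_indices(n, k=1)
    x = d1.values[iu].astype(float)
    Y = d2.values.astype(float)
    y = Y[iu]
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("constant matrix: Mantel r undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])

    rng = np.random.default_rng(rng_seed)
    x0 = x - x.mean()
    xn = np.linalg.norm(x0)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = Y[np.ix_(perm, perm)][iu]
        y0 = yp - yp.mean()
        r_p = float(x0 @ y0 / (xn * np.linalg.norm(y0)))
        if tail == "greater":
            count += r_p >= r_obs - 1e-12
        elif tail == "less":
            count += r_p <= r_obs + 1e-12
        else:
            count += abs(r_p) >= abs(r_obs) - 1e-12
    p = (count + 1.0) / (n_perm + 1.0)
    return MantelResult(r=r_obs, p_value=float(p), n_perm=n_perm, tail=tail)


# --------------------------------------------------------------------- #
# Monte-Carlo mean test
# --------------------------------------------------------------------- #
@dataclass
class GroupDeviationSummary:
    group: str
    mean: float
    sd: float
    n: int
    p_value: float
    n_perm: int


def mean_deviation_test(
    values,
    n_perm: int = 10000,
    rng_seed: int = 0,
    group: str = "",
) -> GroupDeviationSummary:
    """Monte-Carlo test of mean deviation against zero.

    Null distribution from independent random sign flips of the observed
    values (symmetry about zero under H₀); two-tailed p on the mean.
    """
    v = np.asarray(list(values), dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    v = v[np.isfinite(v)]
    obs = v.mean()
    rng = np.random.default_rng(rng_seed)
    signs = rng.integers(0, 2, size=(n_perm, len(v))) * 2 - 1
    null_means = (signs * v).mean(axis=1)
    count = int((np.abs(null_means) >= abs(obs) - 1e-12).sum())
    p = (count + 1.0) / (n_perm + 1.0)
    return GroupDeviationSummary(
        group=group, mean=float(obs), sd=float(v.std(ddof=1)),
        n=len(v), p_value=float(p), n_perm=n_perm,
    )


# --------------------------------------------------------------------- #
# PERMDISP
# --------------------------------------------------------------------- #
@dataclass
class PermdispResult:
    distances: pd.Series        # per-sample distance to own-group centroid
    group_means: pd.Series
    f_statistic: float
    p_value: float
    n_perm: int
    rng_seed: int
    shifted: bool = False       # True when negative dissimilarities were shifted


def _pcoa_axes(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinates embedding of a symmetric dissimilarity matrix.

    Returns (real axes, imaginary axes): eigenvectors scaled by sqrt|λ|,
    split by eigenvalue sign. Squared distances in the embedding are
    (real part)² − (imaginary part)², the standard correction for
    non-Euclidean dissimilarities.
    """
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = 0.5 * (G + G.T)
    w, V = np.linalg.eigh(G)
    tol = 1e-10 * max(1.0, np.abs(w).max())
    pos = w > tol
    neg = w < -tol
    real = V[:, pos] * np.sqrt(w[pos])
    imag = V[:, neg] * np.sqrt(-w[neg])
    return real, imag


def _centroid_distances(real, imag, labels: np.ndarray) -> np.ndarray:
    d2 = np.zeros(real.shape[0])
    for g in np.unique(labels):
        m = labels == g
        cr = real[m].mean(axis=0)
        d2[m] = ((real[m] - cr) ** 2).sum(axis=1)
        if imag.shape[1]:
            ci = imag[m].mean(axis=0)
            d2[m] -= ((imag[m] - ci) ** 2).sum(axis=1)
    return np.sqrt(np.maximum(d2, 0.0))


def _dispersion_f(dists: np.ndarray, labels: np.ndarray) -> float:
    groups = np.unique(labels)
    grand = dists.mean()
    ssb = sum(
        (labels == g).sum() * (dists[labels == g].mean() - grand) ** 2
        for g in groups
    )
    ssw = sum(
        ((dists[labels == g] - dists[labels == g].mean()) ** 2).sum()
        for g in groups
    )
    df1 = len(groups) - 1
    df2 = len(dists) - len(groups)
    if ssw <= 1e-300:
        return np.inf if ssb > 0 else 0.0
    return (ssb / df1) / (ssw / df2)


def distances_to_centroid(dmat: pd.DataFrame, groups: pd.Series | None = None) -> pd.Series:
    """Per-sample distance to its group centroid in the PCoA embedding of
    ``dmat``. Signed dissimilarities (negative off-diagonal entries, e.g.
    βNTI matrices) are shifted by |min| first, with a log message."""
    D = dmat.values.astype(float).copy()
    iu = np.triu_indices(D.shape[0], k=1)
    if (D[iu] < 0).any():
        shift = -D[iu].min()
        logger.info("shifting signed dissimilarities by %g before PCoA", shift)
        D = D + shift
        np.fill_diagonal(D, 0.0)
    labels = (
        np.zeros(D.shape[0], dtype=int)
        if groups is None
        else groups.reindex(dmat.index).values
    )
    real, imag = _pcoa_axes(D)
    return pd.Series(_centroid_distances(real, imag, labels), index=dmat.index)


def permdisp(
    dmat: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 999,
    rng_seed: int = 0,
) -> PermdispResult:
    """Permutational analysis of multivariate group dispersions.

    The dissimilarity matrix is embedded by principal coordinates (negative
    eigenvalues handled by the imaginary-axis correction of squared
    distances); the F-like ratio compares between- vs within-group variance
    of distances to own-group centroids, and p comes from permuting group
    labels (centroids recomputed each time).
    """
    groups = groups.reindex(dmat.index)
    if groups.isna().any():
        raise ValueError("group labels missing for some samples")
    labels = groups.values
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError("each group needs at least 2 samples")

    D = dmat.values.astype(float).copy()
    iu = np.triu_indices(D.shape[0], k=1)
    shifted = bool((D[iu] < 0).any())
    if shifted:
        shift = -D[iu].min()
        logger.info("shifting signed dissimilarities by %g before PCoA", shift)
        D = D + shift
        np.fill_diagonal(D, 0.0)
    real, imag = _pcoa_axes(D)

    dists = _centroid_distances(real, imag, labels)
    f_obs = _dispersion_f(dists, labels)
    rng = np.random.default_rng(rng_seed)
    count = 0
    for _ in range(n_perm):
        lp = rng.permutation(labels)
        f_p = _dispersion_f(_centroid_distances(real, imag, lp), lp)
        count += f_p >= f_obs - 1e-12
    p = (count + 1.0) / (n_perm + 1.0)
    gm = pd.Series(
        {g: dists[labels == g].mean() for g in uniq}, name="mean_distance"
    )
    return PermdispResult(
        distances=pd.Series(dists, index=dmat.index),
        group_means=gm,
        f_statistic=float(f_obs),
        p_value=float(p),
        n_perm=n_perm,
        rng_seed=rng_seed,
        shifted=shifted,
    )


# --------------------------------------------------------------------- #
# segmented regression with fixed breakpoint
# --------------------------------------------------------------------- #
@dataclass
class SegmentFit:
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int
    slope_ci: tuple[float, float]


@dataclass
class SegmentedFit:
    breakpoint: float
    left: SegmentFit
    right: SegmentFit
    n_boot: int
    rng_seed: int

    def to_dict(self) -> dict:
        def seg(s: SegmentFit) -> dict:
            return {
                "slope": s.slope, "intercept": s.intercept, "R2": s.r2,
                "p": s.p_value, "n": s.n, "slope_ci": list(s.slope_ci),
            }
        return {
            "breakpoint": self.breakpoint,
            "left": seg(self.left),
            "right": seg(self.right),
        }


def _fit_segment(x, y, n_boot, rng) -> SegmentFit:
    res = stats.linregress(x, y)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    slopes = np.empty(n_boot)
    n = len(x)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(x[idx])) < 2:
            slopes[b] = res.slope
            continue
        slopes[b] = stats.linregress(x[idx], y[idx]).slope
    lo, hi = np.percentile(slopes, [2.5, 97.5])
    return SegmentFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r2=r2, p_value=p, n=n, slope_ci=(float(lo), float(hi)),
    )


def segmented_fit(
    x,
    y,
    breakpoint: float,
    n_boot: int = 1000,
    rng_seed: int = 0,
) -> SegmentedFit:
    """Two independent OLS fits either side of a user-fixed breakpoint.

    The boundary value belongs to both segments (the printed ranges of a
    split like 0–10.5 and 10.5–28 both include 10.5). 95% slope CIs by
    case-resampling percentile bootstrap.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    left = x <= breakpoint
    right = x >= breakpoint
    if left.sum() < 3 or right.sum() < 3:
        raise ValueError("need at least 3 points in each segment")
    rng = np.random.default_rng(rng_seed)
    return SegmentedFit(
        breakpoint=float(breakpoint),
        left=_fit_segment(x[left], y[left], n_boot, rng),
        right=_fit_segment(x[right], y[right], n_boot, rng),
        n_boot=n_boot,
        rng_seed=rng_seed,
    )
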