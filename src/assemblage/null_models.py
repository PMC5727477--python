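"""Null models for phylogenetic and compositional turnover.

βNTI / βNRI standardize the observed βMNTD / βMPD against a null obtained
by shuffling taxon positions on the phylogeny (one joint row/column
permutation of the patristic matrix per null run, shared by every sample
pair — the whole species pool is randomized at once, which fixes observed
α- and β-diversity). Deviations beyond ±2 flag deterministic assembly
(≈ ±1.96 at a two-sided 5% error level).

RC_bray compares observed Bray-Curtis to a null that reassembles each
sample by (1) drawing taxa without replacement with probability
proportional to their occurrence frequency in the species pool until the
observed richness is reached, and (2) distributing the observed number of
individuals over the drawn taxa proportionally to pool relative abundance
(each drawn taxon seeded with one individual so richness is preserved).
RC_bray = 2·((n_below + ½·n_equal)/n_null) − 1 ∈ [−1, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("assemblage")

_SD_TOL = 1e-10


# --------------------------------------------------------------------- #
# observed dissimilarities
# --------------------------------------------------------------------- #
def bray_curtis(cm: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis: 1 − 2·Σ min(x_j, x_k) / (Σ x_j + Σ x_k)."""
    X = cm.values.astype(float)
    totals = X.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError(f"empty samples: {list(cm.index[totals <= 0])}")
    shared = np.minimum(X[:, None, :], X[None, :, :]).sum(axis=-1)
    bc = 1.0 - 2.0 * shared / (totals[:, None] + totals[None, :])
    np.fill_diagonal(bc, 0.0)
    return pd.DataFrame(bc, index=cm.index, columns=cm.index)


def tip_shuffle_null(dmat: pd.DataFrame, rng_seed: int = 0) -> pd.DataFrame:
    """One tip-label shuffle: a single random permutation applied jointly to
    rows and columns. Labels keep their positions; the multiset of
    off-diagonal distances is unchanged."""
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(dmat.shape[0])
    return pd.DataFrame(
        dmat.values[np.ix_(perm, perm)], index=dmat.index, columns=dmat.columns
    )


# --------------------------------------------------------------------- #
# β-deviation (βNTI / βNRI)
# --------------------------------------------------------------------- #
@dataclass
class BetaDeviationResult:
    """Observed β-metric with its tip-shuffle null and standardized deviation."""

    metric: str                 # "bMNTD" or "bMPD"
    observed: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    deviation: pd.DataFrame     # βNTI or βNRI; NaN where undefined
    undefined: pd.DataFrame     # True where null sd ~ 0
    n_null: int
    rng_seed: int

    def pair_values(self) -> pd.DataFrame:
        """Long format: one row per unordered sample pair."""
        samples = list(self.observed.index)
        rows = []
        for a in range(len(samples)):
            for b in range(a + 1, len(samples)):
                rows.append(
                    {
                        "sample_i": samples[a],
                        "sample_j": samples[b],
                        "metric": self.metric,
                        "obs": self.observed.iat[a, b],
                        "null_mean": self.null_mean.iat[a, b],
                        "null_sd": self.null_sd.iat[a, b],
                        "deviation": self.deviation.iat[a, b],
                    }
                )
        return pd.DataFrame(rows)


def _restrict_to_pool(cm, dmat, pool):
    """Scope the analysis to a species pool.

    With ``pool=None`` the pool is the supplied table as-is: every taxon
    column — including zero-only taxa — is part of the declared universe
    and takes part in the shuffle. With ``pool`` a set of samples, the
    comparisons are restricted to those samples and the shuffle universe to
    the union of taxa present in them.
    """
    if pool is None:
        return cm, dmat.loc[cm.columns, cm.columns]
    cm = cm.loc[list(pool)]
    present = cm.columns[(cm > 0).any(axis=0)]
    cm = cm[present]
    dmat = dmat.loc[present, present]
    return cm, dmat


def _beta_deviation(
    cm: pd.DataFrame,
    dmat: pd.DataFrame,
    metric: str,
    n_null: int,
    rng_seed: int,
    pool,
    abundance_weighted: bool,
) -> BetaDeviationResult:
    from .phylo_metrics import _mntd_from_weights, _weights

    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    cm, dmat = _restrict_to_pool(cm, dmat, pool)
    if list(cm.columns) != list(dmat.columns):
        raise ValueError("community taxa and distance matrix taxa differ")
    rng = np.random.default_rng(rng_seed)
    F = _weights(cm, abundance_weighted)
    D = dmat.values
    present = [np.where(row > 0)[0] for row in cm.values]
    n_taxa = D.shape[0]

    if metric == "bMNTD":
        def compute(Dm):
            return _mntd_from_weights(F, present, Dm)
    elif metric == "bMPD":
        def compute(Dm):
            return F @ Dm @ F.T
    else:  # pragma: no cover
        raise ValueError(metric)

    obs = compute(D)
    nulls = np.empty((n_null,) + obs.shape)
    for r in range(n_null):
        perm = rng.permutation(n_taxa)
        nulls[r] = compute(D[np.ix_(perm, perm)])
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    undefined = sd < _SD_TOL
    dev = np.where(undefined, np.nan, (obs - mean) / np.where(undefined, 1.0, sd))
    # self-comparisons carry no information; zero diagonal by convention
    np.fill_diagonal(dev, 0.0)
    np.fill_diagonal(undefined, False)
    n_undef = int(undefined[np.triu_indices_from(undefined, k=1)].sum())
    if n_undef:
        logger.info(
            "%s deviation undefined (null sd ~ 0) for %d pairs", metric, n_undef
        )
    ids = cm.index
    wrap = lambda a: pd.DataFrame(a, index=ids, columns=ids)
    return BetaDeviationResult(
        metric=metric,
        observed=wrap(obs),
        null_mean=wrap(mean),
        null_sd=wrap(sd),
        deviation=wrap(dev),
        undefined=wrap(undefined),
        n_null=n_null,
        rng_seed=rng_seed,
    )


def beta_nti(
    cm: pd.DataFrame,
    dmat: pd.DataFrame,
    n_null: int = 1000,
    rng_seed: int = 0,
    pool=None,
    abundance_weighted: bool = True,
) -> BetaDeviationResult:
    """β nearest taxon index: standardized βMNTD deviation under tip
    shuffling. ``pool`` (an iterable of sample IDs) restricts both the
    samples compared and the taxa that constitute the shuffle universe."""
    return _beta_deviation(cm, dmat, "bMNTD", n_null, rng_seed, pool, abundance_weighted)


def beta_nri(
    cm: pd.DataFrame,
    dmat: pd.DataFrame,
    n_null: int = 1000,
    rng_seed: int = 0,
    pool=None,
    abundance_weighted: bool = True,
) -> BetaDeviationResult:
    """β net relatedness index: as βNTI but on the basal metric βMPD."""
    return _beta_deviation(cm, dmat, "bMPD", n_null, rng_seed, pool, abundance_weighted)


# --------------------------------------------------------------------- #
# Raup-Crick on Bray-Curtis
# --------------------------------------------------------------------- #
@dataclass
class RaupCrickResult:
    observed_bc: pd.DataFrame
    rc: pd.DataFrame            # ∈ [−1, 1]
    n_null: int
    rng_seed: int

    def pair_values(self) -> pd.DataFrame:
        samples = list(self.rc.index)
        rows = []
        for a in range(len(samples)):
            for b in range(a + 1, len(samples)):
                rows.append(
                    {
                        "sample_i": samples[a],
                        "sample_j": samples[b],
                        "bray_curtis": self.observed_bc.iat[a, b],
                        "rc_bray": self.rc.iat[a, b],
                    }
                )
        return pd.DataFrame(rows)


def _null_assemblages(
    rng: np.random.Generator,
    n_null: int,
    richness: int,
    total: int,
    occ_freq: np.ndarray,
    abund_w: np.ndarray,
) -> np.ndarray:
    """``n_null`` null count vectors preserving richness and total count.

    Occupancy uses exponential keys (argmin of Exp(1)/w), distributionally
    identical to sequential weighted draws without replacement; abundance
    seeds each drawn taxon with one individual then assigns the remainder
    multinomially with probability ∝ pool relative abundance.
    """
    n_taxa = len(occ_freq)
    keys = rng.exponential(size=(n_null, n_taxa)) / occ_freq
    sel = np.argpartition(keys, richness - 1, axis=1)[:, :richness]
    P = abund_w[sel]
    P = P / P.sum(axis=1, keepdims=True)
    extra = rng.multinomial(total - richness, P)
    counts = np.zeros((n_null, n_taxa), dtype=np.int64)
    np.put_along_axis(counts, sel, 1 + extra, axis=1)
    return counts


def raup_crick_bray(
    cm: pd.DataFrame,
    n_null: int = 999,
    rng_seed: int = 0,
    pool=None,
) -> RaupCrickResult:
    """Bray-Curtis-based Raup-Crick for all sample pairs.

    Requires integer counts (the null distributes individuals). Ties between
    null and observed Bray-Curtis count half (mid-rank), so RC = 0 is
    attainable and RC is bounded in [−1, 1].
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    X_all = cm.values
    if not np.allclose(X_all, np.round(X_all), atol=1e-9):
        raise ValueError(
            "raup_crick_bray requires integer abundances; round counts or "
            "rescale relative abundances to integers first"
        )
    if pool is not None:
        cm = cm.loc[list(pool)]
    present = cm.columns[(cm > 0).any(axis=0)]
    cm = cm[present]
    X = np.round(cm.values).astype(np.int64)

    occ_freq = (X > 0).sum(axis=0).astype(float)
    abund_w = X.sum(axis=0).astype(float)
    richness = (X > 0).sum(axis=1)
    totals = X.sum(axis=1)
    if (richness > X.shape[1]).any():  # defensive; cannot happen post-restriction
        raise ValueError("sample richness exceeds species-pool size")
    if (totals <= 0).any():
        raise ValueError(f"empty samples: {list(cm.index[totals <= 0])}")

    obs_bc = bray_curtis(cm)
    rng = np.random.default_rng(rng_seed)
    n_s = X.shape[0]
    rc = np.zeros((n_s, n_s))
    for a in range(n_s):
        for b in range(a + 1, n_s):
            A = _null_assemblages(rng, n_null, richness[a], totals[a], occ_freq, abund_w)
            B = _null_assemblages(rng, n_null, richness[b], totals[b], occ_freq, abund_w)
            shared = np.minimum(A, B).sum(axis=1)
            null_bc = 1.0 - 2.0 * shared / (totals[a] + totals[b])
            o = obs_bc.iat[a, b]
            n_below = int((null_bc < o - 1e-12).sum())
            n_equal = int((np.abs(null_bc - o) <= 1e-12).sum())
            val = 2.0 * ((n_below + 0.5 * n_equal) / n_null) - 1.0
            rc[a, b] = rc[b, a] = val
    rc_df = pd.DataFrame(rc, index=cm.index, columns=cm.index)
    return RaupCrickResult(
        observed_bc=obs_bc, rc=rc_df, n_null=n_null, rng_seed=rng_seed
    )
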