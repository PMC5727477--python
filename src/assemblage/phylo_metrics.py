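"""Patristic distances, Faith's PD with standardized effect size, and the
pairwise phylogenetic β-diversity metrics βMPD and βMNTD.

βMNTD is the 'terminal' metric — each taxon is matched to its closest
relative in the other community — while βMPD averages over all cross-pairs
and is therefore sensitive to deep ('basal') phylogenetic structure. Both
default to abundance weighting with within-sample relative abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import PhyloTree

logger = logging.getLogger("assemblage")


def patristic_distances(tree: PhyloTree) -> pd.DataFrame:
    """Square matrix of tip-to-tip path lengths (branch-length units)."""
    d = tree.patristic_matrix()
    assert np.allclose(d.values, d.values.T, atol=1e-12)
    return d


def _check_alignment(cm: pd.DataFrame, ids) -> None:
    if list(cm.columns) != list(ids):
        raise ValueError(
            "community table taxa and tree/distance-matrix taxa differ or "
            "are ordered differently; run align_tree_and_table first"
        )


def faith_pd(cm: pd.DataFrame, tree: PhyloTree) -> pd.Series:
    """Faith's phylogenetic diversity per sample (presence-based).

    Sum of branch lengths of the minimal rooted subtree spanning the root
    and all present taxa — the root path is included, which matters for
    single-tip samples. Zero-richness samples yield NaN with a warning.
    """
    _check_alignment(cm, tree.tip_labels)
    lengths, inc = tree.edge_incidence()
    P = (cm.values > 0)
    covered = inc.astype(float) @ P.T.astype(float) > 0  # edges × samples
    pd_vals = lengths @ covered
    empty = ~P.any(axis=1)
    if empty.any():
        logger.warning(
            "faith_pd undefined for zero-richness samples: %s",
            list(cm.index[empty]),
        )
        pd_vals = pd_vals.astype(float)
        pd_vals[empty] = np.nan
    return pd.Series(pd_vals, index=cm.index, name="PD")


@dataclass
class SesPDResult:
    """Per-sample PD against a tip-label-shuffling null."""

    observed: pd.Series
    null_mean: pd.Series
    null_sd: pd.Series
    ses: pd.Series          # (obs − null mean)/null sd; NaN where undefined
    p_value: pd.Series      # two-tailed rank p
    undefined: pd.Series    # True where null sd ~ 0
    n_null: int
    rng_seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "PD": self.observed,
                "null_mean": self.null_mean,
                "null_sd": self.null_sd,
                "ses_PD": self.ses,
                "p": self.p_value,
                "undefined": self.undefined,
            }
        )


def ses_pd(
    cm: pd.DataFrame,
    tree: PhyloTree,
    n_null: int = 999,
    rng_seed: int = 0,
) -> SesPDResult:
    """Standardized effect size of PD under tip-label shuffling.

    Each null run permutes the assignment of taxa to tips, preserving tree
    shape and sample richness. Samples whose null distribution is constant
    (e.g. containing every taxon) are flagged undefined rather than given
    an infinite score.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    _check_alignment(cm, tree.tip_labels)
    rng = np.random.default_rng(rng_seed)
    lengths, inc = tree.edge_incidence()
    incf = inc.astype(float)
    P = (cm.values > 0).astype(float)  # samples × taxa
    obs = faith_pd(cm, tree)

    n_taxa = P.shape[1]
    nulls = np.empty((n_null, P.shape[0]))
    for r in range(n_null):
        perm = rng.permutation(n_taxa)
        covered = incf @ P[:, perm].T > 0
        nulls[r] = lengths @ covered

    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    undefined = sd < 1e-10
    ses = np.where(undefined, np.nan, (obs.values - mean) / np.where(undefined, 1.0, sd))
    n_le = (nulls <= obs.values[None, :] + 1e-12).sum(axis=0)
    n_ge = (nulls >= obs.values[None, :] - 1e-12).sum(axis=0)
    p = np.minimum(1.0, 2.0 * np.minimum(n_le + 1, n_ge + 1) / (n_null + 1))
    idx = cm.index
    return SesPDResult(
        observed=obs,
        null_mean=pd.Series(mean, index=idx),
        null_sd=pd.Series(sd, index=idx),
        ses=pd.Series(ses, index=idx, name="ses_PD"),
        p_value=pd.Series(p, index=idx),
        undefined=pd.Series(undefined, index=idx),
        n_null=n_null,
        rng_seed=rng_seed,
    )


def _weights(cm: pd.DataFrame, abundance_weighted: bool) -> np.ndarray:
    X = cm.values.astype(float)
    if not abundance_weighted:
        X = (X > 0).astype(float)
    totals = X.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError(
            f"empty samples: {list(cm.index[totals <= 0])}"
        )
    return X / totals[:, None]


def _mntd_from_weights(F: np.ndarray, present: list[np.ndarray], D: np.ndarray) -> np.ndarray:
    """βMNTD for all sample pairs given relative abundances and a distance
    matrix: ½[Σ_i f_ij·min_{i'∈k} d + Σ_i' f_i'k·min_{i∈j} d]."""
    n_s = F.shape[0]
    M = np.empty((D.shape[0], n_s))
    for s, idxs in enumerate(present):
        M[:, s] = D[:, idxs].min(axis=1)
    term = F @ M  # term[j, k] = Σ_i f_ij · min-dist(i → sample k)
    return 0.5 * (term + term.T)


def beta_mntd(
    cm: pd.DataFrame,
    dmat: pd.DataFrame,
    abundance_weighted: bool = True,
) -> pd.DataFrame:
    """Abundance-weighted β mean nearest taxon distance between all sample
    pairs. A taxon shared by both samples contributes zero (its nearest
    relative in the other community is itself)."""
    _check_alignment(cm, dmat.columns)
    F = _weights(cm, abundance_weighted)
    D = dmat.values
    present = [np.where(row > 0)[0] for row in cm.values]
    B = _mntd_from_weights(F, present, D)
    return pd.DataFrame(B, index=cm.index, columns=cm.index)


def beta_mpd(
    cm: pd.DataFrame,
    dmat: pd.DataFrame,
    abundance_weighted: bool = True,
) -> pd.DataFrame:
    """Abundance-weighted β mean pairwise distance: Σ_i Σ_i' f_ij f_i'k d(i,i')."""
    _check_alignment(cm, dmat.columns)
    F = _weights(cm, abundance_weighted)
    B = F @ dmat.values @ F.T
    return pd.DataFrame(B, index=cm.index, columns=cm.index)
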