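"""Input/output and reconciliation of trees, community tables and metadata.

Conventions
-----------
On disk the community table is taxa-by-samples (rows are taxa, columns are
samples, TSV with a header of sample IDs) — the common amplicon layout.
In memory the orientation is samples-major: a :class:`pandas.DataFrame`
whose *index* holds sample IDs and whose *columns* hold taxon IDs.

Trees are rooted newick with branch lengths on every edge (the root edge
may omit its length; it is treated as zero). Zero-length branches are
accepted with a warning because they collapse nearest-taxon distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("assemblage")

__all__ = [
    "PhyloTree",
    "read_tree",
    "read_community",
    "write_community",
    "read_metadata",
    "filter_rare",
    "align_tree_and_table",
]


@dataclass
class PhyloTree:
    """A validated rooted phylogeny with branch lengths.

    Wraps a :class:`dendropy.Tree` and exposes the derived quantities the
    analysis layer needs: patristic distances, root-to-tip depths, the
    Brownian (shared-path-length) covariance structure and an edge/tip
    incidence used for Faith's PD.
    """

    tree: dendropy.Tree
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._validate()

    # ------------------------------------------------------------------ #
    # validation & basic accessors
    # ------------------------------------------------------------------ #
    def _validate(self) -> None:
        seed = self.tree.seed_node
        labels: list[str] = []
        for node in self.tree.preorder_node_iter():
            if node is seed:
                continue
            if node.edge.length is None:
                name = node.taxon.label if node.taxon else "<internal>"
                raise ValueError(
                    f"missing branch length on edge above node {name!r}"
                )
            if node.edge.length < 0:
                raise ValueError(
                    f"negative branch length {node.edge.length} in tree"
                )
            if node.edge.length == 0:
                logger.warning(
                    "zero-length branch in tree: nearest-taxon distances "
                    "may collapse"
                )
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise ValueError("tree has an unlabeled tip")
            labels.append(leaf.taxon.label)
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        if len(labels) < 2:
            raise ValueError("tree must have at least 2 tips")
        self._cache.clear()
        self._cache["tip_labels"] = labels

    @property
    def tip_labels(self) -> list[str]:
        return list(self._cache["tip_labels"])

    @property
    def n_tips(self) -> int:
        return len(self._cache["tip_labels"])

    def total_branch_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self.tree.preorder_edge_iter()
        )

    # ------------------------------------------------------------------ #
    # derived structure
    # ------------------------------------------------------------------ #
    def _build_structure(self) -> None:
        """One postorder/preorder sweep computing depths, MRCA depths and
        the edge-tip incidence."""
        labels = self._cache["tip_labels"]
        idx = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)

        root_dist: dict[int, float] = {}
        seed = self.tree.seed_node
        for node in self.tree.preorder_node_iter():
            if node is seed:
                root_dist[id(node)] = node.edge.length or 0.0
            else:
                root_dist[id(node)] = root_dist[id(node.parent_node)] + node.edge.length

        depths = np.zeros(n)
        mrca = np.zeros((n, n))
        edge_lengths: list[float] = []
        edge_tips: list[np.ndarray] = []
        below: dict[int, np.ndarray] = {}

        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                i = idx[node.taxon.label]
                mask = np.zeros(n, dtype=bool)
                mask[i] = True
                below[id(node)] = mask
                depths[i] = root_dist[id(node)]
            else:
                groups = [below.pop(id(c)) for c in node.child_nodes()]
                d = root_dist[id(node)]
                for a in range(len(groups)):
                    for b in range(a + 1, len(groups)):
                        ia = np.where(groups[a])[0]
                        ib = np.where(groups[b])[0]
                        mrca[np.ix_(ia, ib)] = d
                        mrca[np.ix_(ib, ia)] = d
                mask = np.logical_or.reduce(groups)
                below[id(node)] = mask
            if node is not seed:
                edge_lengths.append(node.edge.length)
                edge_tips.append(below[id(node)].copy())

        np.fill_diagonal(mrca, depths)
        self._cache["depths"] = depths
        self._cache["mrca_depth"] = mrca
        self._cache["edge_lengths"] = np.asarray(edge_lengths, dtype=float)
        self._cache["edge_tips"] = np.asarray(edge_tips, dtype=bool)

    def _structure(self, key: str) -> np.ndarray:
        if key not in self._cache:
            self._build_structure()
        return self._cache[key]

    def root_depths(self) -> pd.Series:
        """Root-to-tip path lengths."""
        return pd.Series(self._structure("depths"), index=self.tip_labels)

    def patristic_matrix(self) -> pd.DataFrame:
        """Pairwise path lengths between tips (d_ij = h_i + h_j − 2·mrca_ij)."""
        depths = self._structure("depths")
        mrca = self._structure("mrca_depth")
        d = depths[:, None] + depths[None, :] - 2.0 * mrca
        np.fill_diagonal(d, 0.0)
        labels = self.tip_labels
        return pd.DataFrame(d, index=labels, columns=labels)

    def shared_path_matrix(self) -> pd.DataFrame:
        """Brownian-motion covariance structure: shared root-path length of
        each tip pair; the diagonal is the tip depth."""
        labels = self.tip_labels
        return pd.DataFrame(
            self._structure("mrca_depth").copy(), index=labels, columns=labels
        )

    def edge_incidence(self) -> tuple[np.ndarray, np.ndarray]:
        """(edge_lengths, incidence) with ``incidence[e, t]`` true when tip
        ``t`` (in ``tip_labels`` order) descends through edge ``e``."""
        return self._structure("edge_lengths"), self._structure("edge_tips")

    # ------------------------------------------------------------------ #
    # manipulation & I/O
    # ------------------------------------------------------------------ #
    def prune_to(self, labels) -> "PhyloTree":
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        clone = self.tree.clone(depth=1)
        clone.retain_taxa_with_labels(sorted(keep))
        return PhyloTree(clone)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        return cls(_parse_newick(data=newick))


def _parse_newick(**source) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            schema="newick", preserve_underscores=True, **source
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip labels in newick: {exc}") from exc


def read_tree(path) -> PhyloTree:
    """Read a rooted newick tree with branch lengths.

    Raises on missing branch lengths (naming the offending edge) and on
    duplicate tip labels.
    """
    pt = PhyloTree(_parse_newick(path=str(path)))
    logger.info("read tree with %d tips from %s", pt.n_tips, path)
    return pt


def read_community(path) -> pd.DataFrame:
    """Read a taxa-by-samples TSV into the in-memory samples × taxa frame.

    Zero-only taxa are retained (filtering is an explicit, separate step);
    all-zero samples are accepted but flagged in the log because the
    β-metrics reject them later.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    try:
        raw = raw.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in community table {path}: {exc}")
    if raw.isna().any().any():
        r, c = np.argwhere(raw.isna().values)[0]
        raise ValueError(
            f"non-numeric cell in community table at taxon {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r}"
        )
    if (raw.values < 0).any():
        r, c = np.argwhere(raw.values < 0)[0]
        raise ValueError(
            f"negative abundance at taxon {raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    cm = raw.T  # samples-major in memory
    cm.index.name = "sample"
    cm.columns.name = "taxon"
    empty = cm.index[cm.sum(axis=1) == 0]
    if len(empty):
        logger.warning("samples with zero total abundance: %s", list(empty))
    return cm


def write_community(cm: pd.DataFrame, path) -> None:
    """Write the samples × taxa frame back to the on-disk taxa × samples TSV."""
    out = cm.T
    out.index.name = "taxon"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata (sample ID index; group and/or numeric covariate
    columns). One record per sample enforced."""
    md = pd.read_csv(path, sep="\t", index_col=0)
    if md.index.duplicated().any():
        dupes = sorted(set(md.index[md.index.duplicated()]))
        raise ValueError(f"duplicate sample IDs in metadata: {dupes}")
    return md


def filter_rare(
    cm: pd.DataFrame,
    min_occupancy: int = 0,
    min_mean_rel_abund: float = 0.0,
) -> pd.DataFrame:
    """Drop rare taxa by occupancy and/or mean relative abundance.

    A taxon is removed when it occurs (abundance > 0) in fewer than
    ``min_occupancy`` samples, or when its mean relative abundance across
    all samples (per-sample normalisation first, absences counted as zero)
    is below ``min_mean_rel_abund``. The two rules are independent; either
    may be disabled with 0.
    """
    if min_occupancy < 0 or min_mean_rel_abund < 0:
        raise ValueError("thresholds must be non-negative")
    occupancy = (cm > 0).sum(axis=0)
    totals = cm.sum(axis=1)
    rel = cm.div(totals.where(totals > 0, np.nan), axis=0).fillna(0.0)
    mean_rel = rel.mean(axis=0)
    keep = (occupancy >= min_occupancy) & (mean_rel >= min_mean_rel_abund)
    dropped = int((~keep).sum())
    if dropped:
        logger.info(
            "filter_rare removed %d/%d taxa (min_occupancy=%d, "
            "min_mean_rel_abund=%g)",
            dropped, cm.shape[1], min_occupancy, min_mean_rel_abund,
        )
    out = cm.loc[:, keep]
    if out.shape[1] == 0:
        raise ValueError("all taxa removed by rare-taxon filter")
    return out


def align_tree_and_table(
    tree: PhyloTree, cm: pd.DataFrame
) -> tuple[PhyloTree, pd.DataFrame]:
    """Reconcile tree tips and table taxa to their intersection.

    The tree is pruned to taxa present in the table; the table is restricted
    to tree tips and reordered to the pruned tree's tip order. Dropped IDs
    on either side are logged.
    """
    tips = set(tree.tip_labels)
    taxa = set(cm.columns)
    shared = tips & taxa
    if not shared:
        raise ValueError("tree and community table share no taxon IDs")
    drop_tree = tips - shared
    drop_cm = taxa - shared
    if drop_tree:
        logger.info("pruning %d tips absent from table", len(drop_tree))
    if drop_cm:
        logger.info("dropping %d taxa absent from tree", len(drop_cm))
    pruned = tree.prune_to(shared) if drop_tree else tree
    out = cm.loc[:, pruned.tip_labels]
    return pruned, out
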