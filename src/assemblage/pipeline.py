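"""End-to-end orchestration of the two study designs.

* Gradient design: spatial turnover along a press gradient (e.g. chronic N
  deposition) — ses.PD with a segmented fit against the gradient, βNTI and
  βNRI between and within gradient levels, and segmented fits of βNRI
  against ln |Δ level|.
* Pulse design: temporal turnover after a pulse disturbance in closed
  microcosms — per-pool βNTI, RC_bray, seven-category process fractions
  (dispersal_possible=False by default), Mantel test of βNTI against
  ln-time differences, Monte-Carlo mean tests, and a dispersion comparison
  of per-pool βNTI distance-to-centroid values.

Every stage writes its artifact to disk (TSV/JSON) so stages are
independently re-runnable, and the manifest records seeds, null counts and
pool definitions. Outputs are deterministic given (inputs, config, seeds).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import assembly_classify as ac
from . import community_stats as cs
from .data_io import (
    align_tree_and_table,
    filter_rare,
    read_community,
    read_metadata,
    read_tree,
)
from .null_models import beta_nri, beta_nti, raup_crick_bray
from .phylo_metrics import patristic_distances, ses_pd

logger = logging.getLogger("assemblage")


@dataclass
class RunConfig:
    tree_path: str = ""
    community_path: str = ""
    metadata_path: str = ""
    out_dir: str = "assemblage_out"
    group_col: str = "group"
    axis_col: str = "env"
    n_null_deviation: int = 1000
    n_null_rc: int = 999
    n_perm: int = 10000
    rng_seed: int = 0
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    dispersal_possible: bool = True
    breakpoint: float | None = None
    min_occupancy: int = 0
    min_mean_rel_abund: float = 0.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _load(config: RunConfig):
    tree = read_tree(config.tree_path)
    cm = read_community(config.community_path)
    md = read_metadata(config.metadata_path)
    if config.min_occupancy or config.min_mean_rel_abund:
        cm = filter_rare(cm, config.min_occupancy, config.min_mean_rel_abund)
    tree, cm = align_tree_and_table(tree, cm)
    md = md.loc[cm.index]
    return tree, cm, md


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _pair_long(dev_result, md: pd.DataFrame, axis_col: str, group_col: str | None) -> pd.DataFrame:
    long = dev_result.pair_values()
    ax = md[axis_col]
    long["axis_i"] = long["sample_i"].map(ax)
    long["axis_j"] = long["sample_j"].map(ax)
    long["abs_axis_diff"] = (long["axis_i"] - long["axis_j"]).abs()
    if group_col and group_col in md:
        gr = md[group_col]
        long["group_i"] = long["sample_i"].map(gr)
        long["group_j"] = long["sample_j"].map(gr)
        long["within_group"] = long["group_i"] == long["group_j"]
    else:
        long["within_group"] = long["axis_i"] == long["axis_j"]
    return long


def run_gradient_pipeline(config: RunConfig) -> dict:
    """Press-gradient spatial-turnover analysis; returns the report bundle
    (also written under ``config.out_dir``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree, cm, md = _load(config)
    if config.axis_col not in md:
        raise ValueError(f"metadata lacks axis column {config.axis_col!r}")
    axis = md[config.axis_col].astype(float)
    dmat = patristic_distances(tree)
    seed = config.rng_seed

    levels = np.sort(axis.unique())
    bundle: dict = {"design": "gradient", "n_samples": len(cm), "levels": levels.tolist()}

    # --- ses.PD and its segmented fit along the gradient -------------- #
    sp = ses_pd(cm, tree, n_null=max(999, config.n_null_deviation - 1), rng_seed=seed)
    sp.to_frame().to_csv(out / "ses_pd.tsv", sep="\t")
    breakpoint = (
        config.breakpoint if config.breakpoint is not None else float(np.median(axis))
    )
    defined = sp.ses.notna()
    if defined.sum() >= 6 and len(levels) > 2:
        fit = cs.segmented_fit(
            axis[defined].values, sp.ses[defined].values, breakpoint,
            rng_seed=seed + 1,
        )
        bundle["ses_pd_segfit"] = fit.to_dict()
        _write_json(out / "ses_pd_segfit.json", fit.to_dict())

    # --- β-deviations over the whole-gradient species pool ------------ #
    bnti = beta_nti(cm, dmat, n_null=config.n_null_deviation, rng_seed=seed + 2)
    bnri = beta_nri(cm, dmat, n_null=config.n_null_deviation, rng_seed=seed + 3)
    bnti_long = _pair_long(bnti, md, config.axis_col, config.group_col)
    bnri_long = _pair_long(bnri, md, config.axis_col, config.group_col)
    bnti_long.to_csv(out / "bnti_pairs.tsv", sep="\t", index=False)
    bnri_long.to_csv(out / "bnri_pairs.tsv", sep="\t", index=False)

    if len(levels) < 2:
        logger.warning("single gradient level: between-level analyses skipped")
        bundle["between_levels_skipped"] = True
    else:
        between = bnri_long[~bnri_long["within_group"]].dropna(subset=["deviation"])
        x = cs.ln_transform_differences(between["abs_axis_diff"].values)
        ln_bp = float(np.log(breakpoint)) if breakpoint > 0 else float(np.median(x))
        try:
            fit = cs.segmented_fit(x, between["deviation"].values, ln_bp, rng_seed=seed + 4)
            bundle["bnri_vs_ln_diff_segfit"] = fit.to_dict()
            _write_json(out / "bnri_vs_ln_diff_segfit.json", fit.to_dict())
        except ValueError as exc:
            logger.warning("βNRI segmented fit skipped: %s", exc)

    within = bnri_long[bnri_long["within_group"]].dropna(subset=["deviation"])
    if len(within):
        try:
            fit = cs.segmented_fit(
                within["axis_i"].values, within["deviation"].values, breakpoint,
                rng_seed=seed + 5,
            )
            bundle["bnri_within_segfit"] = fit.to_dict()
            _write_json(out / "bnri_within_segfit.json", fit.to_dict())
        except ValueError as exc:
            logger.warning("within-level βNRI segmented fit skipped: %s", exc)

    manifest = {
        "config": _config_manifest(config),
        "seeds": {
            "ses_pd": seed, "bnti": seed + 2, "bnri": seed + 3,
        },
        "n_pairs": int(len(bnti_long)),
        "n_undefined_bnti": int(bnti_long["deviation"].isna().sum()),
        "n_undefined_bnri": int(bnri_long["deviation"].isna().sum()),
    }
    _write_json(out / "manifest.json", manifest)
    bundle["manifest"] = manifest
    return bundle


def _config_manifest(config: RunConfig) -> dict:
    d = asdict(config)
    d.pop("out_dir", None)  # identical runs into different folders must match
    return d


def _complete_submatrix(dev: pd.DataFrame) -> pd.DataFrame:
    """Largest complete (NaN-free) principal submatrix, dropping the sample
    with the most undefined pairs first."""
    d = dev.copy()
    while d.isna().values.any():
        worst = d.isna().sum(axis=1).idxmax()
        d = d.drop(index=worst, columns=worst)
    return d


def _two_group_permutation_p(a: np.ndarray, b: np.ndarray, n_perm: int, rng) -> float:
    """Two-tailed permutation p for a difference in group means."""
    obs = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n_a = len(a)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        count += abs(perm[:n_a].mean() - perm[n_a:].mean()) >= obs - 1e-12
    return (count + 1.0) / (n_perm + 1.0)


def run_pulse_pipeline(config: RunConfig) -> dict:
    """Pulse-disturbance temporal-turnover analysis with per-pool nulls.

    Pools (e.g. LN and HN microcosm series) are taken from
    ``config.group_col``; randomizations are carried out within each pool
    separately, and classification defaults to a closed system
    (``dispersal_possible=False`` unless the config says otherwise).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree, cm, md = _load(config)
    if config.group_col not in md:
        raise ValueError(f"metadata lacks pool column {config.group_col!r}")
    if config.axis_col not in md:
        raise ValueError(f"metadata lacks time column {config.axis_col!r}")
    times = md[config.axis_col].astype(float)
    if (times <= 0).any():
        raise ValueError("time axis must be strictly positive for ln transform")
    dmat = patristic_distances(tree)
    seed = config.rng_seed

    bundle: dict = {"design": "pulse", "pools": {}}
    centroid_dists: dict[str, pd.Series] = {}
    pools = sorted(md[config.group_col].unique())
    for k, pool_name in enumerate(pools):
        pool_samples = md.index[md[config.group_col] == pool_name]
        pool_seed = seed + 10 * (k + 1)
        bnti = beta_nti(
            cm, dmat, n_null=config.n_null_deviation,
            rng_seed=pool_seed, pool=pool_samples,
        )
        rc = raup_crick_bray(
            cm, n_null=config.n_null_rc, rng_seed=pool_seed + 1, pool=pool_samples,
        )
        labels = ac.classify_pairs_table(
            bnti.deviation, rc.rc, dispersal_possible=config.dispersal_possible
        )
        try:
            summary = ac.process_fractions(
                labels["label"], dispersal_possible=config.dispersal_possible
            )
            summary_dict = summary.to_dict()
        except ValueError:
            logger.warning(
                "pool %s: every pair undefined (null sd ~ 0); fractions skipped",
                pool_name,
            )
            summary_dict = {
                "counts": None, "fractions": None,
                "n_defined": 0, "n_undefined": int(len(labels)),
                "dispersal_possible": config.dispersal_possible,
            }
        bnti.pair_values().to_csv(out / f"bnti_{pool_name}.tsv", sep="\t", index=False)
        rc.pair_values().to_csv(out / f"rcbray_{pool_name}.tsv", sep="\t", index=False)
        labels.to_csv(out / f"labels_{pool_name}.tsv", sep="\t", index=False)
        _write_json(out / f"fractions_{pool_name}.json", summary_dict)

        ln_t = np.log(times.loc[pool_samples].values)
        tdist = pd.DataFrame(
            np.abs(ln_t[:, None] - ln_t[None, :]),
            index=pool_samples, columns=pool_samples,
        )
        dev = bnti.deviation
        vals = dev.values[np.triu_indices(len(dev), k=1)]
        vals = vals[np.isfinite(vals)]
        pool_report: dict = {
            "n_pairs": int(len(labels)),
            "fractions": summary_dict,
            "mean_deviation": None,
            "mantel": None,
        }
        if len(vals) >= 2:
            mt = cs.mean_deviation_test(
                vals, n_perm=config.n_perm, rng_seed=pool_seed + 2, group=str(pool_name)
            )
            pool_report["mean_deviation"] = {
                "mean": mt.mean, "sd": mt.sd, "n": mt.n, "p": mt.p_value,
            }
        complete = _complete_submatrix(dev)
        if len(complete) < len(dev):
            logger.warning(
                "pool %s: %d samples dropped (undefined pairs) before "
                "Mantel/dispersion steps", pool_name, len(dev) - len(complete),
            )
        if len(complete) >= 3:
            try:
                man = cs.mantel_test(
                    complete,
                    tdist.loc[complete.index, complete.index],
                    n_perm=config.n_perm, tail="greater", rng_seed=pool_seed + 3,
                )
                pool_report["mantel"] = {"r": man.r, "p": man.p_value, "tail": man.tail}
            except ValueError as exc:
                logger.warning("Mantel skipped for pool %s: %s", pool_name, exc)
        if len(complete) >= 2:
            centroid_dists[str(pool_name)] = cs.distances_to_centroid(complete)
        bundle["pools"][str(pool_name)] = pool_report

    if len(centroid_dists) == 2:
        (ga, a), (gb, b) = centroid_dists.items()
        rng = np.random.default_rng(seed + 99)
        p = _two_group_permutation_p(a.values, b.values, config.n_perm, rng)
        bundle["dispersion_comparison"] = {
            "groups": [ga, gb],
            "mean_distance_to_centroid": {ga: float(a.mean()), gb: float(b.mean())},
            "p": p,
        }

    manifest = {
        "config": _config_manifest(config),
        "pools": {str(p): int((md[config.group_col] == p).sum()) for p in pools},
    }
    _write_json(out / "manifest.json", manifest)
    _write_json(out / "report.json", bundle)
    bundle["manifest"] = manifest
    return bundle
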