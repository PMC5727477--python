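# assemblage

Phylogenetic null models for inferring the ecological processes that
assemble microbial communities.

Given a rooted phylogeny with branch lengths and a taxa × samples abundance
table, `assemblage` partitions pairwise community turnover into the
processes of community assembly — homogeneous selection, variable
selection, dispersal limitation coupled with drift, homogenizing dispersal,
weak homogeneous selection, and "undominated" turnover — and provides the
supporting diagnostics this inference rests on: phylogenetic signal in
organismal niches, phylogenetic diversity, and group-level statistics. It
is aimed at microbial ecologists analysing amplicon surveys (e.g. 16S OTU
or ASV tables) along environmental gradients or time series.

## The statistics at its core

* **βMNTD / βMPD** — abundance-weighted between-community mean
  nearest-taxon and mean pairwise phylogenetic distances,

  βMNTD(j,k) = ½ [ Σ_{i∈j} f_ij · min_{i′∈k} d(i,i′) + Σ_{i′∈k} f_i′k · min_{i∈j} d(i′,i) ],
  βMPD(j,k) = Σ_{i∈j} Σ_{i′∈k} f_ij · f_i′k · d(i,i′),

  with `f` within-sample relative abundances and `d` patristic distance.
* **βNTI / βNRI** — standardized effect sizes of βMNTD/βMPD against a null
  that shuffles taxa across the tips of the phylogeny (one shuffle per null
  run, shared by all sample pairs; 1000 runs by default):
  βNTI = (βMNTD_obs − mean βMNTD_null) / sd βMNTD_null. Values < −2 indicate
  homogeneous selection, > +2 variable selection (≈ ±1.96, the two-sided 5%
  normal critical value).
* **RC_bray** — Raup-Crick on Bray-Curtis: each sample is reassembled by
  drawing taxa (probability ∝ occurrence frequency in the species pool)
  until observed richness is reached, then distributing the observed number
  of individuals (probability ∝ pool relative abundance);
  RC = 2·((n_below + ½·n_ties)/n_null) − 1 ∈ [−1, 1]. For pairs with
  |βNTI| < 2, RC > +0.95 indicates dispersal limitation with drift,
  RC < −0.95 homogenizing dispersal (or *weak homogeneous selection* in a
  closed system with no dispersal), |RC| ≤ 0.95 undominated turnover.
* **Phylogenetic signal** — abundance-weighted niche optima per taxon;
  Pagel's λ by maximum likelihood with a boundary-aware likelihood-ratio
  test; Mantel correlograms over patristic distance classes of width 0.02
  (standardized by the maximum distance).
* **Diversity and group statistics** — Faith's PD and its standardized
  effect size (ses.PD) under tip shuffling; Mantel tests; sign-flip
  Monte-Carlo tests of mean deviation; PERMDISP dispersion comparisons;
  segmented regressions with a fixed breakpoint and bootstrap bands.

A synthetic-data module generates pure-birth trees (optionally
crown-compressed to emulate real 16S branch-length structure), traits under
λ-scaled Brownian motion, and communities assembled under known regimes —
so every inference stage can be validated against ground truth.

## Worked example

Generate a community dataset assembled under *variable selection* (twelve
samples filtered toward environments spread across the niche axis) and
recover the generating process:

```python
import numpy as np
import assemblage as A
from assemblage import assembly_classify as ac
from assemblage.synthetic_data import scenario_dataset

tree, traits, cm, md, truth = scenario_dataset("variable_selection", rng_seed=42)
dmat = A.patristic_distances(tree)
bnti = A.beta_nti(cm, dmat, n_null=999, rng_seed=1)
rc = A.raup_crick_bray(cm, n_null=999, rng_seed=2)
labels = ac.classify_pairs_table(bnti.deviation, rc.rc, dispersal_possible=False)
summary = ac.process_fractions(labels["label"], dispersal_possible=False)

iu = np.triu_indices(len(cm), k=1)
print(f"median bNTI = {np.nanmedian(bnti.deviation.values[iu]):+.2f}")
for label, frac in sorted(summary.fractions.items(), key=lambda kv: -kv[1]):
    if frac > 0:
        print(f"{label:27s} {frac:.2f}")
```

prints

```
median bNTI = +6.95
variable_selection          0.68
dispersal_limitation_drift  0.12
homogeneous_selection       0.11
undominated                 0.08
weak_homogeneous_selection  0.02
```

The median βNTI far above +2 and the modal `variable_selection` label
(68% of the 66 sample pairs) recover the regime the generator used:
divergent environmental filtering inflates nearest-taxon phylogenetic
turnover beyond the tip-shuffle null. The same workflow is available from
the shell (`assemblage simulate`, `assemblage bnti`, `assemblage rcbray`,
`assemblage classify`, `assemblage run gradient|pulse --config run.yaml`);
see `assemblage --help`.

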