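"""Turn per-pair (βNTI, RC_bray) values into ecological process labels.

Decision rule (strict inequalities throughout):

* βNTI < −2  → homogeneous selection
* βNTI > +2  → variable selection
* |βNTI| < 2 and RC_bray > +0.95 → dispersal limitation coupled with drift
* |βNTI| < 2 and RC_bray < −0.95 → homogenizing dispersal when dispersal is
  possible, *weak homogeneous selection* in a closed (no-dispersal) system
* |βNTI| < 2 and |RC_bray| ≤ 0.95 → undominated

Values landing exactly on a threshold fall to the stochastic/undominated
side (the published rules are strict on both sides; for continuous
statistics this is a measure-zero event, but a deterministic rule is needed)
and are logged. Pairs whose βNTI is undefined (null sd ≈ 0) are labelled
``undefined`` and excluded from the fractions, with their count reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import math
import numpy as np
import pandas as pd

logger = logging.getLogger("assemblage")

HOMOGENEOUS_SELECTION = "homogeneous_selection"
VARIABLE_SELECTION = "variable_selection"
DISPERSAL_LIMITATION_DRIFT = "dispersal_limitation_drift"
HOMOGENIZING_DISPERSAL = "homogenizing_dispersal"
WEAK_HOMOGENEOUS_SELECTION = "weak_homogeneous_selection"
UNDOMINATED = "undominated"
UNDEFINED = "undefined"

LABELS = (
    HOMOGENEOUS_SELECTION,
    VARIABLE_SELECTION,
    DISPERSAL_LIMITATION_DRIFT,
    HOMOGENIZING_DISPERSAL,
    WEAK_HOMOGENEOUS_SELECTION,
    UNDOMINATED,
    UNDEFINED,
)

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


def classify_pair(
    bnti: float | None,
    rc: float | None = None,
    dispersal_possible: bool = True,
    bnti_threshold: float = BNTI_THRESHOLD,
    rc_threshold: float = RC_THRESHOLD,
) -> str:
    """Label one sample pair from its βNTI and (for the stochastic branch)
    its RC_bray. ``rc`` may be omitted when |βNTI| ≥ threshold."""
    if bnti is None or (isinstance(bnti, float) and math.isnan(bnti)):
        return UNDEFINED
    if bnti < -bnti_threshold:
        return HOMOGENEOUS_SELECTION
    if bnti > bnti_threshold:
        return VARIABLE_SELECTION
    if abs(bnti) == bnti_threshold:
        # strict inequalities on both sides: the boundary itself is not
        # evidence for selection, nor eligible for the RC partition
        logger.info(
            "βNTI exactly on ±%g threshold; assigned undominated", bnti_threshold
        )
        return UNDOMINATED
    if rc is None or (isinstance(rc, float) and math.isnan(rc)):
        raise ValueError("RC_bray required when |βNTI| < threshold")
    if not -1.0 - 1e-9 <= rc <= 1.0 + 1e-9:
        raise ValueError(f"RC_bray out of [-1, 1]: {rc}")
    if rc > rc_threshold:
        return DISPERSAL_LIMITATION_DRIFT
    if rc < -rc_threshold:
        return WEAK_HOMOGENEOUS_SELECTION if not dispersal_possible else HOMOGENIZING_DISPERSAL
    return UNDOMINATED


@dataclass
class AssemblyClassification:
    """Aggregate process fractions over the defined pairs (they sum to 1)."""

    counts: dict = field(default_factory=dict)
    fractions: dict = field(default_factory=dict)
    n_defined: int = 0
    n_undefined: int = 0
    dispersal_possible: bool = True

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "fractions": dict(self.fractions),
            "n_defined": self.n_defined,
            "n_undefined": self.n_undefined,
            "dispersal_possible": self.dispersal_possible,
        }


def process_fractions(labels, dispersal_possible: bool = True) -> AssemblyClassification:
    """Per-label fractions over defined pairs; all seven categories are
    always reported so the fractions are auditable and sum to 1."""
    labels = list(labels)
    counts = {lab: 0 for lab in LABELS}
    for lab in labels:
        if lab not in counts:
            raise ValueError(f"unknown label {lab!r}")
        counts[lab] += 1
    n_undef = counts[UNDEFINED]
    n_def = len(labels) - n_undef
    if n_def == 0:
        raise ValueError("no defined pairs to aggregate")
    fractions = {
        lab: (counts[lab] / n_def if lab != UNDEFINED else 0.0) for lab in LABELS
    }
    if dispersal_possible and counts[WEAK_HOMOGENEOUS_SELECTION]:
        raise ValueError(
            "weak_homogeneous_selection labels present in an open system"
        )
    if not dispersal_possible and counts[HOMOGENIZING_DISPERSAL]:
        raise ValueError(
            "homogenizing_dispersal labels present in a closed system"
        )
    return AssemblyClassification(
        counts=counts,
        fractions=fractions,
        n_defined=n_def,
        n_undefined=n_undef,
        dispersal_possible=dispersal_possible,
    )


def classify_pairs_table(
    bnti_dev: pd.DataFrame,
    rc: pd.DataFrame | None,
    dispersal_possible: bool = True,
) -> pd.DataFrame:
    """Per-pair labels for all unordered sample pairs of a deviation matrix."""
    samples = list(bnti_dev.index)
    if rc is not None and list(rc.index) != samples:
        raise ValueError("βNTI and RC matrices index different samples")
    rows = []
    for a in range(len(samples)):
        for b in range(a + 1, len(samples)):
            bnti = bnti_dev.iat[a, b]
            rc_val = rc.iat[a, b] if rc is not None else None
            finite = bnti is not None and not (isinstance(bnti, float) and math.isnan(bnti))
            needs_rc = finite and abs(bnti) < BNTI_THRESHOLD
            rows.append(
                {
                    "sample_i": samples[a],
                    "sample_j": samples[b],
                    "bnti": bnti,
                    "rc_bray": rc_val if needs_rc else np.nan,
                    "label": classify_pair(
                        bnti, rc_val if needs_rc else None, dispersal_possible
                    ),
                }
            )
    return pd.DataFrame(rows)
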