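"""ROC/AUC evaluation of scorers on labeled envelope matches."""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .scoring import (
    WeightSet,
    dot_product_score,
    kl_divergence,
    l_score,
)

__all__ = ["roc_auc", "compare_scorers"]


def roc_auc(scores: Sequence[float], labels: Sequence[bool], higher_is_better: bool = True) -> float:
    """Exact Mann-Whitney AUC with midrank tie handling.

    ``labels`` are True for the positive (correct) class.  When
    ``higher_is_better`` is False the scores are negated first.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    if not higher_is_better:
        scores = -scores
    ranks = rankdata(scores, method="average")
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


#: scorer name -> (extractor, higher_is_better).  Feature extractors assume
#: matches already carry FeatureVectors.
_FEATURE_SCORERS = {
    "mz_distance": (lambda m: m.features.d_x, False),
    "intensity_distance": (lambda m: m.features.d_y, False),
    "supporting": (lambda m: float(m.features.s), True),
    "neutral_loss": (lambda m: float(m.features.n), True),
    "missing": (lambda m: float(m.features.m), False),
}


def compare_scorers(matches: Sequence, weights: WeightSet | None = None) -> pd.DataFrame:
    """AUC of the linear score, each single feature, dot product and KL.

    Rows: groups 2, 3, 4, 5+ and "pooled"; columns: scorers.  Groups where a
    class is absent get NaN.  Infinite KL values (all-zero experimental
    envelopes) are ranked worst.
    """
    weights = weights or WeightSet.default()
    scorers: dict[str, tuple] = {
        "l_score": (lambda m: l_score(m.features, weights, m.k), False),
    }
    scorers.update(_FEATURE_SCORERS)
    scorers["dot_product"] = (lambda m: dot_product_score(m), True)
    scorers["kl_divergence"] = (lambda m: _finite_kl(m), False)

    rows = {}
    group_sets = {"2": [], "3": [], "4": [], "5+": []}
    for m in matches:
        key = "5+" if m.k >= 5 else str(m.k)
        group_sets[key].append(m)
    group_sets["pooled"] = list(matches)

    for gname, subset in group_sets.items():
        row = {}
        labels = [m.label == "correct" for m in subset]
        for name, (fn, higher) in scorers.items():
            if not subset or len(set(labels)) < 2:
                row[name] = math.nan
                continue
            try:
                row[name] = roc_auc([fn(m) for m in subset], labels, higher_is_better=higher)
            except (ValueError, AttributeError, TypeError):
                row[name] = math.nan
        rows[gname] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def _finite_kl(match) -> float:
    value = kl_divergence(match)
    return 1e12 if math.isinf(value) else value
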