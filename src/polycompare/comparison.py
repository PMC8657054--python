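"""Information-theoretic model comparison: AICc, Akaike weights, confidence sets.

The candidate fits are ranked by the second-order Akaike information criterion

    AICc = -2 LL + 2 K + 2 K (K + 1) / (n - K - 1)

with n the number of retained persons (all baseline rows, matching the FIML
sample-size convention of the fitting stage).  Before weights are computed,
redundant models are pruned: when the log-likelihood gain of a more complex
model over a model nested in it is below a threshold (default 1.0), the more
complex model is excluded.  Akaike weights w_i = exp(-D_i/2) / sum_j exp(-D_j/2)
(D_i = AICc_i - min AICc) are computed over the retained set; the 95% confidence
set is the shortest AICc-ordered prefix whose cumulative weight exceeds the
level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fitting import FitResult

__all__ = [
    "aicc",
    "akaike_weights",
    "prune_redundant",
    "confidence_set",
    "evidence_ratio",
    "build_comparison_table",
    "ComparisonTable",
]


def aicc(ll: float, k: int, n: int) -> float:
    """Second-order Akaike information criterion; requires n > K + 1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, K={k} (need n > K + 1)")
    return -2.0 * ll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aiccs: Sequence[float]) -> np.ndarray:
    """Normalized exp(-delta/2); invariant under adding a constant to all AICcs."""
    arr = np.asarray(list(aiccs), dtype=float)
    if arr.size == 0:
        raise ValueError("no AICc values supplied")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite AICc values")
    rel = np.exp(-(arr - arr.min()) / 2.0)
    return rel / rel.sum()


def prune_redundant(
    fits: Sequence[FitResult],
    nesting_pairs: Iterable[tuple[str, str]],
    threshold: float = 1.0,
) -> tuple[list[FitResult], list[dict]]:
    """Drop more complex models that barely improve on a model nested in them.

    Models are processed in order of increasing K (name-alphabetical within
    ties, so the outcome is deterministic); each candidate is compared against
    every *retained* simpler model nested in it, and excluded as soon as its
    log-likelihood gain over one of them falls below ``threshold``.  Every
    exclusion is logged with the triggering pair.
    """
    nest = set(nesting_pairs)
    retained: list[FitResult] = []
    exclusions: list[dict] = []
    for cand in sorted(fits, key=lambda f: (f.K, f.spec_name)):
        trigger = None
        for simpler in retained:
            if (simpler.spec_name, cand.spec_name) in nest:
                gain = cand.ll - simpler.ll
                if gain < threshold:
                    trigger = {
                        "excluded": cand.spec_name,
                        "against": simpler.spec_name,
                        "ll_gain": float(gain),
                    }
                    break
        if trigger is None:
            retained.append(cand)
        else:
            exclusions.append(trigger)
    return retained, exclusions


def confidence_set(weights: Sequence[float], level: float = 0.95) -> list[int]:
    """Indices (into the weight-descending order) of the smallest prefix
    whose cumulative weight exceeds ``level``."""
    order = np.argsort(np.asarray(weights))[::-1]
    out, cum = [], 0.0
    for i in order:
        out.append(int(i))
        cum += float(weights[i])
        if cum > level:
            break
    return out


def evidence_ratio(w_i: float, w_j: float) -> float:
    """Relative support of model i over model j; infinite when w_j = 0."""
    if w_j == 0:
        return math.inf
    return w_i / w_j


@dataclass
class ComparisonTable:
    """Comparison products for one analysis.

    ``table`` has one row per fitted model (AICc-ascending; redundant-excluded
    models carry no weight), weights over retained models summing to one, the
    confidence-set flag, and adjusted R^2.  ``exclusions`` logs the pruning
    decisions with their triggering nested pairs.
    """

    table: pd.DataFrame
    exclusions: list[dict] = field(default_factory=list)
    level: float = 0.95

    @property
    def confidence_models(self) -> list[str]:
        t = self.table
        return t.loc[t["in_confidence_set"], "model"].tolist()

    @property
    def best_model(self) -> str:
        return str(self.table.iloc[0]["model"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def build_comparison_table(
    fits: Sequence[FitResult],
    nesting_pairs: Iterable[tuple[str, str]],
    level: float = 0.95,
    threshold: float = 1.0,
    renormalize_within_set: bool = False,
) -> ComparisonTable:
    """Assemble the full comparison table from catalogue fits.

    Weights are computed over the pruned candidate set.  With
    ``renormalize_within_set`` an extra column reports weights renormalized
    within the confidence set (some published tables print that convention).
    """
    bad = [f.spec_name for f in fits if not f.converged]
    if bad:
        raise RuntimeError(f"non-converged fits cannot be compared: {bad}")
    retained, exclusions = prune_redundant(fits, nesting_pairs, threshold)
    ret_names = {f.spec_name for f in retained}
    aiccs = {f.spec_name: aicc(f.ll, f.K, f.n_obs) for f in fits}
    w = akaike_weights([aiccs[f.spec_name] for f in retained])
    weights = dict(zip([f.spec_name for f in retained], w))

    # confidence set over retained models, AICc-ordered
    ret_sorted = sorted(retained, key=lambda f: aiccs[f.spec_name])
    cs_names, cum = set(), 0.0
    for f in ret_sorted:
        cs_names.add(f.spec_name)
        cum += weights[f.spec_name]
        if cum > level:
            break

    rows = []
    for f in sorted(fits, key=lambda fr: aiccs[fr.spec_name]):
        name = f.spec_name
        rows.append(
            {
                "model": name,
                **{k: f.beta[k] for k in ("b1", "b2", "b3", "b4", "b5")},
                "K": f.K,
                "LL": f.ll,
                "AICc": aiccs[name],
                "delta": aiccs[name] - min(aiccs.values()),
                "weight": weights.get(name, np.nan),
                "in_confidence_set": name in cs_names,
                "redundant_excluded": name not in ret_names,
                "adj_R2": f.adj_r2,
                "n": f.n_obs,
            }
        )
    table = pd.DataFrame(rows)
    ret_mask = ~table["redundant_excluded"]
    table.loc[ret_mask, "cumulative_weight"] = table.loc[ret_mask, "weight"].cumsum()
    if renormalize_within_set:
        cs_mask = table["in_confidence_set"]
        total = table.loc[cs_mask, "weight"].sum()
        table["weight_in_set"] = np.where(cs_mask, table["weight"] / total, np.nan)
    return ComparisonTable(table=table, exclusions=exclusions, level=level)
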