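"""Per-sample and per-person attribution.

Layer-wise relevance propagation (LRP, epsilon rule) distributes a network's
output over its inputs as signed relevance scores: positive scores pushed the
prediction up, negative scores pushed it down.  With all bias terms locked to
zero the propagation is conservative — the relevances sum to the model output
up to epsilon effects — and for a purely linear network it coincides exactly
with Shapley values at a zero baseline (relevance_i = w_i * x_i).  A
brute-force Shapley enumerator over all 2^d feature subsets serves as the
independent oracle for small networks.

Tree-based models use impurity-decrease importances (for regression trees the
"Gini importance" is the variance-impurity decrease, normalized to sum 1).
Aggregation utilities count how often each feature lands in a person's top-5
importance list and compute per-person median absolute relevance, and a force
report orders one prediction's contributions into upward and downward groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .models import LayerStack, RecurrentNet, TrainedModel

SHAPLEY_MAX_INPUTS = 12


@dataclass
class RelevanceSet:
    """Signed per-input relevance for one prediction."""

    person_id: str
    target_date: object
    feature_names: list[str]
    relevances: np.ndarray
    model_output: float

    def conservation_gap(self) -> float:
        return abs(float(self.relevances.sum()) - self.model_output)


def lrp_layerstack(
    stack: LayerStack, x: np.ndarray, epsilon: float = 1e-9
) -> tuple[np.ndarray, float]:
    """Epsilon-rule backward pass through a dense rectifier network.

    Relevance into input i of a layer is sum_j z_ij / (z_j + eps*sign(z_j)) * R_j
    with z_ij = a_i * w_ij.  The output layer is seeded with the model output.
    Free biases absorb (leak) relevance through the denominator.
    """
    x = np.asarray(x, float).ravel()
    acts = stack.forward(x[None, :])
    output = float(acts[-1].ravel()[0])
    R = np.array([output])
    for l in range(stack.n_layers - 1, -1, -1):
        a = acts[l].ravel()
        W = stack.weights[l]
        z = a[:, None] * W
        zj = z.sum(axis=0) + stack.biases[l]
        if epsilon == 0 and np.any(zj == 0):
            raise ZeroDivisionError(
                "zero pre-activation encountered with epsilon=0; use epsilon>0"
            )
        denom = zj + epsilon * np.where(zj >= 0, 1.0, -1.0)
        R = z @ (R / denom)
    return R, output


def lrp(
    network,
    x: np.ndarray,
    epsilon: float = 1e-9,
    feature_names: Optional[Sequence[str]] = None,
    person_id: str = "",
    target_date: object = None,
) -> RelevanceSet:
    """Relevance scores for one input vector under any supported network.

    ``network`` may be a :class:`LayerStack`, a :class:`RecurrentNet`, or a
    :class:`TrainedModel` wrapping either.
    """
    if isinstance(network, TrainedModel):
        if feature_names is None:
            feature_names = network.feature_names
        network = network.predictor
    if isinstance(network, RecurrentNet):
        relevances, output = network.relevance(x, epsilon=epsilon)
    elif isinstance(network, LayerStack):
        relevances, output = lrp_layerstack(network, x, epsilon=epsilon)
    else:
        raise TypeError(f"cannot propagate relevance through {type(network).__name__}")
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(len(relevances))]
    return RelevanceSet(
        person_id=person_id,
        target_date=target_date,
        feature_names=list(feature_names),
        relevances=np.asarray(relevances, float),
        model_output=output,
    )


def lrp_table(
    model: TrainedModel, samples: pd.DataFrame, epsilon: float = 1e-9
) -> pd.DataFrame:
    """Long-format relevance table (person_id, date, feature, relevance, model_output)."""
    X = samples[model.feature_names].to_numpy(float)
    rows = []
    for i in range(len(samples)):
        rs = lrp(
            model,
            X[i],
            epsilon=epsilon,
            person_id=samples["person_id"].iloc[i],
            target_date=samples["target_date"].iloc[i],
        )
        for name, rel in zip(rs.feature_names, rs.relevances):
            rows.append(
                {
                    "person_id": rs.person_id,
                    "date": rs.target_date,
                    "feature": name,
                    "relevance": rel,
                    "model_output": rs.model_output,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exact Shapley oracle
# ---------------------------------------------------------------------------


def shapley_bruteforce(
    f: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    baseline: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Exact Shapley attribution by enumerating all 2^d feature subsets.

    Features outside the coalition are set to ``baseline`` (default: the zero
    vector, i.e. the training mean after standardization).  ``f`` must accept
    a (n, d) matrix and return (n,) outputs.  Limited to d <= 12 inputs.
    """
    x = np.asarray(x, float).ravel()
    d = x.size
    if d > SHAPLEY_MAX_INPUTS:
        raise ValueError(f"brute-force Shapley limited to {SHAPLEY_MAX_INPUTS} inputs, got {d}")
    base = np.zeros(d) if baseline is None else np.asarray(baseline, float).ravel()
    n_masks = 1 << d
    masks = (np.arange(n_masks)[:, None] >> np.arange(d)) & 1  # (2^d, d)
    X = np.where(masks.astype(bool), x, base)
    vals = np.asarray(f(X), float).ravel()
    sizes = masks.sum(axis=1)
    # weight by coalition size: |S|! (d-|S|-1)! / d!
    w = np.array([factorial(s) * factorial(d - s - 1) / factorial(d) for s in range(d)])
    phi = np.zeros(d)
    for m in range(n_masks):
        for i in range(d):
            if not masks[m, i]:
                phi[i] += w[sizes[m]] * (vals[m | (1 << i)] - vals[m])
    return phi


# ---------------------------------------------------------------------------
# tree importances and aggregation
# ---------------------------------------------------------------------------


def tree_importances(model: TrainedModel) -> np.ndarray:
    """Normalized impurity-decrease importances for a fitted tree/ensemble.

    Sums to 1, or is all zeros for a tree with no splits (constant target).
    """
    if model.family not in ("tree", "random_forest", "gbt"):
        raise TypeError(f"impurity importances undefined for family {model.family!r}")
    return np.asarray(model.predictor.feature_importances_, float)


def top_features(
    importance: np.ndarray, feature_names: Sequence[str], k: int = 5
) -> list[str]:
    """Top-k features by importance; ties broken by canonical feature order.

    Zero-importance features never enter the list, so persons with fewer than
    k informative features contribute shorter lists.
    """
    imp = np.asarray(importance, float)
    order = np.lexsort((np.arange(len(imp)), -imp))  # descending, stable
    return [feature_names[i] for i in order[:k] if imp[i] > 0]


def aggregate_rankings(
    per_person: Mapping[str, np.ndarray],
    feature_names: Sequence[str],
    k: int = 5,
) -> pd.DataFrame:
    """Count how often each feature appears in participants' top-k lists.

    Returns one row per feature with ``top5_count`` and the across-person
    median importance, sorted by count then canonical order.  Invariant under
    permutation of the person order.
    """
    names = list(feature_names)
    counts = {n: 0 for n in names}
    stacked = []
    for pid in sorted(per_person):
        imp = np.asarray(per_person[pid], float)
        stacked.append(imp)
        for name in top_features(imp, names, k=k):
            counts[name] += 1
    med = np.median(np.stack(stacked), axis=0) if stacked else np.zeros(len(names))
    out = pd.DataFrame(
        {"feature": names, "top5_count": [counts[n] for n in names], "median_importance": med}
    )
    return (
        out.sort_values(["top5_count", "feature"], ascending=[False, True])
        .reset_index(drop=True)
    )


def median_abs_relevance(relevance_table: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-person median |relevance| per feature, from an ``lrp_table`` frame.

    This is the LRP analogue of a strictly positive importance vector, used to
    rank features comparably with impurity importances.
    """
    out = {}
    for pid, sub in relevance_table.groupby("person_id", sort=True):
        piv = sub.pivot_table(index="date", columns="feature", values="relevance")
        out[pid] = piv.abs().median(axis=0)
    return out


def person_lrp_profile(
    relevance_table: pd.DataFrame,
    stress_by_date: pd.DataFrame,
    top_stress_fraction: float = 0.25,
) -> dict[str, pd.Series]:
    """Per-person predictors from a pooled model's relevances.

    For each person, restrict to the ``top_stress_fraction`` highest-stress
    sample days and take the median absolute relevance per input variable —
    surfacing which inputs drive that person's worst days.
    """
    if not 0 < top_stress_fraction <= 1:
        raise ValueError("top_stress_fraction must lie in (0, 1]")
    merged = relevance_table.merge(
        stress_by_date[["person_id", "target_date", "y"]].rename(
            columns={"target_date": "date"}
        ),
        on=["person_id", "date"],
    )
    out = {}
    for pid, sub in merged.groupby("person_id", sort=True):
        days = sub[["date", "y"]].drop_duplicates().sort_values("y", ascending=False)
        n_keep = max(1, int(np.ceil(top_stress_fraction * len(days))))
        keep = set(days["date"].iloc[:n_keep])
        top = sub[sub["date"].isin(keep)]
        out[pid] = top.groupby("feature")["relevance"].apply(lambda s: s.abs().median())
    return out


# ---------------------------------------------------------------------------
# force reports
# ---------------------------------------------------------------------------


def force_report(relevance_set: RelevanceSet) -> pd.DataFrame:
    """One prediction's contributions, ordered for a force-plot-style reading.

    Features are sorted by signed relevance (largest upward push first);
    positive contributions are labelled ``upward`` and negative ``downward``.
    Zero-relevance features are omitted, so an all-zero relevance vector
    yields empty groups.
    """
    rel = np.asarray(relevance_set.relevances, float)
    order = np.lexsort((np.arange(rel.size), -rel))
    rows = [
        {
            "feature": relevance_set.feature_names[i],
            "relevance": rel[i],
            "direction": "upward" if rel[i] > 0 else "downward",
        }
        for i in order
        if rel[i] != 0
    ]
    df = pd.DataFrame(rows, columns=["feature", "relevance", "direction"])
    df.attrs["model_output"] = relevance_set.model_output
    return df
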