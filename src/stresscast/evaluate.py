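"""Metrics, the training-proportion sweep, subgroup analyses, and the
warm-start model-switching evaluator.

Pooled (sample-level) metrics mirror a single results row per model; the
sweep additionally recomputes every metric restricted to participants whose
valid-day count exceeds 50 or 100 days, which is where per-person models are
expected to overtake the pooled one.  Undefined metrics (single-class test
sets, zero predicted positives) propagate as missing values, never as 0 or
0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import features as feat
from . import models as mdl

SUBGROUP_ALL = "all"


def auc(scores, labels) -> float:
    """Probability a random positive is ranked above a random negative.

    Computed via the rank-statistic formulation (mid-ranks, so ties count
    one half).  Undefined (NaN) when only one class is present.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def classification_metrics(predictions, labels) -> dict[str, float]:
    """Confusion-matrix metrics; positive class = "above the median".

    Precision is undefined (NaN) with zero predicted positives, recall with
    zero actual positives, and F1 whenever precision + recall is not positive.
    """
    p = np.asarray(predictions, int)
    y = np.asarray(labels, int)
    tp = int(np.sum((p == 1) & (y == 1)))
    fp = int(np.sum((p == 1) & (y == 0)))
    fn = int(np.sum((p == 0) & (y == 1)))
    tn = int(np.sum((p == 0) & (y == 0)))
    precision = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    recall = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    if np.isfinite(precision) and np.isfinite(recall) and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = float("nan")
    accuracy = (tp + tn) / len(y) if len(y) else float("nan")
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "accuracy": accuracy,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
    }


def mae(predictions, targets) -> float:
    return float(np.mean(np.abs(np.asarray(predictions, float) - np.asarray(targets, float))))


@dataclass
class MetricsReport:
    model: str
    scope: str
    proportion: float
    subgroup: str
    mae: float
    precision: float
    recall: float
    f1: float
    auc: float
    accuracy: float
    n_train: int
    n_test: int
    n_persons: int
    mean_train_days: float


def _evaluate(
    cont_pred: np.ndarray,
    test: pd.DataFrame,
    thresholds: dict[str, feat.StressThreshold],
    ties: str = "below",
) -> dict[str, float]:
    labels = feat.binarize_frame(test, test["y"].to_numpy(float), thresholds, ties=ties)
    classes = feat.binarize_frame(test, cont_pred, thresholds, ties=ties)
    out = classification_metrics(classes, labels)
    out["auc"] = auc(cont_pred - np.array(
        [thresholds[p].median_train for p in test["person_id"]]
    ), labels)
    out["mae"] = mae(cont_pred, test["y"].to_numpy(float))
    return out


# ---------------------------------------------------------------------------
# the training-proportion sweep
# ---------------------------------------------------------------------------

DEFAULT_PROPORTIONS = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
DEFAULT_SUBGROUP_CUTOFFS = (50, 100)

_DEFAULT_PARAMS: dict[str, dict] = {
    "elastic_net": {"alpha": 0.01, "l1_ratio": 0.5},
    "tree": {"max_depth": 3, "min_samples_leaf": 5},
    "random_forest": {"n_estimators": 100, "max_depth": 3, "min_samples_leaf": 5},
    "gbt": {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 3,
            "min_samples_leaf": 5},
    "mlp": {"hidden": (32,), "dropout_rate": 0.2, "epochs": 150},
    "rnn": {"hidden_size": 16, "dropout_rate": 0.2, "epochs": 150},
    "ideographic_tree": {"max_depth": 3, "min_samples_leaf": 5},
}


def _trainer(family: str):
    if family == "elastic_net":
        return mdl.train_elastic_net
    if family == "tree":
        return mdl.train_tree
    if family in ("random_forest", "gbt"):
        return lambda train, feature_names, **kw: mdl.train_ensemble(
            train, feature_names, family=family, **kw
        )
    if family == "mlp":
        return mdl.train_mlp
    if family == "rnn":
        return mdl.train_rnn
    raise ValueError(f"unknown model family {family!r}")


def valid_day_counts(samples: pd.DataFrame) -> pd.Series:
    """Number of eligible (valid) prediction days per person."""
    return samples.groupby("person_id").size()


def run_sweep(
    samples: pd.DataFrame,
    families: Sequence[str] = ("baseline", "elastic_net", "ideographic_tree"),
    proportions: Sequence[float] = DEFAULT_PROPORTIONS,
    seed: int = 0,
    subgroup_cutoffs: Sequence[int] = DEFAULT_SUBGROUP_CUTOFFS,
    model_params: Optional[dict[str, dict]] = None,
    grids: Optional[dict[str, dict]] = None,
    ties: str = "below",
) -> pd.DataFrame:
    """Fit and score every requested (family, proportion, subgroup) cell.

    ``samples`` must be a nomothetic sample table (person covariates present);
    ideographic models automatically drop the static covariates.  Nomothetic
    families pool all participants' training rows; ``ideographic_tree`` fits
    one decision tree per participant.  Metrics are pooled over the
    concatenated test samples; subgroup rows restrict to persons whose total
    eligible-day count exceeds the cutoff.  Cells with no qualifying test
    samples are emitted with missing metrics.
    """
    params = dict(_DEFAULT_PARAMS)
    for fam, kw in (model_params or {}).items():
        params[fam] = {**params.get(fam, {}), **kw}
    all_cols = [c for c in samples.columns if c not in feat.ID_COLS]
    nom_cols = all_cols
    ideo_cols = [c for c in all_cols if c not in feat.PERSON_VARS]
    counts = valid_day_counts(samples)
    subgroups = [(SUBGROUP_ALL, None)] + [(f">{c}", c) for c in subgroup_cutoffs]

    rows: list[MetricsReport] = []
    for proportion in proportions:
        split = feat.chronological_split(samples, proportion)
        if len(split.train) == 0 or len(split.test) == 0:
            continue
        thresholds = feat.compute_thresholds(split.train)
        scaler = feat.Scaler.fit(split.train, all_cols)
        train_s = scaler.transform(split.train)
        test_s = scaler.transform(split.test)
        mean_train_days = float(split.train.groupby("person_id").size().mean())

        preds: dict[tuple[str, str], np.ndarray] = {}
        for family in families:
            if family == "baseline":
                model = mdl.train_baseline(split.train)
                preds[("baseline", "nomothetic")] = model.predict(split.test)
            elif family == "ideographic_tree":
                pred = np.full(len(test_s), np.nan)
                kw = dict(params["ideographic_tree"])
                grid = (grids or {}).get("ideographic_tree")
                for pid, tr_idx in train_s.groupby("person_id", sort=True).indices.items():
                    person_train = train_s.iloc[tr_idx]
                    te_mask = (test_s["person_id"] == pid).to_numpy()
                    if not te_mask.any():
                        continue
                    kw_p = dict(kw)
                    if grid:
                        try:
                            best, _ = mdl.grid_search(
                                mdl.train_tree, grid, person_train,
                                feature_names=ideo_cols, seed=seed,
                            )
                            kw_p.update(best)
                        except ValueError:
                            pass  # too few samples for CV: fall back to defaults
                    model = mdl.train_tree(
                        person_train, ideo_cols, seed=seed,
                        scope=f"ideographic:{pid}", **kw_p,
                    )
                    pred[te_mask] = model.predict(test_s.loc[te_mask])
                preds[("ideographic_tree", "ideographic")] = pred
            else:
                trainer = _trainer(family)
                kw = dict(params.get(family, {}))
                grid = (grids or {}).get(family)
                if grid:
                    best, _ = mdl.grid_search(
                        trainer, grid, train_s, feature_names=nom_cols,
                        **({"seed": seed} if family != "elastic_net" else {}),
                    )
                    kw.update(best)
                if family not in ("elastic_net",):
                    kw.setdefault("seed", seed)
                model = trainer(train_s, nom_cols, **kw)
                preds[(family, "nomothetic")] = model.predict(test_s)

        for (family, scope), cont_pred in preds.items():
            for sub_name, cutoff in subgroups:
                if cutoff is None:
                    mask = np.ones(len(split.test), dtype=bool)
                else:
                    qualifying = set(counts[counts > cutoff].index)
                    mask = split.test["person_id"].isin(qualifying).to_numpy()
                mask &= np.isfinite(cont_pred)
                sub_test = split.test.loc[mask]
                if len(sub_test) == 0:
                    rows.append(MetricsReport(
                        model=family, scope=scope, proportion=proportion,
                        subgroup=sub_name, mae=float("nan"), precision=float("nan"),
                        recall=float("nan"), f1=float("nan"), auc=float("nan"),
                        accuracy=float("nan"), n_train=len(split.train), n_test=0,
                        n_persons=0, mean_train_days=mean_train_days,
                    ))
                    continue
                m = _evaluate(cont_pred[mask], sub_test, thresholds, ties=ties)
                rows.append(MetricsReport(
                    model=family, scope=scope, proportion=proportion,
                    subgroup=sub_name, mae=m["mae"], precision=m["precision"],
                    recall=m["recall"], f1=m["f1"], auc=m["auc"],
                    accuracy=m["accuracy"], n_train=len(split.train),
                    n_test=len(sub_test),
                    n_persons=sub_test["person_id"].nunique(),
                    mean_train_days=mean_train_days,
                ))
    return pd.DataFrame([asdict(r) for r in rows])


# ---------------------------------------------------------------------------
# the designed crossover condition
# ---------------------------------------------------------------------------


def crossover_trial(seed: int, n_persons: int = 60) -> dict[str, float]:
    """One trial of the designed high-heterogeneity crossover condition.

    Generates a high-heterogeneity cohort, fits the pooled elastic net and
    per-person decision trees (leaf size 12, matching the constrained-
    complexity guidance for N-of-1 trees) at training proportions 0.30 and
    0.80, and returns the pooled accuracies needed to assess the crossover:
    the pooled model should lead over all persons in the low-data regime
    (proportion 0.30) while the per-person trees should lead for the
    >100-valid-day subgroup in the data-rich regime (proportion 0.80).
    """
    from . import synth

    cfg = synth.CohortConfig.high_heterogeneity(n_persons=n_persons)
    cohort = synth.generate_cohort(cfg, seed=seed)
    samples = feat.build_samples(
        cohort.stress, cohort.activity, cohort.weather,
        mode="nomothetic", persons=cohort.persons,
    )
    sweep = run_sweep(
        samples,
        families=["elastic_net", "ideographic_tree"],
        proportions=[0.3, 0.8],
        seed=seed,
        model_params={"ideographic_tree": {"min_samples_leaf": 12}},
    )

    def acc(model: str, p: float, sub: str) -> float:
        row = sweep[
            (sweep["model"] == model)
            & (sweep["proportion"] == p)
            & (sweep["subgroup"] == sub)
        ]
        return float(row["accuracy"].iloc[0]) if len(row) else float("nan")

    return {
        "nomothetic_acc_p30_all": acc("elastic_net", 0.3, SUBGROUP_ALL),
        "ideographic_acc_p30_all": acc("ideographic_tree", 0.3, SUBGROUP_ALL),
        "nomothetic_acc_p80_over100": acc("elastic_net", 0.8, ">100"),
        "ideographic_acc_p80_over100": acc("ideographic_tree", 0.8, ">100"),
    }


# ---------------------------------------------------------------------------
# warm start
# ---------------------------------------------------------------------------


def warm_start_predict(
    nomothetic: mdl.TrainedModel,
    ideographic: mdl.TrainedModel,
    person_samples: pd.DataFrame,
    threshold: feat.StressThreshold,
    window: int = 14,
    mode: str = "weight",
    ties: str = "below",
) -> pd.DataFrame:
    """Blend a pooled and a personal model while monitoring both on one person.

    Days are processed chronologically.  In ``weight`` mode each model is
    weighted by the inverse of its mean absolute error over its last
    ``window`` scored predictions (uniform 1/2 weights until both models have
    ``window`` scores).  In ``switch`` mode the currently better model (lower
    rolling MAE, ties to the nomothetic model) takes all the weight.  The
    blended continuous prediction is binarized against the person's training
    median.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if mode not in ("weight", "switch"):
        raise ValueError("mode must be 'weight' or 'switch'")
    ordered = person_samples.sort_values("target_date").reset_index(drop=True)
    pred_n = nomothetic.predict(ordered)
    pred_i = ideographic.predict(ordered)
    y = ordered["y"].to_numpy(float)
    errs_n: list[float] = []
    errs_i: list[float] = []
    records = []
    eps = 1e-9
    for t in range(len(ordered)):
        if len(errs_n) >= window and len(errs_i) >= window:
            mae_n = float(np.mean(errs_n[-window:]))
            mae_i = float(np.mean(errs_i[-window:]))
            if mode == "weight":
                inv_n, inv_i = 1.0 / (mae_n + eps), 1.0 / (mae_i + eps)
                w_n = inv_n / (inv_n + inv_i)
            else:
                w_n = 1.0 if mae_n <= mae_i else 0.0
        else:
            w_n = 0.5
        blended = w_n * pred_n[t] + (1 - w_n) * pred_i[t]
        records.append({
            "target_date": ordered["target_date"].iloc[t],
            "weight_nomothetic": w_n,
            "weight_ideographic": 1 - w_n,
            "pred_nomothetic": pred_n[t],
            "pred_ideographic": pred_i[t],
            "prediction": blended,
            "pred_class": int(feat.binarize([blended], threshold, ties=ties)[0]),
            "label": int(feat.binarize([y[t]], threshold, ties=ties)[0]),
            "y": y[t],
        })
        errs_n.append(abs(pred_n[t] - y[t]))
        errs_i.append(abs(pred_i[t] - y[t]))
    out = pd.DataFrame(records)
    out.insert(0, "person_id", ordered["person_id"].iloc[0] if len(ordered) else "")
    return out
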