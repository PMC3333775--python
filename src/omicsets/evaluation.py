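"""Benchmark evaluation: truth labeling, top-k discoveries, ROC/AUC, and
exclusive-discovery fractions.

A discovered set counts as a true positive if it shares at least half of its
genes with the union of genes of the spiked-in sets (for disjoint
collections this reduces to: exactly the spiked sets are true). Methods are
compared by

* the number of true positives among their top-k sets (smallest P-values),
* the area under the ROC curve of spiked vs non-spiked classification by
  P-value, and
* exclusive fractions: EF(i) is the fraction of a platform's true
  discoveries that no *other* platform discovers; EF*(l) is the fraction of
  an integration method's true discoveries that no single platform
  discovers at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .datamodel import GeneSetCollection
from .exceptions import InputError
from .simulation import SimulationResult, SpikeTruth

__all__ = [
    "truth_labels",
    "topk_true_positives",
    "roc_auc",
    "average_roc",
    "exclusive_fraction",
    "exclusive_fraction_integration",
    "EvaluationReport",
    "evaluate_scenario",
]


def truth_labels(
    collection: GeneSetCollection,
    truth: SpikeTruth,
    overlap_threshold: float = 0.5,
) -> pd.Series:
    """Boolean true-positive label per set.

    Set s is true iff |s ∩ union(spiked-set genes)| / |s| >= threshold
    (boundary inclusive). For disjoint collections this marks exactly the
    spiked sets.
    """
    union = truth.spiked_union
    out = {}
    for sid in collection.set_ids:
        genes = collection.genes(sid)
        out[sid] = len(union.intersection(genes)) / len(genes) >= overlap_threshold
    return pd.Series(out, name="true_positive")


def _ranked_sets(results: pd.DataFrame) -> pd.DataFrame:
    # ties in p broken by set id, lexicographic: deterministic and seed-free
    return results.sort_values(["p", "set_id"], kind="stable")


def topk_true_positives(results: pd.DataFrame, truth: pd.Series, k: int = 10) -> int:
    """True positives among the k sets with smallest P-values."""
    if results["p"].isna().any():
        raise InputError("all sets must carry a p-value")
    k = min(k, len(results))
    top = _ranked_sets(results).head(k)["set_id"]
    return int(truth.reindex(top).fillna(False).sum())


def top_sets(results: pd.DataFrame, k: int = 10) -> list[str]:
    """Ids of the k top-ranked sets (smallest P-values, ties by set id)."""
    return _ranked_sets(results).head(min(k, len(results)))["set_id"].tolist()


def roc_auc(
    results: pd.DataFrame, truth: pd.Series
) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """ROC curve and trapezoid AUC of spiked-vs-non-spiked by P-value.

    Sets are scored by -p (smaller P ranks higher); tied P-values are
    grouped on the curve, making the trapezoid area identical to the
    rank-statistic (Mann-Whitney) AUC.
    """
    labels = truth.reindex(results["set_id"]).to_numpy(dtype=bool)
    if labels.all() or not labels.any():
        raise InputError("need at least one true and one false set for a ROC curve")
    fpr, tpr, _ = roc_curve(labels, -results["p"].to_numpy(dtype=float))
    auc = float(np.trapezoid(tpr, fpr))
    return (fpr, tpr), auc


def average_roc(
    curves: Sequence[tuple[np.ndarray, np.ndarray]], n_grid: int = 101
) -> pd.DataFrame:
    """Vertically average ROC curves on a fixed specificity grid."""
    grid = np.linspace(0.0, 1.0, n_grid)
    sens = np.vstack(
        [np.interp(grid, fpr, tpr) for fpr, tpr in curves]
    )
    return pd.DataFrame(
        {
            "fpr": grid,
            "mean_tpr": sens.mean(axis=0),
            "sd_tpr": sens.std(axis=0, ddof=1) if len(curves) > 1 else 0.0,
        }
    )


def exclusive_fraction(tp_sets: Mapping[str, set], target: str) -> float:
    """EF(i) = 1 - |(∪_{j≠i} TP(j)) ∩ TP(i)| / |TP(i)|.

    Fraction of platform i's true discoveries found by no other platform.
    NaN (undefined) when TP(i) is empty.
    """
    tp_i = set(tp_sets[target])
    if not tp_i:
        return float("nan")
    others: set = set()
    for j, tps in tp_sets.items():
        if j != target:
            others |= set(tps)
    return 1.0 - len(others & tp_i) / len(tp_i)


def exclusive_fraction_integration(
    tp_single: Mapping[str, set], tp_method: set
) -> float:
    """EF*(l) = 1 - |(∪_{j∈S} TP(j)) ∩ TP(l)| / |TP(l)|.

    Fraction of an integration method's true discoveries missed by every
    single platform. NaN when TP(l) is empty.
    """
    tp_l = set(tp_method)
    if not tp_l:
        return float("nan")
    union: set = set()
    for tps in tp_single.values():
        union |= set(tps)
    return 1.0 - len(union & tp_l) / len(tp_l)


@dataclass
class EvaluationReport:
    """Aggregated benchmark metrics for one scenario."""

    topk: pd.DataFrame  # method x (mean, sd)
    auc: pd.DataFrame  # method x (mean, sd)
    ef: pd.DataFrame  # platform x (mean, n_defined, n_skipped)
    ef_star: pd.DataFrame  # integration method x (mean, n_defined, n_skipped)
    roc_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    k: int = 10
    n_reps: int = 0

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n_reps": self.n_reps,
            "topk": self.topk.to_dict(orient="index"),
            "auc": self.auc.to_dict(orient="index"),
            "ef": self.ef.to_dict(orient="index"),
            "ef_star": self.ef_star.to_dict(orient="index"),
        }


def evaluate_scenario(
    result: SimulationResult,
    k: int = 10,
    overlap_threshold: float = 0.5,
    n_grid: int = 101,
) -> EvaluationReport:
    """Compute per-method top-k counts, AUCs, averaged ROC curves and
    exclusive fractions across the repetitions of a scenario."""
    methods = result.methods
    single = [m for m in methods if m not in ("INT", "AvgP", "MinP")]
    integr = [m for m in methods if m in ("INT", "AvgP", "MinP")]
    topk_acc: dict[str, list[int]] = {m: [] for m in methods}
    auc_acc: dict[str, list[float]] = {m: [] for m in methods}
    curves: dict[str, list] = {m: [] for m in methods}
    ef_acc: dict[str, list[float]] = {m: [] for m in single}
    ef_star_acc: dict[str, list[float]] = {m: [] for m in integr}

    for rep in result.reps:
        truth = truth_labels(rep.collection, rep.truth, overlap_threshold)
        true_ids = set(truth.index[truth])
        tp: dict[str, set] = {}
        for m, table in rep.tables.items():
            topk_acc[m].append(topk_true_positives(table, truth, k))
            curve, auc = roc_auc(table, truth)
            curves[m].append(curve)
            auc_acc[m].append(auc)
            tp[m] = set(top_sets(table, k)) & true_ids
        for m in single:
            ef_acc[m].append(exclusive_fraction({s: tp[s] for s in single}, m))
        for m in integr:
            ef_star_acc[m].append(
                exclusive_fraction_integration({s: tp[s] for s in single}, tp[m])
            )

    def mean_sd(acc: dict) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean": {m: float(np.mean(v)) for m, v in acc.items()},
                "sd": {m: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
                       for m, v in acc.items()},
            }
        )

    def ef_frame(acc: dict) -> pd.DataFrame:
        rows = {}
        for m, vals in acc.items():
            arr = np.asarray(vals, dtype=float)
            defined = arr[~np.isnan(arr)]
            rows[m] = {
                "mean": float(defined.mean()) if defined.size else float("nan"),
                "n_defined": int(defined.size),
                "n_skipped": int(np.isnan(arr).sum()),
            }
        return pd.DataFrame.from_dict(rows, orient="index")

    return EvaluationReport(
        topk=mean_sd(topk_acc),
        auc=mean_sd(auc_acc),
        ef=ef_frame(ef_acc),
        ef_star=ef_frame(ef_star_acc),
        roc_curves={m: average_roc(c, n_grid) for m, c in curves.items() if c},
        k=k,
        n_reps=len(result.reps),
    )
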