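"""Regression and protonation-state classification metrics.

Regression quality is summarized per holdout split (Pearson correlation,
RMSE, maximum absolute error) and then averaged across splits; protonation
classification is *pooled*: the three-class labels of all splits'
predictions are accumulated into one confusion table before any ratio is
formed.  The two aggregation orders genuinely differ, and the pooled order
is the fixed convention here.

Instances whose experimental OR predicted class is titrating are excluded
from precision/recall and from the critical error rate (CER) — the
fraction of scored instances where a protonated residue is predicted
deprotonated or vice versa, the most consequential failure mode for
downstream structure preparation.  Because the exclusion depends on the
model's own predictions, the scored denominator legitimately differs
between models evaluated on identical test data.  Metrics that would
divide by zero (a class never predicted) are reported as undefined (NaN),
never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .protonation import ClassBoundaries, classify_array

__all__ = ["RegressionMetrics", "ClassificationReport", "EvalReport",
           "regression_metrics", "classification_report",
           "aggregate_protocol", "compare_predictors"]

_CLASSES = ("protonated", "deprotonated", "titrating")


@dataclass
class RegressionMetrics:
    pcc: float          # NaN when undefined (zero variance)
    rmse: float
    maxe: float
    n: int

    @property
    def pcc_defined(self) -> bool:
        return np.isfinite(self.pcc)


@dataclass
class ClassificationReport:
    precision: dict[str, float]     # per non-titrating class; NaN = undefined
    recall: dict[str, float]
    cer_numerator: int
    cer_denominator: int
    excluded_titrating: int
    confusion: pd.DataFrame         # 3x3, experimental rows x predicted cols

    @property
    def cer(self) -> float:
        if self.cer_denominator == 0:
            return float("nan")
        return self.cer_numerator / self.cer_denominator


@dataclass
class EvalReport:
    per_split: pd.DataFrame                  # split_id, pcc, rmse, maxe, n
    mean: dict[str, float]
    sd: dict[str, float]
    pooled_classification: ClassificationReport
    per_aa: dict[str, dict] = field(default_factory=dict)


def regression_metrics(pred, true) -> RegressionMetrics:
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("pred and true must have equal length")
    if pred.size < 2:
        raise ValueError("need >= 2 instances")
    if np.std(pred) == 0 or np.std(true) == 0:
        pcc = float("nan")
    else:
        pcc = float(stats.pearsonr(pred, true).statistic)
    err = pred - true
    return RegressionMetrics(pcc=pcc,
                             rmse=float(np.sqrt(np.mean(err ** 2))),
                             maxe=float(np.max(np.abs(err))),
                             n=pred.size)


def classification_report(pred_pka, true_pka,
                          boundaries: ClassBoundaries = ClassBoundaries()
                          ) -> ClassificationReport:
    pred_pka = np.asarray(pred_pka, dtype=float)
    true_pka = np.asarray(true_pka, dtype=float)
    if pred_pka.shape != true_pka.shape:
        raise ValueError("pred and true must have equal length")
    pred_cls = classify_array(pred_pka, boundaries)
    true_cls = classify_array(true_pka, boundaries)
    confusion = pd.DataFrame(0, index=list(_CLASSES), columns=list(_CLASSES))
    for t, p in zip(true_cls, pred_cls):
        confusion.loc[t, p] += 1
    scored = (true_cls != "titrating") & (pred_cls != "titrating")
    excluded = int(len(pred_pka) - scored.sum())
    precision: dict[str, float] = {}
    recall: dict[str, float] = {}
    for cls in ("protonated", "deprotonated"):
        pred_hits = scored & (pred_cls == cls)
        true_hits = scored & (true_cls == cls)
        tp = int(np.sum(pred_hits & true_hits))
        precision[cls] = tp / pred_hits.sum() if pred_hits.any() else float("nan")
        recall[cls] = tp / true_hits.sum() if true_hits.any() else float("nan")
    cer_num = int(confusion.loc["protonated", "deprotonated"]
                  + confusion.loc["deprotonated", "protonated"])
    return ClassificationReport(precision=precision, recall=recall,
                                cer_numerator=cer_num,
                                cer_denominator=int(scored.sum()),
                                excluded_titrating=excluded,
                                confusion=confusion)


def aggregate_protocol(predictions: pd.DataFrame,
                       boundaries: ClassBoundaries = ClassBoundaries()
                       ) -> EvalReport:
    """Per-split regression mean ± SD plus pooled classification.

    ``predictions`` needs columns split_id, pka_pred, pka_exp and
    optionally aa for per-residue-type slices.  SD uses the n-1
    denominator; with a single split it is reported as 0.
    """
    if len(predictions) == 0:
        raise ValueError("no predictions to aggregate")
    rows = []
    for split_id, grp in predictions.groupby("split_id"):
        m = regression_metrics(grp["pka_pred"], grp["pka_exp"])
        rows.append({"split_id": split_id, "pcc": m.pcc, "rmse": m.rmse,
                     "maxe": m.maxe, "n": m.n})
    per_split = pd.DataFrame(rows)
    mean = {k: float(per_split[k].mean()) for k in ("pcc", "rmse", "maxe")}
    sd = {k: (float(per_split[k].std(ddof=1)) if len(per_split) > 1 else 0.0)
          for k in ("pcc", "rmse", "maxe")}
    pooled = classification_report(predictions["pka_pred"],
                                   predictions["pka_exp"], boundaries)
    per_aa: dict[str, dict] = {}
    if "aa" in predictions.columns:
        for aa, grp in predictions.groupby("aa"):
            aa_rows = []
            for split_id, g in grp.groupby("split_id"):
                if len(g) >= 2:
                    m = regression_metrics(g["pka_pred"], g["pka_exp"])
                    aa_rows.append({"pcc": m.pcc, "rmse": m.rmse,
                                    "maxe": m.maxe})
            aa_cls = classification_report(grp["pka_pred"], grp["pka_exp"],
                                           boundaries)
            per_aa[aa] = {
                "rmse_mean": (float(np.nanmean([r["rmse"] for r in aa_rows]))
                              if aa_rows else float("nan")),
                "pcc_mean": (float(np.nanmean([r["pcc"] for r in aa_rows]))
                             if aa_rows else float("nan")),
                "classification": aa_cls,
            }
    return EvalReport(per_split=per_split, mean=mean, sd=sd,
                      pooled_classification=pooled, per_aa=per_aa)


def compare_predictors(tables: dict[str, pd.DataFrame], truth: pd.DataFrame,
                       boundaries: ClassBoundaries = ClassBoundaries()
                       ) -> dict[str, dict]:
    """Side-by-side reports for several predictors against one truth table.

    Every table is keyed by (unique_key, structure_ref); predictors may
    miss rows (external tools fail on some inputs), and the per-predictor
    missing count is reported alongside metrics on the remainder.
    """
    if not tables:
        raise ValueError("no predictor tables given")
    key_cols = ["unique_key", "structure_ref"]
    truth_idx = truth.set_index(key_cols)
    reports: dict[str, dict] = {}
    for name, tab in tables.items():
        merged = truth_idx.join(tab.set_index(key_cols)["pka_pred"],
                                how="left")
        missing = int(merged["pka_pred"].isna().sum())
        got = merged.dropna(subset=["pka_pred"])
        if len(got) == 0:
            raise ValueError(f"predictor {name!r} shares no instances "
                             f"with the truth table")
        reports[name] = {
            "n_scored": len(got),
            "n_missing": missing,
            "regression": regression_metrics(got["pka_pred"], got["pka_exp"]),
            "classification": classification_report(
                got["pka_pred"], got["pka_exp"], boundaries),
        }
    return reports
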