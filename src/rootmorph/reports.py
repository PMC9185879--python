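"""Cohort-level report builders: group comparison, ROC summary and cut-off
accuracy tables in the layout used throughout the package (rows indexed by
parameter: RL, PRW, RSA, RV, RSA_RL, RV_RL)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diagnostics import (
    classify,
    contingency_metrics,
    group_compare,
    roc_curve,
    youden_cutoff,
)

__all__ = ["metric_columns", "group_comparison_table", "roc_table", "accuracy_table"]


def metric_columns(cohort: pd.DataFrame) -> list[str]:
    return [c for c in cohort.columns if c not in ("tooth_id", "group")]


def _split_groups(cohort: pd.DataFrame, param: str):
    crt = cohort.loc[cohort["group"] == "CRT", param].to_numpy(float)
    nrt = cohort.loc[cohort["group"] == "NRT", param].to_numpy(float)
    return crt, nrt


def group_comparison_table(cohort: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Mean +- SD per group with two-sample test p-values (one row per metric)."""
    rows = {}
    for param in metric_columns(cohort):
        crt, nrt = _split_groups(cohort, param)
        cmp = group_compare(nrt, crt)
        rows[param] = {
            "NRT_mean": round(float(nrt.mean()), decimals),
            "NRT_sd": round(float(nrt.std(ddof=1)), decimals),
            "CRT_mean": round(float(crt.mean()), decimals),
            "CRT_sd": round(float(crt.std(ddof=1)), decimals),
            "t_p": round(cmp["t_p"], 3),
            "rank_p": round(cmp["rank_p"], 3),
        }
    return pd.DataFrame(rows).T


def roc_table(cohort: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """AUC and Youden-optimal cut-off per metric (CRT = low values)."""
    rows = {}
    for param in metric_columns(cohort):
        crt, nrt = _split_groups(cohort, param)
        rep = youden_cutoff(roc_curve(crt, nrt, param), crt, nrt)
        rows[param] = {
            "AUC": round(rep.auc, decimals),
            "cutoff": round(rep.cutoff, decimals),
        }
    return pd.DataFrame(rows).T


def accuracy_table(
    cohort: pd.DataFrame, cutoffs: dict[str, float] | None = None, decimals: int = 2
) -> pd.DataFrame:
    """Se/Sp/PV+-/YI/LR+- per metric after classifying with the cut-off
    (Youden-optimal unless explicit cut-offs are supplied)."""
    rows = {}
    for param in metric_columns(cohort):
        crt, nrt = _split_groups(cohort, param)
        if cutoffs and param in cutoffs:
            cut = cutoffs[param]
        else:
            cut = youden_cutoff(roc_curve(crt, nrt, param), crt, nrt).cutoff
        tp = int((classify(crt, cut) == "CRT").sum())
        fn = len(crt) - tp
        fp = int((classify(nrt, cut) == "CRT").sum())
        tn = len(nrt) - fp
        m = contingency_metrics(tp, fp, fn, tn)
        rows[param] = {
            "cutoff": round(float(cut), decimals),
            **{
                k: (round(v, decimals) if v is not None else np.nan)
                for k, v in m.as_dict().items()
            },
        }
    return pd.DataFrame(rows).T
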