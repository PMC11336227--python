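"""Behavioral statistics: negativity bias, experiment comparison, questionnaires.

The negativity bias is the percentage of negative ratings among all logged
ratings (negative + positive + neutral; missed responses are excluded — a
rating requires a logged response).  Group statistics run on the subjects
usable in both experiments; the bias is compared between experiments with a
paired t-test and correlated (Pearson) with BDI-2 and STAI-S/STAI-T scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "negativity_bias",
    "count_ratings",
    "behavior_table",
    "compare_bias",
    "questionnaire_correlations",
]

QUESTIONNAIRES = ("bdi2", "stai_s", "stai_t")


def count_ratings(ratings) -> dict:
    """Counts of negative / positive / neutral / missed responses."""
    ratings = np.asarray(ratings)
    return {lab: int(np.sum(ratings == lab))
            for lab in ("negative", "positive", "neutral", "missed")}


def negativity_bias(counts: dict) -> float:
    """Percent negative of all logged ratings: 100 * neg / (neg + pos + neu)."""
    rated = counts.get("negative", 0) + counts.get("positive", 0) \
        + counts.get("neutral", 0)
    if rated < 1:
        raise ValueError("negativity bias undefined without logged ratings")
    return 100.0 * counts.get("negative", 0) / rated


def behavior_table(records) -> pd.DataFrame:
    """Per subject-and-experiment table of counts, bias and questionnaires.

    ``records`` is an iterable of dicts with keys ``subject``,
    ``experiment``, ``ratings`` (label sequence) and optionally the
    questionnaire scores ``bdi2``/``stai_s``/``stai_t``.
    """
    rows = []
    for rec in records:
        counts = count_ratings(rec["ratings"])
        row = {"subject": rec["subject"], "experiment": rec["experiment"],
               **{f"n_{k}": v for k, v in counts.items()},
               "negativity_bias_pct": negativity_bias(counts)}
        for q in QUESTIONNAIRES:
            if q in rec:
                row[q] = rec[q]
        rows.append(row)
    return pd.DataFrame(rows)


def compare_bias(bias_exp1, bias_exp2) -> tuple:
    """Paired t-test of per-subject bias between experiments.

    Inputs are aligned over the shared subjects.  Returns (t, df, p
    two-sided); t is NaN (flagged) when the differences have zero variance.
    """
    b1 = np.asarray(bias_exp1, dtype=float)
    b2 = np.asarray(bias_exp2, dtype=float)
    if b1.shape != b2.shape:
        raise ValueError("bias vectors must be paired over shared subjects")
    n = len(b1)
    if n < 2:
        raise ValueError("need at least 2 shared subjects")
    diff = b1 - b2
    if diff.std(ddof=1) == 0:
        if np.all(diff == 0):
            # identical biases: no difference at all, t is exactly 0
            return 0.0, n - 1, 1.0
        return float("nan"), n - 1, float("nan")
    t, p = stats.ttest_rel(b1, b2)
    return float(t), n - 1, float(p)


def questionnaire_correlations(bias, scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (with two-sided p) of bias vs each questionnaire column."""
    bias = np.asarray(bias, dtype=float)
    if len(bias) < 3:
        raise ValueError("correlation needs at least 3 subjects")
    rows = []
    for col in scores.columns:
        x = scores[col].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise ValueError(f"constant scores for {col!r}")
        r, p = stats.pearsonr(bias, x)
        rows.append({"questionnaire": col, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)
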