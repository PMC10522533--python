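"""Signal-detection and categorization scoring for the behavioral tasks.

The sequence task is a yes/no target-detection task scored with d'
(equal-variance Gaussian model); the isolation task is a five-
alternative forced-choice emotion categorization scored with a
confusion matrix and one-vs-rest per-category d' values.  Extreme hit
or false-alarm rates (0 or 1) are clamped by the 1/(2N) rule before the
normal-quantile transform.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .audio import EMOTION_CATEGORIES
from .freqtag import bh_fdr


def _rate(count: int, n: int) -> float:
    """Proportion with 1/(2N) clamping of 0 and 1."""
    r = count / n
    if r <= 0.0:
        return 1.0 / (2 * n)
    if r >= 1.0:
        return 1.0 - 1.0 / (2 * n)
    return r


def dprime(hits: int, misses: int, fas: int, crs: int) -> float:
    """Sensitivity d' = Phi^-1(H) - Phi^-1(F).

    H = hits/(hits+misses), F = fas/(fas+crs); extreme rates are
    adjusted by the 1/(2N) rule.
    """
    n_signal = hits + misses
    n_noise = fas + crs
    if n_signal == 0 or n_noise == 0:
        raise ValueError("need at least one signal and one noise trial")
    h = _rate(hits, n_signal)
    f = _rate(fas, n_noise)
    return float(norm.ppf(h) - norm.ppf(f))


def score_detection(table: pd.DataFrame) -> tuple[int, int, int, int]:
    """Count (hits, misses, false alarms, correct rejections) from a
    yes/no trial table with ``target_present`` and ``response`` columns."""
    present = table["target_present"].astype(bool).to_numpy()
    yes = (table["response"] == "yes").to_numpy()
    hits = int(np.sum(present & yes))
    misses = int(np.sum(present & ~yes))
    fas = int(np.sum(~present & yes))
    crs = int(np.sum(~present & ~yes))
    return hits, misses, fas, crs


def dprime_from_table(table: pd.DataFrame) -> float:
    return dprime(*score_detection(table))


def group_test(dprimes: np.ndarray) -> tuple[float, float, float]:
    """One-sample one-tailed t-test of d' > 0 across participants.

    Returns (t, p, Cohen's d) with d = mean/SD.  A zero-variance
    positive vector yields t = +inf (flagged degenerate); an all-zero
    vector yields (0, 0.5, 0).
    """
    d = np.asarray(dprimes, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two participants")
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0, 0.5, 0.0
        sign = float(np.sign(d.mean()))
        return sign * np.inf, 0.0 if sign > 0 else 1.0, sign * np.inf
    t = d.mean() / (sd / np.sqrt(d.size))
    from scipy.stats import t as tdist
    return float(t), float(tdist.sf(t, df=d.size - 1)), float(d.mean() / sd)


def group_tests(dprimes_by_label: dict[str, np.ndarray],
                q: float = 0.05) -> pd.DataFrame:
    """d' > 0 test per label with FDR correction across the family."""
    rows = []
    for label in sorted(dprimes_by_label):
        t, p, d = group_test(np.asarray(dprimes_by_label[label]))
        rows.append({"label": label, "t": t, "p": p, "cohen_d": d})
    df = pd.DataFrame(rows)
    df["significant_fdr"] = bh_fdr(df["p"].to_numpy(), q)
    return df


def categorization_matrix(table: pd.DataFrame, task: str = "isolation"
                          ) -> tuple[pd.DataFrame, pd.Series, float]:
    """Row-normalized confusion matrix of the forced-choice task.

    Returns (matrix, per-category accuracy, chance level); chance is
    1/(number of alternatives).
    """
    rows = table[table["task"] == task]
    if rows.empty:
        raise ValueError(f"no rows for task {task!r}")
    cats = list(EMOTION_CATEGORIES)
    unknown = set(rows["true_category"]) - set(cats)
    unknown |= set(rows["response"]) - set(cats)
    if unknown:
        raise ValueError(f"unknown category labels: {sorted(unknown)}")
    counts = pd.crosstab(rows["true_category"], rows["response"])
    counts = counts.reindex(index=cats, columns=cats, fill_value=0)
    totals = counts.sum(axis=1)
    matrix = counts.div(totals.replace(0, np.nan), axis=0)
    accuracy = pd.Series(np.diag(matrix), index=cats, name="accuracy")
    return matrix, accuracy, 1.0 / len(cats)


def isolation_dprimes(table: pd.DataFrame, task: str = "isolation"
                      ) -> pd.Series:
    """One-vs-rest per-category d' for the forced-choice task.

    For each category, signal trials are stimuli of that category (hit =
    responding with it) and noise trials are all other stimuli (false
    alarm = responding with that category).
    """
    rows = table[table["task"] == task]
    if rows.empty:
        raise ValueError(f"no rows for task {task!r}")
    true = rows["true_category"].to_numpy()
    resp = rows["response"].to_numpy()
    out = {}
    for cat in EMOTION_CATEGORIES:
        is_sig = true == cat
        said = resp == cat
        out[cat] = dprime(int(np.sum(is_sig & said)),
                          int(np.sum(is_sig & ~said)),
                          int(np.sum(~is_sig & said)),
                          int(np.sum(~is_sig & ~said)))
    return pd.Series(out, name="dprime")


def rating_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Descriptive mean/SD of valence and arousal ratings per category."""
    rows = table.dropna(subset=["valence", "arousal"])
    return rows.groupby("true_category")[["valence", "arousal"]] \
        .agg(["mean", "std"])
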