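"""Clinical-score handling for the paired stroke cohort.

Covers the cohort summary statistics, the percent-difference change
statistic, Spearman rank correlations between metabolite levels and
motor-recovery scores (three correlation families), and the Bonferroni
significance threshold used to control the family-wise error over the
selected biomarker panel.

Score instruments and valid ranges: NIHSS (stroke severity, 0–42,
higher = worse), FIM (functional independence, 18–126), CMSA hand/arm
(motor impairment, 1 = paralysis to 7 = normal movement).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SCORE_RANGES = {
    "nihss_initial": (0.0, 42.0),
    "fim_initial": (18.0, 126.0),
    "fim_6mo": (18.0, 126.0),
    "cmsa_hand_initial": (1.0, 7.0),
    "cmsa_hand_6mo": (1.0, 7.0),
    "cmsa_arm_initial": (1.0, 7.0),
    "cmsa_arm_6mo": (1.0, 7.0),
}

#: (initial, six-month) column pairs for which an improvement is defined
IMPROVEMENT_PAIRS = {
    "fim": ("fim_initial", "fim_6mo"),
    "cmsa_hand": ("cmsa_hand_initial", "cmsa_hand_6mo"),
    "cmsa_arm": ("cmsa_arm_initial", "cmsa_arm_6mo"),
}


@dataclass
class ClinicalRecord:
    """One subject's clinical and demographic row."""

    subject_id: str
    stroke_type: str
    sex: str
    age: float
    acute_day: float
    chronic_day: float
    nihss_initial: float | None = None
    fim_initial: float | None = None
    fim_6mo: float | None = None
    cmsa_hand_initial: float | None = None
    cmsa_hand_6mo: float | None = None
    cmsa_arm_initial: float | None = None
    cmsa_arm_6mo: float | None = None


def validate_record(rec: ClinicalRecord) -> None:
    """Raise ``ValueError`` naming the offending field when a score is out of range."""
    if rec.acute_day < 0 or rec.chronic_day < 0:
        raise ValueError("collection days must be >= 0")
    for col, (lo, hi) in SCORE_RANGES.items():
        v = getattr(rec, col)
        if v is not None and not (lo <= v <= hi):
            raise ValueError(f"{col}={v} outside valid range [{lo}, {hi}]")


def records_to_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records])
    return df.set_index("subject_id")


# ---------------------------------------------------------------------------
# percent difference (the change statistic)

def percent_difference(initial: float | None, six_month: float | None) -> float:
    """Percent change relative to the mean of the two time points.

    ``(six_month - initial) / ((six_month + initial) / 2) * 100``;
    bounded in (-200, 200) for positive inputs.  Missing inputs
    propagate as NaN; a zero mean is undefined and raises.
    """
    if initial is None or six_month is None:
        return float("nan")
    if isinstance(initial, float) and math.isnan(initial):
        return float("nan")
    if isinstance(six_month, float) and math.isnan(six_month):
        return float("nan")
    mean = (initial + six_month) / 2.0
    if mean == 0:
        raise ValueError("percent difference undefined when initial + six_month == 0")
    return (six_month - initial) / mean * 100.0


def percent_difference_array(initial: np.ndarray, six_month: np.ndarray) -> np.ndarray:
    initial = np.asarray(initial, dtype=float)
    six_month = np.asarray(six_month, dtype=float)
    mean = (initial + six_month) / 2.0
    if np.any(mean[np.isfinite(mean)] == 0):
        raise ValueError("percent difference undefined when initial + six_month == 0")
    return (six_month - initial) / mean * 100.0


# ---------------------------------------------------------------------------
# cohort summary

def _iqr(values: np.ndarray) -> float:
    # linear-interpolation quantiles between order statistics
    q75, q25 = np.percentile(values, [75, 25])
    return float(q75 - q25)


def summarize_cohort(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Per-variable n/mean/sd/median/IQR summary of the cohort.

    Improvements are six-month minus initial; a subject missing either
    endpoint is excluded from that improvement's statistics (pairwise
    deletion).  Standard deviation uses the n-1 denominator; quantiles
    interpolate linearly between order statistics.  With a single
    observation the sd is reported missing.
    """
    if not records:
        raise ValueError("summarize_cohort needs at least one record")
    df = records_to_frame(records)
    variables: dict[str, np.ndarray] = {}
    for col in ["age", "acute_day", "chronic_day", *SCORE_RANGES]:
        variables[col] = df[col].dropna().to_numpy(dtype=float)
    for name, (ini, six) in IMPROVEMENT_PAIRS.items():
        both = df[[ini, six]].dropna()
        variables[f"{name}_improvement"] = (
            both[six].to_numpy(dtype=float) - both[ini].to_numpy(dtype=float)
        )
    rows = []
    for name, vals in variables.items():
        if len(vals) == 0:
            rows.append({"variable": name, "n": 0, "mean": np.nan, "sd": np.nan,
                         "median": np.nan, "iqr": np.nan})
            continue
        rows.append(
            {
                "variable": name,
                "n": len(vals),
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                "median": float(np.median(vals)),
                "iqr": _iqr(vals),
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def nihss_severity_counts(records: Sequence[ClinicalRecord]) -> dict[str, int]:
    """Counts by conventional NIHSS strata: mild <=4, moderate 5-15, severe >15."""
    counts = {"mild": 0, "moderate": 0, "severe": 0, "missing": 0}
    for rec in records:
        v = rec.nihss_initial
        if v is None:
            counts["missing"] += 1
        elif v <= 4:
            counts["mild"] += 1
        elif v <= 15:
            counts["moderate"] += 1
        else:
            counts["severe"] += 1
    return counts


# ---------------------------------------------------------------------------
# Spearman correlation

def spearman(
    x: Iterable[float],
    y: Iterable[float],
    method: str = "t",
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is Pearson correlation on mid-ranks (average ranks for ties).
    ``method='t'`` (default) derives p from
    ``t = rho * sqrt((n - 2) / (1 - rho^2))`` on n-2 df; ``'exact'``
    enumerates all rank permutations (n <= 8 only).  Incomplete pairs
    are dropped before ranking.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman rho undefined")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "exact":
        if n > 8:
            raise ValueError("exact permutation p limited to n <= 8")
        obs = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= obs - 1e-12
            total += 1
        return rho, count / total
    return rho, spearman_p_from_rho(rho, n)


def spearman_p_from_rho(rho: float, n: int) -> float:
    """Two-sided p for a Spearman rho via the Student-t approximation.

    ``t = rho * sqrt((n - 2) / (1 - rho^2))`` referred to n-2 degrees
    of freedom; |rho| = 1 maps to p = 0.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold ``alpha / m`` for ``m`` tested panel bins."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# correlation families

FAMILY_1 = "acute-vs-initial"
FAMILY_2 = "acute-vs-pctdiff"
FAMILY_3 = "pctdiff-vs-pctdiff"

#: scores with both an initial and a six-month assessment
_CHANGE_SCORES = ["fim", "cmsa_hand", "cmsa_arm"]
#: scores with an initial assessment only (NIHSS has no 6-month value here)
_INITIAL_SCORES = ["nihss_initial", "fim_initial", "cmsa_hand_initial", "cmsa_arm_initial"]


def correlation_families(
    acute: pd.DataFrame,
    pct_diff: pd.DataFrame,
    records: Sequence[ClinicalRecord],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All three Spearman correlation families over a biomarker panel.

    ``acute`` holds subjects x panel-bins acute-phase levels,
    ``pct_diff`` the per-subject percent difference of the same bins
    (both indexed by subject id).  Family 1 correlates acute levels
    with initial scores; family 2 acute levels with score percent
    differences; family 3 metabolite percent differences with score
    percent differences.  The Bonferroni threshold divides ``alpha`` by
    the panel size.  Combinations with fewer than 3 complete pairs are
    skipped with a log note.
    """
    if acute.shape[1] == 0:
        raise ValueError("empty panel")
    clin = records_to_frame(records)
    clin = clin.reindex(acute.index)
    score_pct = {}
    for name in _CHANGE_SCORES:
        ini, six = IMPROVEMENT_PAIRS[name]
        score_pct[name] = percent_difference_array(
            clin[ini].to_numpy(dtype=float), clin[six].to_numpy(dtype=float)
        )
    threshold = bonferroni_threshold(alpha, acute.shape[1])
    rows = []

    def _append(family: str, metab, score_name: str, x, y) -> None:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        keep = np.isfinite(x) & np.isfinite(y)
        if keep.sum() < 3:
            logger.info("skipping %s %s vs %s: only %d complete pairs",
                        family, metab, score_name, int(keep.sum()))
            return
        rho, p = spearman(x[keep], y[keep])
        rows.append(
            {
                "family": family,
                "metabolite": metab,
                "score": score_name,
                "rho": rho,
                "p": p,
                "n_pairs": int(keep.sum()),
                "passes_bonferroni": p < threshold,
            }
        )

    for bin_id in acute.columns:
        xa = acute[bin_id].to_numpy(dtype=float)
        xp = pct_diff[bin_id].to_numpy(dtype=float)
        for score in _INITIAL_SCORES:
            _append(FAMILY_1, bin_id, score, xa, clin[score].to_numpy(dtype=float))
        for score in _CHANGE_SCORES:
            _append(FAMILY_2, bin_id, f"{score}_pctdiff", xa, score_pct[score])
        for score in _CHANGE_SCORES:
            _append(FAMILY_3, bin_id, f"{score}_pctdiff", xp, score_pct[score])
    return pd.DataFrame(
        rows,
        columns=["family", "metabolite", "score", "rho", "p", "n_pairs", "passes_bonferroni"],
    )
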