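"""Per-bin paired significance testing with normality gating.

For each bin the paired (chronic minus acute) differences are gated by
a Shapiro-Wilk normality test; normal-looking bins get a paired t-test,
the rest a Wilcoxon signed-rank test (exact by default at the study's
sample sizes).  Raw p-values get a step-down Bonferroni-Holm
adjustment, and each bin is labelled up- or down-regulated by the sign
of its median paired difference (chronic vs acute convention).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class UnivariateResult:
    bin_id: object
    test_used: str  # "paired-t" | "wilcoxon"
    statistic: float
    p_raw: float
    p_holm: float
    regulation: str | None  # "up" | "down" | None when median difference is 0


def shapiro_wilk_gate(diffs: np.ndarray, alpha: float = 0.05) -> str:
    """'parametric' iff Shapiro-Wilk on the paired differences has p > alpha.

    Constant differences leave W undefined; such bins are routed to the
    nonparametric branch with a warning.
    """
    diffs = np.asarray(diffs, dtype=float)
    if not 3 <= len(diffs) <= 5000:
        raise ValueError("Shapiro-Wilk gate needs 3 <= n <= 5000")
    if np.ptp(diffs) == 0:
        warnings.warn("constant differences: Shapiro-Wilk W undefined; gating nonparametric")
        return "nonparametric"
    _, p = stats.shapiro(diffs)
    return "parametric" if p > alpha else "nonparametric"


def paired_t(acute: np.ndarray, chronic: np.ndarray) -> tuple[float, float]:
    """Paired t-test on d = chronic - acute; two-sided p on n-1 df."""
    acute = np.asarray(acute, dtype=float)
    chronic = np.asarray(chronic, dtype=float)
    if acute.shape != chronic.shape or acute.ndim != 1:
        raise ValueError("acute and chronic must be 1-D and equal length")
    d = chronic - acute
    if len(d) < 2:
        raise ValueError("need n >= 2 pairs")
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero-variance differences: t undefined")
    res = stats.ttest_rel(chronic, acute)
    return float(res.statistic), float(res.pvalue)


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Counts of subsets of (doubled, integer) ranks by sum, over all 2^n sign
    assignments; shift-algorithm dynamic programme, handles tied mid-ranks."""
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        counts[r:] += counts[: total + 1 - r]
    return counts


def wilcoxon_signed_rank(
    acute: np.ndarray,
    chronic: np.ndarray,
    mode: str = "auto",
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on d = chronic - acute.

    Zero differences are dropped (standard signed-rank convention); W
    is min(W+, W-) over mid-ranks of |d|.  The two-sided p is exact by
    the shift-algorithm over all 2^n equiprobable sign assignments for
    n <= 25 (default), otherwise a normal approximation with tie and
    continuity corrections.
    """
    d = np.asarray(chronic, dtype=float) - np.asarray(acute, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = float(ranks.sum())  # = n(n+1)/2
    w = min(w_plus, total - w_plus)
    if mode not in {"auto", "exact", "normal-approx"}:
        raise ValueError(f"unknown mode: {mode}")
    exact = mode == "exact" or (mode == "auto" and n <= 25)
    if exact:
        ranks2 = np.rint(2 * ranks).astype(int)  # doubled mid-ranks are integers
        counts = _signed_rank_distribution(ranks2)
        total2 = int(ranks2.sum())
        w2 = int(round(2 * w))
        lower = counts[: w2 + 1].sum()
        upper = counts[total2 - w2:].sum()
        p = min(1.0, (lower + upper) / 2.0 ** n)
    else:
        mu = total / 2.0
        tie_sizes = np.unique(np.abs(d), return_counts=True)[1]
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_sizes ** 3 - tie_sizes).sum()) / 48.0
        z = (w - mu + 0.5) / np.sqrt(sigma2)  # continuity correction toward the mean
        p = min(1.0, 2.0 * stats.norm.cdf(z))
    return w, float(p)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Bonferroni-Holm adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def run_univariate(
    matrix: FeatureMatrix,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Gate + paired test + Holm adjustment for every bin.

    ``metadata`` must carry ``subject_id`` and ``phase``
    (acute/chronic) per sample; every subject needs both phases.
    Returns a DataFrame indexed by bin id with the bin center/label,
    the test used, the statistic, raw and Holm-adjusted p, and the
    regulation direction (sign of the median chronic-minus-acute
    difference).
    """
    meta = metadata.reindex(matrix.values.index)
    pivot: dict[str, dict[str, str]] = {}
    for sid, row in meta.iterrows():
        pivot.setdefault(row["subject_id"], {})[row["phase"]] = sid
    unpaired = [s for s, ph in pivot.items() if set(ph) != {"acute", "chronic"}]
    if unpaired:
        raise ValueError(f"subjects without both phases: {sorted(unpaired)}")
    subjects = sorted(pivot)
    acute_ids = [pivot[s]["acute"] for s in subjects]
    chronic_ids = [pivot[s]["chronic"] for s in subjects]

    rows = []
    for bin_id in matrix.values.columns:
        a = matrix.values.loc[acute_ids, bin_id].to_numpy(dtype=float)
        c = matrix.values.loc[chronic_ids, bin_id].to_numpy(dtype=float)
        d = c - a
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gate = shapiro_wilk_gate(d, alpha)
        if gate == "parametric":
            stat, p = paired_t(a, c)
            test = "paired-t"
        else:
            stat, p = wilcoxon_signed_rank(a, c)
            test = "wilcoxon"
        med = float(np.median(d))
        regulation = "up" if med > 0 else ("down" if med < 0 else None)
        rows.append({"bin_id": bin_id, "test_used": test, "statistic": stat,
                     "p_raw": p, "regulation": regulation})
    out = pd.DataFrame(rows).set_index("bin_id")
    out["p_holm"] = holm_adjust(out["p_raw"])
    manifest = matrix.bins
    out.insert(0, "center", manifest.loc[out.index, "center"].to_numpy())
    out.insert(1, "label", manifest.loc[out.index, "label"].to_numpy())
    return out[["center", "label", "test_used", "statistic", "p_raw", "p_holm", "regulation"]]
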