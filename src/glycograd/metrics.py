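"""Confusion matrices, performance metrics, aggregation and exact tests.

The performance suite is the standard 2×2 set — accuracy, precision,
sensitivity, specificity, F1 — plus the Matthews correlation coefficient

    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

a balanced single-number summary in [−1, 1] that is robust to class
imbalance.  A metric with a zero denominator is *undefined* and propagated
as NaN, never coerced to 0.

The consistency tests are implemented exactly (by enumeration of the null
distribution) so that small-sample results are reproducible bit-for-bit:

* Wilcoxon signed-rank: W = min(W⁺, W⁻); two-sided p from the full 2ⁿ
  sign-pattern null (dynamic programming over rank sums); rank-biserial
  effect size r = (W⁺ − W⁻)/(W⁺ + W⁻).
* Mann–Whitney: U reported as max(U₁, U₂); exact two-sided p by
  enumerating all C(m+n, m) group labelings of the observed pooled ranks
  (mid-ranks for ties) when m, n ≤ 10, else a tie-corrected normal
  approximation.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import AnalysisError

logger = logging.getLogger(__name__)

OUTCOMES = ("TP", "TN", "FP", "FN")

#: largest sample size for which the Wilcoxon null is enumerated exactly
WILCOXON_EXACT_LIMIT = 25
#: largest per-group size for which the Mann-Whitney null is enumerated
MANN_WHITNEY_EXACT_LIMIT = 10


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricSet:
    """Proportion metrics of one confusion matrix; NaN marks undefined."""

    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    mcc: float


@dataclass(frozen=True)
class ConsistencyResult:
    statistic: float
    p_value: float
    effect_size: float  # NaN for the Mann-Whitney test
    method: str
    n: int


@dataclass(frozen=True)
class AggregateSummary:
    """Mean / sample-STD / median / mode of a collection of metric values.

    The mode is taken over values rounded to 2 decimals (the precision at
    which percentages are customarily reported); ties resolve to the
    smallest candidate and set ``multimodal``.
    """

    n: int
    mean: float
    std: float  # NaN when n == 1
    median: float
    mode: float
    multimodal: bool


def confusion(events: pd.DataFrame, group_keys: tuple[str, ...] = ()) -> pd.DataFrame:
    """Count TP/TN/FP/FN events, optionally per group.

    ``group_keys`` is a subset of the event columns (e.g. ``participant``,
    ``hypothesis``, ``width_minutes``).  Groups with zero events simply do
    not appear.  Returns a frame with the group keys plus tp/tn/fp/fn.
    """
    if events.empty:
        logger.warning("confusion: no events")
        return pd.DataFrame(columns=[*group_keys, "tp", "tn", "fp", "fn"])
    bad = set(events["outcome"]) - set(OUTCOMES)
    if bad:
        raise AnalysisError(f"unknown outcome labels {sorted(bad)}")
    if group_keys:
        grouped = (events.groupby(list(group_keys), observed=True)["outcome"]
                   .value_counts().unstack(fill_value=0))
    else:
        grouped = events["outcome"].value_counts().to_frame().T
        grouped.index = [0]
    for o in OUTCOMES:
        if o not in grouped.columns:
            grouped[o] = 0
    out = grouped[list(OUTCOMES)].rename(columns=str.lower)
    return out.reset_index() if group_keys else out.reset_index(drop=True)


def matrix_from_events(events: pd.DataFrame) -> ConfusionMatrix:
    """Pool all events into a single confusion matrix."""
    counts = events["outcome"].value_counts()
    return ConfusionMatrix(*(int(counts.get(o, 0)) for o in OUTCOMES))


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def performance(cm: ConfusionMatrix) -> MetricSet:
    """All six performance metrics of one confusion matrix."""
    if cm.total < 1:
        raise AnalysisError("performance metrics require at least one event")
    accuracy = (cm.tp + cm.tn) / cm.total
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    sensitivity = _ratio(cm.tp, cm.tp + cm.fn)
    specificity = _ratio(cm.tn, cm.tn + cm.fp)
    if math.isnan(precision) or math.isnan(sensitivity):
        f1 = math.nan
    else:
        f1 = _ratio(2 * precision * sensitivity, precision + sensitivity)
    denom = math.sqrt(float(cm.tp + cm.fp) * (cm.tp + cm.fn)
                      * (cm.tn + cm.fp) * (cm.tn + cm.fn))
    mcc = (cm.tp * cm.tn - cm.fp * cm.fn) / denom if denom > 0 else math.nan
    return MetricSet(accuracy, precision, sensitivity, specificity, f1, mcc)


def aggregate_metrics(values, round_decimals: int = 2) -> AggregateSummary:
    """Mean, sample STD, median and mode of per-participant metric values."""
    v = np.asarray(list(values), dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise AnalysisError("aggregate_metrics requires at least one value")
    rounded = np.round(v, round_decimals)
    counts = Counter(rounded.tolist())
    top = max(counts.values())
    candidates = sorted(val for val, c in counts.items() if c == top)
    return AggregateSummary(
        n=int(v.size),
        mean=float(v.mean()),
        std=float(v.std(ddof=1)) if v.size > 1 else math.nan,
        median=float(np.median(v)),
        mode=float(candidates[0]),
        multimodal=len(candidates) > 1,
    )


def _signed_rank_null_cdf(scaled_ranks: np.ndarray) -> np.ndarray:
    """Counts of sign patterns by W⁺ (on doubled-rank scale), via DP."""
    total = int(scaled_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.uint64)
    counts[0] = 1
    for r in scaled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    return counts


def wilcoxon_exact(x, y=None) -> ConsistencyResult:
    """Exact two-sided Wilcoxon signed-rank test on paired values.

    ``x`` may be the differences directly, or paired with ``y``.  Zero
    differences are dropped before ranking; ties among |d| get mid-ranks.
    W is the smaller signed-rank sum, so perfect directional consistency
    yields W = 0; eight uniformly signed pairs give p = 2/2⁸ ≈ 0.0078 and
    rank-biserial r = 1.0.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise AnalysisError("all differences are zero; no information")
    if n > WILCOXON_EXACT_LIMIT:
        raise AnalysisError(f"exact enumeration limited to n <= {WILCOXON_EXACT_LIMIT}")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    # mid-ranks can be half-integers; double them so the DP is integral
    scaled = np.rint(ranks * 2).astype(int)
    counts = _signed_rank_null_cdf(scaled)
    w_scaled = int(round(w * 2))
    p_le = counts[:w_scaled + 1].sum() / float(2 ** n)
    p = min(1.0, 2.0 * p_le)
    r = (w_plus - w_minus) / (w_plus + w_minus)
    return ConsistencyResult(statistic=w, p_value=p, effect_size=r,
                             method="wilcoxon_exact", n=n)


def _u_from_rank_sum(r1: float, m: int, n: int) -> tuple[float, float]:
    u1 = r1 - m * (m + 1) / 2.0
    return u1, m * n - u1


def mann_whitney_exact(group_a, group_b) -> ConsistencyResult:
    """Two-sided Mann-Whitney U test; exact by enumeration for m, n <= 10.

    The reported statistic is max(U₁, U₂) — complete separation of two
    groups of 8 gives the maximum possible U = 64.  Ties are handled with
    mid-ranks, the exact null being the permutation distribution over the
    observed pooled values.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    m, n = a.size, b.size
    if m == 0 or n == 0:
        raise AnalysisError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u1, u2 = _u_from_rank_sum(float(ranks[:m].sum()), m, n)
    u_obs = max(u1, u2)
    if m <= MANN_WHITNEY_EXACT_LIMIT and n <= MANN_WHITNEY_EXACT_LIMIT:
        hits = 0
        total = 0
        for comb in combinations(range(m + n), m):
            r1 = float(ranks[list(comb)].sum())
            c1, c2 = _u_from_rank_sum(r1, m, n)
            hits += max(c1, c2) >= u_obs - 1e-12
            total += 1
        p = hits / total
        method = "mann_whitney_exact"
    else:
        mu = m * n / 2.0
        tie_counts = np.array(list(Counter(pooled.tolist()).values()))
        nn = m + n
        tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (nn * (nn - 1))
        sigma = math.sqrt(m * n / 12.0 * (nn + 1 - tie_term))
        if sigma == 0:
            raise AnalysisError("degenerate samples: all pooled values tied")
        z = (u_obs - 0.5 - mu) / sigma  # continuity-corrected
        from scipy.stats import norm
        p = min(1.0, 2.0 * norm.sf(z))
        method = "mann_whitney_normal"
    return ConsistencyResult(statistic=u_obs, p_value=p, effect_size=math.nan,
                             method=method, n=m + n)
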