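"""Hypothesis-driven classification of evaluation instants.

Two directional hypotheses about the glucose response to non-standard
physical activity are evaluated at every instant *x* where both a prior
gradient g_prev (over [x−t, x]) and a post gradient g_post (over [x, x+t])
exist on an unbroken window chain:

* **H1** — blood glucose is already falling at *x* (g_prev < 0): does
  non-standard PA steepen (or sustain) the fall?
* **H2** — blood glucose is rising at *x* (g_prev > 0): does non-standard
  PA slow or reverse the rise?

The "glucose change" category compares the two gradients in the direction
of the prevailing trend: d = g_prev − g_post under H1 (a fall steepening
makes d > 0) and d = g_post − g_prev under H2 (a rise accelerating makes
d > 0).  A dead-zone ``eps`` (mmol/L per min) operationalises "same":
|d| ≤ eps.  The 2 (PA category) × 3 (change) outcome grids are::

    H1               increase  same  decrease
    non-standard PA     TP      TP     FP
    standard PA         FN      FN     TN

    H2               increase  same  decrease
    non-standard PA     FP      FP     TP
    standard PA         TN      TN     FN

An instant is evaluated under at most one hypothesis (disjoint by the sign
of g_prev); |g_prev| ≤ eps is eligible under neither.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .gradients import NON_STANDARD, STANDARD

logger = logging.getLogger(__name__)

H1 = "H1"
H2 = "H2"
HYPOTHESES = (H1, H2)

INCREASE = "increase"
SAME = "same"
DECREASE = "decrease"

#: outcome lookup, (pa_category, change_category) -> outcome
H1_OUTCOMES = {
    (NON_STANDARD, INCREASE): "TP",
    (NON_STANDARD, SAME): "TP",
    (NON_STANDARD, DECREASE): "FP",
    (STANDARD, INCREASE): "FN",
    (STANDARD, SAME): "FN",
    (STANDARD, DECREASE): "TN",
}
H2_OUTCOMES = {
    (NON_STANDARD, INCREASE): "FP",
    (NON_STANDARD, SAME): "FP",
    (NON_STANDARD, DECREASE): "TP",
    (STANDARD, INCREASE): "TN",
    (STANDARD, SAME): "TN",
    (STANDARD, DECREASE): "FN",
}
OUTCOME_TABLES = {H1: H1_OUTCOMES, H2: H2_OUTCOMES}


@dataclass(frozen=True)
class Epsilon:
    """Dead-zone half-width for "glucose change same" (mmol/L per min).

    The default, 0.005, equals one CGM quantisation step (0.1 mmol/L) over a
    20 min window.
    """

    same_tolerance: float = 0.005

    def __post_init__(self):
        if self.same_tolerance < 0:
            raise ConfigurationError("same_tolerance must be >= 0")


DEFAULT_EPS = Epsilon()


def build_instants(gradient_points: pd.DataFrame) -> pd.DataFrame:
    """Pair consecutive gradient points into evaluation instants.

    The gradient point at timestamp *x* supplies g_prev; the point at
    *x + width* (same calendar day) supplies g_post.  Returns
    ``timestamp, width_minutes, g_prev, g_post``.
    """
    if gradient_points.empty:
        return pd.DataFrame(columns=["timestamp", "width_minutes", "g_prev", "g_post"])
    g = gradient_points.sort_values("timestamp").reset_index(drop=True)
    step = pd.to_timedelta(g["width_minutes"], unit="m")
    nxt_ts = g["timestamp"].shift(-1)
    same_day = g["timestamp"].dt.normalize() == nxt_ts.dt.normalize()
    chained = (nxt_ts - g["timestamp"] == step) & same_day
    keep = chained.fillna(False).to_numpy()
    out = pd.DataFrame({
        "timestamp": g["timestamp"].to_numpy()[keep],
        "width_minutes": g["width_minutes"].to_numpy()[keep].astype(int),
        "g_prev": g["glucose_gradient"].to_numpy()[keep],
        "g_post": g["glucose_gradient"].shift(-1).to_numpy()[keep],
    })
    return out


def eligible_instants(instants: pd.DataFrame, hypothesis: str,
                      eps: Epsilon = DEFAULT_EPS) -> pd.DataFrame:
    """Keep the instants evaluable under ``hypothesis``.

    H1 requires g_prev < −eps (an established fall); H2 requires
    g_prev > +eps (an established rise).  The dead zone belongs to neither.
    """
    if hypothesis not in HYPOTHESES:
        raise ConfigurationError(f"hypothesis {hypothesis!r} not in {HYPOTHESES}")
    tol = eps.same_tolerance
    if hypothesis == H1:
        mask = instants["g_prev"] < -tol
    else:
        mask = instants["g_prev"] > tol
    return instants.loc[mask].reset_index(drop=True)


def change_category(g_prev, g_post, hypothesis: str, eps: Epsilon = DEFAULT_EPS):
    """Categorise the trend-directed change as increase / same / decrease.

    Vectorised; accepts scalars or arrays.
    """
    if hypothesis not in HYPOTHESES:
        raise ConfigurationError(f"hypothesis {hypothesis!r} not in {HYPOTHESES}")
    g_prev = np.asarray(g_prev, dtype=float)
    g_post = np.asarray(g_post, dtype=float)
    d = (g_prev - g_post) if hypothesis == H1 else (g_post - g_prev)
    cat = np.where(d > eps.same_tolerance, INCREASE,
                   np.where(d < -eps.same_tolerance, DECREASE, SAME))
    return cat.item() if cat.ndim == 0 else cat


def classify(instants: pd.DataFrame, pa_categories: pd.DataFrame,
             hypothesis: str, eps: Epsilon = DEFAULT_EPS) -> pd.DataFrame:
    """Produce one classified event per eligible instant.

    ``pa_categories`` holds ``timestamp, category`` for the window ending at
    each instant (the activity of the immediately preceding interval).
    Instants lacking a PA category are skipped and counted.

    Returns ``timestamp, hypothesis, width_minutes, pa_category, g_prev,
    g_post, change_category, outcome``.
    """
    elig = eligible_instants(instants, hypothesis, eps)
    merged = pd.merge(elig, pa_categories.rename(columns={"category": "pa_category"}),
                      on="timestamp", how="left")
    missing = merged["pa_category"].isna()
    if missing.any():
        logger.info("classify(%s): skipped %d instants without a PA category",
                    hypothesis, int(missing.sum()))
        merged = merged.loc[~missing].reset_index(drop=True)
    if merged.empty:
        return pd.DataFrame(columns=["timestamp", "hypothesis", "width_minutes",
                                     "pa_category", "g_prev", "g_post",
                                     "change_category", "outcome"])
    merged["hypothesis"] = hypothesis
    merged["change_category"] = change_category(
        merged["g_prev"].to_numpy(), merged["g_post"].to_numpy(), hypothesis, eps)
    table = OUTCOME_TABLES[hypothesis]
    merged["outcome"] = [table[(pa, ch)] for pa, ch in
                         zip(merged["pa_category"], merged["change_category"])]
    cols = ["timestamp", "hypothesis", "width_minutes", "pa_category",
            "g_prev", "g_post", "change_category", "outcome"]
    return merged[cols]


def classify_all(instants: pd.DataFrame, pa_categories: pd.DataFrame,
                 eps: Epsilon = DEFAULT_EPS) -> pd.DataFrame:
    """Classify under both hypotheses and concatenate the event streams."""
    events = [classify(instants, pa_categories, h, eps) for h in HYPOTHESES]
    non_empty = [e for e in events if not e.empty]
    return pd.concat(non_empty, ignore_index=True) if non_empty else events[0]
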