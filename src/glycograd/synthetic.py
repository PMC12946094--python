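"""Synthetic paired actigraphy + CGM streams with ground-truth labels.

The generator emulates the statistical structure the analysis assumes for a
free-living participant with type 1 diabetes:

* 15 s actigraphy epochs over 5–8 full days.  Baseline counts are drawn
  from an overdispersed gamma–Poisson (negative-binomial-like) distribution
  — actigraphy counts are non-negative and right-skewed.  Scheduled
  activity bouts add their intensity on top, with a deterministic
  within-bout modulation (epochs alternate 0.5× / 1.5× the intensity, mean
  1×) because real wrist-worn bouts fluctuate epoch to epoch; this keeps
  the windowed activity std strictly positive wherever a bout is present,
  even in noise-free runs.
* 5 min CGM readings integrated by an Euler step at the CGM tick:
  the glucose slope is −decline_per_count × (scheduled bout excess, lagged
  by ``response_lag_minutes``) plus any intervention effect, with Gaussian
  process noise per step.  The lag is a pure delay — activity begins to
  affect glucose roughly 15–20 min after onset.  The forcing uses the
  *scheduled* bout excess, not the noisy realised counts, so that with no
  bouts and zero glucose noise the trace is exactly constant.
* Behavioural confounders — carbohydrate intake and insulin suspension —
  enter as interventions that add a positive term to the glucose slope,
  blunting or cancelling an expected decline.

Glucose is clipped to [2, 22] mmol/L; clipping events are logged.  Epochs
outside the daytime span (and inside explicit sleep blocks) are labelled
REST-S so the cleaning stage exercises its exclusion path.

Alongside the streams, a ground-truth table records, for every evaluable
instant of every analysis width, the expected PA category (from the bout
schedule), the prior/post glucose gradients of the *noise-free* trajectory,
and the expected classification outcome.  On zero-noise data the pipeline
reproduces these exactly; under noise they are the generative expectation,
not a guarantee.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from datetime import date, datetime, time, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigurationError
from .gradients import NON_STANDARD, STANDARD
from .hypotheses import DEFAULT_EPS, Epsilon
from .preprocess import ACTIVE, REST, REST_S, STANDARD_WIDTHS

logger = logging.getLogger(__name__)

GLUCOSE_CLIP = (2.0, 22.0)

CARBOHYDRATE = "carbohydrate"
INSULIN_SUSPENSION = "insulin_suspension"
INTERVENTION_KINDS = (CARBOHYDRATE, INSULIN_SUSPENSION)

# expected-outcome grids, kept inline so the ground truth does not lean on
# the classifier implementation it is later checked against
_GT_H1 = {(NON_STANDARD, "increase"): "TP", (NON_STANDARD, "same"): "TP",
          (NON_STANDARD, "decrease"): "FP", (STANDARD, "increase"): "FN",
          (STANDARD, "same"): "FN", (STANDARD, "decrease"): "TN"}
_GT_H2 = {(NON_STANDARD, "increase"): "FP", (NON_STANDARD, "same"): "FP",
          (NON_STANDARD, "decrease"): "TP", (STANDARD, "increase"): "TN",
          (STANDARD, "same"): "TN", (STANDARD, "decrease"): "FN"}


@dataclass(frozen=True)
class BoutSpec:
    """One scheduled activity bout.

    ``intensity`` is the mean excess (counts/epoch) above baseline;
    ``is_non_standard`` is the ground-truth label for the bout.
    """

    start: datetime
    duration_minutes: float
    intensity: float
    is_non_standard: bool = True

    def __post_init__(self):
        if self.duration_minutes <= 0:
            raise ConfigurationError("bout_schedule: duration_minutes must be > 0")
        if self.intensity < 0:
            raise ConfigurationError("bout_schedule: intensity must be >= 0")

    @property
    def end(self) -> datetime:
        return self.start + timedelta(minutes=self.duration_minutes)


@dataclass(frozen=True)
class InterventionSpec:
    """A behavioural confounder adding ``glucose_effect`` (mmol/L per min)
    to the glucose slope for ``duration_minutes`` from ``start``."""

    start: datetime
    kind: str
    glucose_effect: float
    duration_minutes: float

    def __post_init__(self):
        if self.kind not in INTERVENTION_KINDS:
            raise ConfigurationError(
                f"intervention_schedule: kind {self.kind!r} not in {INTERVENTION_KINDS}")
        if self.duration_minutes <= 0:
            raise ConfigurationError("intervention_schedule: duration_minutes must be > 0")

    @property
    def end(self) -> datetime:
        return self.start + timedelta(minutes=self.duration_minutes)


def default_bout_schedule(start_date: date, n_days: int) -> list[BoutSpec]:
    """Three extended daily activity periods (morning, midday, evening).

    Starts and durations sit on the 20 min analysis grid so the lagged
    glucose declines align with the finest gradient windows; the midday and
    evening bouts begin during a meal-induced glucose rise so that
    rising-glucose (H2) events occur.  Two-hour durations reflect that
    free-living activity effects on glucose are sustained, not momentary.
    """
    daily = [(time(9, 40), 120, 180.0), (time(12, 40), 120, 260.0),
             (time(17, 40), 120, 150.0)]
    return [BoutSpec(datetime.combine(start_date + timedelta(days=d), t), dur, inten)
            for d in range(n_days) for t, dur, inten in daily]


def default_intervention_schedule(start_date: date, n_days: int,
                                  decline_per_count: float = 0.0001) -> list[InterventionSpec]:
    """Three daily carbohydrate intakes (meals) balancing the bout-induced
    declines so the noise-free trajectory is day-periodic with no drift."""
    daily = [(time(8, 0), 0.074, 40), (time(12, 20), 0.026, 60),
             (time(17, 20), 0.064, 40)]
    return [InterventionSpec(datetime.combine(start_date + timedelta(days=d), t),
                             CARBOHYDRATE, eff, dur)
            for d in range(n_days) for t, eff, dur in daily]


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated participant.

    Defaults describe five days of free-living data: overdispersed baseline
    wrist activity (mean 15 counts/epoch), three daily bouts, three daily
    meals, a 20 min activity-to-glucose lag, and mild glucose process noise
    (0.03 mmol/L per 5 min step).
    """

    n_days: int = 5
    start_date: date = date(2024, 3, 4)
    day_start: time = time(6, 0)
    day_end: time = time(23, 59)
    epoch_seconds: int = 15
    cgm_minutes: int = 5
    baseline_activity_mean: float = 15.0
    baseline_activity_dispersion: float = 0.5
    bout_schedule: tuple[BoutSpec, ...] | None = None
    glucose_start: float = 7.0
    glucose_noise_sd: float = 0.03
    decline_per_count: float = 0.0001
    response_lag_minutes: float = 20.0
    intervention_schedule: tuple[InterventionSpec, ...] | None = None
    sleep_blocks: tuple[tuple[time, time], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_days < 1:
            raise ConfigurationError("n_days must be >= 1")
        if self.epoch_seconds <= 0:
            raise ConfigurationError("epoch_seconds must be > 0")
        if self.cgm_minutes <= 0:
            raise ConfigurationError("cgm_minutes must be > 0")
        if (self.cgm_minutes * 60) % self.epoch_seconds:
            raise ConfigurationError(
                "epoch_seconds must divide cgm_minutes*60 "
                f"({self.epoch_seconds} vs {self.cgm_minutes * 60})")
        if not (2.0 <= self.glucose_start <= 20.0):
            raise ConfigurationError("glucose_start must lie within 2.0-20.0 mmol/L")
        if self.glucose_noise_sd < 0:
            raise ConfigurationError("glucose_noise_sd must be >= 0")
        if self.baseline_activity_mean < 0:
            raise ConfigurationError("baseline_activity_mean must be >= 0")
        if self.baseline_activity_dispersion < 0:
            raise ConfigurationError("baseline_activity_dispersion must be >= 0")
        if self.response_lag_minutes < 0:
            raise ConfigurationError("response_lag_minutes must be >= 0")
        if self.day_start >= self.day_end:
            raise ConfigurationError("day_start must precede day_end")
        if self.bout_schedule is None:
            object.__setattr__(self, "bout_schedule",
                               tuple(default_bout_schedule(self.start_date, self.n_days)))
        else:
            object.__setattr__(self, "bout_schedule", tuple(self.bout_schedule))
        if self.intervention_schedule is None:
            object.__setattr__(
                self, "intervention_schedule",
                tuple(default_intervention_schedule(self.start_date, self.n_days,
                                                    self.decline_per_count)))
        else:
            object.__setattr__(self, "intervention_schedule",
                               tuple(self.intervention_schedule))
        span_start, span_end = self.span
        for b in self.bout_schedule:
            if b.start < span_start or b.end > span_end:
                raise ConfigurationError(
                    f"bout_schedule: bout at {b.start} falls outside the simulated days")
        for iv in self.intervention_schedule:
            if iv.start < span_start or iv.end > span_end:
                raise ConfigurationError(
                    f"intervention_schedule: intervention at {iv.start} falls outside "
                    "the simulated days")
        for s, e in self.sleep_blocks:
            if s >= e:
                raise ConfigurationError("sleep_blocks: start must precede end")

    @property
    def span(self) -> tuple[datetime, datetime]:
        start = datetime.combine(self.start_date, time(0))
        return start, start + timedelta(days=self.n_days)

    def quiet(self) -> "SimConfig":
        """A noise-free copy with no bouts or interventions (for baselines)."""
        return replace(self, bout_schedule=(), intervention_schedule=(),
                       glucose_noise_sd=0.0, baseline_activity_mean=0.0,
                       baseline_activity_dispersion=0.0)


def _seconds_of_day(n: int, step_seconds: int) -> np.ndarray:
    return (np.arange(n, dtype=np.int64) * step_seconds) % 86400


def _time_to_seconds(t: time) -> int:
    return t.hour * 3600 + t.minute * 60 + t.second


def _simulate_glucose(config: SimConfig, rng: np.random.Generator | None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Euler-integrate the CGM trace; returns (timestamps_min, glucose).

    ``rng=None`` produces the noise-free trajectory.
    """
    step = config.cgm_minutes
    n = config.n_days * 1440 // step
    minutes = np.arange(n, dtype=np.int64) * step

    # scheduled excess activity (counts/epoch) at each tick, and intervention slope
    excess = np.zeros(n)
    for b in config.bout_schedule:
        s = (b.start - config.span[0]).total_seconds() / 60.0
        mask = (minutes >= s) & (minutes < s + b.duration_minutes)
        excess[mask] += b.intensity
    interv = np.zeros(n)
    for iv in config.intervention_schedule:
        s = (iv.start - config.span[0]).total_seconds() / 60.0
        mask = (minutes >= s) & (minutes < s + iv.duration_minutes)
        interv[mask] += iv.glucose_effect

    # pure-delay lag: forcing at tick k uses the excess lag minutes earlier
    lag_ticks = int(round(config.response_lag_minutes / step))
    lagged = np.concatenate([np.zeros(lag_ticks), excess])[:n] if lag_ticks else excess

    slope = -config.decline_per_count * lagged + interv  # mmol/L per min
    noise = (rng.normal(0.0, config.glucose_noise_sd, n - 1)
             if rng is not None and config.glucose_noise_sd > 0 else np.zeros(n - 1))

    bg = np.empty(n)
    bg[0] = config.glucose_start
    lo, hi = GLUCOSE_CLIP
    n_clipped = 0
    for k in range(n - 1):
        v = bg[k] + slope[k] * step + noise[k]
        if v < lo or v > hi:
            n_clipped += 1
            v = min(max(v, lo), hi)
        bg[k + 1] = v
    if n_clipped:
        logger.info("glucose clipped to %s at %d of %d steps", GLUCOSE_CLIP, n_clipped, n)
    return minutes, bg


def _epoch_stream(config: SimConfig, rng: np.random.Generator
                  ) -> tuple[pd.DataFrame, np.ndarray]:
    es = config.epoch_seconds
    n = config.n_days * 86400 // es
    start = config.span[0]
    timestamps = pd.date_range(start, periods=n, freq=f"{es}s")

    mu, alpha = config.baseline_activity_mean, config.baseline_activity_dispersion
    if mu == 0:
        counts = np.zeros(n)
    elif alpha == 0:
        counts = rng.poisson(mu, n).astype(float)
    else:  # gamma-Poisson mixture: mean mu, variance mu + alpha*mu^2
        lam = rng.gamma(1.0 / alpha, alpha * mu, n)
        counts = rng.poisson(lam).astype(float)

    sec = np.arange(n, dtype=np.int64) * es
    in_bout = np.zeros(n, dtype=bool)
    ns_bout = np.zeros(n, dtype=bool)
    for b in config.bout_schedule:
        s = int((b.start - start).total_seconds())
        e = int((b.end - start).total_seconds())
        # an epoch stamped t summarises (t - epoch_seconds, t], so a bout
        # over [s, e) manifests in the epochs stamped s+es .. e
        mask = (sec > s) & (sec <= e)
        idx = np.flatnonzero(mask)
        modulation = 1.0 + 0.5 * np.where(np.arange(idx.size) % 2 == 0, 1.0, -1.0)
        counts[idx] += b.intensity * modulation
        in_bout |= mask
        if b.is_non_standard:
            ns_bout |= mask

    tod = _seconds_of_day(n, es)
    asleep = (tod < _time_to_seconds(config.day_start)) | \
             (tod > _time_to_seconds(config.day_end))
    for s_t, e_t in config.sleep_blocks:
        asleep |= (tod >= _time_to_seconds(s_t)) & (tod <= _time_to_seconds(e_t))

    status = np.where(asleep, REST_S, np.where(in_bout, ACTIVE, REST))
    epochs = pd.DataFrame({"timestamp": timestamps, "activity_count": counts,
                           "interval_status": status})
    return epochs, ns_bout, ~asleep


def _ground_truth(config: SimConfig, bg0: np.ndarray, ns_bout: np.ndarray,
                  awake: np.ndarray, eps: Epsilon,
                  widths: tuple[int, ...]) -> pd.DataFrame:
    """Expected per-instant labels from the noise-free trajectory.

    A window only survives the real pipeline if, after sleep/exclusion
    cleaning, it still holds >= 2 activity epochs (a lone sample has an
    undefined sample std and is dropped at the merge); the same survival
    rule is applied here.
    """
    tol = eps.same_tolerance
    day_lo = _time_to_seconds(config.day_start) // 60
    day_hi = _time_to_seconds(config.day_end) // 60
    ns_cum = np.concatenate([[0], np.cumsum(ns_bout)])
    awake_cum = np.concatenate([[0], np.cumsum(awake)])
    es = config.epoch_seconds
    start = config.span[0]
    rows = []
    for width in widths:
        if width % config.cgm_minutes:
            raise ConfigurationError(f"ground-truth width {width} not a multiple of "
                                     f"cgm_minutes={config.cgm_minutes}")
        total_min = config.n_days * 1440
        ends = np.arange(width, total_min + 1, width)  # minutes from sim start
        mod = ends % 1440
        daytime = (mod >= day_lo) & (mod <= day_hi)

        def level(m):  # noise-free BG at a window end (minutes from start)
            return bg0[m // config.cgm_minutes]

        def epoch_range(m):  # epoch indices inside window (m-width, m]
            return (m - width) * 60 // es + 1, m * 60 // es

        def window_survives(m):
            lo, hi = epoch_range(m)
            return awake_cum[hi + 1] - awake_cum[lo] >= 2

        for x in ends[daytime]:
            # an instant needs surviving windows at x-w, x and x+w, all with
            # daytime window ends on the same calendar day
            chain = [x - width, x, x + width]
            if chain[0] <= 0 or chain[-1] >= total_min:
                continue
            day = (x - 1) // 1440
            ok = all(day_lo <= c % 1440 <= day_hi and (c - 1) // 1440 == day
                     and window_survives(c) for c in chain)
            if not ok:
                continue
            g_prev = (level(x) - level(x - width)) / width
            g_post = (level(x + width) - level(x)) / width
            lo_idx, hi_idx = epoch_range(x)
            pa = NON_STANDARD if ns_cum[hi_idx + 1] - ns_cum[lo_idx] > 0 else STANDARD
            if g_prev < -tol:
                hyp, d = "H1", g_prev - g_post
            elif g_prev > tol:
                hyp, d = "H2", g_post - g_prev
            else:
                rows.append((start + timedelta(minutes=int(x)), width, pa,
                             g_prev, g_post, "none", None, None))
                continue
            change = "increase" if d > tol else ("decrease" if d < -tol else "same")
            outcome = (_GT_H1 if hyp == "H1" else _GT_H2)[(pa, change)]
            rows.append((start + timedelta(minutes=int(x)), width, pa,
                         g_prev, g_post, hyp, change, outcome))
    return pd.DataFrame(rows, columns=["timestamp", "width_minutes", "pa_category",
                                       "g_prev", "g_post", "hypothesis",
                                       "change_category", "outcome"])


def generate_participant(config: SimConfig, eps: Epsilon = DEFAULT_EPS,
                         ground_truth_widths: tuple[int, ...] = STANDARD_WIDTHS
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one participant.

    Returns ``(epochs, cgm, ground_truth)``: the 15 s actigraphy stream
    covering every epoch tick of every simulated day, the 5 min CGM stream,
    and the expected-label table.  Identical configs (including seed) give
    identical output.
    """
    rng = np.random.default_rng(config.seed)
    epochs, ns_bout, awake = _epoch_stream(config, rng)
    minutes, bg = _simulate_glucose(config, rng)
    _, bg0 = _simulate_glucose(config, None)
    cgm = pd.DataFrame({
        "timestamp": config.span[0] + pd.to_timedelta(minutes, unit="m"),
        "glucose_mmol_l": bg,
    })
    ground_truth = _ground_truth(config, bg0, ns_bout, awake, eps, ground_truth_widths)
    return epochs, cgm, ground_truth


def write_fixture(epochs: pd.DataFrame, cgm: pd.DataFrame,
                  ground_truth: pd.DataFrame | None, directory) -> dict[str, Path]:
    """Write the two CSV dialects plus the ground-truth JSON-lines sidecar.

    Files round-trip losslessly through :func:`glycograd.preprocess.read_actigraphy`
    / :func:`~glycograd.preprocess.read_cgm`.  Empty streams are refused
    before anything is written.
    """
    if epochs.empty or cgm.empty:
        raise AnalysisError("refusing to write fixture from an empty stream")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {"actigraphy": directory / "actigraphy.csv",
             "cgm": directory / "cgm.csv"}
    epochs.to_csv(paths["actigraphy"], index=False, date_format="%Y-%m-%dT%H:%M:%S")
    cgm.to_csv(paths["cgm"], index=False, date_format="%Y-%m-%dT%H:%M:%S")
    if ground_truth is not None:
        paths["ground_truth"] = directory / "ground_truth.jsonl"
        with open(paths["ground_truth"], "w") as fh:
            for rec in ground_truth.to_dict(orient="records"):
                rec["timestamp"] = rec["timestamp"].isoformat()
                fh.write(json.dumps(rec) + "\n")
    return paths


def read_ground_truth(path) -> pd.DataFrame:
    """Read back a ground-truth sidecar written by :func:`write_fixture`."""
    records = [json.loads(line) for line in Path(path).read_text().splitlines() if line]
    df = pd.DataFrame(records)
    if not df.empty:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df
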