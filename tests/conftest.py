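"""Shared fixtures: small synthetic configurations and generated streams."""

from datetime import datetime

import pandas as pd
import pytest

from glycograd import analyze_participant, generate_participant
from glycograd.synthetic import BoutSpec, SimConfig


def quiet_config(bouts=(), interventions=(), n_days=2, seed=3, **overrides):
    """Deterministic zero-noise configuration (no baseline activity)."""
    defaults = dict(n_days=n_days, glucose_noise_sd=0.0,
                    baseline_activity_mean=0.0, baseline_activity_dispersion=0.0,
                    decline_per_count=0.0001, bout_schedule=tuple(bouts),
                    intervention_schedule=tuple(interventions), seed=seed)
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def one_bout_config():
    """One 60 min bout at 10:00 of intensity 200 counts/epoch, zero noise."""
    return quiet_config(bouts=[BoutSpec(datetime(2024, 3, 4, 10, 0), 60, 200.0)])


@pytest.fixture(scope="session")
def one_bout_streams(one_bout_config):
    return generate_participant(one_bout_config)


@pytest.fixture(scope="session")
def default_participant():
    """One fully-featured participant at the generator defaults."""
    return generate_participant(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_events(default_participant):
    epochs, cgm, _ = default_participant
    events, _ = analyze_participant(epochs, cgm, participant_id="P01")
    return events


def make_merged(levels, start="2024-03-04 10:00", width=20, activity=None):
    """Build a minimal merged-window frame from glucose levels."""
    n = len(levels)
    ends = pd.date_range(start, periods=n, freq=f"{width}min")
    activity = list(activity) if activity is not None else [0.0] * n
    return pd.DataFrame({
        "window_end": ends,
        "width_minutes": width,
        "activity_std": activity,
        "glucose_std": [0.0] * n,
        "glucose_level": list(levels),
        "status": ["REST"] * n,
        "n_activity": [4 * width] * n,
        "n_glucose": [width // 5] * n,
    })
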