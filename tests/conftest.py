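"""Shared fixtures: small simulated sessions with known ground truth.

Module-scoped so expensive simulations and fits are computed once per
test module that uses them.
"""

from __future__ import annotations

import numpy as np
import pytest

from mfv.maternal import detect_r_peaks
from mfv.simulate import ScenarioConfig, simulate_session


@pytest.fixture(scope="session")
def quiet_session():
    """60 s clean session at defaults (80 bpm maternal, 140 bpm fetal)."""
    cfg = ScenarioConfig(duration_s=60.0, seed=11)
    session, truth = simulate_session(cfg)
    return cfg, session, truth


@pytest.fixture(scope="session")
def clinical_rates_session():
    """60 s clean session at clinically reported maternal/fetal rates (94/174 bpm)."""
    cfg = ScenarioConfig(duration_s=60.0, maternal_hr_bpm=94.0, fetal_hr_bpm=174.0, seed=12)
    session, truth = simulate_session(cfg)
    return cfg, session, truth


@pytest.fixture(scope="session")
def clinical_rates_beats(clinical_rates_session):
    _, session, _ = clinical_rates_session
    return detect_r_peaks(session.get("chest", "ecg"))


def match_events(detected_ms: np.ndarray, truth_ms: np.ndarray, tol_ms: float = 50.0):
    """(sensitivity, ppv) of detected event times against ground truth."""
    if detected_ms.size == 0 or truth_ms.size == 0:
        return 0.0, 0.0
    d = np.abs(np.asarray(detected_ms)[:, None] - np.asarray(truth_ms)[None, :])
    sens = float((d.min(axis=0) <= tol_ms).mean())
    ppv = float((d.min(axis=1) <= tol_ms).mean())
    return sens, ppv
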