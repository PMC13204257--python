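import numpy as np
import pandas as pd
import pytest

from carovib.scalogram import Scalogram
from carovib.synth import CohortConfig, generate_cohort
from carovib.pipeline import compute_feature_table


def make_scalogram(freqs, magnitude, fs=2400.0):
    """Hand-built scalogram for closed-form feature checks."""
    magnitude = np.asarray(magnitude, dtype=np.float64)
    freqs = np.asarray(freqs, dtype=np.float64)
    times = np.arange(magnitude.shape[1]) / fs
    return Scalogram(magnitude=magnitude, freqs_hz=freqs, times_s=times, fs=fs)


@pytest.fixture(scope="session")
def small_cohort_features():
    """Feature table of a small default-physics cohort (shared across tests).

    20 patients, both sides, two positions, fast generation at the analysis
    rate; severity effect at the default turbulence gain.
    """
    cfg = CohortConfig(n_patients=20, fast=True, seed=11)
    recordings, truth = generate_cohort(cfg)
    table = compute_feature_table(recordings)
    return table, truth


@pytest.fixture(scope="session")
def toy_predictions():
    """Deterministic segment-level prediction table for aggregation tests."""
    rng = np.random.default_rng(7)
    groups = np.repeat([f"g{i}" for i in range(12)], 10)
    labels = np.repeat(rng.integers(0, 2, 12), 10)
    probs = np.clip(labels * 0.4 + rng.uniform(0, 0.6, groups.size), 0, 1)
    return pd.DataFrame({"group": groups, "label": labels, "proba": probs})
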