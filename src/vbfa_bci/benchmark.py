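"""Simulation benchmarks: session-level accuracy of the full pipeline.

These drive the reduced-scale evaluation scenarios (64 channels, 200
samples per trial, 5 factors) used to check the classifier against the
performance level reported for the motor task: 10 training trials per
class, 60 scored trials, accuracy aggregated as the median over seeds.
"""

from __future__ import annotations

import numpy as np

from .classifier import classify_session, compute_performance, train_pair
from .config import LEFT, RIGHT, FitConfig
from .epoching import build_training_matrix, split_session
from .synthetic import SyntheticSpec, sample_session


def session_accuracy(spec: SyntheticSpec, config: FitConfig) -> float:
    """Simulate one session, train on its first trials, score the rest."""
    epochs = sample_session(spec)
    left, right, test = split_session(epochs, config.n_train_trials)
    pair = train_pair(
        build_training_matrix(left, LEFT, config.n_train_trials),
        build_training_matrix(right, RIGHT, config.n_train_trials),
        config=config,
    )
    records = classify_session(test[: config.n_test_trials] if config.n_test_trials else test, pair)
    return compute_performance(records)


def median_accuracy_over_seeds(
    seeds, config: FitConfig | None = None, **spec_overrides
) -> tuple[float, list[float]]:
    """Median percent-correct across independently seeded sessions.

    ``spec_overrides`` set the :class:`SyntheticSpec` fields shared by all
    sessions (each session differs only in its seed).
    """
    config = config or FitConfig(n_factors=5)
    accs = [
        session_accuracy(SyntheticSpec(seed=int(s), **spec_overrides), config)
        for s in seeds
    ]
    return float(np.median(accs)), accs
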