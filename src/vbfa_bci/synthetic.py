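"""Seeded synthetic two-class MEG session generator.

Sessions are drawn from the same linear-Gaussian model the classifier
assumes: per class, y = A x + v with i.i.d. standard-normal factors and
i.i.d. diagonal Gaussian sensor noise.  The two classes share the noise
level and differ only in their mixing matrices; the difference is a
rotation of the left-class factor subspace toward an orthogonal
complement, controlled by a single ``separation`` parameter (0 = the two
classes are identical, 1 = orthogonal class subspaces).  This mirrors the
physiology being emulated: left and right neuromotor activity differ in
spatial pattern across the sensor array, which is exactly a
mixing-matrix change.

Defaults match one recording session of the motor task: a 274-channel
sensor array sampled at 1200 Hz, 601 samples per trial, 80 trials
alternating left/right (10 per class for training plus 60 for testing).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import LEFT, RIGHT
from .epoching import TrialEpoch
from .model import FactorModel


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth parameters for a simulated two-class session.

    ``separation`` rotates each right-class mixing column by
    ``separation * 90`` degrees out of the left-class subspace.
    ``noise_variance`` is the per-channel sensor noise variance; with
    unit-norm mixing columns the mean per-channel signal variance is
    L/K, so SNR = n_factors_true / (n_channels * noise_variance).  The
    default noise variance puts the session at SNR ~ 10, a strongly
    evoked regime.
    """

    n_channels: int = 274
    samples_per_trial: int = 601
    n_factors_true: int = 10
    n_trials_per_class: int = 40
    separation: float = 0.9
    noise_variance: float = 10 / (274 * 10)  # SNR ~ 10
    seed: int = 0
    sample_rate: float = 1200.0

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.samples_per_trial < 1:
            raise ValueError("n_channels and samples_per_trial must be >= 1")
        if not 1 <= self.n_factors_true <= self.n_channels:
            raise ValueError("n_factors_true must lie in [1, n_channels]")
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if self.noise_variance <= 0:
            raise ValueError("noise_variance must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def snr(self) -> float:
        return self.n_factors_true / (self.n_channels * self.noise_variance)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        return cls(**d)


def make_class_models(spec: SyntheticSpec) -> tuple[FactorModel, FactorModel]:
    """Draw the left/right ground-truth models for a session.

    The left mixing matrix has unit-norm standard-normal columns.  Each
    right-class column is ``cos(theta) b_j + sin(theta) d_j`` where the
    ``d_j`` are unit vectors orthogonal to the whole left subspace and
    ``theta = min(separation, 1) * 90 degrees``, so the right columns stay
    unit-norm and ``separation = 0`` reproduces the left matrix exactly.
    Requires ``2 * n_factors_true <= n_channels`` when ``separation > 0``.
    """
    K, L = spec.n_channels, spec.n_factors_true
    rng = np.random.default_rng(spec.seed)

    B = rng.standard_normal((K, L))
    B /= np.linalg.norm(B, axis=0, keepdims=True)

    if spec.separation > 0 and 2 * L > K:
        raise ValueError(
            "separation > 0 needs an orthogonal complement: require "
            f"2 * n_factors_true <= n_channels, got L={L}, K={K}"
        )
    D = rng.standard_normal((K, L))
    Q, _ = np.linalg.qr(B)
    D -= Q @ (Q.T @ D)
    D /= np.linalg.norm(D, axis=0, keepdims=True)

    theta = min(spec.separation, 1.0) * np.pi / 2.0
    A_right = np.cos(theta) * B + np.sin(theta) * D

    lam = np.full(K, 1.0 / spec.noise_variance)
    alpha = np.ones(L)
    left = FactorModel(A=B, lambda_prec=lam.copy(), alpha_prec=alpha.copy())
    right = FactorModel(A=A_right, lambda_prec=lam.copy(), alpha_prec=alpha.copy())
    return left, right


def sample_session(spec: SyntheticSpec) -> list[TrialEpoch]:
    """Forward-sample a labeled session from the two class models.

    Trials alternate L, R, L, R, ... with sequential trial ids.  For each
    sample, x ~ N(0, I) and v ~ N(0, noise_variance * I); the emitted
    column is ``y = A_class x + v``.  Deterministic per seed (a single
    generator seeded from ``spec.seed`` drives model creation and
    sampling).
    """
    left, right = make_class_models(spec)
    # Continue the stream from a generator offset past the model draw so
    # the trial noise is independent of the mixing matrices.
    rng = np.random.default_rng((spec.seed, 1))
    K, S, L = spec.n_channels, spec.samples_per_trial, spec.n_factors_true
    sd = np.sqrt(spec.noise_variance)

    epochs = []
    for t in range(2 * spec.n_trials_per_class):
        label = LEFT if t % 2 == 0 else RIGHT
        A = left.A if label == LEFT else right.A
        x = rng.standard_normal((L, S))
        v = rng.standard_normal((K, S)) * sd
        epochs.append(
            TrialEpoch(signal=A @ x + v, label=label, trial_id=t, sample_rate=spec.sample_rate)
        )
    return epochs


def save_spec(spec: SyntheticSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(spec.to_dict(), indent=2) + "\n")


def load_spec(path: str | Path) -> SyntheticSpec:
    return SyntheticSpec.from_dict(json.loads(Path(path).read_text()))
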