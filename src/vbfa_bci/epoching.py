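"""Trial-epoch handling: demeaning, training-matrix assembly, session I/O.

A session is an ordered list of trials, each a channels x samples matrix
optionally tagged with the class the subject intended ("L" or "R", read
from the trigger channel at acquisition time).  Training matrices are
built by removing each trial's per-channel mean and concatenating the
trials of one class along the sample axis, one row per channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .config import LEFT, RIGHT

_LABELS = (LEFT, RIGHT)


@dataclass
class TrialEpoch:
    """One trial: a channels x samples signal with optional class label."""

    signal: np.ndarray
    label: str | None = None
    trial_id: int = 0
    sample_rate: float = 1200.0

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.signal.size == 0:
            raise ValueError("epoch signal is empty")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("epoch signal contains non-finite values")
        if self.label is not None and self.label not in _LABELS:
            raise ValueError(f"label must be one of {_LABELS} or None, got {self.label!r}")
        if self.trial_id < 0:
            raise ValueError("trial_id must be >= 0")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class TrainingMatrix:
    """Mean-removed concatenation of one class's training trials."""

    data: np.ndarray
    n_trials: int
    samples_per_trial: int
    class_label: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[1] != self.n_trials * self.samples_per_trial:
            raise ValueError(
                f"training matrix has {self.data.shape[1]} columns, expected "
                f"{self.n_trials} x {self.samples_per_trial}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


def demean_trial(epoch: TrialEpoch) -> TrialEpoch:
    """Remove each channel's mean within the trial.

    Per-channel (not scalar) removal: MEG channel baselines differ by
    orders of magnitude, and only per-channel removal makes rows of the
    training matrix comparable.  If every channel mean is already exactly
    zero the signal is returned unchanged, making repeated application a
    no-op on already-centred data.
    """
    mean = epoch.signal.mean(axis=1, keepdims=True)
    if not mean.any():
        return replace(epoch, signal=epoch.signal.copy())
    return replace(epoch, signal=epoch.signal - mean)


def _ordered_class_epochs(epochs: list[TrialEpoch], class_label: str) -> list[TrialEpoch]:
    selected = [e for e in epochs if e.label == class_label]
    ids = [e.trial_id for e in selected]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate trial_id among class {class_label!r} trials")
    return sorted(selected, key=lambda e: e.trial_id)


def build_training_matrix(
    epochs: list[TrialEpoch], class_label: str, n_train: int
) -> TrainingMatrix:
    """Demean and concatenate the first ``n_train`` trials of one class.

    Trials are taken in ascending ``trial_id`` order.  For the standard
    session geometry (10 trials of 274 channels x 601 samples) the result
    is a 274 x 6010 matrix.
    """
    if class_label not in _LABELS:
        raise ValueError(f"class_label must be one of {_LABELS}")
    selected = _ordered_class_epochs(epochs, class_label)
    if len(selected) < n_train:
        raise ValueError(
            f"insufficient trials: need {n_train} of class {class_label!r}, "
            f"found {len(selected)}"
        )
    selected = selected[:n_train]
    shapes = {e.signal.shape for e in selected}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent trial shapes: {sorted(shapes)}")
    (K, S), = shapes
    data = np.hstack([demean_trial(e).signal for e in selected])
    return TrainingMatrix(data=data, n_trials=n_train, samples_per_trial=S, class_label=class_label)


def split_session(
    epochs: list[TrialEpoch], n_train: int
) -> tuple[list[TrialEpoch], list[TrialEpoch], list[TrialEpoch]]:
    """Split a labeled session into per-class training trials and test trials.

    The first ``n_train`` trials of each class (ascending ``trial_id``) go
    to training; every subsequent labeled trial is returned, in order, for
    testing.  No trial appears twice.
    """
    left = _ordered_class_epochs(epochs, LEFT)
    right = _ordered_class_epochs(epochs, RIGHT)
    if len(left) < n_train or len(right) < n_train:
        raise ValueError(
            f"insufficient trials: need {n_train} per class, found "
            f"{len(left)} left / {len(right)} right"
        )
    train_left, train_right = left[:n_train], right[:n_train]
    train_ids = {e.trial_id for e in train_left} | {e.trial_id for e in train_right}
    test = sorted(
        (e for e in epochs if e.label is not None and e.trial_id not in train_ids),
        key=lambda e: e.trial_id,
    )
    return train_left, train_right, test


# ---------------------------------------------------------------------------
# session container I/O
# ---------------------------------------------------------------------------
# A session directory holds a JSON manifest plus one block per trial:
# either raw little-endian float64 row-major binary (.bin) or, for small
# text fixtures, CSV with one row per channel (.csv).

def save_session(
    epochs: list[TrialEpoch],
    path: str | Path,
    fmt: str = "bin",
    extra_meta: dict | None = None,
) -> Path:
    if fmt not in ("bin", "csv"):
        raise ValueError("fmt must be 'bin' or 'csv'")
    if not epochs:
        raise ValueError("cannot save an empty session")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    trials = []
    for e in epochs:
        fname = f"trial_{e.trial_id:05d}.{fmt}"
        if fmt == "bin":
            np.ascontiguousarray(e.signal, dtype="<f8").tofile(path / fname)
        else:
            np.savetxt(path / fname, e.signal, delimiter=",")
        trials.append(
            {
                "trial_id": e.trial_id,
                "label": e.label,
                "file": fname,
                "n_samples": e.n_samples,
            }
        )
    manifest = {
        "format": "vbfa-session",
        "version": 1,
        "n_channels": epochs[0].n_channels,
        "sample_rate": epochs[0].sample_rate,
        "trials": trials,
    }
    if extra_meta:
        manifest.update(extra_meta)
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def load_session(path: str | Path) -> list[TrialEpoch]:
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise ValueError(f"no session manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("format") != "vbfa-session":
        raise ValueError(f"{path} is not a vbfa session directory")
    K = int(manifest["n_channels"])
    rate = float(manifest["sample_rate"])
    epochs = []
    for t in manifest["trials"]:
        fpath = path / t["file"]
        if fpath.suffix == ".csv":
            signal = np.loadtxt(fpath, delimiter=",", ndmin=2)
        else:
            signal = np.fromfile(fpath, dtype="<f8").reshape(K, int(t["n_samples"]))
        epochs.append(
            TrialEpoch(
                signal=signal,
                label=t.get("label"),
                trial_id=int(t["trial_id"]),
                sample_rate=rate,
            )
        )
    return epochs
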