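"""Two-model likelihood classifier, performance scoring and command encoding.

One VBFA model is fitted per class (left / right).  An unknown trial is
scored under both models with the exact marginal likelihood; the larger
likelihood gives the predicted response.  Predictions against the trigger
labels yield a percent-correct score, and the predicted labels stream out
as single-character pipe commands terminated by a null byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import LEFT, RIGHT, TIE, FitConfig
from .epoching import TrainingMatrix, TrialEpoch
from .model import FactorModel, fit, log_likelihood


@dataclass
class ClassifierPair:
    """Left- and right-class factor models plus the tie policy."""

    model_left: FactorModel
    model_right: FactorModel
    tie_policy: str = "abstain"

    def __post_init__(self) -> None:
        if self.model_left.n_channels != self.model_right.n_channels:
            raise ValueError(
                "left and right models disagree on channel count: "
                f"{self.model_left.n_channels} vs {self.model_right.n_channels}"
            )
        if self.tie_policy not in ("abstain", "emit_left", "emit_right"):
            raise ValueError(f"unknown tie_policy {self.tie_policy!r}")


@dataclass
class PredictionRecord:
    """Outcome of classifying one trial.

    ``predicted`` is "L" iff ll_left > ll_right, "R" iff ll_right >
    ll_left; exact ties are resolved by the pair's tie policy and flagged.
    """

    trial_id: int
    ll_left: float
    ll_right: float
    predicted: str
    actual: str | None = None
    correct: bool | None = None
    tie: bool = False


def train_pair(
    train_left: TrainingMatrix,
    train_right: TrainingMatrix,
    n_factors: int | None = None,
    config: FitConfig | None = None,
) -> ClassifierPair:
    """Fit the two class models independently on their training matrices."""
    if train_left.n_channels != train_right.n_channels:
        raise ValueError("training matrices disagree on channel count")
    config = config or FitConfig()
    return ClassifierPair(
        model_left=fit(train_left, n_factors, config),
        model_right=fit(train_right, n_factors, config),
        tie_policy=config.tie_policy,
    )


def classify_trial(epoch: TrialEpoch, pair: ClassifierPair) -> PredictionRecord:
    """Score one (already demeaned) trial under both models.

    The marginal log likelihood of the whole trial (sum over its samples)
    is computed under each class model; the larger one wins.
    """
    ll_left = log_likelihood(epoch, pair.model_left)
    ll_right = log_likelihood(epoch, pair.model_right)
    tie = ll_left == ll_right
    if tie:
        predicted = {"abstain": TIE, "emit_left": LEFT, "emit_right": RIGHT}[pair.tie_policy]
    else:
        predicted = LEFT if ll_left > ll_right else RIGHT
    actual = epoch.label
    correct = (predicted == actual) if actual is not None else None
    return PredictionRecord(
        trial_id=epoch.trial_id,
        ll_left=ll_left,
        ll_right=ll_right,
        predicted=predicted,
        actual=actual,
        correct=correct,
        tie=tie,
    )


def classify_session(
    epochs: list[TrialEpoch], pair: ClassifierPair, demean: bool = True
) -> list[PredictionRecord]:
    """Classify an ordered stream of trials, demeaning each like training data."""
    from .epoching import demean_trial

    records = []
    for e in epochs:
        records.append(classify_trial(demean_trial(e) if demean else e, pair))
    return records


def compute_performance(records: list[PredictionRecord]) -> float:
    """Percent of trials whose prediction matches the trigger label.

    Abstained ties carry no label and therefore count as incorrect.
    """
    if not records:
        raise ValueError("cannot score an empty record list")
    if any(r.actual is None for r in records):
        raise ValueError("every record needs an actual label to compute performance")
    n_correct = sum(r.predicted == r.actual for r in records)
    return 100.0 * n_correct / len(records)


def summarize(records: list[PredictionRecord], config: FitConfig | None = None) -> dict:
    """Summary statistics; per-class accuracies are reported because the
    test trials are not guaranteed to be class-balanced."""
    labeled = [r for r in records if r.actual is not None]
    summary: dict = {
        "n_trials": len(records),
        "n_ties": sum(r.tie for r in records),
        "tie_policy": None,
    }
    if config is not None:
        summary["tie_policy"] = config.tie_policy
        summary["config"] = config.to_dict()
    if labeled and len(labeled) == len(records):
        summary["accuracy_percent"] = compute_performance(records)
        for cls, key in ((LEFT, "accuracy_left_percent"), (RIGHT, "accuracy_right_percent")):
            cls_records = [r for r in labeled if r.actual == cls]
            if cls_records:
                summary[key] = compute_performance(cls_records)
    return summary


def encode_commands(predictions: list[str]) -> bytes:
    """Encode predicted labels as the single-character pipe protocol.

    One ASCII byte per prediction ('L' = 0x4C, 'R' = 0x52), terminated by
    a single null byte which tells the receiving program that the BCI is
    finished sending commands.
    """
    out = bytearray()
    for p in predictions:
        if p not in (LEFT, RIGHT):
            raise ValueError(f"cannot encode label {p!r}; only 'L' and 'R' are commands")
        out.append(ord(p))
    out.append(0)
    return bytes(out)


# ---------------------------------------------------------------------------
# result files
# ---------------------------------------------------------------------------

def write_results(records: list[PredictionRecord], csv_path: str | Path) -> None:
    """Write one CSV row per prediction (empty actual/correct when unlabeled)."""
    df = pd.DataFrame(
        {
            "trial_id": [r.trial_id for r in records],
            "ll_left": [r.ll_left for r in records],
            "ll_right": [r.ll_right for r in records],
            "predicted": [r.predicted for r in records],
            "actual": [r.actual if r.actual is not None else "" for r in records],
            "correct": ["" if r.correct is None else r.correct for r in records],
        }
    )
    df.to_csv(csv_path, index=False)


def write_summary(summary: dict, json_path: str | Path) -> None:
    Path(json_path).write_text(json.dumps(summary, indent=2) + "\n")
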