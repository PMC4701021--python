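"""Fit and pipeline configuration.

A single flat configuration object drives model fitting and the
train/test protocol.  Values can be loaded from a YAML or JSON document;
explicit keyword overrides (e.g. command-line flags) win over file values.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

#: Class tags used throughout the package.
LEFT = "L"
RIGHT = "R"
TIE = "tie"

_TIE_POLICIES = ("abstain", "emit_left", "emit_right")
_INIT_MODES = ("svd", "random")
_NOISE_DENOMS = ("n", "n_plus_l")


@dataclass(frozen=True)
class FitConfig:
    """Configuration for VBFA fitting and the session protocol.

    Parameters
    ----------
    n_factors
        Number of latent factors L fitted per class model.
    tol
        Relative free-energy change below which EM is declared converged.
    max_iter
        Maximum number of EM sweeps.
    seed
        Seed for any randomized choices (random initialization mode).
    precision_floor
        Relative floor for updated precisions: noise variances are floored
        at ``precision_floor`` times the mean per-channel data variance, so
        precisions stay finite when a channel is explained exactly.
    alpha_cap
        Upper bound on ARD precisions; a pruned factor's alpha saturates
        here instead of overflowing.
    init
        ``"svd"`` (deterministic, scale-aware; default) or ``"random"``.
    noise_denominator
        ``"n"`` uses the maximum-likelihood noise update 1/N;
        ``"n_plus_l"`` uses 1/(N+L), the exact coordinate-ascent update for
        the free energy when the mixing-matrix prior precision scales with
        the noise precision.  Default ``"n_plus_l"`` because it preserves
        free-energy monotonicity exactly; the two coincide as N >> L.
    tie_policy
        What a classifier emits on an exact likelihood tie.
    n_train_trials
        Trials per class concatenated into each training matrix.
    n_test_trials
        Number of subsequent trials scored per session.
    """

    n_factors: int = 10
    tol: float = 1e-6
    max_iter: int = 200
    seed: int = 0
    precision_floor: float = 1e-10
    alpha_cap: float = 1e12
    init: str = "svd"
    noise_denominator: str = "n_plus_l"
    tie_policy: str = "abstain"
    n_train_trials: int = 10
    n_test_trials: int = 60

    def __post_init__(self) -> None:
        if self.n_factors < 1:
            raise ValueError("n_factors must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0 < self.precision_floor < 1:
            raise ValueError("precision_floor must lie in (0, 1)")
        if self.alpha_cap <= 0:
            raise ValueError("alpha_cap must be positive")
        if self.init not in _INIT_MODES:
            raise ValueError(f"init must be one of {_INIT_MODES}")
        if self.noise_denominator not in _NOISE_DENOMS:
            raise ValueError(f"noise_denominator must be one of {_NOISE_DENOMS}")
        if self.tie_policy not in _TIE_POLICIES:
            raise ValueError(f"tie_policy must be one of {_TIE_POLICIES}")
        if self.n_train_trials < 1:
            raise ValueError("n_train_trials must be >= 1")
        if self.n_test_trials < 0:
            raise ValueError("n_test_trials must be >= 0")

    def replace(self, **kwargs) -> "FitConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> FitConfig:
    """Build a :class:`FitConfig` from an optional YAML/JSON file plus overrides.

    Overrides whose value is ``None`` are ignored, so unset command-line
    flags fall through to the file value or the default.
    """
    values: dict = {}
    if path is not None:
        text = Path(path).read_text()
        doc = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
        if doc is None:
            doc = {}
        if not isinstance(doc, dict):
            raise ValueError(f"config file {path} must contain a flat mapping")
        unknown = set(doc) - {f.name for f in dataclasses.fields(FitConfig)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(doc)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return FitConfig(**values)
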