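"""Variational Bayesian factor analysis (VBFA) for multichannel epochs.

The generative model ties K recorded channels to L latent factors:

    y_n = A x_n + v_n,   x_n ~ N(0, I_L),   v_n ~ N(0, diag(lambda)^-1)

where ``A`` is the K x L evoked mixing matrix, ``lambda`` the diagonal
noise precision, and each mixing column carries an automatic-relevance-
determination (ARD) prior A_ij ~ N(0, (lambda_i * alpha_j)^-1) whose
precision ``alpha_j`` shrinks unneeded columns toward zero.

Fitting alternates an exact E-step over the factors (posterior mean
``x_bar`` and shared precision ``Gamma = A' diag(lambda) A + I``) with
M-step updates of ``A``, ``lambda`` and ``alpha`` from the accumulated
sufficient statistics, and is monitored by a variational free energy that
is non-decreasing across sweeps.  Trial scoring uses the exact marginal
likelihood of the data under the fitted model, whose covariance is the
low-rank-plus-diagonal matrix ``A A' + diag(lambda)^-1``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .config import FitConfig

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FitInfo:
    """Metadata recorded by :func:`fit`."""

    n_iter: int = 0
    converged: bool = False
    free_energy: float = float("nan")
    free_energy_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    seed: int = 0
    init: str = "svd"

    def to_dict(self) -> dict:
        return {
            "n_iter": self.n_iter,
            "converged": self.converged,
            "free_energy": self.free_energy,
            "free_energy_trace": [float(v) for v in np.asarray(self.free_energy_trace)],
            "seed": self.seed,
            "init": self.init,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitInfo":
        return cls(
            n_iter=int(d["n_iter"]),
            converged=bool(d["converged"]),
            free_energy=float(d["free_energy"]),
            free_energy_trace=np.asarray(d["free_energy_trace"], dtype=float),
            seed=int(d["seed"]),
            init=str(d.get("init", "svd")),
        )


@dataclass
class FactorModel:
    """A (fitted or ground-truth) factor-analysis model.

    Attributes
    ----------
    A
        Mixing matrix, shape ``(n_channels, n_factors)``.
    lambda_prec
        Diagonal noise precisions, shape ``(n_channels,)``; all positive.
    alpha_prec
        ARD precisions per factor column, shape ``(n_factors,)``; positive.
    fit_info
        Populated by :func:`fit`; ``None`` for hand-built models.
    """

    A: np.ndarray
    lambda_prec: np.ndarray
    alpha_prec: np.ndarray
    fit_info: FitInfo | None = None

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.lambda_prec = np.asarray(self.lambda_prec, dtype=float).ravel()
        self.alpha_prec = np.asarray(self.alpha_prec, dtype=float).ravel()
        self.validate()

    @property
    def n_channels(self) -> int:
        return self.A.shape[0]

    @property
    def n_factors(self) -> int:
        return self.A.shape[1]

    def validate(self) -> None:
        K, L = self.A.shape
        if K < 1 or L < 1:
            raise ValueError("model must have >= 1 channel and >= 1 factor")
        if self.lambda_prec.shape != (K,):
            raise ValueError(
                f"lambda_prec has shape {self.lambda_prec.shape}, expected ({K},)"
            )
        if self.alpha_prec.shape != (L,):
            raise ValueError(
                f"alpha_prec has shape {self.alpha_prec.shape}, expected ({L},)"
            )
        if not np.all(np.isfinite(self.A)):
            raise ValueError("mixing matrix contains non-finite entries")
        if not (np.all(self.lambda_prec > 0) and np.all(np.isfinite(self.lambda_prec))):
            raise ValueError("noise precisions must be strictly positive and finite")
        if not (np.all(self.alpha_prec > 0) and np.all(np.isfinite(self.alpha_prec))):
            raise ValueError("ARD precisions must be strictly positive and finite")


@dataclass
class PosteriorStats:
    """E-step outputs: factor posteriors and accumulated sufficient statistics.

    ``gamma_prec`` is shared across samples because the factor posterior
    precision does not depend on the data.  ``R_yy`` stores only the
    diagonal of the data-data correlation (a length-K vector), which is all
    the diagonal-noise updates require.
    """

    x_mean: np.ndarray        # (L, N) posterior factor means
    gamma_prec: np.ndarray    # (L, L) shared posterior precision
    gamma_cov: np.ndarray     # (L, L) its inverse
    R_yx: np.ndarray          # (K, L) sum_n y_n x_bar_n'
    R_xx: np.ndarray          # (L, L) sum_n x_bar_n x_bar_n' + N * gamma_cov
    R_yy: np.ndarray          # (K,)   diag of sum_n y_n y_n'
    n_samples: int


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _as_matrix(data) -> np.ndarray:
    """Accept a TrainingMatrix-like object (with ``.data``) or a 2-D array."""
    arr = getattr(data, "data", data)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D channels x samples array, got ndim={arr.ndim}")
    return arr


def _check_data(Y: np.ndarray, model: FactorModel) -> None:
    if Y.shape[0] != model.n_channels:
        raise ValueError(
            f"data has {Y.shape[0]} channels but model expects {model.n_channels}"
        )
    if not np.all(np.isfinite(Y)):
        raise ValueError("data contains non-finite values")


def _gamma_cholesky(model: FactorModel):
    """Cholesky factor of Gamma = A' diag(lambda) A + I (always SPD)."""
    AtL = model.A.T * model.lambda_prec  # (L, K) = A' diag(lambda)
    gamma = AtL @ model.A
    gamma += np.eye(model.n_factors)
    gamma = 0.5 * (gamma + gamma.T)
    return gamma, cho_factor(gamma, lower=True), AtL


# ---------------------------------------------------------------------------
# EM steps
# ---------------------------------------------------------------------------

def e_step(data, model: FactorModel) -> PosteriorStats:
    """Posterior over the factors plus accumulated sufficient statistics.

    The posterior of each ``x_n`` is Gaussian with shared precision
    ``Gamma = A' diag(lambda) A + I`` and mean
    ``x_bar_n = Gamma^-1 A' diag(lambda) y_n``.  Means are obtained with a
    Cholesky solve; ``Gamma`` is never inverted on the mean path.
    """
    Y = _as_matrix(data)
    _check_data(Y, model)
    N = Y.shape[1]

    gamma, cho, AtL = _gamma_cholesky(model)
    x_mean = cho_solve(cho, AtL @ Y)
    gamma_cov = cho_solve(cho, np.eye(model.n_factors))
    gamma_cov = 0.5 * (gamma_cov + gamma_cov.T)

    R_yx = Y @ x_mean.T
    R_xx = x_mean @ x_mean.T + N * gamma_cov
    R_xx = 0.5 * (R_xx + R_xx.T)
    R_yy = np.einsum("kn,kn->k", Y, Y)

    return PosteriorStats(
        x_mean=x_mean,
        gamma_prec=gamma,
        gamma_cov=gamma_cov,
        R_yx=R_yx,
        R_xx=R_xx,
        R_yy=R_yy,
        n_samples=N,
    )


def m_step(stats: PosteriorStats, model: FactorModel, config: FitConfig) -> FactorModel:
    """Update ``A``, ``lambda`` and ``alpha`` from the sufficient statistics.

    With ``psi = R_xx + diag(alpha)``:

    * ``A_new = R_yx psi^-1`` (regularized least squares on the factors);
    * noise variances ``lambda^-1 = diag(R_yy - A_new R_yx') / denom`` where
      ``denom`` is N or N+L per ``config.noise_denominator``, floored at
      ``config.precision_floor`` times the mean data variance;
    * ``alpha_j^-1 = (1/K) [A_new' diag(lambda) A_new]_jj + [psi^-1]_jj``,
      capped at ``config.alpha_cap``.
    """
    N = stats.n_samples
    if N == 0:
        raise ValueError("cannot run an M-step on zero samples")
    K, L = model.A.shape

    psi = stats.R_xx + np.diag(model.alpha_prec)
    psi = 0.5 * (psi + psi.T)
    try:
        psi_cho = cho_factor(psi, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate stats
        raise np.linalg.LinAlgError(
            "psi = R_xx + diag(alpha) is not positive definite; the posterior "
            "statistics are degenerate (e.g. all-zero factors). "
            f"diag(psi)={np.diag(psi)}"
        ) from exc

    A_new = cho_solve(psi_cho, stats.R_yx.T).T
    psi_inv = cho_solve(psi_cho, np.eye(L))

    # Residual power per channel; at A_new = R_yx psi^-1 the cross term
    # already accounts for the explained power plus the prior quadratic.
    resid = stats.R_yy - np.einsum("kl,kl->k", A_new, stats.R_yx)
    denom = N + L if config.noise_denominator == "n_plus_l" else N
    mean_var = float(np.sum(stats.R_yy)) / (N * K)
    var_floor = config.precision_floor * mean_var
    if var_floor <= 0:  # all-zero data: fall back to an absolute floor
        var_floor = config.precision_floor
    noise_var = resid / denom
    n_floored = int(np.sum(noise_var < var_floor))
    if n_floored:
        logger.warning("noise variance floored on %d of %d channels", n_floored, K)
        noise_var = np.maximum(noise_var, var_floor)
    lambda_new = 1.0 / noise_var

    alpha_inv = np.einsum("kj,kj,k->j", A_new, A_new, lambda_new) / K + np.diag(psi_inv)
    alpha_new = 1.0 / alpha_inv
    n_capped = int(np.sum(alpha_new > config.alpha_cap))
    if n_capped:
        logger.warning("ARD precision capped on %d of %d factors", n_capped, L)
        alpha_new = np.minimum(alpha_new, config.alpha_cap)

    return FactorModel(
        A=A_new, lambda_prec=lambda_new, alpha_prec=alpha_new, fit_info=model.fit_info
    )


def free_energy(data, model: FactorModel, stats: PosteriorStats) -> float:
    """Variational free energy of (model, factor posterior) on the data.

    The objective combines the expected complete-data log likelihood, the
    factor prior, the ARD prior on the mixing matrix (precision
    ``lambda_i alpha_j`` per entry) and the entropy of the factor
    posterior:

        F = (N+L)/2 log|lambda| - 1/2 sum_i lambda_i E[residual power]_i
            - 1/2 Tr(R_xx) - N/2 log|Gamma| + NL/2
            + K/2 log|alpha| - 1/2 Tr(A' diag(lambda) A diag(alpha))

    Additive constants in 2*pi are dropped, so F is 0 for all-zero data
    with A = 0, lambda = alpha = I.  Coordinate updates of the posterior
    and of A maximize F exactly; F is non-decreasing across EM sweeps.
    """
    Y = _as_matrix(data)
    _check_data(Y, model)
    N = stats.n_samples
    K, L = model.A.shape
    lam = model.lambda_prec
    A = model.A

    AR = A @ stats.R_xx  # (K, L)
    expected_resid = (
        stats.R_yy
        - 2.0 * np.einsum("kl,kl->k", A, stats.R_yx)
        + np.einsum("kl,kl->k", AR, A)
    )
    sign, logdet_gamma = np.linalg.slogdet(stats.gamma_prec)
    if sign <= 0:
        raise np.linalg.LinAlgError("Gamma is not positive definite")
    ata = np.einsum("kj,kj,k->j", A, A, lam)  # diag of A' diag(lambda) A

    return float(
        0.5 * (N + L) * np.sum(np.log(lam))
        - 0.5 * lam @ expected_resid
        - 0.5 * np.trace(stats.R_xx)
        - 0.5 * N * logdet_gamma
        + 0.5 * N * L
        + 0.5 * K * np.sum(np.log(model.alpha_prec))
        - 0.5 * ata @ model.alpha_prec
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _initial_model(Y: np.ndarray, n_factors: int, config: FitConfig) -> FactorModel:
    """Deterministic scale-aware start (or a seeded random one).

    SVD mode projects the data onto its top-L left singular vectors scaled
    by singular value / sqrt(N); noise variances start at the per-channel
    residual variance.
    """
    K, N = Y.shape
    channel_var = np.einsum("kn,kn->k", Y, Y) / N
    mean_var = float(np.mean(channel_var))
    var_floor = config.precision_floor * mean_var if mean_var > 0 else config.precision_floor

    if config.init == "svd":
        U, s, _ = np.linalg.svd(Y, full_matrices=False)
        U = U[:, :n_factors]
        # fix the SVD sign ambiguity by the largest-magnitude channel entry,
        # keeping the start equivariant under channel permutations
        idx = np.argmax(np.abs(U), axis=0)
        signs = np.sign(U[idx, np.arange(n_factors)])
        signs[signs == 0] = 1.0
        A0 = (U * signs) * (s[:n_factors] / np.sqrt(N))
    else:
        rng = np.random.default_rng(config.seed)
        scale = np.sqrt(max(mean_var, var_floor) / n_factors)
        A0 = rng.standard_normal((K, n_factors)) * scale

    resid_var = np.maximum(channel_var - np.einsum("kl,kl->k", A0, A0), var_floor)
    return FactorModel(
        A=A0,
        lambda_prec=1.0 / resid_var,
        alpha_prec=np.ones(n_factors),
        fit_info=FitInfo(seed=config.seed, init=config.init),
    )


def fit(data, n_factors: int | None = None, config: FitConfig | None = None) -> FactorModel:
    """Fit a VBFA model by alternating E- and M-steps until the free energy
    stalls (relative change below ``config.tol``) or ``config.max_iter``.

    Deterministic for a fixed configuration and input.
    """
    if config is None:
        config = FitConfig() if n_factors is None else FitConfig(n_factors=n_factors)
    L = n_factors if n_factors is not None else config.n_factors
    Y = _as_matrix(data)
    if not np.all(np.isfinite(Y)):
        raise ValueError("data contains non-finite values")
    K, N = Y.shape
    if not 1 <= L <= min(K, N):
        raise ValueError(f"n_factors={L} must lie in [1, min(K={K}, N={N})]")

    model = _initial_model(Y, L, config)
    trace: list[float] = []
    converged = False
    for it in range(config.max_iter):
        stats = e_step(Y, model)
        model = m_step(stats, model, config)
        F = free_energy(Y, model, stats)
        trace.append(F)
        logger.info("iter %3d  free_energy=%.6f", it + 1, F)
        if it > 0 and abs(F - trace[-2]) < config.tol * abs(F):
            converged = True
            break

    model.fit_info = FitInfo(
        n_iter=len(trace),
        converged=converged,
        free_energy=trace[-1],
        free_energy_trace=np.asarray(trace),
        seed=config.seed,
        init=config.init,
    )
    return model


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------

def log_likelihood(epoch, model: FactorModel) -> float:
    """Exact marginal log likelihood of an epoch under the model.

    With the factors integrated out, samples are i.i.d. zero-mean Gaussian
    with covariance ``Sigma = A A' + diag(lambda)^-1``.  The quadratic form
    and log determinant are evaluated through the L x L matrix
    ``Gamma = A' diag(lambda) A + I`` (matrix-inversion identity), so the
    cost is linear in the channel count:

        Sigma^-1 = diag(lambda) - diag(lambda) A Gamma^-1 A' diag(lambda)
        log|Sigma| = log|Gamma| - sum_i log(lambda_i)
    """
    Y = _as_matrix(getattr(epoch, "signal", epoch))
    _check_data(Y, model)
    K, N = Y.shape

    gamma, cho, AtL = _gamma_cholesky(model)
    logdet_gamma = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    logdet_sigma = logdet_gamma - float(np.sum(np.log(model.lambda_prec)))

    z = AtL @ Y                      # (L, N)
    w = cho_solve(cho, z)
    quad = float(np.einsum("kn,kn,k->", Y, Y, model.lambda_prec) - np.einsum("ln,ln->", z, w))
    return -0.5 * (N * K * _LOG_2PI + N * logdet_sigma + quad)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_ARRAY_FILES = {"A": "A.bin", "lambda_prec": "lambda_prec.bin", "alpha_prec": "alpha_prec.bin"}


def save_model(model: FactorModel, path: str | Path, config: FitConfig | None = None) -> Path:
    """Serialize a model to a directory: JSON metadata plus raw little-endian
    float64 row-major blocks for each array.  Round-trips bit-exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": "vbfa-model",
        "version": 1,
        "n_channels": model.n_channels,
        "n_factors": model.n_factors,
        "arrays": _ARRAY_FILES,
        "fit_info": model.fit_info.to_dict() if model.fit_info else None,
        "config": config.to_dict() if config else None,
    }
    for name, fname in _ARRAY_FILES.items():
        arr = np.ascontiguousarray(getattr(model, name), dtype="<f8")
        arr.tofile(path / fname)
    (path / "model.json").write_text(json.dumps(meta, indent=2) + "\n")
    return path


def load_model(path: str | Path) -> FactorModel:
    """Load a model saved by :func:`save_model`."""
    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    if meta.get("format") != "vbfa-model":
        raise ValueError(f"{path} does not contain a vbfa model")
    K, L = int(meta["n_channels"]), int(meta["n_factors"])
    arrays = {}
    for name, fname in meta["arrays"].items():
        arrays[name] = np.fromfile(path / fname, dtype="<f8")
    fit_info = FitInfo.from_dict(meta["fit_info"]) if meta.get("fit_info") else None
    return FactorModel(
        A=arrays["A"].reshape(K, L),
        lambda_prec=arrays["lambda_prec"],
        alpha_prec=arrays["alpha_prec"],
        fit_info=fit_info,
    )
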