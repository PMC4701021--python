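# Methods

## Generative model

Each trial is a K × S matrix of MEG samples. Within the post-stimulus
window samples are treated as i.i.d. draws from a linear-Gaussian factor
model per class c ∈ {left, right}:

```
y_n = A_c x_n + v_n,   x_n ~ N(0, I_L),   v_n ~ N(0, diag(λ)⁻¹)
```

The factors are zero-mean with unit precision; the sensor noise is
zero-mean Gaussian with diagonal precision λ (one precision per channel).
Each entry of the mixing matrix carries an ARD prior
`A_ij ~ N(0, (λ_i α_j)⁻¹)`: a per-column precision α_j that grows without
bound when column j explains nothing, shrinking that column toward zero.
Scaling the prior by the channel noise precision λ_i makes the prior
scale-free with respect to per-channel units and, together with the
regularized least-squares form of the A-update, gives the noise update
its simple residual form (below).

## Inference

**E-step.** Conditioned on the current parameters the factor posterior is
Gaussian with a *shared* precision (it does not depend on the data):

```
Γ = Aᵀ diag(λ) A + I          x̄_n = Γ⁻¹ Aᵀ diag(λ) y_n
```

All solves use a Cholesky factorization of Γ; Γ is never inverted on the
mean path. The E-step accumulates `R_yx = Σ y_n x̄_nᵀ`,
`R_xx = Σ x̄_n x̄_nᵀ + N Γ⁻¹` and the diagonal of `R_yy = Σ y_n y_nᵀ`
(the diagonal is sufficient for diagonal-noise updates).

**M-step.** With `ψ = R_xx + diag(α)`:

```
Ā   = R_yx ψ⁻¹
λ⁻¹ = diag(R_yy − Ā R_yxᵀ) / denom
α_j⁻¹ = (1/K) [Āᵀ diag(λ) Ā]_jj + [ψ⁻¹]_jj
```

`denom` is N + L by default (`FitConfig.noise_denominator="n_plus_l"`),
the exact coordinate-ascent maximizer of the free energy below; the
classical maximum-likelihood denominator N is available as `"n"`. The two
differ by a factor N/(N+L) — 0.2 % at the standard session size
(N = 6010, L = 10) — and both were observed to keep the free-energy trace
non-decreasing on batteries of seeded problems; N + L is the default
because its monotonicity is a theorem rather than an observation.

**Free energy.** The objective treats the factor posterior variationally
and the mixing matrix as a penalized point estimate:

```
F = (N+L)/2 log|λ| − ½ Σ_i λ_i E[residual²]_i − ½ Tr(R_xx)
    − N/2 log|Γ| + NL/2 + K/2 log|α| − ½ Tr(Āᵀ diag(λ) Ā diag(α))
```

Additive 2π constants are dropped, so all-zero data with A = 0,
λ = α = I gives F = 0 exactly. The E-step and the Ā-update maximize F
exactly in their coordinates, which is what makes the trace
non-decreasing (checked at 1e-8 relative tolerance in the tests).
Convergence is declared when |ΔF| < tol·|F| (default tol = 1e-6,
max_iter = 200); small sessions converge in a handful of sweeps.

A full variational treatment of A (Gaussian row posteriors with
covariance λ_i⁻¹ψ⁻¹) reproduces the same α-update — the `[ψ⁻¹]_jj` term
is exactly the mixing-uncertainty contribution — but would also add a
K ψ⁻¹ term inside Γ. The module interface computes Γ from the model
alone, so the point-estimate treatment of A is the internally consistent
one and is what the free energy above reflects.

**Numerical safeguards.** Updated noise variances are floored at
`precision_floor` (default 1e-10) times the mean per-channel data
variance, so channels explained exactly keep finite precision; ARD
precisions are capped at `alpha_cap` (default 1e12) so pruned columns
cannot overflow. Floor/cap activations are logged at WARNING. ψ is
factorized by Cholesky; a failure raises with diagnostics rather than
silently regularizing.

**Initialization.** Deterministic and scale-aware: A starts at the top-L
left singular vectors of the training matrix scaled by σ_l/√N, with each
column's sign fixed by its largest-magnitude channel entry (this keeps
fitting equivariant under channel permutations); λ⁻¹ starts at the
per-channel residual variance; α = 1. A seeded random initialization
(`init="random"`) exists for robustness checks. Given the config and the
data, fitting is fully deterministic.

## Classification and protocol

Training uses the first 10 trials per class (ascending trial id), each
trial per-channel demeaned before concatenation — per-channel rather than
per-trial-scalar because MEG channel baselines differ by orders of
magnitude. Test trials are demeaned the same way before scoring; the
session protocol does not say this explicitly anywhere we could pin down,
so consistency with training was chosen and is flagged as an assumption.

A trial is scored under each class model by the exact marginal
log-likelihood of all its samples, `y_n ~ N(0, A Aᵀ + diag(λ)⁻¹)`,
evaluated through the L × L matrix Γ (matrix-inversion lemma), so cost is
linear in K. The larger total wins. Likelihoods are compared as per-trial
sums; trials have fixed length, so sums and per-sample means give the
same decision. Exact float ties are resolved by a configurable policy
(default: abstain with an explicit tie flag — a silent coin flip would
make runs nondeterministic); abstentions count as errors in the accuracy
and are never emitted on the command stream. Accuracy is reported overall
and per class, because a session's test trials need not be balanced.

Commands are emitted one ASCII byte per prediction ('L' = 0x4C,
'R' = 0x52) followed by a single null byte that tells the receiving
program the BCI has finished.

## Synthetic sessions

The generator draws both classes from exactly the model the classifier
assumes: unit-norm standard-normal mixing columns, i.i.d. standard-normal
factors per sample, i.i.d. diagonal Gaussian noise. The right-class
matrix rotates each left column by `separation × 90°` into the orthogonal
complement of the left subspace, so `separation = 0` duplicates the left
class bit-for-bit and `separation = 1` gives orthogonal class subspaces.
This parameterization reflects what distinguishes left from right
neuromotor activity physiologically — a different spatial mixing pattern.
With unit-norm columns the mean per-channel signal power is L/K, so we
define SNR = L / (K · noise_variance).

Default geometry matches a standard recording session: 274 channels,
601 samples per trial at 1200 Hz, 80 alternating trials (10 per class for
training + 60 for testing), SNR ≈ 10. The reduced scale used by the test
suite and the acceptance script (64 channels, 200 samples, 5 factors) was
chosen as the smallest geometry that preserves the K ≫ L regime and
leaves parameter recovery comfortable.

What the generator does **not** emulate: evoked waveform shape (factors
are white in time, exactly the model's assumption — an optional check
with temporally smooth factors would stress model mismatch), temporal
correlations, non-Gaussian artifacts, 1/f sensor noise, head geometry.
Passing tests therefore demonstrate correctness of the algorithm under
its own assumptions, not performance on real MEG — the level of real
recordings is an empirical claim this package cannot re-check.

## Design choices on genuinely open points

* **Number of factors L** — never stated for the deployed system; default
  10, freely configurable (tests use 2–5).
* **λ-denominator** — N vs N + L: both implemented, N + L default (see
  above).
* **α-update** — the printed update contains a dimensionally impossible
  inverse-transpose; implemented as
  `α_j⁻¹ = (1/K)[Āᵀ diag(λ) Ā]_jj + [ψ⁻¹]_jj`, the only dimensionally
  consistent reading, and the exact variational update for Gaussian row
  posteriors on A.
* **`T` in `R_xx = Σ x̄x̄ᵀ + N·T`** — read as the posterior covariance
  Γ⁻¹; any other reading breaks the E-step identities.
* **Trial likelihood** — the exact marginal (integrating the factors out)
  rather than the variational bound; for a fitted model the two are close,
  and the exact form is the better-defined decision statistic.
* **Noise-variance recovery tests** — per-channel residual-variance
  estimates at small K inherit the jitter of the estimated loadings
  (individual channels can be tens of percent off at K = 10, N = 2000),
  so recovery is asserted on the median per-channel relative error
  (observed 2–7 % across seeds) alongside a < 5° subspace angle.

## Limitations

* Two classes only; no time-frequency structure; no artifact rejection,
  filtering or head-movement handling — epochs are taken as given.
* The real-time loop is modeled as ordered iteration over stored trials;
  no timing or hardware interface is implemented.
* CTF/FIF file ingestion is out of scope; sessions use the package's own
  directory format (JSON manifest + float64 blocks, or CSV for small
  fixtures).
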