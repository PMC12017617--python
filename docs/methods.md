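# Methods

## Model overview

`neuroinflux` estimates, per subject, how regional burdens of pathological
factors modulate neuronal excitability, by fitting a biophysical forward
model to observed regional resting-state indicators. The pipeline has four
stages: a linear influence law (burdens → regional excitatory drive),
connectome-coupled Wilson–Cowan population dynamics (drive → neural
activity), a balloon–windkessel hemodynamic model (activity → BOLD), and a
spectral indicator (BOLD → regional fALFF or ALFF). The inverse problem —
observed indicator → influence coefficients — is solved by surrogate
global optimization of a simulation-based objective.

## Influence law

The excitability parameter modulated by pathology is the constant external
drive to each region's excitatory population:

    a_i = a_0 + Σ_f α_f q_{i,f}

The coefficients α_f are global (shared across regions) while the burdens
are regional, so the estimate is subject-specific and the regional
excitability profile is reconstructed through the subject's own burden
maps. Burdens are assumed to act additively across factors; interaction or
nonlinear laws, and factor-specific target parameters, are out of scope.
The phrase "pathology spreading through connections" is realized as
activity coupling through the connectome, not as diffusion of the burdens
themselves: the burdens are taken as measured, static inputs.

## Population dynamics

Each region is a two-population Wilson–Cowan unit with the canonical
couplings c_EE = 16, c_IE = 12, c_EI = 15, c_II = 3, logistic activation
(gain_E = 1.3, θ_E = 4, gain_I = 2, θ_I = 3.7) and τ_E = τ_I = 10 ms. The
unit has a stable low-activity fixed point for small drive and a limit
cycle over a window of drives beginning near a ≈ 0.95 (numerically, for
these couplings). Inter-regional coupling is G·Σ_j C_ij E_j on the
excitatory input, with C the connectome divided by its maximum row sum so
that G is interpretable on a bounded scale.

The default operating point, `P_baseline = 0.2`, places regions in the
noise-driven subcritical regime below the oscillatory instability, so that
positive pathological influences push regions *toward* hyperexcitability —
the mechanistic picture in amyloid/tau studies — while the resting
fluctuations that generate the BOLD signal remain smooth functions of the
drive. This choice also keeps the fitting objective well behaved: in the
oscillatory regime the sampled trajectory becomes chaotic with respect to
parameter perturbations (phase decorrelation), and the objective landscape
degenerates into a needle that no black-box optimizer can descend. The
default optimization intervals are correspondingly narrow and nonnegative
(α_f ∈ [0, 0.2], G ∈ [0, 1]): narrow intervals that keep every region's
drive within the intended dynamical regime are a documented practical
requirement of this model class.

Integration is Euler–Maruyama on a fixed grid (default dt = 2 ms) with
additive Gaussian state noise of per-step standard deviation
noise_sd·√dt (default noise_sd = 0.01) on both populations; states are
clipped to [0, 1], the range of the saturating activation. The scheme is
first order; halving dt changes noise-free trajectories proportionally,
which the tests assert. The compiled kernel (numba) is mathematically
identical to the plain-numpy drift used in tests.

## Hemodynamics and indicators

Excitatory activity drives the standard balloon–windkessel system per
region (κ = 0.65 s⁻¹, γ = 0.41 s⁻¹, τ_h = 0.98 s, α = 0.32, ρ = 0.34,
V₀ = 0.02; k₁ = 7ρ, k₂ = 2, k₃ = 2ρ − 0.2), integrated on the same grid,
with BOLD sampled at the grid point nearest each multiple of TR after a
burn-in (default 30 s) that discards the initial transient. Hemodynamics
are deterministic given the neural trace and homogeneous across regions.

ALFF is the sum of single-sided amplitude-spectrum values over the closed
band [0.01, 0.08] Hz of the demeaned signal; the spectrum is normalized so
the squared amplitudes sum to the signal variance (Parseval). fALFF
divides the in-band sum by the sum over all non-DC bins up to Nyquist,
giving a scale-free value in [0, 1]. No band-pass filtering or detrending
is applied before the spectrum by default (linear detrend available). The
number of volumes trades precision for speed: the spectral estimate at 150
volumes is coarse (bin width 1/(N·TR) ≈ 0.0033 Hz) but consistent between
the simulated and observed sides of the objective, which is what the fit
requires.

## Objective and optimizer

The cost is the mean squared difference between simulated and observed
regional indicator vectors (correlation distance available via
`cost_metric: corr`). The state-noise realization is drawn once per subject
from the study seed and reused in every evaluation (common random
numbers), making the objective a smooth deterministic function of the
parameters whose global minimum, for noise-free synthetic observations, is
exactly zero at the generating values. Divergent simulations return a
penalty cost of 10⁶ rather than aborting.

The optimizer evaluates a Latin-hypercube design of max(2d + 2, 8) points,
then repeats: fit a cubic RBF interpolant with linear tail (tiny smoothing
ridge, 10⁻¹²) to all evaluations; score a seeded candidate cloud —
Gaussian perturbations of the incumbent at five scales (25 %, 5 %, 1 %,
0.2 %, 0.04 % of each bound width), 200 uniform points, and the surrogate's
local minimum found by L-BFGS-B from the incumbent — by
w·(min-max-scaled surrogate value) − (1 − w)·(distance to the nearest
evaluated point, scaled by the box diagonal), cycling w through
{0.3, 0.5, 0.8, 0.95}; evaluate the best-scoring fresh candidate. "Iterations"
of the procedure are counted as objective evaluations. The run is labelled
converged when the incumbent improves by less than 10⁻⁸ over the final
quarter of evaluations.

Checkpoints (JSON: all evaluation records, the parameter spec, the
generator state, a config echo) are rewritten atomically after every
evaluation; a resumed run reproduces the uninterrupted run's evaluation
sequence bit-identically because the initial design derives from the run
seed rather than the evolving generator, and the proposal loop's state is
exactly the record list plus the generator state.

## Synthetic data and what the benchmark shows

The generator emulates the four study inputs. Connectomes are
Erdős–Rényi-style symmetric weighted graphs (density 0.3, uniform weights
0.5–1.5, bridged if disconnected) — not realistic human connectomes, but
carrying the same role in the dynamics. Burdens are i.i.d. gamma (shape 2,
scale 0.5): unit mean and right-skew as in tracer-uptake maps, without
spatial correlation or factor covariance. Observed fALFF is produced by
the package's own forward model at sampled ground-truth coefficients
(uniform over the middle 60 % of each optimization interval), with
optional Gaussian observation noise (default 0, clipped to [0, 1]).

The benchmark — 10 subjects, 20 regions, 2 factors, 150 volumes at TR 2 s,
noise-free observations, 150 evaluations per subject — measures the
average per-subject R² (1 − SS_res/SS_tot) between true and reconstructed
regional excitability. Because observation noise is zero and the observed
vector lies exactly on the model manifold, this is a test of the
optimizer's ability to invert the forward model at desk scale, not of
robustness to model mismatch: passing it shows the estimation machinery is
correct and well conditioned, not that real fMRI would yield equally sharp
estimates. A noisy-observation variant (`obs_noise_sd > 0`) exists for
robustness exploration.

## Numerical choices and degenerate inputs

- BOLD sampling uses nearest-grid-point indices; duration is always
  burn_in + n_volumes·TR, so the last sample is in range by construction.
- Indicator bins use closed-interval inclusion with a 10⁻¹² frequency
  tolerance against grid round-off; signals shorter than 8 samples and
  constant signals (undefined fALFF) are rejected.
- Degenerate optimization boxes (all bounds equal) evaluate their single
  point once; individually degenerate coordinates stay fixed.
- Duplicate surrogate sample points are dropped (first kept, warning);
  exact duplicates can arise only from user-supplied checkpoints since
  proposals never repeat evaluated points.
- Self-connections in loaded connectomes are zeroed with a warning;
  regional tables are aligned to the connectome's label order when labels
  match as sets, positionally (with a warning) otherwise.

## Known limitations

- A single excitability target (the excitatory drive) and a single global
  coefficient per factor; no regional heterogeneity in the hemodynamics or
  the influence law.
- No conduction delays; coupling is instantaneous.
- G is weakly identified from fALFF alone (flat objective direction); it is
  retained as a free parameter because it does not contaminate the
  excitability reconstruction.
- The subcritical operating regime is a modelling commitment: fits whose
  bounds allow drives deep into the oscillatory window will face a rugged
  objective there.
- fALFF at 150 volumes has large estimator variance; with real (noisy)
  data, longer acquisitions or ALFF may be preferable.
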