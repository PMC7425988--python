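# Methods

This note documents the models, the statistical procedures, the synthetic
data the package is validated on, and the numerical/design choices that were
genuinely open. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Firing-rate (neural mass) models

Units follow Wilson-Cowan-type dynamics
τ_i dx_i/dt = −x_i + f(Σ_j w_ij x_j + b_i + s_i(t) + I_i) with the logistic
f(u) = 1/(1+e^{−ku}). `W[i, j]` couples unit j onto unit i; the diagonal is
local coupling.

Default parameterizations:

| model | τ (s) | w | b | k | noise SD | trial |
|---|---|---|---|---|---|---|
| one-unit | 0.1 | 1 | −0.5 | 1 | 0.25 | 20 s |
| two-unit | 0.1 | w11=w22=2, w12=w21=4 | −3 | 0.5 | 1 | 50 s |
| 300-unit | 0.1 | w_ii=1, row off-diag total 2 | −2 | 1 | 1 | 10 s |

**Stochastic integration.** Heun (RK2) steps at dt = 10 ms. The background
input I_i is redrawn independently per unit per step from Normal(0, σ) and
held fixed across both RK2 stages, entering inside the nonlinearity exactly
as written in the model equation; no √dt scaling is applied. This treats the
noise as a piecewise-constant exogenous input with the integration
bandwidth, which is the literal reading of the model. Per-unit noise streams
are child streams of the root seed (unit-major), so block-diagonal systems
decompose exactly into their sub-simulations (tested).

**Boxcar timing.** Stimulus onset is at 1.0 s and lasts to the end of the
trial; statistics are computed from 0.5 s after onset (relaxation with
τ = 0.1 s is complete well within that window). With zero noise, a longer
discard (~2 s) is needed before the residual relaxation tail drops below
1e−12 in variance; tests use that window for the deterministic check.

**Variability statistic.** Sweeps store the variance and expose the SD as a
derived column; every rank-based association is invariant to that monotone
choice.

## Attractor analysis and characteristic timescales

Fixed points are found by integrating the noise-free system until the
per-step change falls below tolerance, then polishing with damped Newton
iterations; the reported residual is max|dx/dt| at the solution (< 1e−10
across the default grids; all Jacobian eigenvalues have negative real part
across both sweep grids — tested).

The Jacobian is J[i,j] = (w_ij·f′(u_i) − δ_ij)/τ_i with u_i the total input
at the fixed point and f′ = k·f·(1−f) taken analytically. (A published
rendering of the two-unit Jacobian omits the chain-rule coupling factors
w_ij; the implementation uses the mathematically correct form, verified
against central finite differences of the flow to 1e−6.)

The 1D timescale is T = 1/|F′(x*)|. The 2D generalization weights the
unit-norm eigenvectors by the real parts of their eigenvalues,
T = 1/‖Re(λ₁)v₁ + Re(λ₂)v₂‖. Eigenvectors are normalized to unit length
with the first non-negligible component made positive — the weighted sum is
otherwise sign-ambiguous for non-orthogonal eigenvectors. For n = 1 the
definition collapses to 1/|Re λ| and matches the 1D formula to 1e−10
(tested). Along the equal-input sweep the two-unit Jacobian is symmetric, so
the eigenvectors stay orthogonal and the sign convention is inert.

Nullclines invert the sigmoid: x₂ = (f⁻¹(x₁) − w₁₁x₁ − b₁ − s₁)/w₁₂ with
f⁻¹(y) = logit(y)/k, defined only on (0,1). (The printed nullcline equations
in the source literature carry f⁻¹(−x); a negative rate has no preimage
under the logistic, so this is treated as a sign typo.)

**Associations.** All timescale-statistic associations are Spearman rank
correlations across the amplitude grid (s ∈ [−5, 5], step 0.01, 1001
points).

**Attainable association strength.** The 1D association is ≈ 0.998: variance
estimates from 2000-sample trials are precise relative to the enormous
(orders-of-magnitude) dynamic range of the variance curve. The 2D
association is bounded by Monte-Carlo noise, not by the timescale formula: a
single 50 s trial of strongly autocorrelated two-unit activity yields
correlation estimates with standard errors around 0.08, and the Spearman
between the *true* (linearized) correlation curve and the measured
correlations — the ceiling for any deterministic predictor — is ≈ 0.92. The
implementation attains ≈ 0.91. The mutual-information variant behaves
similarly (≈ 0.89). These ceilings are properties of the stated study
conditions (one 50 s trial per amplitude); longer trials would raise them.

## Hemodynamic transform

The Balloon-Windkessel system (vasodilatory signal, inflow, volume,
deoxyhemoglobin; oxygen extraction E(f) = 1 − (1−e₀)^{1/f}) with the
canonical constants κ = 0.65 s⁻¹, γ = 0.41 s⁻¹, τ₀ = 0.98 s, α = 0.32,
e₀ = 0.34, v₀ = 0.02 and observation constants k₁ = 7e₀, k₂ = 2,
k₃ = 2e₀ − 0.2, all overridable. Integration is RK2 at the neural dt with
decimation to the output interval; flow, volume and dHb are checked to stay
positive; outputs are de-meaned.

**Neural drive.** The hemodynamic model defines its input as a perturbation
around a zero baseline. The sweep analyses therefore drive it with each
condition's *fluctuations around the fixed point* (stationary segment only,
states initialized at the steady state of the segment mean, a 5 s
hemodynamic transient discarded). Two failure modes motivated this choice
and are documented because they are instructive: (i) feeding the raw (0,1)
trajectories including the stimulus onset makes the onset *step response*
dominate BOLD variance, which grows with |s| and reverses the association
sign; (ii) even on stationary segments, raw-level drive places every
amplitude at a different hemodynamic operating point, and the
operating-point gain differences cap the 1D association near 0.855
regardless of trial length. With fluctuation drive the 1D BOLD association
is ≈ 0.96. The 2D BOLD correlation association is additionally limited by
the hemodynamic low-pass (~0.1 Hz): a 50 s trial contains only a handful of
effective samples, correlation estimates scatter by roughly ±0.3, and the
association saturates near 0.7 — a statistical property of the trial
length, not of the transform.

## Clustered balanced spiking network

Leaky integrate-and-fire neurons (4000 E, 1000 I; V_th = 1, V_reset = 0,
refractory 5 ms; τ_m = 15/10 ms E/I; biases uniform [1.1, 1.2] E and
[1.0, 1.05] I) with double-exponential synapses (rise 1 ms; decay 3/2 ms
E/I; J_EE = 0.024, J_EI = −0.045, J_IE = 0.014, J_II = −0.057;
p_EI = p_IE = p_II = 0.5, p_EE = 0.2). Excitatory-to-excitatory weights
within a cluster are multiplied by 1.9; the full-scale network uses 50
clusters of 80 excitatory neurons (the cluster count is adopted from the
standard clustered-network construction; cluster membership does not
modulate connection probability). Spikes increment both synaptic state
variables by J at the spike time; states decay exponentially between events.
Euler integration at dt = 0.1 ms (guarded by the closed-form single-neuron
rate, reproduced within 2%: 1/(t_ref + τ ln(μ/(μ−V_th))) = 28.13 Hz at
μ = 1.15).

The network is deterministic given its quenched randomness; trials differ
through uniform-random initial voltages, and variability arises from the
chaotic balanced dynamics (cluster switching). "Inhibitory stimulation"
raises the bias of 400 inhibitory neurons, which suppresses the excitatory
population and traces the left limb of the sigmoid transfer function; one
connectivity/bias realization is shared across the stimulation conditions of
a sweep.

Statistics follow the mean-field convention: excitatory population rate in
50 ms windows stepped by 10 ms, cross-trial mean and variance per window, 30
trials of 2 s per condition, stimulation increments 0.05–0.5.

**Scaling.** Analyses default to a proportionally reduced 1000E/250I network
(12 clusters, 100 stimulated neurons) with otherwise identical parameters,
chosen so a full sweep completes in minutes on one CPU. The reduced
network's weaker recurrent excitation makes it silence earlier under
inhibitory stimulation; the transition conditions carry large bimodal
cross-trial variance and the deeply silent conditions near-zero variance,
which scrambles a few ranks on the inhibitory limb. The
stimulation-variability Spearman therefore lands around −0.78 to −0.80 at
this scale (full scale is expected to be stronger).

## 300-region network experiment

Connectivity recipes: random (20% density) or clustered (10 communities of
30; 20% within, 3% between); weights |Normal(1, σ)| with σ = 0.2
(excitatory-only) or σ = 1.2 with 20% of connections negated (E/I mix —
note Φ(1/1.2) ≈ 0.80, so the sign split of raw Normal(1, 1.2) draws gives
the same 80/20 fractions). Each row's off-diagonal entries are rescaled so
their summed input is exactly 2 (2:1 inter-regional to local ratio);
per-subject realizations, 20 subjects, 10 s runs sampled at 100 ms, 1 s
transient discarded.

**Task amplitude.** With row totals of 3 (local 1 + inter-regional 2) and
bias −2, a unit task input makes the task state the exact mirror image of
the rest state: the map x → 1−x carries the s = 1 system onto the s = 0
system whenever 2b + s + w_total = 0, so fixed points have identical slopes
and the rest/task statistics are provably identical (verified numerically —
the contrast is null under s = 1 for every architecture). Quenching requires
the task state to sit deeper in saturation than the rest state sits on its
lower shoulder; the default task amplitude is therefore 2.0 (rest fixed
points near 0.20, task near 0.95), which reproduces the quenching direction
in variance (about five-fold, every subject) and in group-mean FC across all
four architectures.

## Trial-based statistics

Mean-evoked-response removal is per-condition, per-(area, timepoint)
centering, applied identically to ITI ("rest") and cue ("task") epochs;
centering is idempotent and removes any deterministic evoked component.
Epoch rate per trial is the mean over the epoch's samples. Bins are 25
consecutive trials, in recording order, pooled across conditions after
condition-wise centering (the literal reading of "consecutive"); trailing
partial bins are dropped. Variance uses divisor n−1; correlations are Fisher
z-transformed before any averaging; zero-variance bins yield missing values
that are excluded, not imputed. Within-trial (across-timepoint) statistics
require equal epoch lengths. Fano factor is cross-trial variance over mean
of windowed counts. Paired contrasts are two-sided paired t-tests with
Benjamini-Hochberg FDR (the generic "FDR-corrected" is implemented as BH).

## Block-design (fMRI-style) pipeline

FIR designs allocate one indicator column per condition per peristimulus
sample from onset to 25 samples past offset, shared across blocks, so the
mean evoked response of arbitrary shape is absorbed exactly when block
lengths are uniform (tested to 1e−6). OLS includes per-run intercept and
linear trend; collinear columns are dropped via pivoted QR with a warning.
The canonical activation GLM convolves condition boxcars with the SPM
double-gamma HRF (via nilearn). z-normalization (per region per run, sample
variance 1) is applied only after task regression. Block samples are
onset ≤ t < offset with no hemodynamic lag shift by default (configurable).
Rest runs are processed with the identical sham design. Cross-block
statistics (no regression, no normalization) use the first 15 peristimulus
timepoints of blocks with at least 15. Dimensionality is the participation
ratio of the block-sample covariance, computed on the same residual data as
the FC analysis; it is scale-invariant and bounded by [1, n] (tested).
Activation magnitude per region is the mean over conditions of the absolute
group t-statistic of the canonical betas; associations with per-region
variance/FC changes are Spearman.

## Synthetic generators

**Trial generator** (six areas, two alternating conditions, 50 ITI + 50 cue
samples, baseline 10): rate = baseline + evoked (cue only) + loading ×
shared latent × state SD + private noise × state SD. Defaults implement the
quenching preset (shared SD 1.0 → 0.5, private 1.0 → 0.8); the shared latent
is a single global factor with per-area loadings (0.75–1.25), the minimal
structure producing global correlations while letting shared and private
quenching be tuned independently. With 1000 trials the pipeline recovers
designed rest→task variance ratios within 10% and the null preset keeps the
false-positive rate at the nominal α (both tested).

**Block-design BOLD generator** (60 regions × 30 subjects default; TR
0.72 s; 10 blocks per condition of 25 samples with 15-sample ITIs): neural
series = betas × boxcars + shared latent + private noise with state-dependent
gains, convolved region-wise with the canonical HRF. Three choices were
forced by the hemodynamics and are worth knowing when designing variants:
blocks must exceed the hemodynamic delay or the quench smears into the
following interval (hence 18 s blocks); the activation coupling acts on the
*shared* gain only, because correlations are invariant to a region's total
noise scale and because additionally scaling private noise lets smeared
unquenched inter-block noise dominate quenched regions' blocks and reverse
the FC association; and shared loadings default to 1.2–1.8 so the shared
variance share survives smearing. The per-region association effects remain
modest after convolution (|ρ| ≈ 0.3–0.5 at 30–40 regions), so association
analyses need cohort-level power.

**Mechanistic generator** chains the 300-region model through the
hemodynamic transform for a fully mechanistic (non-statistical) fixture.

What passing on these generators shows — and does not: the pipelines detect
designed state-dependent changes of the right sign and magnitude under
Gaussian latent-factor noise with exact block timing; real recordings add
non-Gaussian rate distributions, measurement artifacts, motion, regionally
varying hemodynamics, and timing jitter, none of which are modeled.

## Problem sizes

Defaults are sized for a desktop run: full 1001-point amplitude grids
(seconds to a minute per sweep, vectorized across amplitudes), the
1000E/250I spiking network (a 21-condition × 30-trial sweep in a few
minutes), 20 subjects × 4 architectures for the 300-region experiment
(~1 minute), and 30-subject synthetic cohorts (seconds). The full-scale
4000E/1000I network is available through `full_scale_params()` and behaves
identically in kind.
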