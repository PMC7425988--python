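# neuroquench

Task-evoked neural activity *quenches* moment-to-moment variability and
inter-area correlations, and raises the dimensionality of population
activity. `neuroquench` implements the full computational tool-chain behind
that phenomenon: stochastic neural mass (Wilson-Cowan-type firing-rate)
simulators, a clustered balanced spiking network, fixed-point attractor and
characteristic-timescale analysis, a Balloon-Windkessel hemodynamic forward
model, and the trial-based (spiking-style) and block-design (fMRI-style)
statistical pipelines — exercised end-to-end on synthetic cohorts with known
ground truth.

It is written for computational neuroscientists who want to simulate,
analyze, or stress-test state-dependent variability/correlation effects
without access to primate recordings or large fMRI cohorts.

## The model in brief

A population's activity x_i ∈ (0,1) obeys

    τ_i dx_i/dt = −x_i + f(Σ_j w_ij x_j + b_i + s_i(t) + I_i),
    f(u) = 1 / (1 + e^{−k·u}),

with boxcar task input s_i(t) and per-step Gaussian background input I_i
(Heun/RK2 integration, dt = 10 ms). At the noise-free fixed point x\*, the
linearization defines the **characteristic timescale**

    1D:  T = 1 / |F′(x*)|,            F(x) = (−x + f(wx + b + s))/τ
    2D:  T = 1 / ‖Re(λ₁)v₁ + Re(λ₂)v₂‖,   (λ, v) eigenpairs of the Jacobian.

Evoked input of either sign pushes the attractor into the saturated regime,
steepens the flow, shrinks T, and thereby suppresses the variance and
inter-unit correlation of the stochastic dynamics — no connectivity change
required. The same logic is demonstrated in a 4000E/1000I clustered
leaky integrate-and-fire network (mean-field transfer function and
cross-trial variability), in a 300-region network, and after hemodynamic
transformation to BOLD-like signals.

The statistical side mirrors empirical practice: cross-trial variance over
25-trial bins after mean-evoked-response removal (noise correlations with
Fisher z), FIR task regression + z-normalization + block variance/FC for
block designs, per-timepoint cross-block statistics without regression,
participation-ratio dimensionality dim(W) = (Σλ)²/Σλ², and paired contrasts
with Benjamini–Hochberg FDR.

## Worked example

```python
import numpy as np
from neuroquench.neural_mass import default_1d_spec, evoked_sweep_1d
from neuroquench.dynamics import (timescale_sweep_1d,
                                  timescale_statistic_association)

spec = default_1d_spec()                      # tau=0.1, w=1, b=-0.5, k=1, noise 0.25
grid = np.round(np.arange(-5, 5.0001, 0.01), 4)
variance = evoked_sweep_1d(spec, grid, seed=1)    # one 20 s trial per amplitude
timescale = timescale_sweep_1d(spec, grid)        # Jacobian at each fixed point
rho = timescale_statistic_association(variance, timescale)
print(f"variance peaks at s={variance.loc[variance.variance.idxmax(), 'amplitude']:+.2f}")
print(f"Spearman(timescale, variance) = {rho:.4f}")
```

prints

```
variance peaks at s=-0.13
Spearman(timescale, variance) = 0.9983
```

meaning the simulated variance is largest with no stimulation and its rank
ordering across all 1001 input amplitudes is almost perfectly explained by
the analytically computed relaxation timescale of the attractor.

The numbered scripts under `analysis/` run the full set of analyses
(minimal-model sweeps, BOLD preservation, the spiking transfer function, the
300-region rest/task experiment, and both synthetic-cohort pipelines) and
write tidy TSV tables under `results/`.

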