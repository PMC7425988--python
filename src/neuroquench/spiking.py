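"""Clustered balanced leaky integrate-and-fire network (4000E / 1000I).

Membrane voltages follow dV/dt = (mu - V)/tau_m + I_syn with threshold 1,
reset 0, and a 5 ms absolute refractory period.  Synaptic input is the
normalized difference of exponentials: each presynaptic spike increments both
a rise and a decay trace by the synaptic weight J_ij, the traces decay with
their respective time constants, and the current is
(x_decay - x_rise)/(tau_decay - tau_rise), summed for excitatory and
inhibitory afferents.

Excitatory-to-excitatory connections within a cluster are multiplied by 1.9
(homogeneous clustered regime).  The network is deterministic given its
quenched randomness (connectivity and biases); trial-to-trial variability
arises from random initial membrane voltages and the chaotic balanced-state
dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

__all__ = [
    "LIFNetworkParams",
    "StimulationSpec",
    "SpikeRasterSet",
    "PopulationRateSeries",
    "simulate_lif_network",
    "population_rate_stats",
    "transfer_function_sweep",
    "full_scale_params",
    "desk_scale_params",
    "analytic_lif_rate",
]


@dataclass(frozen=True)
class LIFNetworkParams:
    n_exc: int = 4000
    n_inh: int = 1000
    v_threshold: float = 1.0
    v_reset: float = 0.0
    refractory: float = 0.005  # s
    tau_m_exc: float = 0.015
    tau_m_inh: float = 0.010
    bias_range_exc: tuple = (1.1, 1.2)
    bias_range_inh: tuple = (1.0, 1.05)
    tau_rise: float = 0.001
    tau_decay_exc: float = 0.003
    tau_decay_inh: float = 0.002
    p_ee: float = 0.2
    p_ei: float = 0.5
    p_ie: float = 0.5
    p_ii: float = 0.5
    j_ee: float = 0.024
    j_ei: float = -0.045
    j_ie: float = 0.014
    j_ii: float = -0.057
    cluster_multiplier: float = 1.9
    n_clusters: int = 50

    def __post_init__(self) -> None:
        for name in ("p_ee", "p_ei", "p_ie", "p_ii"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.j_ei >= 0 or self.j_ii >= 0:
            raise ValueError("inhibitory weights j_ei, j_ii must be negative")
        if self.j_ee <= 0 or self.j_ie <= 0:
            raise ValueError("excitatory weights j_ee, j_ie must be positive")
        if self.v_reset >= self.v_threshold:
            raise ValueError("v_reset must be below v_threshold")

    @property
    def n_total(self) -> int:
        return self.n_exc + self.n_inh


def full_scale_params(**kw) -> LIFNetworkParams:
    """4000E/1000I, 50 clusters of 80 excitatory neurons."""
    return LIFNetworkParams(**kw)


def desk_scale_params(**kw) -> LIFNetworkParams:
    """Proportionally reduced 1000E/250I network with identical parameters.

    Cluster count is scaled to keep roughly 80 excitatory neurons per cluster.
    """
    kw.setdefault("n_exc", 1000)
    kw.setdefault("n_inh", 250)
    kw.setdefault("n_clusters", 12)
    return LIFNetworkParams(**kw)


@dataclass(frozen=True)
class StimulationSpec:
    """Sustained bias increment to a subset of one population."""

    target: str = "excitatory"  # "excitatory" | "inhibitory"
    n_stimulated: int = 400
    delta_mu: float = 0.0

    def __post_init__(self) -> None:
        if self.target not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown stimulation target {self.target!r}")
        if self.delta_mu < 0:
            raise ValueError("delta_mu must be non-negative")


@dataclass
class SpikeRasterSet:
    """Per-trial spike event lists from one network realization."""

    trials: list  # list of (neuron_ids int array, spike_times float array)
    duration: float
    params: LIFNetworkParams
    stimulation: StimulationSpec
    seed: object

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass
class PopulationRateSeries:
    """Sliding-window mean excitatory population rate per trial."""

    window: float
    step: float
    rates: np.ndarray       # (n_trials, n_windows), Hz per neuron (or normalized)
    mean: np.ndarray        # per-window cross-trial mean
    variance: np.ndarray    # per-window cross-trial variance


def analytic_lif_rate(mu: float, tau_m: float, refractory: float,
                      v_threshold: float = 1.0, v_reset: float = 0.0) -> float:
    """Closed-form firing rate of an isolated LIF neuron under constant drive."""
    if mu <= v_threshold:
        return 0.0
    t_int = tau_m * np.log((mu - v_reset) / (mu - v_threshold))
    return 1.0 / (refractory + t_int)


def _build_network(params: LIFNetworkParams, rng: np.random.Generator):
    """Quenched randomness: outgoing adjacency (CSR by source) and biases."""
    n_e, n_i = params.n_exc, params.n_inh
    n = n_e + n_i
    cluster_of = np.full(n, -1, dtype=np.int64)
    sizes = np.diff(np.linspace(0, n_e, params.n_clusters + 1).astype(int))
    cluster_of[:n_e] = np.repeat(np.arange(params.n_clusters), sizes)

    # connection probability by (target pop, source pop)
    indptr = np.zeros(n + 1, dtype=np.int64)
    targets_per_source = []
    weights_per_source = []
    tgt_ids = np.arange(n)
    for j in range(n):
        src_exc = j < n_e
        if src_exc:
            p_to_e, p_to_i = params.p_ee, params.p_ie
            j_to_e, j_to_i = params.j_ee, params.j_ie
        else:
            p_to_e, p_to_i = params.p_ei, params.p_ii
            j_to_e, j_to_i = params.j_ei, params.j_ii
        p_vec = np.where(tgt_ids < n_e, p_to_e, p_to_i)
        mask = rng.random(n) < p_vec
        mask[j] = False
        tgts = tgt_ids[mask]
        w = np.where(tgts < n_e, j_to_e, j_to_i).astype(np.float64)
        if src_exc:
            same = (cluster_of[tgts] == cluster_of[j]) & (tgts < n_e) & (cluster_of[j] >= 0)
            w[same] *= params.cluster_multiplier
        targets_per_source.append(tgts)
        weights_per_source.append(w)
        indptr[j + 1] = indptr[j] + tgts.size
    indices = np.concatenate(targets_per_source)
    weights = np.concatenate(weights_per_source)

    mu = np.empty(n)
    mu[:n_e] = rng.uniform(*params.bias_range_exc, size=n_e)
    mu[n_e:] = rng.uniform(*params.bias_range_inh, size=n_i)
    return indptr, indices, weights, mu


@njit(cache=False)
def _run_trial(indptr, indices, weights, mu, tau_m, n_exc, v0,
               n_steps, dt, ref_steps, v_th, v_re,
               d_er, d_ed, d_ir, d_id, inv_e, inv_i,
               spike_neuron, spike_step):
    n = mu.shape[0]
    v = v0.copy()
    ready_at = np.zeros(n, dtype=np.int64)
    x_er = np.zeros(n)
    x_ed = np.zeros(n)
    x_ir = np.zeros(n)
    x_id = np.zeros(n)
    n_spikes = 0
    cap = spike_neuron.shape[0]
    spikers = np.empty(n, dtype=np.int64)
    for step in range(n_steps):
        n_spk = 0
        for i in range(n):
            x_er[i] *= d_er
            x_ed[i] *= d_ed
            x_ir[i] *= d_ir
            x_id[i] *= d_id
            if step >= ready_at[i]:
                i_syn = (x_ed[i] - x_er[i]) * inv_e + (x_id[i] - x_ir[i]) * inv_i
                v[i] += dt * ((mu[i] - v[i]) / tau_m[i] + i_syn)
                if v[i] >= v_th:
                    v[i] = v_re
                    ready_at[i] = step + ref_steps
                    spikers[n_spk] = i
                    n_spk += 1
        for si in range(n_spk):
            j = spikers[si]
            if n_spikes < cap:
                spike_neuron[n_spikes] = j
                spike_step[n_spikes] = step
            n_spikes += 1
            is_exc = j < n_exc
            for kk in range(indptr[j], indptr[j + 1]):
                tgt = indices[kk]
                w = weights[kk]
                if is_exc:
                    x_er[tgt] += w
                    x_ed[tgt] += w
                else:
                    x_ir[tgt] += w
                    x_id[tgt] += w
    return n_spikes


def simulate_lif_network(
    params: LIFNetworkParams,
    stim: StimulationSpec,
    n_trials: int,
    duration: float = 2.0,
    dt: float = 1e-4,
    seed=0,
    _network=None,
) -> SpikeRasterSet:
    """Euler-integrate the network for ``n_trials`` independent trials.

    Connectivity and biases are drawn once per seed and held fixed across
    trials; stimulated neurons receive a sustained ``+delta_mu`` bias for the
    whole trial.  Trials differ through their random initial voltages.
    """
    if dt > 2e-4:
        raise ValueError("dt must be <= 0.2 ms for accurate synaptic kinetics")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    net_ss, *trial_ss = ss.spawn(n_trials + 1)
    if _network is None:
        indptr, indices, weights, mu = _build_network(params, np.random.default_rng(net_ss))
    else:
        indptr, indices, weights, mu = _network
        mu = mu.copy()
    n_e = params.n_exc
    if stim.target == "excitatory":
        if stim.n_stimulated > n_e:
            raise ValueError("cannot stimulate more excitatory neurons than exist")
        mu[: stim.n_stimulated] += stim.delta_mu
    else:
        if stim.n_stimulated > params.n_inh:
            raise ValueError("cannot stimulate more inhibitory neurons than exist")
        mu[n_e: n_e + stim.n_stimulated] += stim.delta_mu
    if np.any(mu <= 0):
        warnings.warn("some neurons have non-positive bias mu")

    n = params.n_total
    tau_m = np.where(np.arange(n) < n_e, params.tau_m_exc, params.tau_m_inh)
    n_steps = int(round(duration / dt))
    ref_steps = int(round(params.refractory / dt))
    d_er = np.exp(-dt / params.tau_rise)
    d_ed = np.exp(-dt / params.tau_decay_exc)
    d_ir = np.exp(-dt / params.tau_rise)
    d_id = np.exp(-dt / params.tau_decay_inh)
    inv_e = 1.0 / (params.tau_decay_exc - params.tau_rise)
    inv_i = 1.0 / (params.tau_decay_inh - params.tau_rise)

    cap = int(n * duration * 200)  # generous ceiling: 200 Hz average
    trials = []
    for t_ss in trial_ss:
        rng = np.random.default_rng(t_ss)
        v0 = rng.uniform(params.v_reset, params.v_threshold, size=n)
        spike_neuron = np.empty(cap, dtype=np.int64)
        spike_step = np.empty(cap, dtype=np.int64)
        n_spikes = _run_trial(
            indptr, indices, weights, mu, tau_m, n_e, v0,
            n_steps, dt, ref_steps, params.v_threshold, params.v_reset,
            d_er, d_ed, d_ir, d_id, inv_e, inv_i,
            spike_neuron, spike_step,
        )
        if n_spikes > cap:
            raise RuntimeError("spike buffer overflow: runaway network activity")
        ids = spike_neuron[:n_spikes].copy()
        times = spike_step[:n_spikes] * dt
        trials.append((ids, times))
    return SpikeRasterSet(trials=trials, duration=duration, params=params,
                          stimulation=stim, seed=seed)


def population_rate_stats(
    rasters: SpikeRasterSet,
    window: float = 0.05,
    step: float = 0.01,
    normalize: bool = False,
) -> PopulationRateSeries:
    """Sliding-window excitatory population rate with cross-trial mean/variance.

    Rates are mean spikes per excitatory neuron per second in each 50 ms
    window (10 ms shifts).  With ``normalize=True`` the per-window rates are
    min-max scaled by the grand range of the cross-trial means.
    """
    if rasters.n_trials < 2:
        raise ValueError("need at least 2 trials for cross-trial statistics")
    if window > rasters.duration:
        raise ValueError("window exceeds trial duration")
    n_e = rasters.params.n_exc
    fine = step
    n_fine = int(round(rasters.duration / fine))
    per = int(round(window / fine))
    n_windows = n_fine - per + 1
    rates = np.empty((rasters.n_trials, n_windows))
    kernel = np.ones(per)
    for t, (ids, times) in enumerate(rasters.trials):
        exc_times = times[ids < n_e]
        counts, _ = np.histogram(exc_times, bins=n_fine, range=(0.0, rasters.duration))
        win_counts = np.convolve(counts, kernel, mode="valid")
        rates[t] = win_counts / (n_e * window)
    mean = rates.mean(axis=0)
    if normalize:
        lo, hi = mean.min(), mean.max()
        if hi > lo:
            rates = (rates - lo) / (hi - lo)
            mean = (mean - lo) / (hi - lo)
    variance = rates.var(axis=0, ddof=1)
    return PopulationRateSeries(window=window, step=step, rates=rates,
                                mean=mean, variance=variance)


def transfer_function_sweep(
    params: LIFNetworkParams,
    delta_grid=None,
    n_trials: int = 30,
    duration: float = 2.0,
    dt: float = 1e-4,
    seed=0,
    window: float = 0.05,
    step: float = 0.01,
    n_stimulated: int | None = None,
) -> pd.DataFrame:
    """Mean-field input-output and variability curves under graded stimulation.

    Excitatory stimulation spans the positive axis (bias increments applied to
    a fixed subset of excitatory neurons), inhibitory stimulation the negative
    axis, plus the unstimulated baseline.  One network realization is shared
    across conditions; trials differ in initial conditions.

    Returns a table with signed ``stimulation``, ``mean_rate`` (Hz),
    ``normalized_rate`` (min-max across the sweep), and ``variance`` (mean
    over windows of the cross-trial variance of the windowed population rate).
    """
    if delta_grid is None:
        delta_grid = np.arange(0.05, 0.5 + 1e-9, 0.05)
    delta_grid = np.asarray(delta_grid, dtype=float)
    if np.any(delta_grid <= 0):
        raise ValueError("delta_grid must contain positive increments; 0 is the baseline")
    if n_stimulated is None:
        n_stimulated = max(1, int(round(400 * params.n_exc / 4000)))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    net_ss, cond_root = ss.spawn(2)
    network = _build_network(params, np.random.default_rng(net_ss))

    conditions = [("excitatory", 0.0)]
    conditions += [("excitatory", d) for d in delta_grid]
    conditions += [("inhibitory", d) for d in delta_grid]
    rows = []
    for cond_ss, (target, delta) in zip(cond_root.spawn(len(conditions)), conditions):
        stim = StimulationSpec(target=target, n_stimulated=n_stimulated, delta_mu=delta)
        rasters = simulate_lif_network(
            params, stim, n_trials, duration=duration, dt=dt, seed=cond_ss,
            _network=network,
        )
        series = population_rate_stats(rasters, window=window, step=step)
        signed = delta if target == "excitatory" else -delta
        rows.append({
            "stimulation": signed,
            "mean_rate": series.mean.mean(),
            "variance": series.variance.mean(),
        })
    table = pd.DataFrame(rows).sort_values("stimulation").reset_index(drop=True)
    lo, hi = table["mean_rate"].min(), table["mean_rate"].max()
    table["normalized_rate"] = (table["mean_rate"] - lo) / (hi - lo) if hi > lo else 0.0
    return table


def stimulation_variability_association(table: pd.DataFrame) -> float:
    """Spearman correlation between |stimulation| and population variance."""
    return float(stats.spearmanr(table["stimulation"].abs(), table["variance"]).statistic)
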