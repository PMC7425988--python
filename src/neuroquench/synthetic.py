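"""Synthetic ground-truth generators for the trial and block-design pipelines.

Two statistical generators with known, controllable rest-to-task changes in
the evoked mean, the private (per-area) noise, and the shared (latent)
fluctuation — so every pipeline stage can be validated against designed
truth — plus a mechanistic generator wiring the large firing-rate network
through the hemodynamic model.

The shared variability is a single global latent per dataset with per-area
loadings: the minimal structure that produces global inter-area correlations
and lets "off-diagonal" (shared) and "diagonal" (private) quenching be tuned
independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from nilearn.glm.first_level import spm_hrf

from .fmri import RegionTimeSeries, TaskDesign
from .hemodynamics import BalloonParams, bold_transform
from .neural_mass import (
    ConnectivityRecipe,
    RestTaskRun,
    rest_task_network_experiment,
)
from .trial_stats import TrialMatrix

__all__ = [
    "TrialGeneratorSpec",
    "BoldGeneratorSpec",
    "gen_trial_rates",
    "gen_block_bold",
    "gen_mechanistic",
    "default_block_design",
]


@dataclass(frozen=True)
class TrialGeneratorSpec:
    """Trial-structured multi-area rate data with ITI (rest) and cue (task) epochs.

    Defaults follow the quenching preset: the shared latent SD halves and the
    private SD drops to 0.8 from rest to task, while the evoked mean rises
    only during the cue epoch.
    """

    n_areas: int = 6
    n_trials: int = 1000
    n_conditions: int = 2
    iti_length: int = 50
    cue_length: int = 50
    baseline_rate: float = 10.0
    evoked_gain: np.ndarray | None = None      # (n_conditions, n_areas)
    shared_sd_rest: float = 1.0
    shared_sd_task: float = 0.5
    private_sd_rest: float = 1.0
    private_sd_task: float = 0.8
    loadings: np.ndarray | None = None
    time_step: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("shared_sd_rest", "shared_sd_task",
                     "private_sd_rest", "private_sd_task"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def resolved_evoked(self) -> np.ndarray:
        if self.evoked_gain is not None:
            return np.asarray(self.evoked_gain, dtype=float).reshape(
                self.n_conditions, self.n_areas)
        base = 3.0 * (1.0 + np.arange(self.n_conditions))[:, None]
        return np.broadcast_to(base, (self.n_conditions, self.n_areas)).copy()

    def resolved_loadings(self) -> np.ndarray:
        if self.loadings is not None:
            return np.asarray(self.loadings, dtype=float).reshape(self.n_areas)
        return np.linspace(0.75, 1.25, self.n_areas)


def gen_trial_rates(spec: TrialGeneratorSpec) -> TrialMatrix:
    """Generate a TrialMatrix: baseline + evoked (cue only) + shared + private.

    Per trial and timepoint the area rate is

        baseline + evoked[cond, area] * cue(t)
                 + loading[area] * shared_sd(state(t)) * z(trial, t)
                 + private_sd(state(t)) * eps(trial, area, t)

    with z and eps standard normal; condition labels alternate; the ITI
    samples precede the cue samples.  Deterministic under the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_t = spec.iti_length + spec.cue_length
    cue_mask = np.zeros(n_t, dtype=bool)
    cue_mask[spec.iti_length:] = True
    shared_sd_t = np.where(cue_mask, spec.shared_sd_task, spec.shared_sd_rest)
    private_sd_t = np.where(cue_mask, spec.private_sd_task, spec.private_sd_rest)
    evoked = spec.resolved_evoked()
    loadings = spec.resolved_loadings()
    condition = np.arange(spec.n_trials) % spec.n_conditions

    z = rng.standard_normal((spec.n_trials, n_t))
    eps = rng.standard_normal((spec.n_trials, spec.n_areas, n_t))
    rates = (
        spec.baseline_rate
        + evoked[condition][:, :, None] * cue_mask[None, None, :]
        + loadings[None, :, None] * (shared_sd_t * z)[:, None, :]
        + private_sd_t[None, None, :] * eps
    )
    return TrialMatrix(
        rates=rates,
        condition=condition,
        epoch_masks={"rest": ~cue_mask, "task": cue_mask},
        time_step=spec.time_step,
    )


def default_block_design(
    n_conditions: int = 2,
    n_blocks_per_condition: int = 6,
    block_samples: int = 25,
    iti_samples: int = 15,
    sampling_interval: float = 0.72,
    fir_lag: int = 10,
) -> tuple[TaskDesign, int]:
    """Alternating block design; returns the design and the run length in samples.

    Blocks are 25 samples (18 s at TR 0.72 s) — comfortably longer than the
    hemodynamic delay, so that state-dependent noise localizes inside its own
    block after HRF convolution rather than bleeding wholly into the next
    interval.
    """
    blocks = []
    t = iti_samples
    for _ in range(n_blocks_per_condition):
        for c in range(n_conditions):
            blocks.append((f"cond{c}", t * sampling_interval,
                           block_samples * sampling_interval))
            t += block_samples + iti_samples
    n_timepoints = t + fir_lag
    return TaskDesign.from_blocks(blocks, fir_lag=fir_lag), n_timepoints


@dataclass(frozen=True)
class BoldGeneratorSpec:
    """Block-design BOLD-like cohort with state-dependent shared/private noise.

    ``activation_coupling`` in [0, 1) shrinks each region's task-state noise
    gain in proportion to its normalized |beta|, linking activation magnitude
    to quenching depth as in the empirical association analyses.
    """

    n_regions: int = 60
    n_subjects: int = 30
    sampling_interval: float = 0.72
    n_blocks_per_condition: int = 10
    block_samples: int = 25
    iti_samples: int = 15
    n_conditions: int = 2
    fir_lag: int = 10
    evoked_betas: np.ndarray | None = None   # (n_regions, n_conditions)
    shared_gain_rest: float = 1.0
    shared_gain_task: float = 0.5
    private_gain_rest: float = 1.0
    private_gain_task: float = 0.8
    activation_coupling: float = 0.0
    seed: int = 0

    def design(self) -> tuple[TaskDesign, int]:
        return default_block_design(
            n_conditions=self.n_conditions,
            n_blocks_per_condition=self.n_blocks_per_condition,
            block_samples=self.block_samples,
            iti_samples=self.iti_samples,
            sampling_interval=self.sampling_interval,
            fir_lag=self.fir_lag,
        )


def gen_block_bold(
    spec: BoldGeneratorSpec,
) -> tuple[list[RegionTimeSeries], list[RegionTimeSeries], TaskDesign, dict]:
    """Generate per-subject task and rest BOLD-like runs plus the design.

    The neural-level series (evoked boxcars x betas + shared latent + private
    noise, with state-dependent gains) is convolved with the canonical HRF at
    the acquisition grid.  Rest runs use the rest gains and no evoked
    component.  Returns (task_runs, rest_runs, design, truth) where ``truth``
    records the betas, loadings and per-region task noise gains.
    """
    design, n_t = spec.design()
    rng = np.random.default_rng(spec.seed)
    si = spec.sampling_interval
    hrf = spm_hrf(si, oversampling=1)

    if spec.evoked_betas is not None:
        betas = np.asarray(spec.evoked_betas, dtype=float).reshape(
            spec.n_regions, spec.n_conditions)
    else:
        betas = rng.normal(0.8, 0.3, size=(spec.n_regions, spec.n_conditions))
    # strong shared loadings: the shared latent must carry a sizable variance
    # share for coupling-driven FC effects to survive hemodynamic smearing
    loadings = np.linspace(1.2, 1.8, spec.n_regions)
    rng.shuffle(loadings)

    boxcars = np.zeros((n_t, spec.n_conditions))
    conditions = design.conditions
    for _, ev in design.events.iterrows():
        onset = int(round(ev["onset"] / si))
        n = int(round(ev["duration"] / si))
        boxcars[onset: onset + n, conditions.index(ev["trial_type"])] = 1.0
    task_state = boxcars.any(axis=1)  # sample-level state indicator

    amag = np.abs(betas).mean(axis=1)
    rel = amag / amag.max() if amag.max() > 0 else np.zeros_like(amag)
    coupling_scale = 1.0 - spec.activation_coupling * rel  # per region, in (0, 1]

    shared_gain_t = np.where(task_state, spec.shared_gain_task, spec.shared_gain_rest)
    private_gain_t = np.where(task_state, spec.private_gain_task, spec.private_gain_rest)

    task_runs, rest_runs = [], []
    for _ in range(spec.n_subjects):
        z = rng.standard_normal(n_t)
        eps = rng.standard_normal((spec.n_regions, n_t))
        # activation coupling shrinks a region's SHARED gain only during task
        # samples: correlations are invariant to a region's total noise
        # scale, so a shared-specific reduction is what couples activation
        # to both variance and FC quenching; touching the private gain as
        # well lets hemodynamically smeared (unquenched) inter-block noise
        # dominate quenched regions' block samples and reverses the FC
        # association
        region_scale_t = np.where(task_state[None, :], coupling_scale[:, None], 1.0)
        neural_task = (
            betas @ boxcars.T
            + loadings[:, None] * (shared_gain_t * z)[None, :] * region_scale_t
            + private_gain_t[None, :] * eps
        )
        z_r = rng.standard_normal(n_t)
        eps_r = rng.standard_normal((spec.n_regions, n_t))
        neural_rest = (
            loadings[:, None] * (spec.shared_gain_rest * z_r)[None, :]
            + spec.private_gain_rest * eps_r
        )
        def convolve(neural):
            out = np.empty_like(neural)
            for r in range(neural.shape[0]):
                out[r] = np.convolve(neural[r], hrf)[:n_t]
            return out
        task_runs.append(RegionTimeSeries(values=convolve(neural_task),
                                          sampling_interval=si))
        rest_runs.append(RegionTimeSeries(values=convolve(neural_rest),
                                          sampling_interval=si))
    truth = {
        "betas": betas,
        "loadings": loadings,
        "coupling_scale": coupling_scale,
        "shared_gain_task": spec.shared_gain_task,
        "shared_gain_rest": spec.shared_gain_rest,
        "private_gain_task": spec.private_gain_task,
        "private_gain_rest": spec.private_gain_rest,
    }
    return task_runs, rest_runs, design, truth


def gen_mechanistic(
    recipe: ConnectivityRecipe,
    n_subjects: int = 5,
    seed=0,
    duration: float = 10.0,
    balloon: BalloonParams | None = None,
    output_dt: float = 0.1,
) -> list[RestTaskRun]:
    """Mechanistic fixture: large firing-rate network through the hemodynamic model.

    Each subject's rest (s=0) and task (s=1) neural runs from
    :func:`rest_task_network_experiment` are passed region-wise through the
    Balloon-Windkessel transform at the neural sampling grid.  With
    ``balloon=None`` the neural series are returned untransformed.
    """
    runs = rest_task_network_experiment(recipe, n_subjects=n_subjects, seed=seed,
                                        duration=duration, sample_interval=output_dt)
    if balloon is None:
        return runs
    out = []
    for run in runs:
        transformed = {}
        for state in ("rest", "task"):
            X = getattr(run, state)  # regions x time at output_dt
            _, bold = bold_transform(X.T, params=balloon, dt=run.sampling_interval)
            transformed[state] = bold.T
        out.append(RestTaskRun(rest=transformed["rest"], task=transformed["task"],
                               sampling_interval=run.sampling_interval, W=run.W))
    return out
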