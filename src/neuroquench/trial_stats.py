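"""Trial-based variability and noise-correlation statistics.

The workflow mirrors standard spike-count analyses: remove each condition's
cross-trial mean response ("signal"), then measure the residual trial-to-trial
fluctuations — variance per area and Pearson correlation per area pair — in
consecutive bins of 25 trials, separately for a rest epoch (inter-trial
interval) and a task epoch (cue period).  Fisher's z-transform is applied to
correlations before any averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TrialMatrix",
    "BinnedStatistics",
    "remove_cross_trial_mean",
    "epoch_trial_rates",
    "cross_trial_variance",
    "cross_trial_correlation",
    "within_trial_stats",
    "fano_factor",
    "paired_contrast",
]


@dataclass
class TrialMatrix:
    """Trials x areas x timepoints rate array with condition and epoch labels."""

    rates: np.ndarray                  # (n_trials, n_areas, n_timepoints)
    condition: np.ndarray              # per-trial labels
    epoch_masks: dict                  # name -> boolean mask over timepoints
    time_step: float = 0.01

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.condition = np.asarray(self.condition)
        if self.rates.ndim != 3:
            raise ValueError("rates must be (n_trials, n_areas, n_timepoints)")
        if self.condition.shape[0] != self.rates.shape[0]:
            raise ValueError("one condition label per trial required")
        for name, mask in self.epoch_masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape[0] != self.rates.shape[2]:
                raise ValueError(f"epoch mask {name!r} does not match the time axis")
            self.epoch_masks[name] = mask

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]

    @property
    def n_areas(self) -> int:
        return self.rates.shape[1]


@dataclass
class BinnedStatistics:
    """Per-bin statistics over consecutive, non-overlapping 25-trial bins."""

    bin_size: int
    epoch: str
    variance: np.ndarray | None = None       # (n_bins, n_areas)
    correlation: np.ndarray | None = None    # (n_bins, n_pairs), Fisher z units
    covariance: np.ndarray | None = None     # (n_bins, n_pairs)
    pairs: list | None = None

    @property
    def n_bins(self) -> int:
        arr = self.variance if self.variance is not None else self.correlation
        return arr.shape[0]


def remove_cross_trial_mean(data: TrialMatrix, by: str = "condition") -> TrialMatrix:
    """Subtract the per-condition cross-trial mean at every (area, timepoint).

    The same centering is applied to rest-epoch samples, which controls for
    artifacts the removal itself could induce.  Centering is idempotent.
    """
    if by != "condition":
        raise ValueError("only condition-wise centering is supported")
    residuals = data.rates.copy()
    for cond in np.unique(data.condition):
        sel = data.condition == cond
        if sel.sum() < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 trials")
        residuals[sel] -= residuals[sel].mean(axis=0, keepdims=True)
    return replace(data, rates=residuals)


def epoch_trial_rates(data: TrialMatrix, epoch: str) -> np.ndarray:
    """Per-trial mean rate over the epoch's timepoints -> (n_trials, n_areas)."""
    mask = data.epoch_masks[epoch]
    return data.rates[:, :, mask].mean(axis=2)


def _bins(n_trials: int, bin_size: int):
    n_bins = n_trials // bin_size
    return [(i * bin_size, (i + 1) * bin_size) for i in range(n_bins)]


def cross_trial_variance(
    residuals: TrialMatrix, epoch: str, bin_size: int = 25
) -> BinnedStatistics:
    """Cross-trial variance (divisor n-1) of epoch-mean rates per 25-trial bin.

    Bins are consecutive, non-overlapping, in recording order; a trailing
    partial bin is dropped.
    """
    if bin_size < 2:
        raise ValueError("bin_size must be at least 2")
    r = epoch_trial_rates(residuals, epoch)
    out = np.stack([r[a:b].var(axis=0, ddof=1) for a, b in _bins(r.shape[0], bin_size)])
    return BinnedStatistics(bin_size=bin_size, epoch=epoch, variance=out)


def cross_trial_correlation(
    residuals: TrialMatrix, epoch: str, bin_size: int = 25
) -> BinnedStatistics:
    """Pairwise cross-trial correlation (Fisher z) and covariance per bin.

    A zero-variance area within a bin yields an undefined correlation,
    recorded as NaN and excluded from downstream averages.
    """
    if bin_size < 2:
        raise ValueError("bin_size must be at least 2")
    r = epoch_trial_rates(residuals, epoch)
    n_areas = r.shape[1]
    iu = np.triu_indices(n_areas, k=1)
    pairs = list(zip(iu[0].tolist(), iu[1].tolist()))
    zs, covs = [], []
    for a, b in _bins(r.shape[0], bin_size):
        seg = r[a:b]
        cov = np.cov(seg.T, ddof=1)
        sd = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = cov / np.outer(sd, sd)
        corr[~np.isfinite(corr)] = np.nan
        c = np.clip(corr[iu], -1 + 1e-15, 1 - 1e-15)
        zs.append(np.arctanh(c))
        covs.append(cov[iu])
    return BinnedStatistics(bin_size=bin_size, epoch=epoch,
                            correlation=np.stack(zs), covariance=np.stack(covs),
                            pairs=pairs)


def within_trial_stats(
    data: TrialMatrix, rest_epoch: str = "rest", task_epoch: str = "task"
) -> pd.DataFrame:
    """Per-trial moment-to-moment variance and correlation for matched epochs.

    The per-condition mean time course is removed first; each trial then
    contributes a variance across timepoints (per area, averaged) and a mean
    pairwise correlation across timepoints, for each epoch.  Epoch masks must
    select equal numbers of timepoints so the estimates are comparable.
    """
    rest_mask = data.epoch_masks[rest_epoch]
    task_mask = data.epoch_masks[task_epoch]
    if rest_mask.sum() != task_mask.sum():
        raise ValueError("rest and task epochs must contain equal numbers of timepoints")
    resid = remove_cross_trial_mean(data)
    rows = []
    iu = np.triu_indices(data.n_areas, k=1)
    for t in range(data.n_trials):
        rec = {"trial": t, "condition": data.condition[t]}
        for label, mask in (("rest", rest_mask), ("task", task_mask)):
            seg = resid.rates[t][:, mask]  # areas x time
            rec[f"{label}_variance"] = seg.var(axis=1, ddof=1).mean()
            if data.n_areas > 1:
                corr = np.corrcoef(seg)
                rec[f"{label}_correlation"] = np.nanmean(corr[iu])
        rows.append(rec)
    return pd.DataFrame(rows)


def fano_factor(counts: np.ndarray, level: str = "neuron") -> np.ndarray | float:
    """Cross-trial variance over cross-trial mean of windowed counts.

    ``counts`` is (n_trials, n_units) or (n_trials, n_units, n_windows); with
    ``level="mean_field"`` counts are first averaged across units.  Zero-mean
    entries yield NaN.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if level == "mean_field":
        counts = counts.mean(axis=1, keepdims=True)
    elif level != "neuron":
        raise ValueError(f"unknown level {level!r}")
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fano = np.where(mean > 0, var / mean, np.nan)
    return fano if level == "neuron" else float(np.nanmean(fano))


def paired_contrast(task_stats, rest_stats, fdr_q: float = 0.05) -> pd.DataFrame:
    """Two-sided paired t-test per unit/pair with Benjamini-Hochberg FDR.

    Inputs are matched (n_observations, n_features) arrays (bins, trials, or
    subjects along axis 0).  NaN pairs are dropped per feature.
    """
    task = np.atleast_2d(np.asarray(task_stats, dtype=float))
    rest = np.atleast_2d(np.asarray(rest_stats, dtype=float))
    if task.shape != rest.shape:
        raise ValueError("task and rest statistics must have matching shapes")
    if task.ndim == 2 and task.shape[0] == 1:
        task, rest = task.T, rest.T
    if task.shape[0] < 3:
        raise ValueError("need at least 3 paired observations")
    n_features = task.shape[1]
    tvals = np.empty(n_features)
    pvals = np.empty(n_features)
    for j in range(n_features):
        ok = np.isfinite(task[:, j]) & np.isfinite(rest[:, j])
        if ok.sum() < 3:
            tvals[j], pvals[j] = np.nan, np.nan
            continue
        d = task[ok, j] - rest[ok, j]
        if np.allclose(d, 0):
            tvals[j], pvals[j] = 0.0, 1.0
            continue
        res = stats.ttest_rel(task[ok, j], rest[ok, j])
        tvals[j], pvals[j] = res.statistic, res.pvalue
    finite = np.isfinite(pvals)
    reject = np.zeros(n_features, dtype=bool)
    if finite.any():
        reject[finite] = multipletests(pvals[finite], alpha=fdr_q, method="fdr_bh")[0]
    return pd.DataFrame({"t": tvals, "p": pvals, "significant": reject})
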