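"""Region x time (BOLD-style) analysis chain.

Implements "background connectivity" style processing on block-design runs:
finite-impulse-response (FIR) task regression to remove the mean evoked
response, per-run z-normalization, within-block variance and functional
connectivity (correlation or covariance), cross-block per-timepoint
statistics without task regression, participation-ratio dimensionality, and
associations between task activation magnitude and variability/FC quenching.

Rest runs are processed with the identical ("sham") task design so that any
artifact of the regression or block extraction applies equally to both
states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from nilearn.glm.first_level import spm_hrf
from scipy import stats

from .trial_stats import paired_contrast

__all__ = [
    "RegionTimeSeries",
    "TaskDesign",
    "GLMResult",
    "DimensionalityInput",
    "build_fir_design",
    "regress_out",
    "build_canonical_design",
    "znormalize_runs",
    "block_variance",
    "block_fc",
    "cross_block_stats",
    "participation_ratio",
    "state_dimensionality_contrast",
    "activation_quenching_association",
    "block_sample_mask",
    "mean_offdiagonal",
]


@dataclass
class RegionTimeSeries:
    """Sampled multi-region series; runs partition the time axis."""

    values: np.ndarray                      # (n_regions, n_timepoints)
    sampling_interval: float = 0.72
    run_boundaries: list = None             # run start indices; first must be 0
    region_labels: list = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be (n_regions, n_timepoints)")
        if self.run_boundaries is None:
            self.run_boundaries = [0]
        if self.run_boundaries[0] != 0:
            raise ValueError("run_boundaries must start at sample 0")
        if self.region_labels is None:
            self.region_labels = [f"region_{i}" for i in range(self.values.shape[0])]

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def run_slices(self) -> list[slice]:
        bounds = list(self.run_boundaries) + [self.n_timepoints]
        return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]


@dataclass
class TaskDesign:
    """Block-design events (BIDS-style onset/duration/trial_type table)."""

    events: pd.DataFrame
    fir_lag: int = 25

    def __post_init__(self) -> None:
        required = {"onset", "duration", "trial_type"}
        if not required.issubset(self.events.columns):
            raise ValueError(f"events table needs columns {sorted(required)}")
        self.events = self.events.sort_values("onset").reset_index(drop=True)

    @property
    def conditions(self) -> list:
        return sorted(self.events["trial_type"].unique().tolist())

    @classmethod
    def from_blocks(cls, blocks, fir_lag: int = 25) -> "TaskDesign":
        """Build from an iterable of (condition, onset_s, duration_s)."""
        df = pd.DataFrame(blocks, columns=["trial_type", "onset", "duration"])
        return cls(events=df[["onset", "duration", "trial_type"]], fir_lag=fir_lag)


@dataclass
class GLMResult:
    design_matrix: np.ndarray       # (n_timepoints, n_regressors)
    coefficients: np.ndarray        # (n_regions, n_regressors)
    residuals: RegionTimeSeries
    column_names: list = None


def _block_samples(design: TaskDesign, sampling_interval: float):
    """Events as (condition, onset_sample, n_samples) tuples."""
    out = []
    for _, ev in design.events.iterrows():
        onset = int(round(ev["onset"] / sampling_interval))
        n = int(round(ev["duration"] / sampling_interval))
        out.append((ev["trial_type"], onset, n))
    return out


def build_fir_design(
    design: TaskDesign, n_timepoints: int, sampling_interval: float
) -> tuple[np.ndarray, list]:
    """Finite impulse response design: one indicator column per condition per
    peristimulus sample, from block onset through ``fir_lag`` samples past
    offset.  Columns are shared across blocks of a condition by peristimulus
    index, so the fitted coefficients trace the mean evoked response shape.
    """
    blocks = _block_samples(design, sampling_interval)
    per_cond_len = {}
    for cond, _, n in blocks:
        per_cond_len[cond] = max(per_cond_len.get(cond, 0), n + design.fir_lag)
    conditions = sorted(per_cond_len)
    col_offset = {}
    names = []
    total = 0
    for cond in conditions:
        col_offset[cond] = total
        names += [f"{cond}_fir{p}" for p in range(per_cond_len[cond])]
        total += per_cond_len[cond]
    X = np.zeros((n_timepoints, total))
    for cond, onset, n in blocks:
        for p in range(n + design.fir_lag):
            t = onset + p
            if t >= n_timepoints:
                warnings.warn(f"block of condition {cond!r} truncated at run end")
                break
            X[t, col_offset[cond] + p] = 1.0
    return X, names


def build_canonical_design(
    design: TaskDesign, n_timepoints: int, sampling_interval: float
) -> tuple[np.ndarray, list]:
    """Boxcar-per-condition design convolved with the SPM canonical HRF."""
    hrf = spm_hrf(sampling_interval, oversampling=1)
    conditions = design.conditions
    X = np.zeros((n_timepoints, len(conditions)))
    names = list(conditions)
    for cond, onset, n in _block_samples(design, sampling_interval):
        j = conditions.index(cond)
        if n == 0:
            warnings.warn(f"zero-duration event of condition {cond!r}; column may be all-zero")
        X[onset: min(onset + n, n_timepoints), j] = 1.0
    for j in range(X.shape[1]):
        col = np.convolve(X[:, j], hrf)[:n_timepoints]
        X[:, j] = col
        if not np.any(col):
            warnings.warn(f"condition {names[j]!r} produced an all-zero regressor")
    return X, names


def _trend_columns(series: RegionTimeSeries) -> np.ndarray:
    """Per-run intercept and linear trend regressors."""
    cols = []
    for sl in series.run_slices():
        n = series.n_timepoints
        ind = np.zeros(n)
        ind[sl] = 1.0
        tr = np.zeros(n)
        length = sl.stop - sl.start
        tr[sl] = np.linspace(-1, 1, length)
        cols += [ind, tr]
    return np.column_stack(cols)


def regress_out(
    series: RegionTimeSeries,
    design_matrix: np.ndarray | None,
    add_trend: bool = True,
) -> GLMResult:
    """Ordinary least squares per region; returns coefficients and residuals.

    Per-run intercept and linear trend columns are appended (de-meaning and
    de-trending).  Collinear columns are dropped with a warning via pivoted
    QR before solving.
    """
    Y = series.values.T  # time x regions
    parts = []
    if design_matrix is not None and design_matrix.size:
        design_matrix = np.asarray(design_matrix, dtype=float)
        if design_matrix.shape[0] != series.n_timepoints:
            raise ValueError("design matrix rows must match the number of timepoints")
        parts.append(design_matrix)
    if add_trend:
        parts.append(_trend_columns(series))
    if not parts:
        raise ValueError("nothing to regress: no design and no trend columns")
    D = np.column_stack(parts)
    if D.shape[0] <= D.shape[1]:
        raise ValueError("need more timepoints than regressors")
    rank = np.linalg.matrix_rank(D)
    keep = np.arange(D.shape[1])
    if rank < D.shape[1]:
        from scipy.linalg import qr
        _, _, piv = qr(D, mode="economic", pivoting=True)
        keep = np.sort(piv[:rank])
        warnings.warn(f"design matrix rank deficient; dropped {D.shape[1] - rank} column(s)")
        D = D[:, keep]
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ beta
    residual_series = replace(series, values=resid.T)
    return GLMResult(design_matrix=D, coefficients=beta.T,
                     residuals=residual_series,
                     column_names=keep.tolist())


def znormalize_runs(series: RegionTimeSeries) -> RegionTimeSeries:
    """Zero-mean, unit-variance (ddof=1) per region per run.

    Applied after task regression, never before.  Idempotent; any zero-variance
    region-run raises.
    """
    values = series.values.copy()
    for sl in series.run_slices():
        seg = values[:, sl]
        sd = seg.std(axis=1, ddof=1)
        if np.any(sd == 0):
            bad = int(np.flatnonzero(sd == 0)[0])
            raise ValueError(f"zero-variance region {bad} in run starting at {sl.start}")
        values[:, sl] = (seg - seg.mean(axis=1, keepdims=True)) / sd[:, None]
    return replace(series, values=values)


def block_sample_mask(
    design: TaskDesign,
    n_timepoints: int,
    sampling_interval: float,
    condition=None,
    lag_shift: int = 0,
) -> np.ndarray:
    """Boolean mask of samples with block onset <= t < offset (optional lag)."""
    mask = np.zeros(n_timepoints, dtype=bool)
    for cond, onset, n in _block_samples(design, sampling_interval):
        if condition is not None and cond != condition:
            continue
        a = min(onset + lag_shift, n_timepoints)
        b = min(onset + lag_shift + n, n_timepoints)
        mask[a:b] = True
    return mask


def block_variance(
    residuals: RegionTimeSeries,
    design: TaskDesign,
    lag_shift: int = 0,
    min_block_samples: int = 2,
) -> np.ndarray:
    """Per-region variance over concatenated within-block samples, averaged
    across conditions.  Apply to post-FIR, post-z-normalized task residuals;
    applying the identical call to rest residuals processed with the same
    sham design yields the rest-equivalent variance (which is ~1 by
    construction after normalization, so the task value is directly an
    inter-block contrast).
    """
    si = residuals.sampling_interval
    per_cond = []
    for cond in design.conditions:
        usable = [
            (onset, n) for c, onset, n in _block_samples(design, si)
            if c == cond and n >= min_block_samples
        ]
        if not usable:
            continue
        mask = np.zeros(residuals.n_timepoints, dtype=bool)
        for onset, n in usable:
            a = min(onset + lag_shift, residuals.n_timepoints)
            b = min(onset + lag_shift + n, residuals.n_timepoints)
            mask[a:b] = True
        per_cond.append(residuals.values[:, mask].var(axis=1, ddof=1))
    if not per_cond:
        raise ValueError("no usable blocks in the design")
    return np.mean(per_cond, axis=0)


def block_fc(
    residuals: RegionTimeSeries,
    design: TaskDesign,
    measure: str = "correlation",
    lag_shift: int = 0,
) -> np.ndarray:
    """Region x region within-block statistic per condition, averaged across
    conditions (Fisher z for correlations, plain mean for covariances).

    The returned correlation matrix is in Fisher z units with zeros on the
    diagonal; it is exactly symmetric.
    """
    if measure not in ("correlation", "covariance"):
        raise ValueError(f"unknown measure {measure!r}")
    si = residuals.sampling_interval
    mats = []
    for cond in design.conditions:
        mask = block_sample_mask(design, residuals.n_timepoints, si,
                                 condition=cond, lag_shift=lag_shift)
        if mask.sum() < 3:
            continue
        seg = residuals.values[:, mask]
        if measure == "correlation":
            C = np.corrcoef(seg)
            C = np.clip(C, -1 + 1e-15, 1 - 1e-15)
            Z = np.arctanh(C)
            np.fill_diagonal(Z, 0.0)
            mats.append(Z)
        else:
            mats.append(np.cov(seg, ddof=1))
    if not mats:
        raise ValueError("no usable blocks in the design")
    out = np.mean(mats, axis=0)
    return 0.5 * (out + out.T)


def mean_offdiagonal(matrix: np.ndarray) -> float:
    iu = np.triu_indices(matrix.shape[0], k=1)
    return float(matrix[iu].mean())


def cross_block_stats(
    raw_series: RegionTimeSeries,
    design: TaskDesign,
    n_block_timepoints: int = 15,
) -> pd.DataFrame:
    """Per-peristimulus-timepoint variance and correlation across blocks.

    Applied to series *without* FIR regression or z-normalization: because
    the statistics are computed per peristimulus timepoint across blocks,
    they inherently discount any block-locked waveform.  Blocks shorter than
    ``n_block_timepoints`` are excluded; fewer than 3 usable blocks per
    condition raises.  Values are averaged over regions (variance), region
    pairs (correlation, Fisher z), and conditions.
    """
    si = raw_series.sampling_interval
    n_regions = raw_series.n_regions
    iu = np.triu_indices(n_regions, k=1)
    var_acc = np.zeros(n_block_timepoints)
    corr_acc = np.zeros(n_block_timepoints)
    n_conds = 0
    for cond in design.conditions:
        onsets = [
            onset for c, onset, n in _block_samples(design, si)
            if c == cond and n >= n_block_timepoints
            and onset + n_block_timepoints <= raw_series.n_timepoints
        ]
        if len(onsets) < 3:
            raise ValueError(
                f"condition {cond!r} has fewer than 3 blocks with "
                f">= {n_block_timepoints} timepoints"
            )
        stack = np.stack([
            raw_series.values[:, o: o + n_block_timepoints] for o in onsets
        ])  # (n_blocks, n_regions, n_t)
        var_acc += stack.var(axis=0, ddof=1).mean(axis=0)
        for t in range(n_block_timepoints):
            C = np.corrcoef(stack[:, :, t].T)
            C = np.clip(C, -1 + 1e-15, 1 - 1e-15)
            corr_acc[t] += np.arctanh(C[iu]).mean()
        n_conds += 1
    return pd.DataFrame({
        "peristimulus_timepoint": np.arange(n_block_timepoints),
        "variance": var_acc / n_conds,
        "correlation_z": corr_acc / n_conds,
    })


@dataclass(frozen=True)
class DimensionalityInput:
    """Covariance matrix and its eigenvalues for participation-ratio analysis."""

    covariance: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.covariance, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        object.__setattr__(self, "covariance", C)

    @property
    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.covariance)


def participation_ratio(input_: DimensionalityInput | np.ndarray) -> float:
    """Effective dimensionality (sum(lambda))^2 / sum(lambda^2), in [1, n].

    Scale-invariant: multiplying the covariance by any positive constant
    leaves the participation ratio unchanged.
    """
    if not isinstance(input_, DimensionalityInput):
        input_ = DimensionalityInput(covariance=input_)
    lam = input_.eigenvalues
    if np.min(lam) < -1e-8 * max(np.max(np.abs(lam)), 1.0):
        raise ValueError("covariance is not positive semidefinite")
    lam = np.clip(lam, 0.0, None)
    total_sq = np.sum(lam) ** 2
    denom = np.sum(lam**2)
    if denom == 0:
        raise ValueError("all-zero covariance has undefined dimensionality")
    return float(total_sq / denom)


def state_dimensionality_contrast(
    task_series: list[RegionTimeSeries],
    rest_series: list[RegionTimeSeries],
    design: TaskDesign,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject participation ratio of task-block vs matched rest samples.

    Returns the per-subject table and a paired t-test (task minus rest).
    """
    rows = []
    for i, (task, rest) in enumerate(zip(task_series, rest_series)):
        mask_t = block_sample_mask(design, task.n_timepoints, task.sampling_interval)
        mask_r = block_sample_mask(design, rest.n_timepoints, rest.sampling_interval)
        pr_task = participation_ratio(np.cov(task.values[:, mask_t], ddof=1))
        pr_rest = participation_ratio(np.cov(rest.values[:, mask_r], ddof=1))
        rows.append({"subject": i, "task_dimensionality": pr_task,
                     "rest_dimensionality": pr_rest})
    table = pd.DataFrame(rows)
    contrast = paired_contrast(
        table["task_dimensionality"].to_numpy(),
        table["rest_dimensionality"].to_numpy(),
    )
    return table, contrast


def activation_quenching_association(
    betas: np.ndarray,
    variance_change: np.ndarray,
    fc_change: np.ndarray | None = None,
) -> pd.DataFrame:
    """Rank-correlate per-region activation magnitude with quenching measures.

    ``betas`` is (n_subjects, n_regions, n_conditions); the activation
    magnitude per region is the mean over conditions of the absolute group
    t-statistic of the betas against zero.  Each change vector is correlated
    (Spearman) with that magnitude across regions.
    """
    betas = np.asarray(betas, dtype=float)
    if betas.ndim != 3:
        raise ValueError("betas must be (n_subjects, n_regions, n_conditions)")
    n_regions = betas.shape[1]
    if n_regions < 10:
        raise ValueError("need at least 10 regions")
    tstats = stats.ttest_1samp(betas, 0.0, axis=0).statistic  # (n_regions, n_cond)
    activation = np.abs(tstats).mean(axis=1)
    rows = []
    for name, change in (("variance", variance_change), ("fc", fc_change)):
        if change is None:
            continue
        change = np.asarray(change, dtype=float)
        if change.shape[0] != n_regions:
            raise ValueError(f"{name}_change must have one entry per region")
        res = stats.spearmanr(activation, change)
        rows.append({"measure": name, "rho": res.statistic, "p": res.pvalue})
    return pd.DataFrame(rows)
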