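"""Fixed points, linear stability, and characteristic timescales of rate models.

The characteristic timescale quantifies how slowly a network relaxes toward
its stable fixed point attractor: in one dimension T = 1/|F'(x*)| where
F(x) = (-x + f(w x + b + s))/tau is the flow; in two dimensions it is
generalized as the reciprocal norm of the eigenvalue-weighted sum of
eigenvectors of the Jacobian, T = 1/||Re(l1) v1 + Re(l2) v2||.  Slower
relaxation (larger T) lets spontaneous input accumulate, producing higher
simulated variability and inter-unit correlation; stimulation steepens the
flow, shrinking T and quenching both.

All analyses here use the noise-free vector field even when the paired
simulation is stochastic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .neural_mass import (
    MassModelSpec,
    sigmoid,
    sigmoid_derivative,
    sigmoid_inverse,
)

__all__ = [
    "FixedPoint",
    "StabilityAnalysis",
    "find_fixed_point",
    "characteristic_timescale_1d",
    "jacobian",
    "stability_analysis",
    "generalized_timescale",
    "nullclines",
    "timescale_statistic_association",
    "timescale_sweep_1d",
    "timescale_sweep_2d",
    "flow_field_1d",
]


@dataclass(frozen=True)
class FixedPoint:
    """Noise-free equilibrium x* for a given per-unit input s."""

    input: np.ndarray
    state: np.ndarray
    residual: float


@dataclass(frozen=True)
class StabilityAnalysis:
    """Jacobian eigenstructure and characteristic timescale at a fixed point."""

    fixed_point: FixedPoint
    jacobian: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns, unit norm, first nonzero component positive
    timescale: float


def _flow(spec: MassModelSpec, x: np.ndarray, s: np.ndarray) -> np.ndarray:
    u = x @ spec.W.T + spec.b + s
    return (-x + sigmoid(u, spec.sigmoid)) / spec.tau


def _settle(spec, s_arr, dt, tol, max_time):
    """Deterministic integration of one or many input vectors until steady state.

    s_arr has shape (n_sys, n_units); returns x of the same shape with each
    row integrated until its max per-step change drops below tol.
    """
    x = np.full_like(s_arr, 0.5)
    n_steps = int(round(max_time / dt))
    active = np.ones(s_arr.shape[0], dtype=bool)
    for _ in range(n_steps):
        F = _flow(spec, x[active], s_arr[active])
        step = dt * F
        x[active] += step
        done = np.max(np.abs(step), axis=1) < tol
        if done.any():
            idx = np.flatnonzero(active)
            active[idx[done]] = False
            if not active.any():
                return x, True
    return x, not active.any()


def _newton_refine(spec, x, s, max_iter=50, damping=1.0):
    """Damped Newton on g(x) = -x + f(Wx + b + s); returns refined x."""
    n = spec.n_units
    for _ in range(max_iter):
        u = spec.W @ x + spec.b + s
        g = -x + sigmoid(u, spec.sigmoid)
        if np.max(np.abs(g)) < 1e-14:
            break
        fp = sigmoid_derivative(u, spec.sigmoid)
        Jg = -np.eye(n) + fp[:, None] * spec.W
        try:
            delta = np.linalg.solve(Jg, -g)
        except np.linalg.LinAlgError:
            break
        x = np.clip(x + damping * delta, 1e-12, 1.0 - 1e-12)
    return x


def find_fixed_point(
    spec: MassModelSpec,
    s,
    tol: float = 1e-10,
    max_time: float = 100.0,
    dt: float = 0.01,
) -> FixedPoint:
    """Locate the fixed point reached from mid-range activity for input s.

    Runs the noise-free model until the per-step state change falls below
    ``tol``, then applies damped-Newton refinement.  The reported residual is
    the max norm of dx/dt at the returned state.
    """
    s_arr = np.broadcast_to(np.asarray(s, dtype=float), (spec.n_units,)).copy()
    x, converged = _settle(spec, s_arr[None, :], dt, tol, max_time)
    if not converged:
        raise RuntimeError(
            f"fixed point search did not converge within max_time={max_time} s for input s={s_arr}"
        )
    x = _newton_refine(spec, x[0], s_arr)
    residual = float(np.max(np.abs(_flow(spec, x[None, :], s_arr[None, :]))))
    return FixedPoint(input=s_arr, state=x, residual=residual)


def characteristic_timescale_1d(spec: MassModelSpec, fp: FixedPoint) -> float:
    """T = 1/|F'(x*)| for the one-unit model, with f' taken analytically."""
    if spec.n_units != 1:
        raise ValueError("characteristic_timescale_1d requires a one-unit spec")
    w = spec.W[0, 0]
    u = w * fp.state[0] + spec.b[0] + fp.input[0]
    Fprime = (-1.0 + w * sigmoid_derivative(u, spec.sigmoid)) / spec.tau[0]
    if abs(Fprime) < 1e-12:
        raise ValueError("non-hyperbolic fixed point: |F'(x*)| < 1e-12")
    return 1.0 / abs(Fprime)


def jacobian(spec: MassModelSpec, fp: FixedPoint) -> np.ndarray:
    """Jacobian of the flow at the fixed point: (w_ij f'(u_i) - delta_ij)/tau_i."""
    u = spec.W @ fp.state + spec.b + fp.input
    fprime = sigmoid_derivative(u, spec.sigmoid)
    J = fprime[:, None] * spec.W - np.eye(spec.n_units)
    return J / spec.tau[:, None]


def _fix_eigvec_signs(V: np.ndarray) -> np.ndarray:
    V = V.copy()
    for j in range(V.shape[1]):
        col = V[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and np.real(col[nz[0]]) < 0:
            V[:, j] = -col
    return V


def stability_analysis(spec: MassModelSpec, fp: FixedPoint) -> StabilityAnalysis:
    """Eigendecompose the Jacobian and compute the characteristic timescale."""
    J = jacobian(spec, fp)
    eigvals, eigvecs = np.linalg.eig(J)
    eigvecs = eigvecs / np.linalg.norm(eigvecs, axis=0, keepdims=True)
    eigvecs = _fix_eigvec_signs(eigvecs)
    analysis = StabilityAnalysis(
        fixed_point=fp, jacobian=J, eigenvalues=eigvals,
        eigenvectors=eigvecs, timescale=np.nan,
    )
    T = generalized_timescale(analysis)
    return StabilityAnalysis(
        fixed_point=fp, jacobian=J, eigenvalues=eigvals,
        eigenvectors=eigvecs, timescale=T,
    )


def generalized_timescale(analysis: StabilityAnalysis) -> float:
    """T = 1/||sum_i Re(lambda_i) v_i|| for unit-norm, sign-fixed eigenvectors.

    Defined for one- and two-unit systems; in one dimension it collapses to
    1/|Re(lambda)|, i.e. the classic characteristic timescale.
    """
    n = analysis.eigenvalues.size
    if n > 2:
        raise ValueError("generalized timescale is defined for n <= 2 units")
    V = analysis.eigenvectors
    if n == 2:
        det = np.abs(np.linalg.det(V))
        if det < 1e-10:
            raise ValueError("defective Jacobian: eigenvectors are collinear")
    v_sum = (np.real(analysis.eigenvalues)[None, :] * V).sum(axis=1)
    norm = np.linalg.norm(v_sum)
    if norm < 1e-14:
        raise ValueError("degenerate eigenstructure: ||v_sum|| ~ 0")
    return float(1.0 / norm)


def nullclines(spec: MassModelSpec, s, grid) -> pd.DataFrame:
    """Nullcline curves of the two-unit model on a grid of activity values.

    For dx1/dt = 0:  x2 = (f^-1(x1) - w11 x1 - b1 - s1) / w12  (w12 couples
    unit 2 into unit 1), and symmetrically for dx2/dt = 0.  Grid values must
    lie strictly inside (0, 1) for the inverse sigmoid to exist.
    """
    if spec.n_units != 2:
        raise ValueError("nullclines are defined for the two-unit model")
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0.0) or np.any(grid >= 1.0):
        raise ValueError("grid values must lie strictly inside (0, 1)")
    s_arr = np.broadcast_to(np.asarray(s, dtype=float), (2,))
    finv = sigmoid_inverse(grid, spec.sigmoid)
    x2_of_x1 = (finv - spec.W[0, 0] * grid - spec.b[0] - s_arr[0]) / spec.W[0, 1]
    x1_of_x2 = (finv - spec.W[1, 1] * grid - spec.b[1] - s_arr[1]) / spec.W[1, 0]
    return pd.DataFrame({
        "grid": grid,
        "x2_where_dx1_zero": x2_of_x1,
        "x1_where_dx2_zero": x1_of_x2,
    })


def flow_field_1d(spec: MassModelSpec, s: float, grid) -> pd.DataFrame:
    """Numeric flow dx/dt over a 1-D activity grid (phase-line export)."""
    grid = np.asarray(grid, dtype=float)
    s_arr = np.full((grid.size, 1), float(s))
    F = _flow(spec, grid[:, None], s_arr)[:, 0]
    return pd.DataFrame({"x": grid, "dxdt": F})


def timescale_sweep_1d(spec: MassModelSpec, amplitudes, **fp_kwargs) -> pd.DataFrame:
    """Characteristic timescale of the one-unit model per boxcar amplitude."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    T = np.empty(amplitudes.size)
    for i, s in enumerate(amplitudes):
        fp = find_fixed_point(spec, s, **fp_kwargs)
        T[i] = characteristic_timescale_1d(spec, fp)
    return pd.DataFrame({"amplitude": amplitudes, "timescale": T})


def timescale_sweep_2d(spec: MassModelSpec, amplitudes, **fp_kwargs) -> pd.DataFrame:
    """Generalized timescale of the two-unit model per (equal-input) amplitude."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    T = np.empty(amplitudes.size)
    max_re = np.empty(amplitudes.size)
    for i, s in enumerate(amplitudes):
        fp = find_fixed_point(spec, (s, s), **fp_kwargs)
        an = stability_analysis(spec, fp)
        T[i] = an.timescale
        max_re[i] = float(np.max(np.real(an.eigenvalues)))
    return pd.DataFrame({"amplitude": amplitudes, "timescale": T, "max_re_eig": max_re})


def timescale_statistic_association(
    sweep: pd.DataFrame,
    timescales: pd.DataFrame,
    method: str = "spearman",
    statistic_column: str | None = None,
) -> float:
    """Spearman rank correlation between the timescale and a sweep statistic.

    Both tables must carry an ``amplitude`` column on the same grid.
    """
    if method != "spearman":
        raise ValueError("only the spearman association is supported")
    if len(sweep) < 10 or len(timescales) < 10:
        raise ValueError("need at least 10 amplitude grid points")
    merged = sweep.merge(timescales, on="amplitude", validate="one_to_one")
    if len(merged) != len(sweep):
        raise ValueError("sweep and timescale tables do not share the amplitude grid")
    if statistic_column is None:
        candidates = [c for c in ("variance", "sd", "dependence") if c in sweep.columns]
        if not candidates:
            raise ValueError("no recognizable statistic column in sweep table")
        statistic_column = candidates[0]
    rho = stats.spearmanr(merged["timescale"], merged[statistic_column]).statistic
    return float(rho)
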