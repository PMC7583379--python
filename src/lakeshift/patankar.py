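"""Positivity-preserving conservative time stepping for production-
destruction systems (first-order extended Modified Patankar scheme).

A production-destruction system is written as a non-negative flux matrix
``F`` where ``F[i, j]`` is the instantaneous rate of transfer from pool i
to pool j.  The modified Patankar update scales every destruction term of
pool i by the unknown ratio ``a_i = c_i^{n+1} / c_i^n`` and every
production term by the donor's ratio, which turns the update into a
linear system with an M-matrix: the solution is strictly positive and any
conservative pair conserves its sum to machine precision, for arbitrary
step size.  Unpaired external sources are integrated explicitly (they can
only add mass); unpaired boundary sinks are scaled like destructions, so
positivity still holds.
"""

from __future__ import annotations

import numpy as np

__all__ = ["emp_step", "emp_step_batched"]

_EPS = 1e-30


def emp_step(c: np.ndarray, flux: np.ndarray, dt: float, *,
             sources: np.ndarray | None = None,
             boundary_sinks: np.ndarray | None = None) -> np.ndarray:
    """Advance one production-destruction system by one step.

    Parameters
    ----------
    c : (n,) array
        Pool values at the start of the step (non-negative).
    flux : (n, n) array
        ``flux[i, j] >= 0`` is the rate of transfer from pool i to pool j
        (units of ``c`` per day).  The diagonal must be zero.
    dt : float
        Step size (days).
    sources : (n,) array, optional
        External production rates (explicit, non-negative).
    boundary_sinks : (n,) array, optional
        Destruction rates leaving the system (scaled like internal
        destructions, non-negative).

    Returns
    -------
    (n,) array — the pools after the step; strictly positive wherever the
    inputs admit it, and exactly conservative over internal fluxes.
    """
    c = np.asarray(c, dtype=float)
    out = emp_step_batched(c[None, :], np.asarray(flux, dtype=float)[None, :, :], dt,
                           sources=None if sources is None else np.asarray(sources, float)[None, :],
                           boundary_sinks=None if boundary_sinks is None
                           else np.asarray(boundary_sinks, float)[None, :])
    return out[0]


def emp_step_batched(c: np.ndarray, flux: np.ndarray, dt: float, *,
                     sources: np.ndarray | None = None,
                     boundary_sinks: np.ndarray | None = None,
                     validate: bool = True) -> np.ndarray:
    """Vectorized :func:`emp_step` over a leading batch axis.

    ``c`` has shape (B, n) and ``flux`` (B, n, n); one independent linear
    solve per batch member (e.g., per lake layer).  ``validate=False``
    skips the non-negativity checks (for callers that construct rates
    non-negative by design).
    """
    c = np.asarray(c, dtype=float)
    flux = np.asarray(flux, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if validate:
        if np.any(flux < 0):
            raise ValueError("negative production-destruction rate supplied")
        if np.any(c < 0):
            raise ValueError("negative pool supplied to emp_step")
        if boundary_sinks is not None and np.any(boundary_sinks < 0):
            raise ValueError("negative boundary sink supplied")
        if sources is not None and np.any(sources < 0):
            raise ValueError("negative source supplied")
    b, n = c.shape
    d_tot = flux.sum(axis=2)  # destruction of i = sum_j F[i,j]
    if boundary_sinks is not None:
        d_tot = d_tot + boundary_sinks

    c_eff = np.maximum(c, _EPS)
    # M a = c_eff + dt*s ; M_ii = c_eff_i + dt d_i, M_ij = -dt F[j,i]
    m = -dt * np.swapaxes(flux, 1, 2).copy()
    idx = np.arange(n)
    m[:, idx, idx] = c_eff + dt * d_tot
    rhs = c_eff.copy()
    if sources is not None:
        rhs = rhs + dt * sources
    a = np.linalg.solve(m, rhs[..., None])[..., 0]
    a = np.maximum(a, 0.0)  # guard against rounding

    prod = np.einsum("bij,bi->bj", flux, a)
    out = c + dt * (prod - d_tot * a)
    if sources is not None:
        out = out + dt * sources
    return np.maximum(out, 0.0)
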