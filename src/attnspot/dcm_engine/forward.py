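"""Deterministic DCM forward model: bilinear neuronal dynamics coupled to
balloon hemodynamics, integrated with a fixed-step 4th-order Runge-Kutta
scheme at dt = TR/16. Hemodynamic states (flow f, volume v, deoxyhemoglobin
q) are integrated in log space to enforce positivity. The integrator is
JIT-compiled with a batched parameter axis so finite-difference
sensitivities integrate in a single call.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .model import ALPHA, E0, GAMMA, K1, K2, K3, V0, DCMModel

N_SUBSTEPS = 16
DIVERGENCE_LIMIT = 1.0e6


@dataclass
class DCMTrajectory:
    """States and predicted BOLD sampled on the TR grid."""

    z: np.ndarray  # (n, T) neuronal
    s: np.ndarray  # vasodilatory signal
    f: np.ndarray  # blood inflow
    v: np.ndarray  # venous volume
    q: np.ndarray  # deoxyhemoglobin
    y: np.ndarray  # (n, T) predicted BOLD (percent-signal scale)


@njit(cache=True, inline="always", fastmath=True)
def _deriv_into(x, M, cu, kappa, tau, gamma, ialpha, e0, dx):
    """Write state derivatives into ``dx``; state layout x[b, i, 0..4] =
    (z, s, log f, log v, log q). Log-states are clamped so pathological
    parameter probes cannot produce zero divides; such trajectories are
    caught as divergent by the integrator."""
    nb, n = x.shape[0], x.shape[1]
    log_1m_e0 = np.log(1.0 - e0)
    for b in range(nb):
        for i in range(n):
            acc = cu[b, i]
            for j in range(n):
                acc += M[b, i, j] * x[b, j, 0]
            dx[b, i, 0] = acc
            xf = min(max(x[b, i, 2], -30.0), 30.0)
            xv = min(max(x[b, i, 3], -30.0), 30.0)
            xq = min(max(x[b, i, 4], -30.0), 30.0)
            f = np.exp(xf)
            v = np.exp(xv)
            q = np.exp(xq)
            dx[b, i, 1] = x[b, i, 0] - kappa[b, i] * x[b, i, 1] - gamma * (f - 1.0)
            dx[b, i, 2] = x[b, i, 1] / f
            fv = np.exp(ialpha * xv)  # v ** (1/alpha)
            dx[b, i, 3] = (f - fv) / (tau[b, i] * v)
            ef = 1.0 - np.exp(log_1m_e0 / f)  # 1 - (1 - E0)^(1/f)
            dx[b, i, 4] = (f * ef / e0 - fv * q / v) / (tau[b, i] * q)


@njit(cache=True)
def _integrate(A, B, C, kappa, tau, u, dt, n_sub, gamma, ialpha, e0, v0, k1, k2, k3):
    nb, n = A.shape[0], A.shape[1]
    n_u, T = u.shape
    y = np.zeros((nb, n, T))
    states = np.zeros((nb, 5, n, T))

    x = np.zeros((nb, n, 5))
    xt = np.empty((nb, n, 5))
    d1 = np.empty((nb, n, 5))
    d2 = np.empty((nb, n, 5))
    d3 = np.empty((nb, n, 5))
    d4 = np.empty((nb, n, 5))
    M = np.empty((nb, n, n))
    cu = np.empty((nb, n))
    diverged_at = -1

    for t in range(T):
        # inputs are piecewise constant over each TR
        for b in range(nb):
            for i in range(n):
                for j in range(n):
                    acc = A[b, i, j]
                    for k in range(n_u):
                        acc += u[k, t] * B[b, i, j, k]
                    M[b, i, j] = acc
                accc = 0.0
                for k in range(n_u):
                    accc += C[b, i, k] * u[k, t]
                cu[b, i] = accc
        for _ in range(n_sub):
            _deriv_into(x, M, cu, kappa, tau, gamma, ialpha, e0, d1)
            for b in range(nb):
                for i in range(n):
                    for m in range(5):
                        xt[b, i, m] = x[b, i, m] + 0.5 * dt * d1[b, i, m]
            _deriv_into(xt, M, cu, kappa, tau, gamma, ialpha, e0, d2)
            for b in range(nb):
                for i in range(n):
                    for m in range(5):
                        xt[b, i, m] = x[b, i, m] + 0.5 * dt * d2[b, i, m]
            _deriv_into(xt, M, cu, kappa, tau, gamma, ialpha, e0, d3)
            for b in range(nb):
                for i in range(n):
                    for m in range(5):
                        xt[b, i, m] = x[b, i, m] + dt * d3[b, i, m]
            _deriv_into(xt, M, cu, kappa, tau, gamma, ialpha, e0, d4)
            c = dt / 6.0
            for b in range(nb):
                for i in range(n):
                    for m in range(5):
                        x[b, i, m] += c * (
                            d1[b, i, m] + 2.0 * d2[b, i, m] + 2.0 * d3[b, i, m] + d4[b, i, m]
                        )
        bad = False
        for b in range(nb):
            for i in range(n):
                if (
                    not np.isfinite(x[b, i, 0])
                    or abs(x[b, i, 0]) > DIVERGENCE_LIMIT
                    or abs(x[b, i, 2]) > 25.0
                    or abs(x[b, i, 3]) > 25.0
                    or abs(x[b, i, 4]) > 25.0
                ):
                    bad = True
        if bad:
            diverged_at = t
            break
        for b in range(nb):
            for i in range(n):
                f = np.exp(x[b, i, 2])
                v = np.exp(x[b, i, 3])
                q = np.exp(x[b, i, 4])
                y[b, i, t] = 100.0 * v0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
                states[b, 0, i, t] = x[b, i, 0]
                states[b, 1, i, t] = x[b, i, 1]
                states[b, 2, i, t] = f
                states[b, 3, i, t] = v
                states[b, 4, i, t] = q
    return y, states, diverged_at


def integrate_params(model: DCMModel, theta_batch: np.ndarray):
    """Integrate a batch of parameter vectors; returns y of shape
    (batch, nodes, T)."""
    theta_batch = np.atleast_2d(np.asarray(theta_batch, float))
    nb = theta_batch.shape[0]
    n = len(model.nodes)
    n_u = model.u.shape[0]
    A = np.empty((nb, n, n))
    B = np.empty((nb, n, n, n_u))
    C = np.empty((nb, n, n_u))
    kappa = np.empty((nb, n))
    tau = np.empty((nb, n))
    for b in range(nb):
        A[b], B[b], C[b], kappa[b], tau[b] = model.unpack(theta_batch[b])
    dt = model.tr / N_SUBSTEPS
    y, states, diverged_at = _integrate(
        A, B, C, kappa, tau, np.ascontiguousarray(model.u), dt, N_SUBSTEPS,
        GAMMA, 1.0 / ALPHA, E0, V0, K1, K2, K3,
    )
    if diverged_at >= 0:
        raise FloatingPointError(
            f"neuronal state diverged during integration at TR index {diverged_at}"
        )
    return y, states


def forward(model: DCMModel, params) -> DCMTrajectory:
    """Integrate one parameter vector and return the full trajectory."""
    y, states = integrate_params(model, np.asarray(params, float)[None, :])
    return DCMTrajectory(
        z=states[0, 0], s=states[0, 1], f=states[0, 2], v=states[0, 3], q=states[0, 4],
        y=y[0],
    )
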