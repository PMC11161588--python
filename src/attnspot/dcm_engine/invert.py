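"""Variational-Laplace inversion of a DCM.

Gaussian priors over the free parameters, iid Gaussian observation noise
with one precision hyperparameter per node. Posterior moments are found by
iterated Gauss-Newton ascent on the free energy

    F = -1/2 sum_i lambda_i (||e_i||^2 + tr(J_i Sigma J_i'))
        + (T/2) sum_i log lambda_i - (nT/2) log 2pi
        - 1/2 (m - m0)' S0^-1 (m - m0) + 1/2 log det(Sigma S0^-1),

i.e. expected accuracy under the posterior minus the KL complexity of the
posterior against the prior. Sensitivities come from central finite
differences through the integrator; steps use Levenberg-style trust-region
damping and are rejected whenever they lower F. Noise precisions are
updated by a capped fixed-point (E/M alternation) — the cap anneals the
precision so the objective stays smooth early in the ascent. Data and
predictions are mean-centered per run, so run offsets are not fit.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import integrate_params
from .model import DCMModel


@dataclass
class DCMPosterior:
    """Posterior over free parameters plus the free-energy evidence bound."""

    mean: np.ndarray
    cov: np.ndarray
    noise_precision: np.ndarray  # per node
    free_energy: float
    converged: bool
    trace: list = field(default_factory=list)
    param_names: list = field(default_factory=list)

    def get(self, name: str) -> float:
        return float(self.mean[self.param_names.index(name)])

    def sd(self, name: str) -> float:
        i = self.param_names.index(name)
        return float(np.sqrt(self.cov[i, i]))


def _demean_runs(y: np.ndarray, run_slices) -> np.ndarray:
    out = y.copy()
    for sl in run_slices:
        out[..., sl] = out[..., sl] - out[..., sl].mean(axis=-1, keepdims=True)
    return out


def _free_energy(rss_eff, lam, theta, model, logdet_post_cov, t_eff):
    """rss_eff[i] = ||e_i||^2 + tr(J_i Sigma J_i')."""
    n = rss_eff.size
    acc = -0.5 * float(np.sum(lam * rss_eff))
    acc += 0.5 * t_eff * float(np.sum(np.log(lam)))
    acc -= 0.5 * n * t_eff * np.log(2 * np.pi)
    d = theta - model.prior_mean
    s0inv = 1.0 / model.prior_var
    complexity = 0.5 * float(d @ (s0inv * d)) - 0.5 * (
        logdet_post_cov + float(np.sum(np.log(s0inv)))
    )
    return acc - complexity


def invert(
    model: DCMModel,
    data: np.ndarray,
    max_iter: int = 128,
    tol: float = 0.01,
    fd_step: float = 1.0e-4,
    lam_cap: float = 4.0,
    verbose: bool = False,
) -> DCMPosterior:
    """Invert ``model`` against a (nodes, T) BOLD matrix.

    Convergence: free-energy change below ``tol`` nats on 3 successive
    accepted steps, or ``max_iter`` iterations (returned with
    ``converged=False``). Singular curvature is ridge-regularized;
    ``lam_cap`` bounds the per-iteration multiplicative change of the noise
    precisions.
    """
    data = np.asarray(data, float)
    n, T = data.shape
    if n != len(model.nodes) or T != model.u.shape[1]:
        raise ValueError("data shape does not match the model's nodes/inputs")
    y = _demean_runs(data, model.run_slices)
    t_eff = T - len(model.run_slices)  # df spent on per-run means

    p = model.n_params
    theta = model.prior_mean.copy()
    s0inv = 1.0 / model.prior_var
    lam = 1.0 / np.maximum(y.var(axis=1), 1e-6)

    def predict(th):
        pred, _ = integrate_params(model, th[None, :])
        return _demean_runs(pred[0], model.run_slices)

    def jacobian(th):
        steps = np.concatenate([np.eye(p) * fd_step, -np.eye(p) * fd_step])
        batch = th[None, :] + steps
        preds, _ = integrate_params(model, batch)
        preds = _demean_runs(preds, model.run_slices)
        return (preds[:p] - preds[p:]) / (2 * fd_step)  # (p, n, T)

    def rss_eff_of(e, J, cov):
        out = np.empty(n)
        for i in range(n):
            Ji = J[:, i, :]  # (p, T)
            out[i] = float(e[i] @ e[i]) + float(np.sum((cov @ Ji) * Ji))
        return out

    g = predict(theta)
    e = y - g
    cov = np.diag(model.prior_var)
    sign, logdet = np.linalg.slogdet(cov)
    J = jacobian(theta)
    F = _free_energy(rss_eff_of(e, J, cov), lam, theta, model, logdet, t_eff)
    trace = [F]
    nu = 1e-6  # Levenberg damping
    n_small = 0
    converged = False
    have_J = True

    for it in range(max_iter):
        if not have_J:
            J = jacobian(theta)
        JtJ = np.zeros((p, p))
        grad = -s0inv * (theta - model.prior_mean)
        for i in range(n):
            Ji = J[:, i, :]  # (p, T)
            JtJ += lam[i] * (Ji @ Ji.T)
            grad += lam[i] * (Ji @ e[i])
        P = JtJ + np.diag(s0inv)

        accepted = False
        for _ in range(8):
            P_reg = P + nu * np.diag(np.diag(P))
            try:
                delta = np.linalg.solve(P_reg, grad)
            except np.linalg.LinAlgError:
                P_reg = P_reg + 1e-6 * np.eye(p)
                delta = np.linalg.solve(P_reg, grad)
            cand = theta + delta
            try:
                g_c = predict(cand)
            except (FloatingPointError, ZeroDivisionError):
                nu = max(nu * 10, 1e-4)
                continue
            e_c = y - g_c
            cov_c = np.linalg.inv(P_reg)
            sign, logdet_c = np.linalg.slogdet(cov_c)
            rss_c = rss_eff_of(e_c, J, cov_c)
            F_c = _free_energy(rss_c, lam, cand, model, logdet_c, t_eff)
            if F_c >= F:
                accepted = True
                dF = F_c - F
                theta, e, cov, F = cand, e_c, cov_c, F_c
                nu = max(nu / 2, 1e-8)
                break
            nu = max(nu * 10, 1e-4)

        if accepted:
            # M-step: capped fixed-point ascent on the noise precisions
            J = jacobian(theta)
            have_J = True
            rss = rss_eff_of(e, J, cov)
            lam_star = t_eff / np.maximum(rss, 1e-12)
            lam = np.clip(lam_star, lam / lam_cap, lam * lam_cap)
            lam = np.clip(lam, 1e-8, 1e12)
            sign, logdet = np.linalg.slogdet(cov)
            F = _free_energy(rss, lam, theta, model, logdet, t_eff)
        trace.append(F)
        if verbose:
            print(f"iter {it}: F = {F:.3f} (accepted={accepted})")
        if accepted and dF < tol and np.allclose(lam, np.clip(t_eff / np.maximum(rss, 1e-12), 1e-8, 1e12), rtol=0.05):
            n_small += 1
            if n_small >= 3:
                converged = True
                break
        elif accepted:
            n_small = 0
        else:
            # no acceptable step found at maximal damping: local optimum
            converged = True
            break

    return DCMPosterior(
        mean=theta,
        cov=cov,
        noise_precision=lam,
        free_energy=float(F),
        converged=converged,
        trace=trace,
        param_names=list(model.param_names),
    )
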