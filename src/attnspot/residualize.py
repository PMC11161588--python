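"""Nuisance regression and FIR evoked-response removal.

Background connectivity is computed on residual BOLD time series: per run,
the signal is high-pass filtered, eight nuisance regressors (six motion
parameters, white-matter and ventricle means) are regressed out in a GLM,
and the mean stimulus-evoked response is removed with a finite impulse
response (FIR) basis — one delta regressor per TR of the stimulus+fixation
cycle (24 at the default design). What remains is the "background" signal.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import Dataset, DesignSpec


@dataclass
class EvokedModel:
    """FIR fit of the mean evoked response: per-run betas and reconstruction."""

    fir_betas: list  # per run: (n_nodes, n_fir)
    fir_design: np.ndarray  # (n_tr, n_fir) 0/1 indicators
    fitted_evoked: list  # per run: (n_nodes, n_tr)


@dataclass
class ResidualSet:
    """Background residual time series for V1 nodes and downstream areas."""

    v1: list  # per run: (n_nodes, n_tr)
    downstream: dict  # area -> per-run list of (n_tr,)
    condition: list
    purpose: list
    nuisance_removed: bool = False
    evoked_removed: bool = False
    highpass_s: Optional[float] = None
    evoked_model: Optional[EvokedModel] = None

    def run_indices(self, condition=None, purpose="main"):
        out = []
        for i in range(len(self.v1)):
            if purpose is not None and self.purpose[i] != purpose:
                continue
            if condition is not None and self.condition[i] != condition:
                continue
            out.append(i)
        return out


def dct_basis(n_tr: int, cutoff_s: float, tr: float) -> np.ndarray:
    """Discrete-cosine drift regressors with period above ``cutoff_s``.

    Column k (k >= 1) is cos(pi*k*(2t+1)/(2T)), period 2*T*tr/k seconds;
    the basis spans all fluctuations slower than the cutoff.
    """
    t = np.arange(n_tr)
    duration = n_tr * tr
    k_max = int(np.floor(2.0 * duration / cutoff_s))
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2.0 * n_tr)) for k in range(1, k_max + 1)]
    if not cols:
        return np.empty((n_tr, 0))
    return np.column_stack(cols)


def regress_out(ts: np.ndarray, X: np.ndarray, add_intercept: bool = True):
    """OLS-residualize each row of ``ts`` against the columns of ``X``.

    Returns (residuals, betas). ``X`` is (time, k); an intercept column is
    appended when absent so residuals are mean-free. Rank-deficient designs
    are handled by the pseudoinverse with a warning.
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n_t = ts.shape[1]
    if X.shape[0] != n_t:
        raise ValueError("regressor time axis does not match the data")
    if add_intercept:
        has_const = X.shape[1] > 0 and np.any(
            np.all(np.isclose(X, X[0:1, :]), axis=0) & np.any(X != 0, axis=0)
        )
        if not has_const:
            X = np.column_stack([np.ones(n_t), X])
    if X.shape[1] + 2 > n_t:
        raise ValueError("more regressors than supportable by the time axis")
    # QR solve; fall back to the pseudoinverse when the design is singular
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    if diag.min() <= 1e-10 * max(diag.max(), 1.0):
        warnings.warn("rank-deficient design; using pseudoinverse", RuntimeWarning)
        betas = np.linalg.pinv(X) @ ts.T  # (k, nodes)
    else:
        betas = np.linalg.solve(r, q.T @ ts.T)
    resid = ts - (X @ betas).T
    return resid, betas.T


def highpass(ts: np.ndarray, cutoff_s: float, tr: float) -> np.ndarray:
    """High-pass filter by projecting out slow DCT regressors (and the mean)."""
    if cutoff_s <= 2 * tr:
        raise ValueError("high-pass cutoff must exceed twice the TR")
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    X = dct_basis(ts.shape[1], cutoff_s, tr)
    resid, _ = regress_out(ts, X, add_intercept=True)
    return resid


def build_fir_design(design: DesignSpec) -> np.ndarray:
    """FIR indicator design: column j flags every TR at within-cycle phase j.

    Columns are disjoint 0/1 indicators, hence mutually orthogonal, and each
    sums to the number of cycles.
    """
    n_tr = design.n_tr
    cyc = design.cycle_tr
    if n_tr % cyc != 0:
        raise ValueError("run length is not an integer number of cycles")
    phase = np.arange(n_tr) % cyc
    return (phase[:, None] == np.arange(cyc)[None, :]).astype(float)


def remove_evoked(runs: list, design: DesignSpec, nuisance_removed: bool = True):
    """Remove the FIR-estimated mean evoked response from each run.

    ``runs`` is a list of (n_nodes, n_tr) arrays. The FIR columns are
    orthogonal indicators that jointly span the constant, so the fit equals
    the cycle-phase mean pattern of each node and any cycle-locked signal is
    annihilated exactly. Returns (residual runs, EvokedModel).
    """
    if not nuisance_removed:
        warnings.warn(
            "removing the evoked response from data without prior nuisance regression",
            RuntimeWarning,
        )
    X = build_fir_design(design)
    betas, fits, resids = [], [], []
    for ts in runs:
        r, b = regress_out(ts, X, add_intercept=False)
        resids.append(r)
        betas.append(b)
        fits.append(ts - r)
    return resids, EvokedModel(fir_betas=betas, fir_design=X, fitted_evoked=fits)


def residualize_dataset(
    ds: Dataset,
    remove_evoked_flag: bool = True,
    cutoff_s: Optional[float] = 100.0,
    purpose_filter: Optional[str] = None,
) -> ResidualSet:
    """Full residualization: joint GLM of drift, nuisance and (optionally) FIR.

    Applied per run, identically to V1 node series and downstream area
    series. All regressor sets enter one design matrix, so the residuals
    are exactly orthogonal to every set; in particular, a purely
    cycle-locked signal is annihilated exactly regardless of its overlap
    with the drift or nuisance columns (sequential regression would leak
    the nuisance projection of the evoked response back into the
    residuals). With ``remove_evoked_flag`` False the evoked component is
    kept, supporting the check that the connectivity pattern is preserved
    with and without evoked removal. ``purpose_filter`` restricts
    processing to runs of one purpose ("main" or "localizer").
    """
    run_ids = [
        i for i in range(ds.n_runs)
        if purpose_filter is None or ds.purpose[i] == purpose_filter
    ]
    if cutoff_s is not None and cutoff_s <= 2 * ds.design.tr:
        raise ValueError("high-pass cutoff must exceed twice the TR")
    fir = build_fir_design(ds.design) if remove_evoked_flag else None
    v1_runs, area_runs = [], {a: [] for a in ds.areas}
    fir_betas, fitted = [], []
    for i in run_ids:
        stack = np.vstack([ds.bold[i]] + [ds.downstream[a][i][None, :] for a in ds.areas])
        cols = []
        if cutoff_s is not None:
            cols.append(dct_basis(stack.shape[1], cutoff_s, ds.design.tr))
        cols.append(np.asarray(ds.nuisance[i], dtype=float))
        if fir is not None:
            cols.append(fir)
        X = np.column_stack(cols)
        # the FIR indicators span the constant, so no intercept is needed then
        resid, betas = regress_out(stack, X, add_intercept=fir is None)
        if fir is not None:
            b_fir = betas[:, -fir.shape[1]:]
            fir_betas.append(b_fir)
            fitted.append(b_fir @ fir.T)
        v1_runs.append(resid[: ds.geometry.n_nodes])
        for j, a in enumerate(ds.areas):
            area_runs[a].append(resid[ds.geometry.n_nodes + j])

    evoked_model = None
    if remove_evoked_flag:
        evoked_model = EvokedModel(fir_betas=fir_betas, fir_design=fir, fitted_evoked=fitted)

    return ResidualSet(
        v1=v1_runs,
        downstream=area_runs,
        condition=[ds.condition[i] for i in run_ids],
        purpose=[ds.purpose[i] for i in run_ids],
        nuisance_removed=True,
        evoked_removed=remove_evoked_flag,
        highpass_s=cutoff_s,
        evoked_model=evoked_model,
    )
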