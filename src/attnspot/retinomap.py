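"""ROI definition on the retinotopic V1 map.

The stimulated region ("stim") is defined functionally: nodes with a
stronger response to stimulus blocks than fixation (one-sided p < 0.01) in
independent localizer runs. Peripheral bins are defined geometrically:
nodes within +/-10 deg polar angle of the horizontal meridian, binned by
eccentricity into 4-6, 6-8 and 8-10 deg. Bin edges are half-open [lo, hi)
with the last bin closed at 10.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import BINS, BIN_STIM, BIN_4_6, BIN_6_8, BIN_8_10, DesignSpec, VertexGeometry
from .hrf import double_gamma_hrf
from .residualize import ResidualSet

EXCLUDED = "excluded"

POLAR_WINDOW_DEG = 10.0
PERIPHERAL_EDGES = {BIN_4_6: (4.0, 6.0), BIN_6_8: (6.0, 8.0), BIN_8_10: (8.0, 10.0)}


@dataclass
class RoiAssignment:
    """Per-node analysis label: one of stim / 4-6 / 6-8 / 8-10 / excluded."""

    labels: np.ndarray  # array of strings, one per node

    def members(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"node_id": np.arange(self.labels.size), "label": self.labels})


def _evoked_regressor(design: DesignSpec) -> np.ndarray:
    box = design.stimulus_boxcar()
    h = double_gamma_hrf(design.tr)
    reg = np.convolve(box, h)[: box.size]
    return reg - reg.mean()


def localizer_contrast(runs: list, design: DesignSpec, evoked_removed: bool = False):
    """Per-node one-sided test for stimulus > fixation over localizer runs.

    Each run is fit with a GLM whose regressor is the stimulus boxcar
    convolved with a canonical HRF; per-run betas are pooled by
    inverse-variance fixed effects. Returns (t, p) arrays over nodes.
    Degenerate (zero-variance) nodes get t = 0, p = 1, hence never selected.
    """
    if evoked_removed:
        raise ValueError("localizer contrast requires the evoked signal; got evoked-removed data")
    if not runs:
        raise ValueError("no localizer runs provided")
    reg = _evoked_regressor(design)
    n_nodes = runs[0].shape[0]
    betas = np.zeros((len(runs), n_nodes))
    variances = np.zeros((len(runs), n_nodes))
    df_total = 0
    for r, ts in enumerate(runs):
        X = np.column_stack([np.ones(reg.size), reg])
        beta_hat = np.linalg.pinv(X) @ ts.T
        resid = ts - (X @ beta_hat).T
        df = reg.size - 2
        sigma2 = (resid**2).sum(axis=1) / df
        xtx_inv = np.linalg.inv(X.T @ X)
        betas[r] = beta_hat[1]
        variances[r] = sigma2 * xtx_inv[1, 1]
        df_total += df
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 1.0 / variances
        bad = ~np.isfinite(w)
        w[bad] = 0.0
        wsum = w.sum(axis=0)
        pooled_beta = np.where(wsum > 0, (w * betas).sum(axis=0) / np.where(wsum > 0, wsum, 1), 0.0)
        pooled_se = np.where(wsum > 0, 1.0 / np.sqrt(np.where(wsum > 0, wsum, 1)), np.inf)
        t = np.where(pooled_se < np.inf, pooled_beta / pooled_se, 0.0)
    p = stats.t.sf(t, df_total)
    p = np.where(np.isfinite(t) & (pooled_se < np.inf), p, 1.0)
    t = np.nan_to_num(t)
    return t, p


def assign_rois(geometry: VertexGeometry, localizer_p: np.ndarray, alpha: float = 0.01) -> RoiAssignment:
    """Assign each node to stim / a peripheral eccentricity bin / excluded.

    stim = localizer p < alpha; peripheral bins require |polar angle| <= 10
    deg and eccentricity in the bin range. A node meeting both criteria goes
    to stim. Raises if any analysis bin ends up empty.
    """
    localizer_p = np.asarray(localizer_p, dtype=float)
    if localizer_p.shape != (geometry.n_nodes,):
        raise ValueError("localizer_p length does not match geometry")
    labels = np.full(geometry.n_nodes, EXCLUDED, dtype=object)
    on_meridian = np.abs(geometry.polar_angle) <= POLAR_WINDOW_DEG
    for name, (lo, hi) in PERIPHERAL_EDGES.items():
        if hi >= 10.0:
            in_bin = (geometry.eccentricity >= lo) & (geometry.eccentricity <= hi)
        else:
            in_bin = (geometry.eccentricity >= lo) & (geometry.eccentricity < hi)
        labels[on_meridian & in_bin] = name
    labels[localizer_p < alpha] = BIN_STIM
    assignment = RoiAssignment(labels=np.asarray(labels, dtype=object))
    for name in BINS:
        if assignment.members(name).size == 0:
            raise ValueError(f"analysis bin {name!r} is empty")
    return assignment


def roi_mean_timeseries(residuals: ResidualSet, members: np.ndarray) -> list:
    """Unweighted mean residual series over member nodes, per run."""
    members = np.asarray(members, dtype=int)
    if members.size == 0:
        raise ValueError("empty ROI member list")
    return [run[members].mean(axis=0) for run in residuals.v1]
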