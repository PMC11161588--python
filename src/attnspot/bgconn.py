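"""Background connectivity maps, eccentricity-binned profiles, and the group
statistics applied to them.

Connectivity between each V1 node and a downstream area is the Pearson
correlation of their background residual time series, Fisher z-transformed
(atanh) for averaging and inference. The default aggregation computes r per
run and averages z over runs of the same attention condition; computing a
single r over concatenated residuals is available as an alternative.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import BINS, CONDITIONS, StatResult
from .residualize import ResidualSet
from .retinomap import RoiAssignment

_R_CLIP = 1.0 - 1e-12


@dataclass
class ConnectivityMap:
    """Fisher-z connectivity per V1 node, per downstream area, per condition.

    ``z[(condition, area)]`` is a per-node array; undefined correlations
    (zero-variance series) are NaN and excluded from bin means.
    """

    z: dict  # (condition, area) -> (n_nodes,) array

    def r(self, condition: str, area: str) -> np.ndarray:
        return np.tanh(self.z[(condition, area)])


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with clipping to keep z finite at |r| ~ 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > _R_CLIP):
        warnings.warn("|r| at machine limit; clipping before Fisher transform", RuntimeWarning)
    return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))


def _pearson_rows(ts: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``ts`` with the vector ``y``; NaN when either
    side has zero variance."""
    tsc = ts - ts.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((tsc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (tsc @ yc) / denom
    r[~np.isfinite(r)] = np.nan
    return r


def connectivity_map(
    v1_res: ResidualSet,
    conditions=CONDITIONS,
    method: str = "per_run_z_mean",
) -> ConnectivityMap:
    """Node-by-area background connectivity per attention condition.

    ``per_run_z_mean``: Pearson r per run -> Fisher z -> mean over the
    condition's runs. ``concatenated``: one r over the concatenated
    residuals of the condition.
    """
    if method not in ("per_run_z_mean", "concatenated"):
        raise ValueError(f"unknown aggregation method {method!r}")
    z = {}
    for cond in conditions:
        idx = v1_res.run_indices(condition=cond, purpose="main")
        if not idx:
            raise ValueError(f"no main runs for condition {cond!r}")
        for i in idx:
            if v1_res.v1[i].shape[1] < 30:
                raise ValueError("need at least 30 time points per run")
        for area, runs in v1_res.downstream.items():
            if method == "per_run_z_mean":
                zs = []
                for i in idx:
                    r = _pearson_rows(v1_res.v1[i], runs[i])
                    if np.any(np.isnan(r)):
                        warnings.warn(
                            "zero-variance series: correlation undefined for some nodes",
                            RuntimeWarning,
                        )
                    zs.append(fisher_z(np.where(np.isnan(r), np.nan, r)))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", category=RuntimeWarning)
                    z[(cond, area)] = np.nanmean(np.vstack(zs), axis=0)
            else:
                v1_cat = np.hstack([v1_res.v1[i] for i in idx])
                area_cat = np.hstack([runs[i] for i in idx])
                r = _pearson_rows(v1_cat, area_cat)
                z[(cond, area)] = fisher_z(r)
    return ConnectivityMap(z=z)


def profile_by_bin(
    cmap: ConnectivityMap,
    rois: RoiAssignment,
    subject_id: str = "sub-00",
) -> pd.DataFrame:
    """Mean Fisher z over bin members, tidy per subject/condition/area/bin."""
    rows = []
    for (cond, area), zvals in cmap.z.items():
        for b in BINS:
            members = rois.members(b)
            if members.size == 0:
                raise ValueError(f"analysis bin {b!r} is empty")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                val = np.nanmean(zvals[members])
            rows.append(
                {"subject": subject_id, "condition": cond, "area": area, "bin": b, "z": val}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k, k-1) orthonormal basis of the subspace orthogonal to the constant."""
    q, _ = np.linalg.qr(np.column_stack([np.ones(k), np.eye(k)[:, :-1]]))
    return q[:, 1:]


def _gg_epsilon(y_cells: np.ndarray, C: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon of an effect with contrast matrix ``C``.

    ``y_cells`` is (subjects, cells); epsilon = tr(S)^2 / (k tr(S^2)) with
    S the between-subject covariance of the k contrast variables, clipped
    to [1/k, 1].
    """
    z = y_cells @ C  # (n, k)
    S = np.atleast_2d(np.cov(z, rowvar=False))
    k = C.shape[1]
    denom = k * float(np.trace(S @ S))
    if denom <= 0:
        return 1.0
    eps = float(np.trace(S)) ** 2 / denom
    return float(np.clip(eps, 1.0 / k, 1.0))


def _hf_epsilon(gg: float, n: int, d: float) -> float:
    """Huynh-Feldt epsilon from the Greenhouse-Geisser estimate.

    Corrects the small-sample downward bias of the GG estimate (which makes
    the GG-corrected test conservative when the data are near-spherical);
    never below the GG value, capped at 1.
    """
    den = d * (n - 1 - d * gg)
    if den <= 0:
        return 1.0
    return float(np.clip((n * d * gg - 2) / den, gg, 1.0))


def rm_anova_2way(table: np.ndarray, factor_names=("visual_field", "attention")) -> list:
    """Two-way fully within-subject ANOVA on a (subjects, a, b) array.

    Each effect's sum of squares is tested against its own
    effect-by-subject interaction error term. p values carry the
    Huynh-Feldt sphericity correction (epsilon scales both df; the reported
    F and df are unadjusted and epsilon is flagged in the note). Returns
    StatResults for main A, main B, and A x B.
    """
    y = np.asarray(table, dtype=float)
    if y.ndim != 3:
        raise ValueError("table must be (subjects, a, b)")
    if np.any(~np.isfinite(y)):
        raise ValueError("missing cells in the within-subject table")
    n, a, b = y.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    grand = y.mean()
    m_i = y.mean(axis=(1, 2))  # subject means
    m_j = y.mean(axis=(0, 2))  # factor A level means
    m_k = y.mean(axis=(0, 1))  # factor B level means
    m_ij = y.mean(axis=2)
    m_ik = y.mean(axis=1)
    m_jk = y.mean(axis=0)

    ss_a = n * b * np.sum((m_j - grand) ** 2)
    ss_b = n * a * np.sum((m_k - grand) ** 2)
    ss_ab = n * np.sum((m_jk - m_j[:, None] - m_k[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_ij - m_i[:, None] - m_j[None, :] + grand) ** 2)
    ss_bs = a * np.sum((m_ik - m_i[:, None] - m_k[None, :] + grand) ** 2)
    resid = (
        y
        - m_ij[:, :, None]
        - m_ik[:, None, :]
        - m_jk[None, :, :]
        + m_i[:, None, None]
        + m_j[None, :, None]
        + m_k[None, None, :]
        - grand
    )
    ss_abs = np.sum(resid**2)

    # sphericity epsilons from effect-specific contrast covariances
    # (Greenhouse-Geisser estimate, Huynh-Feldt bias correction at use site)
    ca = _orthonormal_contrasts(a)
    cb = _orthonormal_contrasts(b)
    eps_a = _gg_epsilon(m_ij, ca) if a > 1 else 1.0
    eps_b = _gg_epsilon(m_ik, cb) if b > 1 else 1.0
    eps_ab = _gg_epsilon(y.reshape(n, a * b), np.kron(ca, cb)) if a > 1 and b > 1 else 1.0

    effects = [
        (f"main_{factor_names[0]}", ss_a, a - 1, ss_as, (a - 1) * (n - 1), eps_a),
        (f"main_{factor_names[1]}", ss_b, b - 1, ss_bs, (b - 1) * (n - 1), eps_b),
        (
            f"{factor_names[0]}_x_{factor_names[1]}",
            ss_ab,
            (a - 1) * (b - 1),
            ss_abs,
            (a - 1) * (b - 1) * (n - 1),
            eps_ab,
        ),
    ]
    out = []
    for name, ss, df1, ss_err, df2, eps in effects:
        if df1 == 0:
            continue
        if ss_err <= 0 or df2 == 0:
            raise ValueError(f"zero error sum of squares for {name}; F undefined")
        F = (ss / df1) / (ss_err / df2)
        eps = _hf_epsilon(eps, n, df1)
        p = sps.f.sf(F, eps * df1, eps * df2)
        out.append(
            StatResult(
                name=name, kind="F", statistic=float(F), df=(df1, df2), p=float(p),
                note=f"Huynh-Feldt corrected (epsilon={eps:.3f})",
            )
        )
    return out


def paired_t(x, y, name: str = "paired") -> StatResult:
    """Two-sided paired t test on per-subject condition values; df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("paired_t needs two equal-length vectors, n >= 2")
    d = x - y
    if np.allclose(d, d[0]) and np.isclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0):
            return StatResult(name=name, kind="t", statistic=0.0, df=(x.size - 1,), p=1.0)
        raise ValueError("zero-variance differences with nonzero mean: t undefined")
    t, p = sps.ttest_rel(x, y)
    return StatResult(name=name, kind="t", statistic=float(t), df=(x.size - 1,), p=float(p))


def one_sample_t(x, popmean: float = 0.0, name: str = "one_sample") -> StatResult:
    """Two-sided one-sample t test against ``popmean``; df = n - 1."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("one_sample_t needs a vector of n >= 2")
    if np.isclose(x.std(ddof=1), 0.0):
        if np.isclose(x.mean(), popmean):
            return StatResult(name=name, kind="t", statistic=0.0, df=(x.size - 1,), p=1.0)
        raise ValueError("zero-variance sample away from the null mean: t undefined")
    t, p = sps.ttest_1samp(x, popmean)
    return StatResult(name=name, kind="t", statistic=float(t), df=(x.size - 1,), p=float(p))


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def attach_fdr(results: list) -> list:
    """FDR-adjust a family of StatResults in place (fills ``q``)."""
    if results:
        qs = fdr_adjust([r.p for r in results])
        for r, q in zip(results, qs):
            r.q = float(q)
    return results


def profile_anova_tables(profiles: pd.DataFrame) -> dict:
    """Pivot a tidy cohort profile table into per-area (subjects, bin,
    condition) arrays for the repeated-measures ANOVA."""
    if profiles.duplicated(["subject", "area", "bin", "condition"]).any():
        raise ValueError("profile table has duplicate cells")
    wide = profiles.pivot_table(
        index="subject", columns=["area", "bin", "condition"], values="z", sort=True
    )
    subjects = list(wide.index)
    out = {}
    for area in sorted(profiles["area"].unique()):
        arr = np.empty((len(subjects), len(BINS), len(CONDITIONS)))
        for j, b in enumerate(BINS):
            for k, c in enumerate(CONDITIONS):
                if (area, b, c) not in wide.columns:
                    raise ValueError("profile table is not a complete crossing")
                col = wide[(area, b, c)].to_numpy()
                if np.any(~np.isfinite(col)):
                    raise ValueError("profile table is not a complete crossing")
                arr[:, j, k] = col
        out[area] = arr
    return out
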