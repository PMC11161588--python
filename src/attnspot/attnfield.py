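"""Stimulus/attention-field center and size from the eccentricity profile
of evoked responses.

The spatial distribution of the BOLD response across eccentricity is
treated as a probability distribution: negative responses are truncated to
zero and the rest normalized to sum to 1. The field center is the
probability-weighted mean eccentricity E(x) = sum x_i p(x_i); the field
size is twice the corresponding standard deviation
Sd(x) = sqrt(sum (x_i - E(x))^2 p(x_i)), both in degrees of visual angle.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CONDITIONS, Dataset, StatResult
from .bgconn import one_sample_t, paired_t
from .retinomap import localizer_contrast

#: physical eccentricity of the stimulus array center
STIMULUS_ECC_DEG = 2.5


@dataclass
class FieldEstimate:
    x: np.ndarray  # eccentricity grid (deg)
    p: np.ndarray  # normalized response distribution
    center: float  # E(x), deg
    size: float    # 2 * Sd(x), deg


def response_profile(responses, x=None) -> np.ndarray:
    """Truncate negatives and normalize responses to a distribution."""
    r = np.asarray(responses, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 eccentricity bins")
    r = np.where(r > 0, r, 0.0)
    total = r.sum()
    if total <= 0:
        raise ValueError("all responses non-positive: distribution undefined")
    return r / total


def field_center(x, p) -> float:
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    return float(np.sum(x * p))


def field_size(x, p) -> float:
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    mu = field_center(x, p)
    return float(2.0 * np.sqrt(np.sum((x - mu) ** 2 * p)))


def estimate_field(responses, x) -> FieldEstimate:
    p = response_profile(responses)
    return FieldEstimate(
        x=np.asarray(x, float), p=p, center=field_center(x, p), size=field_size(x, p)
    )


def eccentricity_responses(
    ds: Dataset, condition: str, bin_width: float = 1.0, ecc_max: float = 10.0
):
    """Per-eccentricity-bin stimulus-vs-fixation GLM betas for one condition.

    Nodes are binned on ``bin_width``-deg bins from 0 to ``ecc_max``; the
    per-node GLM beta (pooled over the condition's main runs) is averaged
    within each bin. Truncation happens downstream, after this within-bin
    averaging. Returns (bin centers, mean response per bin).
    """
    idx = ds.run_indices(condition=condition, purpose="main")
    if not idx:
        raise ValueError(f"no main runs for condition {condition!r}")
    runs = [ds.bold[i] for i in idx]
    # betas via the same pooled GLM used by the localizer (t is ignored here)
    from .retinomap import _evoked_regressor

    reg = _evoked_regressor(ds.design)
    X = np.column_stack([np.ones(reg.size), reg])
    pinv = np.linalg.pinv(X)
    betas = np.mean([(pinv @ ts.T)[1] for ts in runs], axis=0)

    edges = np.arange(0.0, ecc_max + bin_width / 2, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2
    mean_resp = np.full(centers.size, np.nan)
    ecc = ds.geometry.eccentricity
    for k in range(centers.size):
        members = (ecc >= edges[k]) & (ecc < edges[k + 1])
        if members.any():
            mean_resp[k] = betas[members].mean()
    keep = np.isfinite(mean_resp)
    return centers[keep], mean_resp[keep]


def estimate_field_from_dataset(
    ds: Dataset, condition: str, bin_width: float = 1.0, ecc_max: float = 10.0
) -> FieldEstimate:
    x, resp = eccentricity_responses(ds, condition, bin_width, ecc_max)
    return estimate_field(resp, x)


def compare_fields(estimates: dict, stimulus_ecc: float = STIMULUS_ECC_DEG):
    """Group tests on per-subject, per-condition field estimates.

    ``estimates`` maps subject -> {condition: FieldEstimate}. Returns
    StatResults: paired t on centers and on sizes between conditions, and a
    one-sample t of centers (per condition) against the physical stimulus
    eccentricity.
    """
    subjects = sorted(estimates)
    for s in subjects:
        for c in CONDITIONS:
            if c not in estimates[s]:
                raise ValueError(f"subject {s!r} missing condition {c!r}")
    centers = {c: np.array([estimates[s][c].center for s in subjects]) for c in CONDITIONS}
    sizes = {c: np.array([estimates[s][c].size for s in subjects]) for c in CONDITIONS}
    focal, diffused = CONDITIONS[0], CONDITIONS[1]
    results = [
        paired_t(centers[focal], centers[diffused], name="center_focal_vs_diffused"),
        paired_t(sizes[focal], sizes[diffused], name="size_focal_vs_diffused"),
    ]
    for c in CONDITIONS:
        results.append(
            one_sample_t(centers[c], stimulus_ecc, name=f"center_{c}_vs_stimulus")
        )
    return results
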