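"""Core containers shared across the pipeline.

The pipeline is node-based and surface/volume agnostic: a "node" is a V1
surface vertex (or voxel) with retinotopic coordinates, and each downstream
visual area (V2, V3, V4) enters as a single aggregate time series.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

FOCAL = "focal"
DIFFUSED = "diffused"
CONDITIONS = (FOCAL, DIFFUSED)

#: analysis bins: localizer-defined stimulated region plus three peripheral
#: eccentricity bins on the horizontal meridian
BIN_STIM = "stim"
BIN_4_6 = "4-6"
BIN_6_8 = "6-8"
BIN_8_10 = "8-10"
BINS = (BIN_STIM, BIN_4_6, BIN_6_8, BIN_8_10)

DOWNSTREAM_AREAS = ("V2", "V3", "V4")


@dataclass
class VertexGeometry:
    """Retinotopic coordinates of V1 nodes.

    eccentricity is in degrees of visual angle (>= 0); polar_angle in degrees
    in (-180, 180] with 0 on the horizontal meridian of the contralateral
    hemifield. ``is_stimulated_truth`` is the generator's ground-truth flag
    for nodes whose receptive fields fall inside the stimulus footprint.
    """

    eccentricity: np.ndarray
    polar_angle: np.ndarray
    is_stimulated_truth: np.ndarray

    def __post_init__(self):
        self.eccentricity = np.asarray(self.eccentricity, dtype=float)
        self.polar_angle = np.asarray(self.polar_angle, dtype=float)
        self.is_stimulated_truth = np.asarray(self.is_stimulated_truth, dtype=bool)
        if self.eccentricity.ndim != 1:
            raise ValueError("eccentricity must be 1-D")
        n = self.eccentricity.size
        if self.polar_angle.shape != (n,) or self.is_stimulated_truth.shape != (n,):
            raise ValueError("geometry fields must share one length")
        if np.any(self.eccentricity < 0):
            raise ValueError("eccentricities must be non-negative")
        if np.any(self.polar_angle <= -180) or np.any(self.polar_angle > 180):
            raise ValueError("polar angles must lie in (-180, 180]")

    @property
    def n_nodes(self) -> int:
        return self.eccentricity.size

    @property
    def node_id(self) -> np.ndarray:
        return np.arange(self.n_nodes)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "node_id": self.node_id,
                "eccentricity": self.eccentricity,
                "polar_angle": self.polar_angle,
                "is_stimulated_truth": self.is_stimulated_truth,
            }
        )


@dataclass(frozen=True)
class DesignSpec:
    """Block design timing: alternating stimulus and fixation blocks.

    Defaults reproduce the study design: TR = 1 s, 12 s stimulus blocks
    interleaved with 12 s fixation, 10 cycles per run, 8 runs per attention
    condition.
    """

    tr: float = 1.0
    block_s: float = 12.0
    fix_s: float = 12.0
    n_cycles: int = 10
    n_runs_per_condition: int = 8

    def __post_init__(self):
        for name in ("block_s", "fix_s"):
            v = getattr(self, name)
            if abs(v / self.tr - round(v / self.tr)) > 1e-9:
                raise ValueError(f"{name} must be an integer multiple of tr")
        if self.tr <= 0 or self.block_s <= 0 or self.fix_s <= 0:
            raise ValueError("tr, block_s, fix_s must be positive")
        if self.n_cycles < 1 or self.n_runs_per_condition < 1:
            raise ValueError("n_cycles and n_runs_per_condition must be >= 1")

    @property
    def cycle_tr(self) -> int:
        """Volumes per stimulus+fixation cycle (24 at the defaults)."""
        return int(round((self.block_s + self.fix_s) / self.tr))

    @property
    def block_tr(self) -> int:
        return int(round(self.block_s / self.tr))

    @property
    def n_tr(self) -> int:
        """Volumes per run."""
        return self.cycle_tr * self.n_cycles

    def stimulus_boxcar(self) -> np.ndarray:
        """0/1 indicator of stimulus-on volumes for one run."""
        phase = np.arange(self.n_tr) % self.cycle_tr
        return (phase < self.block_tr).astype(float)


@dataclass
class GroundTruth:
    """Generator-side truth stored alongside synthetic data; never consumed
    by analysis stages."""

    coupling_gain: dict  # (bin, condition) -> gain
    evoked_amplitude: np.ndarray  # per node
    dcm_params_true: Optional[dict] = None


@dataclass
class Dataset:
    """Per-subject data: per-run V1 node x time BOLD, downstream area series,
    nuisance regressors, and run condition labels.

    ``purpose`` distinguishes main experimental runs from the independent
    localizer runs reserved for ROI definition.
    """

    bold: list  # list of (n_nodes, n_tr) arrays
    nuisance: list  # list of (n_tr, 8) arrays
    downstream: dict  # area -> list of (n_tr,) arrays
    condition: list  # per-run condition label
    purpose: list  # per-run "main" | "localizer"
    geometry: VertexGeometry
    design: DesignSpec
    subject_id: str = "sub-00"
    ground_truth: Optional[GroundTruth] = None

    def __post_init__(self):
        n_runs = len(self.bold)
        if not (len(self.nuisance) == len(self.condition) == len(self.purpose) == n_runs):
            raise ValueError("per-run lists must have equal length")
        for area, runs in self.downstream.items():
            if len(runs) != n_runs:
                raise ValueError(f"downstream area {area!r} run count mismatch")
        t = self.design.n_tr
        for i, (b, nu) in enumerate(zip(self.bold, self.nuisance)):
            if b.shape[1] != t or nu.shape[0] != t:
                raise ValueError(f"run {i}: time axis does not match design")
            if not (np.isfinite(b).all() and np.isfinite(nu).all()):
                raise ValueError(f"run {i}: non-finite values")

    @property
    def n_runs(self) -> int:
        return len(self.bold)

    @property
    def areas(self) -> tuple:
        return tuple(self.downstream.keys())

    def run_indices(self, condition: str = None, purpose: str = "main") -> list:
        out = []
        for i in range(self.n_runs):
            if purpose is not None and self.purpose[i] != purpose:
                continue
            if condition is not None and self.condition[i] != condition:
                continue
            out.append(i)
        return out


@dataclass
class StatResult:
    """One inferential test result: F or t statistic with its df and p,
    and an optional FDR-adjusted q."""

    name: str
    kind: str  # "t" | "F"
    statistic: float
    df: tuple  # (df,) for t, (df1, df2) for F
    p: float
    q: Optional[float] = None
    note: str = ""

    def __str__(self):
        df = ",".join(str(d) for d in self.df)
        s = f"{self.name}: {self.kind}({df}) = {self.statistic:.3f}, p = {self.p:.4g}"
        if self.q is not None:
            s += f", q = {self.q:.4g}"
        return s
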