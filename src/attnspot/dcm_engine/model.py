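"""Bilinear DCM model specification: nodes, connection masks, inputs, priors.

The neuronal state equation is dz/dt = (A + sum_j u_j B_j) z + C u, with
intrinsic coupling A (Hz), input-dependent modulation B and driving gains
C, coupled to a balloon hemodynamic model per node. Candidate structures
share A and C and differ only in which B entries are free:

* feedforward — attention modulates V1 -> extrastriate connections,
* feedback — extrastriate -> V1 connections,
* recurrent — the union of both;

all structures additionally free the lateral V1_S <-> V1_NS modulations.
Input u1 is the stimulus boxcar driving V1_S; u2 indicates stimulus blocks
of focal-attention runs over the concatenated session.

Matrix convention: entry (i, j) couples source node j to target node i.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core import DesignSpec

NODES_5 = ("V1_S", "V1_NS", "V2", "V3", "V4")
NODES_3 = ("V1_S", "V1_NS", "EX")
STRUCTURES = ("feedforward", "feedback", "recurrent")

# fixed hemodynamic constants (per-node decay kappa and transit tau are free,
# log-scaled around these means)
GAMMA = 0.41   # autoregulation (1/s)
ALPHA = 0.32   # vessel stiffness (Grubb exponent)
E0 = 0.34      # resting oxygen extraction fraction
V0 = 0.04      # resting venous blood volume fraction
KAPPA0 = 0.64  # signal decay prior mean (1/s)
TAU0 = 2.0     # transit time prior mean (s)
K1 = 7.0 * E0
K2 = 2.0
K3 = 2.0 * E0 - 0.2
SELF_SCALE = -0.5  # self-connections are -0.5 * exp(theta) Hz


@dataclass
class DCMModel:
    """A candidate model: masks, inputs, priors, and the parameter packing."""

    nodes: tuple
    structure: str
    a_mask: np.ndarray  # (n, n) bool, free off-diagonal A entries
    b_mask: np.ndarray  # (n, n, n_u) bool
    c_mask: np.ndarray  # (n, n_u) bool
    u: np.ndarray       # (n_u, T) inputs on the concatenated TR grid
    tr: float
    run_slices: list    # per-run slices into the concatenated time axis
    param_names: list = field(default_factory=list)
    prior_mean: np.ndarray = None
    prior_var: np.ndarray = None

    def __post_init__(self):
        if not self.param_names:
            self._build_packing()

    # -- parameter packing ---------------------------------------------------
    def _build_packing(self):
        n = len(self.nodes)
        names, mean, var = [], [], []
        for i in range(n):
            for j in range(n):
                if i != j and self.a_mask[i, j]:
                    names.append(f"A:{self.nodes[i]}<-{self.nodes[j]}")
                    mean.append(0.0)
                    var.append(1.0 / 16)
        for i in range(n):
            names.append(f"Aself:{self.nodes[i]}")
            mean.append(0.0)
            var.append(1.0 / 256)
        for k in range(self.u.shape[0]):
            for i in range(n):
                for j in range(n):
                    if self.b_mask[i, j, k]:
                        names.append(f"B{k + 1}:{self.nodes[i]}<-{self.nodes[j]}")
                        mean.append(0.0)
                        var.append(1.0 / 16)
        for k in range(self.u.shape[0]):
            for i in range(n):
                if self.c_mask[i, k]:
                    names.append(f"C{k + 1}:{self.nodes[i]}")
                    mean.append(0.0)
                    var.append(1.0)
        for i in range(n):
            names.append(f"kappa:{self.nodes[i]}")
            mean.append(0.0)
            var.append(0.01)
        for i in range(n):
            names.append(f"tau:{self.nodes[i]}")
            mean.append(0.0)
            var.append(0.01)
        self.param_names = names
        self.prior_mean = np.array(mean)
        self.prior_var = np.array(var)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def param_index(self, name: str) -> int:
        return self.param_names.index(name)

    def pack(self, values: dict) -> np.ndarray:
        """Parameter vector from a {name: value} mapping; unnamed entries
        stay at the prior mean. A/B/C values are given in Hz (Aself as the
        log-scale deviation)."""
        theta = self.prior_mean.copy()
        for k, v in values.items():
            theta[self.param_index(k)] = v
        return theta

    def unpack(self, theta: np.ndarray):
        """Expand a parameter vector into (A, B, C, kappa, tau)."""
        n = len(self.nodes)
        n_u = self.u.shape[0]
        theta = np.asarray(theta, float)
        A = np.zeros((n, n))
        B = np.zeros((n, n, n_u))
        C = np.zeros((n, n_u))
        kappa = np.zeros(n)
        tau = np.zeros(n)
        pos = 0
        for i in range(n):
            for j in range(n):
                if i != j and self.a_mask[i, j]:
                    A[i, j] = theta[pos]
                    pos += 1
        for i in range(n):
            A[i, i] = SELF_SCALE * np.exp(theta[pos])
            pos += 1
        for k in range(n_u):
            for i in range(n):
                for j in range(n):
                    if self.b_mask[i, j, k]:
                        B[i, j, k] = theta[pos]
                        pos += 1
        for k in range(n_u):
            for i in range(n):
                if self.c_mask[i, k]:
                    C[i, k] = theta[pos]
                    pos += 1
        for i in range(n):
            kappa[i] = KAPPA0 * np.exp(theta[pos])
            pos += 1
        for i in range(n):
            tau[i] = TAU0 * np.exp(theta[pos])
            pos += 1
        assert pos == self.n_params
        return A, B, C, kappa, tau


def build_inputs(design: DesignSpec, run_conditions, mean_center_attention: bool = False):
    """Concatenated-session inputs: u1 = stimulus boxcar in every run,
    u2 = stimulus boxcar restricted to focal-attention runs.

    Returns (u, run_slices) with u of shape (2, n_runs * n_tr).
    """
    box = design.stimulus_boxcar()
    n_tr = design.n_tr
    u1, u2, slices = [], [], []
    for r, cond in enumerate(run_conditions):
        u1.append(box)
        u2.append(box if cond == "focal" else np.zeros(n_tr))
        slices.append(slice(r * n_tr, (r + 1) * n_tr))
    u = np.vstack([np.concatenate(u1), np.concatenate(u2)])
    if mean_center_attention:
        u[1] = u[1] - u[1].mean()
    return u, slices


def _node_groups(nodes):
    v1 = [i for i, nm in enumerate(nodes) if nm.startswith("V1")]
    ex = [i for i in range(len(nodes)) if i not in v1]
    if len(v1) != 2 or not ex:
        raise ValueError("nodes must contain V1_S, V1_NS and at least one extrastriate area")
    s = nodes.index("V1_S")
    ns = nodes.index("V1_NS")
    return s, ns, ex


def specify_model(
    structure: str,
    design: DesignSpec,
    run_conditions,
    nodes=NODES_5,
    mean_center_attention: bool = False,
) -> DCMModel:
    """Build one of the three candidate models.

    Intrinsic connections (shared by all structures): bidirectional links
    between each V1 subregion and every extrastriate node, the lateral
    V1_S <-> V1_NS pair, and self-connections; no extrastriate-extrastriate
    links. The driving input u1 enters V1_S only.
    """
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}")
    nodes = tuple(nodes)
    n = len(nodes)
    s, ns, ex = _node_groups(nodes)

    a_mask = np.zeros((n, n), dtype=bool)
    for k in ex:
        for v in (s, ns):
            a_mask[k, v] = True  # V1 -> extrastriate
            a_mask[v, k] = True  # extrastriate -> V1
    a_mask[s, ns] = a_mask[ns, s] = True

    u, run_slices = build_inputs(design, run_conditions, mean_center_attention)
    b_mask = np.zeros((n, n, u.shape[0]), dtype=bool)
    lateral = [(s, ns), (ns, s)]
    if structure in ("feedforward", "recurrent"):
        for k in ex:
            b_mask[k, s, 1] = b_mask[k, ns, 1] = True
    if structure in ("feedback", "recurrent"):
        for k in ex:
            b_mask[s, k, 1] = b_mask[ns, k, 1] = True
    for i, j in lateral:
        b_mask[i, j, 1] = True

    c_mask = np.zeros((n, u.shape[0]), dtype=bool)
    c_mask[s, 0] = True

    return DCMModel(
        nodes=nodes,
        structure=structure,
        a_mask=a_mask,
        b_mask=b_mask,
        c_mask=c_mask,
        u=u,
        tr=design.tr,
        run_slices=run_slices,
    )
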