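"""Synthetic retinotopic BOLD cohorts with known ground truth.

The generative model mirrors what the background-connectivity analysis
assumes: per run, each V1 node's signal is the sum of (i) a stimulus-evoked
response (boxcar convolved with a double-gamma HRF, confined to nodes whose
receptive fields fall inside the stimulus footprint), (ii) a shared latent
low-frequency "background" fluctuation g(t) injected with a node-specific
gain that depends on the node's eccentricity bin and the run's attention
condition, (iii) nuisance contamination (six motion-like regressors plus
white-matter and ventricle proxies) and (iv) iid Gaussian noise scaled by
the requested signal-to-noise ratio. The same latent g(t) enters every
downstream area's series with unit gain, so bin-level background
connectivity reduces to a gain-weighted shared-variance fraction.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage, signal

from .core import (
    BIN_4_6,
    BIN_6_8,
    BIN_8_10,
    BIN_STIM,
    BINS,
    CONDITIONS,
    DIFFUSED,
    DOWNSTREAM_AREAS,
    FOCAL,
    Dataset,
    DesignSpec,
    GroundTruth,
    VertexGeometry,
)
from .hrf import double_gamma_hrf

#: stimulus footprint: a Gabor array centered at 2.5 deg eccentricity on the
#: horizontal meridian; 0.75 deg spacing plus 0.3125 deg Gabor radius gives
#: a disc of radius ~1.5 deg
STIM_CENTER_ECC = 2.5
STIM_RADIUS = 1.5

#: generating coupling profiles per scenario: (bin, condition) -> gain.
#: weak_crowding reproduces the focal-attention center-enhancement /
#: surround-suppression gradient; strong_crowding keeps a graded field
#: profile but no attention effect; null has no effects at all.
SCENARIO_PROFILES = {
    "weak_crowding": {
        (BIN_STIM, FOCAL): 0.6,
        (BIN_4_6, FOCAL): 0.15,
        (BIN_6_8, FOCAL): 0.15,
        (BIN_8_10, FOCAL): 0.3,
        (BIN_STIM, DIFFUSED): 0.35,
        (BIN_4_6, DIFFUSED): 0.35,
        (BIN_6_8, DIFFUSED): 0.35,
        (BIN_8_10, DIFFUSED): 0.35,
    },
    "strong_crowding": {
        (BIN_STIM, FOCAL): 0.5,
        (BIN_4_6, FOCAL): 0.25,
        (BIN_6_8, FOCAL): 0.25,
        (BIN_8_10, FOCAL): 0.3,
        (BIN_STIM, DIFFUSED): 0.5,
        (BIN_4_6, DIFFUSED): 0.25,
        (BIN_6_8, DIFFUSED): 0.25,
        (BIN_8_10, DIFFUSED): 0.3,
    },
    "null": {(b, c): 0.35 for b in BINS for c in CONDITIONS},
}


def _visual_field_xy(ecc, polar):
    rad = np.deg2rad(polar)
    return ecc * np.cos(rad), ecc * np.sin(rad)


def in_stimulus_disc(ecc, polar) -> np.ndarray:
    x, y = _visual_field_xy(np.asarray(ecc, float), np.asarray(polar, float))
    return np.hypot(x - STIM_CENTER_ECC, y) <= STIM_RADIUS


def make_geometry(n_vertices: int, ecc_max: float = 12.0, seed: int = 0) -> VertexGeometry:
    """Sample node coordinates covering the visual field out to ``ecc_max``.

    Sampling is stratified so every analysis region is populated: one
    stratum per 2-deg eccentricity ring (polar angle uniform over the
    circle, with the 4-10 deg rings splitting half their quota into the
    +/-10 deg horizontal-meridian band the peripheral ROIs live in) plus a
    dedicated stratum inside the stimulus disc.
    """
    if n_vertices < 50:
        raise ValueError("need at least 50 vertices")
    if ecc_max < 10:
        raise ValueError("ecc_max must reach at least 10 deg")
    rng = np.random.default_rng(seed)
    rings = [(lo, min(lo + 2.0, ecc_max)) for lo in np.arange(0.0, ecc_max, 2.0)]
    n_strata = len(rings) + 1
    quota = np.full(n_strata, n_vertices // n_strata)
    quota[: n_vertices - quota.sum()] += 1

    ecc_parts, pol_parts = [], []
    # stimulus-disc stratum: uniform by area inside the footprint
    m = quota[0]
    r = STIM_RADIUS * np.sqrt(rng.uniform(size=m))
    th = rng.uniform(0, 2 * np.pi, size=m)
    x = STIM_CENTER_ECC + r * np.cos(th)
    y = r * np.sin(th)
    ecc_parts.append(np.hypot(x, y))
    pol_parts.append(np.rad2deg(np.arctan2(y, x)))

    for q, (lo, hi) in zip(quota[1:], rings):
        ecc = rng.uniform(lo, hi, size=q)
        if lo >= 4.0 and hi <= 10.0:
            # half on the horizontal-meridian band, half anywhere
            n_band = q // 2
            pol = np.concatenate(
                [
                    rng.uniform(-10.0, 10.0, size=n_band),
                    rng.uniform(-180.0, 180.0, size=q - n_band),
                ]
            )
        else:
            pol = rng.uniform(-180.0, 180.0, size=q)
        ecc_parts.append(ecc)
        pol_parts.append(pol)

    ecc = np.concatenate(ecc_parts)
    pol = np.concatenate(pol_parts)
    pol[pol <= -180.0] += 360.0  # fold onto (-180, 180]
    geom = VertexGeometry(
        eccentricity=ecc,
        polar_angle=pol,
        is_stimulated_truth=in_stimulus_disc(ecc, pol),
    )
    counts = {
        BIN_STIM: int(geom.is_stimulated_truth.sum()),
        BIN_4_6: int(np.sum((ecc >= 4) & (ecc < 6) & (np.abs(pol) <= 10))),
        BIN_6_8: int(np.sum((ecc >= 6) & (ecc < 8) & (np.abs(pol) <= 10))),
        BIN_8_10: int(np.sum((ecc >= 8) & (ecc <= 10) & (np.abs(pol) <= 10))),
    }
    for name, c in counts.items():
        if c == 0:
            raise ValueError(f"n_vertices too small: analysis bin {name!r} is empty")
    return geom


def generation_bins(geometry: VertexGeometry) -> np.ndarray:
    """Ground-truth bin of each node for gain assignment: the stimulus disc,
    else the node's eccentricity bin (ignoring polar angle — the latent
    coupling field varies over eccentricity), else none."""
    ecc = geometry.eccentricity
    labels = np.full(geometry.n_nodes, "none", dtype=object)
    labels[(ecc >= 4) & (ecc < 6)] = BIN_4_6
    labels[(ecc >= 6) & (ecc < 8)] = BIN_6_8
    labels[(ecc >= 8) & (ecc <= 10)] = BIN_8_10
    labels[geometry.is_stimulated_truth] = BIN_STIM
    return labels


from functools import lru_cache


@lru_cache(maxsize=16)
def _lowpass_coeffs(tr: float, cutoff_hz: float):
    nyq = 0.5 / tr
    return signal.butter(4, min(cutoff_hz / nyq, 0.99), btype="low")


def _latent_fluctuation(rng, n_tr, tr, cutoff_hz):
    """Temporally filtered white noise, standardized: the shared background
    source."""
    w = rng.standard_normal(n_tr)
    b, a = _lowpass_coeffs(tr, cutoff_hz)
    g = signal.filtfilt(b, a, w)
    g = g - g.mean()
    sd = g.std()
    return g / sd if sd > 0 else g


def _nuisance_regressors(rng, n_tr, tr):
    """Eight standardized nuisance series: six motion-like smoothed random
    walks plus two low-frequency sinusoids (white-matter, ventricle)."""
    cols = []
    for _ in range(6):
        walk = np.cumsum(rng.standard_normal(n_tr))
        walk = ndimage.gaussian_filter1d(walk, sigma=3.0)
        walk = walk - walk.mean()
        cols.append(walk / max(walk.std(), 1e-12))
    t = np.arange(n_tr) * tr
    for _ in range(2):
        f = rng.uniform(0.005, 0.02)
        phase = rng.uniform(0, 2 * np.pi)
        s = np.sin(2 * np.pi * f * t + phase)
        s = s - s.mean()
        cols.append(s / max(s.std(), 1e-12))
    return np.column_stack(cols)


def simulate_subject(
    geometry: VertexGeometry,
    design: DesignSpec,
    coupling_profile: dict,
    snr: float,
    seed: int,
    evoked_amplitude: float = 1.0,
    nuisance_weight_sd: float = 0.5,
    latent_cutoff_hz: float = 0.1,
    latent_lag_tr: int = 0,
    n_localizer_runs: int = 2,
    subject_id: str = "sub-00",
):
    """Simulate one subject's Dataset (main runs for both conditions plus
    independent localizer runs) with its GroundTruth record.

    ``coupling_profile`` maps (bin, condition) to the latent-coupling gain.
    ``snr`` is the ratio of total deterministic+latent signal SD to the iid
    noise SD (np.inf for noise-free data); localizer runs are generated with
    the diffused-condition gains.
    """
    if not (snr > 0):
        raise ValueError("snr must be positive")
    for b in BINS:
        for c in CONDITIONS:
            if (b, c) not in coupling_profile:
                raise ValueError(f"coupling_profile missing key ({b!r}, {c!r})")
    rng = np.random.default_rng(seed)
    n_nodes = geometry.n_nodes
    n_tr = design.n_tr
    areas = DOWNSTREAM_AREAS

    amp = np.where(geometry.is_stimulated_truth, evoked_amplitude, 0.0)
    hrf = double_gamma_hrf(design.tr)
    # steady-state (periodic) response: convolve a periodic extension of the
    # boxcar and keep a segment past the HRF transient, so the evoked signal
    # is exactly cycle-locked from the first volume
    cyc = design.cycle_tr
    pad_cycles = int(np.ceil(hrf.size / cyc)) + 1
    boxcar_ext = np.tile(design.stimulus_boxcar()[:cyc], design.n_cycles + pad_cycles)
    evoked_shape = np.convolve(boxcar_ext, hrf)[pad_cycles * cyc:][:n_tr]
    evoked = amp[:, None] * evoked_shape[None, :]
    area_evoked = 1.0 * evoked_shape

    bins = generation_bins(geometry)
    w_node = rng.normal(0.0, nuisance_weight_sd, size=(n_nodes, 8))
    w_area = {a: rng.normal(0.0, nuisance_weight_sd, size=8) for a in areas}

    run_conditions = []
    run_purposes = []
    for cond in CONDITIONS:
        run_conditions += [cond] * design.n_runs_per_condition
        run_purposes += ["main"] * design.n_runs_per_condition
    run_conditions += [DIFFUSED] * n_localizer_runs
    run_purposes += ["localizer"] * n_localizer_runs

    bold, nuisance, downstream = [], [], {a: [] for a in areas}
    for cond in run_conditions:
        gain = np.array(
            [coupling_profile[(b, cond)] if b != "none" else 0.0 for b in bins]
        )
        g = _latent_fluctuation(rng, n_tr, design.tr, latent_cutoff_hz)
        g_v1 = np.roll(g, latent_lag_tr) if latent_lag_tr else g
        nuis = _nuisance_regressors(rng, n_tr, design.tr)
        sig = evoked + gain[:, None] * g_v1[None, :] + w_node @ nuis.T
        sig_areas = {a: area_evoked + g + nuis @ w_area[a] for a in areas}
        if np.isinf(snr):
            sigma = 0.0
        else:
            sigma = np.sqrt(np.var(sig)) / snr
        y = sig + (sigma * rng.standard_normal(sig.shape) if sigma else 0.0)
        bold.append(y)
        nuisance.append(nuis)
        for a in areas:
            ya = sig_areas[a] + (sigma * rng.standard_normal(n_tr) if sigma else 0.0)
            downstream[a].append(ya)

    truth = GroundTruth(coupling_gain=dict(coupling_profile), evoked_amplitude=amp)
    ds = Dataset(
        bold=bold,
        nuisance=nuisance,
        downstream=downstream,
        condition=run_conditions,
        purpose=run_purposes,
        geometry=geometry,
        design=design,
        subject_id=subject_id,
        ground_truth=truth,
    )
    return ds, truth


def subject_seed(master_seed: int, subject_index: int) -> int:
    """Deterministic per-subject seed below 2**31."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(subject_index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def make_cohort(
    n_subjects: int,
    scenario: str,
    seed: int,
    design: DesignSpec = None,
    n_vertices: int = 300,
    ecc_max: float = 12.0,
    snr: float = 1.0,
    **subject_kwargs,
):
    """Simulate a cohort of subjects under a named crowding scenario.

    Scenarios fix the generating coupling profiles (see
    ``SCENARIO_PROFILES``); per-subject seeds derive deterministically from
    the master seed; each subject gets its own sampled geometry.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if scenario not in SCENARIO_PROFILES:
        raise ValueError(f"unknown scenario {scenario!r}")
    design = design or DesignSpec()
    profile = SCENARIO_PROFILES[scenario]
    cohort = []
    for i in range(n_subjects):
        s = subject_seed(seed, i)
        geom = make_geometry(n_vertices, ecc_max, seed=s)
        ds, _ = simulate_subject(
            geom,
            design,
            profile,
            snr=snr,
            seed=s + 1,
            subject_id=f"sub-{i:02d}",
            **subject_kwargs,
        )
        cohort.append(ds)
    return cohort


def simulate_dcm_timeseries(model, params, snr: float, seed: int):
    """Generate node-wise BOLD from the bilinear DCM forward model.

    ``params`` is a free-parameter vector in the model's packing (see
    ``dcm_engine``); iid Gaussian observation noise is scaled so that the
    signal SD / noise SD ratio equals ``snr``. Fails before integration if
    the neuronal coupling matrix is unstable at ``params``.
    """
    from .dcm_engine import forward

    if not (snr > 0):
        raise ValueError("snr must be positive")
    A, B, _, _, _ = model.unpack(np.asarray(params, float))[:5]
    # the effective coupling A + sum_j u_j B_j must be stable for every
    # input combination the design realizes, else trajectories grow through
    # entire blocks
    for u_t in np.unique(model.u.T, axis=0):
        M = A + np.tensordot(B, u_t, axes=([2], [0]))
        if np.any(np.linalg.eigvals(M).real >= 0):
            raise ValueError(
                "unstable effective coupling matrix A + u.B at input "
                f"{u_t.tolist()} (eigenvalue with non-negative real part)"
            )
    traj = forward(model, params)
    y = traj.y
    rng = np.random.default_rng(seed)
    sigma = 0.0 if np.isinf(snr) else np.sqrt(np.var(y)) / snr
    noisy = y + (sigma * rng.standard_normal(y.shape) if sigma else 0.0)
    truth = GroundTruth(
        coupling_gain={},
        evoked_amplitude=np.zeros(len(model.nodes)),
        dcm_params_true={"params": np.asarray(params, float).copy(), "sigma": sigma},
    )
    return noisy, truth


def dcm_truth_params(
    model,
    b_s: float = 0.3,
    b_ns: float = -0.2,
    driving: float = 1.0,
    a_forward: float = 0.2,
    a_backward: float = 0.1,
    a_lateral: float = 0.05,
    a_self_log: float = 0.2,
    jitter_sd: float = 0.0,
    rng=None,
):
    """Generating parameter vector for a DCM truth model.

    Modulatory entries on pathways involving V1_S get ``b_s`` and those
    involving V1_NS get ``b_ns`` (only where the structure frees them);
    lateral modulation follows the same rule by connection origin.
    Optional Gaussian jitter on A and B entries emulates between-subject
    heterogeneity.
    """
    rng = rng or np.random.default_rng(0)
    values = {}
    s, ns = "V1_S", "V1_NS"
    ex = [nm for nm in model.nodes if not nm.startswith("V1")]
    for k in ex:
        values[f"A:{k}<-{s}"] = a_forward
        values[f"A:{k}<-{ns}"] = a_forward
        values[f"A:{s}<-{k}"] = a_backward
        values[f"A:{ns}<-{k}"] = a_backward
    values[f"A:{s}<-{ns}"] = a_lateral
    values[f"A:{ns}<-{s}"] = a_lateral
    # slightly stronger-than-prior self-inhibition (-0.5*exp(a_self_log) Hz)
    # keeps the modulated coupling comfortably stable at the +0.3 Hz
    # S-pathway modulation
    for nm in model.nodes:
        values[f"Aself:{nm}"] = a_self_log
    values[f"C1:{s}"] = driving
    # S-pathway entries involve V1_S, NS-pathway entries involve V1_NS; the
    # lateral within-V1 pair is classified by its source node
    for name in model.param_names:
        if not name.startswith("B2:"):
            continue
        target, source = name[3:].split("<-")
        if {target, source} == {s, ns}:
            values[name] = b_s if source == s else b_ns
        elif s in (target, source):
            values[name] = b_s
        else:
            values[name] = b_ns
    if jitter_sd > 0:
        for name in list(values):
            if name.startswith(("A:", "B2:")):
                values[name] += rng.normal(0.0, jitter_sd)
    return model.pack(values)


def make_dcm_cohort(
    n_subjects: int,
    truth_structure: str,
    design: DesignSpec,
    seed: int,
    nodes=None,
    snr: float = 2.0,
    b_s: float = 0.3,
    b_ns: float = -0.2,
    jitter_sd: float = 0.05,
):
    """Simulate a DCM cohort: per subject, concatenated-session BOLD
    generated from ``truth_structure`` with subject-specific jitter on the
    coupling parameters. Returns (list of (data, truth), run_conditions).
    """
    from .dcm_engine import NODES_3, specify_model

    nodes = tuple(nodes) if nodes is not None else NODES_3
    run_conditions = [FOCAL] * design.n_runs_per_condition + [
        DIFFUSED
    ] * design.n_runs_per_condition
    truth_model = specify_model(truth_structure, design, run_conditions, nodes=nodes)
    out = []
    for i in range(n_subjects):
        s = subject_seed(seed, i)
        rng = np.random.default_rng(s)
        # redraw subject jitter (deterministically, from the same stream) in
        # the rare case a tail draw destabilizes the modulated coupling
        for _ in range(20):
            params = dcm_truth_params(
                truth_model, b_s=b_s, b_ns=b_ns, jitter_sd=jitter_sd, rng=rng
            )
            try:
                y, truth = simulate_dcm_timeseries(
                    truth_model, params, snr=snr, seed=s + 1
                )
                break
            except ValueError:
                continue
        else:
            raise ValueError("could not draw stable subject parameters")
        out.append((y, truth))
    return out, run_conditions
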