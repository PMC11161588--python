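"""Fixture file formats, configuration, and the end-to-end pipeline driver.

The canonical on-disk format is HDF5 (the analysis is node-based and
surface/volume agnostic); NIfTI and GIFTI are import-only adapters for real
data. Layout::

    /bold/run_<i>            node x time
    /downstream/<area>/run_<i>
    /nuisance/run_<i>        time x 8
    /geometry                node table (eccentricity, polar_angle, truth flag)
    /design                  attributes (tr, block_s, fix_s, n_cycles, ...)
    /condition, /purpose     per-run labels
    /ground_truth            optional generator record
"""
from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attnfield, bgconn, residualize, retinomap, synthgen
from .core import BINS, CONDITIONS, Dataset, DesignSpec, GroundTruth, VertexGeometry

FORMAT_VERSION = 1
_KNOWN_GROUPS = {
    "bold", "downstream", "nuisance", "geometry", "design", "condition",
    "purpose", "ground_truth",
}


# ---------------------------------------------------------------------------
# HDF5 round-trip
# ---------------------------------------------------------------------------

def write_dataset(path, ds: Dataset):
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["subject_id"] = ds.subject_id
        gb = f.create_group("bold")
        gn = f.create_group("nuisance")
        for i in range(ds.n_runs):
            gb.create_dataset(f"run_{i}", data=ds.bold[i])
            gn.create_dataset(f"run_{i}", data=ds.nuisance[i])
        gd = f.create_group("downstream")
        for area, runs in ds.downstream.items():
            ga = gd.create_group(area)
            for i, r in enumerate(runs):
                ga.create_dataset(f"run_{i}", data=r)
        gg = f.create_group("geometry")
        gg.create_dataset("eccentricity", data=ds.geometry.eccentricity)
        gg.create_dataset("polar_angle", data=ds.geometry.polar_angle)
        gg.create_dataset("is_stimulated_truth", data=ds.geometry.is_stimulated_truth)
        gdes = f.create_group("design")
        for k, v in asdict(ds.design).items():
            gdes.attrs[k] = v
        str_dt = "S32"
        f.create_dataset("condition", data=np.array(ds.condition, dtype=str_dt))
        f.create_dataset("purpose", data=np.array(ds.purpose, dtype=str_dt))
        if ds.ground_truth is not None:
            gt = f.create_group("ground_truth")
            gt.create_dataset("evoked_amplitude", data=ds.ground_truth.evoked_amplitude)
            keys = [f"{b}|{c}" for (b, c) in ds.ground_truth.coupling_gain]
            vals = [ds.ground_truth.coupling_gain[k] for k in ds.ground_truth.coupling_gain]
            gt.create_dataset("coupling_keys", data=np.array(keys, dtype=str_dt))
            gt.create_dataset("coupling_values", data=np.array(vals, dtype=float))


def read_dataset(path) -> Dataset:
    import h5py

    with h5py.File(path, "r") as f:
        for grp in ("bold", "downstream", "nuisance", "geometry", "design",
                    "condition", "purpose"):
            if grp not in f:
                raise KeyError(f"dataset file is missing required group /{grp}")
        extra = set(f.keys()) - _KNOWN_GROUPS
        if extra:
            warnings.warn(f"ignoring unknown groups {sorted(extra)}", RuntimeWarning)
        design = DesignSpec(**{k: v for k, v in f["design"].attrs.items()})
        condition = [c.decode() for c in f["condition"][:]]
        purpose = [c.decode() for c in f["purpose"][:]]
        n_runs = len(condition)
        bold, nuisance = [], []
        for i in range(n_runs):
            for grp in ("bold", "nuisance"):
                if f"run_{i}" not in f[grp]:
                    raise KeyError(f"dataset file is missing /{grp}/run_{i}")
            bold.append(f["bold"][f"run_{i}"][:])
            nuisance.append(f["nuisance"][f"run_{i}"][:])
        downstream = {}
        for area in f["downstream"]:
            downstream[area] = [f["downstream"][area][f"run_{i}"][:] for i in range(n_runs)]
        geometry = VertexGeometry(
            eccentricity=f["geometry"]["eccentricity"][:],
            polar_angle=f["geometry"]["polar_angle"][:],
            is_stimulated_truth=f["geometry"]["is_stimulated_truth"][:],
        )
        truth = None
        if "ground_truth" in f:
            gt = f["ground_truth"]
            coupling = {}
            for k, v in zip(gt["coupling_keys"][:], gt["coupling_values"][:]):
                b, c = k.decode().split("|")
                coupling[(b, c)] = float(v)
            truth = GroundTruth(
                coupling_gain=coupling, evoked_amplitude=gt["evoked_amplitude"][:]
            )
        return Dataset(
            bold=bold,
            nuisance=nuisance,
            downstream=downstream,
            condition=condition,
            purpose=purpose,
            geometry=geometry,
            design=design,
            subject_id=str(f.attrs.get("subject_id", "sub-00")),
            ground_truth=truth,
        )


# ---------------------------------------------------------------------------
# neuroimaging import adapters
# ---------------------------------------------------------------------------

def import_neuroimaging(
    bold_paths,
    nuisance_paths,
    conditions,
    design: DesignSpec,
    mask_path=None,
    geometry=None,
    surface_metric_paths=None,
    downstream=None,
    subject_id="sub-00",
) -> Dataset:
    """Build a Dataset from volumetric NIfTI (with a voxel mask) or surface
    GIFTI runs (with per-vertex eccentricity/polar-angle metric files).

    Nuisance series are supplied as whitespace-delimited text, time x 8.
    """
    import nibabel as nib

    bold = []
    for p in bold_paths:
        p = str(p)
        img = nib.load(p)
        if p.endswith(".gii"):
            data = np.column_stack([d.data for d in img.darrays])  # vertex x time
        else:
            if mask_path is None:
                raise ValueError("volumetric import requires a mask")
            vol = np.asarray(img.dataobj)
            mask = np.asarray(nib.load(str(mask_path)).dataobj).astype(bool)
            if mask.shape != vol.shape[:3]:
                raise ValueError("mask shape does not match the BOLD volume")
            data = vol[mask]  # voxel x time
        if data.shape[1] != design.n_tr:
            raise ValueError(
                f"run {p}: {data.shape[1]} volumes but the design implies {design.n_tr}"
            )
        bold.append(np.asarray(data, float))

    if geometry is None:
        if surface_metric_paths is None:
            raise ValueError("provide either a geometry or surface metric files")
        ecc = np.concatenate([d.data for d in nib.load(str(surface_metric_paths["eccentricity"])).darrays])
        pol = np.concatenate([d.data for d in nib.load(str(surface_metric_paths["polar_angle"])).darrays])
        if ecc.size != bold[0].shape[0] or pol.size != bold[0].shape[0]:
            raise ValueError("metric vertex count does not match the BOLD series")
        geometry = VertexGeometry(
            eccentricity=ecc, polar_angle=pol,
            is_stimulated_truth=np.zeros(ecc.size, dtype=bool),
        )

    nuisance = []
    for p in nuisance_paths:
        arr = np.loadtxt(str(p))
        if arr.ndim != 2 or arr.shape != (design.n_tr, 8):
            raise ValueError(f"nuisance file {p}: expected shape ({design.n_tr}, 8)")
        nuisance.append(arr)

    downstream = downstream or {}
    purpose = ["main"] * len(bold)
    return Dataset(
        bold=bold, nuisance=nuisance, downstream=downstream,
        condition=list(conditions), purpose=purpose,
        geometry=geometry, design=design, subject_id=subject_id,
    )


# ---------------------------------------------------------------------------
# configuration and pipeline driver
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 7,
    "scenario": "weak_crowding",
    "n_subjects": 8,
    "n_vertices": 300,
    "snr": 1.0,
    "design": {},             # DesignSpec overrides
    "highpass_s": 100.0,
    "remove_evoked": True,
    "aggregation": "per_run_z_mean",
    "localizer_alpha": 0.01,
    "stages": {"connectivity": True, "dcm": False, "field": True},
    "dcm": {"nodes": "3node", "snr": 2.0, "n_subjects": 8, "b_s": 0.3, "b_ns": -0.2,
            "n_runs_per_condition": 2, "n_cycles": 10, "truth_structure": "recurrent",
            "max_iter": 64, "mc_draws": 100000},
    "field": {"bin_width": 1.0, "ecc_max": 10.0},
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def analyze_subject(ds: Dataset, cfg=None):
    """Residualize -> ROIs -> connectivity profile for one subject."""
    cfg = cfg or DEFAULT_CONFIG
    res = residualize.residualize_dataset(
        ds, remove_evoked_flag=cfg["remove_evoked"], cutoff_s=cfg["highpass_s"],
        purpose_filter="main",
    )
    if "localizer" not in ds.purpose:
        raise ValueError("dataset has no localizer runs for ROI definition")
    # localizer GLM runs on nuisance-removed but evoked-retained data
    loc_res = residualize.residualize_dataset(
        ds, remove_evoked_flag=False, cutoff_s=cfg["highpass_s"],
        purpose_filter="localizer",
    )
    _, pvals = retinomap.localizer_contrast(loc_res.v1, ds.design)
    rois = retinomap.assign_rois(ds.geometry, pvals, alpha=cfg["localizer_alpha"])
    cmap = bgconn.connectivity_map(res, method=cfg["aggregation"])
    profile = bgconn.profile_by_bin(cmap, rois, subject_id=ds.subject_id)
    return res, rois, cmap, profile


def cohort_profiles(cohort, cfg=None) -> pd.DataFrame:
    return pd.concat([analyze_subject(ds, cfg)[3] for ds in cohort], ignore_index=True)


def cohort_stats(profiles: pd.DataFrame):
    """Per-area rm-ANOVA (visual field x attention) plus per-bin paired t
    contrasts (focal vs diffused), FDR-adjusted within each family."""
    tables = bgconn.profile_anova_tables(profiles)
    anova, contrasts = {}, {}
    for area, arr in tables.items():
        anova[area] = bgconn.rm_anova_2way(arr)
        tests = []
        for j, b in enumerate(BINS):
            tests.append(bgconn.paired_t(arr[:, j, 0], arr[:, j, 1], name=f"{area}_{b}"))
        bgconn.attach_fdr(tests)
        contrasts[area] = tests
    return anova, contrasts


def run_pipeline(config, out_dir):
    """Execute the configured pipeline end to end and write tidy TSVs, a
    text report, and a reproducibility manifest."""
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = json.loads(json.dumps(DEFAULT_CONFIG))
        for k, v in (config or {}).items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    design = DesignSpec(**cfg["design"])
    report_lines = [f"attnspot pipeline report (scenario={cfg['scenario']}, seed={seed})", ""]

    cohort = synthgen.make_cohort(
        cfg["n_subjects"], cfg["scenario"], seed,
        design=design, n_vertices=cfg["n_vertices"], snr=cfg["snr"],
    )

    results = {}
    if cfg["stages"]["connectivity"]:
        profiles = cohort_profiles(cohort, cfg)
        profiles.to_csv(out / "profiles.tsv", sep="\t", index=False, float_format="%.6f")
        anova, contrasts = cohort_stats(profiles)
        stat_rows = []
        report_lines.append("== background connectivity ==")
        alpha = 0.05
        any_sig_interaction = False
        for area in sorted(anova):
            for r in anova[area]:
                stat_rows.append((area, r.name, r.kind, str(r.df), r.statistic, r.p, r.q))
                report_lines.append(f"  {area} {r}")
                if "_x_" in r.name and r.p < alpha:
                    any_sig_interaction = True
            for r in contrasts[area]:
                stat_rows.append((area, r.name, r.kind, str(r.df), r.statistic, r.p, r.q))
                report_lines.append(f"  {area} contrast {r}")
        if not any_sig_interaction:
            report_lines.append("  no significant interaction at alpha=0.05")
        pd.DataFrame(
            stat_rows, columns=["area", "effect", "kind", "df", "statistic", "p", "q"]
        ).to_csv(out / "stats.tsv", sep="\t", index=False, float_format="%.6g")
        results["profiles"] = profiles
        results["anova"] = anova
        results["contrasts"] = contrasts
        report_lines.append("")

    if cfg["stages"]["dcm"]:
        from . import dcm_engine

        dcfg = cfg["dcm"]
        nodes = dcm_engine.NODES_3 if dcfg["nodes"] == "3node" else dcm_engine.NODES_5
        dcm_design = DesignSpec(
            tr=design.tr, block_s=design.block_s, fix_s=design.fix_s,
            n_cycles=dcfg["n_cycles"], n_runs_per_condition=dcfg["n_runs_per_condition"],
        )
        sims, run_conditions = synthgen.make_dcm_cohort(
            dcfg["n_subjects"], dcfg["truth_structure"], dcm_design, seed,
            nodes=nodes, snr=dcfg["snr"], b_s=dcfg["b_s"], b_ns=dcfg["b_ns"],
        )
        models = {
            s: dcm_engine.specify_model(s, dcm_design, run_conditions, nodes=nodes)
            for s in dcm_engine.STRUCTURES
        }
        F = np.zeros((len(sims), len(dcm_engine.STRUCTURES)))
        posteriors = {s: [] for s in dcm_engine.STRUCTURES}
        for i, (y, _) in enumerate(sims):
            for k, s in enumerate(dcm_engine.STRUCTURES):
                post = dcm_engine.invert(models[s], y, max_iter=dcfg["max_iter"])
                F[i, k] = post.free_energy
                posteriors[s].append(post)
        bms = dcm_engine.rfx_bms(F, n_draws=dcfg["mc_draws"], seed=seed)
        best = dcm_engine.STRUCTURES[int(np.argmax(bms.exceedance_prob))]
        tab, mod_stats = dcm_engine.modulation_group_stats(posteriors[best], models[best])
        report_lines.append("== DCM ==")
        report_lines.append("  BMS exceedance probability:")
        for s, xp in zip(dcm_engine.STRUCTURES, bms.exceedance_prob):
            report_lines.append(f"    {s}: {xp:.3f}")
        report_lines.append(f"  best model: {best}")
        for r in mod_stats:
            report_lines.append(f"  {r}")
        pd.DataFrame(
            {"structure": dcm_engine.STRUCTURES,
             "alpha": bms.dirichlet_alpha,
             "exceedance": bms.exceedance_prob}
        ).to_csv(out / "bms.tsv", sep="\t", index=False, float_format="%.6g")
        tab.to_csv(out / "modulation.tsv", sep="\t", index=False, float_format="%.6f")
        results["bms"] = bms
        results["modulation"] = (tab, mod_stats)
        report_lines.append("")

    if cfg["stages"]["field"]:
        fcfg = cfg["field"]
        estimates = {}
        for ds in cohort:
            estimates[ds.subject_id] = {
                c: attnfield.estimate_field_from_dataset(
                    ds, c, bin_width=fcfg["bin_width"], ecc_max=fcfg["ecc_max"]
                )
                for c in CONDITIONS
            }
        field_rows = [
            (s, c, est.center, est.size)
            for s, per_cond in estimates.items()
            for c, est in per_cond.items()
        ]
        field_df = pd.DataFrame(field_rows, columns=["subject", "condition",
                                                     "center_deg", "size_deg"])
        field_df.to_csv(out / "field.tsv", sep="\t", index=False, float_format="%.6f")
        field_stats = attnfield.compare_fields(estimates)
        report_lines.append("== stimulus field ==")
        for c in CONDITIONS:
            sub = field_df[field_df.condition == c]
            report_lines.append(
                f"  {c}: center {sub.center_deg.mean():.2f} deg, size {sub.size_deg.mean():.2f} deg"
            )
        for r in field_stats:
            report_lines.append(f"  {r}")
        results["field"] = (field_df, field_stats)

    (out / "report.txt").write_text("\n".join(report_lines) + "\n")
    manifest = {"config": cfg, "seed": seed, "format_version": FORMAT_VERSION,
                "outputs": sorted(p.name for p in out.iterdir())}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["report"] = "\n".join(report_lines)
    results["manifest"] = manifest
    return results
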