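"""Group statistics on the modulatory (B) parameters of the selected model.

Connections are classified by their V1 end: the "S pathway" links V1_S with
a downstream area, the "NS pathway" links V1_NS; the lateral within-V1 pair
is treated separately. Tests per family: paired t between S- and
NS-pathway modulation (per area and direction), one-sample t of each entry
against 0, a visual-field x cortical-area repeated-measures ANOVA when at
least two areas are modeled, and Benjamini-Hochberg FDR over the reported
family.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from ..bgconn import attach_fdr, one_sample_t, paired_t, rm_anova_2way
from .model import DCMModel


def modulation_table(posteriors: list, model: DCMModel) -> pd.DataFrame:
    """Tidy per-subject table of posterior-mean B entries.

    Columns: subject, direction (feedforward/feedback/lateral), area,
    visual_field (S/NS), value.
    """
    s_name, ns_name = "V1_S", "V1_NS"
    ex = [nm for nm in model.nodes if not nm.startswith("V1")]
    rows = []
    for si, post in enumerate(posteriors):
        if post.param_names != model.param_names:
            raise ValueError("posterior parameter packing does not match the model")

        def b(target, source):
            return post.get(f"B2:{target}<-{source}")

        for area in ex:
            if model.b_mask[model.nodes.index(area), model.nodes.index(s_name), 1]:
                rows.append((si, "feedforward", area, "S", b(area, s_name)))
                rows.append((si, "feedforward", area, "NS", b(area, ns_name)))
            if model.b_mask[model.nodes.index(s_name), model.nodes.index(area), 1]:
                rows.append((si, "feedback", area, "S", b(s_name, area)))
                rows.append((si, "feedback", area, "NS", b(ns_name, area)))
        rows.append((si, "lateral", "V1", "S", b(ns_name, s_name)))   # from V1_S
        rows.append((si, "lateral", "V1", "NS", b(s_name, ns_name)))  # from V1_NS
    return pd.DataFrame(rows, columns=["subject", "direction", "area", "visual_field", "value"])


def modulation_group_stats(posteriors: list, model: DCMModel):
    """Run the family of group tests on modulatory parameters.

    Returns (tidy table, list of StatResult with FDR-adjusted q).
    """
    tab = modulation_table(posteriors, model)
    results = []

    def pivot(direction, area):
        sub = tab[(tab.direction == direction) & (tab.area == area)]
        s = sub[sub.visual_field == "S"].sort_values("subject")["value"].to_numpy()
        ns = sub[sub.visual_field == "NS"].sort_values("subject")["value"].to_numpy()
        return s, ns

    for direction in ("feedforward", "feedback", "lateral"):
        for area in sorted(tab[tab.direction == direction]["area"].unique()):
            s, ns = pivot(direction, area)
            if s.size == 0:
                continue
            results.append(paired_t(s, ns, name=f"{direction}_{area}_S_vs_NS"))
            results.append(one_sample_t(s, 0.0, name=f"{direction}_{area}_S_vs_0"))
            results.append(one_sample_t(ns, 0.0, name=f"{direction}_{area}_NS_vs_0"))

    # visual field x area ANOVA per direction, when >= 2 areas carry free B
    for direction in ("feedforward", "feedback"):
        sub = tab[tab.direction == direction]
        areas = sorted(sub["area"].unique())
        if len(areas) >= 2:
            n_sub = sub["subject"].nunique()
            arr = np.empty((n_sub, 2, len(areas)))
            for i_vf, vf in enumerate(("S", "NS")):
                for i_a, area in enumerate(areas):
                    v = sub[(sub.visual_field == vf) & (sub.area == area)].sort_values("subject")
                    arr[:, i_vf, i_a] = v["value"].to_numpy()
            for r in rm_anova_2way(arr, factor_names=("visual_field", "area")):
                r.name = f"{direction}_{r.name}"
                results.append(r)

    attach_fdr(results)
    return tab, results
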