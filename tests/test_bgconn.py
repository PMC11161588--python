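import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from attnspot import bgconn
from attnspot.core import BINS, CONDITIONS, StatResult
from attnspot.residualize import ResidualSet
from attnspot.retinomap import RoiAssignment


class TestFisherZ:
    def test_matches_arctanh(self):
        r = np.array([-0.9, -0.5, 0.0, 0.3, 0.99])
        np.testing.assert_allclose(bgconn.fisher_z(r), np.arctanh(r))

    def test_clips_at_machine_limit(self):
        with pytest.warns(RuntimeWarning, match="clipping"):
            z = bgconn.fisher_z(np.array([1.0]))
        assert np.isfinite(z).all()


def _residual_set(rho, n_tr=240, n_runs_per_cond=2, seed=0):
    """Two-condition residual set where each V1 node shares variance rho**?
    with the area series: node = rho*g + sqrt(1-rho^2)*noise."""
    rng = np.random.default_rng(seed)
    v1, area = [], []
    conds, purps = [], []
    for cond in CONDITIONS:
        for _ in range(n_runs_per_cond):
            g = rng.standard_normal(n_tr)
            noise = rng.standard_normal((len(rho), n_tr))
            v1.append(np.asarray(rho)[:, None] * g + np.sqrt(1 - np.asarray(rho)[:, None] ** 2) * noise)
            area.append(g)
            conds.append(cond)
            purps.append("main")
    return ResidualSet(v1=v1, downstream={"V4": area}, condition=conds, purpose=purps)


class TestConnectivityMap:
    def test_recovers_known_correlation(self):
        rho = [0.8, 0.0]
        res = _residual_set(rho, n_tr=2000, seed=1)
        cmap = bgconn.connectivity_map(res)
        r = cmap.r("focal", "V4")
        assert r[0] == pytest.approx(0.8, abs=0.06)
        assert abs(r[1]) < 0.08

    def test_methods_agree_on_long_runs(self):
        res = _residual_set([0.6], n_tr=2000, seed=2)
        a = bgconn.connectivity_map(res, method="per_run_z_mean")
        b = bgconn.connectivity_map(res, method="concatenated")
        assert a.z[("focal", "V4")][0] == pytest.approx(b.z[("focal", "V4")][0], abs=0.05)

    def test_unknown_method(self):
        res = _residual_set([0.5])
        with pytest.raises(ValueError, match="method"):
            bgconn.connectivity_map(res, method="median")

    def test_short_runs_rejected(self):
        res = _residual_set([0.5], n_tr=20)
        with pytest.raises(ValueError, match="30"):
            bgconn.connectivity_map(res)

    def test_zero_variance_node_is_nan(self):
        res = _residual_set([0.5, 0.5], n_tr=100, seed=3)
        for run in res.v1:
            run[1] = 0.0
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            cmap = bgconn.connectivity_map(res)
        assert np.isnan(cmap.z[("focal", "V4")][1])
        assert np.isfinite(cmap.z[("focal", "V4")][0])


class TestProfileByBin:
    def test_tidy_output(self):
        res = _residual_set([0.5, 0.4, 0.3, 0.2], n_tr=100, seed=4)
        cmap = bgconn.connectivity_map(res)
        rois = RoiAssignment(labels=np.array(list(BINS), dtype=object))
        prof = bgconn.profile_by_bin(cmap, rois, subject_id="s1")
        assert set(prof.columns) == {"subject", "condition", "area", "bin", "z"}
        assert len(prof) == len(BINS) * len(CONDITIONS)  # one area
        # bin mean equals the node value when bins are singletons
        row = prof[(prof.condition == "focal") & (prof.bin == BINS[0])]
        assert row.z.iloc[0] == pytest.approx(cmap.z[("focal", "V4")][0])

    def test_empty_bin_raises(self):
        res = _residual_set([0.5], n_tr=100)
        cmap = bgconn.connectivity_map(res)
        rois = RoiAssignment(labels=np.array(["excluded"], dtype=object))
        with pytest.raises(ValueError, match="empty"):
            bgconn.profile_by_bin(cmap, rois)


class TestRmAnova:
    @pytest.fixture(scope="class")
    def table(self):
        rng = np.random.default_rng(7)
        n, a, b = 8, 2, 4
        subj = rng.normal(0, 1, size=(n, 1, 1))
        eff_a = np.array([0.3, -0.3]).reshape(1, a, 1)
        eff_b = rng.normal(0, 0.2, size=(1, 1, b))
        return subj + eff_a + eff_b + rng.normal(0, 0.5, size=(n, a, b))

    def test_against_pingouin(self, table):
        pg = pytest.importorskip("pingouin")
        n, a, b = table.shape
        df = pd.DataFrame(
            [
                (s, f"a{i}", f"b{j}", table[s, i, j])
                for s in range(n) for i in range(a) for j in range(b)
            ],
            columns=["subject", "A", "B", "y"],
        )
        ours = {r.name: r for r in bgconn.rm_anova_2way(table, factor_names=("A", "B"))}
        ref = pg.rm_anova(dv="y", within=["A", "B"], subject="subject", data=df,
                          detailed=True)
        for name, key, within in (
            ("main_A", "A", ["A"]),
            ("main_B", "B", ["B"]),
            ("A_x_B", "A * B", ["A", "B"]),
        ):
            row = ref[ref.Source == key].iloc[0]
            assert ours[name].statistic == pytest.approx(row.F, rel=1e-6)
            # our p carries the Huynh-Feldt correction: rebuild it from
            # pingouin's epsilon and the uncorrected F/df
            eps = pg.epsilon(df, dv="y", within=within, subject="subject",
                             correction="hf")
            d1, d2 = ours[name].df
            p_ref = sps.f.sf(ours[name].statistic, eps * d1, eps * d2)
            assert ours[name].p == pytest.approx(p_ref, rel=1e-6)

    def test_df_and_note(self, table):
        res = bgconn.rm_anova_2way(table)
        by = {r.name: r for r in res}
        n, a, b = table.shape
        assert by["main_visual_field"].df == (a - 1, (a - 1) * (n - 1))
        assert by["visual_field_x_attention"].df == ((a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1))
        assert all("Huynh-Feldt" in r.note for r in res)

    def test_missing_cells_rejected(self, table):
        bad = table.copy()
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            bgconn.rm_anova_2way(bad)

    def test_min_subjects(self):
        with pytest.raises(ValueError, match="2 subjects"):
            bgconn.rm_anova_2way(np.zeros((1, 2, 2)))


class TestTTests:
    def test_paired_matches_scipy(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(0.3, 1, 12), rng.normal(0, 1, 12)
        ours = bgconn.paired_t(x, y)
        t, p = sps.ttest_rel(x, y)
        assert ours.statistic == pytest.approx(t)
        assert ours.p == pytest.approx(p)
        assert ours.df == (11,)

    def test_one_sample_matches_scipy(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0.5, 1, 10)
        ours = bgconn.one_sample_t(x, 0.2)
        t, p = sps.ttest_1samp(x, 0.2)
        assert ours.statistic == pytest.approx(t)
        assert ours.p == pytest.approx(p)

    def test_identical_pairs_give_t0(self):
        x = np.array([1.0, 2.0, 3.0])
        res = bgconn.paired_t(x, x)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_constant_nonzero_difference_undefined(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="zero-variance"):
            bgconn.paired_t(x + 0.5, x)


class TestFDR:
    def test_matches_hand_bh(self):
        p = np.array([0.01, 0.04, 0.03, 0.20])
        q = bgconn.fdr_adjust(p)
        # hand BH: sort p, q_i = min over j>=i of p_(j)*m/j, cummin from the top
        order = np.argsort(p)
        m = p.size
        raw = p[order] * m / np.arange(1, m + 1)
        hand = np.minimum.accumulate(raw[::-1])[::-1]
        np.testing.assert_allclose(q[order], np.minimum(hand, 1.0))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bgconn.fdr_adjust([0.5, 1.5])

    def test_attach_fdr_fills_q(self):
        results = [
            StatResult("a", "t", 1.0, (5,), 0.01),
            StatResult("b", "t", 1.0, (5,), 0.04),
        ]
        bgconn.attach_fdr(results)
        assert all(r.q is not None and r.q >= r.p for r in results)


class TestProfileAnovaTables:
    def _profiles(self):
        rows = []
        for s in ("s0", "s1"):
            for c in CONDITIONS:
                for b in BINS:
                    rows.append({"subject": s, "condition": c, "area": "V4",
                                 "bin": b, "z": 0.1})
        return pd.DataFrame(rows)

    def test_shapes(self):
        out = bgconn.profile_anova_tables(self._profiles())
        assert out["V4"].shape == (2, len(BINS), len(CONDITIONS))

    def test_incomplete_crossing_rejected(self):
        prof = self._profiles().iloc[:-1]
        with pytest.raises(ValueError, match="crossing"):
            bgconn.profile_anova_tables(prof)

    def test_duplicates_rejected(self):
        prof = pd.concat([self._profiles()] * 2)
        with pytest.raises(ValueError, match="duplicate"):
            bgconn.profile_anova_tables(prof)
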