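import numpy as np
import pytest
from scipy.linalg import expm

from attnspot import dcm_engine as de, synthgen
from attnspot.core import DIFFUSED, FOCAL, DesignSpec
from attnspot.dcm_engine.model import NODES_3, NODES_5, SELF_SCALE, build_inputs


@pytest.fixture(scope="module")
def tiny_design():
    return DesignSpec(n_runs_per_condition=1, n_cycles=3)


@pytest.fixture(scope="module")
def run_conds():
    return [FOCAL, DIFFUSED]


@pytest.fixture(scope="module")
def rec3(tiny_design, run_conds):
    return de.specify_model("recurrent", tiny_design, run_conds, nodes=NODES_3)


class TestSpecifyModel:
    def test_b_mask_counts_3node(self, tiny_design, run_conds):
        # lateral pair always free; ff/fb add 2 each at 3 nodes
        for structure, n_b in (("feedforward", 4), ("feedback", 4), ("recurrent", 6)):
            m = de.specify_model(structure, tiny_design, run_conds, nodes=NODES_3)
            assert int(m.b_mask.sum()) == n_b
            assert not m.b_mask[..., 0].any()  # no modulation by the stimulus input

    def test_b_mask_counts_5node(self, tiny_design, run_conds):
        m = de.specify_model("recurrent", tiny_design, run_conds, nodes=NODES_5)
        # 3 areas x 2 V1 x 2 directions + 2 lateral
        assert int(m.b_mask.sum()) == 14

    def test_a_mask_shared(self, tiny_design, run_conds):
        masks = [
            de.specify_model(s, tiny_design, run_conds, nodes=NODES_3).a_mask
            for s in de.STRUCTURES
        ]
        assert all(np.array_equal(masks[0], m) for m in masks[1:])
        # no extrastriate-extrastriate links at 5 nodes
        m5 = de.specify_model("recurrent", tiny_design, run_conds, nodes=NODES_5)
        for i in range(2, 5):
            for j in range(2, 5):
                assert not m5.a_mask[i, j]

    def test_driving_input_v1s_only(self, rec3):
        assert rec3.c_mask[rec3.nodes.index("V1_S"), 0]
        assert int(rec3.c_mask.sum()) == 1

    def test_unknown_structure(self, tiny_design, run_conds):
        with pytest.raises(ValueError, match="structure"):
            de.specify_model("full", tiny_design, run_conds)

    def test_inputs(self, tiny_design, run_conds):
        u, slices = build_inputs(tiny_design, run_conds)
        n_tr = tiny_design.n_tr
        assert u.shape == (2, 2 * n_tr)
        box = tiny_design.stimulus_boxcar()
        np.testing.assert_array_equal(u[0, :n_tr], box)
        np.testing.assert_array_equal(u[1, :n_tr], box)       # focal run
        np.testing.assert_array_equal(u[1, n_tr:], np.zeros(n_tr))  # diffused run
        assert slices == [slice(0, n_tr), slice(n_tr, 2 * n_tr)]


class TestPacking:
    def test_round_trip(self, rec3):
        rng = np.random.default_rng(0)
        theta = rec3.prior_mean + rng.normal(0, 0.1, rec3.n_params)
        A, B, C, kappa, tau = rec3.unpack(theta)
        # re-pack from named values
        vals = dict(zip(rec3.param_names, theta))
        np.testing.assert_allclose(rec3.pack(vals), theta)
        # convention: A[i, j] couples source j to target i
        i, j = rec3.nodes.index("EX"), rec3.nodes.index("V1_S")
        assert A[i, j] == vals["A:EX<-V1_S"]
        assert B[i, j, 1] == vals["B2:EX<-V1_S"]

    def test_self_connections_log_scaled(self, rec3):
        theta = rec3.pack({"Aself:EX": 0.2})
        A = rec3.unpack(theta)[0]
        i = rec3.nodes.index("EX")
        assert A[i, i] == pytest.approx(SELF_SCALE * np.exp(0.2))
        assert all(rec3.unpack(rec3.prior_mean)[0][k, k] == SELF_SCALE for k in range(3))

    def test_masked_entries_zero(self, rec3):
        A, B, C, _, _ = rec3.unpack(rec3.prior_mean + 0.3)
        assert A[rec3.nodes.index("EX"), rec3.nodes.index("EX")] != 0  # self
        # B on input 1 (stimulus) is fully masked
        assert np.all(B[:, :, 0] == 0)


class TestForward:
    def test_zero_drive_is_flat(self, rec3):
        theta = rec3.pack({"C1:V1_S": 0.0})
        traj = de.forward(rec3, theta)
        assert np.abs(traj.y).max() < 1e-12
        assert np.abs(traj.z).max() < 1e-12

    def test_neuronal_matches_matrix_exponential(self, rec3):
        """Piecewise-constant-input closed form: over each TR,
        z(t+dt) = e^(M dt) (z + M^-1 c) - M^-1 c."""
        theta = synthgen.dcm_truth_params(rec3)
        traj = de.forward(rec3, theta)
        A, B, C, _, _ = rec3.unpack(theta)
        u = rec3.u
        z = np.zeros(3)
        zs = []
        for t in range(u.shape[1]):
            M = A + u[1, t] * B[:, :, 1]
            c = C[:, 0] * u[0, t]
            minv_c = np.linalg.solve(M, c)
            z = expm(M * rec3.tr) @ (z + minv_c) - minv_c
            zs.append(z.copy())
        assert np.abs(np.array(zs).T - traj.z).max() < 1e-5

    def test_divergence_raises(self, rec3):
        theta = rec3.pack({"A:EX<-V1_S": 3.0, "A:V1_S<-EX": 3.0, "C1:V1_S": 1.0})
        with pytest.raises(FloatingPointError, match="TR index"):
            de.forward(rec3, theta)

    def test_batch_matches_single(self, rec3):
        rng = np.random.default_rng(1)
        thetas = rec3.prior_mean + rng.normal(0, 0.05, (3, rec3.n_params))
        y_batch, _ = de.integrate_params(rec3, thetas)
        for b in range(3):
            y_single, _ = de.integrate_params(rec3, thetas[b][None])
            np.testing.assert_array_equal(y_batch[b], y_single[0])

    def test_hemodynamics_at_rest(self, rec3):
        theta = rec3.pack({"C1:V1_S": 0.0})
        traj = de.forward(rec3, theta)
        np.testing.assert_allclose(traj.f, 1.0)
        np.testing.assert_allclose(traj.v, 1.0)
        np.testing.assert_allclose(traj.q, 1.0)


class TestInvert:
    def test_shape_mismatch(self, rec3):
        with pytest.raises(ValueError, match="shape"):
            de.invert(rec3, np.zeros((3, 10)))

    def test_recovers_signs_and_improves_f(self, rec3):
        theta = synthgen.dcm_truth_params(rec3, jitter_sd=0.0)
        y, _ = synthgen.simulate_dcm_timeseries(rec3, theta, snr=3.0, seed=7)
        post = de.invert(rec3, y, max_iter=48, tol=0.01)
        assert post.converged
        # trace is non-decreasing after the first entry by construction
        accepted = np.array(post.trace)
        assert accepted[-1] > accepted[0]
        # key modulatory contrast has the right sign
        assert post.get("B2:EX<-V1_S") > post.get("B2:EX<-V1_NS")
        assert post.get("C1:V1_S") > 0.2
        # posterior variances shrink below the prior for identified params
        i = post.param_names.index("C1:V1_S")
        assert post.cov[i, i] < 1.0

    def test_noise_precision_positive(self, rec3):
        theta = synthgen.dcm_truth_params(rec3)
        y, _ = synthgen.simulate_dcm_timeseries(rec3, theta, snr=2.0, seed=8)
        post = de.invert(rec3, y, max_iter=8)
        assert np.all(post.noise_precision > 0)


class TestBMS:
    def test_dominant_model(self):
        F = np.zeros((6, 3))
        F[:, 1] = 10.0  # model 1 better by 10 nats for everyone
        res = de.rfx_bms(F, seed=1)
        assert res.exceedance_prob[1] > 0.95
        assert res.expected_frequency[1] > 0.7
        assert np.argmax(res.subject_posteriors.sum(axis=0)) == 1

    def test_symmetric_case(self):
        F = np.zeros((4, 2))
        res = de.rfx_bms(F, seed=2)
        assert res.exceedance_prob[0] == pytest.approx(0.5, abs=0.01)
        np.testing.assert_allclose(res.dirichlet_alpha, res.dirichlet_alpha[::-1])

    def test_exceedance_matches_mc_oracle(self):
        alpha = np.array([3.0, 6.0, 1.5])
        xp = de.dirichlet_exceedance(alpha, n_draws=400_000, seed=3)
        # independent oracle: gamma representation of Dirichlet draws
        rng = np.random.default_rng(99)
        g = rng.gamma(shape=alpha, size=(400_000, 3))
        oracle = np.bincount(np.argmax(g / g.sum(1, keepdims=True), axis=1),
                             minlength=3) / 400_000
        np.testing.assert_allclose(xp, oracle, atol=0.01)
        assert xp.sum() == pytest.approx(1.0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            de.rfx_bms(np.zeros((1, 3)))
        with pytest.raises(ValueError):
            de.rfx_bms(np.array([[np.inf, 0.0], [0.0, 0.0]]))


class TestGroupStats:
    def _posteriors(self, model, b_vals, n_sub=4):
        out = []
        rng = np.random.default_rng(5)
        for _ in range(n_sub):
            mean = model.prior_mean.copy()
            for name, v in b_vals.items():
                mean[model.param_index(name)] = v + rng.normal(0, 0.01)
            out.append(
                de.DCMPosterior(
                    mean=mean, cov=np.eye(model.n_params), noise_precision=np.ones(3),
                    free_energy=0.0, converged=True,
                    param_names=list(model.param_names),
                )
            )
        return out

    def test_table_and_contrast(self, rec3):
        posts = self._posteriors(
            rec3,
            {"B2:EX<-V1_S": 0.3, "B2:EX<-V1_NS": -0.2,
             "B2:V1_S<-EX": 0.3, "B2:V1_NS<-EX": -0.2,
             "B2:V1_NS<-V1_S": 0.3, "B2:V1_S<-V1_NS": -0.2},
        )
        tab, stats = de.modulation_group_stats(posts, rec3)
        assert set(tab.direction) == {"feedforward", "feedback", "lateral"}
        by = {r.name: r for r in stats}
        assert by["feedforward_EX_S_vs_NS"].statistic > 0
        assert by["feedforward_EX_S_vs_NS"].p < 0.01
        assert all(r.q is not None for r in stats)

    def test_mismatched_posterior_rejected(self, rec3, tiny_design, run_conds):
        other = de.specify_model("feedforward", tiny_design, run_conds, nodes=NODES_3)
        posts = self._posteriors(other, {})
        with pytest.raises(ValueError, match="packing"):
            de.modulation_group_stats(posts, rec3)
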