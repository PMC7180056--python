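"""Weight-matrix construction, variants, and stability classification."""

import numpy as np
import pytest

from specisn.connectivity import (
    BLOCKS,
    BlockParams,
    WeightMatrix,
    apply_broad_inhibition_variant,
    apply_ei_ratio_variant,
    build_rf_weights,
    build_ring_weights,
    stability_report,
)


def uniform_params(m, zeta=False, **kw):
    return BlockParams(m={b: m for b in BLOCKS}, zeta=zeta, **kw)


class TestRingWeights:
    def test_cosine_modulation_values(self):
        # J (1 + m cos(2 dtheta)): 0.10 at dtheta=0, 0 at dtheta=pi/2
        theta = np.array([0.0, 0.0, np.pi / 2, np.pi / 4])
        wm = build_ring_weights(theta, uniform_params(1.0), n_e=2)
        assert wm.w[0, 1] == pytest.approx(0.10)
        assert wm.w[2, 0] == pytest.approx(0.05 * (1 + np.cos(np.pi)), abs=1e-12)  # 0
        assert wm.w[3, 0] == pytest.approx(0.05, abs=1e-12)  # cos(pi/2) = 0

    def test_zeta_preserves_block_means(self):
        theta = np.random.default_rng(0).uniform(0, np.pi, 640)
        det = build_ring_weights(theta, uniform_params(1.0), n_e=320)
        noisy = build_ring_weights(theta, uniform_params(1.0, zeta=True), seed=1, n_e=320)
        for b in BLOCKS:
            ratio = noisy.block(b).mean() / det.block(b).mean()
            assert ratio == pytest.approx(1.0, abs=0.02)

    def test_dale_sign_pattern(self):
        theta = np.random.default_rng(1).uniform(0, np.pi, 100)
        wm = build_ring_weights(theta, uniform_params(0.7, zeta=True), seed=2, n_e=50)
        assert np.all(wm.w[:, :50] >= 0)  # excitatory columns
        assert np.all(wm.w[:, 50:] <= 0)  # inhibitory columns

    def test_invalid_specificity_rejected(self):
        with pytest.raises(ValueError, match="m"):
            BlockParams(m={b: 1.5 for b in BLOCKS})

    def test_heterogeneous_m_spreads_weights(self):
        theta = np.zeros(40)  # identical orientations: deterministic rule is constant
        det = build_ring_weights(theta, uniform_params(1.0), n_e=20)
        het = build_ring_weights(
            theta, uniform_params(1.0, heterogeneous_m=True), seed=3, n_e=20
        )
        assert np.ptp(det.block("EE")) == pytest.approx(0.0)
        assert np.ptp(het.block("EE")) > 0.01


class TestRFWeights:
    def test_exponential_rule_values(self):
        # excitatory block only: J (0.1 + m exp(eta psi))
        psi = np.array([[1.0, 0.0], [0.0, 1.0]])
        wm = build_rf_weights(psi, uniform_params(0.5), n_e=2)
        assert wm.w[0, 1] == pytest.approx(0.03)  # psi=0 -> 0.05*0.6
        assert wm.w[0, 0] == pytest.approx(0.05 * (0.1 + 0.5 * np.e**2), rel=1e-12)

    def test_monotone_in_similarity(self):
        psi_vals = np.array([-0.8, -0.2, 0.3, 0.9])
        n = psi_vals.size
        psi = np.tile(psi_vals, (n, 1))
        np.fill_diagonal(psi, 1.0)
        wm = build_rf_weights((psi + psi.T) / 2, uniform_params(0.5), n_e=n)
        # excitatory weights strictly increase with psi for m > 0
        w_by_psi = [wm.w[0, j] for j in range(1, n)]
        assert all(a < b for a, b in zip(w_by_psi, w_by_psi[1:]))

    def test_out_of_range_similarity_rejected(self):
        with pytest.raises(ValueError, match="psi"):
            build_rf_weights(np.array([[1.0, 2.0], [2.0, 1.0]]), uniform_params(0.5))


class TestVariants:
    def test_ei_ratio_80_20_with_4x_inhibition(self):
        n_e, n_i, params = apply_ei_ratio_variant(400, 400, uniform_params(1.0))
        assert (n_e, n_i) == (400, 100)
        assert params.j["EI"] == pytest.approx(-0.3)
        # total inhibitory weight onto a cell is preserved: N_I * |J_EI|
        assert n_i * abs(params.j["EI"]) == pytest.approx(400 * 0.075)

    def test_broad_inhibition_restabilizes(self):
        theta = np.random.default_rng(4).uniform(0, np.pi, 400)

        def builder(params):
            return build_ring_weights(theta, params, seed=5, n_e=200)

        # broadening is bounded: the specific-mode eigenvalue tends to
        # lambda_EE (1 - m_broad) at infinite inhibition, so with
        # lambda_EE = 5 the inhibitory paths can be at most ~20% broader
        wm, scale = apply_broad_inhibition_variant(builder, uniform_params(1.0), 0.9)
        rep = stability_report(wm)
        assert rep.is_stable
        assert rep.is_isn
        assert scale >= 1.0

    def test_fully_flat_inhibition_blocks_are_constant(self):
        theta = np.random.default_rng(4).uniform(0, np.pi, 100)
        params = BlockParams(m={"EE": 1.0, "IE": 0.0, "EI": 0.0, "II": 0.0}, zeta=False)
        wm = build_ring_weights(theta, params, n_e=50)
        assert np.ptp(wm.block("EI")) == pytest.approx(0.0)
        assert np.ptp(wm.block("EE")) > 0.01

    def test_fully_flat_inhibition_cannot_stabilize_specific_mode(self):
        # an orientation-specific E->E mode cannot be balanced by purely
        # nonspecific inhibition, however strong: calibration must fail
        theta = np.random.default_rng(4).uniform(0, np.pi, 400)

        def builder(params):
            return build_ring_weights(theta, params, seed=5, n_e=200)

        with pytest.raises(RuntimeError, match="calibration"):
            apply_broad_inhibition_variant(builder, uniform_params(1.0), 0.0)

    def test_broad_equal_m_is_identity(self):
        theta = np.random.default_rng(6).uniform(0, np.pi, 100)

        def builder(params):
            return build_ring_weights(theta, params, seed=7, n_e=50)

        base = builder(uniform_params(1.0))
        wm, scale = apply_broad_inhibition_variant(builder, uniform_params(1.0), 1.0)
        assert scale == pytest.approx(1.0)
        assert np.allclose(wm.w, base.w)

    def test_broad_exceeding_mee_rejected(self):
        with pytest.raises(ValueError, match="m_broad"):
            apply_broad_inhibition_variant(lambda p: None, uniform_params(0.5), 0.9)


class TestStability:
    def test_fig2_column_is_isn(self):
        # uniform-mode eigenvalue of the E-only block is N_E * J_EE = 20
        theta = np.random.default_rng(8).uniform(0, np.pi, 800)
        wm = build_ring_weights(theta, uniform_params(1.0), n_e=400)
        rep = stability_report(wm)
        assert rep.leading_ee == pytest.approx(400 * 0.05, rel=0.05)
        assert rep.is_isn

    def test_weak_column_is_not_isn(self):
        theta = np.random.default_rng(9).uniform(0, np.pi, 800)
        weak = BlockParams(
            j={"EE": 0.001, "IE": 0.001, "EI": -0.0015, "II": -0.0015},
            m={b: 1.0 for b in BLOCKS},
            zeta=False,
        )
        wm = build_ring_weights(theta, weak, n_e=400)
        rep = stability_report(wm)
        assert rep.leading_ee == pytest.approx(0.4, rel=0.05)
        assert not rep.is_isn
        assert rep.is_stable

    def test_zero_matrix_stable_non_isn(self):
        wm = WeightMatrix(w=np.zeros((10, 10)), n_e=5, n_i=5)
        rep = stability_report(wm)
        assert rep.is_stable and not rep.is_isn

    def test_nonspecific_blocks_spectrum_matches_dense_solve(self):
        # m = 0, zeta off: constant blocks; nonzero eigenvalues are those of
        # the 2x2 reduced matrix [[Ne Jee, Ni Jei], [Ne Jie, Ni Jii]]
        theta = np.random.default_rng(10).uniform(0, np.pi, 200)
        wm = build_ring_weights(theta, uniform_params(0.0), n_e=100)
        eig = np.sort_complex(np.linalg.eigvals(wm.w))
        reduced = np.array([[100 * 0.05, 100 * -0.075], [100 * 0.05, 100 * -0.075]])
        expected = np.linalg.eigvals(reduced)
        for lam in expected:
            assert np.min(np.abs(eig - lam)) < 1e-8
        # all remaining eigenvalues vanish
        assert np.sum(np.abs(eig) > 1e-8) == np.sum(np.abs(expected) > 1e-8)
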