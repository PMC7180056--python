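"""Slope metric, population selectivity, and transition statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specisn.dynamics import ActivityRecord, Schedule, Window
from specisn.metrics import (
    SelectivityTrace,
    bootstrap_st,
    pattern_interval_correlation,
    perturbation_slope,
    population_selectivity,
    st_index,
    windowed_activity,
)


class TestPerturbationSlope:
    def test_exact_negative_line(self):
        res = perturbation_slope([2.0, 1.0, 0.0], [-2.0, -1.0, 0.0])
        assert res.slope == pytest.approx(-1.0)
        assert res.specific_paradoxical
        assert res.nonspecific_paradoxical  # mean dr=1 > 0, mean ds=-1 < 0

    def test_flat_response_is_nonspecific_only(self):
        res = perturbation_slope([1.0, 1.0, 1.0], [-2.0, -1.0, 0.0])
        assert res.slope == pytest.approx(0.0)
        assert not res.specific_paradoxical
        assert res.nonspecific_paradoxical

    def test_degenerate_regressor_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            perturbation_slope([1.0, 2.0, 3.0], [-1.0, -1.0, -1.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            perturbation_slope([1.0, 2.0], [-1.0, 0.0])

    @settings(deadline=None, max_examples=25)
    @given(scale=st.floats(0.01, 100.0))
    def test_slope_sign_invariant_under_axis_rescale(self, scale):
        rng = np.random.default_rng(0)
        ds = -rng.uniform(0.1, 1.0, 30)
        dr = -0.7 * ds + rng.normal(0, 0.05, 30)
        a = perturbation_slope(dr, ds)
        b = perturbation_slope(dr, scale * ds)
        assert np.sign(a.slope) == np.sign(b.slope)
        assert b.slope == pytest.approx(a.slope / scale, rel=1e-9)

    def test_summary_mentions_classification(self):
        res = perturbation_slope([2.0, 1.0, 0.0], [-2.0, -1.0, 0.0])
        text = res.summary()
        assert "slope" in text and "paradoxical" in text


def brute_force_selectivity(activity, theta, min_active=5):
    """Independent per-window loop for PO/OSI (the doubled-angle mean)."""
    po, osi, valid = [], [], []
    for row in activity:
        active = int((row > 0).sum())
        valid.append(active >= min_active)
        tot = row.sum()
        if tot == 0 or active < min_active:
            po.append(np.nan)
            osi.append(np.nan)
            continue
        z = sum(r * np.exp(2j * t) for r, t in zip(row, theta)) / tot
        po.append(np.mod(np.angle(z) / 2, np.pi))
        osi.append(abs(z))
    return np.array(po), np.array(osi), np.array(valid)


class TestPopulationSelectivity:
    def test_single_orientation_fully_selective(self):
        theta = np.full(10, np.pi / 2)
        act = np.ones((3, 10))
        trace = population_selectivity(act, theta)
        assert np.allclose(trace.po, np.pi / 2)
        assert np.allclose(trace.osi, 1.0)

    def test_orthogonal_orientations_cancel(self):
        theta = np.array([0.0] * 5 + [np.pi / 2] * 5)
        act = np.ones((2, 10))
        trace = population_selectivity(act, theta)
        assert np.allclose(trace.osi, 0.0, atol=1e-12)

    def test_sparse_windows_masked(self):
        theta = np.linspace(0, np.pi, 10, endpoint=False)
        act = np.zeros((2, 10))
        act[0, :3] = 1.0  # 3 active < min_active 5
        act[1, :6] = 1.0
        trace = population_selectivity(act, theta, min_active=5)
        assert not trace.valid[0] and trace.valid[1]
        assert np.isnan(trace.po[0])

    def test_matches_bruteforce_on_toy_raster(self):
        rng = np.random.default_rng(5)
        theta = rng.uniform(0, np.pi, 20)
        act = rng.poisson(0.8, (50, 20)).astype(float)
        trace = population_selectivity(act, theta)
        po, osi, valid = brute_force_selectivity(act, theta)
        assert np.array_equal(trace.valid, valid)
        assert np.allclose(trace.po[valid], po[valid], atol=1e-12)
        assert np.allclose(trace.osi[valid], osi[valid], atol=1e-12)


def make_trace(po, osi):
    po, osi = np.asarray(po, dtype=float), np.asarray(osi, dtype=float)
    return SelectivityTrace(
        po=po, osi=osi, valid=np.ones(po.size, bool), window_ms=10.0, min_active=5
    )


class TestSTIndex:
    def test_single_state_gives_zero(self):
        trace = make_trace(np.full(30, 0.4), np.ones(30))
        res = st_index(trace)
        assert res.h_osi == pytest.approx(1.0)
        assert res.sti == pytest.approx(0.0, abs=1e-12)

    def test_uniform_transitions_give_one(self):
        centers = (np.arange(24) + 0.5) * np.pi / 24
        trace = make_trace(centers, np.ones(24))
        res = st_index(trace)
        assert res.h_osi == pytest.approx(0.0, abs=1e-12)
        assert res.sti == pytest.approx(1.0)

    def test_zero_selective_windows_degenerate(self):
        trace = make_trace(np.full(10, 0.3), np.full(10, 0.2))  # all below 0.5
        res = st_index(trace)
        assert res.degenerate and res.sti == 0.0

    def test_matches_bruteforce_composition(self):
        rng = np.random.default_rng(6)
        po = rng.uniform(0, np.pi, 40)
        osi = rng.uniform(0, 1, 40)
        res = st_index(make_trace(po, osi))
        sel = osi > 0.5
        hist, edges = np.histogram(po[sel], bins=np.linspace(0, np.pi, 25))
        centers = (edges[:-1] + edges[1:]) / 2
        h_osi = abs((hist * np.exp(2j * centers)).sum()) / hist.sum()
        expected = (1 - h_osi) * osi.mean()
        assert res.sti == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_sti_bounded_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 60)
        trace = make_trace(rng.uniform(0, np.pi, n), rng.uniform(0, 1, n))
        res = st_index(trace)
        assert 0.0 <= res.sti <= 1.0
        assert 0.0 <= res.h_osi <= 1.0


class TestBootstrapST:
    def test_stationary_raster_near_null(self):
        rng = np.random.default_rng(7)
        theta = rng.uniform(0, np.pi, 30)
        act = rng.poisson(1.0, (200, 30)).astype(float)
        res = bootstrap_st(act, theta, n_shuffles=100, seed=8)
        assert abs(res.sti_bootstrapped) < 3 * res.null_std

    def test_null_reproducible_under_seed(self):
        rng = np.random.default_rng(9)
        theta = rng.uniform(0, np.pi, 20)
        act = rng.poisson(1.0, (60, 20)).astype(float)
        a = bootstrap_st(act, theta, n_shuffles=20, seed=10)
        b = bootstrap_st(act, theta, n_shuffles=20, seed=10)
        assert a.null_mean == b.null_mean and a.null_std == b.null_std


class TestPatternIntervalCorrelation:
    def test_zero_interval_is_unity(self):
        act = np.random.default_rng(11).uniform(0, 1, (30, 15))
        intervals, corr = pattern_interval_correlation(act)
        assert corr[0] == pytest.approx(1.0)

    def test_iid_raster_decorrelates(self):
        act = np.random.default_rng(12).poisson(2.0, (400, 25)).astype(float)
        _, corr = pattern_interval_correlation(act, max_interval=50)
        assert np.nanmax(np.abs(corr[1:])) < 0.15

    def test_periodic_raster_recorrelates_at_period(self):
        base = np.random.default_rng(13).uniform(0, 1, (5, 12))
        act = np.tile(base, (8, 1))
        _, corr = pattern_interval_correlation(act, max_interval=12)
        assert corr[5] == pytest.approx(1.0)
        assert corr[10] == pytest.approx(1.0)


class TestWindowedActivity:
    def test_spike_counts_per_window(self):
        sched = Schedule([Window("baseline", 0.0, 30.0, np.zeros(3))])
        rec = ActivityRecord(
            kind="spikes",
            n_e=2,
            n_i=1,
            schedule=sched,
            spike_ids=np.array([0, 1, 0, 2, 1]),
            spike_times=np.array([1.0, 5.0, 12.0, 15.0, 25.0]),
        )
        act = windowed_activity(rec, window_ms=10.0, population="E")
        assert act.shape == (3, 2)
        assert act[0].tolist() == [1, 1]
        assert act[1].tolist() == [1, 0]  # the I spike at 15 ms is excluded
        assert act[2].tolist() == [0, 1]
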