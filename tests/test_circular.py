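"""Circular descriptive statistics, Rayleigh and Wallraff tests, von Mises
sampling and fitting."""

import numpy as np
import pingouin
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from discorient.circular import (
    angular_deviation,
    circ_mean_ci,
    circ_mean_r,
    rayleigh_test,
    relative_angles,
    vm_fit,
    vm_sample,
    wallraff_test,
)

angle_lists = st.lists(
    st.floats(min_value=0.0, max_value=359.99), min_size=2, max_size=40
)


class TestCircMean:
    @pytest.mark.parametrize(
        "angles, mean, r",
        [
            ([0.0, 0.0, 0.0], 0.0, 1.0),
            ([10.0, 350.0], 0.0, np.cos(np.radians(10.0))),  # two unit vectors by hand
            ([90.0, 90.0], 90.0, 1.0),
        ],
    )
    def test_examples(self, angles, mean, r):
        summ = circ_mean_r(angles)
        assert summ.mean_bearing == pytest.approx(mean, abs=1e-9)
        assert summ.r == pytest.approx(r, abs=1e-12)
        assert summ.mean_defined

    def test_symmetric_sample_has_zero_r_and_flagged_mean(self):
        summ = circ_mean_r([0.0, 90.0, 180.0, 270.0])
        assert summ.r == 0.0
        assert not summ.mean_defined
        assert summ.mean_bearing == 0.0  # reported by convention, not an error

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            circ_mean_r([])

    @settings(derandomize=True, max_examples=60)
    @given(angles=angle_lists, delta=st.floats(min_value=-720, max_value=720))
    def test_rotation_equivariance(self, angles, delta):
        """Adding a constant shifts the mean by that constant (mod 360) and
        leaves r unchanged."""
        a = circ_mean_r(angles)
        b = circ_mean_r([x + delta for x in angles])
        assert b.r == pytest.approx(a.r, abs=1e-9)
        if a.mean_defined and a.r > 1e-6:
            diff = (b.mean_bearing - a.mean_bearing - delta) % 360.0
            assert min(diff, 360.0 - diff) < 1e-6

    def test_matches_scipy_directional_stats(self, rng):
        a = rng.uniform(0, 360, 50)
        from scipy.stats import directional_stats

        vecs = np.column_stack([np.cos(np.radians(a)), np.sin(np.radians(a))])
        ref = directional_stats(vecs)
        summ = circ_mean_r(a)
        assert summ.r == pytest.approx(float(ref.mean_resultant_length), abs=1e-12)


class TestRayleigh:
    def test_identical_bearings_maximally_significant(self):
        res = rayleigh_test([42.0] * 180)
        assert res.summary.r == pytest.approx(1.0)
        assert res.p_value < 1e-10

    def test_evenly_spaced_bearings_uniform(self):
        res = rayleigh_test(np.arange(180) * 2.0)
        assert res.summary.r < 1e-12
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_p_strictly_decreasing_in_r(self):
        """At fixed n, more concentrated samples get smaller p."""
        n = 30
        ps = []
        for kappa in (0.2, 0.8, 2.0, 6.0):
            a = vm_sample(0.0, kappa, n, seed=5)
            ps.append(rayleigh_test(a).p_value)
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))

    def test_agrees_with_independent_implementation(self, rng):
        """Analytic p matches pingouin's Rayleigh test on random samples
        (both are tail approximations in Z = n r^2; they agree to ~1e-2)."""
        for n in (10, 30, 180):
            a = rng.uniform(0, 360, n)
            z, p_ref = pingouin.circ_rayleigh(np.radians(a))
            assert rayleigh_test(a).p_value == pytest.approx(p_ref, abs=5e-3)

    def test_permutation_close_to_analytic(self):
        a = vm_sample(120.0, 0.8, 30, seed=7)
        p_a = rayleigh_test(a).p_value
        p_p = rayleigh_test(a, method="permutation", n_perm=4999, seed=11).p_value
        assert p_p == pytest.approx(p_a, abs=0.02)

    def test_small_n_flagged(self):
        assert rayleigh_test([0.0, 10.0, 20.0]).small_n
        assert not rayleigh_test([0.0] * 10).small_n

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            rayleigh_test([10.0])
        with pytest.raises(ValueError):
            rayleigh_test([0.0, 1.0], method="permutation", n_perm=99, seed=1)
        with pytest.raises(ValueError):
            rayleigh_test([0.0, 1.0], method="permutation", seed=None)
        with pytest.raises(ValueError):
            rayleigh_test([0.0, 1.0], method="bootstrap")

    @settings(derandomize=True, max_examples=40)
    @given(angles=angle_lists, delta=st.floats(min_value=-360, max_value=360))
    def test_p_rotation_invariant(self, angles, delta):
        p0 = rayleigh_test(angles).p_value
        p1 = rayleigh_test([x + delta for x in angles]).p_value
        assert p1 == pytest.approx(p0, abs=1e-9)


class TestRelativeAngles:
    @pytest.mark.parametrize(
        "bearing, cue, expected",
        [
            (45.0, 45.0, 0.0),  # toward the cue
            (10.0, 190.0, 180.0),  # away from it
            (20.0, 30.0, 350.0),
        ],
    )
    def test_contract(self, bearing, cue, expected):
        assert relative_angles([bearing], [cue])[0] == pytest.approx(expected)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            relative_angles([0.0, 1.0], [0.0])


class TestWallraff:
    def test_identical_groups_not_significant(self):
        g = [10.0, 40.0, 350.0, 20.0, 80.0, 330.0]
        res = wallraff_test([g, list(g)])
        assert res.p_value > 0.9  # identical deviation multisets

    def test_label_exchange_invariance(self):
        a = vm_sample(0.0, 3.0, 25, seed=1)
        b = vm_sample(200.0, 0.7, 25, seed=2)
        assert wallraff_test([a, b]).p_value == wallraff_test([b, a]).p_value

    def test_detects_dispersion_difference(self):
        a = vm_sample(0.0, 50.0, 40, seed=3)
        b = vm_sample(0.0, 0.5, 40, seed=4)
        assert wallraff_test([a, b]).p_value < 0.01

    def test_three_groups_uses_kruskal(self):
        groups = [vm_sample(0.0, 2.0, 20, seed=s) for s in (5, 6, 7)]
        res = wallraff_test(groups)
        assert res.method == "kruskal-wallis"
        assert len(res.group_dispersions) == 3

    def test_deviations_are_shorter_arc(self):
        # deviations from the mean of [350, 10] (= 0) are 10, not 350
        d = angular_deviation([350.0, 10.0])
        assert np.allclose(d, [10.0, 10.0])

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            wallraff_test([[0.0, 1.0], [5.0]])


class TestVonMises:
    def test_zero_kappa_is_uniform(self):
        a = vm_sample(0.0, 0.0, 10_000, seed=8)
        assert circ_mean_r(a).r < 0.05

    def test_mean_recovery(self):
        a = vm_sample(90.0, 2.0, 10_000, seed=9)
        diff = abs((circ_mean_r(a).mean_bearing - 90.0 + 180.0) % 360.0 - 180.0)
        assert diff < 3.0

    def test_high_kappa_concentrates(self):
        a = vm_sample(250.0, 500.0, 1000, seed=10)
        dev = np.abs((a - 250.0 + 180.0) % 360.0 - 180.0)
        assert dev.max() < 10.0

    def test_negative_kappa_errors(self):
        with pytest.raises(ValueError):
            vm_sample(0.0, -1.0, 10, seed=1)

    def test_reproducible(self):
        assert np.array_equal(vm_sample(10, 3, 50, seed=2), vm_sample(10, 3, 50, seed=2))

    def test_fit_recovers_kappa(self):
        fit = vm_fit(vm_sample(180.0, 4.0, 5000, seed=12))
        assert abs(fit.kappa - 4.0) / 4.0 < 0.10
        assert abs((fit.mu - 180.0 + 180.0) % 360.0 - 180.0) < 3.0

    def test_fit_uniform_sample_near_zero(self):
        assert vm_fit(vm_sample(0.0, 0.0, 5000, seed=13)).kappa < 0.1

    def test_fit_degenerate_sample_capped(self):
        fit = vm_fit([77.0] * 20)
        assert fit.capped
        assert fit.kappa == 1e4

    def test_fit_consistent_with_scipy_mle(self, rng):
        from scipy.stats import vonmises as scipy_vm

        a = vm_sample(40.0, 1.5, 2000, seed=14)
        kappa_ref, _, _ = scipy_vm.fit(np.radians(a), fscale=1)
        assert vm_fit(a).kappa == pytest.approx(kappa_ref, rel=0.02)


class TestMeanCI:
    def test_halfwidth_shrinks_with_n(self):
        wide = circ_mean_ci(vm_sample(0, 2, 30, seed=15))[1]
        narrow = circ_mean_ci(vm_sample(0, 2, 3000, seed=15))[1]
        assert narrow < wide

    def test_uninformative_for_uniform(self):
        _, hw = circ_mean_ci(vm_sample(0, 0.0, 20, seed=16))
        assert hw == 180.0
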