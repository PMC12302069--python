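import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from redoxlra import (
    GapEnsemble,
    SyntheticGapConfig,
    ValidationError,
    average_gap,
    decorrelation_check,
    gap_histogram_modes,
    generate_gap_ensembles,
    lra_free_energy,
    marcus_parabolas,
    running_average,
    zwanzig_free_energy,
)
from redoxlra.constants import KB_EV
from redoxlra.structures_io import Atom, Snapshot, Trajectory

KT310 = KB_EV * 310.0


def ens(state, gaps, T=310.0):
    return GapEnsemble(state=state, gaps=np.asarray(gaps, float), temperature=T)


class TestAverageGap:
    def test_constant_ensemble(self):
        assert average_gap(ens("reduced", [5.0, 5.0, 5.0])) == 5.0

    def test_matches_sum_over_n(self):
        gaps = [9.0, 9.5, 9.1, 9.4, 9.6]
        oracle = sum(gaps) / len(gaps)  # independent brute-force mean
        assert average_gap(ens("reduced", gaps)) == pytest.approx(oracle, abs=1e-14)

    def test_clt_bound_on_synthetic_ensemble(self):
        rng = np.random.default_rng(42)
        gaps = rng.normal(9.32, 0.23, 500)
        assert abs(average_gap(ens("reduced", gaps)) - 9.32) < 3 * 0.23 / np.sqrt(500)


class TestZwanzig:
    def test_constant_gaps_return_constant(self):
        for state in ("reduced", "oxidized"):
            assert zwanzig_free_energy(ens(state, [2.5] * 3)) == pytest.approx(2.5)

    def test_single_sample(self):
        assert zwanzig_free_energy(ens("reduced", [6.25])) == pytest.approx(6.25)

    def test_exponential_gaussian_closed_form_well_sampled(self):
        """In the well-sampled regime (sigma ~ 2 kBT) the log-sum-exp estimate
        matches the Gaussian second-cumulant closed form."""
        m, sigma, n = 6.0, 0.05, 100_000
        rng = np.random.default_rng(11)
        e = ens("reduced", rng.normal(m, sigma, n))
        expected = m - sigma**2 / (2 * KT310)
        assert zwanzig_free_energy(e) == pytest.approx(expected, abs=3e-3)

    def test_reverse_direction_sign(self):
        m, sigma, n = 4.0, 0.05, 100_000
        rng = np.random.default_rng(12)
        e = ens("oxidized", rng.normal(m, sigma, n))
        expected = m + sigma**2 / (2 * KT310)
        assert zwanzig_free_energy(e) == pytest.approx(expected, abs=3e-3)

    def test_gaussian_method_equals_sample_cumulant(self):
        """method='gaussian' is exactly mean -/+ var/(2 kBT) of the samples."""
        rng = np.random.default_rng(13)
        g = rng.normal(6.0, 0.2, 5000)
        e = ens("reduced", g)
        oracle = np.mean(g) - np.var(g, ddof=1) / (2 * KT310)
        assert zwanzig_free_energy(e, method="gaussian") == pytest.approx(
            oracle, abs=1e-12
        )

    def test_no_overflow_at_large_reduced_units(self):
        e = ens("reduced", [10.0, 10.5], T=310.0)  # |dE|/kBT ~ 390
        assert np.isfinite(zwanzig_free_energy(e))

    def test_invalid_temperature(self):
        with pytest.raises(ValidationError):
            GapEnsemble(state="reduced", gaps=np.array([1.0]), temperature=-1.0)


class TestLRA:
    @pytest.mark.parametrize(
        "mean_red, mean_ox, expected",
        [(9.32, 4.95, 7.135), (5.93, 2.31, 4.12)],
    )
    def test_published_mean_gap_pairs(self, mean_red, mean_ox, expected):
        res = lra_free_energy(
            ens("reduced", [mean_red] * 4), ens("oxidized", [mean_ox] * 4),
            n_boot=50, seed=0,
        )
        assert res.dG_ox == pytest.approx(expected, abs=1e-12)

    def test_zero_reorganization_limit(self):
        rng = np.random.default_rng(5)
        g = rng.normal(3.0, 0.1, 100)
        res = lra_free_energy(ens("reduced", g), ens("oxidized", g.copy()),
                              n_boot=100, seed=1)
        assert res.dG_ox == pytest.approx(np.mean(g))
        assert res.lambda_reorg == pytest.approx(0.0, abs=1e-15)

    def test_temperature_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="temperature"):
            lra_free_energy(ens("reduced", [1.0], T=310.0),
                            ens("oxidized", [1.0], T=300.0))

    def test_anomalous_lambda_flagged_not_raised(self):
        res = lra_free_energy(ens("reduced", [2.0] * 3), ens("oxidized", [5.0] * 3),
                              n_boot=10, seed=0)
        assert res.anomalous_lambda
        assert res.lambda_reorg < 0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        mr=st.floats(-5, 15), d=st.floats(0.01, 5),
        spread=st.floats(0.001, 0.5), seed=st.integers(0, 1000),
    )
    def test_swap_and_negate_symmetry(self, mr, d, spread, seed):
        """Exchanging the states and negating the gaps negates dG_ox."""
        rng = np.random.default_rng(seed)
        g_red = rng.normal(mr, spread, 50)
        g_ox = rng.normal(mr - d, spread, 50)
        fwd = lra_free_energy(ens("reduced", g_red), ens("oxidized", g_ox), n_boot=0)
        rev = lra_free_energy(ens("reduced", -g_ox), ens("oxidized", -g_red), n_boot=0)
        assert rev.dG_ox == pytest.approx(-fwd.dG_ox, abs=1e-12)
        assert rev.lambda_reorg == pytest.approx(fwd.lambda_reorg, abs=1e-12)

    def test_bootstrap_ci_shrinks_as_sqrt_n(self):
        widths = {}
        for n in (125, 500, 2000):
            cfg = SyntheticGapConfig(dG_true=5.0, lambda_true=1.0,
                                     n_per_state=n, seed=17)
            red, ox = generate_gap_ensembles(cfg)
            res = lra_free_energy(red, ox, n_boot=800, seed=29)
            widths[n] = res.ci_dG[1] - res.ci_dG[0]
        for a, b in ((125, 500), (500, 2000)):
            ratio = widths[a] / widths[b]
            assert ratio == pytest.approx(2.0, rel=0.25)

    def test_linear_response_consistency(self):
        """With variance 2 kBT lambda, both Zwanzig directions and LRA agree
        on dG in the regime where exponential averaging converges."""
        dg, lam, n = 3.0, 0.01, 2000
        cfg = SyntheticGapConfig(dG_true=dg, lambda_true=lam, n_per_state=n, seed=23)
        red, ox = generate_gap_ensembles(cfg)
        se = cfg.sigma / np.sqrt(n)
        assert abs(lra_free_energy(red, ox, n_boot=0).dG_ox - dg) < 3 * se
        assert abs(zwanzig_free_energy(red) - dg) < 3 * se
        assert abs(zwanzig_free_energy(ox) - dg) < 3 * se


class TestMarcusParabolas:
    def _result(self, mean_red=9.32, mean_ox=4.95):
        return lra_free_energy(ens("reduced", [mean_red] * 3),
                               ens("oxidized", [mean_ox] * 3), n_boot=0)

    def test_gap_identity_along_coordinate(self):
        (ar, br, cr), (ao, bo, co) = marcus_parabolas(self._result())
        x = np.linspace(-5, 15, 100)
        diff = (ao - ar) * x**2 + (bo - br) * x + (co - cr)
        np.testing.assert_allclose(diff, x, atol=1e-10)

    def test_vertex_values(self):
        res = self._result()
        (ar, br, cr), (ao, bo, co) = marcus_parabolas(res)
        g_red = ar * res.mean_red**2 + br * res.mean_red + cr
        g_ox = ao * res.mean_ox**2 + bo * res.mean_ox + co
        assert g_red == pytest.approx(0.0, abs=1e-12)
        assert g_ox == pytest.approx(res.dG_ox, abs=1e-12)

    def test_curves_cross_at_zero_gap(self):
        """G_ox - G_red = x, so the surfaces intersect exactly at x = 0."""
        (ar, br, cr), (ao, bo, co) = marcus_parabolas(self._result(9.32, 4.95))
        assert (ao - ar) * 0.0 + (bo - br) * 0.0 + (co - cr) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValidationError, match="lambda"):
            marcus_parabolas(self._result(4.0, 4.0))


class TestRunningAverage:
    def test_hand_example(self):
        np.testing.assert_allclose(
            running_average(ens("reduced", [1.0, 2.0, 3.0])), [1.0, 1.5, 2.0]
        )

    def test_constant_vector(self):
        np.testing.assert_allclose(
            running_average(ens("reduced", [2.0] * 5)), [2.0] * 5
        )

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 300))
    def test_last_element_is_ensemble_mean(self, seed, n):
        g = np.random.default_rng(seed).normal(5, 1, n)
        e = ens("reduced", g)
        ra = running_average(e)
        assert ra[-1] == pytest.approx(average_gap(e), rel=1e-12)


class TestHistogramModes:
    def test_unimodal_gaussian(self):
        g = np.random.default_rng(7).normal(6.0, 0.2, 500)
        _, n_modes = gap_histogram_modes(ens("reduced", g), bin_width=0.05)
        assert n_modes == 1

    def test_bimodal_mixture(self):
        rng = np.random.default_rng(8)
        g = np.concatenate([rng.normal(5, 0.1, 250), rng.normal(9, 0.1, 250)])
        _, n_modes = gap_histogram_modes(ens("reduced", g), bin_width=0.05)
        assert n_modes == 2

    def test_constant_data_single_mode(self):
        (edges, counts), n_modes = gap_histogram_modes(ens("reduced", [4.0] * 10))
        assert n_modes == 1
        assert counts.sum() == 10

    def test_bin_width_exceeding_range_collapses_to_one_bin(self):
        (edges, counts), n_modes = gap_histogram_modes(
            ens("reduced", [4.0, 4.1, 4.2]), bin_width=5.0
        )
        assert len(counts) == 1 and n_modes == 1


def _solute_traj(coords_per_frame, box=50.0):
    snaps = []
    for i, coords in enumerate(coords_per_frame):
        atoms = [
            Atom("C", c, charge_red=0.0, charge_ox=1.0 if j == 0 else 0.0,
                 role="solute", residue_id=1)
            for j, c in enumerate(coords)
        ]
        snaps.append(Snapshot(atoms=atoms, box_edge=box, frame_index=i))
    return Trajectory(snaps)


class TestDecorrelation:
    BASE = np.array([[0.0, 0, 0], [1.4, 0, 0], [0.7, 1.2, 0], [0.7, -1.2, 0]]) + 25.0

    def test_pure_translations_report_zero(self):
        rng = np.random.default_rng(1)
        frames = [self.BASE + rng.normal(size=3) for _ in range(20)]
        traj = _solute_traj(frames)
        gaps = ens("reduced", rng.normal(6, 0.2, 20))
        rep = decorrelation_check(traj, gaps)
        assert rep.pc_variances[0] == pytest.approx(0.0, abs=1e-12)
        assert rep.pc_gap_correlations == (0.0, 0.0, 0.0)

    def test_independent_gaps_weakly_correlated(self):
        rng = np.random.default_rng(2)
        frames = [self.BASE + rng.normal(scale=0.1, size=self.BASE.shape)
                  for _ in range(500)]
        traj = _solute_traj(frames)
        gaps = ens("reduced", rng.normal(6, 0.2, 500))
        rep = decorrelation_check(traj, gaps)
        assert rep.pc_gap_correlations[0] < 0.2
        assert rep.pc_gap_correlations[1] < 0.2

    def test_gap_built_from_leading_mode_is_detected(self):
        rng = np.random.default_rng(3)
        mode = rng.normal(size=self.BASE.shape)
        mode -= mode.mean(axis=0, keepdims=True)  # internal, not a translation
        t = rng.normal(size=200)
        frames = [self.BASE + 0.1 * ti * mode for ti in t]
        traj = _solute_traj(frames)
        gaps = ens("reduced", 6.0 + 0.3 * t)
        rep = decorrelation_check(traj, gaps)
        assert rep.pc_gap_correlations[0] > 0.99

    def test_too_few_solute_atoms_rejected(self):
        traj = _solute_traj([[[25.0, 25, 25], [26.4, 25, 25]]] * 3)
        with pytest.raises(ValidationError, match="3 solute atoms"):
            decorrelation_check(traj, ens("reduced", [1.0, 1.0, 1.0]))
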