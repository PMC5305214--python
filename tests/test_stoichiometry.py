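import numpy as np
import pytest

from replicount import changepoint as cp
from replicount import synthetic_data as sd
from replicount import stoichiometry as st
from replicount.datatypes import Idealization


def staircase_idealization(n_levels, step, duration=20, variance=1e-8):
    means = step * np.arange(n_levels - 1, -1, -1, dtype=float)
    return Idealization(
        change_points=duration * np.arange(1, n_levels),
        level_means=means,
        level_variances=np.full(n_levels, variance),
        level_durations=np.full(n_levels, duration),
    )


class TestPPDD:
    def test_two_levels_single_kernel(self):
        ideal = staircase_idealization(2, step=5.0)
        ppdd = st.compute_ppdd(ideal)
        assert ppdd.centers.size == 1
        assert ppdd.centers[0] == pytest.approx(5.0)

    def test_staircase_matches_brute_force_pair_sum(self):
        ideal = staircase_idealization(7, step=1.0)  # 6 -> 0
        ppdd = st.compute_ppdd(ideal, pair_weight="product")
        # brute force double loop over level pairs
        means, durs = ideal.level_means, ideal.level_durations
        expect = {}
        for i in range(7):
            for j in range(i + 1, 7):
                d = abs(means[i] - means[j])
                expect[d] = expect.get(d, 0) + durs[i] * durs[j]
        total = sum(expect.values())
        for d, w in expect.items():
            got = ppdd.weights[np.isclose(ppdd.centers, d)].sum()
            assert got == pytest.approx(w / total)
        # kernels at s..6s with multiplicities 6..1
        for mult, d in zip([6, 5, 4, 3, 2, 1], [1, 2, 3, 4, 5, 6]):
            assert np.isclose(ppdd.centers, d).sum() == mult

    def test_density_normalized(self):
        ideal = staircase_idealization(4, step=2.0, variance=0.5)
        ppdd = st.compute_ppdd(ideal)
        assert np.trapezoid(ppdd.density, ppdd.grid) == pytest.approx(1.0, abs=1e-6)
        assert np.all(ppdd.density >= 0)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            st.compute_ppdd(staircase_idealization(1, 1.0))


class TestPowerSpectrum:
    def test_staircase_recovers_exact_step(self):
        ppdd = st.compute_ppdd(staircase_idealization(7, step=100.0))
        step = st.power_spectrum(ppdd)
        assert step.delta_I == pytest.approx(100.0, rel=0.01)

    def test_two_level_difference_recovered(self):
        ppdd = st.compute_ppdd(staircase_idealization(2, step=7.3, variance=1e-4))
        step = st.power_spectrum(ppdd)
        assert step.delta_I == pytest.approx(7.3, rel=0.01)

    def test_power_nonnegative(self):
        ppdd = st.compute_ppdd(staircase_idealization(5, step=3.0, variance=0.2))
        step = st.power_spectrum(ppdd)
        assert np.all(step.power >= 0)

    def test_fig_style_simulation_modal_step_near_truth(self, table_long):
        # staircase traces at the observed noise: the modal recovered step
        # across seeds sits at the true unitary step
        deltas = []
        for r in range(100):
            tr, _ = sd.simulate_state_dwell_trace(6, seed=200_000 + r)
            ideal = cp.idealize_cp(tr, table_long)
            if ideal.n_levels < 2:
                continue
            try:
                deltas.append(st.power_spectrum(st.compute_ppdd(ideal)).delta_I)
            except ValueError:
                continue
        deltas = np.array(deltas)
        assert np.mean(np.abs(deltas - 1.0) < 0.25) > 0.4  # modal bin at 1.0
        hist, edges = np.histogram(deltas, bins=np.arange(0, 8, 0.5))
        mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        assert abs(mode - 1.0) <= 0.5


class TestInitialIntensity:
    def test_noiseless_exponential_exact(self):
        t = np.arange(120)
        fit = st.fit_initial_intensity(100.0 * np.exp(-t / 41.0))
        assert fit.I0 == pytest.approx(100.0, rel=1e-4)
        assert fit.t_b == pytest.approx(41.0, rel=1e-4)

    def test_mean_I0_recovers_initial_intensity(self):
        i0s = []
        for r in range(400):
            cfg = sd.TraceSimConfig(n_fluorophores=12, seed=300_000 + r)
            tr, _ = sd.simulate_bleach_trace(cfg)
            fit = st.fit_initial_intensity(tr)
            if fit.converged:
                i0s.append(fit.I0)
        assert abs(np.mean(i0s) - 12.0) < 0.05 * 12.0

    def test_exponential_fit_beats_highest_level(self, table_120):
        # the highest idealized level underestimates I0 at high copy number
        # because early, short bleaching steps merge
        i0_fit, i0_high = [], []
        for r in range(150):
            cfg = sd.TraceSimConfig(n_fluorophores=12, seed=310_000 + r)
            tr, _ = sd.simulate_bleach_trace(cfg)
            fit = st.fit_initial_intensity(tr)
            ideal = cp.idealize_cp(tr, table_120)
            if fit.converged:
                i0_fit.append(fit.I0)
                i0_high.append(ideal.level_means.max())
        assert np.mean(i0_high) < np.mean(i0_fit)
        assert np.mean(i0_high) < 12.0 - 0.5  # clearly biased low

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            st.fit_initial_intensity(np.ones(5))


class TestStoichiometryEstimate:
    def test_direct_division(self):
        fit = st.BleachFit(I0=612.0, t_b=41.0, residual=0.0)
        step = st.UnitaryStep(51.0, np.array([51.0]), np.array([1.0]), 1.0, 0.0)
        rec = st.estimate_stoichiometry(fit, step)
        assert rec.n == pytest.approx(12.0)

    def test_zero_intensity(self):
        fit = st.BleachFit(I0=0.0, t_b=41.0, residual=0.0)
        step = st.UnitaryStep(51.0, np.array([51.0]), np.array([1.0]), 1.0, 0.0)
        assert st.estimate_stoichiometry(fit, step).n == 0.0

    def test_end_to_end_scale_invariance(self, table_120):
        cfg = sd.TraceSimConfig(n_fluorophores=6, seed=17)
        tr, _ = sd.simulate_bleach_trace(cfg)
        rec1 = st.stoichiometry_pipeline(tr, table_120)
        tr_scaled = type(tr)(values=1000.0 * tr.values)
        rec2 = st.stoichiometry_pipeline(tr_scaled, table_120)
        assert rec1 is not None and rec2 is not None
        assert rec2.I0 == pytest.approx(1000.0 * rec1.I0, rel=1e-6)
        assert rec2.delta_I == pytest.approx(1000.0 * rec1.delta_I, rel=1e-6)
        assert rec2.n == pytest.approx(rec1.n, rel=1e-6)


class TestQCFilter:
    def _record(self, n=6.0, delta=1.0, i0=6.0, first=6.0, peak=1.0, runner=0.5):
        rec = st.StoichiometryRecord(n=n, I0=i0, delta_I=delta)
        rec.meta = {
            "peak_power": peak,
            "runner_up_power": runner,
            "first_frame_intensity": first,
        }
        return rec

    def test_clean_record_passes(self):
        ok, reasons = st.qc_filter(self._record(), in_vitro_step=1.0)
        assert ok and reasons == []

    def test_ellipticity_gate(self):
        ok, reasons = st.qc_filter(self._record(), in_vitro_step=1.0, ellipticity=1.3)
        assert not ok and "ellipticity" in reasons

    def test_step_size_gate(self):
        ok, reasons = st.qc_filter(self._record(delta=3.0), in_vitro_step=1.0)
        assert not ok and "step-size" in reasons

    def test_dominance_gate(self):
        ok, reasons = st.qc_filter(
            self._record(peak=1.0, runner=0.95), in_vitro_step=1.0
        )
        assert not ok and "peak-dominance" in reasons

    def test_initial_intensity_gate(self):
        ok, reasons = st.qc_filter(self._record(i0=10.0, first=6.0), in_vitro_step=1.0)
        assert not ok and "initial-intensity" in reasons

    def test_localization_and_high_copy_gates(self):
        ok, reasons = st.qc_filter(
            self._record(n=12.0), in_vitro_step=1.0, in_factory_band=False, max_copies=10
        )
        assert not ok and set(reasons) >= {"localization", "high-copy"}

    def test_incomplete_metadata(self):
        rec = st.StoichiometryRecord(n=6.0, I0=6.0, delta_I=1.0)
        ok, reasons = st.qc_filter(rec, in_vitro_step=1.0)
        assert not ok and reasons == ["incomplete"]


class TestMixture:
    def test_two_point_populations(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([6 + 0.01 * rng.standard_normal(100), 12 + 0.01 * rng.standard_normal(100)])
        fit = st.fit_mixture(x)
        assert fit.mu1 == pytest.approx(6.0, abs=0.05)
        assert fit.mu2 == pytest.approx(12.0, abs=0.05)
        assert fit.frac_low == pytest.approx(0.5, abs=0.02)

    def test_parameter_recovery_at_large_n(self):
        x = sd.simulate_stoichiometry_samples(6.2, 11.2, 1.2, 1.5, 0.41, 10_000, seed=9)
        fit = st.fit_mixture(x)
        assert fit.mu1 == pytest.approx(6.2, abs=0.15)
        assert fit.mu2 == pytest.approx(11.2, abs=0.15)
        assert fit.sigma1 == pytest.approx(1.2, abs=0.15)
        assert fit.sigma2 == pytest.approx(1.5, abs=0.15)
        assert fit.frac_low == pytest.approx(0.41, abs=0.03)

    def test_single_population_collapses(self):
        x = np.random.default_rng(1).normal(11.0, 1.2, size=300)
        fit = st.fit_mixture(x)
        assert fit.single_component
        assert fit.frac_low == 0.0
        assert fit.mu2 == pytest.approx(11.0, abs=0.3)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            st.fit_mixture(np.arange(10.0))

    def test_bootstrap_error_shrinks_with_n(self):
        errs = []
        for n in (100, 400):
            x = sd.simulate_stoichiometry_samples(6.0, 12.0, 1.0, 1.2, 0.5, n, seed=4)
            fit = st.fit_mixture(x)
            errs.append(st.mixture_error(fit, n_sim=150, seed=5))
        assert errs[0] > 0
        # ~ 1/sqrt(N): doubling N twice should halve the error, roughly
        assert errs[0] / errs[1] == pytest.approx(2.0, rel=0.5)


class TestKDE:
    def test_normal_reference_bandwidth(self):
        x = np.random.default_rng(2).standard_normal(10_000)
        _, _, bw = st.kde(x)
        assert bw == pytest.approx(1.06 * 10_000 ** (-0.2), rel=0.15)

    def test_density_integrates_to_one(self):
        x = np.random.default_rng(3).normal(8, 2, size=500)
        support, density, _ = st.kde(x)
        assert np.trapezoid(density, support) == pytest.approx(1.0, abs=1e-3)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            st.kde(np.full(100, 3.0))
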