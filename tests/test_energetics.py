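"""Window means, SEM estimators, binding enthalpies and classification."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glycolink.energetics import (
    EXCLUDED,
    FAVOURABLE,
    UNFAVOURABLE,
    AnalysisWindow,
    EnergySeries,
    EnthalpyResult,
    binding_enthalpy,
    classify,
    convergence_time,
    excluded_result,
    read_amber_mdout,
    sem_estimate,
    summarize,
    window_mean,
)
from glycolink.errors import (
    EmptyWindowError,
    SeriesMismatchError,
    ValidationError,
)
from glycolink.synthetic import SeriesSpec, generate_energy_series, make_table1_fixture


def series(values, dt=1.0, label="s"):
    values = np.asarray(values, dtype=float)
    return EnergySeries(label=label, times=np.arange(len(values)) * dt, energies=values)


class TestSeries:
    def test_nonuniform_spacing_rejected(self):
        with pytest.raises(ValidationError):
            EnergySeries("x", times=[0.0, 1.0, 3.0], energies=[1.0, 2.0, 3.0])

    def test_table_roundtrip(self, tmp_path):
        s = series([1.5, 2.5, 3.5], dt=0.5)
        path = tmp_path / "e.dat"
        s.to_table(path)
        s2 = EnergySeries.from_table(path)
        np.testing.assert_allclose(s2.times, s.times)
        np.testing.assert_allclose(s2.energies, s.energies)

    def test_table_comments_ignored(self):
        text = io.StringIO("# time energy\n0.0 -10.0\n1.0 -12.0\n2.0 -11.0\n")
        s = EnergySeries.from_table(text)
        assert len(s.times) == 3

    def test_amber_mdout_importer(self):
        text = (
            " NSTEP =      500   TIME(PS) =     1000.000  TEMP(K) =   310.0\n"
            " Etot   =   -1000.5  EKtot  =  200.0\n"
            " NSTEP =     1000   TIME(PS) =     2000.000  TEMP(K) =   310.0\n"
            " Etot   =   -1002.5  EKtot  =  201.0\n"
        )
        s = read_amber_mdout(io.StringIO(text))
        np.testing.assert_allclose(s.times, [1.0, 2.0])
        np.testing.assert_allclose(s.energies, [-1000.5, -1002.5])


class TestWindowMean:
    def test_constant_series(self):
        s = series([7.0] * 10)
        assert window_mean(s, AnalysisWindow(0.0, 10.0)) == 7.0

    def test_full_coverage(self):
        s = series([1.0, 2.0, 3.0, 4.0])
        assert window_mean(s, AnalysisWindow(0.0, 4.0)) == pytest.approx(2.5)

    def test_partial_window_is_half_open(self):
        s = series([1.0, 2.0, 3.0, 4.0])
        # [2, 4) covers frames at t = 2, 3 only
        assert window_mean(s, AnalysisWindow(2.0, 4.0)) == pytest.approx(3.5)

    def test_adjacent_windows_partition_frames(self):
        s = series(np.arange(10.0))
        full = window_mean(s, AnalysisWindow(0.0, 10.0)) * 10
        left = window_mean(s, AnalysisWindow(0.0, 5.0)) * 5
        right = window_mean(s, AnalysisWindow(5.0, 10.0)) * 5
        assert left + right == pytest.approx(full)

    def test_empty_window_reports_frame_count(self):
        s = series([1.0, 2.0, 3.0])
        with pytest.raises(EmptyWindowError, match="0 frame"):
            window_mean(s, AnalysisWindow(10.0, 12.0))


class TestSem:
    def test_constant_series_has_zero_sem(self):
        s = series([3.0] * 50)
        w = AnalysisWindow(0.0, 50.0)
        assert sem_estimate(s, w, "naive") == 0.0
        assert sem_estimate(s, w, "block") == 0.0

    def test_naive_sem_matches_closed_form(self):
        rng = np.random.default_rng(0)
        sigma, n = 4.0, 4000
        sems = []
        for _ in range(40):
            s = series(rng.normal(0.0, sigma, n))
            sems.append(sem_estimate(s, AnalysisWindow(0.0, n), "naive"))
        assert np.mean(sems) == pytest.approx(sigma / np.sqrt(n), rel=0.05)

    def test_block_sem_exceeds_naive_under_autocorrelation(self):
        ratios = []
        for seed in range(30):
            s = generate_energy_series(
                SeriesSpec(n_frames=4000, dt=0.01, sd=2.0, ar1_phi=0.9, seed=seed)
            )
            w = AnalysisWindow(0.0, 40.0)
            ratios.append(
                sem_estimate(s, w, "block") / sem_estimate(s, w, "naive")
            )
        assert np.mean(ratios) > 1.5

    def test_too_few_blocks_rejected(self):
        s = series([1.0, 2.0, 3.0])
        with pytest.raises(EmptyWindowError):
            sem_estimate(s, AnalysisWindow(0.0, 3.0), "block", n_blocks=5)


class TestBindingEnthalpy:
    def test_identical_series_give_zero_unfavourable(self):
        s = series(np.sin(np.arange(100.0)))
        r = binding_enthalpy(s, s, AnalysisWindow(0.0, 100.0))
        assert r.delta_h == pytest.approx(0.0)
        assert r.classification == UNFAVOURABLE

    def test_planted_offset_recovered_within_3_sem(self):
        native = generate_energy_series(
            SeriesSpec(n_frames=2500, dt=0.01, mean=0.0, sd=5.0, seed=21)
        )
        cross = generate_energy_series(
            SeriesSpec(n_frames=2500, dt=0.01, mean=-10.0, sd=5.0, seed=22)
        )
        w = AnalysisWindow(0.0, 25.0)
        r = binding_enthalpy(cross, native, w)
        assert r.n_frames_used == 2500
        assert abs(r.delta_h - (-10.0)) <= 3 * r.sem
        assert r.classification == FAVOURABLE

    def test_spacing_mismatch_rejected(self):
        a = series([1.0, 2.0, 3.0, 4.0], dt=1.0)
        b = series([1.0, 2.0, 3.0, 4.0], dt=0.5)
        with pytest.raises(SeriesMismatchError):
            binding_enthalpy(a, b, AnalysisWindow(0.0, 2.0))

    def test_shift_linearity(self):
        rng = np.random.default_rng(5)
        base = rng.normal(-100.0, 3.0, 500)
        native = series(base)
        cross = series(rng.normal(-100.0, 3.0, 500))
        w = AnalysisWindow(0.0, 500.0)
        r0 = binding_enthalpy(cross, native, w)
        # adding c to both series leaves dH unchanged
        r1 = binding_enthalpy(
            series(cross.energies + 42.0), series(base + 42.0), w
        )
        assert r1.delta_h == pytest.approx(r0.delta_h, abs=1e-9)
        # adding c to the cross-linked series only shifts dH by exactly c
        r2 = binding_enthalpy(series(cross.energies + 42.0), native, w)
        assert r2.delta_h - r0.delta_h == pytest.approx(42.0, abs=1e-9)


class TestClassify:
    @pytest.mark.parametrize(
        "delta,expected",
        [(-13.572, FAVOURABLE), (-23.968, FAVOURABLE), (4.076, UNFAVOURABLE),
         (0.0, UNFAVOURABLE)],
    )
    def test_sign_convention(self, delta, expected):
        assert classify(delta) == expected

    def test_excluded_wins(self):
        assert classify(-50.0, excluded=True) == EXCLUDED

    @settings(max_examples=50, derandomize=True)
    @given(
        st.floats(min_value=-100.0, max_value=100.0, allow_nan=False),
        st.booleans(),
    )
    def test_pure_function_of_inputs(self, delta, excluded):
        assert classify(delta, excluded) == classify(delta, excluded)
        if not excluded:
            assert classify(delta) == (FAVOURABLE if delta < 0 else UNFAVOURABLE)


class TestConvergence:
    def test_constant_series_converges_immediately(self):
        s = series([5.0] * 100, dt=0.1)
        assert convergence_time(s, slope_tol=0.01, window_len=1.0) == 0.0

    def test_piecewise_drift_converges_near_breakpoint(self):
        dt = 0.01
        tol = 0.5  # kcal/mol per ns
        t = np.arange(0.0, 35.0, dt)
        drift = np.where(t < 30.0, 10.0 * tol * t, 10.0 * tol * 30.0)
        s = EnergySeries("drift", times=t, energies=drift)
        ct = convergence_time(s, slope_tol=tol, window_len=2.0)
        assert ct is not None
        # the slope only drops below tolerance once the window is nearly past
        # the drift: detection lands within one window length of 30 ns
        assert 30.0 - 2.0 <= ct <= 30.0

    def test_steep_drift_never_converges(self):
        s = series(np.arange(0.0, 100.0, 1.0))
        assert convergence_time(s, slope_tol=0.01, window_len=10.0) is None


class TestSummarize:
    def test_reference_rows_summary(self, table1_rows):
        results = []
        for row in table1_rows:
            if row.excluded:
                results.append(excluded_result(row.site_id))
            else:
                results.append(
                    EnthalpyResult(
                        site_id=row.site_id, delta_h=row.delta_h, sem=0.7,
                        window=None, n_frames_used=2500,
                        classification=classify(row.delta_h),
                    )
                )
        summary = summarize(results)
        assert summary.n_sites == 24
        assert summary.n_favourable == 6
        assert summary.n_not_favourable == 18
        assert summary.n_excluded == 2
        assert (summary.min_delta_h, summary.min_site_id) == (-36.130, 22)
        assert (summary.max_delta_h, summary.max_site_id) == (92.728, 15)

    def test_empty_input(self):
        summary = summarize([])
        assert summary.n_sites == 0
        assert summary.min_delta_h is None

    def test_counts_total_input_length(self):
        results = [
            excluded_result(1),
            EnthalpyResult(2, -1.0, 0.1, None, 10, FAVOURABLE),
            EnthalpyResult(3, 2.0, 0.1, None, 10, UNFAVOURABLE),
        ]
        s = summarize(results)
        assert (
            s.n_favourable + s.n_unfavourable + s.n_excluded + s.n_no_data
            == len(results)
        )

    def test_classification_consistency_enforced(self):
        with pytest.raises(ValidationError):
            EnthalpyResult(1, -5.0, 0.1, None, 10, UNFAVOURABLE)
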