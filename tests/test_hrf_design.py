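import numpy as np
import pandas as pd
import pytest

from synbold import hrf_design as hd
from synbold import predictors as pr
from synbold import synthetic_data as sd


class TestKernel:
    def test_starts_at_zero_and_peaks_near_peak_delay(self):
        spec = hd.HRFSpec()
        h = hd.hrf_kernel(spec)
        assert h[0] == 0.0
        t_peak = np.argmax(h) * spec.oversampling_dt
        assert 4.5 <= t_peak <= 6.5

    def test_undershoot_present(self):
        spec = hd.HRFSpec()
        h = hd.hrf_kernel(spec)
        t = np.arange(len(h)) * spec.oversampling_dt
        assert h[(t > 10) & (t < 30)].min() < 0

    def test_infinite_ratio_removes_undershoot(self):
        spec = hd.HRFSpec(peak_undershoot_ratio=1e12)
        assert hd.hrf_kernel(spec).min() >= -1e-9

    def test_matches_nilearn_spm_reference(self):
        # independent oracle: SPM's double gamma as computed in nilearn
        from nilearn.glm.first_level.hemodynamic_models import spm_hrf

        spec = hd.HRFSpec(oversampling_dt=0.1)
        ours = hd.hrf_kernel(spec)
        ref = spm_hrf(1.0, oversampling=10, time_length=32.1)
        n = min(len(ours), len(ref))
        a, b = ours[:n], ref[:n]
        # same double-gamma shape up to normalisation and the reference's
        # one-bin grid offset
        assert np.corrcoef(a, b)[0, 1] > 0.999
        t_peak_ours = np.argmax(a) * spec.oversampling_dt
        t_peak_ref = np.argmax(b) * spec.oversampling_dt
        assert abs(t_peak_ours - t_peak_ref) <= 0.15
        a_n, b_n = a / a.max(), b / b.max()
        assert np.max(np.abs(a_n - b_n)) < 0.08
        # undershoot depth matches on the normalised scale
        assert a_n.min() == pytest.approx(b_n.min(), abs=0.02)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            hd.HRFSpec(peak_delay=-1)
        with pytest.raises(ValueError):
            hd.HRFSpec(kernel_length=10.0)


class TestConvolveEvents:
    def test_single_impulse_reproduces_sampled_kernel(self):
        spec = hd.HRFSpec()
        col = hd.convolve_events([0.0], [1.0], spec, tr=1.5, n_scans=20)
        h = hd.hrf_kernel(spec)
        step = int(round(1.5 / spec.oversampling_dt))
        expected = np.zeros(20)
        for k in range(20):
            if k * step < len(h):
                expected[k] = h[k * step]
        np.testing.assert_allclose(col, expected, atol=1e-12)

    def test_zero_amplitudes_give_zero_column(self):
        col = hd.convolve_events([1.0, 5.0], [0.0, 0.0], n_scans=30)
        np.testing.assert_allclose(col, 0.0)

    def test_superposition(self, rng):
        spec = hd.HRFSpec()
        on = np.array([3.1, 17.4])
        a = hd.convolve_events([on[0]], [1.3], spec, 1.5, 60)
        b = hd.convolve_events([on[1]], [-0.7], spec, 1.5, 60)
        both = hd.convolve_events(on, [1.3, -0.7], spec, 1.5, 60)
        np.testing.assert_allclose(both, a + b, atol=1e-10)

    def test_linearity(self, rng):
        on = np.sort(rng.uniform(0, 80, size=40))
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        lhs = hd.convolve_events(on, 2.0 * x + 3.0 * y, n_scans=70)
        rhs = (
            2.0 * hd.convolve_events(on, x, n_scans=70)
            + 3.0 * hd.convolve_events(on, y, n_scans=70)
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_tr_shift_moves_one_scan(self, rng):
        on = np.sort(rng.uniform(0, 50, size=30))
        amp = rng.normal(size=30)
        base = hd.convolve_events(on, amp, tr=1.5, n_scans=60)
        shifted = hd.convolve_events(on + 1.5, amp, tr=1.5, n_scans=60)
        np.testing.assert_allclose(shifted[1:], base[:-1], atol=1e-8)

    def test_onset_beyond_run_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped"):
            col = hd.convolve_events([500.0], [1.0], n_scans=20)
        np.testing.assert_allclose(col, 0.0)


class TestTemporalDerivative:
    def test_zero_amplitudes_give_zeros(self):
        parent = hd.convolve_events([0.0], [0.0], n_scans=30)
        deriv = hd.temporal_derivative([0.0], [0.0], parent, n_scans=30)
        np.testing.assert_allclose(deriv, 0.0)

    def test_orthogonal_to_parent(self, rng):
        on = np.sort(rng.uniform(0, 60, size=50))
        amp = rng.normal(size=50)
        parent = hd.convolve_events(on, amp, n_scans=70)
        deriv = hd.temporal_derivative(on, amp, parent, n_scans=70)
        assert abs(parent @ deriv) < 1e-10 * np.linalg.norm(parent) * max(
            np.linalg.norm(deriv), 1.0
        )

    def test_captures_small_latency_shift(self, rng):
        # a response delayed by 0.5 s is approximated better by
        # parent + derivative than by the parent alone
        on = np.sort(rng.uniform(0, 120, size=80))
        amp = np.ones(80)
        parent = hd.convolve_events(on, amp, tr=1.5, n_scans=100)
        target = hd.convolve_events(on + 0.5, amp, tr=1.5, n_scans=100)
        deriv = hd.temporal_derivative(on, amp, parent, tr=1.5, n_scans=100)

        def resid(X):
            beta, *_ = np.linalg.lstsq(X, target, rcond=None)
            return np.sum((target - X @ beta) ** 2)

        r_parent = resid(parent[:, None])
        r_both = resid(np.column_stack([parent, deriv]))
        assert r_both < 0.5 * r_parent


@pytest.fixture(scope="module")
def word_table():
    cfg = sd.SimulationConfig(seed=5, n_participants=1, n_sentences=40,
                              n_scans=200)
    rng = np.random.default_rng(5)
    table, _ = sd.participant_word_table(cfg, rng, "p0")
    return pr.mean_center(table)


class TestDesignMatrix:

    def test_columns_finite_and_named(self, word_table):
        dm = hd.build_design_matrix(word_table, tr=1.5, n_scans=200)
        assert list(dm.columns) == list(hd.DEFAULT_COLUMNS)
        assert np.isfinite(dm.to_numpy()).all()
        assert dm.shape == (200, 9)
        # no constant column
        assert (dm.std() > 0).all()

    def test_word_rate_steady_state_ripple(self):
        # evenly spaced words: away from run edges the word-rate regressor
        # approaches a constant
        onsets = np.arange(0.0, 300.0, 0.4)
        col = hd.convolve_events(onsets, np.ones(len(onsets)), tr=1.5,
                                 n_scans=200)
        interior = col[30:170]
        ripple = (interior.max() - interior.min()) / interior.mean()
        assert ripple < 0.1

    def test_deterministic(self, word_table):
        a = hd.build_design_matrix(word_table, tr=1.5, n_scans=200)
        b = hd.build_design_matrix(word_table, tr=1.5, n_scans=200)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_column_raises(self, word_table):
        with pytest.raises(KeyError, match="missing"):
            hd.build_design_matrix(
                word_table.drop(columns=["surprisal"]), tr=1.5, n_scans=200
            )

    def test_derivative_columns_appended(self, word_table):
        dm = hd.build_design_matrix(word_table, tr=1.5, n_scans=200,
                                    derivatives=True)
        assert "top_down_derivative" in dm.columns
        r = np.corrcoef(dm["top_down"], dm["top_down_derivative"])[0, 1]
        assert abs(r) < 1e-8


class TestCollinearityReport:
    def test_duplicated_column_flagged(self, rng):
        x = rng.normal(size=50)
        dm = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=50)})
        rep = hd.collinearity_report(dm)
        row = rep[(rep.col_a == "a") & (rep.col_b == "b")].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert bool(row.flagged)

    def test_zero_variance_reported_na(self, rng):
        dm = pd.DataFrame({"a": np.ones(30), "b": rng.normal(size=30)})
        rep = hd.collinearity_report(dm)
        assert np.isnan(rep.iloc[0].r)

    def test_convolution_raises_parser_correlation(self):
        # smoothing with the HRF makes the structure-building regressors more
        # similar than their word-level counts
        cfg = sd.SimulationConfig(seed=11, n_participants=1, n_sentences=40,
                                  n_scans=200)
        rng = np.random.default_rng(11)
        table, _ = sd.participant_word_table(cfg, rng, "p0")
        raw_r = np.corrcoef(table["top_down"], table["early_top_down"])[0, 1]
        dm = hd.build_design_matrix(
            pr.mean_center(table), tr=1.5, n_scans=200,
            columns=("top_down", "early_top_down"),
        )
        conv_r = np.corrcoef(dm["top_down"], dm["early_top_down"])[0, 1]
        assert abs(conv_r) > abs(raw_r)
        assert abs(conv_r) > 0.7

    def test_boundary_regressors_positively_correlated_after_convolution(self):
        cfg = sd.SimulationConfig(seed=12, n_participants=1, n_sentences=40,
                                  n_scans=200)
        rng = np.random.default_rng(12)
        table, _ = sd.participant_word_table(cfg, rng, "p0")
        dm = hd.build_design_matrix(
            pr.mean_center(table), tr=1.5, n_scans=200,
            columns=("sentence_onset", "sentence_offset"),
        )
        r = np.corrcoef(dm["sentence_onset"], dm["sentence_offset"])[0, 1]
        assert r > 0
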