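"""FC estimation, Fisher transform, filtering and the reconfiguration statistic."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fcreconf import connectivity as cn
from fcreconf.exceptions import (
    ConsistencyError,
    DegenerateInputError,
    PairingError,
    ShapeError,
)

Z_MAX = float(np.arctanh(1 - 1e-7))


def _fc(values, subject="s1", state="rest"):
    return cn.FCMatrix(values=np.asarray(values, float), subject_id=subject, state=state)


class TestFisherZ:
    @pytest.mark.parametrize(
        "r, expected",
        [(0.0, 0.0), (0.5, np.arctanh(0.5)), (1.0, Z_MAX), (-1.0, -Z_MAX)],
    )
    def test_known_values(self, r, expected):
        assert cn.fisher_z(r) == pytest.approx(expected, abs=1e-12)

    def test_half_matches_printed_value(self):
        assert cn.fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cn.fisher_z(1.001)

    @given(st.floats(-0.999, 0.999))
    def test_inverse_round_trip_and_oddness(self, r):
        z = cn.fisher_z(r)
        assert cn.inverse_fisher_z(z) == pytest.approx(r, abs=1e-12)
        assert cn.fisher_z(-r) == pytest.approx(-z, abs=1e-12)


class TestFilters:
    TR = 1.25

    def _sine(self, freq, T=4096):
        t = np.arange(T) * self.TR
        return np.sin(2 * np.pi * freq * t)[:, None]

    def test_constant_column_removed(self):
        out = cn.bandpass_filter(np.full((256, 2), 3.0), 0.008, 0.08, self.TR)
        assert np.abs(out).max() < 1e-8
        out = cn.highpass_filter(np.full((256, 2), 3.0), 0.01, self.TR)
        assert np.abs(out).max() < 1e-8

    def test_passband_amplitude_preserved(self):
        x = self._sine(0.03)
        y = cn.bandpass_filter(x, 0.008, 0.08, self.TR)
        core = slice(500, -500)  # avoid reflection-padding edges
        ratio = np.abs(y[core]).max() / np.abs(x[core]).max()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_stopband_attenuated(self):
        x = self._sine(0.3)  # well above the 0.08 Hz edge, below Nyquist (0.4)
        y = cn.bandpass_filter(x, 0.008, 0.08, self.TR)
        core = slice(500, -500)  # forward-backward filtering has edge transients
        assert np.abs(y[core]).max() < 0.05 * np.abs(x[core]).max()

    def test_highpass_preserves_fast_component(self):
        x = self._sine(0.05)
        y = cn.highpass_filter(x, 0.01, self.TR)
        core = slice(500, -500)
        assert np.abs(y[core]).max() / np.abs(x[core]).max() == pytest.approx(1.0, abs=0.05)

    def test_highpass_removes_linear_trend(self):
        x = np.linspace(0, 10, 1024)[:, None]
        y = cn.highpass_filter(x, 0.01, self.TR)
        assert y.var() < 0.10 * x.var()

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            cn.bandpass_filter(np.zeros((128, 2)), 0.008, 0.5, self.TR)

    def test_filtered_columns_are_mean_free(self, rng):
        # the 5.0 offset (DC) is fully removed; the residual mean is a small
        # fraction of the remaining fluctuation scale
        x = rng.normal(size=(512, 3)) + 5.0
        y = cn.bandpass_filter(x, 0.008, 0.08, self.TR)
        assert np.abs(y.mean(axis=0)).max() < 0.05 * y.std(axis=0).min()


class TestFCFromTimeseries:
    def test_proportional_columns_hit_clip(self):
        ts = np.column_stack([[1, 2, 3, 4], [2, 4, 6, 8]])
        fc = cn.fc_from_timeseries(ts)
        assert fc.values[0, 1] == pytest.approx(Z_MAX)

    def test_anticorrelated_columns_hit_negative_clip(self):
        ts = np.column_stack([[1, 2, 3, 4], [4, 3, 2, 1]])
        fc = cn.fc_from_timeseries(ts)
        assert fc.values[0, 1] == pytest.approx(-Z_MAX)

    def test_matches_direct_pearson_computation(self, rng):
        ts = rng.normal(size=(6, 3))
        fc = cn.fc_from_timeseries(ts)
        # independent covariance-formula oracle
        for i in range(3):
            for j in range(i + 1, 3):
                xi = ts[:, i] - ts[:, i].mean()
                xj = ts[:, j] - ts[:, j].mean()
                r = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert fc.values[i, j] == pytest.approx(np.arctanh(r), abs=1e-12)

    def test_zero_variance_roi_named(self):
        ts = np.column_stack([np.ones(8), np.arange(8.0)])
        with pytest.raises(DegenerateInputError, match="ROI01"):
            cn.fc_from_timeseries(ts)

    def test_affine_rescaling_invariance(self, rng):
        ts = rng.normal(size=(30, 4))
        scaled = ts * np.array([2.0, 0.5, 7.0, 1.3]) + np.array([1, -4, 0, 9.0])
        a = cn.fc_from_timeseries(ts).values
        b = cn.fc_from_timeseries(scaled).values
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_diagonal_excluded(self, rng):
        fc = cn.fc_from_timeseries(rng.normal(size=(10, 3)))
        assert np.isnan(np.diag(fc.values)).all()


class TestAverageFC:
    def _pair(self, z1, z2):
        m1 = _fc(cn.devectorize(np.array(z1)), state="task_run1")
        m2 = _fc(cn.devectorize(np.array(z2)), state="task_run2")
        return m1, m2

    def test_identical_runs_idempotent(self):
        m1, m2 = self._pair([0.3, 0.1, -0.2], [0.3, 0.1, -0.2])
        avg = cn.average_fc([m1, m2])
        np.testing.assert_allclose(cn.vectorize_upper(avg), [0.3, 0.1, -0.2])

    def test_z_scale_arithmetic(self):
        m1, m2 = self._pair([0.2] * 3, [0.6] * 3)
        np.testing.assert_allclose(cn.vectorize_upper(cn.average_fc([m1, m2])), 0.4)

    def test_single_run_returned_unchanged(self):
        m1, _ = self._pair([0.3, 0.1, -0.2], [0.0] * 3)
        np.testing.assert_allclose(
            cn.vectorize_upper(cn.average_fc([m1])), [0.3, 0.1, -0.2]
        )

    def test_z_scale_mean_differs_from_r_scale_mean(self):
        z1, z2 = 0.2, 1.2
        z_scale = (z1 + z2) / 2
        r_scale = cn.fisher_z((np.tanh(z1) + np.tanh(z2)) / 2)
        m1, m2 = self._pair([z1] * 3, [z2] * 3)
        avg = cn.vectorize_upper(cn.average_fc([m1, m2]))[0]
        assert avg == pytest.approx(z_scale, abs=1e-12)
        assert abs(avg - r_scale) > 0.01  # the two conventions genuinely differ

    def test_mismatched_size_rejected(self):
        m1 = _fc(cn.devectorize(np.zeros(3)))
        m2 = _fc(cn.devectorize(np.zeros(6)))
        with pytest.raises(ShapeError):
            cn.average_fc([m1, m2])

    def test_mismatched_subject_rejected(self):
        m1 = _fc(cn.devectorize(np.zeros(3)), subject="s1")
        m2 = _fc(cn.devectorize(np.zeros(3)), subject="s2")
        with pytest.raises(PairingError):
            cn.average_fc([m1, m2])


class TestReconfiguration:
    def test_identical_states_give_zero(self):
        m = _fc(cn.devectorize(np.array([0.3, 0.1, -0.2])))
        np.testing.assert_array_equal(cn.reconfiguration(m, m).values, 0.0)

    @pytest.mark.parametrize(
        "rest_z, task_z, expected",
        [(0.30, 0.41, 0.11), (0.20, -0.10, 0.30), (-0.15, -0.05, 0.10)],
    )
    def test_absolute_difference(self, rest_z, task_z, expected):
        rest = _fc(cn.devectorize(np.full(3, rest_z)))
        task = _fc(cn.devectorize(np.full(3, task_z)))
        np.testing.assert_allclose(
            cn.reconfiguration(rest, task).values, expected, atol=1e-12
        )

    def test_symmetric_in_arguments(self, rng):
        a = _fc(cn.devectorize(rng.normal(size=10)))
        b = _fc(cn.devectorize(rng.normal(size=10)))
        np.testing.assert_array_equal(
            cn.reconfiguration(a, b).values, cn.reconfiguration(b, a).values
        )

    def test_subject_mismatch_rejected(self):
        a = _fc(cn.devectorize(np.zeros(3)), subject="s1")
        b = _fc(cn.devectorize(np.zeros(3)), subject="s2")
        with pytest.raises(PairingError):
            cn.reconfiguration(a, b)


class TestEdgeVectorization:
    def test_sixteen_rois_give_120_edges(self):
        m = _fc(cn.devectorize(np.arange(120.0)))
        assert m.n_rois == 16
        assert cn.vectorize_upper(m).size == 120

    def test_row_major_ordering(self):
        values = np.array([[np.nan, 1.0, 2.0], [1.0, np.nan, 3.0], [2.0, 3.0, np.nan]])
        np.testing.assert_array_equal(cn.vectorize_upper(values), [1.0, 2.0, 3.0])

    def test_devectorize_round_trip(self, rng):
        edges = rng.normal(size=28)
        np.testing.assert_array_equal(
            cn.vectorize_upper(cn.devectorize(edges)), edges
        )

    def test_asymmetry_rejected(self):
        bad = np.array([[0.0, 1.0], [1.0 + 1e-6, 0.0]])
        with pytest.raises(ConsistencyError):
            cn.vectorize_upper(bad)

    def test_invalid_edge_count_rejected(self):
        with pytest.raises(ShapeError):
            cn.devectorize(np.zeros(4))

    def test_edge_pair_labels(self):
        labels = cn.edge_pair_labels(["ROI01", "ROI02", "ROI03"])
        assert labels == ["ROI01-ROI02", "ROI01-ROI03", "ROI02-ROI03"]
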