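"""Volume dropping, confound regression and band-pass filtering."""

import numpy as np
import pytest

from atlasfusion import VoxelSeriesSet, bandpass, drop_initial_volumes, linear_drift, regress_confounds


def _series_set(data, tr=2.0):
    data = np.atleast_2d(data)
    idx = np.zeros((data.shape[0], 3), dtype=int)
    idx[:, 0] = np.arange(data.shape[0])
    return VoxelSeriesSet(
        data=data, mask_indices=idx, tr_seconds=tr, grid_shape=(data.shape[0], 1, 1)
    )


class TestDropInitialVolumes:
    def test_paper_like_counts(self):
        series = np.zeros((2, 2, 2, 239))
        assert drop_initial_volumes(series, 10).shape[-1] == 229

    def test_zero_is_identity(self, rng):
        series = rng.standard_normal((2, 2, 2, 20))
        assert np.array_equal(drop_initial_volumes(series, 0), series)

    def test_dropping_too_many_fails(self):
        with pytest.raises(ValueError):
            drop_initial_volumes(np.zeros((2, 2, 2, 20)), 25)


class TestRegressConfounds:
    def test_series_equal_to_confound_leaves_zero_residual(self, rng):
        conf = rng.standard_normal((64, 1))
        ts = _series_set(np.tile(conf.T, (3, 1)))
        out = regress_confounds(ts, conf)
        assert np.allclose(out.data, 0.0, atol=1e-10)

    def test_empty_confounds_demean(self, rng):
        data = rng.standard_normal((4, 64))
        ts = _series_set(data)
        out = regress_confounds(ts, np.empty((64, 0)))
        assert np.allclose(out.data, data - data.mean(axis=1, keepdims=True))

    def test_matches_normal_equations_oracle(self, rng):
        data = rng.standard_normal((5, 80))
        conf = rng.standard_normal((80, 4))
        out = regress_confounds(_series_set(data), conf)
        design = np.column_stack([np.ones(80), conf])
        beta = np.linalg.solve(design.T @ design, design.T @ data.T)
        oracle = data - (design @ beta).T
        assert np.allclose(out.data, oracle, atol=1e-8)

    def test_residuals_orthogonal_to_confounds(self, rng):
        data = rng.standard_normal((3, 100))
        conf = np.column_stack([rng.standard_normal((100, 2)), linear_drift(100)])
        out = regress_confounds(_series_set(data), conf)
        assert np.allclose(out.data @ conf, 0.0, atol=1e-8)

    def test_idempotent(self, rng):
        data = rng.standard_normal((3, 64))
        conf = rng.standard_normal((64, 3))
        once = regress_confounds(_series_set(data), conf)
        twice = regress_confounds(once, conf)
        assert np.allclose(once.data, twice.data, atol=1e-10)

    def test_rank_deficient_confounds_warn_but_solve(self, rng, caplog):
        conf = rng.standard_normal((64, 2))
        conf = np.column_stack([conf, conf[:, 0]])  # duplicated column
        out = regress_confounds(_series_set(rng.standard_normal((2, 64))), conf)
        assert np.allclose(out.data @ conf, 0.0, atol=1e-8)
        assert any("rank deficient" in r.getMessage() for r in caplog.records)

    def test_row_count_mismatch_fails(self, rng):
        with pytest.raises(ValueError):
            regress_confounds(_series_set(rng.standard_normal((2, 64))), np.zeros((50, 2)))


class TestBandpass:
    # TR = 2 s, 200 volumes: 400 s record, so 0.05 Hz and 0.2 Hz fall on
    # exact DFT bins (20 and 80) and amplitude checks are clean.
    def _sinusoid(self, freq_hz, n=200, tr=2.0):
        t = np.arange(n) * tr
        return np.sin(2 * np.pi * freq_hz * t)

    def test_passband_amplitude_preserved(self):
        ts = _series_set(self._sinusoid(0.05))
        out = bandpass(ts, 0.01, 0.10)
        in_rms = np.sqrt((ts.data**2).mean())
        out_rms = np.sqrt((out.data**2).mean())
        assert abs(out_rms - in_rms) / in_rms < 0.05

    def test_stopband_attenuated(self):
        ts = _series_set(self._sinusoid(0.2))
        out = bandpass(ts, 0.01, 0.10)
        assert np.sqrt((out.data**2).mean()) < 0.1 * np.sqrt((ts.data**2).mean())

    def test_dc_removed(self):
        ts = _series_set(np.full((1, 64), 5.0))
        out = bandpass(ts, 0.01, 0.10)
        assert np.allclose(out.data, 0.0, atol=1e-10)

    def test_brickwall_filter_is_a_projection(self, rng):
        ts = _series_set(rng.standard_normal((3, 128)))
        once = bandpass(ts, 0.01, 0.10)
        twice = bandpass(once, 0.01, 0.10)
        assert np.allclose(once.data, twice.data, atol=1e-10)

    def test_butterworth_alternative_attenuates_stopband(self):
        # zero-phase IIR filtering leaves edge transients on short records,
        # so judge the steady-state interior of the series
        ts = _series_set(self._sinusoid(0.2))
        out = bandpass(ts, 0.01, 0.10, method="butterworth")
        core = slice(50, 150)
        in_rms = np.sqrt((ts.data[:, core] ** 2).mean())
        out_rms = np.sqrt((out.data[:, core] ** 2).mean())
        assert out_rms < 0.1 * in_rms

    def test_band_above_nyquist_fails(self, rng):
        ts = _series_set(rng.standard_normal((1, 64)), tr=2.0)  # Nyquist 0.25 Hz
        with pytest.raises(ValueError):
            bandpass(ts, 0.01, 0.3)


class TestVoxelSeriesSet:
    def test_too_few_timepoints_rejected(self, rng):
        with pytest.raises(ValueError):
            _series_set(rng.standard_normal((2, 16)))

    def test_non_finite_rejected(self, rng):
        data = rng.standard_normal((2, 64))
        data[0, 5] = np.nan
        with pytest.raises(ValueError):
            _series_set(data)

    def test_from_4d_extracts_mask_rows(self, rng):
        vol = rng.standard_normal((4, 4, 4, 40))
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 2, 3] = mask[0, 0, 0] = True
        ts = VoxelSeriesSet.from_4d(vol, mask, tr_seconds=2.0, drop_initial=5)
        assert ts.n_voxels == 2
        assert ts.n_timepoints == 35
        assert ts.n_dropped_initial == 5
        assert np.allclose(ts.data[1], vol[1, 2, 3, 5:])
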