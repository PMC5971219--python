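import numpy as np
import pytest
from hypothesis import given, strategies as st

from babydcm.design import build_block_design
from babydcm.preprocess import (
    ArtifactMask,
    ChannelTimeSeries,
    default_extinction_matrix,
    design_filters,
    detect_artifacts,
    epoch_average,
    intensity_to_od,
    mbll,
    mbll_forward,
    moving_std,
    od_to_intensity,
    spline_correct,
    temporal_filter,
)


def _series(values, fs=10.0, kind="optical_density"):
    return ChannelTimeSeries(values, fs, kind)


class TestOpticalDensity:
    def test_constant_intensity_gives_zero_od(self):
        s = _series(np.full((2, 50), 3.7), kind="intensity")
        od = intensity_to_od(s)
        assert np.allclose(od.values, 0.0)

    def test_intensity_over_e_gives_unit_od(self):
        vals = np.ones((1, 10))
        vals[0, 5] = 1.0 / np.e
        s = _series(vals, kind="intensity")
        od = intensity_to_od(s, baseline_window=(0.0, 0.4))
        assert od.values[0, 5] == pytest.approx(1.0, abs=1e-12)

    def test_round_trip(self, rng):
        vals = np.exp(rng.normal(0, 0.1, size=(3, 100)))
        s = _series(vals, kind="intensity")
        od = intensity_to_od(s)
        back = od_to_intensity(od)
        assert np.allclose(back.values, vals, atol=1e-12)

    def test_nonpositive_intensity_located(self):
        vals = np.ones((2, 10))
        vals[1, 3] = -1.0
        with pytest.raises(ValueError, match="channel 1, sample 3"):
            intensity_to_od(_series(vals, kind="intensity"))


class TestMBLL:
    def test_zero_od_gives_zero_concentration(self):
        conc = mbll(_series(np.zeros((4, 20))))
        assert np.allclose(conc.values, 0.0)
        assert conc.kind == "concentration"

    def test_forward_inverse_round_trip_dpf_513(self, rng):
        hbo = rng.normal(0, 1.0, size=(9, 200))
        hbr = rng.normal(0, 0.5, size=(9, 200))
        od = mbll_forward(hbo, hbr, distance_mm=20.0, dpf=5.13)
        conc = mbll(_series(od), distance_mm=20.0, dpf=5.13)
        assert np.allclose(conc.values[:9], hbo, atol=1e-10)
        assert np.allclose(conc.values[9:], hbr, atol=1e-10)

    def test_doubling_dpf_halves_concentrations(self, rng):
        od = rng.normal(0, 0.01, size=(2, 50))
        c1 = mbll(_series(od), dpf=5.13).values
        c2 = mbll(_series(od), dpf=10.26).values
        assert np.allclose(c2, c1 / 2, atol=1e-12)

    @given(
        st.tuples(*[st.floats(0.2, 2.0) for _ in range(4)]).filter(
            lambda e: abs(e[0] * e[3] - e[1] * e[2]) > 0.05
        )
    )
    def test_round_trip_for_any_invertible_extinction(self, eps):
        extinction = np.array(eps).reshape(2, 2)
        rng = np.random.default_rng(7)
        hbo = rng.normal(0, 1, (1, 30))
        hbr = rng.normal(0, 1, (1, 30))
        od = mbll_forward(hbo, hbr, extinction)
        conc = mbll(_series(od), extinction)
        assert np.allclose(conc.values, np.vstack([hbo, hbr]), atol=1e-8)

    def test_singular_extinction_rejected(self):
        with pytest.raises(ValueError, match="uninformative"):
            mbll(_series(np.zeros((2, 10))), extinction=np.array([[1.0, 1.0], [1.0, 1.0]]))


class TestTemporalFilter:
    def _attenuation_db(self, freq, fs=10.0):
        t = np.arange(int(600 * fs)) / fs
        x = np.sin(2 * np.pi * freq * t)
        y = temporal_filter(_series(x[None, :], fs)).values[0]
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        return 20 * np.log10(np.std(y[mid]) / np.std(x[mid]))

    def test_mayer_band_attenuated_by_20db(self):
        assert self._attenuation_db(0.10) < -20.0

    def test_task_band_preserved_within_1db(self):
        assert abs(self._attenuation_db(0.03)) < 1.0

    def test_constant_offset_removed(self):
        y = temporal_filter(_series(np.full((1, 6000), 5.0))).values
        assert np.abs(y.mean()) < 1e-6 * 5.0

    def test_linearity(self, rng):
        x = rng.normal(0, 1, (1, 3000))
        y = rng.normal(0, 1, (1, 3000))
        fa = temporal_filter(_series(2 * x + 3 * y)).values
        fb = 2 * temporal_filter(_series(x)).values + 3 * temporal_filter(_series(y)).values
        assert np.allclose(fa, fb, atol=1e-9)

    def test_stopband_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            design_filters(2.0, stopbands=((0.8, 1.8),))


class TestArtifacts:
    def test_constant_series_unflagged(self):
        mask = detect_artifacts(_series(np.ones((2, 100)), kind="concentration"))
        assert not mask.any_flagged

    def test_toy_step_flagged_near_transition(self):
        # hand computation: a 10 uM step in a 10-sample (1 s) window gives a
        # moving SD of 10*sqrt(k(w-k))/sqrt(w(w-1)) ~ 5 uM > 3 uM near the edge
        x = np.zeros((1, 100))
        x[0, 50:] = 10.0
        mask = detect_artifacts(_series(x, kind="concentration"))
        flagged = np.nonzero(mask.flags[0])[0]
        assert flagged.size > 0
        assert flagged.min() >= 45 and flagged.max() <= 55
        assert 50 in flagged

    def test_infinite_threshold_flags_nothing(self, rng):
        x = rng.normal(0, 5, (3, 200))
        mask = detect_artifacts(_series(x, kind="concentration"), threshold_uM=np.inf)
        assert not mask.any_flagged

    def test_offset_invariance(self, rng):
        x = rng.normal(0, 1, (2, 300))
        m1 = detect_artifacts(_series(x, kind="concentration"), threshold_uM=1.5)
        m2 = detect_artifacts(_series(x + 100.0, kind="concentration"), threshold_uM=1.5)
        assert np.array_equal(m1.flags, m2.flags)

    def test_moving_std_matches_pandas(self, rng):
        import pandas as pd

        x = rng.normal(0, 1, 50)
        ours = moving_std(x[None], 10)[0]
        theirs = (
            pd.Series(x).rolling(10, center=True, min_periods=1).std().to_numpy()
        )
        assert np.allclose(ours, np.nan_to_num(theirs, nan=0.0), atol=1e-10)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="window"):
            detect_artifacts(_series(np.zeros((1, 5)), kind="concentration"), window_s=1.0)


class TestSplineCorrection:
    def test_empty_mask_is_identity(self, rng):
        x = rng.normal(0, 1, (2, 100))
        s = _series(x, kind="concentration")
        mask = ArtifactMask(np.zeros_like(x, dtype=bool), 1.0, 3.0)
        out = spline_correct(s, mask)
        assert np.array_equal(out.values, x)

    def test_spike_removed_within_10pct_rms(self):
        # slow physiological sinusoid (nearly constant over the flagged 4 s)
        # plus one large decaying motion spike
        fs = 10.0
        t = np.arange(600) / fs
        clean = np.sin(2 * np.pi * 0.01 * t - 0.44)  # flat (peak) over the segment
        spiked = clean.copy()
        seg = slice(300, 340)
        spiked[seg] += 8.0 * np.exp(-(t[seg] - t[300]) / 1.0)
        s = _series(spiked[None], kind="concentration")
        flags = np.zeros((1, 600), dtype=bool)
        flags[0, seg] = True
        out = spline_correct(s, ArtifactMask(flags, 1.0, 3.0))
        resid = out.values[0, seg] - clean[seg]
        assert np.sqrt(np.mean(resid**2)) < 0.1 * np.sqrt(np.mean(clean[seg] ** 2))

    def test_unflagged_samples_bit_identical(self, rng):
        x = rng.normal(0, 1, (1, 200))
        flags = np.zeros_like(x, dtype=bool)
        flags[0, 80:100] = True
        out = spline_correct(_series(x, kind="concentration"), ArtifactMask(flags, 1, 3))
        assert np.array_equal(out.values[0, :80], x[0, :80])
        assert np.array_equal(out.values[0, 100:], x[0, 100:])

    def test_fully_flagged_channel_rejected(self):
        x = np.zeros((1, 50))
        flags = np.ones_like(x, dtype=bool)
        with pytest.raises(ValueError, match="exclude"):
            spline_correct(_series(x, kind="concentration"), ArtifactMask(flags, 1, 3))


class TestEpochAverage:
    @pytest.fixture(scope="class")
    def design(self):
        return build_block_design(seed=5)

    def test_identical_epochs_average_to_one_epoch(self, design):
        fs = design.sampling_rate
        T = design.n_samples
        # build a signal that repeats identically around every onset
        x = np.zeros(T)
        # 22 s template: short enough that epochs never overlap (>= 22 s
        # onset spacing), so every extracted epoch is bit-identical
        template = np.sin(np.linspace(0, np.pi, 200))
        for ev in design.events:
            i = int(round(ev.onset * fs))
            x[i : i + 200] += template
        avg = epoch_average(_series(x[None]), design, (-2.0, 22.0))
        w = avg.window_samples
        expected = np.concatenate([np.zeros(20), template, np.zeros(20)])
        expected = expected - expected[:20].mean()
        for c in range(len(avg.conditions)):
            seg = avg.data[0, c * w : (c + 1) * w]
            assert np.allclose(seg, expected, atol=1e-9)

    def test_two_condition_averages_from_12_plus_12(self, design):
        avg = epoch_average(_series(np.zeros((1, design.n_samples))), design, (-2, 22))
        assert avg.conditions == ["V", "NV"]
        assert avg.n_epochs == {"V": 12, "NV": 12}
        assert avg.data.shape[1] == 2 * avg.window_samples

    def test_noise_variance_shrinks_as_one_over_n(self, design, rng):
        # Monte-Carlo: averaged white noise variance ~ single epoch / 12
        ratios = []
        for _ in range(10):
            x = rng.normal(0, 1, (1, design.n_samples))
            avg = epoch_average(_series(x), design, (-2, 22))
            ratios.append(avg.data.var())
        # baselining inflates slightly above 1/12
        assert np.mean(ratios) == pytest.approx(1 / 12, rel=0.3)

    def test_split_half_noise_estimate_scale(self, design, rng):
        x = rng.normal(0, 1, (1, design.n_samples))
        avg = epoch_average(_series(x), design, (-2, 22))
        # the split-half estimate has the same variance as the average itself
        assert avg.noise_estimate.var() == pytest.approx(avg.data.var(), rel=0.5)
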