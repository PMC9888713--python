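"""MRW tuning-curve evaluation and the rectified response operator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mrwfbra as m
from mrwfbra.mrw_model import mrw_weights


class TestPhiStar:
    def test_symmetric_weight_is_half(self):
        f = np.linspace(0, 8, 100)
        assert np.allclose(m.phi_star(f, mu=3.0, w=0.3, s=0.0), 0.5)

    def test_value_at_mu(self):
        assert m.phi_star(3.0, mu=3.0, w=0.3, s=1.0) == pytest.approx(0.5)

    def test_cdf_limits(self):
        assert m.phi_star(-50.0, mu=3.0, w=0.3, s=1.0) == pytest.approx(0.0, abs=1e-12)
        assert m.phi_star(50.0, mu=3.0, w=0.3, s=1.0) == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        f=st.floats(-10, 10),
        s=st.floats(-1, 1),
        w=st.floats(0.05, 2.0),
    )
    def test_bounded_in_unit_interval(self, f, s, w):
        v = m.phi_star(f, mu=0.0, w=w, s=s)
        assert 0.0 <= v <= 1.0


class TestMRWEval:
    def test_ricker_limit(self, axis):
        """IE=1, s=0 equals the classic Ricker wavelet bin-for-bin."""
        p = m.MRWParams(mu=np.log2(8), w=0.3, IE=1.0, s=0.0)
        curve = m.mrw_eval(p, axis)
        x = axis.oct - p.mu
        ricker = (1 - x**2 / p.w**2) * np.exp(-(x**2) / (2 * p.w**2))
        assert np.abs(curve.weights - ricker).max() < 1e-9

    def test_gaussian_limit(self, axis):
        """IE=0, s=0 equals a unit-peak Gaussian; no negative lobe."""
        p = m.MRWParams(mu=np.log2(8), w=0.3, IE=0.0, s=0.0)
        curve = m.mrw_eval(p, axis)
        x = axis.oct - p.mu
        gauss = np.exp(-(x**2) / (2 * p.w**2))
        assert np.abs(curve.weights - gauss).max() < 1e-9
        assert curve.weights.min() >= 0.0

    def test_ricker_zero_crossings_at_w(self, axis):
        p = m.MRWParams(mu=np.log2(8), w=0.3, IE=1.0, s=0.0)
        raw = mrw_weights(p, np.array([p.mu - p.w, p.mu + p.w]))
        assert np.allclose(raw, 0.0, atol=1e-12)

    def test_full_skew_one_sided_inhibition(self, axis):
        """s=1 leaves meaningful inhibition only above mu: the sigmoid tail
        passes < 0.5% of the peak into the lower flank (numeric scan), while
        the upper flank keeps a deep negative lobe."""
        p = m.MRWParams(mu=np.log2(8), w=0.3, IE=1.0, s=1.0)
        curve = m.mrw_eval(p, axis)
        below = curve.weights[axis.oct < p.mu]
        above = curve.weights[axis.oct > p.mu]
        assert below.min() >= -0.005
        assert above.min() < -0.1
        assert abs(below.min()) < 0.02 * abs(above.min())

    def test_normalized_maximum_is_one(self, axis):
        rng = np.random.default_rng(11)
        for _ in range(200):
            p = m.MRWParams(
                mu=rng.uniform(1, 7),
                w=rng.uniform(0.05, 2.0),
                IE=rng.uniform(0, 1),
                s=rng.uniform(-1, 1),
            )
            assert abs(m.mrw_eval(p, axis).weights.max() - 1.0) < 1e-9

    def test_skew_mirror_symmetry(self, axis):
        """mrw(f; s) mirrored about mu equals mrw(2 mu - f; -s)."""
        mu = 4.0  # octaves; exactly on the bin grid so mirroring is exact
        x = axis.oct
        for s in (0.3, 0.8, 1.0):
            p_pos = m.MRWParams(mu=mu, w=0.4, IE=0.9, s=s)
            p_neg = m.MRWParams(mu=mu, w=0.4, IE=0.9, s=-s)
            w_pos = mrw_weights(p_pos, x)
            w_neg = mrw_weights(p_neg, 2 * mu - x)
            assert np.abs(w_pos - w_neg).max() < 1e-9

    def test_peak_outside_axis_rejected(self, axis):
        p = m.MRWParams(mu=20.0, w=0.3, IE=1.0, s=0.0)
        with pytest.raises(ValueError):
            m.mrw_eval(p, axis)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            m.MRWParams(mu=3.0, w=0.01, IE=0.5, s=0.0)
        with pytest.raises(ValueError):
            m.MRWParams(mu=3.0, w=0.3, IE=1.5, s=0.0)
        with pytest.raises(ValueError):
            m.MRWParams(mu=3.0, w=0.3, IE=0.5, s=-2.0)


class TestRespond:
    def test_zero_stimulus_gives_zero(self, axis):
        p = m.MRWParams(mu=np.log2(8), w=0.3, IE=1.0, s=0.0)
        curve = m.mrw_eval(p, axis)
        stim = m.SpectrumVector(axis=axis, weights=np.zeros(len(axis)))
        assert m.respond(curve, stim) == 0.0

    def test_stimulus_in_inhibitory_lobe_rectified_to_zero(self, axis):
        p = m.MRWParams(mu=np.log2(8), w=0.2, IE=1.0, s=0.0)
        curve = m.mrw_eval(p, axis)
        # narrow band sitting inside the upper inhibitory lobe, no widening
        x = axis.oct
        w = np.where((x > p.mu + 1.1 * p.w) & (x < p.mu + 1.6 * p.w), 1.0, 0.0)
        stim = m.SpectrumVector(axis=axis, weights=w)
        assert m.respond(curve, stim) == 0.0

    def test_axis_mismatch_rejected(self, axis):
        other = m.FrequencyAxis(1.0, 256.0, 0.01)
        p = m.MRWParams(mu=np.log2(8), w=0.3, IE=0.0, s=0.0)
        curve = m.mrw_eval(p, axis)
        stim = m.SpectrumVector(axis=other, weights=np.zeros(len(other)))
        with pytest.raises(ValueError):
            m.respond(curve, stim)

    def test_resolution_independence(self):
        """step_oct as integration measure: responses agree across grid steps."""
        p = m.MRWParams(mu=np.log2(8), w=0.3, IE=0.5, s=0.5)
        spec = m.StimulusSpec(kind=m.StimKind.bbs, f_c=8.0, b=0.6)
        vals = []
        for step in (0.005, 0.0025):
            ax = m.FrequencyAxis(1.0, 256.0, step)
            vals.append(m.respond(m.mrw_eval(p, ax), m.spectral_vector(spec, ax)))
        assert vals[0] == pytest.approx(vals[1], rel=1e-3)


class TestModelFBRA:
    def test_gaussian_columns_monotone_in_bandwidth(self, grid11, axis):
        """An energy-summing (IE=0) unit never loses response as b grows."""
        p = m.MRWParams(mu=np.log2(8), w=0.3, IE=0.0, s=0.0)
        fbra = m.model_fbra(p, grid11, axis)
        diffs = np.diff(fbra.values, axis=0)  # rows ordered by bandwidth
        assert diffs.min() >= -1e-12

    def test_skewed_ricker_column_nonmonotonic(self, grid11, axis):
        """With one-sided inhibition, widening past the sideband suppresses."""
        p = m.MRWParams(mu=np.log2(8), w=0.2, IE=1.0, s=1.0)
        fbra = m.model_fbra(p, grid11, axis)
        col = fbra.values[:, 3]  # f_c just below mu: top edge sweeps the lobe
        k = col.argmax()
        assert 0 < k < len(col) - 1  # rises while the band fills the peak...
        assert col[-1] < 0.6 * col[k]  # ...then the top edge hits inhibition

    def test_positive_homogeneity(self, grid11, axis):
        p = m.MRWParams(mu=np.log2(8), w=0.3, IE=0.8, s=0.5)
        S = m.stimulus_matrix(grid11, axis)
        f1 = m.model_fbra(p, grid11, axis, S=S)
        f2 = m.model_fbra(p, grid11, axis, S=0.7 * S)
        assert np.allclose(f2.values, 0.7 * f1.values)

    def test_values_nonnegative(self, grid11, axis):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = m.MRWParams(
                mu=rng.uniform(2, 4.5),
                w=rng.uniform(0.05, 1.0),
                IE=rng.uniform(0, 1),
                s=rng.uniform(-1, 1),
            )
            assert m.model_fbra(p, grid11, axis).values.min() >= 0.0


class TestModelNotch:
    def test_notch_far_from_mu_equals_full_band(self, notch_grid11, axis):
        """A notch well away from the tuning curve removes nothing."""
        p = m.MRWParams(mu=np.log2(6), w=0.1, IE=0.0, s=0.0)
        curve = m.mrw_eval(p, axis)
        # full-band profile = the widest-notch grid's band with no dip
        x = axis.oct
        band = (x >= 1.0) & (x <= np.log2(notch_grid11.band_hi_khz))
        full = m.respond(curve, m.SpectrumVector(axis=axis, weights=band.astype(float)))
        nf = m.model_nfbra(p, notch_grid11, axis)
        # notch centered at the top frequency, far from mu = 6 kHz
        j = len(notch_grid11.center_freqs) - 1
        narrow_far = nf.values[0, j]  # narrowest notch, farthest f_c
        assert narrow_far == pytest.approx(full, rel=1e-3)

    def test_notch_covering_support_kills_response(self, notch_grid11, axis):
        p = m.MRWParams(mu=np.log2(8), w=0.08, IE=0.0, s=0.0)
        nf = m.model_nfbra(p, notch_grid11, axis)
        j = list(notch_grid11.center_freqs).index(8.0)
        widest = nf.values[-1, j]
        narrow_far = nf.values[0, 0]
        assert widest < 0.1 * narrow_far

    def test_bbs_notch_additivity_for_gaussian_unit(self, grid11, notch_grid11, axis):
        """BBS response + notch response = full-band response when nothing
        rectifies (IE=0) and the supports stay inside the band."""
        p = m.MRWParams(mu=np.log2(8), w=0.15, IE=0.0, s=0.0)
        curve = m.mrw_eval(p, axis)
        x = axis.oct
        band = (x >= 1.0) & (x <= np.log2(notch_grid11.band_hi_khz))
        full = m.respond(curve, m.SpectrumVector(axis=axis, weights=band.astype(float)))
        fb = m.model_fbra(p, grid11, axis)
        nf = m.model_nfbra(p, notch_grid11, axis)
        j = list(grid11.center_freqs).index(8.0)
        for i_bw in (1, 5, 10):  # skip the pure-tone row of the BBS grid
            b = grid11.bandwidths[i_bw]
            i_notch = list(notch_grid11.bandwidths).index(b)
            total = fb.values[i_bw, j] + nf.values[i_notch, j]
            assert total == pytest.approx(full, rel=1e-6)
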