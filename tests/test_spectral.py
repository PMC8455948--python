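"""Spectral chain: detrending, nuisance regression, FFT power, band ratio."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scontrast import (
    BandSpec,
    Bold4D,
    band_rv,
    compute_scm_map,
    compute_spectrum,
    detrend,
    regress_nuisance,
    scm_value,
    zscore_map,
)

from conftest import make_map, single_voxel_bold


def dft_power_oracle(x, tr):
    """O(T^2) cosine/sine least-squares amplitudes, unit-sinusoid convention."""
    T = len(x)
    t = np.arange(T)
    n_bins = T // 2 + 1
    power = np.zeros(n_bins)
    for k in range(n_bins):
        self_conj = k == 0 or (T % 2 == 0 and k == T // 2)
        scale = (1.0 if self_conj else 2.0) / T
        a = scale * (x * np.cos(2 * np.pi * k * t / T)).sum()
        b = scale * (x * np.sin(2 * np.pi * k * t / T)).sum()
        power[k] = a * a + b * b
    return power


class TestDetrend:
    def test_constant_removed(self):
        assert np.allclose(detrend([5.0, 5, 5, 5]), 0.0, atol=1e-12)

    def test_pure_line_removed(self):
        assert np.allclose(detrend([1.0, 2, 3, 4]), 0.0, atol=1e-12)

    def test_line_plus_sinusoid_matches_ols_residual_oracle(self, rng):
        T = 60
        t = np.arange(T, dtype=float)
        x = 0.7 * t - 3.0 + np.sin(2 * np.pi * 5 * t / T)
        design = np.column_stack([np.ones(T), t])
        beta = np.linalg.solve(design.T @ design, design.T @ x)
        oracle = x - design @ beta
        assert np.allclose(detrend(x), oracle, atol=1e-8)

    def test_output_has_zero_mean_and_slope(self, rng):
        x = rng.normal(size=100) + np.linspace(-4, 9, 100)
        d = detrend(x)
        assert abs(d.mean()) < 1e-10
        assert abs(np.polyfit(np.arange(100), d, 1)[0]) < 1e-10

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="T >= 3"):
            detrend([1.0, 2.0])


class TestNuisanceRegression:
    def test_series_equal_to_regressor_gives_zero(self, rng):
        r = rng.normal(size=(30, 1))
        assert np.allclose(regress_nuisance(r[:, 0], r), 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        T, R = 50, 4
        y = rng.normal(size=T)
        regs = rng.normal(size=(T, R))
        design = np.column_stack([np.ones(T), regs])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        oracle = y - design @ beta
        resid = regress_nuisance(y, regs)
        assert np.allclose(resid, oracle, atol=1e-8)
        # residual orthogonal to every regressor column
        assert np.all(np.abs(resid @ regs) < 1e-8 * np.abs(regs).sum(axis=0))

    def test_rank_deficiency_names_columns(self, rng):
        r = rng.normal(size=(20, 2))
        regs = np.column_stack([r, r[:, 0] + r[:, 1]])
        with pytest.raises(ValueError, match="collinear"):
            regress_nuisance(rng.normal(size=20), regs)


class TestSpectrum:
    def test_exact_bin_cosine_has_unit_power(self):
        T, k0 = 64, 7
        x = np.cos(2 * np.pi * k0 * np.arange(T) / T)
        spec = compute_spectrum(x, tr=2.0)
        assert spec.power[k0] == pytest.approx(1.0, abs=1e-12)
        others = np.delete(spec.power, k0)
        assert others.max() < 1e-20

    def test_all_zero_series(self):
        spec = compute_spectrum(np.zeros(16), tr=2.0)
        assert np.all(spec.power == 0)

    def test_matches_direct_dft_oracle(self, rng):
        for T in (16, 17, 33, 64):
            x = rng.normal(size=T)
            spec = compute_spectrum(x, tr=2.0)
            oracle = dft_power_oracle(x, 2.0)
            assert np.allclose(spec.power, oracle, rtol=1e-10, atol=1e-14)

    def test_freq_grid(self):
        spec = compute_spectrum(np.random.default_rng(0).normal(size=20), tr=2.5)
        assert spec.freqs[0] == 0
        assert np.allclose(np.diff(spec.freqs), 1 / (20 * 2.5))
        assert spec.freqs[-1] == pytest.approx(1 / (2 * 2.5))

    def test_non_finite_raises(self):
        x = np.zeros(16)
        x[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            compute_spectrum(x, tr=2.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=8, max_value=64), st.integers(0, 2**31 - 1))
    def test_parseval(self, T, seed):
        """sum_{k>=1} P_k/2 (Nyquist counted once) = sample variance."""
        x = np.random.default_rng(seed).normal(size=T)
        x = x - x.mean()
        spec = compute_spectrum(x, tr=2.0)
        total = spec.power[1:].sum() / 2
        if T % 2 == 0:
            total += spec.power[-1] / 2  # un-halve the Nyquist term
        var = x.var()
        assert total == pytest.approx(var, rel=1e-8, abs=1e-12)


class TestBandRV:
    def _spec(self, powers, tr=2.0, T=None):
        powers = np.asarray(powers, dtype=float)
        T = T or 2 * (len(powers) - 1)
        from scontrast.spectral import PowerSpectrum

        freqs = np.arange(len(powers)) / (T * tr)
        return PowerSpectrum(freqs=freqs, power=powers, tr=tr, n_samples=T)

    def test_single_bin_max(self):
        spec = compute_spectrum(2 * np.cos(2 * np.pi * 3 * np.arange(16) / 16), 2.0)
        # bin 3 at f = 3/32 Hz; tight band holding only that bin
        assert band_rv(spec, (0.09, 0.095, "[]"), "max") == pytest.approx(4.0)

    @pytest.mark.parametrize(
        "method,expected", [("mean", 4 / 3), ("sum", 4.0), ("max", 4.0)]
    )
    def test_rv_methods_on_three_bins(self, method, expected):
        spec = self._spec([9.0, 0.0, 4.0, 0.0, 1.0], tr=2.0)
        lo, hi = spec.freqs[1], spec.freqs[3]
        assert band_rv(spec, (lo, hi, "[]"), method) == pytest.approx(expected)

    def test_low_band_bins_for_T230_tr2(self, rng):
        """T=230, tr=2: spacing 1/460 Hz; [0.01, 0.1] spans bins k=5..46."""
        from scontrast.spectral import _band_members

        freqs = np.fft.rfftfreq(230, d=2.0)
        members = _band_members(freqs, 0.01, 0.1, "[]")
        expected = [k for k in range(116) if 0.01 <= k / 460 <= 0.1]
        assert expected == list(np.nonzero(members)[0])
        assert expected[0] == 5 and expected[-1] == 46

    def test_empty_band_raises_with_spacing(self):
        spec = compute_spectrum(np.arange(8.0), tr=2.0)
        with pytest.raises(ValueError, match="bin spacing"):
            band_rv(spec, (0.011, 0.012, "[]"), "mean")

    def test_boundary_bin_goes_to_low_band_only(self):
        """A bin exactly at mid is in [low, mid] and excluded from (mid, high]."""
        from scontrast.spectral import _band_members

        freqs = np.fft.rfftfreq(240, d=2.0)  # bin 48 sits at 0.1 Hz exactly
        low = _band_members(freqs, 0.01, 0.1, "[]")
        high = _band_members(freqs, 0.1, 0.25, "(]")
        assert low[48] and not high[48]
        assert not np.any(low & high)

    def test_band_partition_up_to_nyquist(self):
        """low + high + sub-low + DC partition all bins when high = Nyquist."""
        from scontrast.spectral import _band_members

        freqs = np.fft.rfftfreq(240, d=2.0)
        low = _band_members(freqs, 0.01, 0.1, "[]")
        high = _band_members(freqs, 0.1, 0.25, "(]")
        sub = (freqs > 0) & ~low & (freqs < 0.01)
        dc = freqs == 0
        counts = low.astype(int) + high.astype(int) + sub.astype(int) + dc.astype(int)
        assert np.all(counts == 1)


class TestScmValue:
    def test_direct_ratio(self):
        assert scm_value(4.0, 1.0) == 4.0
        assert scm_value(0.0, 5.0) == 0.0

    def test_zero_reference_is_missing_with_warning(self):
        with pytest.warns(RuntimeWarning, match="zero high-band"):
            assert np.isnan(scm_value(3.0, 0.0))

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            scm_value(-1.0, 2.0)


class TestScmMap:
    def test_two_sinusoid_voxel_analytic(self, two_sinusoid_bold):
        scm = compute_scm_map(two_sinusoid_bold, method="max")
        assert scm.values[0, 0, 0] == pytest.approx(4.0, abs=1e-6)

    def test_scale_invariance(self, two_sinusoid_bold):
        base = compute_scm_map(two_sinusoid_bold, method="mean")
        scaled_bold = Bold4D(
            data=3.7 * two_sinusoid_bold.data,
            tr=2.0,
            mask=two_sinusoid_bold.mask,
        )
        scaled = compute_scm_map(scaled_bold, method="mean")
        assert scaled.values[0, 0, 0] == pytest.approx(
            base.values[0, 0, 0], rel=1e-12
        )

    def test_trend_invariance(self, two_sinusoid_bold):
        t = np.arange(240) * 2.0
        shifted = Bold4D(
            data=two_sinusoid_bold.data + 5.0 + 0.3 * t,
            tr=2.0,
            mask=two_sinusoid_bold.mask,
        )
        a = compute_scm_map(two_sinusoid_bold, method="mean").values[0, 0, 0]
        b = compute_scm_map(shifted, method="mean").values[0, 0, 0]
        assert b == pytest.approx(a, rel=1e-9)

    def test_high_band_only_voxel_gives_zero(self):
        # midpoint-symmetric phase: detrending leaves the sinusoid untouched
        t = np.arange(240) * 2.0
        tc = (240 - 1) / 2 * 2.0
        bold = single_voxel_bold(np.cos(2 * np.pi * 0.15 * (t - tc)))
        scm = compute_scm_map(bold, method="max")
        assert scm.values[0, 0, 0] == pytest.approx(0.0, abs=1e-15)

    def test_nyquist_violation_states_required_tr(self):
        bold = single_voxel_bold(np.random.default_rng(0).normal(size=100), tr=3.0)
        with pytest.raises(ValueError, match="tr"):
            compute_scm_map(bold, BandSpec(0.01, 0.1, 0.25))

    def test_out_of_mask_voxels_missing(self, rng):
        data = rng.normal(size=(3, 3, 2, 64))
        mask = np.zeros((3, 3, 2), dtype=bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        bold = Bold4D(data=data, tr=2.0, mask=mask)
        scm = compute_scm_map(bold)
        assert np.isfinite(scm.values[mask]).all()
        assert np.isnan(scm.values[~mask]).all()

    def test_nuisance_regression_removes_regressor_signal(self):
        t = np.arange(240) * 2.0
        tc = (240 - 1) / 2 * 2.0
        confound = np.cos(2 * np.pi * 0.05 * (t - tc))
        clean = 0.5 * np.cos(2 * np.pi * 0.15 * (t - tc))
        bold = single_voxel_bold(clean + 2.0 * confound)
        with_reg = compute_scm_map(bold, method="max", regressors=confound[:, None])
        without = compute_scm_map(bold, method="max")
        assert without.values[0, 0, 0] == pytest.approx(16.0, rel=1e-6)
        assert with_reg.values[0, 0, 0] == pytest.approx(0.0, abs=1e-10)


class TestZscore:
    def test_three_values_sample_sd(self):
        z = zscore_map(make_map(np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)))
        assert np.allclose(z.values.ravel(), [-1.0, 0.0, 1.0])

    def test_idempotent(self, rng):
        m = make_map(rng.normal(size=(4, 4, 2)))
        z1 = zscore_map(m)
        z2 = zscore_map(z1)
        assert np.allclose(z1.values, z2.values, atol=1e-10)

    def test_missing_excluded_and_preserved(self, rng):
        vals = rng.normal(size=(3, 3, 1))
        vals[0, 0, 0] = np.nan
        z = zscore_map(make_map(vals))
        assert np.isnan(z.values[0, 0, 0])
        finite = z.values[np.isfinite(z.values)]
        assert abs(finite.mean()) < 1e-10
        assert finite.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_zero_spread_raises(self):
        with pytest.raises(ValueError, match="spread"):
            zscore_map(make_map(np.ones((2, 2, 1))))
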