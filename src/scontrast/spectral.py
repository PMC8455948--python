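"""Spectrum contrast mapping: detrend, FFT power spectrum, band ratio.

The SCM statistic of a voxel time course f(t) is built from its Fourier
series f(t) = sum_k [a_k cos(2*pi*f_k*t) + b_k sin(2*pi*f_k*t)]:
the per-bin power P_k = a_k^2 + b_k^2 is segmented into a target
low-frequency band [low, mid] and a reference high-frequency band
(mid, high], a representative value (mean, sum or max of P_k) is taken
over each band, and

    SCM = LFRV / HFRV

is the ratio of the two representative values. Default cuts are
0.01 / 0.1 / 0.25 Hz, so with TR = 2 s the reference band runs up to the
Nyquist frequency.

Normalisation: a unit-amplitude sinusoid sitting exactly on a DFT bin has
P_k = 1 at that bin. Any fixed normalisation cancels in the SCM ratio;
this one makes analytic examples exact. With the Nyquist term counted
once (even T), sum_{k>=1} P_k / 2 equals the sample variance
(denominator T) of the mean-removed series (Parseval).

SCM is invariant to positive rescaling of the series (the ratio cancels)
and — because the series is linearly detrended first — to adding any
constant or linear trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.linalg
import scipy.signal

from .io import MISSING, Bold4D, MetricMap

__all__ = [
    "PowerSpectrum",
    "BandSpec",
    "RV_METHODS",
    "detrend",
    "regress_nuisance",
    "compute_spectrum",
    "band_rv",
    "scm_value",
    "compute_scm_map",
    "zscore_map",
]

RV_METHODS = ("mean", "sum", "max")
RVName = Literal["mean", "sum", "max"]

# relative slack on band-edge comparisons; a bin exactly at a cut frequency
# must land deterministically despite binary rounding of k/(T*tr)
_EDGE_RTOL = 1e-9


@dataclass
class PowerSpectrum:
    """Per-voxel Fourier power by frequency bin.

    freqs[k] = k / (T * tr) for k = 0 ... floor(T/2); power[k] = a_k^2 + b_k^2
    with the unit-sinusoid normalisation described in the module docstring.
    ``coeffs`` optionally holds the (a_k, b_k) pairs themselves.
    """

    freqs: np.ndarray
    power: np.ndarray
    tr: float
    n_samples: int
    coeffs: np.ndarray | None = None  # shape (n_bins, 2): columns a_k, b_k

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have the same shape")

    @property
    def bin_spacing(self) -> float:
        return 1.0 / (self.n_samples * self.tr)

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.tr)


@dataclass(frozen=True)
class BandSpec:
    """Low / mid / high cut frequencies (Hz) partitioning the spectrum.

    The target band is [low, mid] (both edges included), the reference band
    (mid, high]: a bin exactly at ``mid`` belongs to the target band only.
    """

    low: float = 0.01
    mid: float = 0.1
    high: float = 0.25

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.mid < self.high):
            raise ValueError(
                f"require 0 <= low < mid < high, got "
                f"({self.low}, {self.mid}, {self.high})"
            )

    def check_nyquist(self, tr: float) -> None:
        nyq = 1.0 / (2.0 * tr)
        if self.high > nyq * (1 + _EDGE_RTOL):
            required_tr = 1.0 / (2.0 * self.high)
            raise ValueError(
                f"high cut {self.high} Hz exceeds Nyquist {nyq:.4g} Hz at "
                f"tr={tr}; requires tr <= {required_tr:.4g} s"
            )


def _check_rv_method(method: str) -> str:
    if method not in RV_METHODS:
        raise ValueError(f"rv method must be one of {RV_METHODS}, got {method!r}")
    return method


def detrend(series: np.ndarray) -> np.ndarray:
    """Residual of an OLS fit of intercept + linear slope against time index.

    Works on the last axis, so a (n_voxels, T) block detrends in one call.
    The output has zero mean and zero linear trend.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.shape[-1] < 3:
        raise ValueError(f"detrending needs T >= 3, got {series.shape[-1]}")
    return scipy.signal.detrend(series, axis=-1, type="linear")


def regress_nuisance(series: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """OLS residual of series on [intercept | regressors].

    ``series`` may be 1D (length T) or (n_voxels, T); regressors are (T, R).
    The residual is orthogonal to every regressor column. A rank-deficient
    design raises, naming the collinear regressor columns by index.
    """
    series = np.asarray(series, dtype=np.float64)
    regressors = np.asarray(regressors, dtype=np.float64)
    if regressors.ndim != 2:
        raise ValueError("regressors must be a (T, R) matrix")
    t_len = series.shape[-1]
    if regressors.shape[0] != t_len:
        raise ValueError(
            f"regressors have {regressors.shape[0]} rows but series has "
            f"{t_len} time points"
        )
    design = np.column_stack([np.ones(t_len), regressors])
    # QR with pivoting localises which columns are collinear
    _, r, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(np.float64).eps
    rank = int((diag > tol).sum())
    if rank < design.shape[1]:
        bad = sorted(int(piv[i]) - 1 for i in range(rank, design.shape[1]))
        raise ValueError(
            f"rank-deficient nuisance design: regressor columns {bad} are "
            "collinear with the others (index -1 = intercept)"
        )
    y = np.atleast_2d(series)
    beta, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    resid = y - (design @ beta).T
    return resid.reshape(series.shape)


def _batch_power(block: np.ndarray, tr: float, keep_coeffs: bool = False):
    """Power spectra of a (n, T) block under the unit-sinusoid convention.

    Returns (freqs, power[, coeffs]); power has shape (n, n_bins).
    """
    n_t = block.shape[-1]
    fourier = np.fft.rfft(block, axis=-1)
    freqs = np.fft.rfftfreq(n_t, d=tr)
    # a_k = 2 Re(X_k)/T, b_k = -2 Im(X_k)/T for interior bins; the DC and
    # (even T) Nyquist bins are their own conjugates, so the factor is 1/T
    scale = np.full(freqs.shape, 2.0 / n_t)
    scale[0] = 1.0 / n_t
    if n_t % 2 == 0:
        scale[-1] = 1.0 / n_t
    a = fourier.real * scale
    b = -fourier.imag * scale
    power = a * a + b * b
    if keep_coeffs:
        return freqs, power, np.stack([a, b], axis=-1)
    return freqs, power


def compute_spectrum(series: np.ndarray, tr: float) -> PowerSpectrum:
    """FFT power spectrum of a single (already detrended) time course."""
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 1:
        raise ValueError("compute_spectrum takes a 1D series")
    if series.size < 8:
        raise ValueError(f"need T >= 8, got {series.size}")
    if not np.isfinite(series).all():
        raise ValueError("non-finite values in series")
    if not tr > 0:
        raise ValueError(f"tr must be positive, got {tr}")
    freqs, power, coeffs = _batch_power(series[None, :], tr, keep_coeffs=True)
    return PowerSpectrum(
        freqs=freqs,
        power=power[0],
        tr=float(tr),
        n_samples=series.size,
        coeffs=coeffs[0],
    )


def _band_members(
    freqs: np.ndarray, lo: float, hi: float, closure: str
) -> np.ndarray:
    """Boolean bin membership for interval (lo, hi] or [lo, hi]."""
    tol = _EDGE_RTOL * max(abs(lo), abs(hi), 1e-3)
    if closure == "[]":
        return (freqs >= lo - tol) & (freqs <= hi + tol)
    if closure == "(]":
        return (freqs > lo + tol) & (freqs <= hi + tol)
    raise ValueError(f"closure must be '[]' or '(]', got {closure!r}")


def band_rv(
    spectrum: PowerSpectrum,
    interval: tuple[float, float, str],
    method: RVName = "mean",
) -> float:
    """Representative value (mean / sum / max of P_k) over a frequency band.

    ``interval`` is (lo, hi, closure) with closure "[]" (both edges in) or
    "(]" (lower edge out). An empty band raises, reporting the bin spacing
    so the caller can see why no bin fell inside.
    """
    _check_rv_method(method)
    lo, hi, closure = interval
    members = _band_members(spectrum.freqs, lo, hi, closure)
    if not members.any():
        raise ValueError(
            f"band {closure[0]}{lo}, {hi}{closure[1]} Hz contains no bins "
            f"(bin spacing {spectrum.bin_spacing:.4g} Hz); series too short"
        )
    vals = spectrum.power[members]
    if method == "mean":
        return float(vals.mean())
    if method == "sum":
        return float(vals.sum())
    return float(vals.max())


_zero_hfrv_count = 0


def scm_value(lfrv: float, hfrv: float) -> float:
    """SCM = LFRV / HFRV; missing (NaN) when the reference value is zero.

    A dead reference band in one voxel must not abort a whole-brain run, so
    division by zero yields NaN with a counted warning rather than raising.
    """
    global _zero_hfrv_count
    if lfrv < 0 or hfrv < 0:
        raise ValueError(f"band values must be nonnegative, got ({lfrv}, {hfrv})")
    if hfrv == 0:
        _zero_hfrv_count += 1
        warnings.warn(
            "zero high-band reference value; SCM set to missing",
            RuntimeWarning,
            stacklevel=2,
        )
        return MISSING
    return lfrv / hfrv


def _band_reduce(power: np.ndarray, members: np.ndarray, method: RVName) -> np.ndarray:
    block = power[:, members]
    if method == "mean":
        return block.mean(axis=1)
    if method == "sum":
        return block.sum(axis=1)
    return block.max(axis=1)


def compute_scm_map(
    bold: Bold4D,
    bands: BandSpec = BandSpec(),
    method: RVName = "mean",
    regressors: np.ndarray | None = None,
    zscore: bool = False,
) -> MetricMap:
    """Whole-brain SCM: detrend, optional nuisance regression, FFT, band ratio.

    Per in-mask voxel the chain is detrend -> (regress_nuisance) ->
    power spectrum -> representative value over [low, mid] and (mid, high]
    -> ratio. Out-of-mask voxels are missing; voxels whose reference band
    power is exactly zero are missing with a counted warning.
    """
    _check_rv_method(method)
    bands.check_nyquist(bold.tr)
    series = detrend(bold.masked_series())
    if regressors is not None:
        series = regress_nuisance(series, regressors)
    freqs, power = _batch_power(series, bold.tr)
    low_members = _band_members(freqs, bands.low, bands.mid, "[]")
    high_members = _band_members(freqs, bands.mid, bands.high, "(]")
    for name, members, closure in (
        ("target", low_members, f"[{bands.low}, {bands.mid}]"),
        ("reference", high_members, f"({bands.mid}, {bands.high}]"),
    ):
        if not members.any():
            raise ValueError(
                f"{name} band {closure} Hz contains no bins (bin spacing "
                f"{1.0 / (bold.n_volumes * bold.tr):.4g} Hz)"
            )
    lfrv = _band_reduce(power, low_members, method)
    hfrv = _band_reduce(power, high_members, method)
    with np.errstate(divide="ignore", invalid="ignore"):
        scm = np.where(hfrv > 0, lfrv / np.where(hfrv > 0, hfrv, 1.0), MISSING)
    n_zero = int((hfrv == 0).sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} voxel(s) with zero reference-band power set to missing",
            RuntimeWarning,
            stacklevel=2,
        )
    values = np.full(bold.spatial_shape, MISSING)
    values[bold.mask] = scm
    out = MetricMap(
        values=values,
        mask=bold.mask,
        metric_name="scm",
        params={
            "bands": (bands.low, bands.mid, bands.high),
            "rv": method,
            "tr": bold.tr,
            "n_volumes": bold.n_volumes,
            "nuisance_regressors": 0 if regressors is None else int(regressors.shape[1]),
            "n_zero_hfrv": n_zero,
            "zscored": bool(zscore),
        },
        spatial_meta=dict(bold.spatial_meta),
    )
    return zscore_map(out) if zscore else out


def zscore_map(metric_map: MetricMap) -> MetricMap:
    """Standardise a map to in-mask mean 0 and sample SD 1.

    Uses the sample standard deviation (denominator n-1) over non-missing
    in-mask voxels; missing voxels stay missing.
    """
    finite = metric_map.finite_mask()
    vals = metric_map.values[finite]
    if vals.size < 2:
        raise ValueError("z-scoring needs at least 2 non-missing voxels")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError("z-scoring undefined for a map with zero spread")
    values = (metric_map.values - vals.mean()) / sd
    params = dict(metric_map.params)
    params["zscored"] = True
    return MetricMap(
        values=values,
        mask=metric_map.mask,
        metric_name=metric_map.metric_name,
        params=params,
        spatial_meta=dict(metric_map.spatial_meta),
    )
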