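"""Companion low-frequency fluctuation metrics: ALFF, fALFF and PerAF.

These three are the standard voxel-wise amplitude measures SCM is usually
contrasted with, and they behave differently under rescaling of the raw
signal:

* ALFF — mean spectral *amplitude* (sqrt of power, per the original
  definition) over a low band, default 0.01–0.08 Hz. Homogeneous of
  degree 1: doubling the signal doubles ALFF.
* fALFF — low-band amplitude as a fraction of total amplitude over
  (0, Nyquist]; dimensionless, always in [0, 1].
* PerAF — mean absolute percent deviation of the raw time course from
  its own mean; scale-invariant but undefined for zero-mean series.

Note the convention split: ALFF/fALFF work on amplitude sqrt(P_k), while
SCM's band representative values use power P_k itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import MISSING, Bold4D, MetricMap
from .spectral import PowerSpectrum, _band_members, _batch_power, detrend

__all__ = ["CompanionParams", "alff", "falff", "peraf", "compute_metric_map"]

METRIC_NAMES = ("alff", "falff", "peraf")


@dataclass(frozen=True)
class CompanionParams:
    """Band settings for ALFF/fALFF plus the PerAF detrending flag.

    The 0.01–0.08 Hz default follows the original ALFF/fALFF definitions
    (narrower than SCM's 0.01–0.1 Hz target band). fALFF's denominator is
    always the full (0, Nyquist] range. PerAF is computed on the raw series
    by default so its mean is meaningful.
    """

    alff_band: tuple[float, float] = (0.01, 0.08)
    falff_target_band: tuple[float, float] = (0.01, 0.08)
    peraf_detrend: bool = False

    def __post_init__(self) -> None:
        for lo, hi in (self.alff_band, self.falff_target_band):
            if not (0 <= lo < hi):
                raise ValueError(f"band must satisfy 0 <= lo < hi, got ({lo}, {hi})")


def _amplitude(power: np.ndarray) -> np.ndarray:
    return np.sqrt(power)


def alff(spectrum: PowerSpectrum, band: tuple[float, float] = (0.01, 0.08)) -> float:
    """Mean spectral amplitude sqrt(P_k) over a closed band [lo, hi]."""
    lo, hi = band
    members = _band_members(spectrum.freqs, lo, hi, "[]")
    if not members.any():
        raise ValueError(
            f"ALFF band [{lo}, {hi}] Hz contains no bins "
            f"(bin spacing {spectrum.bin_spacing:.4g} Hz)"
        )
    return float(_amplitude(spectrum.power[members]).mean())


def falff(
    spectrum: PowerSpectrum, target_band: tuple[float, float] = (0.01, 0.08)
) -> float:
    """Fraction of total amplitude in the target band: value in [0, 1].

    The denominator sums sqrt(P_k) over every non-DC bin up to Nyquist.
    Returns missing (NaN) for an identically zero spectrum.
    """
    lo, hi = target_band
    members = _band_members(spectrum.freqs, lo, hi, "[]")
    amp = _amplitude(spectrum.power)
    total = amp[1:].sum()
    if total == 0:
        return MISSING
    return float(amp[members].sum() / total)


def peraf(series: np.ndarray) -> float:
    """Percent amplitude of fluctuation: 100 * mean |x_t - m| / |m|.

    ``m`` is the mean of the *raw* series; a zero-mean series has no
    meaningful percent scale and yields missing.
    """
    series = np.asarray(series, dtype=np.float64)
    m = series.mean()
    if m == 0:
        return MISSING
    return float(100.0 * np.abs(series - m).mean() / np.abs(m))


def compute_metric_map(
    bold: Bold4D,
    metric: str,
    params: CompanionParams = CompanionParams(),
) -> MetricMap:
    """Whole-brain ALFF / fALFF / PerAF map mirroring compute_scm_map.

    The series is detrended before the spectral metrics (ALFF, fALFF) but
    left raw for PerAF unless ``params.peraf_detrend`` is set.
    """
    if metric not in METRIC_NAMES:
        raise ValueError(f"metric must be one of {METRIC_NAMES}, got {metric!r}")
    series = bold.masked_series()
    out = np.full(bold.spatial_shape, MISSING)
    map_params: dict = {"tr": bold.tr, "n_volumes": bold.n_volumes}

    if metric == "peraf":
        if params.peraf_detrend:
            series = detrend(series)
        means = series.mean(axis=1)
        dead = means == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = 100.0 * np.abs(series - means[:, None]).mean(axis=1) / np.abs(means)
        vals[dead] = MISSING
        if dead.any():
            warnings.warn(
                f"{int(dead.sum())} voxel(s) with zero mean set to missing",
                RuntimeWarning,
                stacklevel=2,
            )
        map_params["detrended"] = params.peraf_detrend
    else:
        freqs, power = _batch_power(detrend(series), bold.tr)
        amp = _amplitude(power)
        band = params.alff_band if metric == "alff" else params.falff_target_band
        lo, hi = band
        if hi > bold.nyquist * (1 + 1e-9):
            raise ValueError(
                f"band upper edge {hi} Hz exceeds Nyquist {bold.nyquist:.4g} Hz"
            )
        members = _band_members(freqs, lo, hi, "[]")
        if not members.any():
            raise ValueError(f"band [{lo}, {hi}] Hz contains no bins")
        if metric == "alff":
            vals = amp[:, members].mean(axis=1)
        else:
            totals = amp[:, 1:].sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = amp[:, members].sum(axis=1) / totals
            vals[totals == 0] = MISSING
        map_params["band"] = band

    out[bold.mask] = vals
    return MetricMap(
        values=out,
        mask=bold.mask,
        metric_name=metric,
        params=map_params,
        spatial_meta=dict(bold.spatial_meta),
    )
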