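# Methods

## The SCM model

Each voxel's BOLD time course (T samples at repetition time `tr` seconds)
is treated as a stationary sum of sinusoids plus noise. After removing an
ordinary-least-squares linear trend (intercept + slope), the discrete
Fourier transform gives real amplitudes `(a_k, b_k)` at bin frequencies
`f_k = k/(T·tr)`, `k = 0 … ⌊T/2⌋`, and per-bin power `P_k = a_k² + b_k²`.
The spectrum is segmented at three cut frequencies `low < mid < high`
(defaults 0.01, 0.1, 0.25 Hz) into a target band `[low, mid]` and a
reference band `(mid, high]`; a representative value (RV) is taken over
each band's `P_k`, and the voxel's score is `SCM = LFRV / HFRV`.

Assumptions this encodes:

- the band-energy contrast of a voxel is stable within a scan (stationary
  spectra — no time-varying amplitude or phase estimation);
- the reference band carries enough energy to be a meaningful benchmark
  (a voxel with exactly zero reference power is reported missing, with a
  counted warning, rather than aborting the run);
- spatial preprocessing (slice timing, realignment, normalisation,
  smoothing) happened upstream; the package only discards leading dummy
  volumes (default 10) and detrends/regresses in time.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| band cuts (low, mid, high) | 0.01, 0.1, 0.25 | Hz | conventional low-frequency band against a high-frequency reference reaching the TR = 2 s Nyquist limit; fully configurable (e.g. 0.01–0.05 or 0.05–0.1 Hz targets) |
| RV method | mean | – | robust to band width; `sum` and `max` are exposed and recorded in each map's provenance |
| discard | 10 | volumes | standard dummy-volume removal; explicit, never silent |
| ALFF/fALFF band | 0.01–0.08 | Hz | follows the original definitions of those metrics (narrower than the SCM target band) |
| FDR q | 0.05 | – | Benjamini–Hochberg step-up over finite voxel p-values |
| ICC form | ICC(3,1) | – | two-way mixed, consistency: pairwise session reliability without penalising additive session offsets; ICC(2,1) by flag |

Conventions worth stating once:

- **Spectrum normalisation.** A unit-amplitude sinusoid on an exact bin has
  `P_k = 1`. Any fixed normalisation cancels in the SCM ratio; this one
  makes analytic examples exact and gives the Parseval identity
  `Σ_{k≥1} P_k/2 = var(x)` (Nyquist term counted once for even T,
  population-variance denominator T).
- **Power vs amplitude.** SCM's representative values use power `P_k`;
  ALFF/fALFF use amplitude `√P_k`, matching their original definitions.
  The conventions are deliberately not unified.
- **Band closure.** A bin exactly at `mid` belongs to the target band only;
  membership tests carry a 1e-9 relative tolerance so that bins landing
  exactly on a cut are assigned deterministically despite binary rounding.
- **z-scoring** uses the sample SD (n−1) over non-missing in-mask voxels.
- **Missing values** are NaN throughout; degenerate voxels (zero variance,
  zero reference power, zero PerAF mean) become missing, never zero.

## Group statistics

One-sample and paired t-maps use the textbook per-voxel formulas
(df = n−1, two-sided p). The multi-group path computes the one-way ANOVA
F and, per group pair, the Tukey–Kramer studentized-range statistic
`q = |m_i − m_j| / √(MSW/2 · (1/n_i + 1/n_j))` with df = N − g, valid for
unequal group sizes; the adjusted p is converted to a signed
standard-normal quantile for presentation as a z-map. Because scipy's
studentized-range survival function integrates numerically per value, maps
larger than 512 voxels use a cached monotone-cubic interpolant of log p on
a q grid (relative error ~1e-4, far below any thresholding sensitivity);
smaller inputs — including every hand-checked identity test — use the
exact evaluation. Figure-style thresholding is the explicit conjunction of
a statistic floor and the FDR rejection mask, since published map captions
state both.

## Reliability

Map similarity is the Pearson correlation of vectorised maps over jointly
non-missing in-mask voxels (affine-invariant, so z-scored and raw maps
give identical correlations; duplicated maps return exactly 1.0). The
voxel-wise ICC comes from the two-way ANOVA decomposition over
subjects × 2 sessions; negative estimates are reported as computed.
Voxels with zero between-subject variance are missing.

## What the synthetic generator emulates — and what it does not

`gen_scenario` produces multi-subject, multi-session 4D volumes of
197–240 volumes at TR = 2 s: band-limited sinusoids per region, per-voxel
lognormal amplitude factors (log-SD 0.4) providing spatial structure
shared by all subjects and sessions, per-subject lognormal factors
(log-SD 0.1) persisting across sessions, white Gaussian session noise
(SD 0.5 against unit signal amplitudes), optional 40-s OFF/ON block
paradigms (fundamental 0.0125 Hz, inside the target band), and optional
linear trends. Effect sizes are expressed as low/high amplitude ratios,
matching SCM's scale invariance. All randomness flows from one seeded
PCG64 generator; structure and noise use separate streams so paired
conditions can share brains while their noise stays independent.

Two fixture choices make analytic oracles exact rather than approximate:
component frequencies snap to exact DFT bins (no leakage), and
`contrast_recipe` uses midpoint-symmetric phases. A sinusoid symmetric
about the series midpoint is exactly orthogonal to both the intercept and
the linear ramp, so linear detrending leaves it numerically untouched and
the two-sinusoid voxel (amplitudes 1 and 0.5) yields SCM = 4.0 under
`rv max` to machine precision. With arbitrary phases the ramp-sinusoid
non-orthogonality perturbs band power at the 1e-3 level — a property of
finite-sample detrending, not an implementation artifact; off-bin
frequencies and free phases remain available for leakage robustness
checks.

Deliberately not modelled: hemodynamic response convolution (optional
block designs are raw boxcars; the analyses here are spectral, not GLM
fits), 1/f or physiological noise spectra, head motion, scanner drift
beyond a linear trend, and spatial autocorrelation. Passing tests
therefore demonstrate correctness of the estimators under their stated
assumptions, not performance on real scanner data — in particular, white
noise makes the null calibration clean, whereas real BOLD noise is
temporally autocorrelated.

## Problem sizes

The bundled checks run at deliberately modest scale, chosen to make the
statistical assertions stable: 100 random series (T ≤ 64) for the
spectral oracle; 10,000 voxels × 3 groups × 15 subjects for null
calibration of the ANOVA (false-positive band 0.04–0.06 at α = 0.05); 50
subjects × 300 voxels per point of the ICC variance-ratio grid
{0.2, 0.5, 0.8} (recovery within ±0.05); 20 subjects × 864 voxels with a
48-voxel effect region for paired-design recovery (sensitivity ≥ 0.9,
off-region false-positive fraction ≤ 0.10); and 12 subjects × 3 sessions
× 500 voxels for reproducibility structure (per-subject session-pair
correlations > 0.9, group-level correlations higher still).

## Known limitations

- Real multi-session correlations depend on registration quality and
  physiological state; the generator's "shared structure" idealises both.
- The studentized-range interpolation caps q at 50 (p ≈ 1e-300); z-maps
  saturate around |z| ≈ 37 rather than growing without bound.
- ICC maps are currently pairwise (two sessions per call), mirroring the
  pairwise framing of session comparisons; a pooled k-session ICC is a
  straightforward extension.
- Nuisance regression assumes a full-rank design and reports collinear
  columns by index instead of dropping them silently.
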