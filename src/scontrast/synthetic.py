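"""Synthetic BOLD generation for testing every analysis in the package.

The generator emulates the study designs the spectral metrics are aimed
at: voxel time courses of ~200-240 volumes at TR = 2 s containing
band-limited sinusoids plus Gaussian white noise, 40-s OFF/ON block
paradigms, multi-subject groups with localized effect regions, and
multi-session sets with tunable shared structure.

Generation model, per voxel v in region r, subject s, session:

    x(t) = sum_c amp_c * g[v,c] * h[s,r,c] * cos(2*pi*f_c*t + phi_c)
           + trend + paradigm + N(0, sigma^2)

where g[v,c] are per-voxel lognormal amplitude factors (spatial structure,
shared by all subjects and sessions), h[s,r,c] are subject-level lognormal
perturbations persisting across that subject's sessions, and only the
noise is redrawn per session. Effect sizes are therefore specified as
low/high amplitude *ratios*, matching SCM's scale invariance.

Frequencies are snapped to exact DFT bins by default so analytic oracles
are exact; off-bin leakage is an explicit opt-out. All randomness flows
from one seeded numpy Generator (PCG64), giving bit-identical output for
a given (spec, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import Bold4D

__all__ = [
    "VoxelRecipe",
    "Region",
    "Paradigm",
    "ScenarioSpec",
    "ScenarioResult",
    "snap_frequency",
    "centered_phase",
    "gen_voxel",
    "gen_block_paradigm",
    "gen_scenario",
    "scenario_from_dict",
    "contrast_recipe",
]


def snap_frequency(freq: float, n_samples: int, tr: float) -> float:
    """Nearest exact DFT bin frequency k/(T*tr) to ``freq``."""
    return round(freq * n_samples * tr) / (n_samples * tr)


def centered_phase(freq: float, n_samples: int, tr: float) -> float:
    """Phase making cos(2*pi*f*t + phase) symmetric about the series midpoint.

    A midpoint-symmetric sinusoid on an exact bin is orthogonal to both the
    constant and the linear ramp, so linear detrending leaves it untouched
    and analytic band-power oracles are exact to machine precision.
    """
    return -2.0 * np.pi * freq * tr * (n_samples - 1) / 2.0


@dataclass(frozen=True)
class VoxelRecipe:
    """Deterministic composition of one voxel time course.

    components: list of (frequency Hz, amplitude, phase rad) sinusoids.
    trend: (intercept, slope per second) added on top.
    """

    components: tuple[tuple[float, float, float], ...] = ()
    noise_sd: float = 0.0
    trend: tuple[float, float] = (0.0, 0.0)
    T: int = 240
    tr: float = 2.0

    def __post_init__(self) -> None:
        if self.T < 8:
            raise ValueError(f"T must be >= 8, got {self.T}")
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        nyq = 1.0 / (2.0 * self.tr)
        for f, amp, _ in self.components:
            if f >= nyq:
                raise ValueError(f"component frequency {f} Hz >= Nyquist {nyq} Hz")
            if amp < 0:
                raise ValueError(f"component amplitude {amp} < 0")

    def snapped(self) -> "VoxelRecipe":
        """Recipe with every component frequency moved to its nearest bin."""
        comps = tuple(
            (snap_frequency(f, self.T, self.tr), a, p) for f, a, p in self.components
        )
        return VoxelRecipe(comps, self.noise_sd, self.trend, self.T, self.tr)


def contrast_recipe(
    low_amp: float = 1.0,
    high_amp: float = 0.7,
    low_freq: float = 0.05,
    high_freq: float = 0.15,
    T: int = 240,
    tr: float = 2.0,
    noise_sd: float = 0.0,
) -> VoxelRecipe:
    """One low-band and one high-band sinusoid: the canonical SCM test voxel.

    Frequencies are snapped to exact bins and phases centred on the series
    midpoint, so the analytic SCM (low_amp/high_amp)^2 survives linear
    detrending to machine precision.
    """
    components = tuple(
        (snap_frequency(f, T, tr), a, centered_phase(snap_frequency(f, T, tr), T, tr))
        for f, a in ((low_freq, low_amp), (high_freq, high_amp))
    )
    return VoxelRecipe(components=components, noise_sd=noise_sd, T=T, tr=tr)


def gen_voxel(recipe: VoxelRecipe, seed: int | np.random.Generator) -> np.ndarray:
    """Realise one voxel time course: components + trend + Gaussian noise."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    t = np.arange(recipe.T) * recipe.tr
    series = np.zeros(recipe.T)
    for f, amp, phase in recipe.components:
        series += amp * np.cos(2 * np.pi * f * t + phase)
    intercept, slope = recipe.trend
    series += intercept + slope * t
    if recipe.noise_sd > 0:
        series += rng.normal(0.0, recipe.noise_sd, recipe.T)
    return series


def gen_block_paradigm(
    block_seconds: float, pattern: str, tr: float
) -> np.ndarray:
    """0/1 boxcar for an OFF/ON block design, e.g. "OFF-ON-OFF-ON-OFF-ON".

    Each block lasts ``block_seconds``; the fundamental frequency of an
    alternating design is 1/(2*block_seconds) (0.0125 Hz for 40-s blocks,
    inside the low band). block_seconds is rounded down to a whole number
    of TRs with a warning if not an exact multiple.
    """
    states = [s.strip().upper() for s in pattern.split("-") if s.strip()]
    if not states:
        raise ValueError("empty block pattern")
    bad = [s for s in states if s not in ("OFF", "ON")]
    if bad:
        raise ValueError(f"pattern blocks must be OFF or ON, got {bad}")
    samples = block_seconds / tr
    if abs(samples - round(samples)) > 1e-9:
        warnings.warn(
            f"block of {block_seconds}s is not a multiple of tr={tr}s; "
            "rounding down",
            RuntimeWarning,
            stacklevel=2,
        )
        samples = int(samples)
    else:
        samples = round(samples)
    if samples < 1:
        raise ValueError("block shorter than one TR")
    return np.concatenate(
        [np.full(samples, 1.0 if s == "ON" else 0.0) for s in states]
    )


@dataclass(frozen=True)
class Region:
    """A named set of voxels sharing one recipe."""

    mask: np.ndarray
    recipe: VoxelRecipe


@dataclass(frozen=True)
class Paradigm:
    """Block design added to selected regions' time courses."""

    pattern: str = "OFF-ON-OFF-ON-OFF-ON"
    block_seconds: float = 40.0
    amplitude: float = 1.0
    region_names: tuple[str, ...] = ()


@dataclass
class ScenarioSpec:
    """Full description of a multi-subject, multi-session synthetic study.

    ``regions`` map names to disjoint masks with their recipes; voxels in
    no region get ``background`` (omit both for an error). Amplitude
    heterogeneity: per-voxel lognormal factors with log-SD
    ``voxel_amp_sd`` (spatial structure shared by everyone), per-subject
    lognormal factors with log-SD ``between_subject_sd`` (persist across
    sessions). ``within_session_sd`` is the white-noise SD redrawn per
    subject and session. The seed is mandatory.
    """

    shape: tuple[int, int, int]
    regions: dict[str, Region]
    seed: int
    background: VoxelRecipe | None = None
    n_subjects: int = 1
    n_sessions: int = 1
    between_subject_sd: float = 0.1
    within_session_sd: float = 0.5
    voxel_amp_sd: float = 0.4
    paradigm: Paradigm | None = None
    snap_to_bins: bool = True
    noise_seed: int | None = None  # defaults to seed; set to pair conditions

    def __post_init__(self) -> None:
        if not self.regions and self.background is None:
            raise ValueError("need at least one region or a background recipe")
        counts = np.zeros(self.shape, dtype=int)
        for name, region in self.regions.items():
            if region.mask.shape != self.shape:
                raise ValueError(f"region {name!r} mask shape mismatch")
            counts += region.mask.astype(int)
        if (counts > 1).any():
            raise ValueError("regions overlap")
        recipes = [r.recipe for r in self.regions.values()]
        if self.background is not None:
            recipes.append(self.background)
        t_set = {(r.T, r.tr) for r in recipes}
        if len(t_set) != 1:
            raise ValueError("all recipes in a scenario must share T and tr")
        self.T, self.tr = t_set.pop()
        if self.paradigm is not None:
            for name in self.paradigm.region_names:
                if name not in self.regions:
                    raise ValueError(f"paradigm region {name!r} not defined")


@dataclass
class ScenarioResult:
    """Generated scans plus the ground truth that produced them."""

    bolds: list[list[Bold4D]]  # [subject][session]
    region_masks: dict[str, np.ndarray]
    truth: dict

    def subject(self, s: int, session: int = 0) -> Bold4D:
        return self.bolds[s][session]

    def flat(self) -> list[Bold4D]:
        return [b for subj in self.bolds for b in subj]


def scenario_from_dict(config: dict, seed: int | None = None) -> ScenarioSpec:
    """Build a ScenarioSpec from a plain dict (e.g. parsed YAML).

    Regions are given as axis-aligned boxes ``[x0, x1, y0, y1, z0, z1]``
    (half-open slices); recipes as ``components`` lists of
    [frequency, amplitude, phase]. ``seed`` overrides any seed in the dict.
    """
    shape = tuple(config["shape"])
    t_len = int(config.get("T", 240))
    tr = float(config.get("tr", 2.0))

    def recipe_from(d: dict) -> VoxelRecipe:
        return VoxelRecipe(
            components=tuple(tuple(c) for c in d.get("components", [])),
            noise_sd=float(d.get("noise_sd", 0.0)),
            trend=tuple(d.get("trend", (0.0, 0.0))),
            T=t_len,
            tr=tr,
        )

    regions = {}
    for name, rconf in (config.get("regions") or {}).items():
        mask = np.zeros(shape, dtype=bool)
        x0, x1, y0, y1, z0, z1 = rconf["box"]
        mask[x0:x1, y0:y1, z0:z1] = True
        regions[name] = Region(mask=mask, recipe=recipe_from(rconf))

    paradigm = None
    if "paradigm" in config and config["paradigm"]:
        p = config["paradigm"]
        paradigm = Paradigm(
            pattern=p.get("pattern", "OFF-ON-OFF-ON-OFF-ON"),
            block_seconds=float(p.get("block_seconds", 40.0)),
            amplitude=float(p.get("amplitude", 1.0)),
            region_names=tuple(p.get("regions", ())),
        )

    if seed is None:
        if "seed" not in config:
            raise ValueError("a seed is required (in the dict or as argument)")
        seed = int(config["seed"])
    return ScenarioSpec(
        shape=shape,
        regions=regions,
        seed=seed,
        background=(
            recipe_from(config["background"]) if config.get("background") else None
        ),
        n_subjects=int(config.get("n_subjects", 1)),
        n_sessions=int(config.get("n_sessions", 1)),
        between_subject_sd=float(config.get("between_subject_sd", 0.1)),
        within_session_sd=float(config.get("within_session_sd", 0.5)),
        voxel_amp_sd=float(config.get("voxel_amp_sd", 0.4)),
        paradigm=paradigm,
        snap_to_bins=bool(config.get("snap_to_bins", True)),
    )


def gen_scenario(spec: ScenarioSpec) -> ScenarioResult:
    """Generate the full subject x session grid of Bold4D scans.

    Structure (voxel factors) and subject factors are drawn once; a
    subject's deterministic signal is identical across sessions, and only
    the additive noise differs session to session.

    Structure and noise use separate seeded streams: two specs with the
    same ``seed`` but different ``noise_seed`` share voxel and subject
    factors (same subjects, same brains) while their noise realisations
    are independent — the natural construction for paired two-condition
    designs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 17]))
    noise_rng = np.random.default_rng(
        np.random.SeedSequence(
            [spec.seed if spec.noise_seed is None else spec.noise_seed, 29]
        )
    )
    shape, T, tr = spec.shape, spec.T, spec.tr
    t = np.arange(T) * tr

    regions = dict(spec.regions)
    covered = np.zeros(shape, dtype=bool)
    for region in regions.values():
        covered |= region.mask
    if spec.background is not None and (~covered).any():
        regions = {**regions, "__background__": Region(~covered, spec.background)}

    # fixed draw order: region by region, voxel factors then subject factors
    voxel_factors: dict[str, np.ndarray] = {}
    subject_factors: dict[str, np.ndarray] = {}
    for name, region in regions.items():
        recipe = region.recipe.snapped() if spec.snap_to_bins else region.recipe
        n_vox = int(region.mask.sum())
        n_comp = max(len(recipe.components), 1)
        voxel_factors[name] = np.exp(
            rng.normal(0.0, spec.voxel_amp_sd, (n_vox, n_comp))
        )
        subject_factors[name] = np.exp(
            rng.normal(0.0, spec.between_subject_sd, (spec.n_subjects, n_comp))
        )

    boxcar = None
    if spec.paradigm is not None:
        base = gen_block_paradigm(
            spec.paradigm.block_seconds, spec.paradigm.pattern, tr
        )
        reps = int(np.ceil(T / base.size))
        boxcar = np.tile(base, reps)[:T] * spec.paradigm.amplitude

    bolds: list[list[Bold4D]] = []
    for s in range(spec.n_subjects):
        # deterministic per-subject signal, shared by all its sessions
        signal = np.zeros(shape + (T,))
        for name, region in regions.items():
            recipe = region.recipe.snapped() if spec.snap_to_bins else region.recipe
            block = np.zeros((int(region.mask.sum()), T))
            for c, (f, amp, phase) in enumerate(recipe.components):
                amps = amp * voxel_factors[name][:, c] * subject_factors[name][s, c]
                block += amps[:, None] * np.cos(2 * np.pi * f * t + phase)[None, :]
            intercept, slope = recipe.trend
            block += intercept + slope * t
            if (
                boxcar is not None
                and spec.paradigm is not None
                and name in spec.paradigm.region_names
            ):
                block += boxcar[None, :]
            signal[region.mask] = block
        subject_runs: list[Bold4D] = []
        for _ in range(spec.n_sessions):
            noise_sd = np.zeros(shape)
            for name, region in regions.items():
                noise_sd[region.mask] = np.hypot(
                    region.recipe.noise_sd, spec.within_session_sd
                )
            data = signal.copy()
            if (noise_sd > 0).any():
                data += noise_rng.normal(0.0, 1.0, shape + (T,)) * noise_sd[..., None]
            subject_runs.append(
                Bold4D(
                    data=data,
                    tr=tr,
                    mask=covered if spec.background is None else None,
                    spatial_meta={"affine": np.eye(4)},
                )
            )
        bolds.append(subject_runs)

    truth = {
        "voxel_factors": voxel_factors,
        "subject_factors": subject_factors,
        "T": T,
        "tr": tr,
        "seed": spec.seed,
    }
    return ScenarioResult(
        bolds=bolds,
        region_masks={n: r.mask for n, r in spec.regions.items()},
        truth=truth,
    )
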