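"""Voxel-wise group inference: t-tests, one-way ANOVA with Tukey-Kramer
post hoc comparisons, and Benjamini-Hochberg FDR correction.

All tests run independently per voxel over stacks of aligned metric maps.
Degenerate voxels (zero variance, missing inputs) are reported missing,
never silently zero. Figure-style thresholding is the explicit conjunction
of a statistic floor and an FDR rejection mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from typing import Any, Sequence

import numpy as np
import scipy.interpolate
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import MISSING, MetricMap

__all__ = [
    "GroupSet",
    "StatMap",
    "one_sample_t",
    "paired_t",
    "anova_tukey",
    "fdr_correct",
    "threshold_map",
]


@dataclass
class GroupSet:
    """A stack of aligned MetricMaps (one per subject / condition)."""

    maps: list[MetricMap]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.maps) < 2:
            raise ValueError(f"a group needs at least 2 maps, got {len(self.maps)}")
        first = self.maps[0]
        for m in self.maps[1:]:
            if m.values.shape != first.values.shape:
                raise ValueError("all maps in a group must share shape")
            if not np.array_equal(m.mask, first.mask):
                raise ValueError("all maps in a group must share the mask")
            if m.metric_name != first.metric_name:
                raise ValueError("all maps in a group must share metric_name")
        if self.labels is None:
            self.labels = [f"map{i}" for i in range(len(self.maps))]
        elif len(self.labels) != len(self.maps):
            raise ValueError("labels length must match number of maps")

    def __len__(self) -> int:
        return len(self.maps)

    @property
    def mask(self) -> np.ndarray:
        return self.maps[0].mask

    @property
    def spatial_meta(self) -> dict:
        return self.maps[0].spatial_meta

    def stacked(self) -> np.ndarray:
        """Values as an (n_maps, x, y, z) array (missing = NaN)."""
        return np.stack([m.values for m in self.maps])


@dataclass
class StatMap:
    """A 3D statistic map with matching p-values and threshold metadata."""

    stat: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    df: float | tuple[float, ...]
    stat_name: str = "t"
    contrast: str = ""
    threshold_info: dict[str, Any] = field(default_factory=dict)
    spatial_meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stat = np.where(self.mask, self.stat, MISSING)
        self.p = np.where(self.mask, self.p, MISSING)
        finite = np.isfinite(self.p)
        if finite.any() and ((self.p[finite] < 0) | (self.p[finite] > 1)).any():
            raise ValueError("p-values outside [0, 1]")

    def as_metric_map(self, which: str = "stat") -> MetricMap:
        values = self.stat if which == "stat" else self.p
        return MetricMap(
            values=values,
            mask=self.mask,
            metric_name=f"{self.stat_name}_{which}",
            params={"contrast": self.contrast, "df": self.df, **self.threshold_info},
            spatial_meta=dict(self.spatial_meta),
        )


def one_sample_t(group: GroupSet, null_value: float = 0.0) -> StatMap:
    """Per-voxel one-sample t-test of the group mean against ``null_value``.

    t = (mean - null) / (SD / sqrt(n)) with df = n - 1 and a two-sided p.
    Voxels with zero SD or any missing input are set missing.
    """
    data = group.stacked()
    n = len(group)
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    valid = np.isfinite(data).all(axis=0) & (sd > 0) & group.mask
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - null_value) / (sd / np.sqrt(n))
    t = np.where(valid, t, MISSING)
    p = np.where(valid, 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 1), MISSING)
    return StatMap(
        stat=t,
        p=p,
        mask=group.mask,
        df=n - 1,
        stat_name="t",
        contrast=f"mean vs {null_value}",
        spatial_meta=dict(group.spatial_meta),
    )


def paired_t(group_a: GroupSet, group_b: GroupSet) -> StatMap:
    """Paired t-test: one-sample test of per-subject differences against 0.

    Maps must be matched in length and subject order. Swapping the
    arguments negates the statistic exactly and leaves p unchanged.
    """
    if len(group_a) != len(group_b):
        raise ValueError(
            f"paired groups must match in length: {len(group_a)} vs {len(group_b)}"
        )
    diffs = [
        MetricMap(
            values=a.values - b.values,
            mask=group_a.mask,
            metric_name=f"{a.metric_name}_diff",
            spatial_meta=dict(a.spatial_meta),
        )
        for a, b in zip(group_a.maps, group_b.maps)
    ]
    out = one_sample_t(GroupSet(diffs, labels=group_a.labels), null_value=0.0)
    out.contrast = "paired A-B"
    return out


_TUKEY_EXACT_LIMIT = 512
_TUKEY_GRID_MAX = 50.0  # q beyond this has p below any mapping threshold


@lru_cache(maxsize=32)
def _tukey_log_sf_interpolant(k: int, df: int):
    grid = np.linspace(0.0, _TUKEY_GRID_MAX, 257)
    logp = np.log(
        np.clip(scipy.stats.studentized_range.sf(grid, k, df), 1e-300, 1.0)
    )
    return scipy.interpolate.PchipInterpolator(grid, logp, extrapolate=True)


def _tukey_sf(q: np.ndarray, k: int, df: int) -> np.ndarray:
    """Survival function of the studentized range, vectorised.

    scipy's quadrature is exact but slow per value; above a few hundred
    voxels the sf comes from a cached monotone-cubic interpolant of log p
    on a q grid (relative error well below any mapping threshold in use).
    """
    flat = np.asarray(q, dtype=np.float64).ravel()
    out = np.full(flat.shape, np.nan)
    finite = np.isfinite(flat)
    vals = flat[finite]
    if vals.size == 0:
        return out.reshape(np.shape(q))
    if vals.size <= _TUKEY_EXACT_LIMIT:
        out[finite] = scipy.stats.studentized_range.sf(vals, k, df)
    else:
        interp = _tukey_log_sf_interpolant(k, df)
        out[finite] = np.exp(interp(np.clip(vals, 0.0, _TUKEY_GRID_MAX)))
    return out.reshape(np.shape(q))


def anova_tukey(
    groups: Sequence[GroupSet], alpha: float = 0.05
) -> tuple[StatMap, list[StatMap]]:
    """One-way ANOVA with Tukey-Kramer post hoc pairwise z-maps, per voxel.

    Returns the omnibus F map and, for each group pair (i, j), a StatMap
    whose ``stat`` is a signed z value: the Tukey-Kramer adjusted p of the
    studentized-range statistic

        q = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))

    converted to a standard-normal quantile, signed by (mean_i - mean_j).
    The Kramer form of q is valid for unequal group sizes.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    stacks = [g.stacked() for g in groups]
    mask = groups[0].mask
    for g in groups[1:]:
        if not np.array_equal(g.mask, mask):
            raise ValueError("all groups must share the mask")
    ns = np.array([len(g) for g in groups])
    n_total, n_groups = int(ns.sum()), len(groups)
    df_within = n_total - n_groups

    means = np.stack([s.mean(axis=0) for s in stacks])
    variances = np.stack([s.std(axis=0, ddof=1) ** 2 for s in stacks])
    valid = mask & np.all(
        [np.isfinite(s).all(axis=0) for s in stacks], axis=0
    )
    ssw = (variances * (ns - 1)[:, None, None, None]).sum(axis=0)
    msw = ssw / df_within
    grand = (means * ns[:, None, None, None]).sum(axis=0) / n_total
    ssb = ((means - grand) ** 2 * ns[:, None, None, None]).sum(axis=0)
    msb = ssb / (n_groups - 1)
    valid &= msw > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = np.where(valid, msb / np.where(msw > 0, msw, 1.0), MISSING)
    f_p = np.where(
        valid, scipy.stats.f.sf(f_stat, n_groups - 1, df_within), MISSING
    )
    f_map = StatMap(
        stat=f_stat,
        p=f_p,
        mask=mask,
        df=(n_groups - 1, df_within),
        stat_name="F",
        contrast="one-way ANOVA",
        threshold_info={"alpha": alpha, "correction": "none"},
        spatial_meta=dict(groups[0].spatial_meta),
    )

    pair_maps: list[StatMap] = []
    labels = [f"group{i}" for i in range(n_groups)]
    for i, j in combinations(range(n_groups), 2):
        delta = means[i] - means[j]
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = np.abs(delta) / np.where(se > 0, se, 1.0)
        p_adj = _tukey_sf(q, n_groups, df_within)
        # numerical floor keeps the normal quantile finite
        p_adj = np.clip(p_adj, 1e-300, 1.0)
        z = np.sign(delta) * scipy.stats.norm.isf(p_adj / 2.0)
        z = np.where(valid, z, MISSING)
        p_adj = np.where(valid, p_adj, MISSING)
        pair_maps.append(
            StatMap(
                stat=z,
                p=p_adj,
                mask=mask,
                df=df_within,
                stat_name="z",
                contrast=f"{labels[i]} - {labels[j]}",
                threshold_info={"alpha": alpha, "correction": "tukey_kramer"},
                spatial_meta=dict(groups[0].spatial_meta),
            )
        )
    return f_map, pair_maps


def fdr_correct(
    p_values: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up over the finite p-values.

    Returns (rejections, threshold): a boolean array of the input shape
    (missing p -> not rejected) and the largest rejected p-value (0.0 when
    nothing is rejected).
    """
    p_values = np.asarray(p_values, dtype=np.float64)
    if p_values.size == 0:
        raise ValueError("empty p-value array")
    if not (0 < q < 1):
        raise ValueError(f"q must be in (0, 1), got {q}")
    finite = np.isfinite(p_values)
    reject = np.zeros(p_values.shape, dtype=bool)
    if finite.any():
        flat = p_values[finite]
        if ((flat < 0) | (flat > 1)).any():
            raise ValueError("p-values outside [0, 1]")
        rej, *_ = multipletests(flat, alpha=q, method="fdr_bh")
        reject[finite] = rej
    threshold = float(p_values[reject].max()) if reject.any() else 0.0
    return reject, threshold


def threshold_map(
    stat_map: StatMap,
    stat_floor: float,
    rejections: np.ndarray,
    signed: bool = False,
) -> MetricMap:
    """Joint statistic-floor + FDR threshold, figure-caption style.

    A voxel survives iff |stat| > stat_floor (or stat > stat_floor when
    ``signed``) AND its FDR rejection flag is set; survivors keep their
    statistic value, all others become missing.
    """
    if rejections.shape != stat_map.stat.shape:
        raise ValueError("rejection array shape does not match the stat map")
    stat = stat_map.stat
    magnitude = stat if signed else np.abs(stat)
    with np.errstate(invalid="ignore"):
        survives = (magnitude > stat_floor) & rejections & np.isfinite(stat)
    values = np.where(survives, stat, MISSING)
    return MetricMap(
        values=values,
        mask=stat_map.mask,
        metric_name=f"{stat_map.stat_name}_thresholded",
        params={
            "stat_floor": stat_floor,
            "signed": signed,
            "contrast": stat_map.contrast,
            **stat_map.threshold_info,
        },
        spatial_meta=dict(stat_map.spatial_meta),
    )
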