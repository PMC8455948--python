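"""Test-retest reliability: map correlations and voxel-wise ICC.

Two complementary views of reproducibility across scanning sessions:

* ``map_corrcoef`` — the Pearson correlation of two vectorised maps,
  corrcoef(A, B) = cov(vec(A), vec(B)) / sqrt(var(A) var(B)), computed
  over jointly non-missing in-mask voxels. Affine-invariant, so it does
  not matter whether maps were z-scored first.
* ``icc_map`` — voxel-wise intraclass correlation between a pair of
  sessions. The default ICC(3,1) (two-way mixed, consistency) treats the
  two sessions as fixed raters and ignores additive session effects;
  ICC(2,1) (two-way random, absolute agreement) penalises them.

Negative ICC estimates are reported as computed, not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .io import MISSING, MetricMap
from .stats import GroupSet, one_sample_t

__all__ = [
    "SessionSet",
    "ReliabilityReport",
    "map_corrcoef",
    "session_corr_matrix",
    "group_map_corr",
    "icc_map",
]


@dataclass
class SessionSet:
    """Per-session lists of subject maps, same subjects in the same order."""

    sessions: list[list[MetricMap]]
    session_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.sessions) < 2:
            raise ValueError("need at least 2 sessions")
        n_subj = len(self.sessions[0])
        if n_subj < 1:
            raise ValueError("sessions must contain at least one subject")
        for s in self.sessions[1:]:
            if len(s) != n_subj:
                raise ValueError("sessions must have equal subject counts")
        ref_mask = self.sessions[0][0].mask
        for s in self.sessions:
            for m in s:
                if not np.array_equal(m.mask, ref_mask):
                    raise ValueError("all maps must share the mask")
        if self.session_labels is None:
            self.session_labels = [f"session{i + 1}" for i in range(len(self.sessions))]

    @property
    def n_subjects(self) -> int:
        return len(self.sessions[0])

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)

    def pairs(self) -> list[tuple[int, int]]:
        return list(combinations(range(self.n_sessions), 2))


@dataclass
class ReliabilityReport:
    """Correlation and ICC summaries of a multi-session dataset."""

    per_subject_corr: pd.DataFrame  # subjects x session-pairs
    summary: pd.DataFrame  # mean / sd per session pair
    group_corr: dict[str, float] = field(default_factory=dict)
    icc_maps: dict[str, np.ndarray] = field(default_factory=dict)
    n_voxels: int = 0


def map_corrcoef(a: MetricMap, b: MetricMap) -> float:
    """Pearson correlation of two vectorised maps over shared voxels.

    Only jointly non-missing in-mask voxels enter; returns missing (NaN)
    when fewer than 2 such voxels exist or either map has zero variance.
    """
    if a.values.shape != b.values.shape:
        raise ValueError("maps must share shape")
    joint = a.finite_mask() & b.finite_mask()
    if joint.sum() < 2:
        return MISSING
    va, vb = a.values[joint], b.values[joint]
    if va.std() == 0 or vb.std() == 0:
        return MISSING
    if np.array_equal(va, vb):
        return 1.0  # duplicated maps correlate exactly, no rounding residue
    return float(np.clip(np.corrcoef(va, vb)[0, 1], -1.0, 1.0))


def _pair_label(labels: list[str], i: int, j: int) -> str:
    return f"{labels[i]}-{labels[j]}"


def session_corr_matrix(sessions: SessionSet) -> ReliabilityReport:
    """Per-subject Pearson correlations for every unordered session pair.

    The report's ``summary`` holds the across-subject mean and SD per pair
    — the headline individual-reproducibility numbers.
    """
    labels = sessions.session_labels
    cols = {}
    for i, j in sessions.pairs():
        cols[_pair_label(labels, i, j)] = [
            map_corrcoef(sessions.sessions[i][s], sessions.sessions[j][s])
            for s in range(sessions.n_subjects)
        ]
    per_subject = pd.DataFrame(
        cols, index=[f"subject{s + 1}" for s in range(sessions.n_subjects)]
    )
    summary = pd.DataFrame({"mean": per_subject.mean(), "sd": per_subject.std()})
    n_vox = int(sessions.sessions[0][0].finite_mask().sum())
    return ReliabilityReport(
        per_subject_corr=per_subject, summary=summary, n_voxels=n_vox
    )


def group_map_corr(sessions: SessionSet, stat: str = "mean") -> dict[str, float]:
    """Session-pair correlations of group-level maps (voxel mean or t-map)."""
    if stat not in ("mean", "tmap"):
        raise ValueError(f"stat must be 'mean' or 'tmap', got {stat!r}")
    group_maps = []
    for maps in sessions.sessions:
        if stat == "mean":
            stacked = np.stack([m.values for m in maps])
            gmap = MetricMap(
                values=np.nanmean(stacked, axis=0),
                mask=maps[0].mask,
                metric_name=f"{maps[0].metric_name}_groupmean",
                spatial_meta=dict(maps[0].spatial_meta),
            )
        else:
            gmap = one_sample_t(GroupSet(list(maps))).as_metric_map("stat")
        group_maps.append(gmap)
    labels = sessions.session_labels
    return {
        _pair_label(labels, i, j): map_corrcoef(group_maps[i], group_maps[j])
        for i, j in sessions.pairs()
    }


def icc_map(
    session_a: list[MetricMap],
    session_b: list[MetricMap],
    form: str = "icc31",
) -> np.ndarray:
    """Voxel-wise intraclass correlation between two sessions.

    From the two-way ANOVA decomposition over subjects x sessions (k = 2
    raters):

        ICC(3,1) = (BMS - EMS) / (BMS + (k-1) EMS)
        ICC(2,1) = (BMS - EMS) / (BMS + (k-1) EMS + k (JMS - EMS) / n)

    with BMS the between-subject, JMS the between-session and EMS the
    residual mean square. Voxels with zero between-subject variance or any
    missing input are set missing.
    """
    if form not in ("icc31", "icc21"):
        raise ValueError(f"form must be 'icc31' or 'icc21', got {form!r}")
    n = len(session_a)
    if n < 2 or len(session_b) != n:
        raise ValueError("need matched sessions with at least 2 subjects each")
    shape = session_a[0].values.shape
    # y: (n_subjects, 2, voxels)
    y = np.stack(
        [
            np.stack([a.values.ravel() for a in session_a]),
            np.stack([b.values.ravel() for b in session_b]),
        ],
        axis=1,
    )
    k = 2
    grand = y.mean(axis=(0, 1))
    subj_mean = y.mean(axis=1)
    sess_mean = y.mean(axis=0)
    ss_subj = k * ((subj_mean - grand) ** 2).sum(axis=0)
    ss_sess = n * ((sess_mean - grand) ** 2).sum(axis=0)
    ss_total = ((y - grand) ** 2).sum(axis=(0, 1))
    ss_err = ss_total - ss_subj - ss_sess
    bms = ss_subj / (n - 1)
    jms = ss_sess / (k - 1)
    ems = ss_err / ((n - 1) * (k - 1))

    if form == "icc31":
        denom = bms + (k - 1) * ems
    else:
        denom = bms + (k - 1) * ems + k * (jms - ems) / n
    valid = np.isfinite(y).all(axis=(0, 1)) & (ss_subj > 0) & (denom > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = (bms - ems) / np.where(denom > 0, denom, 1.0)
    icc = np.where(valid, icc, MISSING)
    mask = session_a[0].mask.ravel()
    return np.where(mask, icc, MISSING).reshape(shape)
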