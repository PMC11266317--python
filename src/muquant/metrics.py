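"""VOI statistics, mu-error analysis, the COV noise chain and group tests.

The noise chain mirrors the repeated-acquisition protocol: for each of J
repeated scans, the mu-map mean over I cubic VOIs in the homogeneous
plastic-water section is formed (per-repetition mean); the grand mean and
the (n-1)-divisor sample SD over repetitions then give the coefficient of
variation COV = SD / mean.  Defaults are J = 10 repetitions and I = 8 VOIs
of 1000 voxels (10 x 10 x 10).

Group comparisons follow a normality gate at alpha = 0.05: Shapiro-Wilk per
group, then an unpaired t-test (2 groups) or one-way ANOVA (more) when every
group is consistent with normality, otherwise Mann-Whitney / Kruskal-Wallis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .grids import Volume

__all__ = [
    "BoxVOI",
    "InsertStats",
    "NoiseAnalysis",
    "StatsReport",
    "voi_mean",
    "relative_error",
    "inner_outer_mean",
    "cov_chain",
    "compare_groups",
    "default_noise_vois",
]


@dataclass(frozen=True)
class BoxVOI:
    """Axis-aligned box of voxels: anchor index (corner) plus extent."""

    anchor: tuple[int, int, int]
    extent: tuple[int, int, int]

    @classmethod
    def from_center(cls, center: tuple[int, int, int], extent: tuple[int, int, int]) -> "BoxVOI":
        return cls(tuple(int(c - e // 2) for c, e in zip(center, extent)), tuple(extent))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.extent))

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, a + e) for a, e in zip(self.anchor, self.extent))

    def check_inside(self, shape: tuple[int, int, int]) -> None:
        for a, e, n in zip(self.anchor, self.extent, shape):
            if a < 0 or e < 1 or a + e > n:
                raise ValueError(f"VOI {self} outside volume of shape {shape}")


def voi_mean(volume, voi: BoxVOI) -> float:
    """Arithmetic mean of the voxels inside a box VOI."""
    values = volume.values if isinstance(volume, Volume) else np.asarray(volume)
    voi.check_inside(values.shape)
    return float(values[voi.slices()].mean())


def relative_error(measured, theoretical):
    """(measured - theoretical) / theoretical * 100, in percent."""
    t = np.asarray(theoretical, dtype=float)
    if np.any(t == 0):
        raise ZeroDivisionError("theoretical value is zero")
    out = (np.asarray(measured, dtype=float) - t) / t * 100.0
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class InsertStats:
    """Per-insert measured/theoretical attenuation summary."""

    insert: str
    mu_inner: float | None
    mu_outer: float | None
    mu_theoretical: float
    single_ring: bool = False

    @property
    def mu_mean(self) -> float:
        return inner_outer_mean(self.mu_inner, self.mu_outer)[0]

    @property
    def error_percent(self) -> float:
        return relative_error(self.mu_mean, self.mu_theoretical)


def inner_outer_mean(mu_inner: float | None, mu_outer: float | None) -> tuple[float, bool]:
    """Mean of the inner- and outer-ring VOI means.

    Returns ``(value, single_ring)``; inserts present in only one ring (the
    1250 mg/cm^3 HA bone) return that ring's value with the flag set.
    """
    if mu_inner is None and mu_outer is None:
        raise ValueError("no ring values available")
    if mu_inner is None or mu_outer is None:
        return float(mu_inner if mu_outer is None else mu_outer), True
    return (float(mu_inner) + float(mu_outer)) / 2.0, False


@dataclass(frozen=True)
class NoiseAnalysis:
    """Repetition means, grand mean, SD and COV of the noise chain."""

    per_repetition_mean: tuple[float, ...]
    mean: float
    sd: float

    @property
    def cov(self) -> float:
        return self.sd / self.mean


def cov_chain(mu_maps, vois) -> NoiseAnalysis:
    """COV of repeated mu-map VOI means (see module docstring).

    ``mu_maps`` is one volume (or array) per repetition; ``vois`` the common
    set of box VOIs.  Requires at least two repetitions (the sample SD is
    undefined for one) and at least one VOI.
    """
    mu_maps = list(mu_maps)
    vois = list(vois)
    if len(mu_maps) < 2:
        raise ValueError("need at least two repetitions for a sample SD")
    if not vois:
        raise ValueError("need at least one VOI")
    rep_means = tuple(
        float(np.mean([voi_mean(m, v) for v in vois])) for m in mu_maps
    )
    mean = float(np.mean(rep_means))
    sd = float(np.std(rep_means, ddof=1))
    return NoiseAnalysis(per_repetition_mean=rep_means, mean=mean, sd=sd)


def default_noise_vois(
    grid, homogeneous_z: tuple[float, float] = (105.0, 245.0), ring_radius_mm: float = 70.0
) -> list[BoxVOI]:
    """Eight 10x10x10-voxel VOIs on a ring in the homogeneous section."""
    extent = (10, 10, 10)
    zc = 0.5 * (homogeneous_z[0] + homogeneous_z[1])
    vois = []
    for k in range(8):
        t = 2 * np.pi * k / 8
        w = (ring_radius_mm * np.cos(t), ring_radius_mm * np.sin(t), zc)
        idx = np.rint(grid.world_to_index(np.array(w))).astype(int)
        voi = BoxVOI.from_center(tuple(idx), extent)
        voi.check_inside(grid.shape)
        vois.append(voi)
    return vois


@dataclass(frozen=True)
class StatsReport:
    """Outcome of one gated group comparison."""

    test: str
    statistic: float
    p_value: float
    normality_p: tuple[float, ...]
    all_normal: bool
    alpha: float = 0.05


def compare_groups(groups, alpha: float = 0.05) -> StatsReport:
    """Normality-gated location test across independent groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 3 for g in groups):
        raise ValueError("each group needs n >= 3")
    norm_p = tuple(float(stats.shapiro(g).pvalue) for g in groups)
    all_normal = all(p > alpha for p in norm_p)
    if all_normal:
        if len(groups) == 2:
            res = stats.ttest_ind(groups[0], groups[1])
            name = "unpaired t-test"
        else:
            res = stats.f_oneway(*groups)
            name = "one-way ANOVA"
    else:
        if len(groups) == 2:
            res = stats.mannwhitneyu(groups[0], groups[1])
            name = "Mann-Whitney U"
        else:
            res = stats.kruskal(*groups)
            name = "Kruskal-Wallis"
    return StatsReport(
        test=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        normality_p=norm_p,
        all_normal=all_normal,
        alpha=alpha,
    )
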