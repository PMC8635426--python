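"""Clonal-proliferation analysis on multicolor reporter images.

In a stochastic multicolor (Brainbow-type) reporter, a contiguous cluster
of same-color cells descends from one recombined progenitor.  Each color
channel is binarized and labeled independently (color is the clone
identity), and labeled components are classified by area: components at or
above 2000 px count as clones, smaller ones as single cells.  The 2000-px
boundary is inclusive, mirroring the inclusive nucleus-size rule.

Group comparisons use one-way ANOVA with either Tukey's HSD or
Benjamini-Hochberg-adjusted pairwise Welch tests as the post hoc
procedure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage import measure
from statsmodels.stats.multitest import multipletests

from .config import DEFAULT_CLONE_MIN_AREA, DEFAULT_MARKER_THRESHOLD
from .if_quant import binarize_fixed, _as_binary, _skimage_connectivity

__all__ = [
    "LabeledComponents",
    "CloneReport",
    "GroupComparison",
    "label_components",
    "classify_clones",
    "analyze_clone_image",
    "one_way_anova",
    "tukey_posthoc",
    "bh_posthoc",
    "compare_clone_groups",
]

#: p-value floor used when within-group variance is exactly zero and the F
#: statistic diverges.
P_FLOOR = 1e-300


@dataclass
class LabeledComponents:
    """Connected components of one binary channel."""

    labels: np.ndarray  # labeled image, 0 = background, labels contiguous
    areas: np.ndarray  # pixels per label, index 0 <-> label 1
    centroids: np.ndarray  # (n, 2) row/col centroids
    channel: str = ""

    @property
    def n_components(self) -> int:
        return len(self.areas)


@dataclass
class CloneReport:
    """Per-image clone/singleton partition of labeled components."""

    image_id: str
    clone_count: int
    singleton_count: int
    clone_areas: list[int]  # descending
    total_clone_area: int
    per_channel_clones: dict[str, int] = field(default_factory=dict)
    clone_min_area: int = DEFAULT_CLONE_MIN_AREA

    @property
    def component_count(self) -> int:
        return self.clone_count + self.singleton_count


@dataclass
class GroupComparison:
    """One-way ANOVA plus pairwise post hoc over named groups."""

    metric: str
    group_means: dict[str, float]
    group_sems: dict[str, float]
    group_ns: dict[str, int]
    f_statistic: float
    p_value: float
    posthoc: dict[tuple[str, str], float]
    posthoc_method: str


def label_components(
    mask: np.ndarray, connectivity: int = 8, channel: str = ""
) -> LabeledComponents:
    """Label connected components of a binary mask (8-connected default)."""
    arr = _as_binary(mask)
    labels = measure.label(arr, connectivity=_skimage_connectivity(connectivity))
    n = int(labels.max())
    if n == 0:
        return LabeledComponents(
            labels=labels,
            areas=np.zeros(0, dtype=int),
            centroids=np.zeros((0, 2)),
            channel=channel,
        )
    areas = np.bincount(labels.ravel())[1:]
    centroids = np.array(
        [p.centroid for p in measure.regionprops(labels)], dtype=float
    )
    return LabeledComponents(
        labels=labels, areas=areas.astype(int), centroids=centroids, channel=channel
    )


def classify_clones(
    components: LabeledComponents | list[LabeledComponents],
    clone_min_area: int = DEFAULT_CLONE_MIN_AREA,
    image_id: str = "",
) -> CloneReport:
    """Partition components into clones (area >= threshold) and singletons.

    Accepts one channel's components or a list of per-channel components
    (pooled, since each color is an independent clone identity).
    """
    if clone_min_area <= 0:
        raise ValueError("clone_min_area must be positive")
    comps = components if isinstance(components, list) else [components]
    clone_areas: list[int] = []
    per_channel: dict[str, int] = {}
    singletons = 0
    for c in comps:
        is_clone = c.areas >= clone_min_area
        ch_clones = [int(a) for a in c.areas[is_clone]]
        clone_areas.extend(ch_clones)
        singletons += int((~is_clone).sum())
        key = c.channel or f"channel_{len(per_channel)}"
        per_channel[key] = per_channel.get(key, 0) + len(ch_clones)
    clone_areas.sort(reverse=True)
    return CloneReport(
        image_id=image_id,
        clone_count=len(clone_areas),
        singleton_count=singletons,
        clone_areas=clone_areas,
        total_clone_area=int(sum(clone_areas)),
        per_channel_clones=per_channel,
        clone_min_area=clone_min_area,
    )


def analyze_clone_image(
    rgb: np.ndarray,
    image_id: str = "",
    threshold: float = DEFAULT_MARKER_THRESHOLD,
    clone_min_area: int = DEFAULT_CLONE_MIN_AREA,
    channels: tuple[str, ...] = ("red", "green", "blue"),
) -> CloneReport:
    """Threshold, label, and classify each reporter color channel of an image."""
    img = np.asarray(rgb)
    if img.ndim != 3 or img.shape[-1] != len(channels):
        raise ValueError(
            f"expected (H, W, {len(channels)}) image, got {img.shape}"
        )
    comps = [
        label_components(binarize_fixed(img[..., i], threshold), channel=name)
        for i, name in enumerate(channels)
    ]
    return classify_clones(comps, clone_min_area=clone_min_area, image_id=image_id)


def one_way_anova(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within.

    Computed from the standard sums of squares so the degenerate case of
    zero within-group variance is handled explicitly: F diverges and p is
    reported as the documented floor ``P_FLOOR`` (0 exactly would be a
    lie at finite n).  Agrees with ``scipy.stats.f_oneway`` elsewhere.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    all_vals = np.concatenate(list(arrays.values()))
    grand = all_vals.mean()
    n_total = all_vals.size
    k = len(arrays)
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_between, df_within = k - 1, n_total - k
    ms_between = ss_between / df_between
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0  # all observations identical
        return float("inf"), P_FLOOR
    ms_within = ss_within / df_within
    f = ms_between / ms_within
    p = float(stats.f.sf(f, df_between, df_within))
    return float(f), max(min(p, 1.0), P_FLOOR)


def tukey_posthoc(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Pairwise Tukey HSD adjusted p-values (studentized-range family)."""
    names = list(groups)
    res = stats.tukey_hsd(*[np.asarray(groups[n], dtype=float) for n in names])
    out: dict[tuple[str, str], float] = {}
    for i, j in itertools.combinations(range(len(names)), 2):
        out[(names[i], names[j])] = float(res.pvalue[i, j])
    return out


def bh_posthoc(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Pairwise two-sample t tests with Benjamini-Hochberg adjustment."""
    names = list(groups)
    pairs = list(itertools.combinations(names, 2))
    raw = [
        stats.ttest_ind(groups[a], groups[b], equal_var=True).pvalue
        for a, b in pairs
    ]
    raw = [1.0 if np.isnan(p) else float(p) for p in raw]
    adj = multipletests(raw, method="fdr_bh")[1]
    return {pair: float(p) for pair, p in zip(pairs, adj)}


def compare_clone_groups(
    group_values: dict[str, np.ndarray],
    metric: str = "clone_count",
    posthoc: str = "tukey",
) -> GroupComparison:
    """Compare a clone metric across >= 2 groups of images.

    Reports per-group mean +/- SEM, the one-way ANOVA F and p, and pairwise
    post hoc adjusted p-values (Tukey HSD by default, BH by flag).
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in group_values.items()}
    f, p = one_way_anova(arrays)
    if posthoc == "tukey":
        ph = tukey_posthoc(arrays)
    elif posthoc == "bh":
        ph = bh_posthoc(arrays)
    else:
        raise ValueError(f"posthoc must be 'tukey' or 'bh', got {posthoc!r}")
    return GroupComparison(
        metric=metric,
        group_means={k: float(a.mean()) for k, a in arrays.items()},
        group_sems={k: float(stats.sem(a)) for k, a in arrays.items()},
        group_ns={k: int(a.size) for k, a in arrays.items()},
        f_statistic=f,
        p_value=p,
        posthoc=ph,
        posthoc_method=posthoc,
    )


def clone_reports_to_groups(
    reports: dict[str, list[CloneReport]], metric: str = "clone_count"
) -> dict[str, np.ndarray]:
    """Extract a per-image metric array per group from clone reports."""
    getters = {
        "clone_count": lambda r: r.clone_count,
        "singleton_count": lambda r: r.singleton_count,
        "total_clone_area": lambda r: r.total_clone_area,
    }
    if metric not in getters:
        raise ValueError(f"unknown clone metric {metric!r}")
    get = getters[metric]
    return {g: np.array([get(r) for r in rs], dtype=float) for g, rs in reports.items()}
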