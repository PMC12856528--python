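"""Extraction of the PPfpm key features and derived extent metrics.

The *pli-de-passage fronto-parietal moyen* (PPfpm) is located in a depth
profile through two landmarks:

PPfpm-II
    the lateral end of the fold — the deepest local minimum at positions
    strictly lateral of a threshold (default 45).  If no local minimum lies
    lateral of the threshold, the deepest grid point lateral of it is used
    instead, so the landmark exists for every profile.
PPfpm-I
    the fold's peak height — the local maximum directly medially adjacent
    to PPfpm-II.  Absent when the profile has no maximum medial of PPfpm-II
    (overall flat profiles, or all maxima lateral of the landmark).

From the pair, three extent metrics follow: absolute height |y_II - y_I| in
mm, relative height |(y_II - y_I)/y_II| (reported as a percentage of the
profile depth at PPfpm-II), and peak-to-lateral width |x_II - x_I| in
positions, i.e. percent of sulcus length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .extrema import Extremum, find_turnpoints
from .profiles import Cohort, DepthProfile

__all__ = [
    "FeatureConfig",
    "PPfpmFeatures",
    "ExtentMetrics",
    "extract_ppfpm2",
    "extract_ppfpm1",
    "extract_features",
    "compute_extent",
    "recenter_profiles",
    "average_profile",
    "feature_table",
]


@dataclass(frozen=True)
class FeatureConfig:
    lateral_threshold: int = 45  # strict ">": candidate minima need position > this

    def __post_init__(self) -> None:
        if not 0 < self.lateral_threshold < 100:
            raise ValueError("lateral_threshold must be inside (0, 100)")


@dataclass(frozen=True)
class ExtentMetrics:
    absolute_height_mm: float
    relative_height: float  # fraction; *100 for percent
    peak_to_lateral_width: float  # positions == percent of sulcus length

    @property
    def relative_height_pct(self) -> float:
        return 100.0 * self.relative_height


@dataclass
class PPfpmFeatures:
    subject_id: str
    hemisphere: str
    ppfpm2: tuple[int, float]  # (position, depth)
    ppfpm1: tuple[int, float] | None
    deepest_point: tuple[int, float]
    extent: ExtentMetrics | None
    flags: set[str] = field(default_factory=set)

    @property
    def ppfpm1_absent(self) -> bool:
        return self.ppfpm1 is None


def extract_ppfpm2(
    profile: DepthProfile,
    extrema: list[Extremum],
    cfg: FeatureConfig | None = None,
) -> tuple[tuple[int, float], set[str]]:
    """Locate PPfpm-II: deepest local minimum lateral of the threshold.

    Total on valid profiles: when no local minimum lies lateral of the
    threshold the deepest grid point lateral of it is returned and flagged.
    Equal-depth candidates resolve to the most medial position.  A whole-
    profile global minimum at or medial of the threshold is flagged
    ``global_min_medial_of_threshold``.
    """
    cfg = cfg or FeatureConfig()
    flags: set[str] = set()
    minima = [e for e in extrema if e.kind == "minimum" and e.position > cfg.lateral_threshold]
    if minima:
        best = min(minima, key=lambda e: (e.depth, e.position))
        pos, depth = best.position, best.depth
    else:
        flags.add("ppfpm2_fallback_grid_point")
        lateral = profile.depths[cfg.lateral_threshold + 1 :]
        off = int(np.argmin(lateral))
        pos = cfg.lateral_threshold + 1 + off
        depth = float(lateral[off])
    gpos = int(np.argmin(profile.depths))
    if gpos <= cfg.lateral_threshold:
        flags.add("global_min_medial_of_threshold")
    return (int(pos), float(depth)), flags


def extract_ppfpm1(
    profile: DepthProfile,
    extrema: list[Extremum],
    ppfpm2: tuple[int, float],
    cfg: FeatureConfig | None = None,
) -> tuple[int, float] | None:
    """Locate PPfpm-I: the local maximum with the largest position < x_II."""
    x2 = ppfpm2[0]
    maxima = [e for e in extrema if e.kind == "maximum" and e.position < x2]
    if not maxima:
        return None
    best = max(maxima, key=lambda e: e.position)
    return (int(best.position), float(best.depth))


def compute_extent(
    ppfpm1: tuple[int, float], ppfpm2: tuple[int, float]
) -> ExtentMetrics:
    """Extent metrics from the two landmarks; requires both present."""
    (x1, y1), (x2, y2) = ppfpm1, ppfpm2
    abs_height = abs(y2 - y1)
    if y2 == 0:
        raise ValueError("relative height undefined: PPfpm-II depth is 0")
    return ExtentMetrics(
        absolute_height_mm=float(abs_height),
        relative_height=float(abs((y2 - y1) / y2)),
        peak_to_lateral_width=float(abs(x2 - x1)),
    )


def extract_features(
    profile: DepthProfile,
    extrema: list[Extremum] | None = None,
    cfg: FeatureConfig | None = None,
) -> PPfpmFeatures:
    """Full per-profile extraction: PPfpm-II, PPfpm-I, extent, bookkeeping flags."""
    cfg = cfg or FeatureConfig()
    if extrema is None:
        extrema = find_turnpoints(profile)
    ppfpm2, flags = extract_ppfpm2(profile, extrema, cfg)
    ppfpm1 = extract_ppfpm1(profile, extrema, ppfpm2, cfg)
    if ppfpm1 is None:
        flags.add("ppfpm1_absent")
    dpos = int(np.argmin(profile.depths))
    deepest = (dpos, float(profile.depths[dpos]))
    if deepest != ppfpm2:
        flags.add("ppfpm2_not_deepest")
    extent = compute_extent(ppfpm1, ppfpm2) if ppfpm1 is not None else None
    return PPfpmFeatures(
        subject_id=profile.subject_id,
        hemisphere=profile.hemisphere.value,
        ppfpm2=ppfpm2,
        ppfpm1=ppfpm1,
        deepest_point=deepest,
        extent=extent,
        flags=flags,
    )


def average_profile(profiles: list[DepthProfile]) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and SD of depth across profiles on the common grid."""
    if not profiles:
        raise ValueError("average_profile needs at least one profile")
    stack = np.stack([p.depths for p in profiles])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(profiles) > 1 else np.zeros_like(mean)
    return mean, sd


def recenter_profiles(
    profiles: list[DepthProfile], features: list[PPfpmFeatures]
) -> pd.DataFrame:
    """Re-index each profile so its PPfpm-II sits at offset 0.

    Offsets k = position - x_II run negative medially, positive laterally.
    Returns a tidy frame with columns ``offset, mean, sd, n``; mean/SD are
    computed per offset over the profiles covering that offset, and the
    value at offset 0 is the mean of the profiles' y_II by construction.
    """
    if len(profiles) != len(features):
        raise ValueError("profiles and features must align")
    by_offset: dict[int, list[float]] = {}
    for p, f in zip(profiles, features):
        x2 = f.ppfpm2[0]
        for i, d in enumerate(p.depths):
            by_offset.setdefault(i - x2, []).append(float(d))
    rows = []
    for k in sorted(by_offset):
        v = np.asarray(by_offset[k])
        rows.append(
            {
                "offset": k,
                "mean": v.mean(),
                "sd": v.std(ddof=1) if v.size > 1 else 0.0,
                "n": v.size,
            }
        )
    return pd.DataFrame(rows)


def feature_table(cohort: Cohort, features: list[PPfpmFeatures]) -> pd.DataFrame:
    """Tidy per-hemisphere feature table joined to subject metadata.

    One row per profile with landmark coordinates, extent metrics, flags,
    and the subject's sex, age, Oldfield index and handedness class; this is
    the input to the group-statistics battery.
    """
    rows = []
    for f in features:
        s = cohort.subjects[f.subject_id]
        x1, y1 = (f.ppfpm1 if f.ppfpm1 is not None else (np.nan, np.nan))
        rows.append(
            {
                "subject_id": f.subject_id,
                "hemisphere": f.hemisphere,
                "sex": s.sex,
                "age": s.age,
                "oldfield": np.nan if s.oldfield is None else s.oldfield,
                "handedness": s.handedness_class.value,
                "x_I": x1,
                "y_I": y1,
                "x_II": f.ppfpm2[0],
                "y_II": f.ppfpm2[1],
                "deepest_x": f.deepest_point[0],
                "deepest_y": f.deepest_point[1],
                "abs_height_mm": f.extent.absolute_height_mm if f.extent else np.nan,
                "rel_height_pct": f.extent.relative_height_pct if f.extent else np.nan,
                "width_pct": f.extent.peak_to_lateral_width if f.extent else np.nan,
                "ppfpm1_absent": f.ppfpm1_absent,
                "ppfpm2_is_deepest": "ppfpm2_not_deepest" not in f.flags,
                "flags": ";".join(sorted(f.flags)),
            }
        )
    return pd.DataFrame(rows)
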