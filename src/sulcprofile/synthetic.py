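"""Generative model of central sulcus depth profiles with ground truth.

Each profile is built in the inverted convention (0 at the ridge, negative
into the sulcus) as

* a U-shaped base: a shape-preserving (PCHIP) spline through anchor points
  declining monotonically from a shallow medial end to the deepest point
  (the lateral trough), then inclining to the lateral end;
* one or two Gaussian elevations ("bumps") standing in for the PPfpm, per
  shape class (unimodal profiles carry no bump; trimodal ones an extra
  medial elevation; double-elevation ones a split PPfpm peak);
* smooth low-frequency cosine noise.

Defaults follow the cohort statistics printed for the human data the model
emulates: lateral trough position ~ N(60.79, 5.12) truncated to (45, 80],
trough depth ~ N(-23.78, 1.60) mm, bump apex position ~ N(45.77, 6.12),
bump height ~ N(4.53, 2.70) truncated at 0.02 mm, shape mix
8/70/15/7 % (unimodal/bimodal/trimodal/double elevation).  Bump width
scales with height (sigma = width_scale * height^gamma), which induces the
observed positive height-width correlation; subject-level parameter draws
are shared across hemispheres with smaller hemisphere-level jitter, giving
within-subject correlation for the paired analyses.

Profiles are returned in the raw (positive-mm) convention so the pipeline's
explicit inversion step is exercised; ground truth is recorded in the
inverted convention used by the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .profiles import Cohort, DepthProfile, Hemisphere, SubjectRecord, POSITIONS

__all__ = [
    "GeneratorConfig",
    "BaseCurveConfig",
    "BumpConfig",
    "EffectsConfig",
    "NoiseConfig",
    "GroundTruth",
    "simulate_profile",
    "simulate_cohort",
    "groundtruth_table",
]

SHAPE_CLASSES = ("unimodal", "bimodal", "trimodal", "double_elevation")


@dataclass(frozen=True)
class BaseCurveConfig:
    medial_end_depth: float = -2.0  # mm at position 0, near the interhemispheric cleft
    trough_depth_mean: float = -23.78
    trough_depth_sd: float = 1.60
    trough_pos_mean: float = 60.79
    trough_pos_sd: float = 5.12
    lateral_end_depth: float = -4.0  # mm at position 100, near the lateral sulcus


@dataclass(frozen=True)
class BumpConfig:
    apex_pos_mean: float = 45.77
    apex_pos_sd: float = 6.12
    height_mean: float = 4.53
    height_sd: float = 2.70
    height_min: float = 0.02
    width_scale: float = 2.6  # sigma = width_scale * height**width_gamma
    width_gamma: float = 0.5


@dataclass(frozen=True)
class EffectsConfig:
    male_depth_offset: float = -1.0  # whole-profile shift, mm
    right_lateral_shift: float = 1.8  # positions, applied to trough and apex
    right_ppfpm1_depth_offset: float = -0.82  # mm, via reduced bump height


@dataclass(frozen=True)
class NoiseConfig:
    amplitude: float = 0.5  # total SD of the cosine perturbation, mm
    min_components: int = 3
    max_components: int = 5
    max_frequency: int = 6  # cycles over the full profile
    # expected displacement of a noisy valley minimum below the noiseless
    # trough (mm) and lateral of it (positions, from the bump-tail tilt of
    # the valley); the construction draws the trough this much shallower and
    # more medial so the realized lateral minimum stays on the calibration
    # targets
    min_selection_bias: float = 0.50
    lateral_selection_bias: float = 0.40


@dataclass(frozen=True)
class GeneratorConfig:
    n_subjects: int = 100
    seed: int = 0
    shape_mix: dict = field(
        default_factory=lambda: {
            "unimodal": 0.08,
            "bimodal": 0.70,
            "trimodal": 0.15,
            "double_elevation": 0.07,
        }
    )
    base_curve: BaseCurveConfig = field(default_factory=BaseCurveConfig)
    bump: BumpConfig = field(default_factory=BumpConfig)
    effects: EffectsConfig = field(default_factory=EffectsConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    sex_ratio_male: float = 0.4536  # fraction of male subjects
    handedness_left_prob: float = 0.086
    handedness_zero_prob: float = 0.007
    subject_variance_fraction: float = 0.7  # share of trait variance at subject level

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if set(self.shape_mix) - set(SHAPE_CLASSES):
            raise ValueError(f"unknown shape class in {self.shape_mix}")
        tot = sum(self.shape_mix.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"shape_mix must sum to 1, got {tot}")
        for sd in (
            self.base_curve.trough_depth_sd,
            self.base_curve.trough_pos_sd,
            self.bump.apex_pos_sd,
            self.bump.height_sd,
            self.noise.amplitude,
        ):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if not 0 < self.subject_variance_fraction <= 1:
            raise ValueError("subject_variance_fraction must be in (0, 1]")


@dataclass
class GroundTruth:
    subject_id: str
    hemisphere: str
    shape_class: str
    apex_pos: float | None  # inverted-convention landmark of the constructed curve
    apex_depth: float | None
    latmin_pos: int
    latmin_depth: float
    sex: str = ""
    oldfield: int | None = None


@dataclass
class _SubjectDraw:
    """Subject-level latent parameters, shared across hemispheres."""

    shape_class: str
    trough_pos: float
    trough_depth: float
    apex_pos: float
    height: float
    sex: str
    oldfield: int | None


_MAX_REJECT = 1000


def _trunc_normal(rng, mean, sd, low=-np.inf, high=np.inf, warn_counter=None):
    """Rejection-sampled truncated normal; degenerate configs raise after many redraws."""
    if sd == 0:
        v = mean
        if not low <= v <= high:
            raise ValueError(f"degenerate truncation: {mean} outside [{low}, {high}]")
        return float(v)
    for k in range(_MAX_REJECT):
        v = rng.normal(mean, sd)
        if low <= v <= high:
            if k > 0 and warn_counter is not None:
                warn_counter["rejections"] = warn_counter.get("rejections", 0) + k
            return float(v)
    raise ValueError(
        f"rejection sampling failed for N({mean}, {sd}) on [{low}, {high}]"
    )


_OLDFIELD_GRID = np.arange(-100, 101, 5)


def _draw_oldfield(cfg: GeneratorConfig, rng: np.random.Generator) -> int:
    """Skewed Oldfield index: right-handers concentrated at +100, left milder."""
    u = rng.random()
    if u < cfg.handedness_left_prob:
        grid = _OLDFIELD_GRID[_OLDFIELD_GRID < 0]
        w = np.exp(-grid / 60.0)
    elif u < cfg.handedness_left_prob + cfg.handedness_zero_prob:
        return 0
    else:
        grid = _OLDFIELD_GRID[_OLDFIELD_GRID > 0]
        w = np.exp(grid / 30.0)
    return int(rng.choice(grid, p=w / w.sum()))


def _draw_subject(cfg: GeneratorConfig, rng: np.random.Generator, counters: dict) -> _SubjectDraw:
    bc, bp = cfg.base_curve, cfg.bump
    fsub = np.sqrt(cfg.subject_variance_fraction)
    cls = rng.choice(SHAPE_CLASSES, p=[cfg.shape_mix.get(c, 0.0) for c in SHAPE_CLASSES])
    return _SubjectDraw(
        shape_class=str(cls),
        trough_pos=_trunc_normal(
            rng, bc.trough_pos_mean, fsub * bc.trough_pos_sd, 45.0 + 1e-9, 80.0, counters
        ),
        trough_depth=rng.normal(bc.trough_depth_mean, fsub * bc.trough_depth_sd),
        apex_pos=rng.normal(bp.apex_pos_mean, fsub * bp.apex_pos_sd),
        height=_trunc_normal(
            rng, bp.height_mean, fsub * bp.height_sd, bp.height_min, np.inf, counters
        ),
        sex="male" if rng.random() < cfg.sex_ratio_male else "female",
        oldfield=_draw_oldfield(cfg, rng),
    )


def _base_curve(
    trough_pos: float,
    trough_depth: float,
    med: float,
    lat: float,
    plateau: bool,
    trough_drop: float = 0.0,
) -> np.ndarray:
    """Monotone decline to the trough then incline, via PCHIP anchors.

    ``plateau=True`` (profiles carrying a PPfpm elevation) levels off into a
    deep mid-section before a short accentuated drop to the trough, so the
    elevation stands on a nearly flat floor; ``plateau=False`` (unimodal
    profiles) declines steeply all the way, which suppresses noise-induced
    maxima and yields the sharp medial incline of that shape class.
    """
    tp = trough_pos
    dd = trough_depth - med
    if plateau:
        xs = [0.0, 0.35 * tp, 0.62 * tp, tp - 6.0, tp, tp + 0.45 * (100.0 - tp), 100.0]
        ys = [
            med,
            med + 0.82 * dd,
            trough_depth + 1.55,
            trough_depth + 0.95,
            trough_depth - trough_drop,
            trough_depth + 0.45 * (lat - trough_depth),
            lat,
        ]
    else:
        xs = [0.0, 0.45 * tp, tp - 6.0, tp, tp + 0.45 * (100.0 - tp), 100.0]
        ys = [
            med,
            med + 0.55 * dd,
            trough_depth + 1.20,
            trough_depth - trough_drop,
            trough_depth + 0.45 * (lat - trough_depth),
            lat,
        ]
    return PchipInterpolator(xs, ys)(POSITIONS.astype(float))


def _gauss_bump(apex: float, height: float, sigma: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((POSITIONS - apex) / sigma) ** 2)


def _cosine_noise(cfg: NoiseConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.amplitude == 0:
        return np.zeros(POSITIONS.size)
    k = int(rng.integers(cfg.min_components, cfg.max_components + 1))
    freqs = rng.integers(1, cfg.max_frequency + 1, size=k)
    phases = rng.uniform(0, 2 * np.pi, size=k)
    amps = rng.uniform(0.5, 1.0, size=k)
    wave = np.sum(
        amps[:, None] * np.cos(2 * np.pi * freqs[:, None] * POSITIONS / 100.0 + phases[:, None]),
        axis=0,
    )
    return cfg.amplitude * wave / np.std(wave)


def _build_hemisphere(
    cfg: GeneratorConfig,
    sub: _SubjectDraw,
    hemisphere: Hemisphere,
    subject_id: str,
    rng: np.random.Generator,
    counters: dict,
) -> tuple[DepthProfile, GroundTruth]:
    bc, bp, ef = cfg.base_curve, cfg.bump, cfg.effects
    fhem = np.sqrt(1.0 - cfg.subject_variance_fraction)
    right = hemisphere is Hemisphere.RIGHT
    # hemisphere contrasts are applied centred (half the configured delta to
    # each side) so population means stay on the calibration targets
    shift = 0.5 * ef.right_lateral_shift * (1.0 if right else -1.0)
    h_off = 0.5 * ef.right_ppfpm1_depth_offset * (1.0 if right else -1.0)

    trough_pos = float(
        np.clip(
            sub.trough_pos
            + shift
            - cfg.noise.lateral_selection_bias
            + rng.normal(0, fhem * bc.trough_pos_sd),
            46.0,
            80.0,
        )
    )
    trough_depth = (
        sub.trough_depth
        + rng.normal(0, fhem * bc.trough_depth_sd)
        + cfg.noise.min_selection_bias
    )
    apex = sub.apex_pos + shift + rng.normal(0, fhem * bp.apex_pos_sd)
    apex = float(np.clip(apex, 10.0, trough_pos - 4.0))
    height = max(sub.height + rng.normal(0, fhem * bp.height_sd) + h_off, bp.height_min)

    # sex contrast, centred by the cohort's male fraction
    depth_offset = ef.male_depth_offset * (
        (1.0 - cfg.sex_ratio_male) if sub.sex == "male" else -cfg.sex_ratio_male
    )
    cls = sub.shape_class
    med = bc.medial_end_depth
    lat = bc.lateral_end_depth + depth_offset
    trough = trough_depth + depth_offset

    def bumps_for(base: np.ndarray) -> np.ndarray:
        """Sum of elevations for the shape class, on top of a given base.

        The configured "height" is the intended landmark depth difference
        y_II - y_I, so the Gaussian amplitude is height minus the base's own
        elevation at the apex, clipped to a visible minimum.
        """
        if cls == "unimodal":
            return np.zeros_like(base)
        elev = float(np.interp(apex, POSITIONS, base)) - float(
            np.interp(trough_pos, POSITIONS, base)
        )
        amp = max(height - elev, bp.height_min)
        sigma = bp.width_scale * height**bp.width_gamma
        if cls == "bimodal":
            return _gauss_bump(apex, amp, sigma)
        if cls == "trimodal":
            # extra medial elevation, clearly separated from the PPfpm bump
            a2 = float(np.clip(aux[0], 12.0, apex - 10.0))
            h2 = 0.6 * amp * aux[1]
            return _gauss_bump(apex, amp, sigma) + _gauss_bump(
                a2, h2, bp.width_scale * max(h2, bp.height_min) ** bp.width_gamma
            )
        # double elevation: the PPfpm peak splits into two close sub-peaks
        gap = max(aux[0], 5.0)
        return _gauss_bump(apex, amp, 0.7 * sigma) + _gauss_bump(
            apex - gap, amp * aux[1], 0.7 * sigma
        )

    # class-specific auxiliary draws, taken once so both passes agree
    if cls == "trimodal":
        aux = (rng.normal(27.0, 4.0), rng.uniform(0.6, 1.2))
    elif cls == "double_elevation":
        aux = (rng.normal(8.0, 1.5), rng.uniform(0.6, 0.95))
    else:
        aux = (0.0, 0.0)

    # two-pass construction: the bump tail lifts the trough, so the trough
    # anchor alone is deepened by that lift (the surrounding anchors stay
    # put) to keep the realized lateral-minimum depth on the drawn target
    plateau = cls != "unimodal"
    base = _base_curve(trough_pos, trough, med, lat, plateau)
    lift = float(np.interp(trough_pos, POSITIONS, bumps_for(base)))
    base = _base_curve(trough_pos, trough, med, lat, plateau, trough_drop=lift)
    curve = base + bumps_for(base)

    noisy = curve + _cosine_noise(cfg.noise, rng)
    noisy = np.minimum(noisy, -1e-6)  # the sulcus never rises above the ridge

    # ground truth: the landmark rules applied to the constructed curve
    # itself (noise included); the extraction pipeline sees this curve only
    # after smoothing, so recovery measures the smoothing stage's footprint
    latmin_pos, latmin_depth = _lateral_minimum(noisy)
    truth_apex = _adjacent_medial_maximum(noisy, latmin_pos)
    if truth_apex is not None:
        truth_apex_pos, truth_apex_depth = truth_apex
    else:
        truth_apex_pos = truth_apex_depth = None

    profile = DepthProfile(
        subject_id=subject_id,
        hemisphere=hemisphere,
        depths=-noisy,  # stored raw (positive mm); inversion is a pipeline step
        inverted=False,
    )
    truth = GroundTruth(
        subject_id=subject_id,
        hemisphere=hemisphere.value,
        shape_class=cls,
        apex_pos=truth_apex_pos,
        apex_depth=truth_apex_depth,
        latmin_pos=latmin_pos,
        latmin_depth=latmin_depth,
        sex=sub.sex,
        oldfield=sub.oldfield,
    )
    return profile, truth


def _lateral_minimum(curve: np.ndarray, threshold: int = 45) -> tuple[int, float]:
    """Deepest discrete local minimum lateral of the threshold (grid fallback)."""
    d1 = np.diff(curve)
    cand = [
        i
        for i in range(1, curve.size - 1)
        if d1[i - 1] < 0 <= d1[i] and i > threshold
    ]
    if cand:
        pos = min(cand, key=lambda i: (curve[i], i))
    else:
        lateral = curve[threshold + 1 :]
        pos = threshold + 1 + int(np.argmin(lateral))
    return int(pos), float(curve[pos])


def _adjacent_medial_maximum(curve: np.ndarray, latmin_pos: int) -> tuple[int, float] | None:
    """Local maximum with the largest position strictly medial of the lateral minimum."""
    d1 = np.diff(curve)
    for i in range(latmin_pos - 1, 0, -1):
        if d1[i - 1] > 0 >= d1[i]:
            return int(i), float(curve[i])
    return None


def simulate_profile(
    config: GeneratorConfig, rng: np.random.Generator | int | None = None
) -> tuple[DepthProfile, GroundTruth]:
    """Draw one subject and build their left-hemisphere profile."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    counters: dict = {}
    sub = _draw_subject(config, rng, counters)
    return _build_hemisphere(config, sub, Hemisphere.LEFT, "sim0000", rng, counters)


def simulate_cohort(config: GeneratorConfig) -> tuple[Cohort, list[GroundTruth]]:
    """Simulate a full cohort: two hemispheres per subject, reproducible from seed."""
    rng = np.random.default_rng(config.seed)
    counters: dict = {}
    profiles: list[DepthProfile] = []
    subjects: dict[str, SubjectRecord] = {}
    truths: list[GroundTruth] = []
    for k in range(config.n_subjects):
        sid = f"sim{k:04d}"
        sub = _draw_subject(config, rng, counters)
        subjects[sid] = SubjectRecord(
            subject_id=sid,
            sex=sub.sex,
            age=float(np.round(rng.uniform(22, 37), 0)),
            oldfield=sub.oldfield,
        )
        for hemi in (Hemisphere.LEFT, Hemisphere.RIGHT):
            p, t = _build_hemisphere(config, sub, hemi, sid, rng, counters)
            profiles.append(p)
            truths.append(t)
    cohort = Cohort(profiles=profiles, subjects=subjects, provenance=f"synthetic(seed={config.seed})")
    return cohort, truths


def groundtruth_table(truths: list[GroundTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": t.subject_id,
                "hemisphere": t.hemisphere,
                "shape_class": t.shape_class,
                "apex_pos": np.nan if t.apex_pos is None else t.apex_pos,
                "apex_depth": np.nan if t.apex_depth is None else t.apex_depth,
                "latmin_pos": t.latmin_pos,
                "latmin_depth": t.latmin_depth,
                "sex": t.sex,
                "oldfield": np.nan if t.oldfield is None else t.oldfield,
            }
            for t in truths
        ]
    )
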