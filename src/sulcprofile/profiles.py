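"""Data model and I/O for central sulcus depth-profile cohorts.

A depth profile samples the depth of the central sulcus (ridge-to-fundus
length, mm) at 101 equidistant positions along its medial (0) to lateral
(100) trajectory.  Raw parametrization output stores depth as positive mm;
analysis uses the inverted convention (0 at the top ridge, negative values
downward), with inversion an explicit, audited pipeline step.

Files use a wide TSV dialect: one row per (subject, hemisphere) with columns
``subject_id, hemisphere, d000..d100``, plus a subject metadata CSV with
columns ``subject_id, sex, age, oldfield, excluded, exclusion_reason``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

N_POSITIONS = 101
POSITIONS = np.arange(N_POSITIONS)

__all__ = [
    "N_POSITIONS",
    "POSITIONS",
    "Hemisphere",
    "HandednessClass",
    "DepthProfile",
    "SubjectRecord",
    "Cohort",
    "CohortFormatError",
    "classify_handedness",
    "read_cohort",
    "write_cohort",
]


class CohortFormatError(ValueError):
    """Malformed profile or metadata file (missing column, bad value, duplicate row)."""


class Hemisphere(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"

    @classmethod
    def parse(cls, token: str) -> "Hemisphere":
        t = str(token).strip().lower()
        if t in ("l", "left"):
            return cls.LEFT
        if t in ("r", "right"):
            return cls.RIGHT
        raise CohortFormatError(f"unrecognized hemisphere label {token!r}")

    @property
    def code(self) -> str:
        return "L" if self is Hemisphere.LEFT else "R"


class HandednessClass(str, enum.Enum):
    LEFT_HANDED = "left_handed"
    RIGHT_HANDED = "right_handed"
    EXCLUDED_ZERO = "excluded_zero"
    MISSING = "missing"


def classify_handedness(oldfield: int | float | None) -> HandednessClass:
    """Classify an Edinburgh/Oldfield handedness index.

    Left-handed iff index < 0, right-handed iff index > 0; an index of
    exactly 0 is excluded as ambiguous.  The index must lie in [-100, 100]
    on the 5-point grid; a missing value maps to ``MISSING``.
    """
    if oldfield is None or (isinstance(oldfield, float) and np.isnan(oldfield)):
        return HandednessClass.MISSING
    v = float(oldfield)
    if not v.is_integer() or not -100 <= v <= 100 or int(v) % 5 != 0:
        raise ValueError(
            f"Oldfield index must be a multiple of 5 in [-100, 100], got {oldfield!r}"
        )
    if v < 0:
        return HandednessClass.LEFT_HANDED
    if v > 0:
        return HandednessClass.RIGHT_HANDED
    return HandednessClass.EXCLUDED_ZERO


@dataclass
class DepthProfile:
    """One hemisphere's 101-point depth curve plus identity metadata.

    ``depths`` holds one value per position 0..100.  ``inverted`` records the
    sign convention: False means raw positive mm, True means the analysis
    convention (all values <= 0).
    """

    subject_id: str
    hemisphere: Hemisphere
    depths: np.ndarray
    inverted: bool = False
    smoothed: bool = False
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if self.depths.shape != (N_POSITIONS,):
            raise CohortFormatError(
                f"profile {self.subject_id}/{self.hemisphere.value}: expected "
                f"{N_POSITIONS} depth values, got {self.depths.shape}"
            )
        if not np.all(np.isfinite(self.depths)):
            bad = int(np.flatnonzero(~np.isfinite(self.depths))[0])
            raise CohortFormatError(
                f"profile {self.subject_id}/{self.hemisphere.value}: non-finite "
                f"depth at position {bad}"
            )
        if self.inverted and np.any(self.depths > 0):
            raise CohortFormatError(
                f"profile {self.subject_id}/{self.hemisphere.value}: inverted "
                "profile has positive depths"
            )

    @property
    def positions(self) -> np.ndarray:
        return POSITIONS

    @property
    def key(self) -> tuple[str, str]:
        return (self.subject_id, self.hemisphere.value)

    def with_depths(self, depths: np.ndarray, **changes) -> "DepthProfile":
        return replace(self, depths=np.asarray(depths, dtype=float), **changes)


@dataclass
class SubjectRecord:
    subject_id: str
    sex: str  # "male" | "female"
    age: float
    oldfield: int | None = None
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        s = str(self.sex).strip().lower()
        if s in ("m", "male"):
            self.sex = "male"
        elif s in ("f", "female"):
            self.sex = "female"
        else:
            raise CohortFormatError(f"subject {self.subject_id}: bad sex {self.sex!r}")
        if self.oldfield is not None:
            # validate eagerly so a bad index fails at load, not at analysis
            classify_handedness(self.oldfield)

    @property
    def handedness_class(self) -> HandednessClass:
        return classify_handedness(self.oldfield)


@dataclass
class Cohort:
    """A validated collection of depth profiles plus their subject metadata."""

    profiles: list[DepthProfile] = field(default_factory=list)
    subjects: dict[str, SubjectRecord] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for p in self.profiles:
            if p.key in seen:
                raise CohortFormatError(
                    f"duplicate profile for subject {p.subject_id} "
                    f"hemisphere {p.hemisphere.value}"
                )
            seen.add(p.key)
            if p.subject_id not in self.subjects:
                raise CohortFormatError(
                    f"profile subject {p.subject_id} has no metadata record"
                )

    def __len__(self) -> int:
        return len(self.profiles)

    def get(self, subject_id: str, hemisphere: Hemisphere) -> DepthProfile:
        for p in self.profiles:
            if p.key == (subject_id, hemisphere.value):
                return p
        raise KeyError((subject_id, hemisphere))

    def active_profiles(self) -> list[DepthProfile]:
        return [p for p in self.profiles if not p.excluded]

    def map_depths(self, fn) -> "Cohort":
        """Apply ``fn(profile) -> profile`` to every profile, keeping metadata."""
        return Cohort(
            profiles=[fn(p) for p in self.profiles],
            subjects=dict(self.subjects),
            provenance=self.provenance,
        )


_DEPTH_COLS = [f"d{i:03d}" for i in range(N_POSITIONS)]


def read_cohort(profiles_path: str | Path, metadata_path: str | Path) -> Cohort:
    """Read a cohort from a wide profiles TSV and a metadata CSV.

    Raises :class:`CohortFormatError` naming the offending row/column for
    missing columns, non-numeric depths, duplicate (subject, hemisphere)
    rows, or profiles without metadata.
    """
    profiles_path, metadata_path = Path(profiles_path), Path(metadata_path)
    prof = pd.read_csv(profiles_path, sep="\t", dtype={"subject_id": str})
    missing = [c for c in ["subject_id", "hemisphere", *_DEPTH_COLS] if c not in prof.columns]
    if missing:
        raise CohortFormatError(
            f"{profiles_path.name}: missing column(s) {', '.join(missing[:5])}"
            + (" ..." if len(missing) > 5 else "")
        )
    meta = pd.read_csv(metadata_path, dtype={"subject_id": str})
    need = ["subject_id", "sex", "age"]
    miss = [c for c in need if c not in meta.columns]
    if miss:
        raise CohortFormatError(f"{metadata_path.name}: missing column(s) {', '.join(miss)}")

    def _clean_str(v) -> str:
        return "" if v is None or (isinstance(v, float) and pd.isna(v)) else str(v)

    subjects: dict[str, SubjectRecord] = {}
    for _, r in meta.iterrows():
        old = r.get("oldfield")
        if old is not None and pd.isna(old):
            old = None
        subjects[str(r["subject_id"])] = SubjectRecord(
            subject_id=str(r["subject_id"]),
            sex=r["sex"],
            age=float(r["age"]),
            oldfield=None if old is None else int(old),
            excluded=bool(int(r.get("excluded", 0) or 0)),
            exclusion_reason=_clean_str(r.get("exclusion_reason", "")),
        )

    inverted = bool(prof.attrs.get("inverted", False))
    profiles: list[DepthProfile] = []
    for idx, r in prof.iterrows():
        vals = r[_DEPTH_COLS]
        depths = pd.to_numeric(vals, errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(depths)):
            pos = int(np.flatnonzero(~np.isfinite(depths))[0])
            raise CohortFormatError(
                f"{profiles_path.name} row {idx + 2}: non-numeric depth "
                f"{vals.iloc[pos]!r} at position {pos}"
            )
        profiles.append(
            DepthProfile(
                subject_id=str(r["subject_id"]),
                hemisphere=Hemisphere.parse(r["hemisphere"]),
                depths=depths,
                inverted=inverted or bool(np.any(depths < 0)),
                excluded=bool(int(r.get("excluded", 0) or 0)),
                exclusion_reason=_clean_str(r.get("exclusion_reason", "")),
            )
        )
    return Cohort(profiles=profiles, subjects=subjects, provenance=str(profiles_path))


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write ``profiles.tsv`` and ``metadata.csv``; re-reading reproduces the cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort.profiles:
        row: dict[str, object] = {
            "subject_id": p.subject_id,
            "hemisphere": p.hemisphere.code,
            "excluded": int(p.excluded),
            "exclusion_reason": p.exclusion_reason,
        }
        row.update({c: d for c, d in zip(_DEPTH_COLS, p.depths)})
        rows.append(row)
    prof = pd.DataFrame(rows, columns=["subject_id", "hemisphere", "excluded", "exclusion_reason", *_DEPTH_COLS])
    profiles_path = out / "profiles.tsv"
    prof.to_csv(profiles_path, sep="\t", index=False, float_format="%.10g")

    meta = pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "sex": "M" if s.sex == "male" else "F",
                "age": s.age,
                "oldfield": "" if s.oldfield is None else s.oldfield,
                "excluded": int(s.excluded),
                "exclusion_reason": s.exclusion_reason,
            }
            for s in cohort.subjects.values()
        ],
        columns=["subject_id", "sex", "age", "oldfield", "excluded", "exclusion_reason"],
    )
    metadata_path = out / "metadata.csv"
    meta.to_csv(metadata_path, index=False)
    return {"profiles": profiles_path, "metadata": metadata_path}


def profiles_by_subject(profiles: Iterable[DepthProfile]) -> dict[str, dict[str, DepthProfile]]:
    """Index profiles as {subject_id: {"left": ..., "right": ...}}."""
    out: dict[str, dict[str, DepthProfile]] = {}
    for p in profiles:
        out.setdefault(p.subject_id, {})[p.hemisphere.value] = p
    return out
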