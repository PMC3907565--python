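"""24-2 field layout, cohort records and I/O, reliability filtering, mean deviation.

The unit of analysis is one eye's FDT Matrix 24-2 field: 52 threshold
sensitivities in dB (the 54-point 24-2 grid minus the two blind-spot
locations), the subject's age, reliability indices and a normal/abnormal
label supplied by the instrument's statistics (GHT / PSD); the label is an
input to evaluation, never computed here.

Coordinate convention: all in-memory fields are in a right-eye frame with
superior = y > 0 and nasal = x > 0; the two nasal-extension points sit at
(+27, ±3) and the excluded blind-spot locations at (15, ±3).  Left-eye
fields are mirrored onto this frame at load time and un-mirrored on save,
so files keep native-frame values and save∘load is the identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

N_POINTS = 52
BLIND_SPOT = ((15.0, 3.0), (15.0, -3.0))

#: half-row x extents for |y| in the 24-2 grid (x symmetric about 0)
_HALF_ROW = {21: (3, 9), 15: (3, 9, 15), 9: (3, 9, 15, 21), 3: (3, 9, 15, 21)}


class CohortFormatError(ValueError):
    """Raised when a cohort file does not match the expected column layout."""


def _grid_points() -> tuple[tuple[float, float], ...]:
    pts: list[tuple[float, float]] = []
    for y in (21, 15, 9, 3, -3, -9, -15, -21):
        half = _HALF_ROW[abs(y)]
        xs = sorted([-x for x in half] + list(half))
        if abs(y) == 3:
            xs.append(27)  # nasal extension of the 24-2 pattern
        for x in xs:
            if (x, y) in ((15, 3), (15, -3)):
                continue  # physiological blind spot
            pts.append((float(x), float(y)))
    return tuple(pts)


@dataclass(frozen=True)
class Grid242Layout:
    """The 52-point 24-2 test pattern in right-eye orientation.

    Point order is fixed: rows from superior to inferior (y descending),
    within a row x ascending; this order defines the p01..p52 file columns.
    """

    points: tuple[tuple[float, float], ...] = field(default_factory=_grid_points)
    eye_frame: str = "right"

    def __post_init__(self) -> None:
        if len(self.points) != N_POINTS:
            raise ValueError(f"layout must have {N_POINTS} points, got {len(self.points)}")
        if len(set(self.points)) != N_POINTS:
            raise ValueError("duplicate layout coordinates")

    def coordinates(self) -> np.ndarray:
        """(52, 2) array of (x_deg, y_deg)."""
        return np.asarray(self.points, dtype=float)

    @property
    def superior_mask(self) -> np.ndarray:
        return self.coordinates()[:, 1] > 0

    @property
    def inferior_mask(self) -> np.ndarray:
        return self.coordinates()[:, 1] < 0

    @property
    def nasal_mask(self) -> np.ndarray:
        return self.coordinates()[:, 0] > 0

    def mirror_permutation(self) -> np.ndarray:
        """Index permutation mapping (x, y) -> (-x, y) where the partner exists.

        Points without a mirror partner (the nasal-extension points and the
        two points whose mirrors are the excluded blind-spot locations) map
        to themselves.  The permutation is an involution.
        """
        index = {p: i for i, p in enumerate(self.points)}
        perm = np.arange(N_POINTS)
        for i, (x, y) in enumerate(self.points):
            perm[i] = index.get((-x, y), i)
        return perm

    def point_columns(self) -> list[str]:
        return [f"p{i + 1:02d}" for i in range(N_POINTS)]


_LAYOUT = Grid242Layout()


def layout_242() -> Grid242Layout:
    """The canonical 52-point 24-2 layout (stable across calls)."""
    return _LAYOUT


@dataclass(eq=False)
class FieldRecord:
    """One eye's FDT field: 52 thresholds (dB), age, reliability, label."""

    subject_id: str
    eye: str
    thresholds: np.ndarray
    age: float
    fp_rate: float
    fl_rate: float
    fn_rate: float
    fdt_label: str
    archetype: Optional[str] = None  # ground truth, synthetic cohorts only
    severity: Optional[float] = None

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.shape != (N_POINTS,):
            raise ValueError(f"thresholds must have shape ({N_POINTS},)")
        if np.any(self.thresholds < 0) or not np.all(np.isfinite(self.thresholds)):
            raise ValueError("thresholds must be finite and non-negative dB")
        if self.eye not in ("left", "right"):
            raise ValueError(f"eye must be left|right, got {self.eye!r}")
        for name in ("fp_rate", "fl_rate", "fn_rate"):
            r = getattr(self, name)
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"{name}={r} outside [0, 1]")
        if self.fdt_label not in ("normal", "abnormal"):
            raise ValueError(f"fdt_label must be normal|abnormal, got {self.fdt_label!r}")

    def equals(self, other: "FieldRecord", atol: float = 0.0) -> bool:
        same_meta = (
            self.subject_id == other.subject_id
            and self.eye == other.eye
            and self.fdt_label == other.fdt_label
            and self.archetype == other.archetype
        )
        scalars = np.array([self.age, self.fp_rate, self.fl_rate, self.fn_rate], float)
        others = np.array([other.age, other.fp_rate, other.fl_rate, other.fn_rate], float)
        sev_ok = (self.severity is None) == (other.severity is None) and (
            self.severity is None or abs(self.severity - other.severity) <= atol
        )
        return bool(
            same_meta
            and sev_ok
            and np.allclose(self.thresholds, other.thresholds, atol=atol, rtol=0)
            and np.allclose(scalars, others, atol=atol, rtol=0)
        )


@dataclass
class Cohort:
    """A collection of field records sharing one layout."""

    layout: Grid242Layout
    records: list[FieldRecord]
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("cohort must be non-empty")

    def __len__(self) -> int:
        return len(self.records)

    def thresholds_matrix(self) -> np.ndarray:
        return np.stack([r.thresholds for r in self.records])

    def ages(self) -> np.ndarray:
        return np.array([r.age for r in self.records], dtype=float)

    def labels(self) -> np.ndarray:
        return np.array([r.fdt_label for r in self.records])

    def equals(self, other: "Cohort", atol: float = 0.0) -> bool:
        return len(self) == len(other) and all(
            a.equals(b, atol=atol) for a, b in zip(self.records, other.records)
        )


def feature_matrix(cohort: Cohort, include_age: str = "auto") -> tuple[np.ndarray, bool]:
    """Build the analysis matrix: 52 thresholds (+ age -> 53 dims).

    include_age: "auto" drops the age column only when it is constant
    (e.g. after an age ablation, where it would break standardization);
    "always"/"never" force the choice.  Returns (X, age_included).
    """
    X = cohort.thresholds_matrix()
    ages = cohort.ages()
    if include_age == "never":
        return X, False
    if include_age == "auto" and np.ptp(ages) == 0.0:
        log.info("age column is constant; dropping it from the feature matrix")
        return X, False
    return np.column_stack([X, ages]), True


def _to_frame(cohort: Cohort, native_frame: bool) -> pd.DataFrame:
    perm = cohort.layout.mirror_permutation()
    rows = []
    for r in cohort.records:
        thr = r.thresholds[perm] if (native_frame and r.eye == "left") else r.thresholds
        row = {"subject_id": r.subject_id, "eye": r.eye}
        row.update({c: t for c, t in zip(cohort.layout.point_columns(), thr)})
        row.update(
            age=r.age, fp_rate=r.fp_rate, fl_rate=r.fl_rate, fn_rate=r.fn_rate,
            fdt_label=r.fdt_label, archetype=r.archetype if r.archetype is not None else "",
            severity=r.severity if r.severity is not None else "",
        )
        rows.append(row)
    return pd.DataFrame(rows)


def save_cohort(cohort: Cohort, path: str | Path, dialect: str = "csv") -> None:
    """Write a cohort file (one row per eye, thresholds in native eye frame)."""
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    _to_frame(cohort, native_frame=True).to_csv(path, sep=sep, index=False)


def load_cohort(path: str | Path, dialect: str = "csv") -> Cohort:
    """Read a cohort file; left-eye fields are mirrored to the right-eye frame."""
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str})
    layout = layout_242()
    cols = layout.point_columns()
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CohortFormatError(f"missing threshold column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c.startswith("p") and c[1:].isdigit() and c not in cols]
    if extra:
        raise CohortFormatError(f"unexpected threshold column(s): {', '.join(extra)}")
    perm = layout.mirror_permutation()
    records = []
    for i, row in df.iterrows():
        try:
            thr = np.array([float(row[c]) for c in cols])
        except (TypeError, ValueError) as exc:
            raise CohortFormatError(f"non-numeric threshold in row {i}: {exc}") from exc
        if row["eye"] == "left":
            thr = thr[perm]
        arch = row.get("archetype", "")
        sev = row.get("severity", "")
        records.append(
            FieldRecord(
                subject_id=str(row["subject_id"]), eye=str(row["eye"]), thresholds=thr,
                age=float(row["age"]), fp_rate=float(row["fp_rate"]),
                fl_rate=float(row["fl_rate"]), fn_rate=float(row["fn_rate"]),
                fdt_label=str(row["fdt_label"]),
                archetype=None if (pd.isna(arch) or arch == "") else str(arch),
                severity=None if (pd.isna(sev) or sev == "") else float(sev),
            )
        )
    return Cohort(layout=layout, records=records, provenance="clinical")


def apply_reliability_filter(cohort: Cohort, max_rate: float = 0.33) -> Cohort:
    """Retain records with fp, fl and fn rates all <= max_rate (inclusive).

    Idempotent and order-preserving; the number removed is logged.  An empty
    result raises no error but is logged as a warning (Cohort itself rejects
    emptiness, so the caller sees the ValueError from construction).
    """
    kept = [
        r for r in cohort.records
        if r.fp_rate <= max_rate and r.fl_rate <= max_rate and r.fn_rate <= max_rate
    ]
    removed = len(cohort.records) - len(kept)
    if removed:
        log.info("reliability filter removed %d of %d records", removed, len(cohort))
    if not kept:
        # contract: warn, don't error -- sidestep the non-empty construction check
        log.warning("reliability filter removed every record")
        out = replace(cohort)
        out.records = []
        return out
    return replace(cohort, records=kept)


def mean_deviation(record: FieldRecord, normative_means: np.ndarray) -> float:
    """Unweighted mean over the 52 points of (threshold - normative mean), dB.

    A simplification of the instrument's proprietary eccentricity-weighted MD;
    the synthetic generator calibrates to this same statistic, so targets are
    self-consistent.
    """
    normative_means = np.asarray(normative_means, dtype=float)
    if normative_means.shape != (N_POINTS,):
        raise ValueError(f"normative_means must have shape ({N_POINTS},)")
    return float(np.mean(record.thresholds - normative_means))
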