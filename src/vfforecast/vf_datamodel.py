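"""Domain model for Humphrey 24-2 / 30-2 visual-field series.

Grid geometry, per-exam and per-eye containers, glaucoma severity staging,
reliability screening, 30-2 -> 24-2 subsetting, and CSV/JSON ingestion.

Conventions
-----------
All point-wise arrays (total deviation, pattern deviation) are stored in a
single canonical order: the 24-2 grid in *right-eye orientation*, row-major
from the superior row down, left to right (row sizes 4, 6, 8, 9, 9, 8, 6, 4;
54 points total).  Positive x is the temporal field for a right eye; the two
physiologic blind-spot points sit at (15, +/-3) degrees.  Left-eye (OS) data
are mirrored about the vertical axis on ingestion — within each row the
values are reversed — so that stored arrays are laterality-independent.
Blind-spot entries are stored as 0 dB.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GridPoint",
    "GRID_24_2",
    "GRID_30_2",
    "BLIND_SPOT_INDICES",
    "SEEING_INDICES",
    "N_POINTS_24_2",
    "N_POINTS_30_2",
    "Pattern",
    "Laterality",
    "Severity",
    "VFExam",
    "EyeSeries",
    "FormatError",
    "classify_severity",
    "is_reliable",
    "subset_30_2",
    "mirror_index_order",
    "read_series",
    "write_series",
    "export_grid_table",
]


class FormatError(ValueError):
    """Raised when an input file or array violates the documented schema."""


class Pattern(str, enum.Enum):
    P24_2 = "24-2"
    P30_2 = "30-2"


class Laterality(str, enum.Enum):
    OD = "OD"
    OS = "OS"


class Severity(str, enum.Enum):
    """Glaucoma stage from mean deviation: early / moderate / advanced."""

    EARLY = "early"
    MODERATE = "moderate"
    ADVANCED = "advanced"


@dataclass(frozen=True)
class GridPoint:
    index: int
    x_deg: int
    y_deg: int
    is_blind_spot: bool


def _build_grid(row_specs: Sequence[tuple[int, Sequence[int]]],
                blind_spots: frozenset[tuple[int, int]]) -> tuple[GridPoint, ...]:
    pts = []
    for y, xs in row_specs:
        for x in xs:
            pts.append(GridPoint(len(pts), x, y, (x, y) in blind_spots))
    return tuple(pts)


def _row(lo: int, hi: int) -> tuple[int, ...]:
    return tuple(range(lo, hi + 1, 6))


# 24-2: 54 points; rows 4,6,8,9,9,8,6,4.  The 9-point rows carry the extra
# nasal point at x = -27; blind spot temporal at (15, +/-3).
_ROWS_24_2: tuple[tuple[int, tuple[int, ...]], ...] = (
    (21, _row(-9, 9)),
    (15, _row(-15, 15)),
    (9, _row(-21, 21)),
    (3, _row(-27, 21)),
    (-3, _row(-27, 21)),
    (-9, _row(-21, 21)),
    (-15, _row(-15, 15)),
    (-21, _row(-9, 9)),
)

# 30-2: 76 points; rows 4,6,8,10,10,10,10,8,6,4.
_ROWS_30_2: tuple[tuple[int, tuple[int, ...]], ...] = (
    (27, _row(-9, 9)),
    (21, _row(-15, 15)),
    (15, _row(-21, 21)),
    (9, _row(-27, 27)),
    (3, _row(-27, 27)),
    (-3, _row(-27, 27)),
    (-9, _row(-27, 27)),
    (-15, _row(-21, 21)),
    (-21, _row(-15, 15)),
    (-27, _row(-9, 9)),
)

_BLIND = frozenset({(15, 3), (15, -3)})

GRID_24_2: tuple[GridPoint, ...] = _build_grid(_ROWS_24_2, _BLIND)
GRID_30_2: tuple[GridPoint, ...] = _build_grid(_ROWS_30_2, _BLIND)

N_POINTS_24_2 = 54
N_POINTS_30_2 = 76

assert len(GRID_24_2) == N_POINTS_24_2
assert len(GRID_30_2) == N_POINTS_30_2

BLIND_SPOT_INDICES: tuple[int, ...] = tuple(
    p.index for p in GRID_24_2 if p.is_blind_spot
)
SEEING_INDICES: tuple[int, ...] = tuple(
    p.index for p in GRID_24_2 if not p.is_blind_spot
)
assert len(BLIND_SPOT_INDICES) == 2

# Index of each 24-2 point inside the 30-2 canonical order (coordinate match).
_COORD_30_2 = {(p.x_deg, p.y_deg): p.index for p in GRID_30_2}
SUBSET_30_2_TO_24_2: tuple[int, ...] = tuple(
    _COORD_30_2[(p.x_deg, p.y_deg)] for p in GRID_24_2
)


def mirror_index_order(grid: Sequence[GridPoint]) -> np.ndarray:
    """Per-row reversal permutation mapping a left-eye native ordering onto
    the right-eye canonical ordering (and vice versa; it is an involution)."""
    order = np.empty(len(grid), dtype=int)
    i = 0
    rows: dict[int, list[int]] = {}
    for p in grid:
        rows.setdefault(p.y_deg, []).append(p.index)
    for y, idxs in rows.items():
        order[idxs] = idxs[::-1]
    return order


_MIRROR_24_2 = mirror_index_order(GRID_24_2)
_MIRROR_30_2 = mirror_index_order(GRID_30_2)


# --------------------------------------------------------------------------
# Exam / series containers
# --------------------------------------------------------------------------

def _as_float_array(values: Iterable[float], n: int, name: str) -> np.ndarray:
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                     dtype=float)
    if arr.shape != (n,):
        raise FormatError(f"{name} must have length {n}, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise FormatError(f"{name} contains non-finite values")
    return arr


@dataclass
class VFExam:
    """A single standard-automated-perimetry test.

    ``td``/``pd`` are total/pattern deviation values in dB, canonical grid
    order, blind-spot entries zero.  ``md``/``psd`` in dB, ``vfi`` in percent,
    ``fp``/``fn``/``fl`` reliability rates in percent.
    """

    exam_date: _dt.date
    td: np.ndarray
    pd: np.ndarray
    md: float
    psd: float
    vfi: float
    fp: float
    fn: float
    fl: float
    pattern: Pattern = Pattern.P24_2

    def __post_init__(self) -> None:
        n = N_POINTS_24_2 if self.pattern is Pattern.P24_2 else N_POINTS_30_2
        self.td = _as_float_array(self.td, n, "td")
        self.pd = _as_float_array(self.pd, n, "pd")
        for name in ("md", "psd", "vfi", "fp", "fn", "fl"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise FormatError(f"{name} is not finite")
            setattr(self, name, v)
        if self.psd < 0:
            raise FormatError(f"psd must be non-negative, got {self.psd}")
        if not 0.0 <= self.vfi <= 100.0:
            raise FormatError(f"vfi must be in [0, 100], got {self.vfi}")
        if self.pattern is Pattern.P24_2:
            bs = self.td[list(BLIND_SPOT_INDICES)]
            if np.any(bs != 0) or np.any(self.pd[list(BLIND_SPOT_INDICES)] != 0):
                raise FormatError("blind-spot td/pd entries must be stored as 0")

    @property
    def severity(self) -> Severity:
        return classify_severity(self.md)


@dataclass
class EyeSeries:
    """Chronologically ascending exams for one eye."""

    eye_id: str
    laterality: Laterality
    exams: list[VFExam] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.exams) < 1:
            raise FormatError(f"eye {self.eye_id}: a series needs at least one exam")
        dates = [e.exam_date for e in self.exams]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise FormatError(
                f"eye {self.eye_id}: exam dates must be strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.exams)

    @property
    def dates(self) -> list[_dt.date]:
        return [e.exam_date for e in self.exams]


# --------------------------------------------------------------------------
# Clinical rules
# --------------------------------------------------------------------------

def classify_severity(md: float) -> Severity:
    """Stage glaucoma from mean deviation.

    early: MD > -6 dB; moderate: -12 < MD <= -6 dB; advanced: MD <= -12 dB.
    """
    md = float(md)
    if not math.isfinite(md):
        raise ValueError(f"md must be finite, got {md}")
    if md > -6.0:
        return Severity.EARLY
    if md > -12.0:
        return Severity.MODERATE
    return Severity.ADVANCED


def is_reliable(exam: VFExam) -> bool:
    """True iff fixation loss, false-positive and false-negative rates are
    each strictly below 33%."""
    for name in ("fp", "fn", "fl"):
        v = getattr(exam, name)
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} rate must be in [0, 100], got {v}")
    return exam.fl < 33.0 and exam.fp < 33.0 and exam.fn < 33.0


def subset_30_2(exam: VFExam) -> VFExam:
    """Project a 30-2 exam onto the 54 spatially coincident 24-2 locations.

    Global and reliability indices are carried over unchanged; the two
    physiologic blind-spot entries are zeroed to satisfy the 24-2 storage
    convention.  A 24-2 exam passes through untouched (the projection is
    idempotent); any other point count is a format error.
    """
    if exam.pattern is Pattern.P24_2:
        return exam
    if exam.pattern is not Pattern.P30_2 or exam.td.shape != (N_POINTS_30_2,):
        raise FormatError(
            f"subset_30_2 expects a 76-point 30-2 exam, got {exam.td.shape}"
        )
    sel = list(SUBSET_30_2_TO_24_2)
    td = exam.td[sel]
    pd_ = exam.pd[sel]
    td[list(BLIND_SPOT_INDICES)] = 0.0
    pd_[list(BLIND_SPOT_INDICES)] = 0.0
    return VFExam(
        exam_date=exam.exam_date,
        td=td,
        pd=pd_,
        md=exam.md,
        psd=exam.psd,
        vfi=exam.vfi,
        fp=exam.fp,
        fn=exam.fn,
        fl=exam.fl,
        pattern=Pattern.P24_2,
    )


# --------------------------------------------------------------------------
# I/O — documented schema
#
# CSV: one row per exam with columns
#   eye_id, laterality, exam_date (YYYY-MM-DD), pattern, md, psd, vfi,
#   fp, fn, fl, td_1..td_54, pd_1..pd_54   (td_1..td_76 / pd_1..pd_76 for 30-2)
# JSON: {"eyes": [{"eye_id", "laterality", "exams": [{...same fields,
#   "td": [...], "pd": [...]}]}]}
#
# Files carry native-orientation values; OS rows are mirrored to the
# right-eye canonical order on read and mirrored back on write.
# --------------------------------------------------------------------------

def _grid_cols(prefix: str, n: int) -> list[str]:
    return [f"{prefix}_{i}" for i in range(1, n + 1)]


def _maybe_mirror(values: np.ndarray, laterality: Laterality,
                  pattern: Pattern) -> np.ndarray:
    if laterality is Laterality.OD:
        return values
    order = _MIRROR_24_2 if pattern is Pattern.P24_2 else _MIRROR_30_2
    return values[order]


def _exam_from_fields(rec: dict, td: np.ndarray, pd_: np.ndarray,
                      laterality: Laterality, where: str) -> VFExam:
    try:
        pattern = Pattern(str(rec["pattern"]))
        date_raw = rec["exam_date"]
        if isinstance(date_raw, _dt.date):
            exam_date = date_raw
        else:
            exam_date = _dt.date.fromisoformat(str(date_raw))
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{where}: bad exam_date/pattern ({exc})") from exc
    td = _maybe_mirror(td, laterality, pattern)
    pd_ = _maybe_mirror(pd_, laterality, pattern)
    try:
        exam = VFExam(
            exam_date=exam_date, td=td, pd=pd_,
            md=float(rec["md"]), psd=float(rec["psd"]), vfi=float(rec["vfi"]),
            fp=float(rec["fp"]), fn=float(rec["fn"]), fl=float(rec["fl"]),
            pattern=pattern,
        )
    except (KeyError, FormatError, TypeError, ValueError) as exc:
        raise FormatError(f"{where}: {exc}") from exc
    return exam


def _finalize_series(
    groups: dict[tuple[str, str], list[VFExam]],
    *,
    subset: bool,
    reliable_only: bool,
) -> list[EyeSeries]:
    out = []
    for (eye_id, lat), exams in groups.items():
        if subset:
            exams = [subset_30_2(e) for e in exams]
        if reliable_only:
            exams = [e for e in exams if is_reliable(e)]
        if not exams:
            continue
        exams.sort(key=lambda e: e.exam_date)
        out.append(EyeSeries(eye_id=eye_id, laterality=Laterality(lat), exams=exams))
    return out


def read_series(path: str | Path, format: str | None = None, *,
                subset_to_24_2: bool = True,
                reliable_only: bool = True) -> list[EyeSeries]:
    """Read eye series from CSV or JSON (format inferred from suffix).

    30-2 exams are subset to the 24-2 grid and unreliable exams dropped by
    default; exams are grouped by (eye_id, laterality) and date-sorted.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    groups: dict[tuple[str, str], list[VFExam]] = {}
    if fmt == "json":
        with open(path) as fh:
            payload = json.load(fh)
        for eye in payload.get("eyes", []):
            eye_id = str(eye["eye_id"])
            lat = Laterality(str(eye["laterality"]))
            for k, rec in enumerate(eye.get("exams", [])):
                where = f"{path.name}: eye {eye_id} exam {k}"
                n = N_POINTS_24_2 if str(rec.get("pattern")) == "24-2" else N_POINTS_30_2
                try:
                    td = _as_float_array(rec["td"], n, "td")
                    pd_ = _as_float_array(rec["pd"], n, "pd")
                except (KeyError, FormatError) as exc:
                    raise FormatError(f"{where}: {exc}") from exc
                groups.setdefault((eye_id, lat.value), []).append(
                    _exam_from_fields(rec, td, pd_, lat, where)
                )
    elif fmt == "csv":
        df = pd.read_csv(path, dtype={"eye_id": str})
        required = {"eye_id", "laterality", "exam_date", "pattern",
                    "md", "psd", "vfi", "fp", "fn", "fl"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"{path.name}: missing columns {sorted(missing)}")
        for i, row in df.iterrows():
            where = f"{path.name}: row {i + 2}"  # 1-based + header
            rec = row.to_dict()
            try:
                lat = Laterality(str(rec["laterality"]))
            except ValueError as exc:
                raise FormatError(f"{where}: {exc}") from exc
            n = N_POINTS_24_2 if str(rec["pattern"]) == "24-2" else N_POINTS_30_2
            td_cols = _grid_cols("td", n)
            pd_cols = _grid_cols("pd", n)
            if not set(td_cols).issubset(df.columns):
                raise FormatError(f"{where}: missing td_1..td_{n} columns")
            if not set(pd_cols).issubset(df.columns):
                raise FormatError(f"{where}: missing pd_1..pd_{n} columns")
            td = _as_float_array(row[td_cols].to_numpy(dtype=float), n, "td")
            pd_ = _as_float_array(row[pd_cols].to_numpy(dtype=float), n, "pd")
            groups.setdefault((str(rec["eye_id"]), lat.value), []).append(
                _exam_from_fields(rec, td, pd_, lat, where)
            )
    else:
        raise FormatError(f"unknown format {fmt!r}")
    return _finalize_series(groups, subset=subset_to_24_2,
                            reliable_only=reliable_only)


def write_series(series: Sequence[EyeSeries], path: str | Path,
                 format: str | None = None) -> None:
    """Write eye series to CSV or JSON in the documented schema."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        payload = {"eyes": []}
        for s in series:
            exams = []
            for e in s.exams:
                exams.append({
                    "exam_date": e.exam_date.isoformat(),
                    "pattern": e.pattern.value,
                    "md": e.md, "psd": e.psd, "vfi": e.vfi,
                    "fp": e.fp, "fn": e.fn, "fl": e.fl,
                    "td": _maybe_mirror(e.td, s.laterality, e.pattern).tolist(),
                    "pd": _maybe_mirror(e.pd, s.laterality, e.pattern).tolist(),
                })
            payload["eyes"].append({
                "eye_id": s.eye_id, "laterality": s.laterality.value,
                "exams": exams,
            })
        with open(path, "w") as fh:
            json.dump(payload, fh)
    elif fmt == "csv":
        rows = []
        for s in series:
            for e in s.exams:
                n = len(e.td)
                td = _maybe_mirror(e.td, s.laterality, e.pattern)
                pd_ = _maybe_mirror(e.pd, s.laterality, e.pattern)
                row = {
                    "eye_id": s.eye_id, "laterality": s.laterality.value,
                    "exam_date": e.exam_date.isoformat(),
                    "pattern": e.pattern.value,
                    "md": e.md, "psd": e.psd, "vfi": e.vfi,
                    "fp": e.fp, "fn": e.fn, "fl": e.fl,
                }
                row.update(dict(zip(_grid_cols("td", n), td)))
                row.update(dict(zip(_grid_cols("pd", n), pd_)))
                rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise FormatError(f"unknown format {fmt!r}")


def export_grid_table(path: str | Path, grid: Sequence[GridPoint] = GRID_24_2) -> None:
    """Write the canonical grid as a CSV table (index, x_deg, y_deg, is_blind_spot)."""
    pd.DataFrame([dataclasses.asdict(p) for p in grid]).to_csv(path, index=False)
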