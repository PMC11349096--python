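"""Encode exam series into the fixed-shape masked input the network expects.

Each eye becomes an 80-row × 115-column matrix.  Data rows are ordered
newest-first; row 0 is the most recent exam and carries, in its interval
slot, the normalized distance to the *future* date being forecast — this is
how the desired horizon is communicated to the model.  Rows beyond the
available exams are all-zero and flagged invalid so the recurrent layers
skip them.

Per-row layout (115 values)::

    [interval, fp, fn, fl, md, psd, vfi, pd_1..pd_54, td_1..td_54]

Normalization: day gaps / 1000; reliability rates / 100; MD and PSD / 50;
VFI / 100; all pattern- and total-deviation values / 50.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass

import numpy as np

from .vf_datamodel import EyeSeries, FormatError, VFExam

__all__ = [
    "N_ROWS",
    "N_FEATURES",
    "N_TARGETS",
    "EncodedSequence",
    "InsufficientHistoryError",
    "InvalidHorizonError",
    "encode_exam_row",
    "encode_series",
    "encode_target",
    "decode_prediction",
    "enumerate_pairs",
]

logger = logging.getLogger(__name__)

N_ROWS = 80        # container rows (maximum exams per input)
N_FEATURES = 115   # per-row features: 1 interval + 3 reliability + 3 global + 54 PD + 54 TD
N_TARGETS = 57     # 54 TD + MD + PSD + VFI

DAYS_DIVISOR = 1000.0
RELIABILITY_DIVISOR = 100.0
MD_PSD_DIVISOR = 50.0
VFI_DIVISOR = 100.0
TD_PD_DIVISOR = 50.0

MIN_INPUT_EXAMS = 3


class InsufficientHistoryError(ValueError):
    """Fewer than three prior exams are available."""


class InvalidHorizonError(ValueError):
    """The prediction date does not lie strictly after the last exam."""


@dataclass
class EncodedSequence:
    """An 80×115 normalized input matrix with row-validity mask."""

    matrix: np.ndarray   # (80, 115) float
    mask: np.ndarray     # (80,) bool, True on data rows
    n_valid: int

    def __post_init__(self) -> None:
        if self.matrix.shape != (N_ROWS, N_FEATURES):
            raise FormatError(
                f"matrix must be {N_ROWS}x{N_FEATURES}, got {self.matrix.shape}"
            )
        if self.mask.shape != (N_ROWS,):
            raise FormatError(f"mask must have length {N_ROWS}")
        if not (MIN_INPUT_EXAMS <= self.n_valid <= N_ROWS):
            raise FormatError(f"n_valid out of range: {self.n_valid}")


def encode_exam_row(exam: VFExam, interval_days: float) -> np.ndarray:
    """Normalize one exam plus its forward time gap into a 115-vector."""
    row = np.empty(N_FEATURES)
    row[0] = interval_days / DAYS_DIVISOR
    row[1] = exam.fp / RELIABILITY_DIVISOR
    row[2] = exam.fn / RELIABILITY_DIVISOR
    row[3] = exam.fl / RELIABILITY_DIVISOR
    row[4] = exam.md / MD_PSD_DIVISOR
    row[5] = exam.psd / MD_PSD_DIVISOR
    row[6] = exam.vfi / VFI_DIVISOR
    row[7:61] = exam.pd / TD_PD_DIVISOR
    row[61:115] = exam.td / TD_PD_DIVISOR
    return row


def encode_series(series: EyeSeries, prediction_date: _dt.date) -> EncodedSequence:
    """Build the masked input matrix for one eye and one forecast date.

    Data rows are newest-first.  Row 0's interval is the gap from the most
    recent exam to ``prediction_date``; row i>0's interval is the gap from
    exam i to the chronologically next exam (which sits in row i−1).  Series
    longer than 80 exams are truncated to the 80 most recent (logged).
    """
    exams = list(series.exams)
    if len(exams) < MIN_INPUT_EXAMS:
        raise InsufficientHistoryError(
            f"eye {series.eye_id}: need >= {MIN_INPUT_EXAMS} exams, have {len(exams)}"
        )
    if prediction_date <= exams[-1].exam_date:
        raise InvalidHorizonError(
            f"eye {series.eye_id}: prediction date {prediction_date} is not "
            f"after the last exam ({exams[-1].exam_date})"
        )
    if len(exams) > N_ROWS:
        logger.warning("eye %s: %d exams, truncating to the most recent %d",
                       series.eye_id, len(exams), N_ROWS)
        exams = exams[-N_ROWS:]

    newest_first = exams[::-1]
    matrix = np.zeros((N_ROWS, N_FEATURES))
    next_date = prediction_date
    for i, exam in enumerate(newest_first):
        gap = (next_date - exam.exam_date).days
        matrix[i] = encode_exam_row(exam, gap)
        next_date = exam.exam_date
    n_valid = len(newest_first)
    mask = np.zeros(N_ROWS, dtype=bool)
    mask[:n_valid] = True
    # strict date ordering makes every data row's interval > 0, so no data
    # row can collide with the all-zero padding format; verify anyway.
    if np.any(~matrix[:n_valid].any(axis=1)):
        raise FormatError(f"eye {series.eye_id}: produced an all-zero data row")
    return EncodedSequence(matrix=matrix, mask=mask, n_valid=n_valid)


def encode_target(exam: VFExam) -> np.ndarray:
    """Normalize an exam into the 57-value regression target
    (54 TD, MD, PSD, VFI)."""
    t = np.empty(N_TARGETS)
    t[:54] = exam.td / TD_PD_DIVISOR
    t[54] = exam.md / MD_PSD_DIVISOR
    t[55] = exam.psd / MD_PSD_DIVISOR
    t[56] = exam.vfi / VFI_DIVISOR
    return t


def decode_prediction(v: np.ndarray) -> tuple[np.ndarray, float, float, float]:
    """Map a 57-value network output back to physical units.

    Returns ``(td_dB, md_dB, psd_dB, vfi_percent)``.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (N_TARGETS,):
        raise FormatError(f"prediction must have length {N_TARGETS}, got {v.shape}")
    td = v[:54] * TD_PD_DIVISOR
    md = float(v[54] * MD_PSD_DIVISOR)
    psd = float(v[55] * MD_PSD_DIVISOR)
    vfi = float(v[56] * VFI_DIVISOR)
    return td, md, psd, vfi


def enumerate_pairs(
    series_list: list[EyeSeries],
    strategy: str = "last",
) -> list[tuple[EyeSeries, EncodedSequence, np.ndarray, VFExam]]:
    """Enumerate (input window, target exam) training pairs.

    ``strategy='last'`` holds out each eye's final exam as the target
    (one pair per eye; requires >= 4 exams).  ``strategy='prefixes'`` emits
    every prefix of length >= 3 predicting the next exam.

    Returns tuples of (series, encoded input, encoded target, target exam).
    """
    if strategy not in ("last", "prefixes"):
        raise ValueError(f"unknown strategy {strategy!r}")
    pairs = []
    for s in series_list:
        n = len(s.exams)
        if n < MIN_INPUT_EXAMS + 1:
            continue
        stops = [n - 1] if strategy == "last" else range(MIN_INPUT_EXAMS, n)
        for stop in stops:
            target = s.exams[stop]
            window = EyeSeries(eye_id=s.eye_id, laterality=s.laterality,
                               exams=s.exams[:stop])
            enc = encode_series(window, target.exam_date)
            pairs.append((window, enc, encode_target(target), target))
    return pairs
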