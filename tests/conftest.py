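import datetime as dt

import numpy as np
import pytest

from vfforecast.synthetic_data import derive_indices
from vfforecast.vf_datamodel import (
    BLIND_SPOT_INDICES,
    EyeSeries,
    Laterality,
    VFExam,
)


def make_exam(exam_date, td=None, *, fp=5.0, fn=5.0, fl=5.0, rng=None):
    """Build a consistent 24-2 exam: indices derived from the TD field."""
    if td is None:
        td = (rng or np.random.default_rng(0)).normal(0.0, 2.0, size=54)
    td = np.asarray(td, dtype=float).copy()
    td[list(BLIND_SPOT_INDICES)] = 0.0
    md, psd, vfi, pd_ = derive_indices(td)
    return VFExam(exam_date=exam_date, td=td, pd=pd_, md=md, psd=psd,
                  vfi=vfi, fp=fp, fn=fn, fl=fl)


def make_series(n_exams=4, *, eye_id="eye_A", start=dt.date(2020, 1, 1),
                gap_days=200, td_fn=None, rng=None):
    """A series of ``n_exams`` spaced ``gap_days`` apart.

    ``td_fn(k)`` may supply the TD field of exam k."""
    rng = rng or np.random.default_rng(1)
    exams = []
    for k in range(n_exams):
        td = td_fn(k) if td_fn is not None else rng.normal(-2.0, 2.0, size=54)
        exams.append(make_exam(start + dt.timedelta(days=gap_days * k),
                               td=td, rng=rng))
    return EyeSeries(eye_id=eye_id, laterality=Laterality.OD, exams=exams)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_series():
    return make_series(4)
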