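"""Error metrics, stratification, statistical tests and trend baselines."""

import datetime as dt
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vfforecast.evaluation import (
    PredictionRecord,
    baseline_last_exam,
    baseline_pointwise_lr,
    compare_groups,
    global_abs_errors,
    stratify,
    tdv_mae,
    tdv_rmse,
)
from vfforecast.synthetic_data import derive_indices
from vfforecast.vf_datamodel import (
    BLIND_SPOT_INDICES,
    EyeSeries,
    FormatError,
    Laterality,
    Severity,
)

from conftest import make_exam, make_series

BS = list(BLIND_SPOT_INDICES)


def _record(true_td, pred_td, *, n_input=4, horizon=200, eye_id="e"):
    tmd, tpsd, tvfi, _ = derive_indices(true_td)
    pmd, ppsd, pvfi, _ = derive_indices(pred_td)
    return PredictionRecord(
        eye_id=eye_id, n_input_exams=n_input, horizon_days=horizon,
        true_td=true_td, pred_td=pred_td,
        true_md=tmd, pred_md=pmd, true_psd=tpsd, pred_psd=ppsd,
        true_vfi=tvfi, pred_vfi=pvfi)


def _field(rng, lo=-30, hi=5):
    td = rng.uniform(lo, hi, size=54)
    td[BS] = 0.0
    return td


class TestPointwiseMetrics:
    def test_identity_and_constant_offset(self):
        a = np.zeros(54)
        b = np.ones(54)
        b[BS] = 0.0  # offset applied at seeing points only would not be 1.0;
        # use the full 54-point constant-offset case instead:
        b = np.ones(54)
        assert tdv_rmse(a, a) == 0.0
        assert tdv_mae(a, a) == 0.0
        assert tdv_rmse(a, b) == pytest.approx(1.0)
        assert tdv_mae(a, b) == pytest.approx(1.0)

    def test_single_point_discrepancy(self):
        a = np.zeros(54)
        b = np.zeros(54)
        b[10] = 5.4
        assert tdv_rmse(a, b) == pytest.approx(np.sqrt(29.16 / 54))
        assert tdv_mae(a, b) == pytest.approx(5.4 / 54)

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(120):
            a, b = _field(rng), _field(rng)
            rmse_brute = float(np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)) / 54))
            mae_brute = float(sum(abs(x - y) for x, y in zip(a, b)) / 54)
            assert tdv_rmse(a, b) == pytest.approx(rmse_brute, rel=1e-12)
            assert tdv_mae(a, b) == pytest.approx(mae_brute, rel=1e-12)
            assert tdv_mae(a, b) <= tdv_rmse(a, b) + 1e-12

    @given(st.integers(0, 2**31 - 1), st.floats(-10, 10))
    @settings(max_examples=60, deadline=None)
    def test_symmetry_and_translation_invariance(self, seed, c):
        r = np.random.default_rng(seed)
        a, b = r.normal(size=54), r.normal(size=54)
        assert tdv_rmse(a, b) == pytest.approx(tdv_rmse(b, a))
        assert tdv_mae(a, b) == pytest.approx(tdv_mae(b, a))
        assert tdv_rmse(a + c, b + c) == pytest.approx(tdv_rmse(a, b), abs=1e-9)
        assert tdv_mae(a + c, b + c) == pytest.approx(tdv_mae(a, b), abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(FormatError):
            tdv_rmse(np.zeros(54), np.zeros(52))

    def test_52_point_variant_drops_blind_spot(self):
        a = np.zeros(54)
        b = np.zeros(54)
        b[BS[0]] = 3.0  # a discrepancy only at the blind spot
        assert tdv_mae(a, b) > 0
        assert tdv_mae(a, b, exclude_blind_spot=True) == 0.0


class TestGlobalErrors:
    def test_absolute_differences(self):
        r = _record(np.zeros(54), np.zeros(54))
        r.true_md, r.pred_md = -5.0, -6.0
        r.true_vfi, r.pred_vfi = 90.0, 85.5
        md_e, psd_e, vfi_e = global_abs_errors(r)
        assert md_e == pytest.approx(1.0)
        assert vfi_e == pytest.approx(4.5)
        identical = _record(np.zeros(54), np.zeros(54))
        assert global_abs_errors(identical) == (0.0, 0.0, 0.0)


class TestStratify:
    def test_single_input_count_bin(self, rng):
        records = [_record(_field(rng), _field(rng), n_input=4,
                           eye_id=f"e{i}") for i in range(6)]
        summary = stratify(records, "input_count")
        assert summary.table.loc["3~5", "n"] == 6
        assert summary.table.loc["6~10", "n"] == 0
        assert np.isnan(summary.p_values["tdv_mae"])  # single populated bin

    def test_horizon_month_convention(self, rng):
        # 200 days / 30.44 = 6.57 months -> the 6-12 month bin
        records = [_record(_field(rng), _field(rng), horizon=200,
                           eye_id=f"e{i}") for i in range(4)]
        summary = stratify(records, "horizon")
        assert summary.table.loc["6~12", "n"] == 4

    def test_partition_counts_conserved(self, rng):
        records = []
        for i in range(30):
            records.append(_record(_field(rng), _field(rng),
                                   n_input=int(rng.integers(3, 25)),
                                   horizon=int(rng.integers(40, 900)),
                                   eye_id=f"e{i}"))
        for scheme in ("severity", "input_count", "horizon"):
            summary = stratify(records, scheme)
            assert int(summary.table["n"].sum()) == len(records)

    def test_severity_uses_true_target_md(self):
        deep = np.full(54, -15.0)
        deep[BS] = 0.0
        r = _record(deep, np.zeros(54))
        assert r.severity is Severity.ADVANCED


def _brute_force_u(x, y):
    """U statistic of x: pairwise wins + half-ties."""
    return sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)


def _brute_force_h(groups):
    pooled = np.concatenate(groups)
    order = np.argsort(pooled)
    ranks = np.empty(len(pooled))
    # midranks
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    n = len(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    return h / tie if tie > 0 else 0.0


def _exact_mwu_p(x, y):
    """Two-sided exact permutation p for tie-free samples."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = _brute_force_u(x, y)
    us = [
        _brute_force_u(pooled[list(c)],
                       pooled[[i for i in range(len(pooled)) if i not in c]])
        for c in itertools.combinations(range(len(pooled)), n1)
    ]
    us = np.array(us)
    p = 2 * min((us <= u_obs + 1e-9).mean(), (us >= u_obs - 1e-9).mean())
    return min(1.0, p)


def _exact_kw_p(groups):
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    h_obs = _brute_force_h(groups)
    n = len(pooled)
    hits = total = 0
    for c1 in itertools.combinations(range(n), sizes[0]):
        rest1 = [i for i in range(n) if i not in c1]
        for c2 in itertools.combinations(rest1, sizes[1]):
            rest2 = [i for i in rest1 if i not in c2]
            gs = [pooled[list(c1)], pooled[list(c2)], pooled[rest2]]
            total += 1
            if _brute_force_h(gs) >= h_obs - 1e-12:
                hits += 1
    return hits / total


class TestCompareGroups:
    def test_identical_groups_no_shift(self):
        g = np.array([1.0, 2.0, 3.0])
        stat, p = compare_groups([g, g.copy()], "mann_whitney")
        assert p == pytest.approx(1.0, abs=0.01)
        h, pk = compare_groups([g, g.copy(), g.copy()], "kruskal_wallis")
        assert h == pytest.approx(0.0, abs=1e-9)
        assert pk == pytest.approx(1.0)

    def test_complete_separation_exact_p(self):
        stat, p = compare_groups([np.array([1.0, 2, 3]),
                                  np.array([101.0, 102, 103])], "mann_whitney")
        assert stat == 0.0
        assert p == pytest.approx(2 / 20)  # 2 / C(6,3)

    @pytest.mark.parametrize("n1,n2,seed", [(3, 3, 0), (4, 5, 1), (5, 5, 2), (3, 5, 3)])
    def test_mann_whitney_matches_exact_enumeration(self, n1, n2, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=n1)
        y = r.normal(loc=0.8, size=n2)
        stat, p = compare_groups([x, y], "mann_whitney")
        # statistic: independent pairwise-count oracle (U of the first group)
        assert stat == pytest.approx(_brute_force_u(x, y))
        assert p == pytest.approx(_exact_mwu_p(x, y), abs=1e-9)

    @pytest.mark.parametrize("sizes,seed", [((3, 3, 3), 0), ((4, 4, 4), 1),
                                            ((3, 4, 5), 2)])
    def test_kruskal_wallis_matches_exact_enumeration(self, sizes, seed):
        r = np.random.default_rng(seed)
        groups = [r.normal(loc=k * 0.7, size=n) for k, n in enumerate(sizes)]
        h, p = compare_groups(groups, "kruskal_wallis")
        assert h == pytest.approx(_brute_force_h(groups), abs=1e-9)
        assert p == pytest.approx(_exact_kw_p(groups), abs=1e-9)

    def test_shapiro_gate_recommendation(self, rng):
        normals = [rng.normal(size=30) for _ in range(2)]
        ps, rec = compare_groups(normals, "shapiro_gate")
        assert rec == "parametric"
        skewed = [np.exp(rng.normal(size=40) * 2) for _ in range(2)]
        _, rec2 = compare_groups(skewed, "shapiro_gate")
        assert rec2 == "nonparametric"

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([np.array([1.0, 2]), np.array([3.0, 4, 5])],
                           "mann_whitney")
        with pytest.raises(ValueError):
            compare_groups([np.array([1.0, 2, 3])], "kruskal_wallis")


class TestBaselines:
    def test_lr_exact_on_noise_free_linear_series(self):
        slope_per_day = -1.0 / 365.0
        base = np.linspace(-20, 2, 54)
        base[BS] = 0.0

        def td_at(k):
            td = base + slope_per_day * 180 * k
            td[BS] = 0.0
            return td

        series = make_series(4, gap_days=180, td_fn=td_at)
        target_date = series.exams[-1].exam_date + dt.timedelta(days=365)
        td, md, psd, vfi, pd_ = baseline_pointwise_lr(series, target_date)
        days_from_start = (target_date - series.exams[0].exam_date).days
        expected = base + slope_per_day * days_from_start
        expected[BS] = 0.0
        np.testing.assert_allclose(td, np.clip(expected, -38, 6), atol=1e-8)

    def test_constant_series_predicts_the_constant(self):
        const = np.full(54, -4.0)
        const[BS] = 0.0
        series = make_series(3, td_fn=lambda k: const)
        td, *_ = baseline_pointwise_lr(
            series, series.exams[-1].exam_date + dt.timedelta(days=100))
        np.testing.assert_allclose(td, const, atol=1e-9)

    def test_needs_three_exams(self):
        series = make_series(2)
        with pytest.raises(ValueError):
            baseline_pointwise_lr(series, dt.date(2030, 1, 1))

    def test_last_exam_carried_forward(self):
        series = make_series(4)
        td, md, psd, vfi, pd_ = baseline_last_exam(series)
        np.testing.assert_array_equal(td, series.exams[-1].td)
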