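"""Accuracy metrics, stratified error tables, statistical comparisons, and
trend-extrapolation baselines for visual-field forecasts.

Per-eye metrics are the point-wise total-deviation RMSE and MAE over all 54
grid positions (the two blind-spot entries are zero in both truth and
prediction, so they enter the denominators but not the numerators; a
52-point variant that drops them is available), plus absolute errors of the
global indices MD, PSD and VFI.  Cohorts are stratified by glaucoma
severity, number of input exams (3–5, 6–10, 11–15, >15) and forecast
horizon in months (<6, 6–12, 12–24, >=24; 1 month = 30.44 days), and
strata are compared with Kruskal-Wallis / Mann-Whitney (default) or
one-way ANOVA.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import TD_MAX, TD_MIN, derive_indices
from .vf_datamodel import (
    BLIND_SPOT_INDICES,
    N_POINTS_24_2,
    SEEING_INDICES,
    EyeSeries,
    FormatError,
    Severity,
    classify_severity,
)

__all__ = [
    "PredictionRecord",
    "ErrorSummary",
    "tdv_rmse",
    "tdv_mae",
    "global_abs_errors",
    "record_metrics",
    "stratify",
    "stratify_metrics",
    "compare_groups",
    "baseline_pointwise_lr",
    "baseline_last_exam",
]

DAYS_PER_MONTH = 30.44

INPUT_COUNT_BINS = ("3~5", "6~10", "11~15", ">15")
HORIZON_BINS = ("<6", "6~12", "12~24", ">=24")
SEVERITY_BINS = tuple(s.value for s in Severity)

METRICS = ("md_error", "psd_error", "vfi_error", "tdv_mae", "tdv_rmse")

_SEE = np.array(SEEING_INDICES)


def _check_pair(true_td: np.ndarray, pred_td: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    true_td = np.asarray(true_td, dtype=float)
    pred_td = np.asarray(pred_td, dtype=float)
    if true_td.shape != (N_POINTS_24_2,) or pred_td.shape != (N_POINTS_24_2,):
        raise FormatError(
            f"td arrays must have length {N_POINTS_24_2}, got "
            f"{true_td.shape} and {pred_td.shape}")
    return true_td, pred_td


def tdv_rmse(true_td: np.ndarray, pred_td: np.ndarray, *,
             exclude_blind_spot: bool = False) -> float:
    """Root mean square error of the 54 total-deviation values (dB)."""
    true_td, pred_td = _check_pair(true_td, pred_td)
    d = true_td - pred_td
    if exclude_blind_spot:
        d = d[_SEE]
    return float(np.sqrt(np.mean(d * d)))


def tdv_mae(true_td: np.ndarray, pred_td: np.ndarray, *,
            exclude_blind_spot: bool = False) -> float:
    """Mean absolute error of the 54 total-deviation values (dB)."""
    true_td, pred_td = _check_pair(true_td, pred_td)
    d = np.abs(true_td - pred_td)
    if exclude_blind_spot:
        d = d[_SEE]
    return float(np.mean(d))


@dataclass
class PredictionRecord:
    """One eye's forecast next to its ground truth, with strata labels."""

    eye_id: str
    n_input_exams: int
    horizon_days: int
    true_td: np.ndarray
    pred_td: np.ndarray
    true_md: float
    pred_md: float
    true_psd: float
    pred_psd: float
    true_vfi: float
    pred_vfi: float
    severity: Severity = field(init=False)

    def __post_init__(self) -> None:
        if self.horizon_days <= 0:
            raise ValueError("horizon_days must be > 0")
        if self.n_input_exams < 3:
            raise ValueError("n_input_exams must be >= 3")
        self.true_td, self.pred_td = _check_pair(self.true_td, self.pred_td)
        # stage from the prediction-target exam's true MD
        self.severity = classify_severity(self.true_md)


def global_abs_errors(record: PredictionRecord) -> tuple[float, float, float]:
    """Absolute errors of (MD dB, PSD dB, VFI %)."""
    return (abs(record.true_md - record.pred_md),
            abs(record.true_psd - record.pred_psd),
            abs(record.true_vfi - record.pred_vfi))


def record_metrics(records: list[PredictionRecord], *,
                   exclude_blind_spot: bool = False) -> pd.DataFrame:
    """Per-eye metric table: one row per record, all five error metrics."""
    rows = []
    for r in records:
        md_e, psd_e, vfi_e = global_abs_errors(r)
        rows.append({
            "eye_id": r.eye_id,
            "severity": r.severity.value,
            "n_input_exams": r.n_input_exams,
            "horizon_days": r.horizon_days,
            "md_error": md_e,
            "psd_error": psd_e,
            "vfi_error": vfi_e,
            "tdv_mae": tdv_mae(r.true_td, r.pred_td,
                               exclude_blind_spot=exclude_blind_spot),
            "tdv_rmse": tdv_rmse(r.true_td, r.pred_td,
                                 exclude_blind_spot=exclude_blind_spot),
        })
    return pd.DataFrame(rows)


_SCHEME_BINS = {
    "severity": SEVERITY_BINS,
    "input_count": INPUT_COUNT_BINS,
    "horizon": HORIZON_BINS,
}


@dataclass
class ErrorSummary:
    """Stratified error table for one stratification scheme."""

    scheme: str
    table: pd.DataFrame        # index: stratum; columns: n and mean/sd per metric
    p_values: dict[str, float] # omnibus p per metric (NaN if < 2 populated strata)
    omnibus_test: str
    per_stratum_values: dict[str, dict[str, np.ndarray]]

    def to_text(self) -> str:
        lines = [f"Prediction errors by {self.scheme} "
                 f"(omnibus: {self.omnibus_test})"]
        header = ["stratum", "n"] + [m for m in METRICS]
        rows = [header]
        for stratum in self.table.index:
            row = [str(stratum), str(int(self.table.loc[stratum, "n"]))]
            for m in METRICS:
                mean = self.table.loc[stratum, f"{m}_mean"]
                sd = self.table.loc[stratum, f"{m}_sd"]
                row.append("-" if math.isnan(mean) else f"{mean:.2f} +/- {sd:.2f}")
            rows.append(row)
        prow = ["P value", ""]
        for m in METRICS:
            p = self.p_values.get(m, float("nan"))
            prow.append("n/a" if math.isnan(p) else f"{p:.3g}")
        rows.append(prow)
        widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
        for r in rows:
            lines.append("  ".join(s.ljust(w) for s, w in zip(r, widths)))
        return "\n".join(lines)


def _label_from_row(row: pd.Series, scheme: str) -> str:
    if scheme == "severity":
        return str(row["severity"])
    if scheme == "input_count":
        n = int(row["n_input_exams"])
        return "3~5" if n <= 5 else "6~10" if n <= 10 else "11~15" if n <= 15 else ">15"
    if scheme == "horizon":
        months = float(row["horizon_days"]) / DAYS_PER_MONTH
        return "<6" if months < 6 else "6~12" if months < 12 else "12~24" if months < 24 else ">=24"
    raise ValueError(f"unknown stratification scheme {scheme!r}")


def stratify_metrics(metrics_df: pd.DataFrame, scheme: str, *,
                     omnibus: str = "kruskal_wallis") -> ErrorSummary:
    """Stratified mean ± SD error table from a per-eye metric table
    (as produced by :func:`record_metrics`)."""
    if metrics_df.empty:
        raise ValueError("no prediction records to stratify")
    bins = _SCHEME_BINS[scheme]
    metrics_df = metrics_df.copy()
    metrics_df["stratum"] = [
        _label_from_row(row, scheme) for _, row in metrics_df.iterrows()
    ]
    rows = []
    per_stratum: dict[str, dict[str, np.ndarray]] = {}
    for b in bins:
        sub = metrics_df[metrics_df["stratum"] == b]
        row: dict[str, float] = {"n": len(sub)}
        per_stratum[b] = {}
        for m in METRICS:
            vals = sub[m].to_numpy()
            per_stratum[b][m] = vals
            row[f"{m}_mean"] = float(np.mean(vals)) if len(vals) else float("nan")
            row[f"{m}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
        rows.append(row)
    table = pd.DataFrame(rows, index=list(bins))
    assert int(table["n"].sum()) == len(metrics_df)

    p_values: dict[str, float] = {}
    for m in METRICS:
        groups = [per_stratum[b][m] for b in bins if len(per_stratum[b][m]) >= 3]
        if len(groups) >= 2:
            try:
                _, p = compare_groups(groups, method=omnibus)
            except ValueError:
                p = float("nan")
        else:
            p = float("nan")
        p_values[m] = p
    return ErrorSummary(scheme=scheme, table=table, p_values=p_values,
                        omnibus_test=omnibus, per_stratum_values=per_stratum)


def stratify(records: list[PredictionRecord], scheme: str, *,
             omnibus: str = "kruskal_wallis",
             exclude_blind_spot: bool = False) -> ErrorSummary:
    """Stratified mean ± SD error table with an omnibus group comparison.

    Empty strata are reported with n=0 and no statistics.  The omnibus test
    (default Kruskal-Wallis; one-way ANOVA available) runs per metric over
    the populated strata; it needs at least two populated strata with >= 3
    observations each, otherwise p is NaN.
    """
    if not records:
        raise ValueError("no prediction records to stratify")
    metrics_df = record_metrics(records, exclude_blind_spot=exclude_blind_spot)
    return stratify_metrics(metrics_df, scheme, omnibus=omnibus)


_KW_EXACT_MAX_N = 12


def _kw_exact_p(groups: list[np.ndarray], h_obs: float) -> float:
    """Exact permutation tail P(H >= h_obs) for the Kruskal-Wallis statistic,
    enumerating every assignment of the pooled observations to groups."""
    import itertools

    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    sizes = [len(g) for g in groups]
    # tie correction factor, constant across permutations of the same pool
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)

    def h_of(assign_ranks: list[np.ndarray]) -> float:
        s = sum(np.sum(r) ** 2 / len(r) for r in assign_ranks)
        h = 12.0 / (n * (n + 1)) * s - 3.0 * (n + 1)
        return h / tie if tie > 0 else 0.0

    hits = total = 0
    idx_all = frozenset(range(n))

    def rec(remaining: frozenset, k: int, chosen: list[np.ndarray]) -> None:
        nonlocal hits, total
        if k == len(sizes) - 1:
            chosen = chosen + [ranks[sorted(remaining)]]
            total += 1
            if h_of(chosen) >= h_obs - 1e-12:
                hits += 1
            return
        for combo in itertools.combinations(sorted(remaining), sizes[k]):
            rec(remaining - set(combo), k + 1, chosen + [ranks[list(combo)]])

    rec(idx_all, 0, [])
    return hits / total


def compare_groups(groups: list[np.ndarray], method: str = "kruskal_wallis"):
    """Group-location comparison.

    ``kruskal_wallis`` / ``anova`` are omnibus tests over >= 2 groups;
    ``mann_whitney`` requires exactly 2.  ``shapiro_gate`` runs Shapiro-Wilk
    normality per group and returns (per-group p-values, recommendation),
    recommending the parametric route only when every group looks normal at
    the 0.05 level.  Other methods return ``(statistic, p_value)``.

    Small-sample p-values: Mann-Whitney uses the exact null distribution for
    tie-free samples up to size 8 and the tie-corrected normal approximation
    otherwise; Kruskal-Wallis uses the exact permutation distribution when
    the pooled sample has at most 12 observations (the chi-square
    approximation is unreliable there) and the chi-square tail otherwise.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if method != "mann_whitney" and len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 3 for g in groups):
        raise ValueError("each group needs at least 3 observations")
    if method == "kruskal_wallis":
        if np.ptp(np.concatenate(groups)) == 0:
            return 0.0, 1.0  # all observations identical: no evidence of shift
        res = stats.kruskal(*groups)
        h = float(res.statistic)
        if sum(len(g) for g in groups) <= _KW_EXACT_MAX_N:
            return h, float(_kw_exact_p(groups, h))
        return h, float(res.pvalue)
    if method == "anova":
        res = stats.f_oneway(*groups)
        return float(res.statistic), float(res.pvalue)
    if method == "mann_whitney":
        if len(groups) != 2:
            raise ValueError("mann_whitney compares exactly 2 groups")
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided",
                                 method="auto")
        return float(res.statistic), float(res.pvalue)
    if method == "shapiro_gate":
        ps = {i: float(stats.shapiro(g).pvalue) for i, g in enumerate(groups)}
        recommendation = ("parametric" if all(p >= 0.05 for p in ps.values())
                          else "nonparametric")
        return ps, recommendation
    raise ValueError(f"unknown method {method!r}")


# --------------------------------------------------------------------------
# Baselines
# --------------------------------------------------------------------------

def baseline_pointwise_lr(series: EyeSeries, prediction_date: _dt.date
                          ) -> tuple[np.ndarray, float, float, float, np.ndarray]:
    """Point-wise ordinary-least-squares trend extrapolation.

    Fits TD vs. time independently at each seeing point over the whole
    series, extrapolates to ``prediction_date``, clamps to the instrument
    range, zeroes the blind spot, and derives global indices with the
    simulator's surrogate conventions.

    Returns ``(td, md, psd, vfi, pd)``.
    """
    if len(series.exams) < 3:
        raise ValueError("pointwise LR needs at least 3 exams")
    t0 = series.exams[0].exam_date
    t = np.array([(e.exam_date - t0).days for e in series.exams], dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("degenerate time spread: all exams on the same date")
    Y = np.stack([e.td for e in series.exams])          # (n, 54)
    tbar = t.mean()
    denom = float(np.sum((t - tbar) ** 2))
    slope = (t - tbar) @ (Y - Y.mean(axis=0)) / denom   # (54,)
    intercept = Y.mean(axis=0) - slope * tbar
    tp = float((prediction_date - t0).days)
    td = np.clip(intercept + slope * tp, TD_MIN, TD_MAX)
    td[list(BLIND_SPOT_INDICES)] = 0.0
    md, psd, vfi, pd_ = derive_indices(td)
    return td, md, psd, vfi, pd_


def baseline_last_exam(series: EyeSeries
                       ) -> tuple[np.ndarray, float, float, float, np.ndarray]:
    """Last-observation-carried-forward: the most recent exam's field is the
    forecast, whatever the horizon.  Returns ``(td, md, psd, vfi, pd)``."""
    last = series.exams[-1]
    td = last.td.copy()
    md, psd, vfi, pd_ = derive_indices(td)
    return td, md, psd, vfi, pd_
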