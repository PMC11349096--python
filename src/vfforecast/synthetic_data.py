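"""Seedable simulator of longitudinal glaucomatous visual-field cohorts.

Stands in for a clinical perimetry archive: each simulated eye draws a
defect archetype (normal, superior/inferior arcuate, diffuse depression,
advanced tunnel field), a baseline total-deviation field, per-point linear
progression rates, and an irregular visit calendar; observed fields add
test–retest noise whose standard deviation grows with defect depth, the
dominant variability pattern in perimetry.

Global indices (MD, PSD, VFI) and pattern deviation use documented
surrogate conventions (see :func:`derive_indices`), not Humphrey's
proprietary eccentricity-weighted formulas: the forecasting network treats
them as opaque features, so only internal consistency matters.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .vf_datamodel import (
    BLIND_SPOT_INDICES,
    GRID_24_2,
    N_POINTS_24_2,
    SEEING_INDICES,
    EyeSeries,
    FormatError,
    Laterality,
    VFExam,
    write_series,
)

__all__ = [
    "ARCHETYPES",
    "SimConfig",
    "GroundTruth",
    "derive_indices",
    "simulate_eye",
    "simulate_cohort",
    "write_cohort",
]

# Instrument dynamic range for total deviation (dB).
TD_MIN, TD_MAX = -38.0, 6.0

ARCHETYPES = ("normal", "superior_arcuate", "inferior_arcuate",
              "diffuse", "advanced_tunnel")

_X = np.array([p.x_deg for p in GRID_24_2], dtype=float)
_Y = np.array([p.y_deg for p in GRID_24_2], dtype=float)
_ECC = np.hypot(_X, _Y)
_BS = np.array(BLIND_SPOT_INDICES)
_SEE = np.array(SEEING_INDICES)


def _archetype_weights(name: str) -> np.ndarray:
    """Unit spatial profile of the defect (0 = spared, larger = deeper)."""
    w = np.zeros(N_POINTS_24_2)
    if name == "normal":
        pass
    elif name == "superior_arcuate":
        sup = _Y > 0
        w[sup] = np.exp(-((_ECC[sup] - 15.0) / 8.0) ** 2)
    elif name == "inferior_arcuate":
        inf = _Y < 0
        w[inf] = np.exp(-((_ECC[inf] - 15.0) / 8.0) ** 2)
    elif name == "diffuse":
        w[:] = 1.0
    elif name == "advanced_tunnel":
        # deep peripheral loss with relative central sparing
        w[:] = np.where(_ECC > 10.0, 1.0, 0.3)
    else:
        raise ValueError(f"unknown archetype {name!r}")
    w[_BS] = 0.0
    return w


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults emulate a tertiary glaucoma-clinic population: early-stage
    majority, 4–9 visits per eye (so 3–8 input exams once the last visit is
    held out as the forecast target), visit spacing of 3–12 months and a
    forecast horizon averaging ~8 months.
    """

    n_eyes: int = 100
    archetype_weights: dict[str, float] = field(default_factory=lambda: {
        "normal": 0.30,
        "superior_arcuate": 0.20,
        "inferior_arcuate": 0.20,
        "diffuse": 0.15,
        "advanced_tunnel": 0.15,
    })
    # target baseline MD interval (dB) per archetype
    baseline_md_range: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "normal": (-1.5, 0.5),
        "superior_arcuate": (-7.0, -1.0),
        "inferior_arcuate": (-7.0, -1.0),
        "diffuse": (-11.0, -5.0),
        "advanced_tunnel": (-24.0, -13.0),
    })
    progression_rate_mean: float = -0.6   # dB/year per affected point
    progression_rate_sd: float = 0.4
    noise_floor_sd: float = 1.0           # test-retest SD at TD = 0 (dB)
    noise_slope: float = 0.15             # extra SD per dB of defect depth
    noise_sd_cap: float = 6.0
    visits_min: int = 4
    visits_max: int = 9
    interval_days_min: int = 90
    interval_days_max: int = 365
    horizon_days_min: int = 60
    horizon_days_max: int = 420
    start_date: _dt.date = _dt.date(2015, 1, 6)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.start_date, str):
            self.start_date = _dt.date.fromisoformat(self.start_date)
        self.validate()

    def validate(self) -> None:
        if self.n_eyes < 0:
            raise ValueError("n_eyes must be >= 0")
        unknown = set(self.archetype_weights) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes {sorted(unknown)}")
        total = sum(self.archetype_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype weights must sum to 1, got {total}")
        if any(w < 0 for w in self.archetype_weights.values()):
            raise ValueError("archetype weights must be non-negative")
        if self.visits_min < 3:
            raise ValueError("visits_min must be >= 3")
        if self.visits_max > 80:
            raise ValueError("visits_max must be <= 80")
        if self.visits_min > self.visits_max:
            raise ValueError("visits_min must be <= visits_max")
        for name in ("progression_rate_sd", "noise_floor_sd",
                     "noise_slope", "noise_sd_cap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for lo, hi in (("interval_days_min", "interval_days_max"),
                       ("horizon_days_min", "horizon_days_max")):
            if getattr(self, lo) < 1 or getattr(self, lo) > getattr(self, hi):
                raise ValueError(f"require 1 <= {lo} <= {hi}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["start_date"] = self.start_date.isoformat()
        d["baseline_md_range"] = {k: list(v) for k, v in self.baseline_md_range.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "baseline_md_range" in d:
            d["baseline_md_range"] = {
                k: tuple(v) for k, v in d["baseline_md_range"].items()
            }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class GroundTruth:
    """Noise-free generative state of one simulated eye."""

    eye_id: str
    archetype: str
    baseline_td: np.ndarray          # (54,) dB at the first visit
    rates: np.ndarray                # (54,) dB/year
    visit_days: np.ndarray           # (n_visits,) days since first visit
    true_td: np.ndarray              # (n_visits, 54) dB, clamped, noise-free

    def to_dict(self) -> dict:
        return {
            "eye_id": self.eye_id,
            "archetype": self.archetype,
            "baseline_td": self.baseline_td.tolist(),
            "rates": self.rates.tolist(),
            "visit_days": self.visit_days.tolist(),
            "true_td": self.true_td.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            eye_id=d["eye_id"], archetype=d["archetype"],
            baseline_td=np.asarray(d["baseline_td"], dtype=float),
            rates=np.asarray(d["rates"], dtype=float),
            visit_days=np.asarray(d["visit_days"], dtype=int),
            true_td=np.asarray(d["true_td"], dtype=float),
        )


def derive_indices(td: Sequence[float] | np.ndarray) -> tuple[float, float, float, np.ndarray]:
    """Surrogate global indices and pattern deviation from a 54-point TD field.

    Over the 52 seeing (non-blind-spot) points:

    * ``md``  — unweighted mean of TD
    * ``GH``  — general height, the 7th largest TD
    * ``pd``  — TD − GH (blind-spot entries 0)
    * ``psd`` — population SD of TD about ``md``
    * ``vfi`` — ``clamp(100 × (1 + md/30), 0, 100)``

    These are deliberately simple stand-ins for the instrument's proprietary
    eccentricity-weighted definitions; they preserve the qualitative
    behaviour (md tracks overall depression, psd tracks localisation, vfi
    decreases with damage) that downstream models rely on.

    Returns ``(md, psd, vfi, pd)``.
    """
    td = np.asarray(td, dtype=float)
    if td.shape != (N_POINTS_24_2,):
        raise FormatError(f"td must have length {N_POINTS_24_2}, got {td.shape}")
    see = td[_SEE]
    md = float(np.mean(see))
    gh = float(np.sort(see)[-7])  # 7th largest
    pd_ = td - gh
    pd_[_BS] = 0.0
    psd = float(np.sqrt(np.mean((see - md) ** 2)))
    vfi = float(np.clip(100.0 * (1.0 + md / 30.0), 0.0, 100.0))
    return md, psd, vfi, pd_


def _sample_baseline(archetype: str, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    w = _archetype_weights(archetype)
    lo, hi = cfg.baseline_md_range[archetype]
    md_target = rng.uniform(lo, hi)
    if archetype == "normal" or not np.any(w[_SEE] > 0):
        base = np.full(N_POINTS_24_2, md_target)
    else:
        # scale the unit profile so the seeing-point mean equals md_target
        base = md_target * w / np.mean(w[_SEE])
    base = base + rng.normal(0.0, 0.8, size=N_POINTS_24_2)
    base = np.clip(base, TD_MIN, TD_MAX)
    base[_BS] = 0.0
    return base


def _noise_sd(true_td: np.ndarray, cfg: SimConfig) -> np.ndarray:
    depth = np.maximum(0.0, -true_td)
    return np.minimum(cfg.noise_floor_sd + cfg.noise_slope * depth, cfg.noise_sd_cap)


def simulate_eye(cfg: SimConfig, rng: np.random.Generator,
                 eye_id: str = "eye_0") -> tuple[EyeSeries, GroundTruth]:
    """Simulate one eye: archetype, linear per-point progression, irregular
    visit calendar, depth-dependent Gaussian test–retest noise.

    The final visit is spaced by a draw from the horizon range (it is the
    natural forecast target); earlier visits by draws from the interval
    range.  Observed TD is clamped to the instrument range [−38, +6] dB;
    blind-spot points are fixed at 0; reliability rates are uniform on
    [0, 33) so every simulated exam passes the reliability screen.
    """
    names = sorted(cfg.archetype_weights)
    probs = np.array([cfg.archetype_weights[n] for n in names])
    archetype = names[rng.choice(len(names), p=probs / probs.sum())]

    baseline = _sample_baseline(archetype, cfg, rng)
    w = _archetype_weights(archetype)
    rates = np.where(w > 0.05, w * rng.normal(cfg.progression_rate_mean,
                                              cfg.progression_rate_sd,
                                              size=N_POINTS_24_2), 0.0)
    rates[_BS] = 0.0

    n_visits = int(rng.integers(cfg.visits_min, cfg.visits_max + 1))
    gaps = rng.integers(cfg.interval_days_min, cfg.interval_days_max + 1,
                        size=n_visits - 1)
    gaps[-1] = rng.integers(cfg.horizon_days_min, cfg.horizon_days_max + 1)
    visit_days = np.concatenate([[0], np.cumsum(gaps)]).astype(int)

    years = visit_days / 365.25
    true_td = baseline[None, :] + rates[None, :] * years[:, None]
    true_td = np.clip(true_td, TD_MIN, TD_MAX)
    true_td[:, _BS] = 0.0

    sd = _noise_sd(true_td, cfg)
    observed = true_td + rng.normal(0.0, 1.0, size=true_td.shape) * sd
    observed = np.clip(observed, TD_MIN, TD_MAX)
    observed[:, _BS] = 0.0

    laterality = Laterality.OD if rng.random() < 0.5 else Laterality.OS
    exams = []
    for k in range(n_visits):
        md, psd, vfi, pd_ = derive_indices(observed[k])
        fp, fn, fl = rng.uniform(0.0, 33.0, size=3)
        exams.append(VFExam(
            exam_date=cfg.start_date + _dt.timedelta(days=int(visit_days[k])),
            td=observed[k], pd=pd_, md=md, psd=psd, vfi=vfi,
            fp=float(fp), fn=float(fn), fl=float(fl),
        ))
    series = EyeSeries(eye_id=eye_id, laterality=laterality, exams=exams)
    truth = GroundTruth(eye_id=eye_id, archetype=archetype,
                        baseline_td=baseline, rates=rates,
                        visit_days=visit_days, true_td=true_td)
    return series, truth


def simulate_cohort(cfg: SimConfig) -> list[tuple[EyeSeries, GroundTruth]]:
    """Simulate ``cfg.n_eyes`` independent eyes; deterministic given ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    width = max(4, len(str(max(cfg.n_eyes, 1))))
    return [
        simulate_eye(cfg, rng, eye_id=f"eye_{i:0{width}d}")
        for i in range(cfg.n_eyes)
    ]


def write_cohort(cohort: Sequence[tuple[EyeSeries, GroundTruth]],
                 out_dir: str | Path, format: str = "csv") -> dict[str, Path]:
    """Write a cohort as series file + ground-truth sidecar JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series_path = out_dir / ("cohort.json" if format == "json" else "cohort.csv")
    write_series([s for s, _ in cohort], series_path, format=format)
    truth_path = out_dir / "ground_truth.json"
    with open(truth_path, "w") as fh:
        json.dump({"eyes": [t.to_dict() for _, t in cohort]}, fh)
    return {"series": series_path, "ground_truth": truth_path}
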