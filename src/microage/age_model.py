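"""Microbiota-age prediction from phase attributions.

The predicted age is the midpoint formula

    y_age = a_MR x_MR + a_MA x_MA + a_MD x_MD + a_OD x_OD + a_VO x_VO

with a the life-phase midpoints in weeks (MR 10.5, MA 19.5, MD 51.5,
OD 93, VO 110) and x the attributed phase proportions.  By default the
proportions are renormalized by (1 - unknown) before the weighted sum,
so predictions stay within [10.5, 110]; the raw mode reproduces literal
term-by-term summation.  Sinks whose "unknown" attribution exceeds the
uncertainty threshold (default 30%, strict inequality: exactly 0.30 is
retained) are flagged out of the evaluation.  Batch calibration appends
pooled control samples from a new batch as extra source rows labelled
with their life phase; their attributed mass folds back onto the phase
before the weighted sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import scipy.stats

from .io_formats import DEFAULT_PHASE_MIDPOINTS, PHASE_ORDER, CountTable, phase_of_age
from .source_tracking import (
    UNKNOWN,
    Attribution,
    ShallowSinkError,
    SourceSet,
    SourceTrackingParams,
    _harmonize,
    _rarefy_vector,
)

__all__ = [
    "PhaseMidpoints",
    "AgePrediction",
    "EvaluationReport",
    "predict_age",
    "filter_uncertain",
    "calibrate_sources",
    "evaluate",
]


@dataclass(frozen=True)
class PhaseMidpoints:
    """Life-phase midpoints in weeks; must increase MR < MA < MD < OD < VO."""

    midpoints: Mapping[str, float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "midpoints",
                           dict(self.midpoints or DEFAULT_PHASE_MIDPOINTS))
        vals = [self.midpoints[p] for p in PHASE_ORDER]
        if not all(a < b for a, b in zip(vals, vals[1:])):
            raise ValueError("midpoints must be strictly increasing in phase order")

    def __getitem__(self, phase: str) -> float:
        return self.midpoints[phase]


@dataclass
class AgePrediction:
    sink_id: str
    predicted_age_weeks: float  # NaN when undefined
    unknown_proportion: float
    retained: bool
    actual_age_weeks: float = math.nan


@dataclass
class EvaluationReport:
    spearman_rho: float
    spearman_p: float
    polynomial_degree: int
    adjusted_r2: float
    strata: dict[str, dict[str, float]]
    n_retained: int


def predict_age(attr: Attribution,
                midpoints: PhaseMidpoints | Mapping[str, float] | None = None,
                renormalize: bool = True,
                uncertainty_threshold: float = 0.30,
                actual_age_weeks: float = math.nan) -> AgePrediction:
    """Apply the midpoint formula to one attribution.

    Calibration rows (``<phase>#cal...``) are folded onto their phase
    first.  With ``renormalize`` on (default), proportions are divided
    by (1 - unknown); an all-unknown attribution then has no defined
    prediction and is never retained.
    """
    if midpoints is None or isinstance(midpoints, Mapping):
        midpoints = PhaseMidpoints(midpoints)
    by_phase = attr.by_phase()
    unknown = by_phase.pop(UNKNOWN, 0.0)
    stray = set(by_phase) - set(PHASE_ORDER)
    if stray:
        raise ValueError(f"attribution has non-phase source labels: {sorted(stray)}")
    x = np.array([by_phase.get(p, 0.0) for p in PHASE_ORDER])
    a = np.array([midpoints[p] for p in PHASE_ORDER])
    retained = unknown <= uncertainty_threshold
    if renormalize:
        known = 1.0 - unknown
        if known <= 0.0:
            return AgePrediction(attr.sink_id, math.nan, unknown, False,
                                 actual_age_weeks)
        x = x / known
    return AgePrediction(attr.sink_id, float(a @ x), float(unknown), retained,
                         actual_age_weeks)


def filter_uncertain(preds: Sequence[AgePrediction],
                     threshold: float = 0.30) -> list[AgePrediction]:
    """Re-flag predictions: retained iff unknown <= threshold (strict '>').

    Nothing is deleted; only the ``retained`` flag changes.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    out = []
    for p in preds:
        retained = (p.unknown_proportion <= threshold
                    and not math.isnan(p.predicted_age_weeks))
        out.append(AgePrediction(p.sink_id, p.predicted_age_weeks,
                                 p.unknown_proportion, retained,
                                 p.actual_age_weeks))
    return out


def calibrate_sources(base: SourceSet, control_sinks: CountTable,
                      control_ages: Mapping[str, float],
                      params: SourceTrackingParams,
                      phase_map: Callable[[float], str] = phase_of_age,
                      ) -> SourceSet:
    """Append pooled control-batch samples as extra per-phase source rows.

    Each control sample maps through ``phase_map`` by its age; samples
    of the same phase pool into one row labelled ``<phase>#cal``,
    rarefied like any other source.  An empty control set returns the
    base SourceSet unchanged.
    """
    if control_sinks.n_samples == 0:
        return base
    missing = [s for s in control_sinks.sample_ids if s not in control_ages]
    if missing:
        raise KeyError(f"control samples without ages: {missing}")
    by_phase: dict[str, list[str]] = {}
    for sid in control_sinks.sample_ids:
        phase = phase_map(control_ages[sid])
        if phase not in PHASE_ORDER:
            raise ValueError(
                f"control sample {sid!r} (age {control_ages[sid]}) maps to "
                f"no life phase")
        by_phase.setdefault(phase, []).append(sid)

    # harmonize base and control taxa
    tables: dict[str, CountTable] = {
        label: CountTable(base.taxon_ids, [label],
                          base.source_counts[i][:, None])
        for i, label in enumerate(base.labels)
    }
    for phase, sids in by_phase.items():
        tables[f"{phase}#cal"] = control_sinks.select_samples(sids)
    taxon_ids, pooled = _harmonize(tables)

    labels, rows = [], []
    for i, (label, vec) in enumerate(pooled.items()):
        if label in base.labels:
            labels.append(label)
            rows.append(vec)  # already rarefied
            continue
        if vec.sum() < params.rarefaction_depth:
            raise ShallowSinkError(
                f"calibration pool {label}: total {int(vec.sum())} below "
                f"rarefaction depth {params.rarefaction_depth}")
        rng = np.random.default_rng([params.seed, 74, i])
        labels.append(label)
        rows.append(_rarefy_vector(vec, params.rarefaction_depth, rng))
    return SourceSet(labels=labels, source_counts=np.vstack(rows),
                     taxon_ids=taxon_ids)


def evaluate(preds: Sequence[AgePrediction], split_age: float = 62.0,
             polynomial_degree: int = 2) -> EvaluationReport:
    """Spearman correlation and polynomial fit of predicted vs actual age.

    Computed on retained predictions only, overall and per stratum
    (actual age below/above ``split_age``).  Adjusted R^2 is
    1 - (1-R^2)(n-1)/(n-k-1) for the degree-k least-squares fit of
    predicted on actual age.
    """
    kept = [p for p in preds
            if p.retained and not math.isnan(p.actual_age_weeks)]
    actual = np.array([p.actual_age_weeks for p in kept])
    predicted = np.array([p.predicted_age_weeks for p in kept])

    def _stats(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            return {"spearman_rho": math.nan, "spearman_p": math.nan,
                    "adjusted_r2": math.nan, "n": float(len(x))}
        rho, p = scipy.stats.spearmanr(x, y)
        k = polynomial_degree
        coeffs = np.polyfit(x, y, k)
        resid = y - np.polyval(coeffs, x)
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        n = len(x)
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1) if n > k + 1 else math.nan
        return {"spearman_rho": float(rho), "spearman_p": float(p),
                "adjusted_r2": adj, "n": float(n)}

    overall = _stats(actual, predicted)
    young = actual < split_age
    strata = {
        "young": _stats(actual[young], predicted[young]),
        "old": _stats(actual[~young], predicted[~young]),
    }
    return EvaluationReport(
        spearman_rho=overall["spearman_rho"], spearman_p=overall["spearman_p"],
        polynomial_degree=polynomial_degree, adjusted_r2=overall["adjusted_r2"],
        strata=strata, n_retained=len(kept))
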