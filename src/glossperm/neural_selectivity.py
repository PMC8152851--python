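"""Gloss-selectivity classification of multiunit records.

Per-trial responses are baseline-subtracted rates over the 300-ms analysis
window.  A site is classified gloss-selective when (i) a one-way ANOVA over
gloss levels is significant for the optimal shape and at least one other
shape, (ii) the 7-point tuning to the optimal shape correlates (Pearson)
with the tuning to at least one other significant shape, and (iii) the
shuffled-image control fails to explain the tuning: either the shuffled
ANOVA is non-significant, or the optimal-vs-shuffled tuning correlation is
non-significant.  Sites passing only the optimal-shape ANOVA are "not
classifiable", distinct from "not selective".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientRepeatsError,
    MissingShuffledDataError,
    ValidationError,
)
from .synthetic_data import SpikeTrialRecord

__all__ = [
    "TuningCurve",
    "AnovaResult",
    "SelectivityResult",
    "MIN_REPEATS",
    "compute_trial_response",
    "build_tuning_curves",
    "tuning_anova",
    "select_optimal_shape",
    "classify_unit",
    "preference_sign",
]

#: minimum accepted repetitions of each stimulus
MIN_REPEATS = 5


def compute_trial_response(record: SpikeTrialRecord) -> float:
    """Baseline-subtracted response rate in spk/s; may be negative."""
    if record.response_window_s <= 0 or record.baseline_window_s <= 0:
        raise ValidationError("window durations must be positive")
    baseline_rate = record.baseline_count / record.baseline_window_s
    response_rate = record.response_count / record.response_window_s
    return response_rate - baseline_rate


@dataclass(frozen=True)
class TuningCurve:
    """Per-level baseline-subtracted rates for one (unit, shape) pair."""

    unit_id: str
    shape_id: str
    shuffled: bool
    levels: tuple[int, ...]
    samples: tuple[tuple[float, ...], ...]  # per-level per-repeat rates

    @property
    def n_repeats(self) -> int:
        return min(len(s) for s in self.samples)

    @property
    def mean_responses(self) -> np.ndarray:
        return np.array([np.mean(s) for s in self.samples])

    @property
    def peak_response(self) -> float:
        return float(self.mean_responses.max())


@dataclass(frozen=True)
class AnovaResult:
    p_value: float
    significant: bool


@dataclass(frozen=True)
class SelectivityResult:
    """Outcome of the gloss-selectivity classification for one unit."""

    unit_id: str
    anova_p: Mapping[str, float]  # per object shape
    shuffled_anova_p: float | None
    optimal_shape_id: str
    correlations: Mapping[str, tuple[float, float]]  # shape -> (r, p)
    shuffled_correlation: tuple[float, float] | None
    status: str  # gloss_selective | not_selective | not_classifiable
    is_gloss_selective: bool
    preference_sign: str  # glossy | matte | undefined


def build_tuning_curves(
    records: Sequence[SpikeTrialRecord],
) -> tuple[dict[str, TuningCurve], TuningCurve | None]:
    """Group spike records into tuning curves.

    Returns ``(object_curves_by_shape, shuffled_curve_or_None)``.  Repeat
    order within a level is irrelevant to every downstream statistic.
    """
    buckets: dict[tuple[str, bool], dict[int, list[float]]] = {}
    unit_ids = set()
    for rec in records:
        unit_ids.add(rec.unit_id)
        buckets.setdefault((rec.shape_id, rec.shuffled), {}).setdefault(
            rec.gloss_level, []
        ).append(compute_trial_response(rec))
    if len(unit_ids) != 1:
        raise ValidationError(f"records span {len(unit_ids)} units; expected exactly 1")
    unit_id = unit_ids.pop()

    object_curves: dict[str, TuningCurve] = {}
    shuffled_curve: TuningCurve | None = None
    for (shape_id, shuffled), by_level in buckets.items():
        levels = tuple(sorted(by_level))
        curve = TuningCurve(
            unit_id=unit_id,
            shape_id=shape_id,
            shuffled=shuffled,
            levels=levels,
            samples=tuple(tuple(by_level[lv]) for lv in levels),
        )
        if shuffled:
            if shuffled_curve is not None:
                raise ValidationError("multiple shuffled shapes in one record set")
            shuffled_curve = curve
        else:
            object_curves[shape_id] = curve
    return object_curves, shuffled_curve


def tuning_anova(curve: TuningCurve, alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA of per-repeat responses across gloss levels."""
    if len(curve.levels) < 2:
        raise ValidationError("ANOVA needs at least 2 gloss levels")
    if curve.n_repeats < MIN_REPEATS:
        raise InsufficientRepeatsError(
            f"unit {curve.unit_id} shape {curve.shape_id}: "
            f"{curve.n_repeats} repeats < required {MIN_REPEATS}"
        )
    groups = [np.asarray(s, dtype=float) for s in curve.samples]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant input yields nan, handled below
        _, p = stats.f_oneway(*groups)
    p = 1.0 if np.isnan(p) else float(p)
    return AnovaResult(p_value=p, significant=p < alpha)


def select_optimal_shape(curves: Mapping[str, TuningCurve]) -> str:
    """Shape yielding the largest peak mean response; ties break to the
    lexicographically smallest shape id."""
    if not curves:
        raise ValidationError("need at least one object tuning curve")
    best = max(sorted(curves), key=lambda s: (curves[s].peak_response, ))
    # max() keeps the first of equal values; sorting first makes it the
    # lexicographically smallest id.
    return best


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, p = stats.pearsonr(x, y)
    if np.isnan(r):
        return 0.0, 1.0
    return float(r), float(p)


def preference_sign(curve: TuningCurve) -> str:
    """'glossy' / 'matte' from the sign of the Spearman rank correlation
    between gloss level and mean response; zero or undefined -> 'undefined'."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, _ = stats.spearmanr(curve.levels, curve.mean_responses)
    if np.isnan(rho) or rho == 0:
        return "undefined"
    return "glossy" if rho > 0 else "matte"


def classify_unit(
    object_curves: Mapping[str, TuningCurve],
    shuffled_curve: TuningCurve | None,
    alpha: float = 0.05,
    require_all_correlations: bool = False,
) -> SelectivityResult:
    """Run the full gloss-selectivity decision rule for one unit.

    ``require_all_correlations=True`` demands a significant optimal-vs-other
    correlation for every significant non-optimal shape instead of at least
    one (both readings of the rule are defensible; "at least one" is the
    default).
    """
    anova_p = {s: tuning_anova(c, alpha).p_value for s, c in object_curves.items()}
    optimal = select_optimal_shape(object_curves)
    sig_shapes = {s for s, p in anova_p.items() if p < alpha}

    correlations: dict[str, tuple[float, float]] = {}
    shuffled_corr: tuple[float, float] | None = None
    shuffled_p: float | None = (
        tuning_anova(shuffled_curve, alpha).p_value if shuffled_curve is not None else None
    )

    sign = preference_sign(object_curves[optimal])

    if optimal not in sig_shapes:
        status = "not_selective"
        return SelectivityResult(
            unit_id=object_curves[optimal].unit_id,
            anova_p=anova_p,
            shuffled_anova_p=shuffled_p,
            optimal_shape_id=optimal,
            correlations=correlations,
            shuffled_correlation=None,
            status=status,
            is_gloss_selective=False,
            preference_sign="undefined",
        )

    other_sig = sorted(sig_shapes - {optimal})
    if not other_sig:
        # significant only for the optimal shape: cannot run the correlation
        # stage, reported separately from "not selective"
        return SelectivityResult(
            unit_id=object_curves[optimal].unit_id,
            anova_p=anova_p,
            shuffled_anova_p=shuffled_p,
            optimal_shape_id=optimal,
            correlations=correlations,
            shuffled_correlation=None,
            status="not_classifiable",
            is_gloss_selective=False,
            preference_sign="undefined",
        )

    opt_means = object_curves[optimal].mean_responses
    for s in other_sig:
        correlations[s] = _pearson(opt_means, object_curves[s].mean_responses)
    corr_sig = [p < alpha for _, p in correlations.values()]
    corr_ok = all(corr_sig) if require_all_correlations else any(corr_sig)

    if shuffled_curve is None:
        raise MissingShuffledDataError(
            f"unit {object_curves[optimal].unit_id}: shuffled-image control "
            "required for classification but absent"
        )
    if shuffled_p is not None and shuffled_p < alpha:
        shuffled_corr = _pearson(opt_means, shuffled_curve.mean_responses)
        shuffled_ok = shuffled_corr[1] >= alpha
    else:
        shuffled_ok = True

    selective = bool(corr_ok and shuffled_ok)
    return SelectivityResult(
        unit_id=object_curves[optimal].unit_id,
        anova_p=anova_p,
        shuffled_anova_p=shuffled_p,
        optimal_shape_id=optimal,
        correlations=correlations,
        shuffled_correlation=shuffled_corr,
        status="gloss_selective" if selective else "not_selective",
        is_gloss_selective=selective,
        preference_sign=sign if selective else "undefined",
    )


def results_to_frame(results: Sequence[SelectivityResult]) -> pd.DataFrame:
    """Flatten classification results into a tidy table."""
    rows = []
    for r in results:
        rows.append(
            {
                "unit_id": r.unit_id,
                "optimal_shape_id": r.optimal_shape_id,
                "status": r.status,
                "is_gloss_selective": r.is_gloss_selective,
                "preference_sign": r.preference_sign,
                "shuffled_anova_p": r.shuffled_anova_p,
                "n_significant_shapes": sum(
                    1 for p in r.anova_p.values() if p < 0.05
                ),
            }
        )
    return pd.DataFrame(rows)
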