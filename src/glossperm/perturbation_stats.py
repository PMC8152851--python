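"""Permutation test for psychometric-parameter shifts, muscimol time-course
summaries and the repeated-injection attenuation table.

The test pools the per-level binary choice samples of the two groups
(canonically 15 + 15 per gloss level), repeatedly re-splits them, refits a
logistic to each pseudo-group, and locates the observed slope/offset
differences within the resulting null.  An observed difference is flagged
significant when it lies at or beyond the 2.5th/97.5th percentile of its
null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .psychometrics import PsychometricFit, fit_logistic, fit_logistic_batch

__all__ = [
    "PermutationResult",
    "TimeCoursePoint",
    "per_level_samples",
    "permutation_test",
    "permutation_test_from_trials",
    "classify_shift_direction",
    "slope_timecourse",
    "repeated_injection_summary",
    "shift_histogram_table",
]


@dataclass(frozen=True)
class PermutationResult:
    """Observed Δa/Δb (condition − control), their permutation nulls, and
    two-tailed significance under the 2.5%-tail criterion."""

    delta_a: float
    delta_b: float
    null_delta_a: np.ndarray
    null_delta_b: np.ndarray
    p_a: float
    p_b: float
    significant_a: bool
    significant_b: bool
    n_perm: int
    seed: int | None
    mode: str
    n_dropped: int  # non-convergent permutation fits excluded from the null
    unreliable: bool  # >5% of permutation fits dropped, or observed fit failed
    fit_condition: PsychometricFit
    fit_control: PsychometricFit

    def to_dict(self) -> dict:
        return {
            "delta_a": self.delta_a,
            "delta_b": self.delta_b,
            "p_a": self.p_a,
            "p_b": self.p_b,
            "significant_a": self.significant_a,
            "significant_b": self.significant_b,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "mode": self.mode,
            "n_dropped": self.n_dropped,
            "unreliable": self.unreliable,
            "a_condition": self.fit_condition.a,
            "b_condition": self.fit_condition.b,
            "a_control": self.fit_control.a,
            "b_control": self.fit_control.b,
        }


@dataclass(frozen=True)
class TimeCoursePoint:
    """Slope difference post − pre at one muscimol timepoint."""

    timepoint_h: float
    slope_difference: float
    significant: bool
    result: PermutationResult = field(repr=False, compare=False, default=None)


def per_level_samples(
    trials: pd.DataFrame,
    group_col: str,
    group_value,
) -> dict[int, np.ndarray]:
    """Extract per-gloss-level binary 'glossier' outcomes for one group.

    Each sample corresponds to one (shape, illumination) trial at that level.
    """
    sub = trials[trials[group_col] == group_value]
    if sub.empty:
        raise ValidationError(f"no trials with {group_col} == {group_value!r}")
    out: dict[int, np.ndarray] = {}
    for level, chunk in sub.groupby("gloss_level"):
        out[int(level)] = (chunk["choice"] == "glossier").to_numpy(dtype=float)
    return out


def _proportions(samples: Mapping[int, np.ndarray], levels: Sequence[int]) -> np.ndarray:
    return np.array([samples[lv].mean() for lv in levels])


def permutation_test(
    samples_condition: Mapping[int, np.ndarray],
    samples_control: Mapping[int, np.ndarray],
    n_perm: int = 10_000,
    seed: int | None = None,
    mode: str = "complement",
    max_dropped_frac: float = 0.05,
) -> PermutationResult:
    """Permutation test of the psychometric slope/offset contrast.

    Parameters
    ----------
    samples_condition, samples_control
        ``{gloss_level: binary array}``; the two groups must contribute equal
        sample counts at every level (canonically 15 each, 30 pooled).
    mode
        ``"complement"`` (default): each permutation draws one pseudo-group
        without replacement and assigns the complement to the other — a true
        permutation, exactly exchangeable.  ``"independent"``: the two
        pseudo-groups are drawn independently from the pool.
    """
    if mode not in ("complement", "independent"):
        raise ValidationError(f"unknown permutation mode {mode!r}")
    levels = sorted(samples_condition)
    if sorted(samples_control) != levels:
        raise ValidationError("condition and control cover different gloss levels")
    for lv in levels:
        if len(samples_condition[lv]) != len(samples_control[lv]):
            raise ValidationError(
                f"level {lv}: unequal group sizes "
                f"({len(samples_condition[lv])} vs {len(samples_control[lv])})"
            )
    x = np.asarray(levels, dtype=float)

    fit_cond = fit_logistic(x, _proportions(samples_condition, levels))
    fit_ctrl = fit_logistic(x, _proportions(samples_control, levels))
    delta_a = fit_cond.a - fit_ctrl.a
    delta_b = fit_cond.b - fit_ctrl.b
    observed_ok = fit_cond.converged and fit_ctrl.converged

    rng = np.random.default_rng(seed)
    props_a = np.empty((n_perm, len(levels)))
    props_b = np.empty((n_perm, len(levels)))
    for j, lv in enumerate(levels):
        pool = np.concatenate([samples_condition[lv], samples_control[lv]])
        m = pool.size
        half = len(samples_condition[lv])
        order = np.argsort(rng.random((n_perm, m)), axis=1)
        props_a[:, j] = pool[order[:, :half]].mean(axis=1)
        if mode == "complement":
            props_b[:, j] = pool[order[:, half:]].mean(axis=1)
        else:
            order2 = np.argsort(rng.random((n_perm, m)), axis=1)
            props_b[:, j] = pool[order2[:, :half]].mean(axis=1)

    stacked = np.vstack([props_a, props_b])
    a_hat, b_hat, _, conv = fit_logistic_batch(x, stacked)
    valid = conv[:n_perm] & conv[n_perm:]
    null_a = (a_hat[:n_perm] - a_hat[n_perm:])[valid]
    null_b = (b_hat[:n_perm] - b_hat[n_perm:])[valid]
    n_dropped = int(n_perm - valid.sum())

    def _tail(null: np.ndarray, obs: float) -> tuple[float, bool]:
        if null.size == 0 or not np.isfinite(obs):
            return 1.0, False
        n_le = int((null <= obs).sum())
        n_ge = int((null >= obs).sum())
        # rank-based two-tailed p, add-one convention so p is never 0
        p = min(1.0, 2.0 * (min(n_le, n_ge) + 1) / (null.size + 1))
        lo, hi = np.quantile(null, [0.025, 0.975])
        return p, bool(obs <= lo or obs >= hi)

    p_a, sig_a = _tail(null_a, delta_a)
    p_b, sig_b = _tail(null_b, delta_b)
    if not observed_ok:
        sig_a = sig_b = False
    unreliable = (n_dropped > max_dropped_frac * n_perm) or not observed_ok

    return PermutationResult(
        delta_a=delta_a,
        delta_b=delta_b,
        null_delta_a=null_a,
        null_delta_b=null_b,
        p_a=p_a,
        p_b=p_b,
        significant_a=sig_a,
        significant_b=sig_b,
        n_perm=n_perm,
        seed=seed,
        mode=mode,
        n_dropped=n_dropped,
        unreliable=unreliable,
        fit_condition=fit_cond,
        fit_control=fit_ctrl,
    )


def permutation_test_from_trials(
    trials: pd.DataFrame,
    group_col: str = "stimulation",
    condition_value=True,
    control_value=False,
    n_perm: int = 10_000,
    seed: int | None = None,
    mode: str = "complement",
) -> PermutationResult:
    """Run the permutation test straight from a trial table."""
    return permutation_test(
        per_level_samples(trials, group_col, condition_value),
        per_level_samples(trials, group_col, control_value),
        n_perm=n_perm,
        seed=seed,
        mode=mode,
    )


def classify_shift_direction(result: PermutationResult) -> str:
    """Direction of a significant horizontal (offset) shift.

    A negative Δb moves the 50% point toward lower test-gloss levels, i.e.
    the condition makes 'glossier' judgments more likely -> ``"glossier"``;
    positive Δb -> ``"less_glossy"``; non-significant -> ``"none"``.
    """
    if not result.significant_b:
        return "none"
    return "glossier" if result.delta_b < 0 else "less_glossy"


def slope_timecourse(
    pre_trials: pd.DataFrame,
    post_trials_by_timepoint: Mapping[float, pd.DataFrame],
    n_perm: int = 10_000,
    seed: int | None = None,
    mode: str = "complement",
) -> list[TimeCoursePoint]:
    """Permutation significance of the post−pre slope difference at each
    muscimol timepoint.  The before/after epochs replace the stimulation
    on/off groups of the microstimulation analysis."""
    if pre_trials is None or len(pre_trials) == 0:
        raise ValidationError("pre-injection session is required")
    pre_samples = per_level_samples(
        pre_trials.assign(_grp="pre"), "_grp", "pre"
    )
    points: list[TimeCoursePoint] = []
    seeds = np.random.SeedSequence(seed).spawn(len(post_trials_by_timepoint))
    for (tp, post), ss in zip(sorted(post_trials_by_timepoint.items()), seeds):
        if post is None or len(post) == 0:
            raise ValidationError(f"no trials for timepoint {tp} h")
        post_samples = per_level_samples(post.assign(_grp="post"), "_grp", "post")
        res = permutation_test(
            post_samples,
            pre_samples,
            n_perm=n_perm,
            seed=int(ss.generate_state(1)[0]),
            mode=mode,
        )
        points.append(
            TimeCoursePoint(
                timepoint_h=float(tp),
                slope_difference=res.delta_a,
                significant=res.significant_a,
                result=res,
            )
        )
    return points


def repeated_injection_summary(
    effects: Sequence[tuple[int, float, bool]],
) -> pd.DataFrame:
    """Tabulate the 18-h slope effect per injection and its attenuation trend.

    ``effects`` is a sequence of ``(injection_index, slope_difference,
    significant)``.  The returned frame carries a ``trend_rho`` column with
    the Spearman correlation of |effect| against injection index (NaN when
    fewer than 3 injections make the trend undefined).
    """
    if not effects:
        raise ValidationError("need at least one injection")
    frame = pd.DataFrame(
        sorted(effects), columns=["injection_index", "slope_difference", "significant"]
    )
    if len(frame) >= 3:
        rho, _ = stats.spearmanr(
            frame["injection_index"], frame["slope_difference"].abs()
        )
        trend = float(rho)
    else:
        trend = float("nan")
    frame["trend_rho"] = trend
    return frame


def shift_histogram_table(
    delta_bs: Sequence[float],
    significant: Sequence[bool],
    bin_width: float = 0.25,
) -> pd.DataFrame:
    """Histogram of horizontal shifts across sessions, split by significance
    (summary table counterpart of the across-session shift distribution)."""
    db = np.asarray(delta_bs, dtype=float)
    sig = np.asarray(significant, dtype=bool)
    if db.size == 0:
        return pd.DataFrame(
            columns=["bin_left", "bin_right", "n_significant", "n_nonsignificant"]
        )
    lo = np.floor(db.min() / bin_width) * bin_width
    hi = np.ceil(db.max() / bin_width) * bin_width + bin_width / 2
    edges = np.arange(lo, hi + bin_width, bin_width)
    rows = []
    for left, right in zip(edges[:-1], edges[1:]):
        in_bin = (db >= left) & (db < right)
        rows.append(
            {
                "bin_left": left,
                "bin_right": right,
                "n_significant": int((in_bin & sig).sum()),
                "n_nonsignificant": int((in_bin & ~sig).sum()),
            }
        )
    return pd.DataFrame(rows)
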