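"""Choice aggregation and logistic psychometric fitting.

The psychometric model is ``y = 1 / (1 + exp(-a (x - b)))`` with slope ``a``
(sensitivity) and offset ``b`` (the 50% point), fitted by least squares on
per-level choice proportions.

Fitting is implemented as a damped Gauss-Newton solver vectorized over a
batch of proportion curves; the permutation machinery fits thousands of
curves per call, so the batch path is the primitive and the single-curve
fit is a batch of one.  Steps are only accepted when they do not increase
the objective, so the loss trace is non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ValidationError

__all__ = [
    "ChoiceTable",
    "PsychometricFit",
    "FitQualityDecision",
    "aggregate_choice_proportions",
    "fit_logistic",
    "fit_logistic_batch",
    "evaluate_fit_quality",
]

#: fitted |a| below this makes b unidentifiable (curve is flat at 0.5);
#: such fits are reported with converged=False.
SLOPE_IDENTIFIABILITY_FLOOR = 1e-2
#: |b| beyond this is treated as a runaway (data carry no crossing).
OFFSET_CAP = 1e3


@dataclass(frozen=True)
class PsychometricFit:
    """Logistic fit result for one group of per-level choice proportions."""

    a: float
    b: float
    residual_error: float  # RMS residual in proportion units
    converged: bool
    n_iter: int

    def predict(self, x) -> np.ndarray:
        return expit(self.a * (np.asarray(x, dtype=float) - self.b))


@dataclass(frozen=True)
class FitQualityDecision:
    keep: bool
    residual_error: float
    threshold: float
    reason: str


@dataclass(frozen=True)
class ChoiceTable:
    """Per-(group, gloss level) choice counts and glossier-choice proportions."""

    frame: pd.DataFrame  # columns: group, gloss_level, n_trials, n_glossier, proportion
    group_by: str

    @property
    def groups(self) -> tuple:
        return tuple(self.frame["group"].unique())

    def for_group(self, group) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (levels, proportions, n_trials) for one group, level-sorted."""
        sub = self.frame[self.frame["group"] == group].sort_values("gloss_level")
        if sub.empty:
            raise ValidationError(f"no rows for group {group!r}")
        return (
            sub["gloss_level"].to_numpy(),
            sub["proportion"].to_numpy(),
            sub["n_trials"].to_numpy(),
        )


_GROUP_COLUMNS = {"stimulation": "stimulation", "epoch": "epoch"}


def _as_trial_frame(trials) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials
    from .synthetic_data import trials_to_frame  # local import, avoids cycle

    return trials_to_frame(trials)


def aggregate_choice_proportions(
    trials,
    group_by: str = "stimulation",
    n_levels: int = 7,
) -> ChoiceTable:
    """Average choices over shapes and illuminations within each gloss level.

    ``trials`` is a trial table (DataFrame or a list of BehaviorTrialRecord)
    with ``gloss_level`` and ``choice`` columns; every recorded choice counts,
    including mid-level trials that were randomly rewarded.

    ``group_by`` selects the contrast column: ``"stimulation"`` (on/off) or
    ``"epoch"`` (pre/post injection).
    """
    if group_by not in _GROUP_COLUMNS:
        raise ValidationError(
            f"group_by must be one of {sorted(_GROUP_COLUMNS)}, got {group_by!r}"
        )
    frame = _as_trial_frame(trials)
    col = _GROUP_COLUMNS[group_by]
    if col not in frame.columns:
        raise ValidationError(f"trial table lacks a {col!r} column")

    levels = frame["gloss_level"].to_numpy()
    if not np.all((levels >= 1) & (levels <= n_levels) & (levels == levels.astype(int))):
        raise ValidationError(f"gloss_level values must be integers in 1..{n_levels}")

    work = frame[[col, "gloss_level", "choice"]].copy()
    work["glossier"] = (work["choice"] == "glossier").astype(int)
    grouped = (
        work.groupby([col, "gloss_level"], sort=True)["glossier"]
        .agg(n_trials="count", n_glossier="sum")
        .reset_index()
        .rename(columns={col: "group"})
    )
    grouped["proportion"] = grouped["n_glossier"] / grouped["n_trials"]
    return ChoiceTable(frame=grouped, group_by=group_by)


# ----------------------------------------------------------------------------
# logistic fitting
# ----------------------------------------------------------------------------


def _objective(x, P, w, a, b):
    r = P - expit(a[:, None] * (x[None, :] - b[:, None]))
    return (w[None, :] * r * r).sum(axis=1)


def fit_logistic_batch(
    x: Sequence[float],
    P: np.ndarray,
    weights: Sequence[float] | None = None,
    max_iter: int = 100,
    return_trace: bool = False,
):
    """Fit ``1/(1+exp(-a(x-b)))`` to each row of proportions ``P`` by
    (weighted) least squares.

    Parameters
    ----------
    x : (k,) gloss levels (k >= 3 distinct values).
    P : (m, k) proportions in [0, 1], one curve per row.
    weights : optional per-level weights (default: equal).
    return_trace : also return the per-iteration objective matrix, which is
        non-increasing row-wise (accepted steps never increase the loss).

    Returns
    -------
    a, b, rms, converged[, trace] : arrays of shape (m,).

    Notes
    -----
    Deterministic initializer: a0 is the slope of the logit-transformed
    proportions (clipped to [0.01, 0.99]) regressed on x; b0 follows from the
    logit-line intercept.  A fit is flagged ``converged=False`` when the
    optimizer fails to reach a stationary point, or when the solution is
    unidentifiable (|a| below ``SLOPE_IDENTIFIABILITY_FLOOR``, where b is
    arbitrary, or |b| beyond ``OFFSET_CAP``).
    """
    x = np.asarray(x, dtype=float)
    P = np.atleast_2d(np.asarray(P, dtype=float))
    m, k = P.shape
    if x.shape != (k,):
        raise ValidationError(f"x has shape {x.shape}, expected ({k},)")
    if np.unique(x).size < 3:
        raise ValidationError("need at least 3 distinct levels to fit a logistic")
    if not np.isfinite(P).all() or (P < 0).any() or (P > 1).any():
        raise ValidationError("proportions must be finite and within [0, 1]")
    if weights is None:
        w = np.ones(k)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (k,) or (w <= 0).any():
            raise ValidationError("weights must be positive, one per level")

    # --- initializer -------------------------------------------------------
    Pc = np.clip(P, 0.01, 0.99)
    L = np.log(Pc) - np.log1p(-Pc)
    xm = x.mean()
    dx = x - xm
    a = (L @ dx) / (dx @ dx)
    a = np.where(np.abs(a) < 1e-3, np.where(a >= 0, 1e-3, -1e-3), a)
    span = x.max() - x.min()
    b = np.clip(xm - L.mean(axis=1) / a, x.min() - 5 * span, x.max() + 5 * span)

    sse = _objective(x, P, w, a, b)
    trace = [sse.copy()] if return_trace else None
    n_iter = np.zeros(m, dtype=int)
    done = np.zeros(m, dtype=bool)

    for it in range(max_iter):
        f = expit(a[:, None] * (x[None, :] - b[:, None]))
        r = P - f
        g = f * (1.0 - f)
        Ja = g * (x[None, :] - b[:, None])
        Jb = -a[:, None] * g
        ga = (w * Ja * r).sum(axis=1)
        gb = (w * Jb * r).sum(axis=1)
        gnorm = np.hypot(ga, gb)

        newly_done = ~done & (gnorm < 1e-12)
        done |= newly_done
        if done.all():
            break

        Aaa = (w * Ja * Ja).sum(axis=1) + 1e-12
        Abb = (w * Jb * Jb).sum(axis=1) + 1e-12
        Aab = (w * Ja * Jb).sum(axis=1)
        det = Aaa * Abb - Aab * Aab
        det = np.where(np.abs(det) < 1e-30, 1e-30, det)
        da = (Abb * ga - Aab * gb) / det
        db = (Aaa * gb - Aab * ga) / det

        # backtracking: accept the first halved step that does not increase sse
        step = np.ones(m)
        accepted = done.copy()  # frozen rows take no step
        new_a, new_b, new_sse = a.copy(), b.copy(), sse.copy()
        for _ in range(30):
            pending = ~accepted
            if not pending.any():
                break
            ta = a + step * da
            tb = b + step * db
            t_sse = _objective(x, P, w, ta, tb)
            ok = pending & (t_sse <= sse)
            new_a[ok] = ta[ok]
            new_b[ok] = tb[ok]
            new_sse[ok] = t_sse[ok]
            accepted |= ok
            step = np.where(accepted, step, step * 0.5)

        moved = np.maximum(np.abs(new_a - a), np.abs(new_b - b))
        a, b, sse = new_a, new_b, new_sse
        n_iter += (~done).astype(int)
        if return_trace:
            trace.append(sse.copy())
        done |= ~done & (moved < 1e-13)
        if done.all():
            break

    identifiable = (
        np.isfinite(a)
        & np.isfinite(b)
        & (np.abs(a) >= SLOPE_IDENTIFIABILITY_FLOOR)
        & (np.abs(b) <= OFFSET_CAP)
    )
    converged = done & identifiable
    rms = np.sqrt(sse / w.sum())
    if return_trace:
        return a, b, rms, converged, np.vstack(trace)
    return a, b, rms, converged


def fit_logistic(
    levels: Sequence[float],
    proportions: Sequence[float],
    weights: Sequence[float] | None = None,
    max_iter: int = 100,
) -> PsychometricFit:
    """Fit the logistic psychometric function to one proportion curve."""
    a, b, rms, conv = fit_logistic_batch(
        levels, np.asarray(proportions, dtype=float)[None, :], weights, max_iter
    )
    return PsychometricFit(
        a=float(a[0]),
        b=float(b[0]),
        residual_error=float(rms[0]),
        converged=bool(conv[0]),
        n_iter=max_iter,
    )


def fit_choice_table(
    table: ChoiceTable,
    weighted: bool = False,
) -> dict:
    """Fit each group in a choice table; returns ``{group: PsychometricFit}``.

    With ``weighted=True`` levels are weighted by trial count (only relevant
    for pooled tables with unequal counts; canonical sessions are balanced).
    """
    fits = {}
    for group in table.groups:
        lv, pr, n = table.for_group(group)
        fits[group] = fit_logistic(lv, pr, weights=n if weighted else None)
    return fits


def evaluate_fit_quality(
    fit: PsychometricFit,
    threshold: float = 0.25,
) -> FitQualityDecision:
    """Keep/exclude decision for a fitted dataset.

    A dataset is excluded when its RMS residual strictly exceeds
    ``threshold`` (a residual exactly at the threshold is kept), or when the
    fit is degenerate (``converged=False``, e.g. level-independent
    proportions leave the offset unidentifiable).
    """
    if not fit.converged:
        return FitQualityDecision(
            keep=False,
            residual_error=fit.residual_error,
            threshold=threshold,
            reason="fit did not converge (degenerate or non-stationary)",
        )
    if fit.residual_error > threshold:
        return FitQualityDecision(
            keep=False,
            residual_error=fit.residual_error,
            threshold=threshold,
            reason=f"RMS residual {fit.residual_error:.4f} > {threshold}",
        )
    return FitQualityDecision(
        keep=True,
        residual_error=fit.residual_error,
        threshold=threshold,
        reason="ok",
    )
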