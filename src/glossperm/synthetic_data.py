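"""Synthetic generators with known ground truth.

Three generators mirror the data the downstream analyses consume:

* Poisson spike-count records for multiunit sites probed with the
  object/shuffled selectivity set (optionally with a luminance confound in
  which shuffled-image responses track gloss level);
* Bernoulli choice records for behavioral sessions, driven by a logistic
  psychometric truth whose slope/offset can be perturbed by a stimulation
  flag or a muscimol slope-multiplier profile;
* pre/post muscimol session series across a timepoint schedule, with a
  geometric attenuation of the drug effect over repeated injections.

Every latent parameter lives in a frozen ground-truth dataclass and can be
emitted as a JSON manifest, so tests validate recovery against the manifest
instead of reverse-engineering it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ValidationError
from .stimulus_design import ConditionGrid, SelectivityStimulusSet

__all__ = [
    "GroundTruthUnit",
    "BehaviorGroundTruth",
    "SpikeTrialRecord",
    "BehaviorTrialRecord",
    "DEFAULT_MUSCIMOL_PROFILE",
    "linear_tuning",
    "make_unit",
    "mean_response_rate",
    "simulate_unit_responses",
    "choice_probability",
    "slope_multiplier",
    "simulate_session_choices",
    "simulate_muscimol_series",
    "trials_to_frame",
    "spikes_to_frame",
    "frame_to_spike_records",
    "ground_truth_manifest",
]

DEFAULT_MUSCIMOL_PROFILE: Mapping[float, float] = {0.5: 0.8, 18.0: 0.4, 42.0: 1.0}


def linear_tuning(n_levels: int = 7) -> tuple[float, ...]:
    """Linear monotone tuning from 0 at level 1 to 1 at the top level."""
    return tuple(i / (n_levels - 1) for i in range(n_levels))


@dataclass(frozen=True)
class GroundTruthUnit:
    """Latent parameters of one simulated multiunit site.

    ``tuning`` maps gloss level 1..n to [0, 1] (monotone non-decreasing);
    ``sign=+1`` prefers glossy (tuning applied as-is), ``sign=-1`` prefers
    matte (tuning reversed across levels).  With ``confound_mode='luminance'``
    shuffled-image responses also track gloss level (gain ``confound_gain``),
    emulating a unit driven by mean luminance rather than gloss.
    """

    unit_id: str
    shape_gains: Mapping[str, float]
    base_rate: float = 40.0  # emulated MUA baseline criterion, spk/s
    tuning: tuple[float, ...] = field(default_factory=linear_tuning)
    sign: int = 1
    confound_mode: str = "none"
    confound_gain: float = 0.0

    def __post_init__(self):
        if self.base_rate <= 0:
            raise ValidationError(f"base_rate must be > 0, got {self.base_rate}")
        if self.sign not in (1, -1):
            raise ValidationError(f"sign must be +1 or -1, got {self.sign}")
        if self.confound_mode not in ("none", "luminance"):
            raise ValidationError(f"unknown confound_mode {self.confound_mode!r}")
        t = np.asarray(self.tuning, dtype=float)
        if t.size < 2 or (np.diff(t) < 0).any():
            raise ValidationError("tuning must be monotone non-decreasing, length >= 2")
        if t.min() < 0 or t.max() > 1:
            raise ValidationError("tuning values must lie in [0, 1]")


def make_unit(
    unit_id: str,
    shape_ids: Sequence[str],
    kind: str = "gloss",
    gain: float = 40.0,
    base_rate: float = 40.0,
    sign: int = 1,
) -> GroundTruthUnit:
    """Convenience factory for the three canonical unit archetypes.

    ``kind='gloss'``: gloss-tuned on every shape, flat shuffled responses.
    ``kind='flat'``: no tuning anywhere (null unit).
    ``kind='luminance'``: looks gloss-tuned on objects but shuffled responses
    track level too, so the shuffled-image control should reject it.
    """
    if kind == "gloss":
        return GroundTruthUnit(
            unit_id=unit_id,
            shape_gains={s: gain for s in shape_ids},
            base_rate=base_rate,
            sign=sign,
        )
    if kind == "flat":
        return GroundTruthUnit(
            unit_id=unit_id,
            shape_gains={s: 0.0 for s in shape_ids},
            base_rate=base_rate,
            sign=sign,
        )
    if kind == "luminance":
        return GroundTruthUnit(
            unit_id=unit_id,
            shape_gains={s: gain for s in shape_ids},
            base_rate=base_rate,
            sign=sign,
            confound_mode="luminance",
            confound_gain=gain,
        )
    raise ValidationError(f"unknown unit kind {kind!r}")


@dataclass(frozen=True)
class SpikeTrialRecord:
    """Spike counts for one stimulus presentation.

    ``response_count`` covers the analysis window starting 50 ms after
    stimulus onset; ``baseline_count`` covers the matching pre-stimulus
    window.  Window durations ride along so rates are recomputable.
    """

    unit_id: str
    shape_id: str
    shuffled: bool
    gloss_level: int
    repeat_index: int
    baseline_count: int
    response_count: int
    response_window_s: float = 0.3
    baseline_window_s: float = 0.3


@dataclass(frozen=True)
class BehaviorTrialRecord:
    """One gloss-discrimination trial: condition, binary choice, reward."""

    session_id: str
    gloss_level: int
    shape_id: str
    illumination_id: str
    stimulation: bool
    choice: str  # "glossier" | "less_glossy"
    rewarded: bool
    timepoint_h: float | None = None  # hours after injection; None outside muscimol
    epoch: str | None = None  # "pre" | "post" for muscimol series


@dataclass(frozen=True)
class BehaviorGroundTruth:
    """Latent logistic truth for the choice generator.

    Stimulation perturbs the offset additively (``delta_b_stim``) and the
    slope multiplicatively (``stim_slope_factor``); muscimol multiplies the
    slope by ``muscimol_profile[timepoint_h]``, with the drug effect shrunk
    geometrically by ``injection_attenuation`` on repeated injections.
    """

    a_true: float = 1.0
    b_true: float = 4.0
    delta_b_stim: float = 0.0
    stim_slope_factor: float = 1.0
    muscimol_profile: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_MUSCIMOL_PROFILE)
    )
    injection_attenuation: float = 1.0

    def __post_init__(self):
        if self.a_true <= 0:
            raise ValidationError(f"a_true must be > 0, got {self.a_true}")
        if self.stim_slope_factor <= 0:
            raise ValidationError("stim_slope_factor must be > 0")
        if not 0 < self.injection_attenuation <= 1:
            raise ValidationError("injection_attenuation must lie in (0, 1]")
        for t, mult in self.muscimol_profile.items():
            if not 0 < mult <= 1:
                raise ValidationError(
                    f"muscimol multiplier at {t} h must lie in (0, 1], got {mult}"
                )


def slope_multiplier(
    truth: BehaviorGroundTruth,
    timepoint_h: float | None,
    injection_index: int = 0,
) -> float:
    """Effective slope multiplier at a timepoint for the k-th injection (0-based).

    The drug effect ``1 - profile[t]`` is scaled by
    ``injection_attenuation ** injection_index``, so with attenuation 0.5 a
    second injection at a timepoint with multiplier 0.4 yields
    ``1 - 0.6 * 0.5 = 0.7``.  ``timepoint_h=None`` (pre-injection) maps to 1.
    """
    if timepoint_h is None:
        return 1.0
    key = float(timepoint_h)
    if key not in {float(t) for t in truth.muscimol_profile}:
        raise ValidationError(
            f"timepoint {timepoint_h} h missing from muscimol profile "
            f"{sorted(truth.muscimol_profile)}"
        )
    mult = {float(t): m for t, m in truth.muscimol_profile.items()}[key]
    if injection_index < 0:
        raise ValidationError("injection_index must be >= 0")
    return 1.0 - (1.0 - mult) * truth.injection_attenuation**injection_index


def choice_probability(
    truth: BehaviorGroundTruth,
    gloss_level: float,
    stimulation: bool = False,
    timepoint_h: float | None = None,
    injection_index: int = 0,
) -> float:
    """P(choose 'glossier') for one condition under the generator truth."""
    a_eff = truth.a_true * slope_multiplier(truth, timepoint_h, injection_index)
    b_eff = truth.b_true
    if stimulation:
        a_eff *= truth.stim_slope_factor
        b_eff += truth.delta_b_stim
    if a_eff <= 0:
        raise ValidationError(f"effective slope must be > 0, got {a_eff}")
    return float(expit(a_eff * (gloss_level - b_eff)))


# ----------------------------------------------------------------------------
# spiking simulator
# ----------------------------------------------------------------------------


def mean_response_rate(
    unit: GroundTruthUnit, shape_id: str, gloss_level: int, shuffled: bool
) -> float:
    """Ground-truth mean firing rate (spk/s) in the response window."""
    n = len(unit.tuning)
    if not 1 <= gloss_level <= n:
        raise ValidationError(f"gloss_level {gloss_level} outside 1..{n}")
    if shuffled:
        if unit.confound_mode == "luminance":
            proxy = (gloss_level - 1) / (n - 1)
            rate = unit.base_rate + unit.confound_gain * proxy
        else:
            rate = unit.base_rate
    else:
        if shape_id not in unit.shape_gains:
            raise ValidationError(f"shape {shape_id!r} unknown to unit {unit.unit_id}")
        idx = gloss_level - 1 if unit.sign == 1 else n - gloss_level
        rate = unit.base_rate + unit.shape_gains[shape_id] * unit.tuning[idx]
    if rate < 0:
        raise ValidationError(
            f"negative mean rate {rate} for unit {unit.unit_id}, shape {shape_id}"
        )
    return float(rate)


def simulate_unit_responses(
    unit: GroundTruthUnit,
    stimulus_set: SelectivityStimulusSet | pd.DataFrame,
    n_repeats: int,
    seed: int,
    response_window_s: float = 0.3,
    baseline_window_s: float = 0.3,
) -> list[SpikeTrialRecord]:
    """Draw Poisson spike counts for every stimulus in the selectivity set.

    Response counts are Poisson with mean ``rate * response_window_s`` where
    the rate composes base rate, per-shape gain and the (sign-oriented)
    tuning; baseline counts are Poisson at the base rate.
    """
    if n_repeats < 5:
        raise ValidationError(
            f"n_repeats must be >= 5 (minimum accepted repetitions), got {n_repeats}"
        )
    frame = stimulus_set.frame if isinstance(stimulus_set, SelectivityStimulusSet) else stimulus_set
    rng = np.random.default_rng(seed)
    records: list[SpikeTrialRecord] = []
    for row in frame.itertuples(index=False):
        rate = mean_response_rate(
            unit, row.shape_id, int(row.gloss_level), bool(row.shuffled)
        )
        resp = rng.poisson(rate * response_window_s, size=n_repeats)
        base = rng.poisson(unit.base_rate * baseline_window_s, size=n_repeats)
        for rep in range(n_repeats):
            records.append(
                SpikeTrialRecord(
                    unit_id=unit.unit_id,
                    shape_id=row.shape_id,
                    shuffled=bool(row.shuffled),
                    gloss_level=int(row.gloss_level),
                    repeat_index=rep,
                    baseline_count=int(base[rep]),
                    response_count=int(resp[rep]),
                    response_window_s=response_window_s,
                    baseline_window_s=baseline_window_s,
                )
            )
    return records


# ----------------------------------------------------------------------------
# behavioral simulator
# ----------------------------------------------------------------------------


def simulate_session_choices(
    truth: BehaviorGroundTruth,
    grid: ConditionGrid,
    seed: int,
    session_id: str = "session-0",
    timepoint_h: float | None = None,
    injection_index: int = 0,
    epoch: str | None = None,
    reference_level: int = 4,
) -> list[BehaviorTrialRecord]:
    """Simulate one session: exactly one Bernoulli choice per grid condition.

    Trials at ``reference_level`` are rewarded at random regardless of the
    choice; elsewhere reward tracks correctness against the reference.
    """
    rng = np.random.default_rng(seed)
    records: list[BehaviorTrialRecord] = []
    for cond in grid.conditions:
        p = choice_probability(
            truth,
            cond.gloss_level,
            stimulation=cond.stimulation,
            timepoint_h=timepoint_h,
            injection_index=injection_index,
        )
        glossier = bool(rng.random() < p)
        choice = "glossier" if glossier else "less_glossy"
        if cond.gloss_level == reference_level:
            rewarded = bool(rng.random() < 0.5)
        else:
            rewarded = glossier == (cond.gloss_level > reference_level)
        records.append(
            BehaviorTrialRecord(
                session_id=session_id,
                gloss_level=cond.gloss_level,
                shape_id=cond.shape_id,
                illumination_id=cond.illumination_id,
                stimulation=cond.stimulation,
                choice=choice,
                rewarded=rewarded,
                timepoint_h=timepoint_h,
                epoch=epoch,
            )
        )
    return records


def simulate_muscimol_series(
    truth: BehaviorGroundTruth,
    grid_no_stim: ConditionGrid,
    seeds: Sequence[int],
    timepoints: Sequence[object] = ("pre", 0.5, 18.0, 42.0),
    injection_index: int = 0,
    session_prefix: str = "inj0",
) -> list[BehaviorTrialRecord]:
    """Simulate one pre-injection session plus one session per post timepoint.

    ``timepoints`` mixes the literal ``"pre"`` (slope multiplier 1) with
    post-injection hours that must all appear in the muscimol profile.
    """
    if len(seeds) != len(timepoints):
        raise ValidationError(
            f"need one seed per timepoint ({len(timepoints)}), got {len(seeds)}"
        )
    for tp in timepoints:
        if tp != "pre":
            slope_multiplier(truth, float(tp), injection_index)  # validates presence
    records: list[BehaviorTrialRecord] = []
    for tp, seed in zip(timepoints, seeds):
        pre = tp == "pre"
        records.extend(
            simulate_session_choices(
                truth,
                grid_no_stim,
                seed=seed,
                session_id=f"{session_prefix}-{'pre' if pre else f'{float(tp):g}h'}",
                timepoint_h=None if pre else float(tp),
                injection_index=injection_index,
                epoch="pre" if pre else "post",
            )
        )
    return records


# ----------------------------------------------------------------------------
# tabular conversion and manifests
# ----------------------------------------------------------------------------

_TRIAL_COLUMNS = [
    "session_id",
    "gloss_level",
    "shape_id",
    "illumination_id",
    "stimulation",
    "choice",
    "rewarded",
    "timepoint_h",
    "epoch",
]


def trials_to_frame(records: Sequence[BehaviorTrialRecord]) -> pd.DataFrame:
    frame = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=_TRIAL_COLUMNS)
    return frame


def spikes_to_frame(records: Sequence[SpikeTrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def frame_to_spike_records(frame: pd.DataFrame) -> list[SpikeTrialRecord]:
    return [
        SpikeTrialRecord(
            unit_id=str(row.unit_id),
            shape_id=str(row.shape_id),
            shuffled=bool(row.shuffled),
            gloss_level=int(row.gloss_level),
            repeat_index=int(row.repeat_index),
            baseline_count=int(row.baseline_count),
            response_count=int(row.response_count),
            response_window_s=float(row.response_window_s),
            baseline_window_s=float(row.baseline_window_s),
        )
        for row in frame.itertuples(index=False)
    ]


def ground_truth_manifest(truth, **extra) -> dict:
    """Serializable manifest of every latent parameter plus seed metadata."""
    payload = dataclasses.asdict(truth)
    for key, value in list(payload.items()):
        if isinstance(value, Mapping):
            payload[key] = {str(k): v for k, v in value.items()}
    payload.update(extra)
    return payload
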