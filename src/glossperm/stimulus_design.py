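"""Stimulus-parameter design for the gloss discrimination task.

Builds the 7-level gloss parameter ladder in (c, d) space, seeded
spherical-harmonics shape families at 5 complexity levels, the factorial
condition grid for behavioral sessions, and the object/shuffled stimulus
set used to probe neural gloss selectivity.

Shapes are represented as coefficient vectors only; rendering is out of
scope, so a :class:`ShapeSpec` is a recipe, not an image.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "GlossLevelParams",
    "GlossLadder",
    "ShapeSpec",
    "Condition",
    "ConditionGrid",
    "SelectivityStimulusSet",
    "build_gloss_ladder",
    "generate_shape_set",
    "shape_complexity",
    "build_condition_grid",
    "build_selectivity_stimulus_set",
]

#: default illumination set (three high-dynamic-range environments)
DEFAULT_ILLUMINATIONS = ("Eucalyptus", "Campus", "Building")


@dataclass(frozen=True)
class GlossLevelParams:
    """One rung of the gloss ladder: highlight-contrast (c) and sharpness (d)."""

    level: int
    c: float
    d: float


@dataclass(frozen=True)
class GlossLadder:
    """Equally spaced gloss levels along the diagonal of c-d space.

    Adjacent steps keep ``delta_c / delta_d`` equal to ``cd_ratio``; the c
    endpoints are exact.  Only differences of d are constrained, so d is
    stored relative to ``d_anchor`` (the d value at level 1).
    """

    levels: tuple[GlossLevelParams, ...]
    c_min: float
    c_max: float
    cd_ratio: float
    d_anchor: float = 0.0

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def delta_c(self) -> float:
        return (self.c_max - self.c_min) / (self.n_levels - 1)

    @property
    def delta_d(self) -> float:
        return self.delta_c / self.cd_ratio

    @property
    def level_ids(self) -> tuple[int, ...]:
        return tuple(p.level for p in self.levels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": [p.level for p in self.levels],
                "c": [p.c for p in self.levels],
                "d": [p.d for p in self.levels],
            }
        )


@dataclass(frozen=True)
class ShapeSpec:
    """Recipe for one random object shape.

    ``coefficients`` are weights on a real spherical-harmonics basis of
    ``basis_order`` (coefficient ``i`` belongs to harmonic order
    ``order_index[i]``).  Identical ``(seed, complexity_level, basis_order)``
    reproduce identical coefficients (NumPy PCG64 via ``default_rng``,
    which has a stable documented stream).
    """

    shape_id: str
    complexity_level: int
    seed: int
    basis_order: int
    coefficients: tuple[float, ...]

    def order_index(self) -> np.ndarray:
        ells = np.arange(self.basis_order + 1)
        return np.repeat(ells, 2 * ells + 1)


@dataclass(frozen=True)
class Condition:
    """One cell of the behavioral factorial design."""

    gloss_level: int
    shape_id: str
    illumination_id: str
    stimulation: bool


@dataclass(frozen=True)
class ConditionGrid:
    """Full factorial trial-design table with its factor sets as metadata."""

    conditions: tuple[Condition, ...]
    factors: Mapping[str, tuple] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.conditions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gloss_level": [c.gloss_level for c in self.conditions],
                "shape_id": [c.shape_id for c in self.conditions],
                "illumination_id": [c.illumination_id for c in self.conditions],
                "stimulation": [c.stimulation for c in self.conditions],
            }
        )


@dataclass(frozen=True)
class SelectivityStimulusSet:
    """Object images (shape x gloss level, one illumination) plus shuffled
    controls of one shape, used to test gloss selectivity of multiunit sites."""

    frame: pd.DataFrame  # columns: shape_id, gloss_level, illumination_id, shuffled
    illumination_id: str
    shuffled_shape_id: str

    @property
    def n_object_images(self) -> int:
        return int((~self.frame["shuffled"]).sum())

    @property
    def n_shuffled_images(self) -> int:
        return int(self.frame["shuffled"].sum())


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    return value


def build_gloss_ladder(
    c_min: float,
    c_max: float,
    n_levels: int = 7,
    cd_ratio: float = 1.78,
    d_anchor: float = 0.0,
) -> GlossLadder:
    """Build a gloss ladder with equal c spacing and fixed delta-c/delta-d ratio.

    Parameters
    ----------
    c_min, c_max
        Highlight-contrast coordinate at the lowest and highest gloss level;
        endpoints are reproduced exactly.
    n_levels
        Number of rungs (>= 2).
    cd_ratio
        Ratio of adjacent c spacing to adjacent d spacing (> 0).
    d_anchor
        d value assigned to level 1; only d differences are design-constrained.
    """
    c_min = _require_finite("c_min", c_min)
    c_max = _require_finite("c_max", c_max)
    cd_ratio = _require_finite("cd_ratio", cd_ratio)
    d_anchor = _require_finite("d_anchor", d_anchor)
    n_levels = int(n_levels)
    if c_max <= c_min:
        raise ValidationError(f"c_max ({c_max}) must exceed c_min ({c_min})")
    if n_levels < 2:
        raise ValidationError(f"n_levels must be >= 2, got {n_levels}")
    if cd_ratio <= 0:
        raise ValidationError(f"cd_ratio must be > 0, got {cd_ratio}")

    c = np.linspace(c_min, c_max, n_levels)
    delta_d = (c_max - c_min) / (n_levels - 1) / cd_ratio
    d = d_anchor + np.arange(n_levels) * delta_d
    levels = tuple(
        GlossLevelParams(level=i + 1, c=float(c[i]), d=float(d[i]))
        for i in range(n_levels)
    )
    return GlossLadder(
        levels=levels, c_min=c_min, c_max=c_max, cd_ratio=cd_ratio, d_anchor=d_anchor
    )


def shape_complexity(spec: ShapeSpec, order_cutoff: int = 2) -> float:
    """Complexity metric: total power in harmonics above ``order_cutoff``."""
    coeffs = np.asarray(spec.coefficients)
    high = spec.order_index() > order_cutoff
    return float(np.sum(coeffs[high] ** 2))


def generate_shape_set(
    session_seed: int,
    n_complexity: int = 5,
    basis_order: int = 10,
    order_cutoff: int = 2,
    power_step: float = 0.25,
) -> list[ShapeSpec]:
    """Generate one daily shape family: ``n_complexity`` seeded shapes of
    strictly increasing complexity.

    Each shape draws uniform coefficients for a spherical-harmonics basis of
    ``basis_order``; the part above ``order_cutoff`` is renormalized so its
    total power equals ``(power_step * complexity_level)**2``, making the
    complexity metric exactly monotone in ``complexity_level`` while level 1
    stays close to a smooth ellipsoid.
    """
    session_seed = int(session_seed)
    if session_seed < 0:
        raise ValidationError("session_seed must be a non-negative integer")
    if basis_order < 1:
        raise ValidationError("basis_order must be >= 1")
    if n_complexity < 1:
        raise ValidationError("n_complexity must be >= 1")

    ells = np.arange(basis_order + 1)
    order_index = np.repeat(ells, 2 * ells + 1)
    high = order_index > order_cutoff
    if not high.any():
        raise ValidationError(
            f"basis_order={basis_order} has no harmonics above order {order_cutoff}"
        )

    shapes: list[ShapeSpec] = []
    for k in range(1, n_complexity + 1):
        # independent, portable stream per (session, complexity level)
        rng = np.random.default_rng([session_seed, k, basis_order])
        coeffs = rng.random(order_index.size)
        norm = np.linalg.norm(coeffs[high])
        coeffs[high] *= (power_step * k) / norm
        shapes.append(
            ShapeSpec(
                shape_id=f"s{session_seed:04d}-c{k}",
                complexity_level=k,
                seed=session_seed,
                basis_order=basis_order,
                coefficients=tuple(float(v) for v in coeffs),
            )
        )
    return shapes


def _shape_ids(shapes: Sequence[ShapeSpec | str]) -> tuple[str, ...]:
    ids = tuple(s.shape_id if isinstance(s, ShapeSpec) else str(s) for s in shapes)
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate shape ids: {ids}")
    return ids


def build_condition_grid(
    ladder: GlossLadder,
    shapes: Sequence[ShapeSpec | str],
    illuminations: Sequence[str] = DEFAULT_ILLUMINATIONS,
    include_stimulation_factor: bool = True,
) -> ConditionGrid:
    """Full factorial grid over gloss level x shape x illumination
    (x stimulation on/off when ``include_stimulation_factor``).

    Row order is fixed: gloss slowest, then shape, then illumination, then
    stimulation fastest, so downstream joins are deterministic.
    """
    shape_ids = _shape_ids(shapes)
    illum_ids = tuple(str(i) for i in illuminations)
    if not shape_ids or not illum_ids or ladder.n_levels == 0:
        raise ValidationError("all factor sets must be non-empty")
    if len(set(illum_ids)) != len(illum_ids):
        raise ValidationError(f"duplicate illumination ids: {illum_ids}")

    stim_values = (False, True) if include_stimulation_factor else (False,)
    conditions = tuple(
        Condition(gloss_level=lvl, shape_id=sh, illumination_id=il, stimulation=st)
        for lvl, sh, il, st in itertools.product(
            ladder.level_ids, shape_ids, illum_ids, stim_values
        )
    )
    factors = {
        "gloss_level": ladder.level_ids,
        "shape_id": shape_ids,
        "illumination_id": illum_ids,
        "stimulation": stim_values,
    }
    return ConditionGrid(conditions=conditions, factors=factors)


def build_selectivity_stimulus_set(
    ladder: GlossLadder,
    shapes: Sequence[ShapeSpec | str],
    illumination: str = "Eucalyptus",
    shuffled_shape_id: str | None = None,
) -> SelectivityStimulusSet:
    """Stimulus set for selectivity mapping: every shape at every gloss level
    in a single illumination, plus one shuffled image per gloss level for
    ``shuffled_shape_id`` (default: first shape).

    Shuffled images are specs carrying a flag; pixel shuffling itself belongs
    to rendering and is not modeled.
    """
    shape_ids = _shape_ids(shapes)
    if not shape_ids:
        raise ValidationError("shape set must be non-empty")
    if shuffled_shape_id is None:
        shuffled_shape_id = shape_ids[0]
    if shuffled_shape_id not in shape_ids:
        raise ValidationError(
            f"shuffled_shape_id {shuffled_shape_id!r} not in shape set {shape_ids}"
        )
    rows = [
        (sh, lvl, illumination, False)
        for lvl, sh in itertools.product(ladder.level_ids, shape_ids)
    ]
    rows += [(shuffled_shape_id, lvl, illumination, True) for lvl in ladder.level_ids]
    frame = pd.DataFrame(
        rows, columns=["shape_id", "gloss_level", "illumination_id", "shuffled"]
    )
    return SelectivityStimulusSet(
        frame=frame, illumination_id=illumination, shuffled_shape_id=shuffled_shape_id
    )
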