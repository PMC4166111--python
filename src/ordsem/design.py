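"""Experimental design: the 216-cell grid and its translation to models.

Each cell crosses modeling strategy (ignore vs. model the non-invariance),
non-invariance type (thresholds / loadings / both), level (0-3 perturbed
items) and nine structural-model/target-position combinations.  A cell
translates into (a) the generating population -- measurement specs per
group plus the structural model -- and (b) the analysis
:class:`~ordsem.model.ModelSpec` implementing the strategy's cross-group
constraints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ordsem.model import EQUAL, FIXED, FREE, ModelLayout, ModelSpec
from ordsem.populations import (
    FOCAL,
    GROUPS,
    REFERENT,
    DesignError,
    MeasurementSpec,
    ModelType,
    NoninvType,
    NONINVARIANT_ITEMS,
    Position,
    StructuralSpec,
    apply_noninvariance,
    default_target_measurement,
    population_structural,
    sample_auxiliary_measurement,
    target_measurement_from_table,
)

STRATEGIES = ("ignore", "model")
NONINV_TYPES = ("thresholds", "loadings", "both")
LEVELS = (0, 1, 2, 3)
MODEL_POSITIONS: tuple[tuple[ModelType, Position], ...] = (
    ("simple", "predictor"),
    ("simple", "criterion"),
    ("partial", "predictor"),
    ("partial", "criterion"),
    ("mediation", "predictor"),
    ("mediation", "mediator"),
    ("mediation", "criterion"),
    ("moderation", "predictor"),
    ("moderation", "criterion"),
)


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the strategy x type x level x model/position design."""

    strategy: str
    noninv_type: NoninvType
    level: int
    model_type: ModelType
    position: Position

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise DesignError(f"unknown strategy {self.strategy!r}")
        if self.noninv_type not in NONINV_TYPES:
            raise DesignError(f"unknown non-invariance type {self.noninv_type!r}")
        if self.level not in LEVELS:
            raise DesignError(f"level must be one of {LEVELS}")
        if (self.model_type, self.position) not in MODEL_POSITIONS:
            raise DesignError(
                f"invalid model/position pair {(self.model_type, self.position)}"
            )

    @property
    def label(self) -> str:
        return (
            f"{self.strategy}-{self.noninv_type}-L{self.level}-"
            f"{self.model_type}-{self.position}"
        )


def condition_grid() -> list[ConditionSpec]:
    """All 216 conditions in stable lexicographic order
    (strategy, type, level, model/position)."""
    out = []
    for strategy in STRATEGIES:
        for typ in NONINV_TYPES:
            for level in LEVELS:
                for model_type, position in MODEL_POSITIONS:
                    out.append(
                        ConditionSpec(strategy, typ, level, model_type, position)
                    )
    return out


def grid_frame() -> pd.DataFrame:
    """The grid as a DataFrame with integer condition ids."""
    rows = [
        {
            "condition_id": i,
            "strategy": c.strategy,
            "noninv_type": c.noninv_type,
            "level": c.level,
            "model_type": c.model_type,
            "position": c.position,
        }
        for i, c in enumerate(condition_grid())
    ]
    return pd.DataFrame(rows)


@dataclass
class ConditionPopulation:
    """Generating population of one design cell."""

    condition: ConditionSpec
    structural: StructuralSpec
    measurements: dict[str, dict[str, MeasurementSpec]]  # group -> latent -> spec

    @property
    def layout(self) -> ModelLayout:
        names = self.structural.latent_names
        cols, ncat = [], []
        ref = self.measurements[REFERENT]
        for name in names:
            m = ref[name]
            cols += [name] * m.n_items
            ncat += [m.n_categories] * m.n_items
        pairs = ()
        if len(self.structural.exogenous) == 2:
            pairs = (tuple(self.structural.exogenous),)
        return ModelLayout(
            latent_names=names,
            column_constructs=tuple(cols),
            n_categories=tuple(ncat),
            edges=self.structural.edges,
            exog_cov_pairs=pairs,
        )


def sample_auxiliary_set(
    rng: np.random.Generator, n_constructs: int = 2
) -> list[MeasurementSpec]:
    """Draw the study's fixed auxiliary measurement models (once per seed)."""
    return [sample_auxiliary_measurement(rng) for _ in range(n_constructs)]


def generating_population(
    condition: ConditionSpec,
    aux_specs: Sequence[MeasurementSpec],
    target_table: Sequence[tuple[float, Sequence[float]]] | None = None,
) -> ConditionPopulation:
    """Assemble the population of one cell.

    The target construct (the one in ``condition.position``) gets the
    referent measurement plus the condition's non-invariance in the focal
    group; every other construct uses the next auxiliary spec in both
    groups.
    """
    structural = population_structural(condition.model_type, condition.position)
    target = (
        default_target_measurement()
        if target_table is None
        else target_measurement_from_table(target_table)
    )
    ref_t, foc_t = apply_noninvariance(target, condition.noninv_type, condition.level)
    measurements: dict[str, dict[str, MeasurementSpec]] = {g: {} for g in GROUPS}
    aux_iter = iter(aux_specs)
    for name in structural.latent_names:
        if name == structural.target:
            measurements[REFERENT][name] = ref_t
            measurements[FOCAL][name] = foc_t
        else:
            aux = next(aux_iter)
            measurements[REFERENT][name] = aux
            measurements[FOCAL][name] = aux
    return ConditionPopulation(
        condition=condition, structural=structural, measurements=measurements
    )


def _freed_parameters(condition: ConditionSpec) -> tuple[set[int], set[int]]:
    """Target-construct items whose (loadings, thresholds) the analysis frees.

    The "model" strategy frees exactly the manipulated items' manipulated
    parameter classes (known non-invariance, no search); "ignore" frees
    nothing.
    """
    if condition.strategy == "ignore" or condition.level == 0:
        return set(), set()
    items = set(NONINVARIANT_ITEMS[: condition.level])
    free_loadings = items if condition.noninv_type in ("loadings", "both") else set()
    free_thresholds = items if condition.noninv_type in ("thresholds", "both") else set()
    return free_loadings, free_thresholds


def analysis_spec(
    condition: ConditionSpec,
    population: ConditionPopulation,
    referent_unit_variances: bool = False,
) -> ModelSpec:
    """Analysis model for one cell under its strategy.

    Shared rules: the first loading of each construct is fixed at its
    population value in both groups; latent variances/residual variances
    are free in both groups; latent means are 0 in the referent and free in
    the focal group; item residual variances are 1 in the referent and free
    in the focal group; structural paths are free in both groups.  The
    ignore strategy constrains all loadings and thresholds equal across
    groups; the model strategy additionally frees the known non-invariant
    items' affected parameter class(es) in the focal group (such items'
    focal residual variances stay fixed at 1 when both classes are freed,
    the standard identification for fully freed ordinal items).

    ``referent_unit_variances=True`` switches to the alternative
    identification in which the referent group's latent variances/residual
    variances are fixed at 1 (their population values) instead of freely
    estimated.
    """
    layout = population.layout
    structural = population.structural
    status: dict[tuple, str] = {}
    values: dict[tuple, float] = {}
    free_loadings, free_thresholds = _freed_parameters(condition)
    target_cols = [
        j for j, c in enumerate(layout.column_constructs) if c == structural.target
    ]
    first = layout.first_items()
    first_cols = set(first.values())

    for g in GROUPS:
        for j in range(layout.n_items):
            name = layout.column_constructs[j]
            within = target_cols.index(j) if j in target_cols else None
            item_ref = population.measurements[REFERENT][name].items[
                _within_construct_index(layout, j)
            ]
            # loading
            slot = ("a", j, g)
            values[slot] = item_ref.discrimination
            if j in first_cols:
                status[slot] = FIXED
            elif g == REFERENT:
                status[slot] = FREE
            else:
                status[slot] = (
                    FREE
                    if within is not None and within in free_loadings
                    else EQUAL
                )
            # thresholds
            for k in range(layout.n_categories[j] - 1):
                slot = ("b", j, k, g)
                values[slot] = item_ref.thresholds[k]
                if g == REFERENT:
                    status[slot] = FREE
                else:
                    status[slot] = (
                        FREE
                        if within is not None and within in free_thresholds
                        else EQUAL
                    )
            # item residual variance (theta parameterization)
            slot = ("theta", j, g)
            values[slot] = 1.0
            if g == REFERENT:
                status[slot] = FIXED
            else:
                fully_freed = (
                    within is not None
                    and within in free_loadings
                    and within in free_thresholds
                )
                status[slot] = FIXED if fully_freed else FREE
        for l in layout.latent_names:
            slot = ("alpha", l, g)
            values[slot] = 0.0
            status[slot] = FIXED if g == REFERENT else FREE
            slot = ("psi", l, g)
            values[slot] = structural.residual_variance(l, g)
            if referent_unit_variances and g == REFERENT:
                # alternative identification: referent latent variances /
                # residual variances fixed (exogenous at 1, endogenous at
                # their population residuals so level-0 models stay correct)
                status[slot] = FIXED
            else:
                status[slot] = FREE
        for pr in layout.exog_cov_pairs:
            slot = ("lcov", pr, g)
            values[slot] = structural.exog_covariance
            status[slot] = FREE
        paths = structural.path_values[g]
        for e, edge in enumerate(layout.edges):
            slot = ("beta", edge, g)
            values[slot] = paths[e]
            status[slot] = FREE

    # truth starts for freed focal measurement parameters use focal values
    for j in target_cols:
        within = target_cols.index(j)
        foc_item = population.measurements[FOCAL][structural.target].items[within]
        if within in free_loadings:
            values[("a", j, FOCAL)] = foc_item.discrimination
        if within in free_thresholds:
            for k, t in enumerate(foc_item.thresholds):
                values[("b", j, k, FOCAL)] = t
    return ModelSpec(layout=layout, status=status, values=values)


def _within_construct_index(layout: ModelLayout, j: int) -> int:
    name = layout.column_constructs[j]
    return [c for c, cc in enumerate(layout.column_constructs) if cc == name].index(j)
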