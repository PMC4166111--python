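"""Population measurement and structural parameters.

Two groups are compared throughout: the *referent* group, whose parameters
anchor the latent metric, and the *focal* group, whose measurement
parameters may be perturbed (non-invariant).

Measurement parameters live in two equivalent metrics:

* the standardized linear-factor metric -- loading ``lambda`` with
  ``|lambda| < 1``, thresholds ``tau`` on the unit-variance latent response,
  and item error variance ``psi = 1 - lambda**2``;
* the IRT/"theta" metric used by normal-ogive graded models -- slope
  ``a = lambda / sqrt(1 - lambda**2)`` and thresholds
  ``b_k = tau_k / sqrt(1 - lambda**2)``, with the item residual variance
  fixed at 1.

The study's target construct is measured by six three-category items;
auxiliary constructs by four five-category items whose parameters are drawn
from the stated sampling distributions.  Non-invariance is introduced on
items 2, 4 and 6 of the target construct: loading non-invariance halves the
focal theta-metric slope, threshold non-invariance (an acquiescent response
style) lowers the focal bottom threshold by 0.8, 1.0 and 1.2 respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

REFERENT = "referent"
FOCAL = "focal"
GROUPS = (REFERENT, FOCAL)

NoninvType = Literal["thresholds", "loadings", "both"]
ModelType = Literal["simple", "partial", "mediation", "moderation"]
Position = Literal["predictor", "mediator", "criterion"]

#: items (0-based) perturbed at non-invariance levels 1, 2, 3 (in order)
NONINVARIANT_ITEMS = (1, 3, 5)
#: amount subtracted from the bottom theta-metric threshold of each
#: perturbed item (paired with NONINVARIANT_ITEMS by level)
THRESHOLD_SHIFTS = (0.8, 1.0, 1.2)
#: multiplicative change of the perturbed focal theta-metric slopes
LOADING_FACTOR = 0.5


class InvalidLoadingError(ValueError):
    """Raised for a standardized loading with ``|lambda| >= 1``."""


class DesignError(ValueError):
    """Raised for an invalid experimental-design request."""


def _check_increasing(thresholds: Sequence[float], what: str) -> tuple[float, ...]:
    thr = tuple(float(t) for t in thresholds)
    if len(thr) < 1:
        raise ValueError(f"{what}: at least one threshold required")
    if any(not (t1 < t2) for t1, t2 in zip(thr, thr[1:])):
        raise ValueError(f"{what}: thresholds must be strictly increasing, got {thr}")
    return thr


@dataclass(frozen=True)
class ItemParams:
    """One ordinal item in the IRT/theta metric.

    Parameters
    ----------
    discrimination
        Slope ``a >= 0`` of the latent trait on the item's latent response
        (residual variance fixed at 1).
    thresholds
        Strictly increasing cut-points ``b_1 < ... < b_{K-1}`` on the latent
        response; ``K`` categories.
    """

    discrimination: float
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "discrimination", float(self.discrimination))
        object.__setattr__(
            self, "thresholds", _check_increasing(self.thresholds, "ItemParams")
        )
        if not math.isfinite(self.discrimination):
            raise ValueError("discrimination must be finite")

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1


@dataclass(frozen=True)
class LinearItemParams:
    """One ordinal item in the standardized linear-factor metric.

    ``error_variance`` is always ``1 - loading**2`` (unit latent-response
    variance).
    """

    loading: float
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "loading", float(self.loading))
        object.__setattr__(
            self, "thresholds", _check_increasing(self.thresholds, "LinearItemParams")
        )
        if abs(self.loading) >= 1.0:
            raise InvalidLoadingError(
                f"standardized loading must satisfy |lambda| < 1, got {self.loading}"
            )

    @property
    def error_variance(self) -> float:
        return 1.0 - self.loading**2


@dataclass(frozen=True)
class MeasurementSpec:
    """Measurement model of one construct in one group (theta metric)."""

    items: tuple[ItemParams, ...]
    n_categories: int
    group: str = REFERENT

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        for it in self.items:
            if it.n_categories != self.n_categories:
                raise ValueError(
                    f"all items must have {self.n_categories} categories, "
                    f"got an item with {it.n_categories}"
                )

    @property
    def n_items(self) -> int:
        return len(self.items)

    def discriminations(self) -> np.ndarray:
        return np.array([it.discrimination for it in self.items])

    def threshold_list(self) -> list[np.ndarray]:
        return [np.array(it.thresholds) for it in self.items]


def linear_to_theta(p: LinearItemParams) -> ItemParams:
    """Convert a standardized linear-factor item to the IRT/theta metric.

    Uses ``a = lambda/sqrt(1 - lambda**2)`` and
    ``b_k = tau_k/sqrt(1 - lambda**2)``; ordering of the thresholds is
    preserved because the scale factor is positive.
    """
    scale = math.sqrt(1.0 - p.loading**2)
    return ItemParams(
        discrimination=p.loading / scale,
        thresholds=tuple(t / scale for t in p.thresholds),
    )


def theta_to_linear(p: ItemParams) -> LinearItemParams:
    """Inverse of :func:`linear_to_theta`: ``lambda = a/sqrt(1 + a**2)``."""
    scale = math.sqrt(1.0 + p.discrimination**2)
    return LinearItemParams(
        loading=p.discrimination / scale,
        thresholds=tuple(t / scale for t in p.thresholds),
    )


# Referent parameters of the six-item, three-category target construct,
# given in the standardized linear metric.  Loadings span 0.6-0.8 and
# thresholds sit near (-0.8, +0.5), values representative of questionnaire
# rating-scale items; they are package defaults and can be overridden via
# the population configuration (see harness.StudyConfig.target_table).
DEFAULT_TARGET_TABLE: tuple[tuple[float, tuple[float, float]], ...] = (
    (0.70, (-0.80, 0.50)),
    (0.75, (-0.90, 0.40)),
    (0.65, (-0.70, 0.60)),
    (0.70, (-0.80, 0.50)),
    (0.80, (-1.00, 0.30)),
    (0.60, (-0.60, 0.70)),
)


def target_measurement_from_table(
    table: Sequence[tuple[float, Sequence[float]]], group: str = REFERENT
) -> MeasurementSpec:
    """Build the target-construct measurement from a linear-metric table.

    ``table`` rows are ``(loading, thresholds)`` in the standardized linear
    metric; they are converted to the theta metric.
    """
    items = tuple(
        linear_to_theta(LinearItemParams(lam, tuple(thr))) for lam, thr in table
    )
    n_cat = items[0].n_categories
    return MeasurementSpec(items=items, n_categories=n_cat, group=group)


def default_target_measurement(group: str = REFERENT) -> MeasurementSpec:
    """Referent measurement of the target construct (6 items, 3 categories)."""
    return target_measurement_from_table(DEFAULT_TARGET_TABLE, group=group)


def sample_auxiliary_measurement(
    rng: np.random.Generator,
    n_items: int = 4,
    n_categories: int = 5,
    loading_mean: float = 0.6,
    loading_var: float = 0.1,
    loading_bounds: tuple[float, float] = (0.05, 0.95),
    threshold_base_mean: float = -1.7,
    threshold_base_sd: float = 0.45,
    threshold_steps: tuple[float, ...] = (1.2, 2.4, 3.6),
    group: str = REFERENT,
) -> MeasurementSpec:
    """Draw the measurement model of one auxiliary construct.

    Standardized loadings are drawn from a normal distribution with mean
    0.6 and variance 0.1, truncated to ``loading_bounds`` so the implied
    communality stays valid; each item's lowest linear-metric threshold is
    drawn from N(-1.7, 0.45**2) and the remaining thresholds are that value
    plus the fixed steps 1.2, 2.4 and 3.6.  Everything is converted to the
    theta metric before return.
    """
    if len(threshold_steps) != n_categories - 2:
        raise ValueError("threshold_steps must provide n_categories - 2 offsets")
    sd = math.sqrt(loading_var)
    lo, hi = loading_bounds
    a, b = (lo - loading_mean) / sd, (hi - loading_mean) / sd
    loadings = stats.truncnorm.rvs(
        a, b, loc=loading_mean, scale=sd, size=n_items, random_state=rng
    )
    base = rng.normal(threshold_base_mean, threshold_base_sd, size=n_items)
    items = []
    for lam, t0 in zip(loadings, base):
        taus = (float(t0),) + tuple(float(t0) + s for s in threshold_steps)
        items.append(linear_to_theta(LinearItemParams(float(lam), taus)))
    return MeasurementSpec(items=tuple(items), n_categories=n_categories, group=group)


def apply_noninvariance(
    target: MeasurementSpec,
    noninv_type: NoninvType,
    level: int,
) -> tuple[MeasurementSpec, MeasurementSpec]:
    """Return (referent, focal) measurement specs for a non-invariance level.

    ``level`` items out of (item 2, item 4, item 6) are perturbed in the
    focal group: ``loadings`` halves the theta-metric discrimination,
    ``thresholds`` lowers the bottom threshold by 0.8/1.0/1.2 (an
    acquiescent response style), ``both`` applies both.  The referent spec
    is returned unchanged; threshold ordering is never disturbed because
    only the bottom threshold moves down.
    """
    if noninv_type not in ("thresholds", "loadings", "both"):
        raise DesignError(f"unknown non-invariance type {noninv_type!r}")
    if not 0 <= level <= len(NONINVARIANT_ITEMS):
        raise DesignError(f"level must be in 0..{len(NONINVARIANT_ITEMS)}, got {level}")
    if target.n_items != 6:
        raise DesignError("the target construct must have 6 items")
    referent = replace(target, group=REFERENT)
    items = list(target.items)
    for pos in range(level):
        idx = NONINVARIANT_ITEMS[pos]
        it = items[idx]
        a = it.discrimination
        thr = list(it.thresholds)
        if noninv_type in ("loadings", "both"):
            a = a * LOADING_FACTOR
        if noninv_type in ("thresholds", "both"):
            thr[0] = thr[0] - THRESHOLD_SHIFTS[pos]
        items[idx] = ItemParams(discrimination=a, thresholds=tuple(thr))
    focal = MeasurementSpec(
        items=tuple(items), n_categories=target.n_categories, group=FOCAL
    )
    return referent, focal


@dataclass(frozen=True)
class StructuralSpec:
    """Population structural model linking the latent variables.

    All latent variables have unit population variance: exogenous variances
    are 1 and each criterion's residual variance is one minus the variance
    explained by its (orthogonal, unit-variance) parents.  Latent means are
    zero in the population.  Paths may differ by group (moderation).
    """

    model_type: ModelType
    position: Position
    latent_names: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    path_values: Mapping[str, tuple[float, ...]]
    exogenous: tuple[str, ...]
    target: str
    exog_covariance: float = 0.0

    def __post_init__(self) -> None:
        for g in GROUPS:
            if g not in self.path_values:
                raise ValueError(f"path values missing for group {g!r}")
            if len(self.path_values[g]) != len(self.edges):
                raise ValueError("path_values must align with edges")

    @property
    def endogenous(self) -> tuple[str, ...]:
        return tuple(n for n in self.latent_names if n not in self.exogenous)

    def paths(self, group: str) -> dict[tuple[str, str], float]:
        return dict(zip(self.edges, self.path_values[group]))

    def residual_variance(self, latent: str, group: str) -> float:
        """Residual variance giving the criterion unit population variance."""
        if latent in self.exogenous:
            return 1.0
        paths = self.paths(group)
        names = self.latent_names
        b = np.zeros((len(names), len(names)))
        for (par, chi), v in paths.items():
            b[names.index(chi), names.index(par)] = v
        # explained variance of `latent` given unit-variance parents with
        # covariance structure implied recursively
        cov = self.latent_covariance(group)
        i = names.index(latent)
        row = b[i]
        explained = float(row @ cov @ row)
        return 1.0 - explained

    def residual_variances(self, group: str) -> dict[str, float]:
        return {n: self.residual_variance(n, group) for n in self.latent_names}

    def latent_covariance(self, group: str) -> np.ndarray:
        """Population covariance matrix of the latent variables (unit diagonal)."""
        names = self.latent_names
        q = len(names)
        b = np.zeros((q, q))
        for (par, chi), v in self.paths(group).items():
            b[names.index(chi), names.index(par)] = v
        psi = np.zeros((q, q))
        for i, n in enumerate(names):
            if n in self.exogenous:
                psi[i, i] = 1.0
            else:
                # solve recursively: unit total variance by construction
                pass
        if len(self.exogenous) == 2 and self.exog_covariance != 0.0:
            i, j = (names.index(e) for e in self.exogenous)
            psi[i, j] = psi[j, i] = self.exog_covariance
        # fill endogenous residuals in causal order so each total variance is 1
        inv = np.linalg.inv(np.eye(q) - b)
        for i, n in enumerate(names):
            if n in self.exogenous:
                continue
            cov = inv @ psi @ inv.T
            psi[i, i] += 1.0 - cov[i, i]
        return inv @ psi @ inv.T


def population_structural(model_type: ModelType, position: Position) -> StructuralSpec:
    """Population structural coefficients for one model type and target role.

    The coefficients come from an empirical nomology of workplace sexual
    harassment: simple slope 0.22; partial slopes 0.22 (target path) and
    0.37 (covariate); mediation paths 0.22 (X->M) and -0.22 (M->Y);
    moderation slopes 0.47 (referent) and 0.18 (focal).  ``position`` marks
    which construct carries the (potentially non-invariant) six-item target
    measurement.
    """
    if model_type == "simple" or model_type == "moderation":
        if position not in ("predictor", "criterion"):
            raise DesignError(f"{model_type} model: position must be predictor/criterion")
        names = ("X", "Y")
        edges = (("X", "Y"),)
        if model_type == "simple":
            vals = {REFERENT: (0.22,), FOCAL: (0.22,)}
        else:
            vals = {REFERENT: (0.47,), FOCAL: (0.18,)}
        target = "X" if position == "predictor" else "Y"
        return StructuralSpec(
            model_type=model_type,
            position=position,
            latent_names=names,
            edges=edges,
            path_values=vals,
            exogenous=("X",),
            target=target,
        )
    if model_type == "partial":
        if position not in ("predictor", "criterion"):
            raise DesignError("partial model: position must be predictor/criterion")
        names = ("X1", "X2", "Y")
        edges = (("X1", "Y"), ("X2", "Y"))
        vals = {REFERENT: (0.22, 0.37), FOCAL: (0.22, 0.37)}
        target = "X1" if position == "predictor" else "Y"
        return StructuralSpec(
            model_type="partial",
            position=position,
            latent_names=names,
            edges=edges,
            path_values=vals,
            exogenous=("X1", "X2"),
            target=target,
            exog_covariance=0.0,
        )
    if model_type == "mediation":
        if position not in ("predictor", "mediator", "criterion"):
            raise DesignError("mediation model: invalid position")
        names = ("X", "M", "Y")
        edges = (("X", "M"), ("M", "Y"))
        vals = {REFERENT: (0.22, -0.22), FOCAL: (0.22, -0.22)}
        target = {"predictor": "X", "mediator": "M", "criterion": "Y"}[position]
        return StructuralSpec(
            model_type="mediation",
            position=position,
            latent_names=names,
            edges=edges,
            path_values=vals,
            exogenous=("X",),
            target=target,
        )
    raise DesignError(f"unknown model type {model_type!r}")
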