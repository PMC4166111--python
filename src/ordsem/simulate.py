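"""Synthetic two-group data: latent scores and graded ordinal responses.

Latent variables are multivariate normal with the covariance implied by a
:class:`~ordsem.populations.StructuralSpec` (unit variances, zero means).
Item responses follow the normal-ogive graded model in the theta
parameterization: the latent response is ``y* = a * eta + eps`` with
``eps ~ N(0, 1)`` and the observed category is the number of thresholds
below ``y*``.  Categories are coded 0..K-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from ordsem.populations import (
    GROUPS,
    ItemParams,
    MeasurementSpec,
    StructuralSpec,
)


@dataclass
class MultiGroupDataset:
    """Integer response matrices for both groups plus the column layout."""

    responses: dict[str, np.ndarray]  # group -> (n, total items) int array
    column_constructs: tuple[str, ...]  # latent name of each column
    column_labels: tuple[str, ...]
    n_categories: tuple[int, ...]  # per column

    @property
    def n_per_group(self) -> dict[str, int]:
        return {g: x.shape[0] for g, x in self.responses.items()}

    @property
    def n_items(self) -> int:
        return len(self.column_constructs)

    def columns_of(self, construct: str) -> list[int]:
        return [i for i, c in enumerate(self.column_constructs) if c == construct]

    def has_empty_category(self) -> bool:
        """True if any item in any group misses an observed category.

        Empty categories make the corresponding sample threshold infinite,
        so such replications are rejected and redrawn by the harness.
        """
        for x in self.responses.values():
            for j in range(x.shape[1]):
                counts = np.bincount(x[:, j], minlength=self.n_categories[j])
                if np.any(counts == 0):
                    return True
        return False

    def to_tsv(
        self, path_by_group: Mapping[str, str], one_based: bool = False
    ) -> None:
        """Export each group's responses as tab-separated text.

        Categories are written 0-based by default; ``one_based=True``
        re-codes them 1..K for software expecting that convention.
        """
        import pandas as pd

        for g, path in path_by_group.items():
            x = self.responses[g] + (1 if one_based else 0)
            pd.DataFrame(x, columns=list(self.column_labels)).to_csv(
                path, sep="\t", index=False
            )


def export_dataset(
    data: "MultiGroupDataset",
    measurements: Mapping[str, Mapping[str, MeasurementSpec]],
    structural: StructuralSpec,
    out_dir: str,
    one_based: bool = False,
) -> None:
    """Write per-group TSV files plus a sidecar of the generating parameters."""
    import json
    import os

    os.makedirs(out_dir, exist_ok=True)
    data.to_tsv(
        {g: os.path.join(out_dir, f"responses_{g}.tsv") for g in data.responses},
        one_based=one_based,
    )
    sidecar = {
        "structural": {
            "model_type": structural.model_type,
            "position": structural.position,
            "edges": [list(e) for e in structural.edges],
            "path_values": {g: list(v) for g, v in structural.path_values.items()},
            "exog_covariance": structural.exog_covariance,
            "target": structural.target,
        },
        "measurements": {
            g: {
                name: {
                    "discriminations": m.discriminations().tolist(),
                    "thresholds": [t.tolist() for t in m.threshold_list()],
                    "n_categories": m.n_categories,
                }
                for name, m in per_group.items()
            }
            for g, per_group in measurements.items()
        },
        "coding": "1-based" if one_based else "0-based",
    }
    with open(os.path.join(out_dir, "generating_parameters.json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def simulate_latent(
    spec: StructuralSpec, group: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw latent scores (n, n_latents) under the structural model.

    Exogenous latents are standard normal (with the spec's covariance when
    there are two); each endogenous latent is the path-weighted sum of its
    parents plus a normal residual with the spec's residual variance.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    names = spec.latent_names
    q = len(names)
    out = np.empty((n, q))
    exog = [names.index(e) for e in spec.exogenous]
    if len(exog) == 2 and spec.exog_covariance != 0.0:
        cov = np.array([[1.0, spec.exog_covariance], [spec.exog_covariance, 1.0]])
        out[:, exog] = rng.multivariate_normal(np.zeros(2), cov, size=n)
    else:
        for i in exog:
            out[:, i] = rng.standard_normal(n)
    paths = spec.paths(group)
    for i, name in enumerate(names):
        if name in spec.exogenous:
            continue
        pred = np.zeros(n)
        for (par, chi), v in paths.items():
            if chi == name:
                pred += v * out[:, names.index(par)]
        resid = spec.residual_variance(name, group)
        out[:, i] = pred + np.sqrt(resid) * rng.standard_normal(n)
    return out


def ordinal_responses(
    latent: np.ndarray, m: MeasurementSpec, rng: np.random.Generator
) -> np.ndarray:
    """Graded responses (n, n_items) of one construct given latent scores."""
    latent = np.asarray(latent, dtype=float).ravel()
    n = latent.shape[0]
    out = np.empty((n, m.n_items), dtype=np.int64)
    for j, item in enumerate(m.items):
        ystar = item.discrimination * latent + rng.standard_normal(n)
        out[:, j] = np.searchsorted(np.asarray(item.thresholds), ystar)
    return out


def marginal_category_probs(
    item: ItemParams, latent_mean: float = 0.0, latent_var: float = 1.0
) -> np.ndarray:
    """Analytic category probabilities of one item.

    With ``eta ~ N(mu, v)`` the latent response ``a*eta + eps`` is normal
    with mean ``a*mu`` and variance ``a**2 * v + 1``, so
    ``P(y = k) = Phi((b_{k+1} - a mu)/s) - Phi((b_k - a mu)/s)`` with
    ``s = sqrt(a**2 v + 1)`` and ``b_0 = -inf``, ``b_K = +inf``.
    """
    if latent_var <= 0:
        raise ValueError("latent_var must be positive")
    a = item.discrimination
    s = np.sqrt(a * a * latent_var + 1.0)
    z = (np.asarray(item.thresholds) - a * latent_mean) / s
    cum = np.concatenate(([0.0], norm.cdf(z), [1.0]))
    return np.diff(cum)


def simulate_condition_dataset(
    structural: StructuralSpec,
    measurements: Mapping[str, Mapping[str, MeasurementSpec]],
    n_per_group: int,
    rng: np.random.Generator,
) -> MultiGroupDataset:
    """Generate a two-group dataset for one design cell.

    ``measurements`` maps group -> latent name -> measurement spec; the
    target construct's focal spec carries the condition's non-invariance,
    all other constructs are measured identically in both groups.
    """
    responses: dict[str, np.ndarray] = {}
    names = structural.latent_names
    for g in GROUPS:
        latents = simulate_latent(structural, g, n_per_group, rng)
        blocks = []
        for i, name in enumerate(names):
            blocks.append(ordinal_responses(latents[:, i], measurements[g][name], rng))
        responses[g] = np.hstack(blocks)
    cols: list[str] = []
    labels: list[str] = []
    ncat: list[int] = []
    ref = measurements[GROUPS[0]]
    for name in names:
        m = ref[name]
        for j in range(m.n_items):
            cols.append(name)
            labels.append(f"{name}_{j + 1}")
            ncat.append(m.n_categories)
    return MultiGroupDataset(
        responses=responses,
        column_constructs=tuple(cols),
        column_labels=tuple(labels),
        n_categories=tuple(ncat),
    )
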