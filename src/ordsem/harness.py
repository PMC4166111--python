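"""Monte Carlo harness: replications, performance criteria and reports.

For each design cell the harness simulates two-group datasets, estimates
polychoric summaries, fits the cell's analysis model by DWLS and collects
the five performance criteria: convergence/admissibility rates, chi-square
calibration at nominal sizes 1/2/5/10%, power, relative bias, and 95%
CI coverage of every structural coefficient.  Replications with an empty
observed category in any item are rejected and redrawn from the next
random substream (counted and reported).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import chi2 as chi2_dist

from ordsem.design import (
    ConditionPopulation,
    ConditionSpec,
    analysis_spec,
    condition_grid,
    generating_population,
    grid_frame,
    sample_auxiliary_set,
)
from ordsem.model import (
    GroupParams,
    ModelSpec,
    TwoGroupOrdinalSEM,
    implied_moments,
    wald_ci,
)
from ordsem.populations import FOCAL, GROUPS, REFERENT, MeasurementSpec
from ordsem.simulate import simulate_condition_dataset

logger = logging.getLogger(__name__)

NOMINAL_LEVELS = (0.01, 0.02, 0.05, 0.10)
#: spawn key prefix reserved for the study-level auxiliary parameter draw
_AUX_KEY = 10**6


# ---------------------------------------------------------------------------
# performance criteria
# ---------------------------------------------------------------------------

def relative_bias(mean_estimate: float, true_value: float) -> float:
    """(mean estimate - truth)/truth; undefined at a zero true value."""
    if true_value == 0:
        raise ValueError("relative bias undefined for a zero true value")
    return (mean_estimate - true_value) / true_value


def coverage_rate(
    estimates: np.ndarray, ses: np.ndarray, true_value: float, level: float = 0.95
) -> float:
    """Share of Wald intervals (robust SE) containing the true value."""
    estimates = np.asarray(estimates, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if estimates.shape != ses.shape:
        raise ValueError("estimates and ses must have equal length")
    lo, hi = np.array([wald_ci(e, s, level) for e, s in zip(estimates, ses)]).T
    return float(np.mean((lo <= true_value) & (true_value <= hi)))


def power_rate(estimates: np.ndarray, ses: np.ndarray, crit: float = 1.959964) -> float:
    """Share of replications rejecting a zero coefficient (|z| >= 1.96)."""
    estimates = np.asarray(estimates, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    return float(np.mean(np.abs(estimates / ses) >= crit))


def chisq_calibration(
    adjusted_stats: np.ndarray,
    df: int,
    nominal_levels: Sequence[float] = NOMINAL_LEVELS,
) -> dict[float, float]:
    """Empirical rejection rates of the adjusted statistic per nominal size."""
    stats = np.asarray(adjusted_stats, dtype=float)
    out = {}
    for lv in nominal_levels:
        crit = chi2_dist.isf(lv, df)
        out[float(lv)] = float(np.mean(stats > crit))
    return out


# ---------------------------------------------------------------------------
# population moments / pseudo-true analysis
# ---------------------------------------------------------------------------

def population_group_params(
    population: ConditionPopulation, group: str
) -> GroupParams:
    """True generating parameters of one group as a GroupParams."""
    structural = population.structural
    layout = population.layout
    loadings, thresholds = [], []
    for name in structural.latent_names:
        m = population.measurements[group][name]
        loadings.extend(m.discriminations())
        thresholds.extend(m.threshold_list())
    q = len(structural.latent_names)
    latent_vars = np.array(
        [structural.residual_variance(l, group) for l in structural.latent_names]
    )
    return GroupParams(
        loadings=np.array(loadings),
        thresholds=thresholds,
        resid_vars=np.ones(layout.n_items),
        latent_means=np.zeros(q),
        latent_vars=latent_vars,
        exog_covs=np.array(
            [structural.exog_covariance] * len(layout.exog_cov_pairs)
        ),
        paths=np.array(structural.path_values[group]),
    )


def population_implied_stats(
    population: ConditionPopulation, group: str
) -> tuple[list[np.ndarray], np.ndarray]:
    """Population thresholds and latent-response correlations of one group."""
    gp = population_group_params(population, group)
    return implied_moments(gp, population.layout)


def pseudo_true_cell(
    condition: ConditionSpec,
    aux_specs: Sequence[MeasurementSpec] | None = None,
    target_table=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Deterministic surrogate for a cell: fit to population moments.

    Fits the cell's analysis model to the population-implied moments with
    unit weights (no sampling error, no randomness in the fit).  The
    resulting "pseudo-true" structural coefficients show the direction and
    rough magnitude of the asymptotic distortion caused by the strategy.
    """
    if aux_specs is None:
        aux_specs = sample_auxiliary_set(np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_AUX_KEY,))))
    population = generating_population(condition, aux_specs, target_table)
    spec = analysis_spec(condition, population)
    moments = {g: population_implied_stats(population, g) for g in GROUPS}
    model = TwoGroupOrdinalSEM.from_moments(spec, moments)
    res = model.fit()
    rows = []
    for edge in population.structural.edges:
        for g in GROUPS:
            true = population.structural.paths(g)[edge]
            est, _ = res.path(edge[0], edge[1], g)
            rows.append(
                {
                    "coefficient": f"{edge[0]}->{edge[1]}",
                    "group": g,
                    "true": true,
                    "pseudo_true": est,
                    "relative_bias": relative_bias(est, true),
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["converged"] = res.converged
    df.attrs["fmin"] = res.fmin
    return df


# ---------------------------------------------------------------------------
# replications
# ---------------------------------------------------------------------------

@dataclass
class ReplicationResult:
    converged: bool
    admissible: bool
    chi2: float
    df: int
    pvalue: float
    coefs: dict[tuple[str, str], tuple[float, float]]  # (edge label, group) -> (est, se)
    resimulations: int


def run_replication(
    condition: ConditionSpec,
    population: ConditionPopulation,
    spec: ModelSpec,
    n_per_group: int,
    master_seed: int,
    cell_id: int,
    rep: int,
    max_attempts: int = 100,
) -> ReplicationResult:
    """simulate -> polychoric (+ asymptotic cov) -> DWLS fit -> extract.

    Datasets with an empty item category are rejected and redrawn from the
    next substream; the number of rejections is recorded.
    """
    attempt = 0
    while True:
        ss = np.random.SeedSequence(master_seed, spawn_key=(cell_id, rep, attempt))
        rng = np.random.default_rng(ss)
        data = simulate_condition_dataset(
            population.structural, population.measurements, n_per_group, rng
        )
        if not data.has_empty_category():
            break
        attempt += 1
        if attempt >= max_attempts:
            raise RuntimeError(
                f"{condition.label}: {max_attempts} consecutive datasets with "
                "empty categories"
            )
    model = TwoGroupOrdinalSEM.from_data(data, spec)
    res = model.fit()
    coefs = {}
    for edge in population.structural.edges:
        for g in GROUPS:
            est, se = res.path(edge[0], edge[1], g)
            coefs[(f"{edge[0]}->{edge[1]}", g)] = (est, se)
    return ReplicationResult(
        converged=res.converged,
        admissible=res.admissible,
        chi2=res.chi2,
        df=res.df,
        pvalue=res.pvalue,
        coefs=coefs,
        resimulations=attempt,
    )


@dataclass
class CellResult:
    """Per-condition Monte Carlo metrics over converged admissible fits."""

    condition: ConditionSpec
    condition_id: int
    n_attempted: int
    n_converged: int
    n_admissible: int
    n_resimulations: int
    coef_stats: pd.DataFrame  # coefficient, group, true, mean, mc_sd, rel bias...
    chisq_rates: dict[float, float]
    df: int
    master_seed: int

    def to_dict(self) -> dict:
        d = {
            "condition_id": self.condition_id,
            **dataclasses.asdict(self.condition),
            "n_attempted": self.n_attempted,
            "n_converged": self.n_converged,
            "n_admissible": self.n_admissible,
            "n_resimulations": self.n_resimulations,
            "df": self.df,
            "master_seed": self.master_seed,
            "chisq_rates": {str(k): v for k, v in self.chisq_rates.items()},
            "coef_stats": self.coef_stats.to_dict(orient="records"),
        }
        return d


# ---------------------------------------------------------------------------
# study configuration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Runtime configuration of a (sub)study.

    ``profile="full"`` runs the study-scale 1,000 replications per cell;
    ``profile="scaled"`` the desk-scale 200.  An explicit ``reps`` wins.
    """

    conditions: list[int] | None = None  # condition ids; None = all 216
    reps: int | None = None
    n_per_group: int = 1000
    seed: int = 12345
    out: str = "results"
    jobs: int = 1
    profile: str = "full"
    target_table: list | None = None  # optional referent item table override

    def __post_init__(self) -> None:
        if self.reps is None:
            self.reps = 1000 if self.profile == "full" else 200
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.n_per_group < 100:
            raise ValueError("n_per_group must be >= 100")

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)


# ---------------------------------------------------------------------------
# cells and studies
# ---------------------------------------------------------------------------

def study_aux_specs(master_seed: int) -> list[MeasurementSpec]:
    """The study's auxiliary measurement models, drawn once per master seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(_AUX_KEY,))
    return sample_auxiliary_set(np.random.default_rng(ss))


def run_cell(
    condition: ConditionSpec,
    config: StudyConfig,
    cell_id: int | None = None,
    aux_specs: Sequence[MeasurementSpec] | None = None,
) -> CellResult:
    """Run all replications of one cell and compute its metrics.

    Metrics are computed over converged, admissible replications only;
    the attempted/converged/admissible counts are always reported.
    Replication substreams depend only on (master seed, cell id, rep), so
    results are reproducible and independent of execution order.
    """
    if cell_id is None:
        cell_id = condition_grid().index(condition)
    if aux_specs is None:
        aux_specs = study_aux_specs(config.seed)
    population = generating_population(condition, aux_specs, config.target_table)
    spec = analysis_spec(condition, population)

    def one(rep: int) -> ReplicationResult:
        return run_replication(
            condition, population, spec, config.n_per_group, config.seed, cell_id, rep
        )

    if config.jobs > 1:
        from joblib import Parallel, delayed

        reps = Parallel(n_jobs=config.jobs)(
            delayed(one)(r) for r in range(config.reps)
        )
    else:
        reps = [one(r) for r in range(config.reps)]

    kept = [r for r in reps if r.converged and r.admissible]
    n_conv = sum(r.converged for r in reps)
    n_adm = sum(r.converged and r.admissible for r in reps)
    n_resim = sum(r.resimulations for r in reps)
    rows = []
    structural = population.structural
    for edge in structural.edges:
        label = f"{edge[0]}->{edge[1]}"
        for g in GROUPS:
            true = structural.paths(g)[edge]
            est = np.array([r.coefs[(label, g)][0] for r in kept])
            se = np.array([r.coefs[(label, g)][1] for r in kept])
            rows.append(
                {
                    "coefficient": label,
                    "group": g,
                    "true": true,
                    "mean": float(est.mean()) if len(est) else np.nan,
                    "mc_sd": float(est.std(ddof=1)) if len(est) > 1 else np.nan,
                    "mean_se": float(se.mean()) if len(se) else np.nan,
                    "relative_bias": relative_bias(float(est.mean()), true)
                    if len(est)
                    else np.nan,
                    "coverage": coverage_rate(est, se, true) if len(est) else np.nan,
                    "power": power_rate(est, se) if len(est) else np.nan,
                    "n_used": len(est),
                }
            )
    coef_stats = pd.DataFrame(rows)
    stats = np.array([r.chi2 for r in kept])
    df_model = kept[0].df if kept else reps[0].df
    rates = chisq_calibration(stats, df_model) if len(stats) else {}
    logger.info(
        "%s: %d/%d converged-admissible, %d resimulations",
        condition.label,
        n_adm,
        config.reps,
        n_resim,
    )
    return CellResult(
        condition=condition,
        condition_id=cell_id,
        n_attempted=config.reps,
        n_converged=n_conv,
        n_admissible=n_adm,
        n_resimulations=n_resim,
        coef_stats=coef_stats,
        chisq_rates=rates,
        df=df_model,
        master_seed=config.seed,
    )


def run_study(config: StudyConfig) -> list[CellResult]:
    """Run the configured subset of the 216-cell grid."""
    grid = condition_grid()
    ids = config.conditions if config.conditions is not None else range(len(grid))
    aux = study_aux_specs(config.seed)
    out = []
    for cid in ids:
        out.append(run_cell(grid[cid], config, cell_id=cid, aux_specs=aux))
    return out


def report_tables(
    results: Iterable[CellResult],
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Relative-bias and coverage tables plus a diagnostics payload.

    Both tables have one row per condition and one column per
    coefficient/group; the diagnostics dictionary carries convergence,
    power and chi-square calibration per condition.
    """
    bias_rows, cov_rows, diag = [], [], {}
    for res in results:
        key = {
            "condition_id": res.condition_id,
            "strategy": res.condition.strategy,
            "noninv_type": res.condition.noninv_type,
            "level": res.condition.level,
            "model_type": res.condition.model_type,
            "position": res.condition.position,
        }
        brow, crow = dict(key), dict(key)
        for _, r in res.coef_stats.iterrows():
            col = f"{r['coefficient']}:{r['group']}"
            brow[col] = r["relative_bias"]
            crow[col] = r["coverage"]
        bias_rows.append(brow)
        cov_rows.append(crow)
        diag[str(res.condition_id)] = {
            "label": res.condition.label,
            "n_attempted": res.n_attempted,
            "n_converged": res.n_converged,
            "n_admissible": res.n_admissible,
            "n_resimulations": res.n_resimulations,
            "chisq_rates": {str(k): v for k, v in res.chisq_rates.items()},
            "power": {
                f"{r['coefficient']}:{r['group']}": r["power"]
                for _, r in res.coef_stats.iterrows()
            },
        }
    return pd.DataFrame(bias_rows), pd.DataFrame(cov_rows), diag


def write_reports(
    results: Sequence[CellResult], config: StudyConfig, out_dir: str | None = None
) -> None:
    """Write table1/table2 CSVs, diagnostics JSON and the config echo."""
    out = out_dir or config.out
    os.makedirs(out, exist_ok=True)
    table1, table2, diag = report_tables(results)
    table1.to_csv(os.path.join(out, "table1_relative_bias.csv"), index=False)
    table2.to_csv(os.path.join(out, "table2_coverage.csv"), index=False)
    with open(os.path.join(out, "diagnostics.json"), "w") as fh:
        json.dump(diag, fh, indent=1)
    long = pd.concat(
        [
            r.coef_stats.assign(condition_id=r.condition_id, label=r.condition.label)
            for r in results
        ],
        ignore_index=True,
    )
    long.to_csv(os.path.join(out, "per_coefficient_long.csv"), index=False)
    with open(os.path.join(out, "config_echo.yaml"), "w") as fh:
        fh.write(config.to_yaml())
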