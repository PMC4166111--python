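"""Two-stage maximum-likelihood polychoric correlations.

Stage one estimates each item's thresholds from its univariate margins
(normal quantiles of the cumulative proportions).  Stage two maximizes,
pair by pair, the bivariate multinomial likelihood over the latent
correlation with the thresholds held fixed.  The asymptotic covariance of
the stacked estimates (thresholds first, then the unique correlations) is
obtained from the estimating-equation sandwich: the per-observation
scores/moment functions combined with the analytic expected Jacobian
(Jöreskog-style), which is the weight-matrix ingredient for DWLS fitting
and its robust corrections.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from ordsem._bvn import bvn_cdf, bvn_cdf_batch, bvn_pdf
from scipy.special import ndtr

logger = logging.getLogger(__name__)

#: absolute bound applied to pairwise correlation estimates
RHO_BOUND = 0.999
_TINY = 1e-300


class EmptyCategoryError(ValueError):
    """An item has an observed category with zero count."""


@dataclass
class PolychoricSummary:
    """Thresholds, polychoric correlations and their asymptotic covariance.

    ``stat_vector`` stacks all thresholds (item by item) followed by the
    unique correlations in row-major upper-triangle order; ``gamma`` is the
    asymptotic covariance matrix of ``sqrt(n) * stat_vector``.
    """

    thresholds: list[np.ndarray]
    corr: np.ndarray
    n: int
    n_categories: np.ndarray
    gamma: np.ndarray | None = None

    @property
    def n_items(self) -> int:
        return len(self.thresholds)

    @property
    def pair_index(self) -> tuple[np.ndarray, np.ndarray]:
        return np.triu_indices(self.n_items, k=1)

    @property
    def stat_vector(self) -> np.ndarray:
        iu = self.pair_index
        return np.concatenate([np.concatenate(self.thresholds), self.corr[iu]])

    def to_json(self, path: str) -> None:
        payload = {
            "n": int(self.n),
            "n_categories": [int(k) for k in self.n_categories],
            "thresholds": [t.tolist() for t in self.thresholds],
            "corr": self.corr.tolist(),
            "gamma": None if self.gamma is None else self.gamma.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "PolychoricSummary":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            thresholds=[np.array(t) for t in payload["thresholds"]],
            corr=np.array(payload["corr"]),
            n=payload["n"],
            n_categories=np.array(payload["n_categories"]),
            gamma=None if payload["gamma"] is None else np.array(payload["gamma"]),
        )


def univariate_thresholds(category_counts: np.ndarray) -> np.ndarray:
    """Sample thresholds: normal quantiles of cumulative category proportions."""
    counts = np.asarray(category_counts, dtype=float)
    if np.any(counts <= 0):
        raise EmptyCategoryError(
            f"all categories need positive counts, got {counts.tolist()}"
        )
    cum = np.cumsum(counts)[:-1] / counts.sum()
    return norm.ppf(cum)


def _padded(thr: np.ndarray) -> np.ndarray:
    return np.concatenate(([-np.inf], np.asarray(thr, dtype=float), [np.inf]))


def bivariate_cell_probs(rho: float, thr_i: np.ndarray, thr_j: np.ndarray) -> np.ndarray:
    """Rectangle probabilities of the bivariate normal over the cut grid."""
    if abs(rho) >= 1.0:
        raise ValueError("|rho| must be < 1")
    ti, tj = _padded(thr_i), _padded(thr_j)
    cdf = bvn_cdf(ti[:, None], tj[None, :], float(rho))
    return np.diff(np.diff(cdf, axis=0), axis=1)


def _pair_loglik(rho: float, table: np.ndarray, thr_i: np.ndarray, thr_j: np.ndarray) -> float:
    probs = bivariate_cell_probs(rho, thr_i, thr_j)
    return float(np.sum(table * np.log(np.maximum(probs, _TINY))))


def polychoric_pair(
    contingency_table: np.ndarray, thr_i: np.ndarray, thr_j: np.ndarray
) -> float:
    """ML polychoric correlation with thresholds fixed at stage-one values."""
    table = np.asarray(contingency_table, dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise EmptyCategoryError("contingency table has a zero margin")
    res = minimize_scalar(
        lambda r: -_pair_loglik(r, table, thr_i, thr_j),
        bounds=(-RHO_BOUND, RHO_BOUND),
        method="bounded",
        options={"xatol": 1e-7},
    )
    rho = float(res.x)
    if abs(rho) >= RHO_BOUND - 1e-6:
        rho = float(np.sign(rho) * RHO_BOUND)
        logger.warning("polychoric correlation clipped at ±%.3f", RHO_BOUND)
    return rho


def _batched_rho(
    data: np.ndarray, thresholds: list[np.ndarray], n_categories: np.ndarray
) -> np.ndarray:
    """All pairwise ML correlations by vectorized Fisher scoring.

    Pairs are grouped by category-count shape and iterated jointly; each
    scoring step solves the same score equation as :func:`polychoric_pair`
    (the two agree to optimizer tolerance) but with one vectorized
    bivariate-normal evaluation per iteration for all pairs at once.
    """
    from collections import defaultdict

    n, p = data.shape
    corr = np.eye(p)
    batches: dict[tuple[int, int], list[tuple[int, int]]] = defaultdict(list)
    for i in range(p):
        for j in range(i + 1, p):
            batches[(int(n_categories[i]), int(n_categories[j]))].append((i, j))
    for (ki, kj), pairs in batches.items():
        m = len(pairs)
        ti = np.array([_padded(thresholds[i]) for i, _ in pairs])
        tj = np.array([_padded(thresholds[j]) for _, j in pairs])
        tables = np.array(
            [
                np.bincount(data[:, i] * kj + data[:, j], minlength=ki * kj).reshape(
                    ki, kj
                )
                for i, j in pairs
            ],
            dtype=float,
        )
        cgrid = np.zeros((m, ki + 1, kj + 1))
        cgrid[:, -1, :] = ndtr(tj)
        cgrid[:, :, -1] = ndtr(ti)
        hi = np.broadcast_to(ti[:, 1:-1, None], (m, ki - 1, kj - 1))
        kk = np.broadcast_to(tj[:, None, 1:-1], (m, ki - 1, kj - 1))
        hp, kp = ti[:, :, None], tj[:, None, :]
        rho = np.zeros(m)
        for _ in range(100):
            cgrid[:, 1:-1, 1:-1] = bvn_cdf_batch(hi, kk, rho[:, None, None])
            probs = np.maximum(np.diff(np.diff(cgrid, axis=1), axis=2), 1e-12)
            dp = np.diff(np.diff(bvn_pdf(hp, kp, rho[:, None, None]), axis=1), axis=2)
            ratio = dp / probs
            score = np.einsum("mab,mab->m", tables, ratio)
            info = np.einsum("mab,mab->m", tables, ratio * ratio)
            step = np.clip(score / np.maximum(info, 1e-10), -0.5, 0.5)
            new = np.clip(rho + step, -RHO_BOUND, RHO_BOUND)
            delta = float(np.max(np.abs(new - rho)))
            rho = new
            if delta < 1e-10:
                break
        else:
            logger.warning("polychoric scoring hit the iteration cap")
        if np.any(np.abs(rho) >= RHO_BOUND - 1e-9):
            logger.warning("polychoric correlation clipped at ±%.3f", RHO_BOUND)
        for (i, j), r in zip(pairs, rho):
            corr[i, j] = corr[j, i] = float(r)
    return corr


def polychoric_matrix(
    group_data: np.ndarray, n_categories: np.ndarray | None = None
) -> PolychoricSummary:
    """Thresholds and all pairwise polychoric correlations of one group."""
    data = np.asarray(group_data)
    n, p = data.shape
    if p < 2:
        raise ValueError("need at least 2 items")
    if n_categories is None:
        n_categories = data.max(axis=0) + 1
    n_categories = np.asarray(n_categories, dtype=int)
    thresholds = []
    for j in range(p):
        counts = np.bincount(data[:, j], minlength=n_categories[j])
        thresholds.append(univariate_thresholds(counts))
    corr = _batched_rho(data, thresholds, n_categories)
    return PolychoricSummary(
        thresholds=thresholds, corr=corr, n=n, n_categories=n_categories
    )


def _pair_derivatives(
    rho: float, thr_i: np.ndarray, thr_j: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cell probabilities and their derivatives for one item pair.

    Returns ``(probs, dp_drho, dcdf_dh)`` where ``dcdf_dh[a, b]`` is the
    partial of Phi_2(t_i[a], t_j[b]; rho) w.r.t. its first argument over
    the padded grid.
    """
    ti, tj = _padded(thr_i), _padded(thr_j)
    probs = bivariate_cell_probs(rho, thr_i, thr_j)
    pdf = bvn_pdf(ti[:, None], tj[None, :], rho)
    dp_drho = np.diff(np.diff(pdf, axis=0), axis=1)  # Plackett's identity
    om = np.sqrt(1.0 - rho * rho)
    with np.errstate(invalid="ignore"):
        cond = ndtr((tj[None, :] - rho * ti[:, None]) / om)
    # d Phi2(h, k)/dh = phi(h) Phi((k - rho h)/sqrt(1-rho^2)); at k = +inf the
    # conditional CDF is 1, at k = -inf or infinite h the derivative is 0
    phi_ti = np.where(np.isfinite(ti), np.exp(-0.5 * np.minimum(ti, 38.0) ** 2) / np.sqrt(2 * np.pi), 0.0)
    dcdf_dh = phi_ti[:, None] * np.where(
        tj[None, :] == np.inf, 1.0, np.where(tj[None, :] == -np.inf, 0.0, cond)
    )
    dcdf_dh = np.where(np.isfinite(ti[:, None]), dcdf_dh, 0.0)
    return probs, dp_drho, dcdf_dh


def asymptotic_cov(group_data: np.ndarray, summary: PolychoricSummary) -> np.ndarray:
    """Asymptotic covariance of sqrt(n) times the stacked (thresholds, rho).

    Estimating-equation sandwich ``A^{-1} M A^{-T}``: ``M`` is the sample
    second moment of the per-observation moment functions (cumulative
    indicators for thresholds, pairwise likelihood scores for the
    correlations); ``A`` is the expected negative Jacobian, assembled
    analytically from bivariate normal densities and conditional CDFs.
    The result is stored on ``summary.gamma`` and returned.
    """
    data = np.asarray(group_data)
    n, p = data.shape
    if n != summary.n or p != summary.n_items:
        raise ValueError("summary was not computed from this data")
    ncat = summary.n_categories
    thr_sizes = [len(t) for t in summary.thresholds]
    thr_offset = np.concatenate(([0], np.cumsum(thr_sizes)))
    n_thr = int(thr_offset[-1])
    iu, ju = summary.pair_index
    n_rho = len(iu)
    dim = n_thr + n_rho

    psi = np.empty((n, dim))
    a_mat = np.zeros((dim, dim))

    # threshold moment functions and Jacobian block
    for j in range(p):
        tau = summary.thresholds[j]
        for k, t in enumerate(tau):
            col = thr_offset[j] + k
            psi[:, col] = (data[:, j] <= k) - norm.cdf(t)
            a_mat[col, col] = norm.pdf(t)

    # correlation scores and information blocks
    for idx, (i, j) in enumerate(zip(iu, ju)):
        rho = summary.corr[i, j]
        rho = np.clip(rho, -RHO_BOUND, RHO_BOUND)
        ti, tj = summary.thresholds[i], summary.thresholds[j]
        probs, dp_drho, dcdf_dh = _pair_derivatives(rho, ti, tj)
        probs_j, dp_drho_j, dcdf_dh_j = (
            probs.T,
            dp_drho.T,
            _pair_derivatives(rho, tj, ti)[2],
        )
        probs_safe = np.maximum(probs, _TINY)
        score_cell = dp_drho / probs_safe
        col = n_thr + idx
        psi[:, col] = score_cell[data[:, i], data[:, j]]
        a_mat[col, col] = float(np.sum(dp_drho * dp_drho / probs_safe))
        # cross-information with the two items' thresholds:
        # d prob[a,b] / d t_i[m] = Gh[m, b] * (delta_{m,a+1} - delta_{m,a})
        for (item, thr, dcdf, pr, dpr) in (
            (i, ti, dcdf_dh, probs_safe, dp_drho),
            (j, tj, dcdf_dh_j, probs_j, dp_drho_j),
        ):
            pr = np.maximum(pr, _TINY)
            gh = np.diff(dcdf, axis=1)  # (K_item+1, K_other)
            ratio = dpr / pr  # cells indexed (item cat, other cat)
            for m in range(1, len(thr) + 1):
                # cells a = m-1 (upper edge) and a = m (lower edge)
                val = float(np.sum(gh[m] * (ratio[m - 1] - ratio[m])))
                a_mat[col, thr_offset[item] + m - 1] = val

    m_mat = psi.T @ psi / n
    try:
        ainv = np.linalg.inv(a_mat)
    except np.linalg.LinAlgError:
        warnings.warn("singular expected Jacobian; ridge-stabilized", RuntimeWarning)
        ainv = np.linalg.inv(a_mat + 1e-8 * np.eye(dim))
    gamma = ainv @ m_mat @ ainv.T
    gamma = (gamma + gamma.T) / 2.0
    summary.gamma = gamma
    return gamma
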