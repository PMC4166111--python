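"""Two-group SEM for ordinal indicators fitted by DWLS with robust corrections.

The model is the theta-parameterized categorical factor model: item latent
responses ``y* = Lambda eta + eps`` with ``Cov(eps) = Theta`` (diagonal),
latent structure ``eta = B eta + zeta`` with ``Cov(zeta) = Psi``, and
thresholds cutting ``y*`` into ordered categories.  The fitted statistics
are the standardized thresholds and latent-response correlations estimated
by :mod:`ordsem.polychoric`; the discrepancy function is diagonally
weighted least squares

``F = sum_g (n_g/N) (s_g - sigma_g(theta))' diag(Gamma_g)^{-1} (s_g - sigma_g(theta))``

minimized by a Levenberg--Marquardt Gauss--Newton iteration with
complex-step Jacobians.  Standard errors come from the full-weight sandwich
and the test statistic is the scaled-and-shifted (mean-and-variance
adjusted) chi-square at the model's nominal degrees of freedom -- the
WLSMV division of labor.

The public surface is statsmodels-like: :class:`TwoGroupOrdinalSEM` is the
model object, :meth:`TwoGroupOrdinalSEM.fit` returns an
:class:`OrdinalSEMResults` with estimates, robust standard errors,
diagnostics and a :meth:`~OrdinalSEMResults.summary` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from ordsem.polychoric import PolychoricSummary, asymptotic_cov, polychoric_matrix
from ordsem.populations import FOCAL, GROUPS, REFERENT

__all__ = [
    "ModelLayout",
    "ModelSpec",
    "GroupParams",
    "TwoGroupOrdinalSEM",
    "OrdinalSEMResults",
    "implied_moments",
    "dwls_fit",
    "robust_corrections",
    "admissibility",
    "wald_ci",
]

#: variance estimates below this are treated as boundary (Heywood) solutions
VARIANCE_FLOOR = 1e-6
_CSTEP = 1e-30


@dataclass(frozen=True)
class ModelLayout:
    """Construct/item layout shared by both groups."""

    latent_names: tuple[str, ...]
    column_constructs: tuple[str, ...]  # latent name per item column
    n_categories: tuple[int, ...]  # per item column
    edges: tuple[tuple[str, str], ...]  # structural paths (parent, child)
    exog_cov_pairs: tuple[tuple[str, str], ...] = ()

    @property
    def n_items(self) -> int:
        return len(self.column_constructs)

    @property
    def n_latent(self) -> int:
        return len(self.latent_names)

    def construct_index(self) -> np.ndarray:
        lut = {n: i for i, n in enumerate(self.latent_names)}
        return np.array([lut[c] for c in self.column_constructs])

    def first_items(self) -> dict[str, int]:
        """Column index of the first (anchor) item of each construct."""
        out: dict[str, int] = {}
        for j, c in enumerate(self.column_constructs):
            out.setdefault(c, j)
        return out


@dataclass
class GroupParams:
    """All theta-parameterization parameters of one group."""

    loadings: np.ndarray
    thresholds: list[np.ndarray]
    resid_vars: np.ndarray
    latent_means: np.ndarray
    latent_vars: np.ndarray
    exog_covs: np.ndarray
    paths: np.ndarray


def implied_moments(
    params: GroupParams, layout: ModelLayout
) -> tuple[list[np.ndarray], np.ndarray]:
    """Model-implied standardized thresholds and latent-response correlations.

    ``Sigma* = Lambda Sigma_eta Lambda' + Theta``; the implied polychoric
    correlation matrix is ``D^{-1/2} Sigma* D^{-1/2}`` with
    ``D = diag(Sigma*)``, and the implied standardized threshold for
    category ``k`` of item ``j`` is ``(b_jk - lambda_j' mu_eta)/sqrt(D_jj)``.
    """
    q = layout.n_latent
    names = layout.latent_names
    b_mat = np.zeros((q, q), dtype=params.paths.dtype)
    for e, (par, chi) in enumerate(layout.edges):
        b_mat[names.index(chi), names.index(par)] = params.paths[e]
    psi = np.zeros((q, q), dtype=np.result_type(params.latent_vars, params.exog_covs))
    psi[np.arange(q), np.arange(q)] = params.latent_vars
    for e, (l1, l2) in enumerate(layout.exog_cov_pairs):
        i, j = names.index(l1), names.index(l2)
        psi[i, j] = psi[j, i] = params.exog_covs[e]
    inv = np.linalg.inv(np.eye(q) - b_mat)
    sigma_eta = inv @ psi @ inv.T
    mu_eta = params.latent_means  # saturated (direct) latent mean structure
    cidx = layout.construct_index()
    a = params.loadings
    lam_sigma = a[:, None] * sigma_eta[cidx, :]
    sigma_star = lam_sigma[:, cidx] * a[None, :]
    d = np.array(sigma_star.diagonal() + params.resid_vars)
    sd = np.sqrt(d)
    mu_star = a * mu_eta[cidx]
    thr = [
        (np.asarray(t) - mu_star[j]) / sd[j] for j, t in enumerate(params.thresholds)
    ]
    corr = sigma_star / np.outer(sd, sd)
    corr[np.arange(len(a)), np.arange(len(a))] = 1.0
    return thr, corr


FIXED = "fixed"
FREE = "free"
EQUAL = "equal"  # focal slot tied to the referent group's parameter


class ModelSpec:
    """Parameter statuses and start/fixed values of a two-group model.

    Every parameter slot ``(kind, where, group)`` has a status: ``"fixed"``
    (held at its value), ``"free"``, or -- for focal slots -- ``"equal"``
    (shares the referent group's parameter).  ``values`` holds fixed values
    and starting values (truth starts in simulations).  Variance-type slots
    are optimized on the log scale internally.
    """

    def __init__(
        self,
        layout: ModelLayout,
        status: Mapping[tuple, str],
        values: Mapping[tuple, float],
    ) -> None:
        self.layout = layout
        self.status = dict(status)
        self.values = dict(values)
        self._build()

    # --- slot enumeration -------------------------------------------------
    def slots(self, group: str) -> list[tuple]:
        lay = self.layout
        out: list[tuple] = []
        for j in range(lay.n_items):
            out.append(("a", j, group))
        for j in range(lay.n_items):
            for k in range(lay.n_categories[j] - 1):
                out.append(("b", j, k, group))
        for j in range(lay.n_items):
            out.append(("theta", j, group))
        for l in lay.latent_names:
            out.append(("alpha", l, group))
        for l in lay.latent_names:
            out.append(("psi", l, group))
        for pr in lay.exog_cov_pairs:
            out.append(("lcov", pr, group))
        for e in lay.edges:
            out.append(("beta", e, group))
        return out

    @staticmethod
    def _is_variance(slot: tuple) -> bool:
        return slot[0] in ("theta", "psi")

    @staticmethod
    def slot_name(slot: tuple) -> str:
        kind = slot[0]
        if kind == "a":
            return f"lambda[{slot[1]}]:{slot[2]}"
        if kind == "b":
            return f"tau[{slot[1]},{slot[2] + 1}]:{slot[3]}"
        if kind == "theta":
            return f"theta[{slot[1]}]:{slot[2]}"
        if kind == "alpha":
            return f"alpha[{slot[1]}]:{slot[2]}"
        if kind == "psi":
            return f"psi[{slot[1]}]:{slot[2]}"
        if kind == "lcov":
            return f"psi[{slot[1][0]},{slot[1][1]}]:{slot[2]}"
        if kind == "beta":
            return f"beta[{slot[1][0]}->{slot[1][1]}]:{slot[2]}"
        raise KeyError(kind)

    def _build(self) -> None:
        """Assign free-parameter indices and flat slot layout."""
        self.all_slots = self.slots(REFERENT) + self.slots(FOCAL)
        self.slot_pos = {s: i for i, s in enumerate(self.all_slots)}
        free_of: dict[tuple, int] = {}
        self.free_slots: list[tuple] = []
        for slot in self.all_slots:
            st = self.status.get(slot, FREE)
            if st == FREE:
                free_of[slot] = len(self.free_slots)
                self.free_slots.append(slot)
            elif st == EQUAL:
                if slot[-1] != FOCAL:
                    raise ValueError(f"'equal' status only valid for focal slots: {slot}")
                ref_slot = slot[:-1] + (REFERENT,)
                if self.status.get(ref_slot, FREE) == FIXED:
                    # equality to a fixed referent value is just fixing
                    self.status[slot] = FIXED
                    self.values[slot] = self.values[ref_slot]
            elif st != FIXED:
                raise ValueError(f"unknown status {st!r} for {slot}")
        # second pass resolves EQUAL links to referent free indices
        self.map_free: list[tuple[int, int]] = []  # (flat slot index, free index)
        base = np.zeros(len(self.all_slots))
        for i, slot in enumerate(self.all_slots):
            st = self.status.get(slot, FREE)
            if st == FIXED:
                base[i] = self.values[slot]
            elif st == FREE:
                self.map_free.append((i, free_of[slot]))
            else:  # EQUAL
                ref_slot = slot[:-1] + (REFERENT,)
                self.map_free.append((i, free_of[ref_slot]))
        self.base = base
        self.map_rows = np.array([r for r, _ in self.map_free], dtype=int)
        self.map_cols = np.array([c for _, c in self.map_free], dtype=int)
        self.log_mask = np.array(
            [self._is_variance(s) for s in self.free_slots], dtype=bool
        )

    @property
    def n_free(self) -> int:
        return len(self.free_slots)

    def start_vector(self, values: Mapping[tuple, float] | None = None) -> np.ndarray:
        """Free-parameter start values on the internal (log-variance) scale."""
        vals = dict(self.values)
        if values:
            vals.update(values)
        x = np.array([vals[s] for s in self.free_slots], dtype=float)
        x[self.log_mask] = np.log(np.maximum(x[self.log_mask], VARIANCE_FLOOR))
        return x

    def natural(self, z: np.ndarray) -> np.ndarray:
        """Map internal coordinates to natural parameter values."""
        x = np.array(z, copy=True)
        x[self.log_mask] = np.exp(x[self.log_mask])
        return x

    def slot_vector(self, z: np.ndarray) -> np.ndarray:
        x = self.natural(z)
        out = self.base.astype(x.dtype) if np.iscomplexobj(x) else self.base.copy()
        out[self.map_rows] = x[self.map_cols]
        return out

    def group_params(self, slot_vec: np.ndarray, group: str) -> GroupParams:
        lay = self.layout
        p, q = lay.n_items, lay.n_latent
        t_sizes = [k - 1 for k in lay.n_categories]
        t_tot = sum(t_sizes)
        gsz = 2 * p + t_tot + 2 * q + len(lay.exog_cov_pairs) + len(lay.edges)
        off = 0 if group == REFERENT else gsz
        a = slot_vec[off : off + p]
        off2 = off + p
        thresholds = []
        for j in range(p):
            thresholds.append(slot_vec[off2 : off2 + t_sizes[j]])
            off2 += t_sizes[j]
        theta = slot_vec[off2 : off2 + p]
        off2 += p
        alpha = slot_vec[off2 : off2 + q]
        off2 += q
        psi = slot_vec[off2 : off2 + q]
        off2 += q
        lcov = slot_vec[off2 : off2 + len(lay.exog_cov_pairs)]
        off2 += len(lay.exog_cov_pairs)
        beta = slot_vec[off2 : off2 + len(lay.edges)]
        return GroupParams(
            loadings=a,
            thresholds=thresholds,
            resid_vars=theta,
            latent_means=alpha,
            latent_vars=psi,
            exog_covs=lcov,
            paths=beta,
        )

    def describe(self) -> pd.DataFrame:
        """One row per slot: group, name, status, value -- serializable view."""
        rows = []
        for slot in self.all_slots:
            rows.append(
                {
                    "name": self.slot_name(slot),
                    "group": slot[-1],
                    "status": self.status.get(slot, FREE),
                    "value": self.values.get(slot, np.nan),
                }
            )
        return pd.DataFrame(rows)


def _stat_dim(layout: ModelLayout) -> int:
    p = layout.n_items
    return sum(k - 1 for k in layout.n_categories) + p * (p - 1) // 2


class TwoGroupOrdinalSEM:
    """Two-group DWLS estimator for the ordinal-indicator SEM.

    Parameters
    ----------
    summaries
        Mapping group -> :class:`~ordsem.polychoric.PolychoricSummary`
        (with ``gamma`` populated for WLSMV weighting; summaries without
        ``gamma`` get unit weights -- useful for pseudo-true fits to
        population moments).
    spec
        The :class:`ModelSpec` defining statuses and start values.
    """

    def __init__(self, summaries: Mapping[str, PolychoricSummary], spec: ModelSpec):
        self.spec = spec
        self.summaries = dict(summaries)
        lay = spec.layout
        dim = _stat_dim(lay)
        self.iu = np.triu_indices(lay.n_items, k=1)
        s_parts, w_parts, cov_parts = [], [], []
        n_tot = sum(self.summaries[g].n for g in GROUPS)
        self.n_per_group = {g: self.summaries[g].n for g in GROUPS}
        self.n_total = n_tot
        for g in GROUPS:
            sm = self.summaries[g]
            if len(sm.stat_vector) != dim:
                raise ValueError("summary dimension does not match layout")
            s_parts.append(sm.stat_vector)
            frac = sm.n / n_tot
            if sm.gamma is not None:
                dg = np.maximum(np.diag(sm.gamma), 1e-12)
                w_parts.append(frac / dg)
                cov_parts.append(sm.gamma / sm.n)
            else:
                w_parts.append(np.full(dim, frac))
                cov_parts.append(None)
        self.s = np.concatenate(s_parts)
        self.w = np.concatenate(w_parts)  # V diagonal incl. group fractions
        self._cov_parts = cov_parts
        self.dim = dim
        # precomputed index structures for the fast implied-moment path
        p, q = lay.n_items, lay.n_latent
        t_sizes = np.array([k - 1 for k in lay.n_categories])
        self._p, self._q, self._ttot = p, q, int(t_sizes.sum())
        self._cidx = lay.construct_index()
        self._thr_item = np.repeat(np.arange(p), t_sizes)
        self._nlcov = len(lay.exog_cov_pairs)
        self._nedge = len(lay.edges)
        self._gsz = 2 * p + self._ttot + 2 * q + self._nlcov + self._nedge
        names = lay.latent_names
        self._edge_child = np.array([names.index(c) for _, c in lay.edges], dtype=int)
        self._edge_parent = np.array([names.index(a) for a, _ in lay.edges], dtype=int)
        self._lcov_i = np.array([names.index(a) for a, _ in lay.exog_cov_pairs], dtype=int)
        self._lcov_j = np.array([names.index(b) for _, b in lay.exog_cov_pairs], dtype=int)

    # --- constructors -----------------------------------------------------
    @classmethod
    def from_data(
        cls,
        data,
        spec: ModelSpec,
        compute_gamma: bool = True,
    ) -> "TwoGroupOrdinalSEM":
        """Build from a :class:`~ordsem.simulate.MultiGroupDataset` (or a
        mapping group -> integer response matrix)."""
        responses = getattr(data, "responses", data)
        ncat = np.asarray(spec.layout.n_categories)
        summaries = {}
        for g in GROUPS:
            sm = polychoric_matrix(responses[g], ncat)
            if compute_gamma:
                asymptotic_cov(responses[g], sm)
            summaries[g] = sm
        return cls(summaries, spec)

    @classmethod
    def from_moments(
        cls,
        spec: ModelSpec,
        moments: Mapping[str, tuple[Sequence[np.ndarray], np.ndarray]],
        n_per_group: int = 1000,
    ) -> "TwoGroupOrdinalSEM":
        """Build from (thresholds, correlation matrix) per group.

        Used for deterministic pseudo-true fits: the "data" are population
        implied moments and the weight matrix is the identity.
        """
        summaries = {}
        for g in GROUPS:
            thr, corr = moments[g]
            summaries[g] = PolychoricSummary(
                thresholds=[np.asarray(t, dtype=float) for t in thr],
                corr=np.asarray(corr, dtype=float),
                n=n_per_group,
                n_categories=np.asarray(spec.layout.n_categories),
            )
        return cls(summaries, spec)

    # --- implied statistics ----------------------------------------------
    def sigma(self, z: np.ndarray) -> np.ndarray:
        """Stacked implied statistics for internal parameter vector ``z``.

        Index-precomputed equivalent of :func:`implied_moments` (the two
        agree to machine precision); complex-safe for complex-step
        differentiation.
        """
        slot_vec = self.spec.slot_vector(z)
        p, q, t_tot = self._p, self._q, self._ttot
        dt = slot_vec.dtype
        parts = []
        eye = np.eye(q)
        for gi in range(2):
            off = gi * self._gsz
            a = slot_vec[off : off + p]
            bflat = slot_vec[off + p : off + p + t_tot]
            theta = slot_vec[off + p + t_tot : off + 2 * p + t_tot]
            o2 = off + 2 * p + t_tot
            alpha = slot_vec[o2 : o2 + q]
            psi = slot_vec[o2 + q : o2 + 2 * q]
            o3 = o2 + 2 * q
            lcov = slot_vec[o3 : o3 + self._nlcov]
            beta = slot_vec[o3 + self._nlcov : o3 + self._nlcov + self._nedge]
            bmat = np.zeros((q, q), dtype=dt)
            bmat[self._edge_child, self._edge_parent] = beta
            psim = np.zeros((q, q), dtype=dt)
            psim[np.arange(q), np.arange(q)] = psi
            if self._nlcov:
                psim[self._lcov_i, self._lcov_j] = lcov
                psim[self._lcov_j, self._lcov_i] = lcov
            inv = np.linalg.inv(eye - bmat)
            seta = inv @ psim @ inv.T
            rsub = seta[np.ix_(self._cidx, self._cidx)]
            sstar = (a[:, None] * a[None, :]) * rsub
            d = np.diagonal(sstar) + theta
            sd = np.sqrt(d)
            mu = a * alpha[self._cidx]
            thr = (bflat - mu[self._thr_item]) / sd[self._thr_item]
            corr = sstar[self.iu] / (sd[self.iu[0]] * sd[self.iu[1]])
            parts.append(np.concatenate([thr, corr]))
        return np.concatenate(parts)

    def _jacobian(self, z: np.ndarray) -> np.ndarray:
        """Complex-step Jacobian of sigma w.r.t. internal coordinates."""
        k = len(z)
        jac = np.empty((2 * self.dim, k))
        zc = z.astype(complex)
        for i in range(k):
            zi = zc.copy()
            zi[i] += 1j * _CSTEP
            jac[:, i] = self.sigma(zi).imag / _CSTEP
        return jac

    def discrepancy(self, z: np.ndarray) -> float:
        r = self.s - self.sigma(z)
        if not np.all(np.isfinite(r)):
            return np.inf
        return float(r @ (self.w * r))

    # --- fitting ----------------------------------------------------------
    def fit(
        self,
        start: Mapping[tuple, float] | None = None,
        maxiter: int = 500,
        gtol: float = 1e-6,
        lm_lambda0: float = 1e-3,
    ) -> "OrdinalSEMResults":
        """Minimize the DWLS discrepancy by Levenberg--Marquardt.

        Convergence requires the gradient infinity-norm below ``gtol``
        within ``maxiter`` iterations; non-convergence is flagged on the
        results object, not raised.
        """
        spec = self.spec
        z = spec.start_vector(start)
        sw = np.sqrt(self.w)
        f = self.discrepancy(z)
        lam = lm_lambda0
        converged = False
        n_iter = 0
        gnorm = np.inf
        for n_iter in range(1, maxiter + 1):
            jac = self._jacobian(z)
            jw = sw[:, None] * jac
            rw = sw * (self.s - self.sigma(z))
            grad = -2.0 * (jw.T @ rw)
            gnorm = float(np.max(np.abs(grad)))
            if gnorm < gtol:
                converged = True
                break
            jtj = jw.T @ jw
            jtr = jw.T @ rw
            improved = False
            for _ in range(40):
                try:
                    step = np.linalg.solve(jtj + lam * np.diag(np.maximum(np.diag(jtj), 1e-10)), jtr)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                f_new = self.discrepancy(z + step)
                if f_new < f:
                    z = z + step
                    f = f_new
                    lam = max(lam / 3.0, 1e-12)
                    improved = True
                    break
                lam *= 10.0
            if not improved:
                # cannot decrease: accept as converged if gradient is tiny
                converged = gnorm < 1e-3
                break
        return OrdinalSEMResults(self, z, f, converged, n_iter, gnorm)


def robust_corrections(
    model: TwoGroupOrdinalSEM, z: np.ndarray, fmin: float
) -> tuple[np.ndarray, float, int, float, float]:
    """Sandwich standard errors and the scaled-shifted chi-square.

    Returns ``(se_natural, t_adj, df, p, t_raw)``.  ``se_natural`` is on the
    natural parameter scale (delta method through the internal log-variance
    transform).  Requires both groups' summaries to carry an asymptotic
    covariance; without it only the raw statistic is defined and SEs are NaN.
    """
    spec = model.spec
    jac = model._jacobian(z)
    w = model.w
    df = 2 * model.dim - spec.n_free
    n_tot = model.n_total
    t_raw = n_tot * fmin
    if any(c is None for c in model._cov_parts):
        return (np.full(spec.n_free, np.nan), np.nan, df, np.nan, t_raw)
    cov_s = np.zeros((2 * model.dim, 2 * model.dim))
    for gi in range(2):
        sl = slice(gi * model.dim, (gi + 1) * model.dim)
        cov_s[sl, sl] = model._cov_parts[gi]
    vj = w[:, None] * jac
    jvj = jac.T @ vj
    try:
        jvj_inv = np.linalg.inv(jvj)
    except np.linalg.LinAlgError:
        warnings.warn("singular information matrix", RuntimeWarning)
        jvj_inv = np.linalg.pinv(jvj)
    middle = vj.T @ cov_s @ vj
    acov_z = jvj_inv @ middle @ jvj_inv
    # delta method: natural = exp(z) on variance coordinates
    x = spec.natural(z)
    scale = np.where(spec.log_mask, x, 1.0)
    se = np.sqrt(np.maximum(np.diag(acov_z), 0.0)) * np.abs(scale)
    # mean-and-variance adjusted statistic: U = V - V J (J'VJ)^{-1} J'V
    # traces of U Gamma_N with Gamma_N = N * cov_s
    u_gamma = n_tot * (w[:, None] * cov_s - vj @ (jvj_inv @ (vj.T @ cov_s)))
    c1 = float(np.trace(u_gamma))
    c2 = float(np.sum(u_gamma * u_gamma.T))
    if df <= 0 or c2 <= 0:
        return (se, 0.0, df, 1.0, t_raw)
    a = np.sqrt(df / c2)
    b = df - a * c1
    t_adj = a * t_raw + b
    p = float(chi2.sf(max(t_adj, 0.0), df))
    return (se, float(t_adj), df, p, t_raw)


def admissibility(results: "OrdinalSEMResults") -> dict[str, bool]:
    """Admissibility flags: positive variances and proper implied correlations."""
    spec = results.model.spec
    slot_vec = spec.slot_vector(results.z)
    ok_var = True
    ok_corr = True
    for g in GROUPS:
        gp = spec.group_params(slot_vec, g)
        if np.any(gp.resid_vars < VARIANCE_FLOOR) or np.any(
            gp.latent_vars < VARIANCE_FLOOR
        ):
            ok_var = False
        _, corr = implied_moments(gp, spec.layout)
        if np.any(np.abs(corr) > 1.0 + 1e-8):
            ok_corr = False
    return {
        "positive_variances": ok_var,
        "proper_correlations": ok_corr,
        "admissible": ok_var and ok_corr,
    }


def wald_ci(estimate: float, robust_se: float, level: float = 0.95) -> tuple[float, float]:
    """Wald confidence interval ``estimate +- z * se``."""
    if robust_se < 0:
        raise ValueError("standard error must be non-negative")
    zq = norm.ppf(0.5 + level / 2.0)
    return (estimate - zq * robust_se, estimate + zq * robust_se)


def dwls_fit(
    summaries: Mapping[str, PolychoricSummary], spec: ModelSpec, **kwargs
) -> "OrdinalSEMResults":
    """Functional entry point: ``TwoGroupOrdinalSEM(summaries, spec).fit()``."""
    return TwoGroupOrdinalSEM(summaries, spec).fit(**kwargs)


class OrdinalSEMResults:
    """Estimates, robust standard errors and diagnostics of one fit."""

    def __init__(
        self,
        model: TwoGroupOrdinalSEM,
        z: np.ndarray,
        fmin: float,
        converged: bool,
        n_iter: int,
        gradient_norm: float,
    ) -> None:
        self.model = model
        self.z = z
        self.fmin = fmin
        self.converged = converged
        self.n_iter = n_iter
        self.gradient_norm = gradient_norm
        spec = model.spec
        se, t_adj, df, p, t_raw = robust_corrections(model, z, fmin)
        self._x = spec.natural(z)
        self._se = se
        self.chi2 = t_adj
        self.chi2_raw = t_raw
        self.df = df
        self.pvalue = p
        flags = admissibility(self)
        self.admissible = flags["admissible"]
        self.admissibility_flags = flags
        names = [spec.slot_name(s) for s in spec.free_slots]
        self.params = pd.Series(self._x, index=names)
        self.bse = pd.Series(self._se, index=names)

    # --- lookups ----------------------------------------------------------
    def _free_index(self, slot: tuple) -> int | None:
        spec = self.model.spec
        st = spec.status.get(slot, FREE)
        if st == FIXED:
            return None
        if st == EQUAL:
            slot = slot[:-1] + (REFERENT,)
        return spec.free_slots.index(slot)

    def value_of(self, slot: tuple) -> float:
        idx = self._free_index(slot)
        if idx is None:
            return float(self.model.spec.values[slot])
        return float(self._x[idx])

    def se_of(self, slot: tuple) -> float:
        idx = self._free_index(slot)
        return 0.0 if idx is None else float(self._se[idx])

    def path(self, parent: str, child: str, group: str) -> tuple[float, float]:
        """(estimate, robust SE) of a structural coefficient."""
        slot = ("beta", (parent, child), group)
        return self.value_of(slot), self.se_of(slot)

    def wald_ci(self, slot: tuple, level: float = 0.95) -> tuple[float, float]:
        return wald_ci(self.value_of(slot), self.se_of(slot), level)

    def param_table(self) -> pd.DataFrame:
        """One row per slot: estimate, SE, status and 95% CI."""
        spec = self.model.spec
        rows = []
        for slot in spec.all_slots:
            est = self.value_of(slot)
            se = self.se_of(slot)
            lo, hi = (np.nan, np.nan)
            if se > 0 and np.isfinite(se):
                lo, hi = wald_ci(est, se)
            rows.append(
                {
                    "name": spec.slot_name(slot),
                    "group": slot[-1],
                    "status": spec.status.get(slot, FREE),
                    "estimate": est,
                    "robust_se": se,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Two-group ordinal SEM (DWLS, robust corrections)",
            "=" * 58,
            f"groups: n = {self.model.n_per_group}",
            f"converged: {self.converged} (iterations {self.n_iter}, "
            f"|grad| {self.gradient_norm:.2e})",
            f"admissible: {self.admissible}",
            f"discrepancy F = {self.fmin:.6f}",
            f"adjusted chi2({self.df}) = {self.chi2:.3f}, p = {self.pvalue:.4f}",
            "",
        ]
        with pd.option_context("display.width", 120, "display.max_rows", 500):
            table = self.param_table()
            lines.append(table.to_string(index=False, float_format=lambda v: f"{v: .4f}"))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<OrdinalSEMResults converged={self.converged} "
            f"chi2({self.df})={self.chi2:.2f}>"
        )
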