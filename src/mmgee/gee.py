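"""Marginal GEE fitting with moment estimation of nuisance parameters.

A single endpoint is modelled by a generalized linear mean structure
mu_ij = g^{-1}(x_ij beta) with a working correlation R(alpha) between
repeated observations of the same subject (cluster).  The coefficient
estimate solves the estimating equation

    sum_i U_i(beta) = sum_i D_i' W_i^{1/2} V_i^{-1} W_i^{1/2} S_i = 0

with S_i = Y_i - mu_i the residual vector, V_i = A_i^{1/2} R_i(alpha)
A_i^{1/2} phi the working covariance and D_i = d mu_i / d beta.  The
scale phi and correlation parameter alpha are re-estimated from Pearson
residuals between Fisher-scoring sweeps (Liang-Zeger alternation).

Besides the coefficients, the fit retains every per-cluster quantity
(U_i, D_i, V_i, S_i) needed to stack several marginal models into a
joint sandwich covariance, including its small-sample bias-adjusted
variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .families import Family, get_family

__all__ = [
    "GEEModelSpec",
    "GEEFit",
    "build_working_correlation",
    "estimate_nuisance",
    "fit_gee",
    "FitError",
    "DegenerateDataError",
]


class FitError(RuntimeError):
    """Estimation failed (divergence, singular system, invalid alpha)."""


class DegenerateDataError(ValueError):
    """Data carry no information for a nuisance parameter (e.g. exact fit)."""


VALID_CORSTR = ("independence", "exchangeable", "ar1", "unstructured", "fixed")


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass
class GEEModelSpec:
    """One endpoint's data and model: response, design, clusters, family.

    Rows are stably re-sorted by cluster id at construction; the
    within-cluster order (which defines the ar1 / unstructured
    correlation entries) is the original row order.
    """

    response: np.ndarray
    design: np.ndarray
    cluster_id: np.ndarray
    family: Family
    working_correlation: str = "independence"
    weights: np.ndarray | None = None
    fixed_R: np.ndarray | None = None
    coef_names: list[str] | None = None
    name: str = "model"
    scale_divisor: str = "n-p"  # "n-p" (Liang-Zeger) or "n"

    # derived, set in __post_init__
    cluster_labels: np.ndarray = field(init=False, repr=False)
    cluster_starts: np.ndarray = field(init=False, repr=False)
    cluster_sizes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        y = np.asarray(self.response, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(self.design, dtype=float))
        ids = np.asarray(self.cluster_id)
        if X.shape[0] != y.size or ids.size != y.size:
            raise ValueError("response, design and cluster_id lengths differ")
        self.family = get_family(self.family)
        self.family.validate_response(y)
        if self.working_correlation not in VALID_CORSTR:
            raise ValueError(f"unknown working correlation {self.working_correlation!r}")
        if self.working_correlation == "fixed" and self.fixed_R is None:
            raise ValueError("fixed working correlation requires fixed_R")
        w = (
            np.ones_like(y)
            if self.weights is None
            else np.asarray(self.weights, dtype=float).ravel()
        )
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")

        order = np.argsort(ids, kind="stable")
        self.response = y[order]
        self.design = X[order]
        self.cluster_id = ids[order]
        self.weights = w[order]

        labels, starts = np.unique(self.cluster_id, return_index=True)
        # np.unique sorts; with sorted ids the starts are increasing already
        self.cluster_labels = labels
        self.cluster_starts = np.sort(starts)
        self.cluster_sizes = np.diff(
            np.append(self.cluster_starts, self.cluster_id.size)
        )
        K, p = self.n_clusters, self.n_params
        if np.linalg.matrix_rank(self.design) < p:
            raise ValueError("design matrix is rank deficient")
        if p >= K:
            raise ValueError(f"need more clusters ({K}) than parameters ({p})")
        if self.coef_names is None:
            self.coef_names = [f"x{j}" for j in range(p)]

    @property
    def n_obs(self) -> int:
        return self.response.size

    @property
    def n_params(self) -> int:
        return self.design.shape[1]

    @property
    def n_clusters(self) -> int:
        return self.cluster_labels.size

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        covariates: list[str],
        family: str,
        working_correlation: str = "independence",
        id_col: str = "id",
        weight_col: str | None = None,
        intercept: bool = True,
        name: str | None = None,
        **kwargs,
    ) -> "GEEModelSpec":
        """Build a spec from a long-format table, dropping rows with missing
        response or covariates for this model only (MCAR handling)."""
        cols = [id_col, response, *covariates] + ([weight_col] if weight_col else [])
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise KeyError(f"columns not found in input data: {missing}")
        sub = data[cols].dropna()
        X = sub[covariates].to_numpy(dtype=float)
        names = list(covariates)
        if intercept:
            X = np.column_stack([np.ones(len(sub)), X])
            names = ["(Intercept)", *names]
        return cls(
            response=sub[response].to_numpy(dtype=float),
            design=X,
            cluster_id=sub[id_col].to_numpy(),
            family=get_family(family),
            working_correlation=working_correlation,
            weights=sub[weight_col].to_numpy(dtype=float) if weight_col else None,
            coef_names=names,
            name=name or response,
            **kwargs,
        )


# ---------------------------------------------------------------------------
# working correlation and nuisance moment estimators
# ---------------------------------------------------------------------------


def build_working_correlation(
    kind: str, alpha, n: int, fixed_R: np.ndarray | None = None
) -> np.ndarray:
    """Return the n x n working correlation matrix R(alpha).

    independence -> identity; exchangeable -> constant off-diagonal alpha;
    ar1 -> alpha^|j-k|; unstructured/fixed -> leading principal submatrix
    of the supplied full matrix.
    """
    if n < 1:
        raise ValueError("cluster size must be >= 1")
    if kind == "independence":
        return np.eye(n)
    if kind == "exchangeable":
        a = float(alpha)
        if n > 1 and not (-1.0 / (n - 1) < a < 1.0):
            raise FitError(f"exchangeable alpha {a} outside (-1/(n-1), 1) for n={n}")
        R = np.full((n, n), a)
        np.fill_diagonal(R, 1.0)
        return R
    if kind == "ar1":
        a = float(alpha)
        if not (-1.0 < a < 1.0):
            raise FitError(f"ar1 alpha {a} outside (-1, 1)")
        idx = np.arange(n)
        return a ** np.abs(idx[:, None] - idx[None, :])
    if kind in ("unstructured", "fixed"):
        R_full = np.asarray(fixed_R if fixed_R is not None else alpha, dtype=float)
        if R_full.shape[0] < n:
            raise ValueError("supplied correlation matrix smaller than cluster size")
        R = R_full[:n, :n].copy()
        np.fill_diagonal(R, 1.0)
        if np.linalg.eigvalsh(R).min() <= 0:
            raise FitError("working correlation matrix is not positive definite")
        return R
    raise ValueError(f"unknown working correlation {kind!r}")


def estimate_nuisance(
    pearson_residuals: list[np.ndarray],
    p: int,
    kind: str,
    scale_divisor: str = "n-p",
):
    """Moment estimators (alpha_hat, phi_hat) from per-cluster Pearson
    residual vectors e_ij = (Y_ij - mu_ij) / sqrt(nu(mu_ij)).

    phi_hat = sum e^2 / (N - p)  (or / N when scale_divisor="n").
    exchangeable: alpha = [sum_i sum_{j<k} e_ij e_ik] / [phi (sum_i
    n_i(n_i-1)/2 - p)];  ar1 uses lag-1 products with denominator
    (sum_i (n_i - 1) - p); unstructured averages products element-wise.
    """
    sizes = np.array([len(e) for e in pearson_residuals])
    N = int(sizes.sum())
    div = N - p if scale_divisor == "n-p" else N
    if div <= 0:
        raise DegenerateDataError("nonpositive scale denominator")
    ssq = float(sum(float(e @ e) for e in pearson_residuals))
    phi = ssq / div
    if kind == "independence":
        return None, phi
    if phi <= 0:
        raise DegenerateDataError("all residuals are zero; scale is degenerate")
    if kind == "exchangeable":
        denom = float((sizes * (sizes - 1)).sum()) / 2.0 - p
        if denom <= 0:
            raise DegenerateDataError("not enough within-cluster pairs")
        num = sum(
            (float(e.sum()) ** 2 - float(e @ e)) / 2.0 for e in pearson_residuals
        )
        return num / (phi * denom), phi
    if kind == "ar1":
        denom = float((sizes - 1).sum()) - p
        if denom <= 0:
            raise DegenerateDataError("not enough lag-1 pairs")
        num = sum(float(e[:-1] @ e[1:]) for e in pearson_residuals if len(e) > 1)
        return num / (phi * denom), phi
    if kind == "unstructured":
        nmax = int(sizes.max())
        num = np.zeros((nmax, nmax))
        cnt = np.zeros((nmax, nmax))
        for e in pearson_residuals:
            k = len(e)
            num[:k, :k] += np.outer(e, e)
            cnt[:k, :k] += 1.0
        denom = cnt - p
        if (denom[np.triu_indices(nmax, 1)] <= 0).any():
            raise DegenerateDataError("not enough clusters for unstructured R")
        R = num / (phi * np.maximum(denom, 1e-12))
        R = np.clip((R + R.T) / 2.0, -0.99, 0.99)
        np.fill_diagonal(R, 1.0)
        return R, phi
    raise ValueError(f"unknown working correlation {kind!r}")


# ---------------------------------------------------------------------------
# fit container
# ---------------------------------------------------------------------------


@dataclass
class GEEFit:
    """Fitted marginal GEE model with per-cluster building blocks.

    ``cluster_D`` and ``cluster_S`` hold the weight-absorbed versions
    W_i^{1/2} D_i and W_i^{1/2} S_i, so that every downstream sandwich
    formula can be written as if unweighted.
    """

    spec: GEEModelSpec
    beta_hat: np.ndarray
    alpha_hat: object
    phi_hat: float
    cluster_scores: list[np.ndarray]
    cluster_D: list[np.ndarray]
    cluster_V: list[np.ndarray]
    cluster_S: list[np.ndarray]
    H_model: np.ndarray
    converged: bool
    n_iterations: int

    @property
    def cluster_labels(self) -> np.ndarray:
        return self.spec.cluster_labels

    @property
    def n_params(self) -> int:
        return self.spec.n_params

    @property
    def n_clusters(self) -> int:
        return self.spec.n_clusters

    def score_sum(self) -> np.ndarray:
        return np.sum(self.cluster_scores, axis=0)

    def robust_covariance(self) -> np.ndarray:
        """Single-model Liang-Zeger sandwich H^-1 B H^-1."""
        B = sum(np.outer(u, u) for u in self.cluster_scores)
        Hinv = np.linalg.inv(self.H_model)
        return Hinv @ B @ Hinv

    def summary(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.robust_covariance()))
        return pd.DataFrame(
            {"estimate": self.beta_hat, "robust_se": se},
            index=self.spec.coef_names,
        )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _cluster_slices(spec: GEEModelSpec):
    starts = spec.cluster_starts
    ends = np.append(starts[1:], spec.n_obs)
    return [slice(int(a), int(b)) for a, b in zip(starts, ends)]


def _pearson_residual_list(spec, slices, mu, sqrtw):
    nu = spec.family.variance(mu)
    e = sqrtw * (spec.response - mu) / np.sqrt(np.maximum(nu, 1e-300))
    return [e[s] for s in slices]


def _glm_init(spec: GEEModelSpec, n_steps: int = 5) -> np.ndarray:
    """A few Fisher-scoring steps of the independence GLM as starting value."""
    X, y, w = spec.design, spec.response, spec.weights
    fam = spec.family
    beta = np.zeros(spec.n_params)
    for _ in range(n_steps):
        eta = X @ beta
        mu = fam.inverse_link(eta)
        d = fam.dmu_deta(eta)
        nu = np.maximum(fam.variance(mu), 1e-10)
        wls = w * d * d / nu
        XtWX = (X * wls[:, None]).T @ X
        XtWz = X.T @ (w * d * (y - mu) / nu)
        try:
            step = np.linalg.solve(XtWX, XtWz)
        except np.linalg.LinAlgError as err:
            raise FitError("singular information matrix in GLM init") from err
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            break
    return beta


def fit_gee(
    spec: GEEModelSpec,
    init: np.ndarray | None = None,
    max_iter: int = 25,
    tol: float = 1e-6,
) -> GEEFit:
    """Fit one marginal GEE model by alternating Fisher scoring for beta
    with moment re-estimation of (alpha, phi)."""
    X, y, w = spec.design, spec.response, spec.weights
    fam = spec.family
    p = spec.n_params
    slices = _cluster_slices(spec)
    sqrtw = np.sqrt(w)
    corstr = spec.working_correlation

    beta = np.asarray(init, dtype=float).copy() if init is not None else _glm_init(spec)
    alpha, phi = None, 1.0
    R_cache: dict[int, np.ndarray] = {}
    converged = False
    n_iter = 0

    def per_cluster(beta, alpha, phi, R_cache):
        """All per-cluster arrays at the current parameter values."""
        eta = X @ beta
        mu = fam.inverse_link(eta)
        dmu = fam.dmu_deta(eta)
        nu = np.maximum(fam.variance(mu), 1e-12)
        Ds, Vs, Ss, Us = [], [], [], []
        M = np.zeros((p, p))
        Usum = np.zeros(p)
        for s in slices:
            n = s.stop - s.start
            if n not in R_cache:
                R_cache[n] = build_working_correlation(
                    corstr, alpha, n, fixed_R=spec.fixed_R
                )
            sa = np.sqrt(nu[s])
            V = (sa[:, None] * R_cache[n] * sa[None, :]) * phi
            Dw = (sqrtw[s] * dmu[s])[:, None] * X[s]
            Sw = sqrtw[s] * (y[s] - mu[s])
            try:
                VinvD = np.linalg.solve(V, Dw)
                VinvS = np.linalg.solve(V, Sw)
            except np.linalg.LinAlgError as err:
                raise FitError("singular working covariance V_i") from err
            U = Dw.T @ VinvS
            M += Dw.T @ VinvD
            Ds.append(Dw)
            Vs.append(V)
            Ss.append(Sw)
            Us.append(U)
            Usum += U
        return mu, Ds, Vs, Ss, Us, M, Usum

    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu = fam.inverse_link(eta)
        if corstr != "fixed":
            alpha, phi = estimate_nuisance(
                _pearson_residual_list(spec, slices, mu, sqrtw),
                p,
                corstr,
                spec.scale_divisor,
            )
        else:
            _, phi = estimate_nuisance(
                _pearson_residual_list(spec, slices, mu, sqrtw),
                p,
                "independence",
                spec.scale_divisor,
            )
        if corstr == "exchangeable":
            nmax = int(spec.cluster_sizes.max())
            lo = -1.0 / max(nmax - 1, 1) + 1e-6
            alpha = float(np.clip(alpha, lo, 1.0 - 1e-6))
        elif corstr == "ar1":
            alpha = float(np.clip(alpha, -1.0 + 1e-6, 1.0 - 1e-6))
        R_cache = {}

        _, _, _, _, _, M, Usum = per_cluster(beta, alpha, phi, R_cache)
        try:
            step = np.linalg.solve(M, Usum)
        except np.linalg.LinAlgError as err:
            raise FitError("singular scoring matrix") from err
        beta = beta + step
        if not np.isfinite(beta).all() or np.abs(beta).max() > 1e8:
            raise FitError("divergence: coefficient estimates are unbounded")
        if np.abs(step).max() < tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"GEE fit for {spec.name!r} did not converge in {max_iter} iterations",
            RuntimeWarning,
        )

    mu, Ds, Vs, Ss, Us, M, Usum = per_cluster(beta, alpha, phi, R_cache)
    return GEEFit(
        spec=spec,
        beta_hat=beta,
        alpha_hat=alpha,
        phi_hat=float(phi),
        cluster_scores=Us,
        cluster_D=Ds,
        cluster_V=Vs,
        cluster_S=Ss,
        H_model=-M,
        converged=converged,
        n_iterations=n_iter,
    )
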