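"""Wald and generalized score tests of H0: L beta = r across stacked models.

Maximum-type tests compare the largest standardized contrast against an
equicoordinate quantile of the joint (possibly degenerate) multivariate
normal or t reference; quadratic-form tests use the Mahalanobis
statistic with chi-squared, F, or Hotelling-type scaled-F references.
Score tests evaluate the stacked estimating function at a restricted
estimate obtained by iterative weighted least squares with Lagrange
multipliers, re-estimating nuisance parameters under the restriction.
Simultaneous confidence intervals invert the single-step maximum-type
Wald test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gee import FitError, GEEModelSpec, estimate_nuisance, fit_gee, _cluster_slices, \
    _pearson_residual_list, build_working_correlation
from .mvprob import equicoordinate_quantile, rectangle_probability
from .stack import MMMFit, _symmetrize

__all__ = [
    "ContrastHypothesis",
    "TestResult",
    "SimultaneousCI",
    "RestrictedFit",
    "RestrictedStack",
    "default_df",
    "max_wald_test",
    "simultaneous_ci",
    "quadratic_wald_test",
    "restricted_fit",
    "restricted_stack",
    "max_score_test",
    "quadratic_score_test",
]


def _matrix_rank(A: np.ndarray) -> int:
    if A.size == 0:
        return 0
    s = np.linalg.svd(A, compute_uv=False)
    tol = max(A.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    return int((s > tol).sum())


# ---------------------------------------------------------------------------
# hypotheses
# ---------------------------------------------------------------------------


@dataclass
class ContrastHypothesis:
    """Linear hypothesis L beta = r on the stacked coefficient vector."""

    L: np.ndarray
    r: np.ndarray | None = None
    row_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.L = np.atleast_2d(np.asarray(self.L, dtype=float))
        c = self.L.shape[0]
        self.r = (
            np.zeros(c)
            if self.r is None
            else np.asarray(self.r, dtype=float).ravel()
        )
        if self.r.size != c:
            raise ValueError("length of r must match the number of contrast rows")
        if _matrix_rank(np.column_stack([self.L, self.r])) != self.rank_L:
            raise ValueError("L beta = r is inconsistent (no solution exists)")
        if self.row_names is None:
            self.row_names = [f"row{i + 1}" for i in range(c)]

    @property
    def n_rows(self) -> int:
        return self.L.shape[0]

    @property
    def rank_L(self) -> int:
        return _matrix_rank(self.L)

    def row_blocks(self, model_slices: list[slice]) -> list[set[int]]:
        """For each contrast row, the set of models with nonzero entries."""
        out = []
        for row in self.L:
            touched = {
                m for m, sl in enumerate(model_slices) if np.any(row[sl] != 0.0)
            }
            out.append(touched)
        return out

    def is_block_diagonal(self, model_slices: list[slice]) -> bool:
        """True when every row involves exactly one model, so the
        restricted estimate decomposes over marginal models."""
        return all(len(b) == 1 for b in self.row_blocks(model_slices))

    def subset(self, rows) -> "ContrastHypothesis":
        rows = list(rows)
        return ContrastHypothesis(
            L=self.L[rows],
            r=self.r[rows],
            row_names=[self.row_names[i] for i in rows],
        )


def default_df(K: int, p_list) -> int:
    """Error degrees of freedom df = min_m (K - p^(m)) over the models
    involved in the tested contrasts."""
    p_list = list(p_list)
    if not p_list:
        raise ValueError("no models involved")
    df = min(K - p for p in p_list)
    if df <= 0:
        raise ValueError(f"nonpositive degrees of freedom (K={K}, p={max(p_list)})")
    return int(df)


def _involved_df(mmm: MMMFit, hyp: ContrastHypothesis) -> int:
    involved = set().union(*hyp.row_blocks(mmm.model_slices))
    if not involved:
        involved = set(range(mmm.n_models))
    return default_df(mmm.n_clusters, [mmm.fits[m].n_params for m in involved])


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class TestResult:
    method: str
    statistic: float
    reference: str
    p_value: float
    df: float | None = None
    df2: float | None = None
    critical_value: float | None = None
    alpha: float = 0.05
    per_row: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def reject(self) -> bool:
        return self.p_value <= self.alpha

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "statistic": self.statistic,
            "reference": self.reference,
            "df": self.df,
            "p_value": self.p_value,
            "critical_value": self.critical_value,
            "alpha": self.alpha,
        }
        if self.per_row is not None:
            d["per_row"] = self.per_row.reset_index().to_dict(orient="records")
        return d


@dataclass
class SimultaneousCI:
    table: pd.DataFrame
    level: float
    critical_value: float
    reference: str
    df: float | None

    def contains(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return (self.table["lower"].to_numpy() <= v) & (
            v <= self.table["upper"].to_numpy()
        )


# ---------------------------------------------------------------------------
# Wald-type inference
# ---------------------------------------------------------------------------


def _contrast_moments(beta, Sigma, hyp):
    est = hyp.L @ beta - hyp.r
    cov = _symmetrize(hyp.L @ Sigma @ hyp.L.T)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    if np.any(se <= 0):
        bad = [hyp.row_names[i] for i in np.where(se <= 0)[0]]
        raise FitError(f"degenerate contrast rows with zero standard error: {bad}")
    corr = np.clip(cov / np.outer(se, se), -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return est, cov, se, corr


def max_wald_test(
    mmm: MMMFit,
    hyp: ContrastHypothesis,
    alpha: float = 0.05,
    reference: str = "mvt",
    bias_adjust: bool = True,
    alternative: str = "two_sided",
    df: float | None = None,
    full_output: bool = True,
) -> TestResult:
    """Maximum-type Wald test: reject when max_i |(L beta - r)_i / SE_i|
    exceeds the equicoordinate 1-alpha quantile of the joint reference.

    ``full_output=False`` skips the critical value and the per-row
    single-step adjusted p-values (used in simulation loops where only
    the global p-value matters)."""
    if reference not in ("mvn", "mvt"):
        raise ValueError("reference must be 'mvn' or 'mvt'")
    if alternative not in ("two_sided", "less", "greater"):
        raise ValueError("invalid alternative")
    Sigma = mmm.covariance(bias_adjust)
    est, _, se, corr = _contrast_moments(mmm.beta_stacked, Sigma, hyp)
    tstat = est / se
    df_used = (_involved_df(mmm, hyp) if df is None else df) if reference == "mvt" else None
    two_sided = alternative == "two_sided"
    signed = tstat if alternative != "less" else -tstat
    statistic = float(np.max(np.abs(tstat) if two_sided else signed))
    p = 1.0 - rectangle_probability(statistic, corr, df=df_used, two_sided=two_sided)
    crit = (
        equicoordinate_quantile(corr, alpha, df=df_used, two_sided=two_sided)
        if full_output
        else None
    )

    uni = stats.t(df=df_used) if df_used is not None else stats.norm()
    if two_sided:
        p_unadj = 2.0 * uni.sf(np.abs(tstat))
        p_adj = (
            np.array(
                [1.0 - rectangle_probability(abs(t), corr, df=df_used) for t in tstat]
            )
            if full_output
            else np.full(tstat.size, np.nan)
        )
    else:
        p_unadj = uni.sf(signed)
        p_adj = (
            np.array(
                [
                    1.0 - rectangle_probability(t, corr, df=df_used, two_sided=False)
                    for t in signed
                ]
            )
            if full_output
            else np.full(tstat.size, np.nan)
        )
    per_row = pd.DataFrame(
        {
            "estimate": hyp.L @ mmm.beta_stacked,
            "rhs": hyp.r,
            "se": se,
            "statistic": tstat,
            "p_unadjusted": np.clip(p_unadj, 0.0, 1.0),
            "p_adjusted": np.clip(p_adj, 0.0, 1.0),
        },
        index=hyp.row_names,
    )
    return TestResult(
        method="max-wald" + ("" if two_sided else f"-{alternative}"),
        statistic=statistic,
        reference=reference if reference == "mvn" else f"mvt({df_used})",
        df=df_used,
        p_value=float(min(max(p, 0.0), 1.0)),
        critical_value=None if crit is None else float(crit),
        alpha=alpha,
        per_row=per_row,
    )


def simultaneous_ci(
    mmm: MMMFit,
    hyp: ContrastHypothesis,
    level: float = 0.95,
    reference: str = "mvt",
    bias_adjust: bool = True,
    df: float | None = None,
) -> SimultaneousCI:
    """Simultaneous confidence intervals (L beta)_i +/- q_{1-alpha} SE_i,
    dual to the single-step maximum-type Wald test."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    Sigma = mmm.covariance(bias_adjust)
    _, _, se, corr = _contrast_moments(mmm.beta_stacked, Sigma, hyp)
    df_used = (_involved_df(mmm, hyp) if df is None else df) if reference == "mvt" else None
    q = equicoordinate_quantile(corr, 1.0 - level, df=df_used)
    est = hyp.L @ mmm.beta_stacked
    table = pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "lower": est - q * se,
            "upper": est + q * se,
        },
        index=hyp.row_names,
    )
    return SimultaneousCI(
        table=table,
        level=level,
        critical_value=float(q),
        reference=reference if reference == "mvn" else f"mvt({df_used})",
        df=df_used,
    )


def _quadratic_form(delta: np.ndarray, cov: np.ndarray, rank: int) -> float:
    if rank == cov.shape[0]:
        return float(delta @ np.linalg.solve(cov, delta))
    return float(delta @ np.linalg.pinv(cov, rcond=1e-10) @ delta)


def quadratic_wald_test(
    mmm: MMMFit,
    hyp: ContrastHypothesis,
    alpha: float = 0.05,
    reference: str = "chisq",
    bias_adjust: bool = True,
    df: float | None = None,
) -> TestResult:
    """Quadratic-form Wald test W = (Lb - r)'(L Sigma L')^- (Lb - r) with
    chi-squared, F, or Hotelling-type scaled-F reference; a generalized
    inverse and c = rank(L) are used when L is rank-deficient."""
    Sigma = mmm.covariance(bias_adjust)
    est, cov, _, _ = _contrast_moments(mmm.beta_stacked, Sigma, hyp)
    c = hyp.rank_L
    W = _quadratic_form(est, cov, c)
    if reference == "chisq":
        p = stats.chi2.sf(W, c)
        crit = stats.chi2.ppf(1 - alpha, c)
        df_used, df2 = c, None
    elif reference == "f":
        df_used = _involved_df(mmm, hyp) if df is None else df
        p = stats.f.sf(W / c, c, df_used)
        crit = c * stats.f.ppf(1 - alpha, c, df_used)
        df2 = df_used
    elif reference == "scaledf":
        df_used = _involved_df(mmm, hyp) if df is None else df
        df2 = df_used - c + 1
        if df2 <= 0:
            raise ValueError(
                f"scaled-F reference needs df - c + 1 > 0 (df={df_used}, c={c})"
            )
        scale = df2 / (df_used * c)
        p = stats.f.sf(W * scale, c, df2)
        crit = stats.f.ppf(1 - alpha, c, df2) / scale
    else:
        raise ValueError("reference must be 'chisq', 'f' or 'scaledf'")
    return TestResult(
        method="quad-wald",
        statistic=W,
        reference=reference,
        df=c,
        df2=df2,
        p_value=float(p),
        critical_value=float(crit),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# restricted estimation and score tests
# ---------------------------------------------------------------------------


@dataclass
class RestrictedFit:
    """A single marginal model refit under L^(m) beta^(m) = r^(m)."""

    spec: GEEModelSpec
    Lm: np.ndarray | None
    rm: np.ndarray | None
    beta_tilde: np.ndarray
    alpha_tilde: object
    phi_tilde: float
    lagrange: np.ndarray
    cluster_scores: list[np.ndarray]
    cluster_D: list[np.ndarray]
    cluster_V: list[np.ndarray]
    cluster_S: list[np.ndarray]
    H_tilde: np.ndarray
    converged: bool
    n_iterations: int

    @property
    def cluster_labels(self):
        return self.spec.cluster_labels

    @property
    def n_params(self):
        return self.spec.n_params


def _per_cluster_at(spec: GEEModelSpec, beta, alpha, phi):
    """Per-cluster D (weighted), V, S (weighted), U and M at given beta."""
    X, y = spec.design, spec.response
    fam = spec.family
    sqrtw = np.sqrt(spec.weights)
    eta = X @ beta
    mu = fam.inverse_link(eta)
    dmu = fam.dmu_deta(eta)
    nu = np.maximum(fam.variance(mu), 1e-12)
    p = spec.n_params
    Ds, Vs, Ss, Us = [], [], [], []
    M = np.zeros((p, p))
    Usum = np.zeros(p)
    for s in _cluster_slices(spec):
        n = s.stop - s.start
        R = build_working_correlation(
            spec.working_correlation, alpha, n, fixed_R=spec.fixed_R
        )
        sa = np.sqrt(nu[s])
        V = (sa[:, None] * R * sa[None, :]) * phi
        Dw = (sqrtw[s] * dmu[s])[:, None] * X[s]
        Sw = sqrtw[s] * (y[s] - mu[s])
        VinvD = np.linalg.solve(V, Dw)
        VinvS = np.linalg.solve(V, Sw)
        U = Dw.T @ VinvS
        M += Dw.T @ VinvD
        Ds.append(Dw)
        Vs.append(V)
        Ss.append(Sw)
        Us.append(U)
        Usum += U
    return mu, Ds, Vs, Ss, Us, M, Usum


def restricted_fit(
    spec: GEEModelSpec,
    Lm: np.ndarray,
    rm: np.ndarray,
    init: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 25,
) -> RestrictedFit:
    """Restricted estimate beta~ solving the estimating equation subject
    to Lm beta = rm, by iterative weighted least squares with Lagrange
    multipliers; nuisance parameters are re-estimated at beta~ each sweep."""
    Lm = np.atleast_2d(np.asarray(Lm, dtype=float))
    rm = np.asarray(rm, dtype=float).ravel()
    if Lm.shape[1] != spec.n_params:
        raise ValueError("contrast block width does not match model parameters")
    if _matrix_rank(np.column_stack([Lm, rm])) != _matrix_rank(Lm):
        raise ValueError("infeasible restriction: Lm beta = rm has no solution")

    if init is None:
        init = fit_gee(spec).beta_hat
    beta = np.asarray(init, dtype=float).copy()
    slices = _cluster_slices(spec)
    sqrtw = np.sqrt(spec.weights)
    p = spec.n_params
    alpha, phi, lam = None, 1.0, np.zeros(Lm.shape[0])
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mu = spec.family.inverse_link(spec.design @ beta)
        kind = spec.working_correlation if spec.working_correlation != "fixed" else "independence"
        alpha_new, phi = estimate_nuisance(
            _pearson_residual_list(spec, slices, mu, sqrtw),
            p,
            kind,
            spec.scale_divisor,
        )
        if spec.working_correlation != "fixed":
            alpha = alpha_new
        if spec.working_correlation == "exchangeable":
            nmax = int(spec.cluster_sizes.max())
            alpha = float(np.clip(alpha, -1.0 / max(nmax - 1, 1) + 1e-6, 1.0 - 1e-6))
        elif spec.working_correlation == "ar1":
            alpha = float(np.clip(alpha, -1.0 + 1e-6, 1.0 - 1e-6))
        _, _, _, _, _, M, Usum = _per_cluster_at(spec, beta, alpha, phi)
        Hinv = -np.linalg.inv(M)  # H = dU/dbeta = -M
        LH = Lm @ Hinv
        lam = -np.linalg.solve(LH @ Lm.T, Lm @ beta - rm - LH @ Usum)
        step = -Hinv @ (Usum - Lm.T @ lam)
        beta = beta + step
        if not np.isfinite(beta).all() or np.abs(beta).max() > 1e8:
            raise FitError("divergence in restricted fit")
        if np.abs(step).max() < tol:
            converged = True
            break
    if np.abs(Lm @ beta - rm).max() > 1e-8:
        raise FitError("restricted fit failed to satisfy the constraint")

    mu, Ds, Vs, Ss, Us, M, Usum = _per_cluster_at(spec, beta, alpha, phi)
    return RestrictedFit(
        spec=spec,
        Lm=Lm,
        rm=rm,
        beta_tilde=beta,
        alpha_tilde=alpha,
        phi_tilde=float(phi),
        lagrange=lam,
        cluster_scores=Us,
        cluster_D=Ds,
        cluster_V=Vs,
        cluster_S=Ss,
        H_tilde=-M,
        converged=converged,
        n_iterations=n_iter,
    )


@dataclass
class RestrictedStack:
    """Stacked state of all marginal models with the hypothesis-restricted
    refits substituted for the models the contrast rows touch."""

    mmm: MMMFit
    hyp: ContrastHypothesis
    fits: list  # RestrictedFit for touched models, GEEFit otherwise
    restricted_mask: list[bool]
    beta_tilde: np.ndarray
    H_tilde: np.ndarray
    score: np.ndarray
    B_tilde: np.ndarray
    _B_adj: np.ndarray | None = field(default=None, repr=False)

    @property
    def model_slices(self):
        return self.mmm.model_slices

    @property
    def B_tilde_adj(self) -> np.ndarray:
        if self._B_adj is None:
            self._B_adj = _restricted_bias_adjusted_B(self)
        return self._B_adj

    def covariance_of_score_stat(self, bias_adjust: bool = False) -> np.ndarray:
        B = self.B_tilde_adj if bias_adjust else self.B_tilde
        Hinv = np.linalg.inv(self.H_tilde)
        return _symmetrize(Hinv @ B @ Hinv)


def restricted_stack(mmm: MMMFit, hyp: ContrastHypothesis) -> RestrictedStack:
    """Refit each touched marginal model under its contrast block and
    rebuild the stacked score and its covariance pieces at beta~."""
    if not hyp.is_block_diagonal(mmm.model_slices):
        raise ValueError(
            "score tests require a block-diagonal hypothesis: each contrast "
            "row may involve coefficients of one marginal model only"
        )
    blocks = hyp.row_blocks(mmm.model_slices)
    fits, mask = [], []
    for m, (f, sl) in enumerate(zip(mmm.fits, mmm.model_slices)):
        rows = [i for i, b in enumerate(blocks) if b == {m}]
        if rows:
            Lm = hyp.L[np.ix_(rows, range(sl.start, sl.stop))]
            rf = restricted_fit(f.spec, Lm, hyp.r[rows], init=f.beta_hat)
            fits.append(rf)
            mask.append(True)
        else:
            fits.append(f)
            mask.append(False)

    P = mmm.n_params_total
    beta_tilde = np.concatenate(
        [getattr(f, "beta_tilde", getattr(f, "beta_hat", None)) for f in fits]
    )
    H = np.zeros((P, P))
    pos = {lab: k for k, lab in enumerate(mmm.cluster_index)}
    Umat = np.zeros((mmm.n_clusters, P))
    for f, sl in zip(fits, mmm.model_slices):
        H[sl, sl] = getattr(f, "H_tilde", getattr(f, "H_model", None))
        for lab, u in zip(f.cluster_labels, f.cluster_scores):
            Umat[pos[lab], sl] = u
    B = Umat.T @ Umat
    return RestrictedStack(
        mmm=mmm,
        hyp=hyp,
        fits=fits,
        restricted_mask=mask,
        beta_tilde=beta_tilde,
        H_tilde=H,
        score=Umat.sum(axis=0),
        B_tilde=B,
    )


def _restricted_bias_adjusted_B(rs: RestrictedStack) -> np.ndarray:
    """B~ with cluster residuals inflated by (I - P~_ii)^{-1}, where the
    restricted leverage projects out the constrained directions:
    P~_ii = D_i (M~^-1 - M~^-1 L'(L M~^-1 L')^-1 L M~^-1) D_i' V_i^-1."""
    P = rs.beta_tilde.size
    pos = {lab: k for k, lab in enumerate(rs.mmm.cluster_index)}
    Umat = np.zeros((rs.mmm.n_clusters, P))
    for f, sl, restricted in zip(rs.fits, rs.mmm.model_slices, rs.restricted_mask):
        H = getattr(f, "H_tilde", getattr(f, "H_model", None))
        Minv = np.linalg.inv(-H)
        if restricted and f.Lm is not None and f.Lm.size:
            Lm = f.Lm
            core = Minv - Minv @ Lm.T @ np.linalg.solve(Lm @ Minv @ Lm.T, Lm @ Minv)
        else:
            core = Minv
        for lab, D, V, S in zip(f.cluster_labels, f.cluster_D, f.cluster_V, f.cluster_S):
            VinvD = np.linalg.solve(V, D)
            Pii = D @ core @ VinvD.T
            S_adj = np.linalg.solve(np.eye(Pii.shape[0]) - Pii, S)
            Umat[pos[lab], sl] = VinvD.T @ S_adj
    return Umat.T @ Umat


def _as_restricted(arg, hyp) -> RestrictedStack:
    if isinstance(arg, RestrictedStack):
        return arg
    if isinstance(arg, MMMFit):
        if hyp is None:
            raise ValueError("hypothesis required when passing an MMMFit")
        return restricted_stack(arg, hyp)
    raise TypeError("expected MMMFit or RestrictedStack")


def max_score_test(
    restricted,
    hyp: ContrastHypothesis | None = None,
    alpha: float = 0.05,
    bias_adjust: bool = False,
    df: float | None = None,
    full_output: bool = True,
) -> TestResult:
    """Maximum-type generalized score test based on L H~^-1 U(beta~) with
    an equicoordinate multivariate normal reference."""
    rs = _as_restricted(restricted, hyp)
    hyp = rs.hyp
    Hinv = np.linalg.inv(rs.H_tilde)
    v = hyp.L @ (Hinv @ rs.score)
    covZ = rs.covariance_of_score_stat(bias_adjust)
    cov = _symmetrize(hyp.L @ covZ @ hyp.L.T)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    if np.any(se <= 0):
        raise FitError("degenerate contrast rows with zero score standard error")
    corr = np.clip(cov / np.outer(se, se), -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    tstat = v / se
    statistic = float(np.max(np.abs(tstat)))
    p = 1.0 - rectangle_probability(statistic, corr, df=df)
    crit = equicoordinate_quantile(corr, alpha, df=df) if full_output else None
    uni = stats.norm() if df is None else stats.t(df=df)
    p_adj = (
        np.clip(
            [1.0 - rectangle_probability(abs(t), corr, df=df) for t in tstat],
            0.0,
            1.0,
        )
        if full_output
        else np.full(tstat.size, np.nan)
    )
    per_row = pd.DataFrame(
        {
            "statistic": tstat,
            "p_unadjusted": np.clip(2.0 * uni.sf(np.abs(tstat)), 0.0, 1.0),
            "p_adjusted": p_adj,
        },
        index=hyp.row_names,
    )
    return TestResult(
        method="max-score",
        statistic=statistic,
        reference="mvn" if df is None else f"mvt({df})",
        df=df,
        p_value=float(min(max(p, 0.0), 1.0)),
        critical_value=None if crit is None else float(crit),
        alpha=alpha,
        per_row=per_row,
    )


def quadratic_score_test(
    restricted,
    hyp: ContrastHypothesis | None = None,
    alpha: float = 0.05,
    bias_adjust: bool = False,
) -> TestResult:
    """Quadratic-form generalized score test with chi-squared reference;
    a generalized inverse and c = rank(L) handle rank-deficient L."""
    rs = _as_restricted(restricted, hyp)
    hyp = rs.hyp
    Hinv = np.linalg.inv(rs.H_tilde)
    v = hyp.L @ (Hinv @ rs.score)
    covZ = rs.covariance_of_score_stat(bias_adjust)
    cov = _symmetrize(hyp.L @ covZ @ hyp.L.T)
    c = hyp.rank_L
    W = _quadratic_form(v, cov, c)
    return TestResult(
        method="quad-score",
        statistic=W,
        reference="chisq",
        df=c,
        p_value=float(stats.chi2.sf(W, c)),
        critical_value=float(stats.chi2.ppf(1 - alpha, c)),
        alpha=alpha,
    )
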