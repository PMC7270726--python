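"""Synthetic clustered data with mixed continuous / count / binary endpoints.

Subjects carry a random number of repeated observations (uniform on
{2,3,4} by default) of M endpoints, one third each continuous, count
and binary.  Dependence is induced by a latent Gaussian copula: a
latent standard-normal vector per subject has correlation rho_within
(default 0.75) between repeats of the same endpoint and rho_between
(0, 0.25, 0.5 or 0.75) between different endpoints; observations are
the marginal quantile transforms of the latent normal CDF values.
Marginals are normal with unit variance (identity link), negative
binomial with dispersion 1, i.e. variance mu + mu^2 (log link), and
Bernoulli (logit link).  The mean structure per endpoint is
beta0 + Group*beta1 + x*beta2 with a subject-level binary group (K/2
per arm) and endpoint-specific covariates that are jointly normal with
pairwise correlation 0.4.

A Monte-Carlo harness fits the analysis models (exchangeable working
correlation, Poisson-family models for the count endpoints whose
overdispersion the robust covariance absorbs), runs the requested
tests or simultaneous intervals per replicate, and reports rejection /
coverage fractions with their binomial standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gee import FitError, GEEModelSpec, fit_gee
from .inference import (
    ContrastHypothesis,
    max_score_test,
    max_wald_test,
    quadratic_score_test,
    quadratic_wald_test,
    simultaneous_ci,
)
from .stack import stack_models

__all__ = [
    "ScenarioConfig",
    "endpoint_types",
    "scenario_coefficients",
    "generate_dataset",
    "analysis_specs",
    "group_contrast",
    "noncentrality",
    "chisq_power",
    "run_scenario",
]

# group effects giving marginal Wald/score expectations near 2.5
_EFFECT_AT_K40 = {"gaussian": 0.75, "poisson": 0.95, "binomial": 1.5}
_EFFECT_AT_K100 = {"gaussian": 0.45, "poisson": 0.6, "binomial": 0.9}
_INTERCEPT = {"gaussian": 0.0, "poisson": 0.0, "binomial": -0.75}


def endpoint_types(M: int) -> list[str]:
    if M % 3 != 0:
        raise ValueError("M must be a multiple of 3")
    third = M // 3
    return ["gaussian"] * third + ["poisson"] * third + ["binomial"] * third


def scenario_coefficients(M: int, K: int, effects="null") -> np.ndarray:
    """Per-endpoint (beta0, beta1, beta2).

    ``effects`` is 'null' (all beta1 = 0), 'all', or a boolean sequence
    per endpoint.  Group effects are the stated values at K = 40 and
    K = 100; other K scale the K = 40 values by sqrt(40 / K), keeping
    the expected standardized effect constant.
    """
    types = endpoint_types(M)
    if effects == "null":
        flags = [False] * M
    elif effects == "all":
        flags = [True] * M
    else:
        flags = [bool(f) for f in effects]
        if len(flags) != M:
            raise ValueError("effects must have one flag per endpoint")
    if K == 40:
        eff = _EFFECT_AT_K40
    elif K == 100:
        eff = _EFFECT_AT_K100
    else:
        scale = np.sqrt(40.0 / K)
        eff = {t: v * scale for t, v in _EFFECT_AT_K40.items()}
    return np.array(
        [
            [_INTERCEPT[t], eff[t] if f else 0.0, 0.25]
            for t, f in zip(types, flags)
        ]
    )


@dataclass
class ScenarioConfig:
    """Complete description of one simulation scenario."""

    M: int = 3
    K: int = 40
    rho_within: float = 0.75
    rho_between: float = 0.5
    covariate_corr: float = 0.4
    cluster_size_support: tuple = (2, 3, 4)
    effects: object = "null"
    coefficients: np.ndarray | None = None
    seed: int = 12345

    def __post_init__(self) -> None:
        if self.M % 3 != 0:
            raise ValueError("M must be a multiple of 3")
        if self.coefficients is None:
            self.coefficients = scenario_coefficients(self.M, self.K, self.effects)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (self.M, 3):
            raise ValueError("coefficients must be an (M, 3) array")
        if np.linalg.eigvalsh(self.latent_correlation()).min() < -1e-10:
            raise ValueError("implied latent correlation matrix is not PSD")

    @property
    def types(self) -> list[str]:
        return endpoint_types(self.M)

    @property
    def n_max(self) -> int:
        return int(max(self.cluster_size_support))

    def latent_correlation(self) -> np.ndarray:
        """Correlation of the latent normal vector, ordered (endpoint,
        occasion) with n_max occasions per endpoint."""
        n, M = self.n_max, self.M
        dim = M * n
        R = np.full((dim, dim), self.rho_between)
        for m in range(M):
            sl = slice(m * n, (m + 1) * n)
            R[sl, sl] = self.rho_within
        np.fill_diagonal(R, 1.0)
        return R

    @property
    def true_beta1(self) -> np.ndarray:
        return self.coefficients[:, 1].copy()


def generate_dataset(
    cfg: ScenarioConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """One long-format dataset: columns id, visit, group, x1..xM, y1..yM."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    M, K, n_max = cfg.M, cfg.K, cfg.n_max
    types = cfg.types

    sizes = rng.choice(np.asarray(cfg.cluster_size_support), size=K)
    group = (np.arange(K) >= K // 2).astype(float)

    # covariates: one per endpoint, jointly normal, pairwise corr 0.4
    Cx = np.full((M, M), cfg.covariate_corr)
    np.fill_diagonal(Cx, 1.0)
    X = rng.standard_normal((K, M)) @ np.linalg.cholesky(Cx).T

    # latent copula normals, (K, M, n_max)
    chol = np.linalg.cholesky(
        cfg.latent_correlation() + 1e-12 * np.eye(M * n_max)
    )
    xi = (rng.standard_normal((K, M * n_max)) @ chol.T).reshape(K, M, n_max)

    # linear predictors and means, (K, M)
    eta = (
        cfg.coefficients[:, 0][None, :]
        + group[:, None] * cfg.coefficients[:, 1][None, :]
        + X * cfg.coefficients[:, 2][None, :]
    )

    Y = np.empty((K, M, n_max))
    u = stats.norm.cdf(xi)
    for m, t in enumerate(types):
        if t == "gaussian":
            Y[:, m, :] = eta[:, m][:, None] + xi[:, m, :]
        elif t == "poisson":
            mu = np.exp(eta[:, m])[:, None]
            # negative binomial, dispersion 1: variance mu + mu^2
            Y[:, m, :] = stats.nbinom.ppf(u[:, m, :], 1.0, 1.0 / (1.0 + mu))
        else:
            mu = 1.0 / (1.0 + np.exp(-eta[:, m]))[:, None]
            Y[:, m, :] = (u[:, m, :] > 1.0 - mu).astype(float)

    rows_i = np.repeat(np.arange(K), sizes)
    rows_j = np.concatenate([np.arange(n) for n in sizes])
    data = {
        "id": rows_i,
        "visit": rows_j,
        "group": group[rows_i],
    }
    for m in range(M):
        data[f"x{m + 1}"] = X[rows_i, m]
    for m in range(M):
        data[f"y{m + 1}"] = Y[rows_i, m, rows_j]
    return pd.DataFrame(data)


_ANALYSIS_FAMILY = {"gaussian": "gaussian", "poisson": "poisson", "binomial": "binomial"}


def analysis_specs(
    data: pd.DataFrame, M: int, working_correlation: str = "exchangeable"
) -> list[GEEModelSpec]:
    """The M analysis models: y_m ~ 1 + group + x_m per endpoint, with
    the count endpoints analysed as Poisson-family models (the sandwich
    absorbs the negative-binomial overdispersion)."""
    types = endpoint_types(M)
    return [
        GEEModelSpec.from_dataframe(
            data,
            response=f"y{m + 1}",
            covariates=["group", f"x{m + 1}"],
            family=_ANALYSIS_FAMILY[t],
            working_correlation=working_correlation,
            id_col="id",
            name=f"y{m + 1}",
        )
        for m, t in enumerate(types)
    ]


def group_contrast(M: int, p: int = 3) -> ContrastHypothesis:
    """H0: beta1^(1) = ... = beta1^(M) = 0 for the group coefficients."""
    L = np.zeros((M, M * p))
    for m in range(M):
        L[m, m * p + 1] = 1.0
    return ContrastHypothesis(L=L, r=np.zeros(M), row_names=[f"beta1_{m+1}" for m in range(M)])


def noncentrality(effects, C) -> float:
    """Quadratic-form noncentrality lambda = e' C^-1 e."""
    e = np.asarray(effects, dtype=float)
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if np.linalg.cond(C) > 1e12:
        raise np.linalg.LinAlgError("correlation matrix is singular")
    return float(e @ np.linalg.solve(C, e))


def chisq_power(lam: float, c: int, alpha: float = 0.05) -> float:
    """P(noncentral chi2_c(lambda) exceeds the central 1-alpha quantile)."""
    if lam < 0:
        raise ValueError("noncentrality must be nonnegative")
    crit = stats.chi2.ppf(1.0 - alpha, c)
    return float(stats.ncx2.sf(crit, c, lam)) if lam > 0 else float(alpha)


# ---------------------------------------------------------------------------
# Monte-Carlo harness
# ---------------------------------------------------------------------------


def _procedure_label(proc: dict) -> str:
    parts = [proc["kind"]]
    if proc.get("reference"):
        parts.append(proc["reference"])
    parts.append("adj" if proc.get("bias_adjust") else "unadj")
    return "/".join(parts)


def _evaluate_procedure(proc, mmm, hyp, alpha, true_beta1):
    kind = proc["kind"]
    ref = proc.get("reference")
    adj = bool(proc.get("bias_adjust", False))
    if kind == "max-wald":
        res = max_wald_test(
            mmm, hyp, alpha=alpha, reference=ref or "mvn", bias_adjust=adj,
            full_output=False,
        )
        return float(res.p_value <= alpha)
    if kind == "quad-wald":
        res = quadratic_wald_test(mmm, hyp, alpha=alpha, reference=ref or "chisq", bias_adjust=adj)
        return float(res.p_value <= alpha)
    if kind == "max-score":
        res = max_score_test(mmm, hyp, alpha=alpha, bias_adjust=adj, full_output=False)
        return float(res.p_value <= alpha)
    if kind == "quad-score":
        res = quadratic_score_test(mmm, hyp, alpha=alpha, bias_adjust=adj)
        return float(res.p_value <= alpha)
    if kind == "bonferroni-max-wald":
        res = max_wald_test(
            mmm, hyp, alpha=alpha, reference=ref or "mvn", bias_adjust=adj,
            full_output=False,
        )
        p_min = res.per_row["p_unadjusted"].min()
        return float(min(1.0, hyp.n_rows * p_min) <= alpha)
    if kind == "ci":
        ci = simultaneous_ci(
            mmm, hyp, level=1.0 - alpha, reference=ref or "mvt", bias_adjust=adj
        )
        return float(ci.contains(true_beta1).all())
    raise ValueError(f"unknown procedure kind {kind!r}")


def run_scenario(
    cfg: ScenarioConfig,
    reps: int,
    procedures: list[dict],
    alpha: float = 0.05,
    max_failure_fraction: float = 0.01,
    progress: bool = False,
) -> pd.DataFrame:
    """Monte-Carlo rejection / coverage rates for the requested procedures.

    Each replicate draws its own generator from the master seed via a
    spawn key, so results do not depend on the number or order of
    replicates computed in one call.  Replicates with failed fits are
    excluded and counted; more than ``max_failure_fraction`` of failures
    aborts the run.
    """
    hyp = group_contrast(cfg.M)
    labels = [_procedure_label(p) for p in procedures]
    hits = np.zeros(len(procedures))
    n_ok = 0
    n_failed = 0
    for rep in range(reps):
        rng = np.random.default_rng(
            np.random.SeedSequence(cfg.seed, spawn_key=(rep,))
        )
        data = generate_dataset(cfg, rng=rng)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", RuntimeWarning)
                fits = [fit_gee(s) for s in analysis_specs(data, cfg.M)]
            mmm = stack_models(fits)
            results = [
                _evaluate_procedure(p, mmm, hyp, alpha, cfg.true_beta1)
                for p in procedures
            ]
        except (FitError, RuntimeWarning, np.linalg.LinAlgError, ValueError):
            n_failed += 1
            if n_failed > max(1, max_failure_fraction * reps):
                raise RuntimeError(
                    f"{n_failed} of {rep + 1} replicates failed to fit"
                )
            continue
        hits += results
        n_ok += 1
        if progress and (rep + 1) % 200 == 0:
            print(f"  rep {rep + 1}/{reps}", flush=True)
    if n_ok == 0:
        raise RuntimeError("all replicates failed")
    rate = hits / n_ok
    return pd.DataFrame(
        {
            "procedure": labels,
            "rate": rate,
            "mc_se": np.sqrt(rate * (1 - rate) / n_ok),
            "n_reps": n_ok,
            "n_failed": n_failed,
        }
    )
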