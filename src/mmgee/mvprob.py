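"""Equicoordinate probabilities and quantiles of multivariate normal / t.

The maximum-type tests need P(max_i |Z_i| <= q) for a c-dimensional
standard multivariate normal or t with a given correlation matrix, and
the inverse problem (the equicoordinate quantile).  Rectangle
probabilities are computed with scipy's Genz quasi-Monte-Carlo
integrator for the multivariate t; the normal case is evaluated as a
t with a very large df (1e8), which agrees with the exact normal
probability to ~1e-4 while being deterministic (fixed internal QMC
seed) and fast.

Singular correlation matrices arise from rank-deficient contrast
matrices.  Coordinates that are perfectly (anti-)correlated with an
earlier one are dropped exactly (they cannot change the maximum of
absolute values); any remaining singularity is handled by a seeded
scrambled-Sobol estimate in the reduced eigenspace.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.optimize import brentq
from scipy.stats import qmc

__all__ = ["rectangle_probability", "equicoordinate_quantile"]

_MVN_DF = 1e8  # df used to emulate the normal reference
_QMC_SEED = 20190917
_EIG_TOL = 1e-10


def _dedup_perfect(corr: np.ndarray, two_sided: bool):
    """Indices of coordinates kept after dropping exact +/-1 duplicates."""
    c = corr.shape[0]
    keep: list[int] = []
    for j in range(c):
        dup = any(
            abs(corr[j, i]) >= 1.0 - 1e-12 if two_sided else corr[j, i] >= 1.0 - 1e-12
            for i in keep
        )
        if not dup:
            keep.append(j)
    return keep


def _qmc_singular_prob(q, corr, df, two_sided, n_pow=14):
    """P(max |Z_i| <= q) under a singular correlation via scrambled Sobol
    in the reduced eigenspace (deterministic seed)."""
    vals, vecs = np.linalg.eigh(corr)
    keep = vals > _EIG_TOL * vals.max()
    E = vecs[:, keep] * np.sqrt(vals[keep])  # c x k factor, Z = E z
    k = E.shape[1]
    dim = k + (0 if np.isinf(df) else 1)
    sob = qmc.Sobol(d=dim, scramble=True, seed=_QMC_SEED)
    u = sob.random(2**n_pow)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    z = stats.norm.ppf(u[:, :k])
    Z = z @ E.T
    if not np.isinf(df):
        scale = np.sqrt(stats.chi2.ppf(u[:, -1], df) / df)
        thresh = q * scale
    else:
        thresh = np.full(len(u), q)
    if two_sided:
        inside = (np.abs(Z) <= thresh[:, None]).all(axis=1)
    else:
        inside = (Z <= thresh[:, None]).all(axis=1)
    return float(inside.mean())


def rectangle_probability(
    q: float,
    corr: np.ndarray,
    df: float | None = None,
    two_sided: bool = True,
) -> float:
    """P(max_i |Z_i| <= q) (or P(max_i Z_i <= q) one-sided) for Z
    multivariate normal (df=None/inf) or t with the given correlation."""
    corr = np.atleast_2d(np.asarray(corr, dtype=float))
    if q <= 0 and two_sided:
        return 0.0
    dfv = _MVN_DF if (df is None or np.isinf(df)) else float(df)
    keep = _dedup_perfect(corr, two_sided)
    corr = corr[np.ix_(keep, keep)]
    c = corr.shape[0]
    if c == 1:
        dist = stats.t(df=dfv)
        return float(dist.cdf(q) - (dist.cdf(-q) if two_sided else 0.0))
    eigs = np.linalg.eigvalsh(corr)
    if eigs.min() <= _EIG_TOL * eigs.max():
        return _qmc_singular_prob(
            q, corr, dfv if df is not None else np.inf, two_sided
        )
    lower = np.full(c, -q) if two_sided else np.full(c, -np.inf)
    p = stats.multivariate_t.cdf(
        np.full(c, q),
        loc=np.zeros(c),
        shape=corr,
        df=dfv,
        lower_limit=lower,
        random_state=_QMC_SEED,
    )
    return float(min(max(p, 0.0), 1.0))


def equicoordinate_quantile(
    corr: np.ndarray,
    alpha: float,
    df: float | None = None,
    two_sided: bool = True,
    tol: float = 1e-4,
) -> float:
    """The critical value q with P(max_i |Z_i| <= q) = 1 - alpha.

    Found by bracketed root search; the Bonferroni bound provides the
    upper bracket, the univariate quantile the lower one.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    corr = np.atleast_2d(np.asarray(corr, dtype=float))
    c = corr.shape[0]
    dfv = _MVN_DF if (df is None or np.isinf(df)) else float(df)
    tail = alpha / 2.0 if two_sided else alpha
    lo = stats.t.ppf(1.0 - tail, dfv)  # perfect dependence
    hi = stats.t.ppf(1.0 - tail / c, dfv)  # Bonferroni
    if c == 1 or np.all(np.abs(corr - 1.0) < 1e-12 if two_sided else corr > 1 - 1e-12):
        return float(lo)

    def f(q):
        return rectangle_probability(q, corr, df=df, two_sided=two_sided) - (1 - alpha)

    flo, fhi = f(lo), f(hi)
    if flo >= 0:
        return float(lo)
    if fhi <= 0:
        return float(hi)
    return float(brentq(f, lo, hi, xtol=tol))
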