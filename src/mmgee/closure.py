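"""Closed testing over elementary linear contrasts with strong FWER control.

An elementary hypothesis H_i is rejected at family-wise level alpha iff
every intersection hypothesis containing it is rejected by a local
level-alpha test; the multiplicity-adjusted p-value of H_i is the
maximum local p-value over those intersections.  When the contrast
matrix is rank-deficient, intersections whose rows span the same
parameter-space region as a larger intersection are redundant
(Shaffer's argument): testing only the larger one is equivalent and
strictly saves power relative to testing all subsets with Bonferroni-
style local tests.  The Bonferroni-Holm step-down procedure is provided
as the classical comparator (it is exactly closed testing with local
Bonferroni tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .inference import (
    ContrastHypothesis,
    _matrix_rank,
    max_score_test,
    max_wald_test,
    quadratic_score_test,
    quadratic_wald_test,
    restricted_stack,
)
from .stack import MMMFit

__all__ = ["ClosureResult", "holm_adjust", "shaffer_reduce", "closed_test"]

MAX_CLOSURE_ROWS = 16


@dataclass
class ClosureResult:
    elementary_p_adjusted: np.ndarray
    elementary_p_unadjusted: np.ndarray
    intersection_p: dict
    substitutions: dict
    row_names: list[str]
    alpha: float

    @property
    def reject(self) -> np.ndarray:
        return self.elementary_p_adjusted <= self.alpha

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "p_unadjusted": self.elementary_p_unadjusted,
                "p_holm": holm_adjust(self.elementary_p_unadjusted),
                "p_closure": self.elementary_p_adjusted,
            },
            index=self.row_names,
        )


def holm_adjust(p) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values: sort ascending,
    multiply the k-th smallest by (c - k + 1), enforce monotonicity by a
    running maximum, cap at 1."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or ((p < 0) | (p > 1)).any():
        raise ValueError("p must be a vector of values in [0, 1]")
    c = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * (c - np.arange(c))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(c)
    out[order] = adj
    return out


def shaffer_reduce(L: np.ndarray, subsets=None) -> dict:
    """Map each redundant subset S of contrast rows to the largest
    superset S' whose rows span the same region, i.e. with
    rank(L_S) = rank(L_{S union S'}).

    Returns {S: S'} over frozensets; subsets absent from the map must be
    tested themselves.
    """
    L = np.atleast_2d(np.asarray(L, dtype=float))
    c = L.shape[0]
    if subsets is None:
        subsets = [
            frozenset(s)
            for k in range(1, c + 1)
            for s in combinations(range(c), k)
        ]
    ranks = {S: _matrix_rank(L[sorted(S)]) for S in subsets}
    by_size = sorted(subsets, key=len, reverse=True)
    substitutions: dict = {}
    for S in subsets:
        if len(S) == c:
            continue
        for T in by_size:
            if len(T) <= len(S):
                break
            # S subset of T and equal rank => same solution region
            if S < T and ranks[T] == ranks[S]:
                substitutions[S] = T
                break
    return substitutions


def _local_p(mmm: MMMFit, hyp_sub: ContrastHypothesis, local_test: str, kwargs) -> float:
    if local_test == "max-wald":
        return max_wald_test(mmm, hyp_sub, full_output=False, **kwargs).p_value
    if local_test == "quad-wald":
        return quadratic_wald_test(mmm, hyp_sub, **kwargs).p_value
    if local_test == "max-score":
        return max_score_test(
            restricted_stack(mmm, hyp_sub), full_output=False, **kwargs
        ).p_value
    if local_test == "quad-score":
        return quadratic_score_test(restricted_stack(mmm, hyp_sub), **kwargs).p_value
    raise ValueError(f"unknown local test {local_test!r}")


def closed_test(
    mmm: MMMFit,
    hyp: ContrastHypothesis,
    local_test: str = "max-wald",
    alpha: float = 0.05,
    use_shaffer: bool = True,
    elementary_p: np.ndarray | None = None,
    max_rows: int = MAX_CLOSURE_ROWS,
    **test_kwargs,
) -> ClosureResult:
    """Closed testing procedure over the elementary contrast rows.

    ``local_test`` is one of 'max-wald', 'quad-wald', 'max-score',
    'quad-score' (score tests refit the restriction per intersection) or
    'bonferroni' (local Bonferroni tests on the elementary p-values,
    reproducing Holm exactly).  ``elementary_p`` supplies the elementary
    p-values for the Bonferroni local tests; by default they come from
    the per-row unadjusted Wald p-values.
    """
    c = hyp.n_rows
    if c > max_rows:
        raise ValueError(
            f"closure over {c} rows needs 2^{c} - 1 intersection tests; "
            f"cap is {max_rows}"
        )
    subsets = [
        frozenset(s) for k in range(1, c + 1) for s in combinations(range(c), k)
    ]
    substitutions = shaffer_reduce(hyp.L, subsets) if use_shaffer else {}
    representatives = [S for S in subsets if S not in substitutions]

    if local_test == "bonferroni":
        if elementary_p is None:
            elementary_p = max_wald_test(
                mmm, hyp, alpha=alpha, **test_kwargs
            ).per_row["p_unadjusted"].to_numpy()
        elementary_p = np.asarray(elementary_p, dtype=float)
        local = {
            S: float(min(1.0, len(S) * min(elementary_p[i] for i in S)))
            for S in representatives
        }
        p_unadj = elementary_p
    else:
        local = {
            S: _local_p(mmm, hyp.subset(sorted(S)), local_test, test_kwargs)
            for S in representatives
        }
        p_unadj = np.array([local[frozenset({i})] if frozenset({i}) in local
                            else local[substitutions[frozenset({i})]]
                            for i in range(c)])

    def p_of(S):
        return local[substitutions.get(S, S)]

    intersection_p = {S: p_of(S) for S in subsets}
    adjusted = np.array(
        [max(p for S, p in intersection_p.items() if i in S) for i in range(c)]
    )
    return ClosureResult(
        elementary_p_adjusted=adjusted,
        elementary_p_unadjusted=p_unadj,
        intersection_p=intersection_p,
        substitutions=substitutions,
        row_names=list(hyp.row_names),
        alpha=alpha,
    )
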