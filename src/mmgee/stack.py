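"""Stacking several marginal GEE fits into a joint coefficient covariance.

Because all marginal models share the same subjects, the per-subject
score contributions U_i^(m) of the M models can be concatenated into one
stacked estimating function.  The joint sandwich covariance of the
stacked coefficient vector is

    Sigma = H^-1 B H^-1,   B = sum_i U_i U_i',   H = blockdiag(H^(m)),

whose diagonal blocks reproduce the single-model robust covariances
while the off-diagonal blocks estimate the covariance between
coefficients of different models.  A subject absent from model m (all
its rows missing for that endpoint) contributes a structural zero to
the m-part of its stacked score.

The small-sample bias adjustment inflates each cluster residual by the
inverse annihilator (I - P_ii)^{-1}, with P_ii = D_i M^-1 D_i' V_i^-1
the cluster leverage and M = sum_i D_i' V_i^-1 D_i, generalizing the
Mancl-DeRouen correction to the stacked setting (P_ii block-diagonal
over models).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gee import GEEFit

__all__ = ["MMMFit", "stack_models", "bias_adjusted_covariance"]


@dataclass
class MMMFit:
    """M marginal fits with their stacked coefficient vector and joint
    (optionally bias-adjusted) sandwich covariance."""

    fits: list[GEEFit]
    cluster_index: np.ndarray
    beta_stacked: np.ndarray
    H_block: np.ndarray
    B_matrix: np.ndarray
    sigma: np.ndarray
    model_slices: list[slice]
    _sigma_adj: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_models(self) -> int:
        return len(self.fits)

    @property
    def n_clusters(self) -> int:
        return self.cluster_index.size

    @property
    def n_params_total(self) -> int:
        return self.beta_stacked.size

    @property
    def coef_names(self) -> list[str]:
        return [
            f"{f.spec.name}:{c}" for f in self.fits for c in f.spec.coef_names
        ]

    @property
    def sigma_adj(self) -> np.ndarray:
        if self._sigma_adj is None:
            self._sigma_adj = bias_adjusted_covariance(self)
        return self._sigma_adj

    def covariance(self, bias_adjust: bool) -> np.ndarray:
        return self.sigma_adj if bias_adjust else self.sigma

    def stacked_cluster_scores(self) -> list[np.ndarray]:
        """Per-subject stacked score vectors (zero-filled where absent)."""
        P = self.n_params_total
        out = [np.zeros(P) for _ in range(self.n_clusters)]
        pos = {lab: k for k, lab in enumerate(self.cluster_index)}
        for f, sl in zip(self.fits, self.model_slices):
            for lab, u in zip(f.cluster_labels, f.cluster_scores):
                out[pos[lab]][sl] = u
        return out

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.beta_stacked,
                "robust_se": np.sqrt(np.diag(self.sigma)),
                "adjusted_se": np.sqrt(np.diag(self.sigma_adj)),
            },
            index=self.coef_names,
        )


def _symmetrize(A: np.ndarray) -> np.ndarray:
    return (A + A.T) / 2.0


def stack_models(
    fits: list[GEEFit], cluster_index: np.ndarray | None = None
) -> MMMFit:
    """Combine fitted marginal models over a shared subject index.

    ``cluster_index`` defaults to the union of the models' cluster
    labels; a subject missing from a model contributes a zero score
    sub-vector there.
    """
    if not fits:
        raise ValueError("need at least one fitted model")
    for f in fits:
        if not f.converged:
            raise ValueError(f"model {f.spec.name!r} did not converge")
    names = [f.spec.name for f in fits]
    if len(set(names)) != len(names):
        raise ValueError("model names must be unique across the stack")
    if cluster_index is None:
        all_labels = np.concatenate([f.cluster_labels for f in fits])
        cluster_index = np.unique(all_labels)
    else:
        cluster_index = np.asarray(cluster_index)
        for f in fits:
            if not np.isin(f.cluster_labels, cluster_index).all():
                raise ValueError(
                    f"model {f.spec.name!r} has clusters outside the declared index"
                )

    p_list = [f.n_params for f in fits]
    P = int(sum(p_list))
    offs = np.concatenate([[0], np.cumsum(p_list)])
    model_slices = [slice(int(a), int(b)) for a, b in zip(offs[:-1], offs[1:])]

    beta = np.concatenate([f.beta_hat for f in fits])
    H = np.zeros((P, P))
    for f, sl in zip(fits, model_slices):
        H[sl, sl] = f.H_model

    # B = sum_i U_i U_i' over stacked per-subject scores
    pos = {lab: k for k, lab in enumerate(cluster_index)}
    Umat = np.zeros((cluster_index.size, P))
    for f, sl in zip(fits, model_slices):
        rows = [pos[lab] for lab in f.cluster_labels]
        Umat[rows, sl] = np.asarray(f.cluster_scores)
    B = Umat.T @ Umat

    Hinv = np.linalg.inv(H)
    sigma = _symmetrize(Hinv @ B @ Hinv)
    return MMMFit(
        fits=fits,
        cluster_index=cluster_index,
        beta_stacked=beta,
        H_block=H,
        B_matrix=B,
        sigma=sigma,
        model_slices=model_slices,
    )


def bias_adjusted_covariance(mmm: MMMFit) -> np.ndarray:
    """Bias-adjusted joint covariance Sigma_adj = H^-1 B_adj H^-1.

    B_adj replaces each cluster residual S_i by (I - P_ii)^{-1} S_i with
    the block-diagonal leverage P_ii = D_i M^-1 D_i' V_i^-1, where
    M = sum_i D_i' V_i^-1 D_i is the (positive definite) per-model
    scoring matrix.  Diagonal blocks equal the Mancl-DeRouen adjusted
    single-model sandwich.
    """
    P = mmm.n_params_total
    pos = {lab: k for k, lab in enumerate(mmm.cluster_index)}
    Umat = np.zeros((mmm.n_clusters, P))
    for f, sl in zip(mmm.fits, mmm.model_slices):
        Minv = np.linalg.inv(-f.H_model)
        for lab, D, V, S in zip(
            f.cluster_labels, f.cluster_D, f.cluster_V, f.cluster_S
        ):
            VinvD = np.linalg.solve(V, D)
            Pii = D @ Minv @ VinvD.T  # D M^-1 D' V^-1 (via V^-1 D transpose)
            I = np.eye(Pii.shape[0])
            try:
                S_adj = np.linalg.solve(I - Pii, S)
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    f"cluster {lab!r} in model {f.spec.name!r} has leverage one; "
                    "bias adjustment is undefined"
                ) from err
            Umat[pos[lab], sl] = VinvD.T @ S_adj
    B_adj = Umat.T @ Umat
    Hinv = np.linalg.inv(mmm.H_block)
    return _symmetrize(Hinv @ B_adj @ Hinv)
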