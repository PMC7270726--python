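"""Canonical GLM family/link pairs used by the marginal models.

Only the three canonical pairs needed for mixed continuous / count /
binary endpoints are provided: identity-Gaussian, log-Poisson and
logit-Bernoulli.  For a canonical link the derivative of the mean with
respect to the linear predictor equals the variance function, so the
derivative matrices D_i of the estimating equations are X_i scaled by
the variance function row-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["Family", "get_family", "FAMILIES"]

_CLIP_EXP = 30.0  # linear predictors beyond this are saturated


def _expit(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -_CLIP_EXP, _CLIP_EXP)))


@dataclass(frozen=True)
class Family:
    """A mean/variance model: link g, inverse link, dmu/deta and nu(mu)."""

    name: str
    link: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    inverse_link: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    dmu_deta: Callable[[np.ndarray], np.ndarray] = field(repr=False)  # of eta
    variance: Callable[[np.ndarray], np.ndarray] = field(repr=False)  # of mu

    def validate_response(self, y: np.ndarray) -> None:
        if self.name == "binomial":
            if not np.isin(y, (0.0, 1.0)).all():
                raise ValueError("binomial responses must be 0/1")
        elif self.name == "poisson":
            if (y < 0).any() or not np.allclose(y, np.round(y)):
                raise ValueError("poisson responses must be nonnegative integers")


FAMILIES = {
    "gaussian": Family(
        "gaussian",
        link=lambda mu: mu,
        inverse_link=lambda eta: eta,
        dmu_deta=lambda eta: np.ones_like(eta),
        variance=lambda mu: np.ones_like(mu),
    ),
    "poisson": Family(
        "poisson",
        link=np.log,
        inverse_link=lambda eta: np.exp(np.clip(eta, -_CLIP_EXP, _CLIP_EXP)),
        dmu_deta=lambda eta: np.exp(np.clip(eta, -_CLIP_EXP, _CLIP_EXP)),
        variance=lambda mu: mu,
    ),
    "binomial": Family(
        "binomial",
        link=lambda mu: np.log(mu / (1.0 - mu)),
        inverse_link=_expit,
        dmu_deta=lambda eta: _expit(eta) * (1.0 - _expit(eta)),
        variance=lambda mu: mu * (1.0 - mu),
    ),
}

_ALIASES = {
    "gaussian": "gaussian",
    "normal": "gaussian",
    "gaussian-identity": "gaussian",
    "poisson": "poisson",
    "poisson-log": "poisson",
    "binomial": "binomial",
    "bernoulli": "binomial",
    "binomial-logit": "binomial",
}


def get_family(name: str | Family) -> Family:
    if isinstance(name, Family):
        return name
    try:
        return FAMILIES[_ALIASES[name.lower()]]
    except KeyError:
        raise ValueError(
            f"unknown family {name!r}; choose from {sorted(set(_ALIASES))}"
        ) from None
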