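"""Weighted GBLUP with fixed variance components.

The model is y = mu 1 + g + e with g ~ N(0, sigma2_g G) over the
phenotyped (reference) individuals and e ~ N(0, sigma2_e W^-1) where
W = diag(w) holds the record weights (a progeny-tested record with
effective-daughter weight w carries residual variance sigma2_e / w).
Variance components are fixed, never estimated: the mixed-model equations

    (W / sigma2_e + G^-1 / sigma2_g) g_hat = W (y - mu 1) / sigma2_e

are solved with mu the generalized-least-squares mean.  Only random
effects plus this single mean are fitted; phenotypes are assumed
pre-corrected for all other fixed effects.

Internally the equivalent single-factorization form is used:

    V = sigma2_g (G + ridge I) + sigma2_e W^-1
    mu = (1' V^-1 y) / (1' V^-1 1)
    alpha = V^-1 (y - mu 1)
    g_hat = sigma2_g (G + ridge I) alpha

which requires one Cholesky factorization of V and no explicit G inverse.
Candidate prediction by the projection g_c = G_cross G_ref^-1 g_hat_ref
collapses to g_c = sigma2_g G_cross alpha, which is algebraically
identical to including the candidates as zero-weight records in a joint
mixed-model solve (the equivalence is covered by tests, not assumed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import linalg

from .grm import DEFAULT_RIDGE, GMatrix, _as_values

__all__ = ["GblupModel", "fit_gblup", "predict_candidates"]

log = logging.getLogger(__name__)


@dataclass
class GblupModel:
    """A fitted GBLUP model over one reference population."""

    ids: np.ndarray
    mu: float
    gebv: np.ndarray          # predicted genetic values of the reference ids
    alpha: np.ndarray         # V^-1 (y - mu 1); the prediction weights
    sigma2_g: float
    sigma2_e: float
    ridge: float

    @property
    def lambda_(self) -> float:
        """Shrinkage ratio sigma2_e / sigma2_g."""
        return self.sigma2_e / self.sigma2_g


def fit_gblup(
    G_ref,
    phenotypes,
    sigma2_g: float,
    sigma2_e: float,
    weights=None,
    ridge: float = DEFAULT_RIDGE,
) -> GblupModel:
    """Solve the weighted mixed-model equations on the reference set.

    Parameters
    ----------
    G_ref:
        :class:`~gsrefresh.grm.GMatrix` (or plain square array) over the
        phenotyped individuals.
    phenotypes:
        Pre-corrected records, one per reference individual.
    sigma2_g, sigma2_e:
        Fixed genetic and residual variance components.
    weights:
        Positive record weights (default 1); the residual variance of a
        record is ``sigma2_e / weight``.
    ridge:
        Diagonal stabiliser added to G before factorization.
    """
    g = _as_values(G_ref)
    ids = G_ref.ids if isinstance(G_ref, GMatrix) else np.arange(1, g.shape[0] + 1)
    y = np.asarray(phenotypes, dtype=float)
    n = g.shape[0]
    if y.shape != (n,):
        raise ValueError(f"phenotypes have shape {y.shape}, expected ({n},)")
    if sigma2_g <= 0 or sigma2_e < 0:
        raise ValueError("sigma2_g must be positive and sigma2_e non-negative")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w <= 0):
        raise ValueError("weights must be positive, one per reference individual")

    gr = g + ridge * np.eye(n)
    V = sigma2_g * gr + np.diag(sigma2_e / w)
    try:
        cf = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"mixed-model system singular after ridge={ridge:g} "
            f"(condition number ~{np.linalg.cond(V):.3g})"
        ) from err
    ones = np.ones(n)
    vi_ones = linalg.cho_solve(cf, ones, check_finite=False)
    mu = float(vi_ones @ y) / float(vi_ones @ ones)
    alpha = linalg.cho_solve(cf, y - mu, check_finite=False)
    gebv = sigma2_g * (gr @ alpha)
    log.debug(
        "GBLUP fit: n=%d, mu=%.6g, lambda=%.4g, ridge=%g (intercept always fitted)",
        n, mu, sigma2_e / sigma2_g, ridge,
    )
    return GblupModel(
        ids=np.asarray(ids),
        mu=mu,
        gebv=gebv,
        alpha=alpha,
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        ridge=ridge,
    )


def predict_candidates(model: GblupModel, G_cross) -> np.ndarray:
    """GEBVs of unphenotyped candidates from their relationships to the
    reference population.

    ``G_cross`` is the candidate-by-reference relationship block.  The
    projection G_cross G_ref^-1 g_hat_ref equals
    ``sigma2_g * G_cross @ model.alpha`` exactly (same ridge convention),
    so no additional solve is performed.
    """
    gc = np.asarray(_as_values(G_cross), dtype=float)
    if gc.ndim == 1:
        gc = gc[None, :]
    if gc.shape[1] != model.alpha.size:
        raise ValueError(
            f"cross block has {gc.shape[1]} reference columns, model has {model.alpha.size}"
        )
    return model.sigma2_g * (gc @ model.alpha)
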