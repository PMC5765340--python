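"""Evaluation metrics: merit, diversity, bias, effective size, and trends.

The per-generation evaluation variables are

* mean true breeding value of the group (response to selection),
* observed heterozygosity (fraction of heterozygous marker loci),
* pedigree inbreeding F (Wright's coefficient, computed either by the
  O(n^2) tabular relationship recursion or by the Meuwissen-Luo style
  ancestor-traversal algorithm; the two must agree),
* absolute standardized prediction bias |GEBV - BV| / sigma_G, with
  sigma_G the true-BV standard deviation of the group under scrutiny,
* effective population size Ne = 1 / (2 f_t) from the mean inbreeding
  level f_t (exactly this form; the conventional rate-based
  Ne = 1/(2 deltaF) is deliberately not implemented here).

Generation trends are estimated as per-replicate ordinary-least-squares
slopes averaged over replicates, with the across-replicate standard error
and a normal-approximation 95% interval — a deliberate simplification of
a REML mixed model with a random replicate effect, unbiased for the slope
under that model.
"""

from __future__ import annotations

from dataclasses import dataclass
from heapq import heappush, heappop
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .synthpop import Pedigree

__all__ = [
    "EffectiveSizeUndefined",
    "observed_heterozygosity",
    "relationship_matrix",
    "pedigree_inbreeding",
    "prediction_bias",
    "effective_size",
    "effective_size_or_nan",
    "generation_equivalents",
    "generation_equivalents_all",
    "estimate_trends",
]


class EffectiveSizeUndefined(ValueError):
    """Signals Ne = 1/(2 f_t) is undefined (infinite) because f_t = 0."""


def observed_heterozygosity(dosages) -> np.ndarray:
    """Per-individual fraction of marker loci with dosage 1.

    Accepts a (n_individuals, n_markers) dosage array (or anything with a
    ``dosages`` attribute); the group mean is simply ``result.mean()``.
    """
    x = getattr(dosages, "dosages", dosages)
    x = np.atleast_2d(np.asarray(x))
    if x.shape[1] == 0:
        raise ValueError("heterozygosity undefined for zero markers")
    return (x == 1).mean(axis=1)


# ---------------------------------------------------------------------------
# pedigree inbreeding
# ---------------------------------------------------------------------------

def relationship_matrix(pedigree: Pedigree) -> np.ndarray:
    """Additive (numerator) relationship matrix A by the tabular method.

    Rows follow pedigree order (parents before offspring).  Memory is
    O(n^2); intended for pedigrees up to a few thousand individuals.
    """
    sidx, didx = pedigree.parent_indices()
    n = pedigree.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sidx[i], didx[i]
        if s >= 0 and d >= 0:
            A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
            A[i, i] = 1.0 + 0.5 * A[s, d]
        elif s >= 0 or d >= 0:
            k = s if s >= 0 else d
            A[i, :i] = 0.5 * A[k, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    return A


def _f_tabular(pedigree: Pedigree) -> np.ndarray:
    return np.diag(relationship_matrix(pedigree)) - 1.0


def _f_meuwissen_luo(pedigree: Pedigree) -> np.ndarray:
    """Wright's F via per-individual ancestor traversal (no A matrix).

    For individual i with both parents known, 1 + F_i is the i-th diagonal
    of A = L D L': the sum over ancestors j of L_ij^2 d_j, where L_ij is
    the expected genome fraction transmitted from j to i and d_j the
    Mendelian-sampling variance given j's parents' inbreeding.
    """
    sidx, didx = pedigree.parent_indices()
    n = pedigree.n
    F = np.zeros(n)

    # Mendelian sampling variance of each individual given its parents
    def dvar(j: int) -> float:
        s, d = sidx[j], didx[j]
        if s >= 0 and d >= 0:
            return 0.5 - 0.25 * (F[s] + F[d])
        if s >= 0 or d >= 0:
            return 0.75 - 0.25 * F[s if s >= 0 else d]
        return 1.0

    for i in range(n):
        s, d = sidx[i], didx[i]
        if s < 0 or d < 0:
            F[i] = 0.0
            continue
        L: dict[int, float] = {i: 1.0}
        heap = [-i]
        a_ii = 0.0
        while heap:
            j = -heappop(heap)
            lj = L.pop(j)
            a_ii += lj * lj * dvar(j)
            for p in (sidx[j], didx[j]):
                if p >= 0:
                    if p not in L:
                        L[p] = 0.0
                        heappush(heap, -p)
                    L[p] += 0.5 * lj
        F[i] = a_ii - 1.0
    return F


def pedigree_inbreeding(pedigree: Pedigree, method: str = "auto") -> np.ndarray:
    """Wright's inbreeding coefficient for every individual.

    ``method`` is ``"tabular"``, ``"meuwissen_luo"``, or ``"auto"`` (tabular
    below 3,000 individuals, traversal above).
    """
    if method == "auto":
        method = "tabular" if pedigree.n <= 3000 else "meuwissen_luo"
    if method == "tabular":
        return _f_tabular(pedigree)
    if method == "meuwissen_luo":
        return _f_meuwissen_luo(pedigree)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# bias, effective size, pedigree completeness
# ---------------------------------------------------------------------------

def prediction_bias(gebv, bv, sigma_g: float) -> np.ndarray:
    """Absolute standardized prediction errors |GEBV_k - BV_k| / sigma_G.

    ``sigma_g`` is the true-BV standard deviation of the group under
    scrutiny (recompute it per evaluated group).
    """
    if sigma_g <= 0:
        raise ValueError("sigma_g must be positive")
    return np.abs(np.asarray(gebv, float) - np.asarray(bv, float)) / sigma_g


def effective_size(mean_f: float) -> float:
    """Effective population size Ne = 1 / (2 f_t) from the inbreeding level."""
    if mean_f < 0 or mean_f >= 1:
        raise ValueError("mean_f must lie in [0, 1)")
    if mean_f == 0:
        raise EffectiveSizeUndefined("mean inbreeding is zero: Ne is infinite")
    return 1.0 / (2.0 * mean_f)


def effective_size_or_nan(mean_f: float) -> float:
    """Table-friendly variant: NaN where :func:`effective_size` is undefined."""
    try:
        return effective_size(mean_f)
    except EffectiveSizeUndefined:
        return np.nan


def generation_equivalents(pedigree: Pedigree, id_) -> float:
    """Pedigree completeness: sum over ancestor generations g of the
    proportion of known ancestors at depth g (each parent contributes 1/2,
    each known grandparent 1/4, ...)."""
    if id_ not in pedigree._index:
        raise KeyError(f"unknown id {id_!r}")
    return float(generation_equivalents_all(pedigree)[pedigree.index_of(id_)])


def generation_equivalents_all(pedigree: Pedigree) -> np.ndarray:
    """Generation equivalents for every individual, in pedigree order.

    Uses the recursion ge(i) = sum over known parents p of (1 + ge(p)) / 2,
    evaluated in pedigree order so each individual is visited once.
    """
    sidx, didx = pedigree.parent_indices()
    ge = np.zeros(pedigree.n)
    for i in range(pedigree.n):
        acc = 0.0
        for p in (sidx[i], didx[i]):
            if p >= 0:
                acc += 0.5 * (1.0 + ge[p])
        ge[i] = acc
    return ge


# ---------------------------------------------------------------------------
# generation trends
# ---------------------------------------------------------------------------

def _arcsine_sqrt(x: np.ndarray) -> np.ndarray:
    return np.arcsin(np.sqrt(np.clip(x, 0.0, 1.0)))


def estimate_trends(
    metrics: pd.DataFrame,
    metric: str,
    transform: Optional[str] = None,
    covariate: Optional[str] = None,
    group_col: str = "strategy",
) -> pd.DataFrame:
    """Per-strategy generation slopes from a tidy metrics table.

    For every (strategy, replicate) an OLS slope of ``metric`` on
    ``generation`` is fitted (optionally adjusting for ``covariate``,
    e.g. ``ne_over_n``); slopes are averaged over replicates, with the
    across-replicate SE and a 1.96-SE confidence interval.  Set
    ``transform="arcsine_sqrt"`` for proportion-valued metrics such as
    heterozygosity or inbreeding.
    """
    required = {group_col, "replicate", "generation", metric}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table lacks columns: {sorted(missing)}")
    if metrics["generation"].nunique() < 2:
        raise ValueError("need at least two generations to estimate a trend")

    rows = []
    for strat, sub in metrics.groupby(group_col, sort=True):
        slopes = []
        for _, rep in sub.groupby("replicate"):
            rep = rep.dropna(subset=[metric] + ([covariate] if covariate else []))
            if rep["generation"].nunique() < 2:
                continue
            y = rep[metric].to_numpy(dtype=float)
            if transform == "arcsine_sqrt":
                y = _arcsine_sqrt(y)
            elif transform is not None:
                raise ValueError(f"unknown transform {transform!r}")
            cols = [np.ones(len(rep)), rep["generation"].to_numpy(dtype=float)]
            if covariate:
                cols.append(rep[covariate].to_numpy(dtype=float))
            X = np.column_stack(cols)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            slopes.append(beta[1])
        if len(slopes) < 2:
            raise ValueError(
                f"strategy {strat!r}: need >=2 replicates with >=2 generations"
            )
        slopes = np.asarray(slopes)
        est = slopes.mean()
        se = slopes.std(ddof=1) / np.sqrt(slopes.size)
        rows.append(
            {
                group_col: strat,
                "metric": metric,
                "slope": est,
                "se": se,
                "ci_low": est - 1.96 * se,
                "ci_high": est + 1.96 * se,
                "n_replicates": slopes.size,
            }
        )
    return pd.DataFrame(rows)
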