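"""Optimal-contribution selection under an inbreeding-rate cap.

Selecting a group with contribution vector c (c >= 0, sum c = 1) from a
candidate set with genomic relationship matrix G gives the group a
coancestry of c'Gc/2 — the expected inbreeding of progeny bred from the
group.  The expected rate of inbreeding relative to the current
generation's mean-inbreeding proxy f_t is

    deltaF(c) = (c'Gc/2 - f_t) / (1 - f_t),  floored at zero.

``optimal_contributions`` maximizes group merit c'ghat subject to
deltaF(c) <= deltaF_max (default 1%, the FAO-recommended ceiling).  The
constrained optimum follows the classical Lagrangian solution
c = G^-1 (ghat - lambda0 1) / (2 lambda) with the multipliers fixed by
the two equality constraints, plus iterative zeroing of negative
contributions.  When the cap is unattainable for the candidate set the
minimum-coancestry solution is returned with ``feasible=False`` — merit
is then effectively not considered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg

from .grm import GMatrix, _as_values

__all__ = [
    "OC_RIDGE",
    "OCParams",
    "ContributionVector",
    "expected_deltaF",
    "min_coancestry",
    "optimal_contributions",
    "select_update_group",
]

log = logging.getLogger(__name__)

# Stabiliser for inverting candidate G-matrices inside the optimizer.  Kept
# tiny (unlike the GBLUP ridge) so the enforced constraint c'(G + r I)c <= C
# implies the raw-G constraint with only an O(r) margin.
OC_RIDGE = 1e-8

_NEG_TOL = 1e-12
_FEAS_TOL = 1e-6


@dataclass
class OCParams:
    """Parameters of the optimal-contribution problem."""

    deltaF_max: float = 0.01
    current_mean_f: float = 0.0
    ridge: float = OC_RIDGE

    def __post_init__(self):
        if not (0.0 < self.deltaF_max < 1.0):
            raise ValueError("deltaF_max must lie in (0, 1)")
        if not (0.0 <= self.current_mean_f < 1.0):
            raise ValueError("current_mean_f must lie in [0, 1)")


@dataclass
class ContributionVector:
    """Nonnegative contributions over a candidate set, summing to one."""

    ids: np.ndarray
    values: np.ndarray
    merit: float = np.nan          # c' ghat
    deltaF: float = np.nan         # achieved expected rate of inbreeding
    coancestry: float = np.nan     # c'Gc / 2 on the raw G
    feasible: bool = True
    gebv: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.ids.shape:
            raise ValueError("ids and values must align")
        if np.any(self.values < -_NEG_TOL):
            raise ValueError("contributions must be nonnegative")
        s = self.values.sum()
        if abs(s - 1.0) > 1e-8:
            raise ValueError(f"contributions must sum to 1 (got {s})")


def expected_deltaF(c, G, current_mean_f: float) -> float:
    """Expected rate of inbreeding of the group defined by contributions c.

    ``current_mean_f`` is the mean-inbreeding proxy of the current
    generation; the rate is the increase of group coancestry over that
    baseline, scaled by the remaining heterozygosity, and floored at zero.
    """
    if current_mean_f >= 1.0:
        raise ValueError("current_mean_f must be below 1")
    v = c.values if isinstance(c, ContributionVector) else np.asarray(c, dtype=float)
    g = _as_values(G)
    coan = 0.5 * float(v @ g @ v)
    return max(0.0, (coan - current_mean_f) / (1.0 - current_mean_f))


def _solve_psd(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return linalg.cho_solve(
        linalg.cho_factor(a, lower=True, check_finite=False), b, check_finite=False
    )


def min_coancestry(G, ids=None, ridge: float = OC_RIDGE) -> ContributionVector:
    """Contributions minimizing group coancestry c'Gc/2 on the simplex.

    The unconstrained solution is G^-1 1 / (1' G^-1 1); negative entries are
    zeroed iteratively and the reduced system re-solved until all remaining
    contributions are nonnegative.
    """
    g = _as_values(G)
    n = g.shape[0]
    if ids is None:
        ids = G.ids if isinstance(G, GMatrix) else np.arange(1, n + 1)
    gr = g + ridge * np.eye(n)
    active = np.ones(n, dtype=bool)
    c = np.zeros(n)
    for _ in range(10 * n):
        idx = np.nonzero(active)[0]
        u = _solve_psd(gr[np.ix_(idx, idx)], np.ones(idx.size))
        ca = u / u.sum()
        if ca.min() >= -_NEG_TOL:
            c[:] = 0.0
            c[idx] = np.clip(ca, 0.0, None)
            c /= c.sum()
            break
        active[idx[ca < -_NEG_TOL]] = False
        if active.sum() == 1:
            c[:] = 0.0
            c[np.nonzero(active)[0]] = 1.0
            break
    coan = 0.5 * float(c @ g @ c)
    return ContributionVector(
        ids=np.asarray(ids), values=c, coancestry=coan, feasible=True
    )


def _constrained_solution(gr: np.ndarray, ghat: np.ndarray, C: float) -> Optional[np.ndarray]:
    """Merit-maximizing contributions on {1'c = 1, c'(gr)c = C}; None when the
    constraint surface degenerates (cap at or below the active-set minimum, or
    flat merit)."""
    gi_one = _solve_psd(gr, np.ones(gr.shape[0]))
    gi_g = _solve_psd(gr, ghat)
    A = float(np.ones(gr.shape[0]) @ gi_one)
    B = float(ghat @ gi_one)
    Q = float(ghat @ gi_g)
    denom = C * A - 1.0
    num = Q * A - B * B
    if denom <= 1e-14 or num <= 1e-14 * max(1.0, abs(Q * A)):
        return None
    s = float(np.sqrt(num / denom))  # s = 2 lambda
    lam0 = (B - s) / A
    return (gi_g - lam0 * gi_one) / s


def optimal_contributions(gebv, G, params: OCParams, ids=None) -> ContributionVector:
    """Maximize group merit subject to the expected inbreeding-rate cap.

    Returns the contribution vector with its achieved merit and expected
    rate of inbreeding (evaluated on the raw G).  ``feasible`` is False
    when the cap is below the minimum rate achievable for the candidate
    set, in which case the minimum-coancestry solution is returned.
    """
    ghat = np.asarray(gebv, dtype=float)
    g = _as_values(G)
    n = g.shape[0]
    if ghat.shape != (n,):
        raise ValueError(f"gebv has shape {ghat.shape}, G is {g.shape}")
    if ids is None:
        ids = G.ids if isinstance(G, GMatrix) else np.arange(1, n + 1)
    ids = np.asarray(ids)

    f_t = params.current_mean_f
    C = 2.0 * (params.deltaF_max * (1.0 - f_t) + f_t)  # cap on c'Gc
    gr = g + params.ridge * np.eye(n)

    def finish(c: np.ndarray, feasible: bool) -> ContributionVector:
        c = np.clip(c, 0.0, None)
        c = c / c.sum()
        return ContributionVector(
            ids=ids,
            values=c,
            merit=float(c @ ghat),
            deltaF=expected_deltaF(c, g, f_t),
            coancestry=0.5 * float(c @ g @ c),
            feasible=feasible,
            gebv=ghat,
        )

    # Feasibility: compare the cap with the minimum achievable coancestry.
    mc = min_coancestry(g, ids=ids, ridge=params.ridge)
    c_min = mc.values
    min_quad = float(c_min @ gr @ c_min)
    if C <= min_quad * (1.0 + 1e-12) + 1e-12:
        feasible = expected_deltaF(c_min, g, f_t) <= params.deltaF_max + _FEAS_TOL
        if not feasible:
            log.info(
                "deltaF cap %.4g unattainable (minimum %.4g); returning "
                "minimum-coancestry contributions", params.deltaF_max,
                expected_deltaF(c_min, g, f_t),
            )
        return finish(c_min, feasible)

    # If the unconstrained merit maximum (a simplex vertex) meets the cap,
    # the linear objective is maximized there.
    id_rank = np.argsort(np.argsort(ids, kind="stable"), kind="stable")
    k_star = int(np.lexsort((id_rank, -ghat))[0])
    if gr[k_star, k_star] <= C:
        c = np.zeros(n)
        c[k_star] = 1.0
        return finish(c, True)

    # Active-set iteration on the Lagrangian solution.
    active = np.ones(n, dtype=bool)
    c = c_min.copy()
    for _ in range(10 * n):
        idx = np.nonzero(active)[0]
        if idx.size == 1:
            c = np.zeros(n)
            c[idx] = 1.0
            break
        sol = _constrained_solution(gr[np.ix_(idx, idx)], ghat[idx], C)
        if sol is None:
            # cap not binding above this face's minimum (or flat merit):
            # fall back to the face's minimum-coancestry point
            sub = min_coancestry(g[np.ix_(idx, idx)], ids=ids[idx], ridge=params.ridge)
            c = np.zeros(n)
            c[idx] = sub.values
            break
        if sol.min() >= -_NEG_TOL:
            c = np.zeros(n)
            c[idx] = np.clip(sol, 0.0, None)
            break
        active[idx[sol < -_NEG_TOL]] = False

    out = finish(c, True)
    # numerical safeguard: the optimizer must never do worse than the
    # feasible minimum-coancestry point it started from
    if np.isfinite(out.merit) and out.merit < float(c_min @ ghat):
        return finish(c_min, True)
    return out


def select_update_group(c: ContributionVector, n: int) -> np.ndarray:
    """The ``n`` candidate ids with the largest contributions.

    Ties are broken by higher GEBV and then by ascending id.  Candidates
    with zero contribution are admitted only when fewer than ``n``
    contributions are positive (logged).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > c.ids.size:
        raise ValueError(f"cannot select {n} from {c.ids.size} candidates")
    gebv = c.gebv if c.gebv is not None else np.zeros(c.ids.size)
    id_rank = np.argsort(np.argsort(c.ids, kind="stable"), kind="stable")
    order = np.lexsort((id_rank, -gebv, -c.values))
    n_pos = int((c.values > 0).sum())
    if n_pos < n:
        log.info(
            "only %d candidates received positive contributions; admitting "
            "%d zero-contribution candidates by GEBV", n_pos, n - n_pos,
        )
    return c.ids[order[:n]]
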