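"""Genomic relationship matrices and marker quality control.

Two relationship constructions are provided:

* ``vanraden_grm`` — the frequency-centred matrix G = ZZ' / (2 sum p_i(1-p_i))
  with Z = X - 2p, the standard choice for GBLUP.
* ``similarity_grm`` — the allele-sharing similarity
  G_jk = (2/N) sum_i (x_ij - 1)(x_ik - 1), which counts identical alleles
  between two individuals averaged over the N markers.  With all allele
  frequencies fixed at 0.5 the VanRaden matrix reduces to exactly this
  similarity matrix; the similarity form is the default relationship used
  by the optimal-contribution update strategy because it tracks overall
  (not frequency-weighted) diversity.

Marker QC implements the usual chip filters: call rate, a one-degree-of-
freedom Hardy-Weinberg chi-square test, and a minor-allele-frequency
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_RIDGE",
    "GenotypeMatrix",
    "GMatrix",
    "EmptyFilterResult",
    "qc_filter",
    "hwe_chi2",
    "impute_missing",
    "vanraden_grm",
    "similarity_grm",
]

# Diagonal ridge added before any inversion of a G-matrix built from a
# finite marker panel (such matrices are routinely singular).
DEFAULT_RIDGE = 1e-2


class EmptyFilterResult(ValueError):
    """Raised when quality control removes every marker."""


@dataclass
class GenotypeMatrix:
    """Dosage matrix (individuals x markers), values in {0, 1, 2} or NaN."""

    dosages: np.ndarray
    ids: np.ndarray = None
    marker_ids: np.ndarray = None
    qc_report: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x markers)")
        n, m = self.dosages.shape
        if self.ids is None:
            self.ids = np.arange(1, n + 1)
        self.ids = np.asarray(self.ids)
        if self.marker_ids is None:
            self.marker_ids = np.asarray([f"m{j + 1}" for j in range(m)])
        self.marker_ids = np.asarray(self.marker_ids)
        if self.ids.size != n or self.marker_ids.size != m:
            raise ValueError("id arrays inconsistent with dosage dimensions")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def allele_freqs(self) -> np.ndarray:
        """Observed alternate-allele frequency per marker (missing ignored)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freqs()
        return np.minimum(p, 1.0 - p)


@dataclass
class GMatrix:
    """Square symmetric genomic relationship matrix with a method tag."""

    values: np.ndarray
    ids: np.ndarray = None
    method: str = "vanraden"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("G must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("G must be symmetric (tolerance 1e-10)")
        if self.ids is None:
            self.ids = np.arange(1, self.values.shape[0] + 1)
        self.ids = np.asarray(self.ids)
        if self.ids.size != self.values.shape[0]:
            raise ValueError("ids inconsistent with matrix dimension")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def with_ridge(self, ridge: float = DEFAULT_RIDGE) -> np.ndarray:
        return self.values + ridge * np.eye(self.n)

    def take(self, rows) -> "GMatrix":
        rows = np.asarray(rows, dtype=np.intp)
        return GMatrix(self.values[np.ix_(rows, rows)], self.ids[rows], self.method)


def _as_values(G) -> np.ndarray:
    return G.values if isinstance(G, GMatrix) else np.asarray(G, dtype=float)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def hwe_chi2(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker 1-df chi-square statistic and p-value for departure from
    Hardy-Weinberg genotype proportions (no continuity correction)."""
    x = np.asarray(dosages, dtype=float)
    obs = np.stack([np.nansum(x == d, axis=0) for d in (0.0, 1.0, 2.0)])  # (3, m)
    n = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (obs[1] + 2 * obs[2]) / (2 * n)
        exp = np.stack([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
        terms = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
    chi2 = terms.sum(axis=0)
    return chi2, stats.chi2.sf(chi2, df=1)


def qc_filter(
    genotypes: GenotypeMatrix,
    call_rate_min: float = 0.9,
    hwe_p_min: float = 1e-4,
    maf_min: float = 0.01,
) -> GenotypeMatrix:
    """Apply the chip QC filters and return the retained markers.

    A marker is kept when its call rate exceeds ``call_rate_min``, its
    minor-allele frequency exceeds ``maf_min``, and its Hardy-Weinberg
    chi-square p-value is at least ``hwe_p_min`` (markers departing from
    HWE at p below the threshold are treated as probable genotyping
    errors).  Individuals are never removed.  The returned matrix carries a
    ``qc_report`` DataFrame with the per-marker decisions.
    """
    for name, v in (("call_rate_min", call_rate_min), ("hwe_p_min", hwe_p_min), ("maf_min", maf_min)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if genotypes.n_markers == 0 or genotypes.n_individuals == 0:
        raise ValueError("genotype matrix is empty")

    cr = genotypes.call_rate()
    maf = genotypes.maf()
    chi2, hwe_p = hwe_chi2(genotypes.dosages)

    keep = (cr > call_rate_min) & (maf > maf_min) & (hwe_p >= hwe_p_min)
    reasons = np.where(
        cr <= call_rate_min,
        "call_rate",
        np.where(maf <= maf_min, "maf", np.where(hwe_p < hwe_p_min, "hwe", "")),
    )
    report = pd.DataFrame(
        {
            "marker_id": genotypes.marker_ids,
            "call_rate": cr,
            "maf": maf,
            "hwe_chi2": chi2,
            "hwe_p": hwe_p,
            "kept": keep,
            "reason": reasons,
        }
    )
    if not keep.any():
        raise EmptyFilterResult("quality control removed every marker")
    return GenotypeMatrix(
        genotypes.dosages[:, keep],
        genotypes.ids,
        genotypes.marker_ids[keep],
        qc_report=report,
    )


def impute_missing(genotypes: GenotypeMatrix, freqs: Optional[np.ndarray] = None) -> GenotypeMatrix:
    """Mean-impute missing dosages to 2p (expected dosage under HWE)."""
    p = genotypes.allele_freqs() if freqs is None else np.asarray(freqs, float)
    x = genotypes.dosages.copy()
    miss = np.isnan(x)
    if miss.any():
        x[miss] = np.broadcast_to(2.0 * p, x.shape)[miss]
    return GenotypeMatrix(x, genotypes.ids, genotypes.marker_ids)


# ---------------------------------------------------------------------------
# relationship matrices
# ---------------------------------------------------------------------------

def vanraden_grm(genotypes, freqs: Optional[np.ndarray] = None) -> GMatrix:
    """Frequency-centred genomic relationship matrix G = ZZ'/(2 sum p(1-p)).

    ``genotypes`` may be a :class:`GenotypeMatrix` or a plain dosage array.
    ``freqs`` defaults to the observed allele frequencies of the supplied
    matrix; pass base-population frequencies to fix the centring across
    repeated evaluations.  Missing dosages must be imputed beforehand (see
    :func:`impute_missing`).
    """
    if isinstance(genotypes, GenotypeMatrix):
        x, ids = genotypes.dosages, genotypes.ids
    else:
        x = np.asarray(genotypes, dtype=float)
        ids = None
    if np.isnan(x).any():
        raise ValueError("missing dosages present; impute before building G")
    p = x.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=float)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all markers monomorphic: zero VanRaden denominator")
    z = x - 2.0 * p
    g = (z @ z.T) / denom
    g = 0.5 * (g + g.T)
    return GMatrix(g, ids, "vanraden")


def similarity_grm(genotypes) -> GMatrix:
    """Allele-sharing similarity matrix G_jk = (2/N) sum_i (x_ij-1)(x_ik-1).

    Self-similarities lie in [0, 2] (0 for a fully heterozygous individual,
    2 for a fully homozygous one); off-diagonal values lie in [-2, 2].
    """
    if isinstance(genotypes, GenotypeMatrix):
        x, ids = genotypes.dosages, genotypes.ids
    else:
        x = np.asarray(genotypes, dtype=float)
        ids = None
    if x.shape[1] < 1:
        raise ValueError("similarity G requires at least one marker")
    if np.isnan(x).any():
        raise ValueError("missing dosages present; impute before building G")
    w = x - 1.0
    g = (2.0 / x.shape[1]) * (w @ w.T)
    g = 0.5 * (g + g.T)
    return GMatrix(g, ids, "similarity")
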