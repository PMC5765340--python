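"""File formats and configuration.

All formats are plain text: pedigrees and matrices are tab-separated,
metrics tables are comma-separated CSV (UTF-8, '.' decimal).  Ids are
treated as strings throughout — simulated integer ids are serialized as
their decimal strings — so the same readers accept registry-style ids
from real data deposits.

* Pedigree: 4 columns (id, sire, dam, generation), "0" = unknown parent.
  Rows may arrive in any order; the reader topologically sorts them and
  reports cycles by id.
* G-matrix: dense square TSV with a leading header row and column of ids.
* Genotypes: PLINK-RAW-style dosage table — header ``id`` + marker names,
  cells in {0, 1, 2, NA}.
* Phenotypes: TSV with header (id, phenotype, weight).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .grm import GenotypeMatrix, GMatrix
from .synthpop import GenomeSpec, Pedigree

__all__ = [
    "PedigreeFormatError",
    "read_pedigree",
    "write_pedigree",
    "read_gmatrix",
    "write_gmatrix",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_metrics",
    "write_metrics",
    "load_config",
    "scheme_config_from_dict",
]

log = logging.getLogger(__name__)

UNKNOWN = "0"


class PedigreeFormatError(ValueError):
    pass


def _toposort(ids, sires, dams):
    """Kahn's algorithm over the parent->child graph; raises on cycles."""
    pos = {i: k for k, i in enumerate(ids)}
    children: dict[str, list[str]] = {i: [] for i in ids}
    indeg = {i: 0 for i in ids}
    for i, s, d in zip(ids, sires, dams):
        for p in (s, d):
            if p != UNKNOWN and p in pos:
                children[p].append(i)
                indeg[i] += 1
    import heapq

    # stable: among ready individuals, keep the original file order
    queue = [pos[i] for i in ids if indeg[i] == 0]
    heapq.heapify(queue)
    order = []
    while queue:
        i = ids[heapq.heappop(queue)]
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(queue, pos[c])
    if len(order) != len(ids):
        cyc = sorted(i for i in ids if indeg[i] > 0)
        raise PedigreeFormatError(f"pedigree contains a cycle involving ids: {cyc}")
    return order


def read_pedigree(path) -> Pedigree:
    """Read a 4-column pedigree TSV, validate it, and order it so parents
    precede offspring."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] != 4:
        raise PedigreeFormatError(
            f"{path}: expected 4 tab-separated columns, found {df.shape[1]}"
        )
    df.columns = ["id", "sire", "dam", "generation"]
    # tolerate a header line
    if not df.iloc[0]["generation"].lstrip("-").isdigit():
        df = df.iloc[1:].reset_index(drop=True)
    dup = df["id"][df["id"].duplicated()]
    if len(dup):
        lines = (df.index[df["id"].isin(dup)] + 1).tolist()
        raise PedigreeFormatError(f"{path}: duplicate ids {sorted(set(dup))} (lines {lines})")
    ids = df["id"].tolist()
    order = _toposort(ids, df["sire"].tolist(), df["dam"].tolist())
    df = df.set_index("id").loc[order].reset_index()
    return Pedigree(
        np.asarray(df["id"], dtype=object),
        np.asarray(df["sire"], dtype=object),
        np.asarray(df["dam"], dtype=object),
        df["generation"].astype(int).to_numpy(),
    )


def write_pedigree(pedigree: Pedigree, path) -> None:
    pd.DataFrame(
        {
            "id": [str(i) for i in pedigree.ids],
            "sire": [str(i) for i in pedigree.sire_ids],
            "dam": [str(i) for i in pedigree.dam_ids],
            "generation": pedigree.generation,
        }
    ).to_csv(path, sep="\t", header=False, index=False)


def read_gmatrix(path, method: str = "vanraden") -> GMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    row_ids = [str(i) for i in df.index]
    if ids != row_ids:
        raise ValueError(f"{path}: row and column ids differ (matrix must be square)")
    return GMatrix(df.to_numpy(dtype=float), np.asarray(ids, dtype=object), method)


def write_gmatrix(G: GMatrix, path) -> None:
    ids = [str(i) for i in G.ids]
    pd.DataFrame(G.values, index=ids, columns=ids).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def read_genotypes(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return GenotypeMatrix(
        df.to_numpy(dtype=float),
        np.asarray([str(i) for i in df.index], dtype=object),
        np.asarray(df.columns, dtype=object),
    )


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        gm.dosages, index=[str(i) for i in gm.ids], columns=gm.marker_ids
    )
    df.index.name = "id"
    with np.errstate(invalid="ignore"):
        df = df.where(~df.isna(), other=np.nan)
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%g")


def write_haplotypes(population, path) -> None:
    """Persist phased haplotypes as text: one line per haplotype,
    ``id<TAB>hap_index<TAB>alleles`` with alleles a 0/1 string over all loci
    (markers and QTL in genome order)."""
    with open(path, "w") as fh:
        fh.write(f"# n_loci={population.genome.n_loci}\n")
        for row in range(population.n):
            for h in (0, 1):
                alleles = "".join(map(str, population.haps[row, h].tolist()))
                fh.write(f"{population.ids[row]}\t{h}\t{alleles}\n")


def read_haplotypes(path) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`write_haplotypes`: returns (ids, haps) with ``haps``
    of shape (n_individuals, 2, n_loci)."""
    ids, rows = [], {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            id_, h, alleles = line.rstrip("\n").split("\t")
            if id_ not in rows:
                rows[id_] = [None, None]
                ids.append(id_)
            rows[id_][int(h)] = np.frombuffer(alleles.encode(), dtype=np.uint8) - ord("0")
    haps = np.stack([np.stack(rows[i]) for i in ids]).astype(np.uint8)
    return np.asarray(ids, dtype=object), haps


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = {"id", "phenotype"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: phenotype file needs columns id, phenotype[, weight]")
    df["phenotype"] = df["phenotype"].astype(float)
    if "weight" not in df.columns:
        df["weight"] = 1.0
    df["weight"] = df["weight"].astype(float)
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["id"] = out["id"].astype(str)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_metrics(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_metrics(df: pd.DataFrame, path, header_comment: Optional[str] = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def scheme_config_from_dict(cfg: dict):
    """Build a SchemeConfig (and its GenomeSpec) from a plain mapping, as
    loaded from YAML.  Unknown keys raise."""
    from .scheme import SchemeConfig

    cfg = dict(cfg)
    genome_cfg = cfg.pop("genome", {})
    genome = GenomeSpec.default(**genome_cfg) if isinstance(genome_cfg, dict) else genome_cfg
    return SchemeConfig(genome=genome, **cfg)
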