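"""Deterministic miniature datasets for end-to-end exercise of the pipeline.

``make_update_fixture`` builds, entirely in silico, a population with the
three-way structure the single-generation update experiment assumes: an
initial phenotyped reference cohort (A1), a phenotyped candidate cohort
(A2) and an unphenotyped validation cohort (V) whose true breeding values
are held out.  Males carry progeny-test-style records: a record weight
around 25 and correspondingly reduced residual noise.

``make_known_answer_sets`` writes micro-fixtures whose expected outputs
are hand-computable (a two-marker relationship case, a full-sib/half-sib
pedigree, an identity-matrix optimal-contribution case) together with a
JSON manifest of the expected values, so file readers and core operations
can be checked end to end from disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as gio
from .grm import GenotypeMatrix
from .synthpop import (
    SEX_FEMALE,
    SEX_MALE,
    GenomeSpec,
    Population,
    TraitModel,
    assign_phenotypes,
    assign_trait,
    make_offspring_batch,
    simulate_founders,
)

__all__ = ["FixtureSpec", "PRESETS", "make_update_fixture", "make_known_answer_sets"]

PRESETS = {
    # ~50 individuals / 200 markers: smoke-test scale
    "tiny": dict(
        n_chromosomes=2,
        n_markers_per_chrom=100,
        n_qtl_per_chrom=10,
        n_founder_males=7,
        n_founder_females=7,
        cohort_size=12,
        n_burnin=10,
        burnin_size=40,
        male_weight=25.0,
    ),
    # 2,000 individuals / 2,000 markers: the desk scale
    "desk": dict(
        n_chromosomes=10,
        n_markers_per_chrom=200,
        n_qtl_per_chrom=20,
        n_founder_males=250,
        n_founder_females=250,
        cohort_size=500,
        n_burnin=50,
        burnin_size=500,
        male_weight=25.0,
    ),
}


@dataclass
class FixtureSpec:
    """Scale and trait preset for a synthetic update-experiment dataset."""

    preset: str = "tiny"
    seed: int = 0
    sigma2_g: float = 423_390.0
    sigma2_e: float = 987_910.0
    overrides: dict = field(default_factory=dict)

    def params(self) -> dict:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        p = dict(PRESETS[self.preset])
        p.update(self.overrides)
        return p


def make_update_fixture(spec: FixtureSpec, outdir: Optional[Path] = None) -> dict:
    """Simulate founders plus three cohorts and split them into A1/A2/V.

    Founders and the first cohort form A1 (phenotyped), the second cohort
    A2 (phenotyped candidates), the third cohort V (unphenotyped, true BVs
    held out).  Returns a dict with ``genotypes`` (:class:`GenotypeMatrix`),
    ``phenotypes`` (DataFrame), ``pedigree``, ``splits`` and ``bv``; when
    ``outdir`` is given, everything is also written in the standard text
    formats.
    """
    p = spec.params()
    rng = np.random.default_rng(spec.seed)
    genome = GenomeSpec.default(
        n_chromosomes=p["n_chromosomes"],
        n_markers_per_chrom=p["n_markers_per_chrom"],
        n_qtl_per_chrom=p["n_qtl_per_chrom"],
    )
    pop = simulate_founders(
        genome,
        p["n_founder_males"],
        p["n_founder_females"],
        p["n_burnin"],
        rng=rng,
        burnin_size=p["burnin_size"],
    )
    trait = TraitModel.draw(genome, rng, spec.sigma2_g, spec.sigma2_e)
    trait = assign_trait(pop, trait, rescale=True)

    for g in (1, 2, 3):
        prev = np.nonzero(pop.generation == g - 1)[0]
        males = prev[pop.sex[prev] == SEX_MALE]
        females = prev[pop.sex[prev] == SEX_FEMALE]
        k = p["cohort_size"]
        sires = males[rng.integers(0, males.size, k)]
        dams = females[rng.integers(0, females.size, k)]
        sexes = np.where(rng.random(k) < 0.5, SEX_MALE, SEX_FEMALE)
        make_offspring_batch(pop, sires, dams, sexes, g, trait, rng)

    a1_rows = np.nonzero(pop.generation <= 1)[0]
    a2_rows = np.nonzero(pop.generation == 2)[0]
    v_rows = np.nonzero(pop.generation == 3)[0]

    # phenotype A1 and A2; males get heavy progeny-test-style records
    for rows in (a1_rows, a2_rows):
        m = rows[pop.sex[rows] == SEX_MALE]
        f = rows[pop.sex[rows] == SEX_FEMALE]
        if m.size:
            assign_phenotypes(pop, m, trait, rng, weight=p["male_weight"])
        if f.size:
            assign_phenotypes(pop, f, trait, rng, weight=1.0)

    ids = np.asarray([str(i) for i in pop.ids], dtype=object)
    genotypes = GenotypeMatrix(
        pop.marker_dosages().astype(float), ids, np.asarray(genome.marker_names())
    )
    phen_rows = np.concatenate([a1_rows, a2_rows])
    phenotypes = pd.DataFrame(
        {
            "id": ids[phen_rows],
            "phenotype": pop.phenotype[phen_rows],
            "weight": pop.weight[phen_rows],
        }
    )
    splits = {
        "a1": ids[a1_rows].tolist(),
        "a2": ids[a2_rows].tolist(),
        "v": ids[v_rows].tolist(),
    }
    bv = pd.Series(pop.tbv, index=ids)
    ped = pop.pedigree()
    ped_str = type(ped)(
        ids, np.asarray([str(i) for i in ped.sire_ids], dtype=object),
        np.asarray([str(i) for i in ped.dam_ids], dtype=object), ped.generation,
    )

    out = {
        "genotypes": genotypes,
        "phenotypes": phenotypes,
        "pedigree": ped_str,
        "splits": splits,
        "bv": bv,
        "trait": trait,
        "population": pop,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gio.write_genotypes(genotypes, outdir / "genotypes.tsv")
        gio.write_phenotypes(phenotypes, outdir / "phenotypes.tsv")
        gio.write_pedigree(ped_str, outdir / "pedigree.tsv")
        pd.DataFrame(
            [(i, grp) for grp, members in splits.items() for i in members],
            columns=["id", "split"],
        ).to_csv(outdir / "splits.tsv", sep="\t", index=False)
        bv.rename("bv").rename_axis("id").reset_index().to_csv(
            outdir / "bv.tsv", sep="\t", index=False, float_format="%.17g"
        )
    return out


def make_known_answer_sets(outdir: Path) -> dict:
    """Write hand-computable micro-fixtures plus a manifest of expected values."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # 1. one individual, two markers, dosages (0, 2), frequencies 0.5:
    #    Z = (-1, 1), denominator 2 * (0.25 + 0.25) = 1 -> self-relationship 2
    gm = GenotypeMatrix(np.array([[0.0, 2.0]]), np.asarray(["ind1"], dtype=object))
    gio.write_genotypes(gm, outdir / "grm_micro_genotypes.tsv")

    # 2. full-sib and half-sib matings among unrelated founders
    ped = pd.DataFrame(
        [
            ("1", "0", "0", 0),
            ("2", "0", "0", 0),
            ("3", "1", "2", 1),
            ("4", "1", "2", 1),
            ("5", "3", "4", 2),  # full-sib offspring: F = 1/4
            ("6", "0", "0", 0),
            ("7", "1", "6", 1),
            ("8", "3", "7", 2),  # parents are paternal half sibs: F = 1/8
        ],
        columns=["id", "sire", "dam", "generation"],
    )
    ped.to_csv(outdir / "pedigree_micro.tsv", sep="\t", header=False, index=False)

    # 3. identity-G optimal contributions with the cap at the simplex minimum
    n = 4
    ids = [f"c{k+1}" for k in range(n)]
    gdf = pd.DataFrame(np.eye(n), index=ids, columns=ids)
    gdf.to_csv(outdir / "oc_micro_G.tsv", sep="\t", float_format="%.17g")
    pd.DataFrame({"id": ids, "gebv": [4.0, 3.0, 2.0, 1.0]}).to_csv(
        outdir / "oc_micro_gebv.tsv", sep="\t", index=False
    )

    manifest = {
        "grm_micro": {
            "freqs": [0.5, 0.5],
            "vanraden_self_relationship": 2.0,
        },
        "pedigree_micro": {"F": {"5": 0.25, "8": 0.125}},
        "oc_micro": {
            "deltaF_max": 1.0 / (2 * n),
            "current_mean_f": 0.0,
            "contributions": {i: 1.0 / n for i in ids},
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
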