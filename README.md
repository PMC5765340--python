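# gsrefresh

Who should be phenotyped next? In genomic selection (GS), breeding
decisions for young animals rest on GEBVs — genomic estimated breeding
values — predicted from a *reference population* of individuals with both
genotypes and phenotypes. Phenotyping is the expensive, limiting step, so
the choice of which newly genotyped candidates to add to the reference
each generation quietly steers the whole breeding population: it reshapes
the prediction equations, hence who gets selected, hence how much genetic
merit is gained and how much genetic diversity is lost.

`gsrefresh` is a simulation and analysis toolkit for studying that choice
in a closed, dairy-cattle-like breeding program. It compares three
reference-update strategies:

* **random** — add candidates uniformly at random;
* **truncation** — add the candidates with the highest GEBVs;
* **oc** — *optimal contributions*: maximize the group's mean GEBV,
  `c'ĝ`, subject to `Σc = 1`, `c ≥ 0`, and a cap on the expected rate of
  inbreeding, `ΔF(c) = (c'Gc/2 − f̄ₜ)/(1 − f̄ₜ) ≤ 1%`, where `c'Gc/2` is
  the group coancestry under the allele-sharing relationship matrix
  `G_jk = (2/N) Σᵢ (x_ij − 1)(x_ik − 1)`. If the cap is unattainable,
  contributions minimize `c'Gc` and merit is not considered.

## What is inside

| module | contents |
| --- | --- |
| `gsrefresh.synthpop` | diploid genome on a genetic map, Haldane meiosis, founder populations with drift-induced LD, additive trait calibrated to σ²g = 423,390, σ²e = 987,910 (h² = 0.3), pedigree bookkeeping |
| `gsrefresh.grm` | marker QC (call rate > 90%, HWE p ≥ 10⁻⁴, MAF > 1%), VanRaden and allele-sharing similarity relationship matrices |
| `gsrefresh.gblup` | weighted GBLUP mixed-model equations with fixed variance components; candidate prediction by projection |
| `gsrefresh.ocsel` | optimal contributions (Lagrangian solution with iterative zeroing of negative contributions), minimum coancestry, fixed-size group selection |
| `gsrefresh.scheme` | the 10-generation breeding loop (150 sires / 500 dams, dams reused ≤ 2 generations, reference 1000 → 2350) and the single-generation A₁ → A₁₊₂ → V update experiment |
| `gsrefresh.metrics` | observed heterozygosity, pedigree inbreeding (tabular and Meuwissen–Luo-style algorithms), standardized prediction bias, Ne = 1/(2 f̄ₜ), generation equivalents, per-strategy generation trends |
| `gsrefresh.fixtures`, `gsrefresh.io`, `gsrefresh.cli` | deterministic synthetic datasets, plain-text file formats, and a thin `gsrefresh` command-line layer |

## A worked example

`examples/` contains one short script per capability. Calibrating a
founder population (`examples/01_simulate_founders.py`) prints:

```
founders:             400 (200 male, 200 female)
TBV variance:         423,390.0 kg^2 (target 423,390 exactly, after calibration)
realized h^2:         0.308 (target 0.30)
mean heterozygosity:  0.338 (burn-in drift pushes this below the HWE value)
```

The QTL effects are rescaled by one constant so the founder true-breeding-
value variance hits the genetic variance exactly; the realized
heritability then lands on 0.3 up to phenotype sampling noise.

Sweeping the inbreeding-rate cap in the optimal-contribution optimizer
(`examples/04_optimal_contributions.py`, 24 candidates in two half-sib
families plus unrelated individuals) prints:

```
   cap   merit  deltaF n_positive  top-5 update group
  0.20   1.855  0.2000          3  [16, 3, 18, 8, 7]
  0.05   1.551  0.0500          7  [16, 18, 3, 7, 22]
  0.02   1.331  0.0200         10  [16, 18, 22, 7, 3]
  0.01   1.231  0.0100         11  [16, 18, 22, 7, 3]
```

Each row is the merit-maximizing contribution vector at that cap: as the
cap tightens the achieved expected ΔF pins to it exactly, contributions
spread over more (and less related) candidates, and group merit falls —
the merit/diversity trade-off the oc update strategy exploits.

`examples/05_breeding_scenario.py` runs the full multi-generation loop at
toy scale; `SchemeConfig.desk()` is the study-scale design (2,000 markers,
10 generations, 10 replicates) used by the acceptance suite, where the oc
strategy retains the most generation-10 heterozygosity while truncation
gains the most merit, and mean inbreeding rises every generation under
every strategy.

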