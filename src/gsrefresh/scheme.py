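"""The two reference-population update experiments.

``run_scenario`` / ``run_comparison`` simulate a closed dairy-cattle-like
breeding program for 10 generations: 150 sires and 500 dams are selected
on GEBV each generation, every dam produces one offspring, offspring sex
is Bernoulli(0.5), dams may breed in two consecutive generations while
sires serve once.  The GBLUP reference population starts as the 1,000
ancestral males and is updated every generation by adding 150 newly
genotyped candidates chosen by one of three strategies:

* ``random``     — uniform sample without replacement,
* ``truncation`` — highest GEBVs,
* ``oc``         — optimal contributions (maximum merit subject to an
  expected inbreeding-rate cap of 1%), ranked by contribution.

Entering the reference implies being phenotyped (phenotyping, not
genotyping, is the limiting resource); no individual is ever removed, so
the reference grows from 1,000 to 2,350 individuals by generation 10.

``run_update_experiment`` is the single-generation analogue on a fixed
three-way split: an initial reference A1 predicts candidates A2, a chosen
subgroup updates the reference, the updated reference predicts a
validation group V, and the evaluation metrics are computed on the top
``top_n`` of V by GEBV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics as met
from .gblup import fit_gblup, predict_candidates
from .grm import DEFAULT_RIDGE, GenotypeMatrix, GMatrix, similarity_grm, vanraden_grm
from .ocsel import ContributionVector, OCParams, optimal_contributions, select_update_group
from .synthpop import (
    SEX_FEMALE,
    SEX_MALE,
    ConfigurationError,
    GenomeSpec,
    Population,
    TraitModel,
    assign_phenotypes,
    assign_trait,
    make_offspring_batch,
    simulate_founders,
)

__all__ = [
    "StrategyConfig",
    "SchemeConfig",
    "SchemeState",
    "update_reference",
    "select_breeders",
    "run_generation",
    "run_scenario",
    "run_comparison",
    "run_update_experiment",
    "METRICS_COLUMNS",
]

log = logging.getLogger(__name__)

STRATEGIES = ("random", "truncation", "oc")

METRICS_COLUMNS = [
    "replicate",
    "generation",
    "strategy",
    "mean_bv",
    "mean_het",
    "mean_f",
    "mean_bias",
    "ne",
    "ne_over_n",
    "ref_size",
]


@dataclass
class StrategyConfig:
    """How the reference population is updated each generation."""

    strategy: str
    update_size: int = 150
    oc_deltaF_max: float = 0.01
    oc_grm: str = "similarity"  # relationship matrix driving the OC update

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ConfigurationError(
                f"strategy must be one of {STRATEGIES}, got {self.strategy!r}"
            )
        if self.update_size <= 0:
            raise ConfigurationError("update_size must be positive")
        if self.oc_grm not in ("similarity", "vanraden"):
            raise ConfigurationError("oc_grm must be 'similarity' or 'vanraden'")


@dataclass
class SchemeConfig:
    """Breeding-scheme and simulation parameters (defaults = study design)."""

    n_generations: int = 10
    n_sires: int = 150
    n_dams: int = 500
    dam_reuse_generations: int = 2
    offspring_per_dam: int = 1
    sex_ratio: float = 0.5          # probability an offspring is male
    ref_update_size: int = 150
    n_replicates: int = 50
    n_ancestral_males: int = 1000
    n_ancestral_females: int = 1000
    n_burnin_generations: int = 100
    burnin_size: int = 500
    sigma2_g: float = 423_390.0
    sigma2_e: float = 987_910.0
    ridge: float = DEFAULT_RIDGE
    genome: GenomeSpec = field(default_factory=GenomeSpec.default)

    def __post_init__(self):
        for name in (
            "n_generations", "n_sires", "n_dams", "dam_reuse_generations",
            "offspring_per_dam", "ref_update_size", "n_replicates",
            "n_ancestral_males", "n_ancestral_females",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not (0.0 < self.sex_ratio < 1.0):
            raise ConfigurationError("sex_ratio must lie in (0, 1)")

    @classmethod
    def desk(cls, **overrides) -> "SchemeConfig":
        """Desk-scale preset: the default design at 10 replicates."""
        overrides.setdefault("n_replicates", 10)
        return cls(**overrides)

    def reference_sizes(self) -> list[int]:
        """Planned reference size per generation: n0, n0 + u, ..."""
        return [
            self.n_ancestral_males + self.ref_update_size * (g - 1)
            for g in range(1, self.n_generations + 1)
        ]


@dataclass
class SchemeState:
    """Mutable state of one replicate of one strategy."""

    config: SchemeConfig
    strategy: StrategyConfig
    population: Population
    trait: TraitModel
    rng: np.random.Generator
    generation: int = 0
    reference_rows: list[int] = field(default_factory=list)
    ref_freqs: np.ndarray = None          # fixed base-population frequencies
    prev_dam_rows: np.ndarray = field(default_factory=lambda: np.empty(0, np.intp))
    dam_uses: dict[int, int] = field(default_factory=dict)
    records: list[dict] = field(default_factory=list)
    breeding_rows_by_gen: dict[int, np.ndarray] = field(default_factory=dict)
    ref_size_by_gen: dict[int, int] = field(default_factory=dict)
    # internal caches
    _Z_ref: np.ndarray = None
    _G_ref: np.ndarray = None
    _vr_denom: float = 0.0

    @property
    def reference_ids(self) -> np.ndarray:
        return self.population.ids[np.asarray(self.reference_rows, dtype=np.intp)]


def _init_state(
    config: SchemeConfig,
    strategy: StrategyConfig,
    founders: Population,
    trait: TraitModel,
    rng: np.random.Generator,
) -> SchemeState:
    pop = founders.copy()
    state = SchemeState(config, strategy, pop, trait, rng)
    # VanRaden centring frequencies are fixed at the founder observed
    # frequencies so relationship blocks stay consistent as the set grows.
    state.ref_freqs = pop.marker_allele_freqs()
    p = state.ref_freqs
    state._vr_denom = 2.0 * float(np.sum(p * (1.0 - p)))
    ref_rows = np.nonzero((pop.generation == 0) & (pop.sex == SEX_MALE))[0]
    if ref_rows.size != config.n_ancestral_males:
        raise ConfigurationError("founder population does not match the config")
    assign_phenotypes(pop, ref_rows, trait, rng)
    state.reference_rows = ref_rows.tolist()
    state._Z_ref = pop.marker_dosages(ref_rows).astype(float) - 2.0 * p
    state._G_ref = (state._Z_ref @ state._Z_ref.T) / state._vr_denom
    return state


def _z_rows(state: SchemeState, rows: np.ndarray) -> np.ndarray:
    return state.population.marker_dosages(rows).astype(float) - 2.0 * state.ref_freqs


def _fit_reference(state: SchemeState):
    pop = state.population
    rows = np.asarray(state.reference_rows, dtype=np.intp)
    cfg = state.config
    model = fit_gblup(
        state._G_ref,
        pop.phenotype[rows],
        cfg.sigma2_g,
        cfg.sigma2_e,
        weights=pop.weight[rows],
        ridge=cfg.ridge,
    )
    # projection weights in marker space: gebv_x = sigma2_g * z_x @ wvec
    wvec = state._Z_ref.T @ model.alpha / state._vr_denom
    return model, wvec


def _gebv_for_rows(state: SchemeState, rows: np.ndarray, model, wvec) -> np.ndarray:
    """GEBVs for arbitrary rows: model solutions for reference members,
    cross-block projection for everyone else."""
    rows = np.asarray(rows, dtype=np.intp)
    out = np.empty(rows.size)
    ref_pos = {r: k for k, r in enumerate(state.reference_rows)}
    in_ref = np.asarray([r in ref_pos for r in rows])
    if (~in_ref).any():
        z = _z_rows(state, rows[~in_ref])
        out[~in_ref] = state.config.sigma2_g * (z @ wvec)
    if in_ref.any():
        pos = np.asarray([ref_pos[r] for r in rows[in_ref]])
        out[in_ref] = model.gebv[pos]
    return out


def update_reference(
    state: SchemeState,
    candidate_rows: np.ndarray,
    gebv: np.ndarray,
    G_candidates: Optional[GMatrix],
    strategy: StrategyConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Choose ``update_size`` candidates and add them to the reference.

    Returns the chosen rows.  ``G_candidates`` is only needed for the OC
    strategy and is computed on demand if omitted.
    """
    pop = state.population
    candidate_rows = np.asarray(candidate_rows, dtype=np.intp)
    k = strategy.update_size
    if k > candidate_rows.size:
        raise ConfigurationError(
            f"update_size {k} exceeds candidate count {candidate_rows.size}"
        )
    if set(candidate_rows.tolist()) & set(state.reference_rows):
        raise ConfigurationError("candidates must be disjoint from the reference")

    if strategy.strategy == "random":
        chosen = rng.choice(candidate_rows, size=k, replace=False)
    elif strategy.strategy == "truncation":
        ids = pop.ids[candidate_rows]
        order = np.lexsort((ids, -gebv))
        chosen = candidate_rows[order[:k]]
    else:  # oc
        if G_candidates is None:
            x = pop.marker_dosages(candidate_rows).astype(float)
            G_candidates = (
                similarity_grm(x)
                if strategy.oc_grm == "similarity"
                else vanraden_grm(x, freqs=state.ref_freqs)
            )
        gmat = G_candidates.values
        # baseline: mean kinship of the candidate generation under equal use
        f_t = float(np.clip(gmat.mean() / 2.0, 0.0, 0.99))
        params = OCParams(deltaF_max=strategy.oc_deltaF_max, current_mean_f=f_t)
        contrib = optimal_contributions(
            gebv, gmat, params, ids=pop.ids[candidate_rows]
        )
        chosen_ids = select_update_group(contrib, k)
        chosen = pop.rows_of(chosen_ids)

    chosen = np.sort(np.asarray(chosen, dtype=np.intp))
    # entering the reference implies phenotyping
    assign_phenotypes(pop, chosen, state.trait, rng)
    z_new = _z_rows(state, chosen)
    cross = (z_new @ state._Z_ref.T) / state._vr_denom
    self_block = (z_new @ z_new.T) / state._vr_denom
    state._G_ref = np.block([[state._G_ref, cross.T], [cross, self_block]])
    state._Z_ref = np.vstack([state._Z_ref, z_new])
    state.reference_rows.extend(chosen.tolist())
    return chosen


def select_breeders(
    state: SchemeState, gebv_of_rows, config: SchemeConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Select sires and dams for the next generation.

    Sires: the ``n_sires`` current-cohort males with the highest GEBVs
    (each sire serves a single generation).  Dams: every current-cohort
    female, topped up to ``n_dams`` with the highest-GEBV dams of the
    previous step that have not yet bred ``dam_reuse_generations`` times.
    ``gebv_of_rows`` maps a population row array to GEBVs.
    """
    pop = state.population
    # the newest cohort was born in the previous step (generation index g-1)
    cohort = np.nonzero(pop.generation == state.generation - 1)[0]
    males = cohort[pop.sex[cohort] == SEX_MALE]
    females = cohort[pop.sex[cohort] == SEX_FEMALE]
    if males.size < config.n_sires:
        raise ConfigurationError(
            f"only {males.size} candidate males for {config.n_sires} sire slots"
        )

    def top(rows: np.ndarray, k: int) -> np.ndarray:
        g = gebv_of_rows(rows)
        order = np.lexsort((pop.ids[rows], -g))
        return rows[order[:k]]

    sires = top(males, config.n_sires)

    if females.size >= config.n_dams:
        dams = top(females, config.n_dams)
    else:
        eligible_prev = np.asarray(
            [
                r
                for r in state.prev_dam_rows
                if state.dam_uses.get(int(r), 0) < config.dam_reuse_generations
            ],
            dtype=np.intp,
        )
        need = config.n_dams - females.size
        if eligible_prev.size < need:
            raise ConfigurationError(
                f"cannot assemble {config.n_dams} dams: {females.size} new females "
                f"and {eligible_prev.size} eligible previous dams"
            )
        dams = np.concatenate([females, top(eligible_prev, need)])
    return sires, dams


def run_generation(state: SchemeState, strategy: StrategyConfig) -> SchemeState:
    """Advance the scheme by one generation (in place) and record metrics."""
    cfg = state.config
    pop = state.population
    rng = state.rng
    state.generation += 1
    g = state.generation

    model, wvec = _fit_reference(state)
    cohort = np.nonzero(pop.generation == g - 1)[0]

    if g >= 2:
        # the newest cohort is disjoint from the reference by construction
        gebv_cand = _gebv_for_rows(state, cohort, model, wvec)
        update_reference(state, cohort, gebv_cand, None, strategy, rng)
        model, wvec = _fit_reference(state)

    state.ref_size_by_gen[g] = len(state.reference_rows)

    def gebv_of(rows: np.ndarray) -> np.ndarray:
        return _gebv_for_rows(state, rows, model, wvec)

    sires, dams = select_breeders(state, gebv_of, cfg)
    breeding = np.concatenate([sires, dams])
    state.breeding_rows_by_gen[g] = breeding

    # evaluation of the cohort predicted by the freshly updated reference;
    # the fitted mean is added back so predictions sit on the TBV scale
    gebv_cohort = gebv_of(cohort) + model.mu
    tbv_cohort = pop.tbv[cohort]
    sigma_g_obs = tbv_cohort.std(ddof=1)
    mean_bias = (
        float(met.prediction_bias(gebv_cohort, tbv_cohort, sigma_g_obs).mean())
        if sigma_g_obs > 0
        else np.nan
    )
    state.records.append(
        {
            "generation": g,
            "strategy": strategy.strategy,
            "mean_bv": float(pop.tbv[breeding].mean()),
            "mean_het": float(
                met.observed_heterozygosity(pop.marker_dosages(breeding)).mean()
            ),
            "mean_bias": mean_bias,
            "ref_size": len(state.reference_rows),
        }
    )

    # breed: each dam once per offspring slot; sires reused at most
    # ceil(n_matings / n_sires) times
    n_off = dams.size * cfg.offspring_per_dam
    dam_order = np.repeat(dams, cfg.offspring_per_dam)
    rng.shuffle(dam_order)
    reps = math.ceil(n_off / sires.size)
    sire_pool = np.tile(sires, reps)[:n_off]
    rng.shuffle(sire_pool)
    # exact sex proportion, randomly assigned: the replacement arithmetic
    # (selection rates 0.6 / 1 / 0.5) balances only with an even sex ratio
    n_male = int(round(n_off * cfg.sex_ratio))
    sexes = np.concatenate(
        [np.full(n_male, SEX_MALE, np.uint8), np.full(n_off - n_male, SEX_FEMALE, np.uint8)]
    )
    rng.shuffle(sexes)
    make_offspring_batch(pop, sire_pool, dam_order, sexes, g, state.trait, rng)

    for r in dams.tolist():
        state.dam_uses[int(r)] = state.dam_uses.get(int(r), 0) + 1
    state.prev_dam_rows = dams
    return state


def _finalize_metrics(state: SchemeState) -> pd.DataFrame:
    """Fill in pedigree-based columns once the full pedigree exists."""
    pop = state.population
    F = met.pedigree_inbreeding(pop.pedigree(), method="tabular")
    ref_rows_all = np.asarray(state.reference_rows, dtype=np.intp)
    rows = []
    for rec in state.records:
        g = rec["generation"]
        breeding = state.breeding_rows_by_gen[g]
        ref_rows = ref_rows_all[: state.ref_size_by_gen[g]]
        mean_f_ref = float(F[ref_rows].mean())
        ne = met.effective_size_or_nan(mean_f_ref)
        rows.append(
            {
                **rec,
                "mean_f": float(F[breeding].mean()),
                "ne": ne,
                "ne_over_n": ne / ref_rows.size if np.isfinite(ne) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _run_replicate(
    config: SchemeConfig,
    strategy: StrategyConfig,
    founders: Population,
    trait: TraitModel,
    rng: np.random.Generator,
) -> pd.DataFrame:
    state = _init_state(config, strategy, founders, trait, rng)
    for _ in range(config.n_generations):
        run_generation(state, strategy)
    return _finalize_metrics(state)


def _founders_for_replicate(
    config: SchemeConfig, seed: int, replicate: int, n_streams: int
) -> tuple[Population, TraitModel, list[np.random.Generator]]:
    ss = np.random.SeedSequence([int(seed), int(replicate)])
    children = ss.spawn(n_streams + 1)
    frng = np.random.default_rng(children[0])
    founders = simulate_founders(
        config.genome,
        config.n_ancestral_males,
        config.n_ancestral_females,
        config.n_burnin_generations,
        rng=frng,
        burnin_size=config.burnin_size,
    )
    trait = TraitModel.draw(config.genome, frng, config.sigma2_g, config.sigma2_e)
    trait = assign_trait(founders, trait, rescale=True)
    strat_rngs = [np.random.default_rng(c) for c in children[1:]]
    return founders, trait, strat_rngs


def run_comparison(
    config: SchemeConfig, strategies: Sequence[StrategyConfig], seed: int
) -> pd.DataFrame:
    """Run all strategies on shared founder populations, replicate by
    replicate, so strategies are paired within replicates."""
    frames = []
    for r in range(config.n_replicates):
        founders, trait, rngs = _founders_for_replicate(
            config, seed, r, len(strategies)
        )
        for strat, rng in zip(strategies, rngs):
            df = _run_replicate(config, strat, founders, trait, rng)
            df.insert(0, "replicate", r)
            frames.append(df)
        log.info("replicate %d/%d done", r + 1, config.n_replicates)
    out = pd.concat(frames, ignore_index=True)
    return out[METRICS_COLUMNS]


def run_scenario(
    config: SchemeConfig, strategy: StrategyConfig, seed: int
) -> pd.DataFrame:
    """Run ``config.n_replicates`` independent replicates of one strategy.

    Founder populations depend only on (seed, replicate), so scenarios run
    separately for different strategies with the same seed share founders.
    """
    return run_comparison(config, [strategy], seed)


# ---------------------------------------------------------------------------
# single-generation update experiment (A1 -> A1+2 -> V -> V_sel)
# ---------------------------------------------------------------------------

def run_update_experiment(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    splits: dict[str, Sequence],
    bv: pd.Series,
    sizes: Sequence[int],
    strategies: Sequence[str] = STRATEGIES,
    top_n: int = 100,
    sigma2_g: float = 423_390.0,
    sigma2_e: float = 987_910.0,
    pedigree=None,
    n_random_repeats: int = 100,
    deltaF_max: float = 0.01,
    ridge: float = DEFAULT_RIDGE,
    seed: int = 0,
) -> pd.DataFrame:
    """Single-generation reference-update experiment on a fixed data split.

    ``splits`` maps ``"a1"`` (initial reference), ``"a2"`` (update
    candidates) and ``"v"`` (validation) to disjoint id lists.
    ``phenotypes`` needs columns ``id``, ``phenotype`` and optionally
    ``weight`` covering A1 and A2; ``bv`` maps ids to (true) breeding
    values for the evaluation.  For each (strategy, size) the reference is
    updated, V is re-predicted, and the metrics are computed on the top
    ``top_n`` individuals of V; the random strategy is repeated
    ``n_random_repeats`` times.
    """
    ids = list(genotypes.ids)
    id_pos = {i: k for k, i in enumerate(ids)}
    a1 = [i for i in splits["a1"]]
    a2 = [i for i in splits["a2"]]
    v = [i for i in splits["v"]]
    if set(a1) & set(a2) or set(a1) & set(v) or set(a2) & set(v):
        raise ValueError("A1, A2 and V must be disjoint")
    for group in (a1, a2, v):
        for i in group:
            if i not in id_pos:
                raise ValueError(f"id {i!r} missing from genotypes")
    sizes = list(sizes)
    if max(sizes) > len(a2):
        raise ValueError(f"largest update size {max(sizes)} exceeds |A2| = {len(a2)}")

    ph = phenotypes.set_index("id")
    y = ph["phenotype"].astype(float)
    w = (
        ph["weight"].astype(float)
        if "weight" in ph.columns
        else pd.Series(1.0, index=ph.index)
    )

    G_all = vanraden_grm(genotypes)
    rows_of = lambda group: np.asarray([id_pos[i] for i in group], dtype=np.intp)
    a1_rows, a2_rows, v_rows = rows_of(a1), rows_of(a2), rows_of(v)

    F = None
    if pedigree is not None:
        Fall = met.pedigree_inbreeding(pedigree)
        F = {i: Fall[pedigree.index_of(i)] for i in ids if i in pedigree._index}

    het_all = met.observed_heterozygosity(genotypes.dosages)
    sigma_g_v = float(bv.loc[list(v)].std(ddof=1))

    def evaluate(strategy: str, size: int, repeat: int, chosen: Sequence) -> dict:
        ref = list(a1) + list(chosen)
        ref_rows = rows_of(ref)
        model = fit_gblup(
            G_all.take(ref_rows),
            y.loc[ref].to_numpy(),
            sigma2_g,
            sigma2_e,
            weights=w.loc[ref].to_numpy(),
            ridge=ridge,
        )
        # predictions on the breeding-value scale (fitted mean added back)
        gebv_v = predict_candidates(
            model, G_all.values[np.ix_(v_rows, ref_rows)]
        ) + model.mu
        order = np.lexsort((np.asarray(v, dtype=object), -gebv_v))
        sel = [v[k] for k in order[:top_n]]
        sel_rows = rows_of(sel)
        bias = met.prediction_bias(
            gebv_v[order[:top_n]], bv.loc[sel].to_numpy(), sigma_g_v
        )
        return {
            "strategy": strategy,
            "update_size": size,
            "repeat": repeat,
            "mean_bv": float(bv.loc[sel].mean()),
            "mean_bias": float(bias.mean()),
            "mean_het": float(het_all[sel_rows].mean()),
            "mean_f": float(np.mean([F[i] for i in sel])) if F is not None else np.nan,
        }

    # GEBVs of the candidate group from the initial reference
    model_a1 = fit_gblup(
        G_all.take(a1_rows),
        y.loc[a1].to_numpy(),
        sigma2_g,
        sigma2_e,
        weights=w.loc[a1].to_numpy(),
        ridge=ridge,
    )
    gebv_a2 = predict_candidates(model_a1, G_all.values[np.ix_(a2_rows, a1_rows)])

    G_sim_a2 = similarity_grm(genotypes.dosages[a2_rows])
    f_t = float(np.clip(G_sim_a2.values.mean() / 2.0, 0.0, 0.99))

    rng = np.random.default_rng(seed)
    results = []
    for size in sizes:
        for strategy in strategies:
            if strategy == "random":
                for rep in range(n_random_repeats):
                    chosen = [a2[k] for k in rng.choice(len(a2), size, replace=False)]
                    results.append(evaluate(strategy, size, rep, chosen))
            elif strategy == "truncation":
                order = np.lexsort((np.asarray(a2, dtype=object), -gebv_a2))
                results.append(
                    evaluate(strategy, size, 0, [a2[k] for k in order[:size]])
                )
            elif strategy == "oc":
                contrib = optimal_contributions(
                    gebv_a2,
                    G_sim_a2.values,
                    OCParams(deltaF_max=deltaF_max, current_mean_f=f_t),
                    ids=np.asarray(a2, dtype=object),
                )
                chosen = list(select_update_group(contrib, size))
                results.append(evaluate(strategy, size, 0, chosen))
            else:
                raise ValueError(f"unknown strategy {strategy!r}")
    return pd.DataFrame(results)
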