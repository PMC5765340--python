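"""Breeding-scheme loop and the single-generation update experiment."""

import numpy as np
import pandas as pd
import pytest

from gsrefresh.fixtures import FixtureSpec, make_update_fixture
from gsrefresh.scheme import (
    SchemeConfig,
    StrategyConfig,
    run_comparison,
    run_scenario,
    run_update_experiment,
    select_breeders,
    update_reference,
    _founders_for_replicate,
    _init_state,
    run_generation,
)
from gsrefresh.synthpop import SEX_FEMALE, SEX_MALE, ConfigurationError, GenomeSpec


def tiny_config(**overrides):
    defaults = dict(
        n_generations=3,
        n_sires=6,
        n_dams=20,
        ref_update_size=5,
        n_replicates=2,
        n_ancestral_males=20,
        n_ancestral_females=40,
        n_burnin_generations=5,
        burnin_size=40,
        genome=GenomeSpec.default(
            n_chromosomes=2, n_markers_per_chrom=50, n_qtl_per_chrom=5
        ),
    )
    defaults.update(overrides)
    return SchemeConfig(**defaults)


def tiny_state(strategy="truncation", seed=5, **overrides):
    cfg = tiny_config(**overrides)
    strat = StrategyConfig(strategy, update_size=cfg.ref_update_size)
    founders, trait, rngs = _founders_for_replicate(cfg, seed, 0, 1)
    return _init_state(cfg, strat, founders, trait, rngs[0]), strat


class TestConfig:
    def test_reference_size_schedule(self):
        cfg = SchemeConfig()
        assert cfg.reference_sizes() == list(range(1000, 2351, 150))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            SchemeConfig(n_sires=0)
        with pytest.raises(ConfigurationError):
            StrategyConfig("mystery")


class TestUpdateReference:
    def test_truncation_takes_top_gebvs(self):
        state, _ = tiny_state()
        strat = StrategyConfig("truncation", update_size=2)
        cand = np.arange(5)
        gebv = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        before = list(state.reference_rows)
        # candidate rows must be outside the current reference
        cand = np.asarray(
            [r for r in range(state.population.n) if r not in before][:5]
        )
        chosen = update_reference(state, cand, gebv, None, strat, state.rng)
        assert set(chosen) == set(cand[:2])
        assert len(state.reference_rows) == len(before) + 2

    def test_random_update_deterministic_for_fixed_seed(self):
        picks = []
        for _ in range(2):
            state, _ = tiny_state("random")
            strat = StrategyConfig("random", update_size=3)
            cand = np.asarray(
                [r for r in range(state.population.n) if r not in state.reference_rows][:10]
            )
            picks.append(
                sorted(update_reference(state, cand, np.zeros(10), None, strat, state.rng))
            )
        assert picks[0] == picks[1]

    def test_update_size_exceeding_candidates_raises(self):
        state, strat = tiny_state()
        cand = np.asarray([r for r in range(state.population.n) if r not in state.reference_rows][:3])
        with pytest.raises(ConfigurationError):
            update_reference(state, cand, np.zeros(3), None, StrategyConfig("truncation", update_size=5), state.rng)

    def test_new_reference_members_are_phenotyped(self):
        state, strat = tiny_state()
        cand = np.asarray([r for r in range(state.population.n) if r not in state.reference_rows][:6])
        chosen = update_reference(state, cand, np.arange(6.0), None, strat, state.rng)
        assert np.isfinite(state.population.phenotype[chosen]).all()


class TestSelectBreeders:
    def test_male_selection_rate(self):
        # 10 cohort males, 6 sire slots -> realized selection rate 0.6
        state, _ = tiny_state()
        state.generation = 1  # cohort = generation 0 founders
        gebv = lambda rows: state.population.tbv[rows]
        sires, dams = select_breeders(state, gebv, state.config)
        assert sires.size == 6 and dams.size == 20
        assert np.all(state.population.sex[sires] == SEX_MALE)
        assert np.all(state.population.sex[dams] == SEX_FEMALE)
        # sires are the top-TBV males of the cohort
        males = np.nonzero((state.population.generation == 0) & (state.population.sex == SEX_MALE))[0]
        expected = males[np.argsort(-state.population.tbv[males])][:6]
        assert set(sires) == set(expected)

    def test_dam_pool_tops_up_from_previous_dams(self):
        state, strat = tiny_state()
        for _ in range(2):
            run_generation(state, strat)
        pop = state.population
        # generation-2 dams: all new females plus top-GEBV previous dams
        dams = state.breeding_rows_by_gen[2][state.config.n_sires:]
        new_f = np.nonzero((pop.generation == 1) & (pop.sex == SEX_FEMALE))[0]
        assert set(new_f) <= set(dams)
        reused = set(dams) - set(new_f)
        assert reused <= set(state.breeding_rows_by_gen[1][state.config.n_sires:])

    def test_dam_reuse_capped_at_two_generations(self):
        state, strat = tiny_state(n_generations=4)
        for _ in range(4):
            run_generation(state, strat)
        first = set(state.breeding_rows_by_gen[1][state.config.n_sires:])
        third = set(state.breeding_rows_by_gen[3][state.config.n_sires:])
        fourth = set(state.breeding_rows_by_gen[4][state.config.n_sires:])
        assert not (first & third) and not (first & fourth)


@pytest.fixture(scope="module")
def tiny_runs():
    cfg = tiny_config()
    strategies = [
        StrategyConfig(s, update_size=cfg.ref_update_size)
        for s in ("random", "truncation", "oc")
    ]
    return cfg, run_comparison(cfg, strategies, seed=3)


@pytest.fixture(scope="module")
def fixture_data():
    return make_update_fixture(FixtureSpec(preset="tiny", seed=4))


class TestRunScenario:
    def test_row_count_is_replicates_by_generations(self, tiny_runs):
        cfg, df = tiny_runs
        assert len(df) == cfg.n_replicates * cfg.n_generations * 3

    def test_reference_growth_arithmetic(self, tiny_runs):
        cfg, df = tiny_runs
        for (_, _), sub in df.groupby(["replicate", "strategy"]):
            assert sub.sort_values("generation")["ref_size"].tolist() == [
                cfg.n_ancestral_males + cfg.ref_update_size * (g - 1)
                for g in range(1, cfg.n_generations + 1)
            ]

    def test_offspring_counts_and_pedigree_closure(self):
        state, strat = tiny_state()
        for _ in range(3):
            run_generation(state, strat)
        pop = state.population
        for g in (1, 2, 3):
            cohort = np.nonzero(pop.generation == g)[0]
            assert cohort.size == state.config.n_dams
            sire_rows = pop.rows_of(pop.sire[cohort])
            dam_rows = pop.rows_of(pop.dam[cohort])
            assert set(sire_rows) <= set(state.breeding_rows_by_gen[g][: state.config.n_sires])
            assert set(dam_rows) <= set(state.breeding_rows_by_gen[g][state.config.n_sires:])

    def test_same_seed_reproduces_metrics(self, tiny_runs):
        cfg, df = tiny_runs
        strategies = [
            StrategyConfig(s, update_size=cfg.ref_update_size)
            for s in ("random", "truncation", "oc")
        ]
        df2 = run_comparison(cfg, strategies, seed=3)
        pd.testing.assert_frame_equal(df.reset_index(drop=True), df2.reset_index(drop=True))

    def test_different_replicates_differ(self, tiny_runs):
        _, df = tiny_runs
        by_rep = df[df.strategy == "truncation"].groupby("replicate")["mean_bv"].mean()
        assert by_rep.nunique() == len(by_rep)

    def test_run_scenario_single_strategy(self):
        cfg = tiny_config(n_replicates=1)
        df = run_scenario(cfg, StrategyConfig("truncation", update_size=5), seed=3)
        assert set(df.strategy) == {"truncation"}
        # selection response: mean BV should rise over the run
        assert df.mean_bv.iloc[-1] > df.mean_bv.iloc[0]


class TestUpdateExperiment:
    def test_result_rows_per_strategy_and_size(self, fixture_data):
        fx = fixture_data
        df = run_update_experiment(
            fx["genotypes"], fx["phenotypes"], fx["splits"], fx["bv"],
            sizes=[4, 8], top_n=6, n_random_repeats=5, seed=0,
        )
        counts = df.groupby(["strategy", "update_size"]).size()
        assert counts.loc[("random", 4)] == 5
        assert counts.loc[("truncation", 8)] == 1
        assert counts.loc[("oc", 4)] == 1

    def test_top_n_equal_validation_reduces_to_whole_group(self, fixture_data):
        fx = fixture_data
        v = fx["splits"]["v"]
        df = run_update_experiment(
            fx["genotypes"], fx["phenotypes"], fx["splits"], fx["bv"],
            sizes=[4], strategies=["truncation"], top_n=len(v),
            n_random_repeats=1, seed=0,
        )
        assert df["mean_bv"][0] == pytest.approx(float(fx["bv"].loc[v].mean()))

    def test_disjointness_enforced(self, fixture_data):
        fx = fixture_data
        bad = dict(fx["splits"])
        bad["a2"] = bad["a2"] + bad["v"][:1]
        with pytest.raises(ValueError, match="disjoint"):
            run_update_experiment(
                fx["genotypes"], fx["phenotypes"], bad, fx["bv"], sizes=[4]
            )

    def test_oversized_update_rejected(self, fixture_data):
        fx = fixture_data
        with pytest.raises(ValueError, match="exceeds"):
            run_update_experiment(
                fx["genotypes"], fx["phenotypes"], fx["splits"], fx["bv"],
                sizes=[10_000],
            )
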