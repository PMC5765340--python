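"""A miniature multi-generation breeding scenario.

Runs the full loop (GBLUP -> reference update -> breeder selection ->
mating) for 4 generations at toy scale under all three update strategies
and prints per-strategy generation trends of merit and heterozygosity.
The desk-scale study design is simply `SchemeConfig.desk()` with the
default strategies; it takes a few minutes per replicate set.
"""

from gsrefresh import GenomeSpec, SchemeConfig, StrategyConfig, run_comparison
from gsrefresh.metrics import estimate_trends

cfg = SchemeConfig(
    n_generations=4,
    n_sires=10,
    n_dams=30,
    ref_update_size=8,
    n_replicates=3,
    n_ancestral_males=30,
    n_ancestral_females=60,
    n_burnin_generations=10,
    burnin_size=60,
    genome=GenomeSpec.default(n_chromosomes=3, n_markers_per_chrom=60, n_qtl_per_chrom=6),
)
strategies = [StrategyConfig(s, update_size=cfg.ref_update_size) for s in ("random", "truncation", "oc")]
df = run_comparison(cfg, strategies, seed=0)

print("reference sizes by generation:", df.groupby("generation").ref_size.first().tolist())
print("\nmean breeding value of the breeding population (kg), by generation:")
print(df.groupby(["strategy", "generation"]).mean_bv.mean().unstack(0).round(0).to_string())
print("\ngeneration trends (per-replicate OLS slopes, averaged):")
for metric, tr in (("mean_bv", None), ("mean_het", "arcsine_sqrt")):
    print(estimate_trends(df, metric, transform=tr).round(5).to_string(index=False))
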