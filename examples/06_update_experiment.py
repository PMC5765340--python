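"""Single-generation reference-update experiment on a synthetic split.

A1 (initial reference) predicts the candidates A2; each strategy picks an
update group; the updated reference re-predicts the validation cohort V;
metrics are computed on the top individuals of V by GEBV — the analogue
of choosing the next breeding population.
"""

from gsrefresh.fixtures import FixtureSpec, make_update_fixture
from gsrefresh import run_update_experiment

fx = make_update_fixture(FixtureSpec(preset="tiny", seed=5, overrides={"cohort_size": 40}))
df = run_update_experiment(
    fx["genotypes"], fx["phenotypes"], fx["splits"], fx["bv"],
    sizes=[10, 20], top_n=15, n_random_repeats=10, seed=0,
    pedigree=fx["pedigree"],
)
summary = (
    df.groupby(["update_size", "strategy"])[["mean_bv", "mean_bias", "mean_het", "mean_f"]]
    .mean()
    .round(3)
)
print(summary.to_string())
print("\nmean_bv: true merit of the selected top of V; mean_bias: |GEBV-BV|/sd(BV);")
print("mean_het/mean_f: marker heterozygosity and pedigree inbreeding of that group.")
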