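"""Weighted GBLUP on a synthetic reference and candidate split.

Uses the bundled fixture generator (A1 = phenotyped reference including
progeny-tested males with heavy record weights, V = unphenotyped
validation cohort) and reports how well GEBVs track the held-out true
breeding values.
"""

import numpy as np

from gsrefresh.fixtures import FixtureSpec, make_update_fixture
from gsrefresh import fit_gblup, predict_candidates, vanraden_grm

fx = make_update_fixture(FixtureSpec(preset="tiny", seed=2, overrides={"cohort_size": 40}))
gm, ph, splits, bv = fx["genotypes"], fx["phenotypes"], fx["splits"], fx["bv"]

pos = {i: k for k, i in enumerate(gm.ids)}
ref = splits["a1"] + splits["a2"]
ref_rows = [pos[i] for i in ref]
v_rows = [pos[i] for i in splits["v"]]

G = vanraden_grm(gm)
phi = ph.set_index("id")
model = fit_gblup(
    G.take(ref_rows),
    phi.loc[ref, "phenotype"].to_numpy(),
    sigma2_g=423_390.0,
    sigma2_e=987_910.0,
    weights=phi.loc[ref, "weight"].to_numpy(),
)
gebv_v = predict_candidates(model, G.values[np.ix_(v_rows, ref_rows)]) + model.mu
true_v = bv.loc[splits["v"]].to_numpy()

print(f"reference size: {len(ref)}  validation size: {len(v_rows)}")
print(f"fitted mean mu: {model.mu:,.1f} kg (phenotype baseline)")
print(f"accuracy corr(GEBV, TBV) on V: {np.corrcoef(gebv_v, true_v)[0, 1]:.3f}")
print(f"mean |GEBV - TBV| / sd(TBV):   {np.mean(np.abs(gebv_v - true_v)) / true_v.std(ddof=1):.3f}")
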