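#!/usr/bin/env python
"""Nondisjunction phenotypes in silico: how obligate-crossover failure
shapes the spore-viability profile, and the chromosome-III non-mater
signature of two-spore-viable tetrads.

Sweeps the MI-nondisjunction probability of achiasmate bivalents at
msh4/5-null-like map lengths and reports the viability-class profile and
the fraction of two-spore tetrads that are sister-spore non-maters.

Writes results/ndj_phenotype.tsv.
"""

from pathlib import Path

import pandas as pd

from tetrakit.sim import msh45_null_params, simulate_dataset, wild_type_params
from tetrakit.strain_stats import ndj_signature, viability_profile

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

rows = []
settings = [("wild-type-like", wild_type_params(n_tetrads=2000, seed=42), None)]
for e0 in (0.0, 0.25, 0.5, 0.75, 1.0):
    settings.append(
        (f"null-like ndj={e0}", msh45_null_params(n_tetrads=2000, seed=43, ndj_prob_e0=e0), e0)
    )

for label, params, _ in settings:
    ds, _ = simulate_dataset(params)
    prof = viability_profile(ds)
    sig = ndj_signature(ds)
    c = prof.counts_by_viable_spores
    rows.append(
        {
            "setting": label,
            "percent_viable": round(prof.percent_viable, 1),
            "viable_4": c[4],
            "viable_3": c[3],
            "viable_2": c[2],
            "viable_1": c[1],
            "viable_0": c[0],
            "excess_0_2_over_1_3": (c[0] + c[2]) - (c[1] + c[3]),
            "two_spore_tetrads": sig.two_spore_tetrads,
            "nonmater_pct": round(sig.nonmater_two_spore_fraction, 1),
            "sister_pct": round(sig.sister_two_spore_fraction, 1),
        }
    )

df = pd.DataFrame(rows)
df.to_csv(OUT / "ndj_phenotype.tsv", sep="\t", index=False)
print(df.to_string(index=False))
print(
    "\nRaising the nondisjunction probability of achiasmate bivalents at "
    "reduced map lengths drives the 0- and 2-viable-spore excess, and the "
    "surviving pairs of chromosome-III nondisjunction are sister-spore "
    "non-maters carrying both mating types."
)
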