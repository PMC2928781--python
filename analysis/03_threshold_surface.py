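#!/usr/bin/env python
"""Spore viability versus chromosome-XV map distance for the 57-allele
mutagenesis panel, plus Fisher-exact comparisons of how often msh4 versus
msh5 mutations drop spore viability to 50% or below.

Writes results/threshold_surface.tsv and results/fisher_tests.tsv.
"""

from pathlib import Path

import pandas as pd

from tetrakit.fixtures import load_fixture
from tetrakit.strain_stats import fisher_exact_2x2, threshold_surface

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

table1 = load_fixture("table1_eay")
strains = list(
    table1[["allele", "total_cM", "spore_viability_pct"]].itertuples(index=False)
)
surf = threshold_surface(strains, viability_cutoff=50.0)
surf.to_csv(OUT / "threshold_surface.tsv", sep="\t", index=False)

# which subunit is more sensitive to mutagenesis?
points = table1[table1.allele.str.match(r"msh[45]-")]
msh4 = points[points.allele.str.startswith("msh4-")]
msh5 = points[points.allele.str.startswith("msh5-")]
rows = []
for label, sub4, sub5 in [
    ("all point mutants", msh4, msh5),
    ("domain IV (DNA binding)", msh4[msh4.domain == "IV"], msh5[msh5.domain == "IV"]),
]:
    # viabilities are compared at integer precision (50.2% counts as 50%)
    a = int((sub5.spore_viability_pct.round() <= 50).sum())
    b = len(sub5) - a
    c = int((sub4.spore_viability_pct.round() <= 50).sum())
    d = len(sub4) - c
    p = fisher_exact_2x2(a, b, c, d)
    rows.append(
        {
            "comparison": label,
            "msh5_low_viability": f"{a}/{len(sub5)}",
            "msh4_low_viability": f"{c}/{len(sub4)}",
            "fisher_p": round(p, 3),
        }
    )
fisher = pd.DataFrame(rows)
fisher.to_csv(OUT / "fisher_tests.tsv", sep="\t", index=False)

lo = surf[(surf.percent_viable >= 85) & (surf.label.str.startswith("msh"))]
print("Threshold region: high-viability (>=85%) mutant alleles span "
      f"{lo.total_cM.min():.1f}-{lo.total_cM.max():.1f} cM on chromosome XV "
      "(wild-type 96.1 cM) - crossing over tolerates ~2-fold reduction.")
print("\nSubunit sensitivity (<=50% spore viability):")
print(fisher.to_string(index=False))
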