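#!/usr/bin/env python
"""Downstream validation arithmetic: KASP co-segregation and qPCR folds.

Reproduces the worked numbers that confirm a mapped candidate: the 63-plant
genotyping panel (15 AA mutant / 33 GA / 15 GG wild type) tested for perfect
recessive co-segregation and 1:2:1 segregation, the between-gene transcript
fold change from mean Ct values 19.8 (FAD7) vs 24.2 (FAD8), and the protein
length implied by a 1356 bp CDS. Writes results/validation.json.
"""

import json

import pandas as pd

from mutmapkit.consequence import protein_length_from_cds
from mutmapkit.stats import cosegregation_test, fold_change_between_genes


def main() -> None:
    rows = [("AA", "msd")] * 15 + [("GA", "WT")] * 33 + [("GG", "WT")] * 15
    panel = pd.DataFrame(
        {
            "plant_id": [f"p{i:02d}" for i in range(63)],
            "genotype": [g for g, _ in rows],
            "phenotype": [p for _, p in rows],
        }
    )
    res = cosegregation_test(panel)
    fold = fold_change_between_genes(19.8, 24.2)
    out = {
        "kasp_panel": {
            "n": res.n,
            "genotype_counts": res.genotype_counts,
            "concordant_mutant_count": res.concordant_mutant_count,
            "discordant_count": res.discordant_count,
            "cosegregates": res.cosegregates,
            "chi2_vs_1_2_1": round(res.chi2_1_2_1, 4),
            "df": res.df,
            "p": round(res.p, 4),
        },
        "fad7_vs_fad8": {
            "ct_fad7": 19.8,
            "ct_fad8": 24.2,
            "fold_change": round(fold, 1),
            "fold_change_rounded": round(fold),
        },
        "protein_length_from_1356bp_cds": protein_length_from_cds(1356),
    }
    with open("results/validation.json", "w") as fh:
        json.dump(out, fh, indent=2)
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
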