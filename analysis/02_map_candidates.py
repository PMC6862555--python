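#!/usr/bin/env python
"""Filter, annotate, and intersect the simulated pools to find the causal gene.

Reads the artifacts written by 01_simulate_populations.py back through the
package's FASTA/GFF3/VCF readers, applies the candidate filter (homozygous
G/C->A/T transitions, depth 3-50, quality > Q20), annotates consequences
against the gene models, and intersects the per-population deleterious gene
sets. Writes results/candidates/{candidates.json,candidates.tsv} and scores
the report against the simulation truth.
"""

import json
from pathlib import Path

from mutmapkit.candidates import build_candidate_report, evaluate_report, write_report
from mutmapkit.filtering import filter_candidate_variants, read_vcf
from mutmapkit.genes import read_fasta, read_gff3
from mutmapkit.simulate import read_truth

STUDY = Path("results/study")


def main() -> None:
    genome = read_fasta(STUDY / "genome.fa")
    genes = read_gff3(STUDY / "genes.gff3")
    truth = read_truth(STUDY / "truth.tsv")
    filtered = {}
    for vcf in sorted(STUDY.glob("pool*.vcf")):
        records = read_vcf(vcf)
        kept = filter_candidate_variants(records)
        filtered[kept[0].pop_id if kept else vcf.stem] = kept
        print(f"{vcf.name}: {len(records)} calls -> {len(kept)} candidate SNVs")
    report = build_candidate_report(filtered, genes, genome)
    write_report(report, "results/candidates")
    print("per-population deleterious gene set sizes:",
          {p: len(s) for p, s in sorted(report.per_population.items())})
    print("intersection:", list(report.intersection))
    for gene_id in report.intersection:
        classes = {}
        for pop, allele in report.allelism[gene_id].items():
            classes.setdefault(allele, []).append(pop)
        for allele, pops in sorted(classes.items()):
            print(f"  {gene_id} {allele[0]}:{allele[1]} {allele[2]}>{allele[3]}: "
                  f"{', '.join(sorted(pops))}")
    print("evaluation:", json.dumps(evaluate_report(report, truth)))


if __name__ == "__main__":
    main()
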