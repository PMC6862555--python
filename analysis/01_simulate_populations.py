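#!/usr/bin/env python
"""Simulate the four-population bulked-segregant study and write its artifacts.

Generates the default study: a 1 Mb / 100-gene toy genome, four independently
EMS-mutagenized mutant lines sharing one causal gene (the last two carrying an
identical allele), three backcross generations each, and a phenotype-selected
F2 bulk of 20 homozygous mutants per line sequenced to ~20x pooled depth.
Artifacts (FASTA, GFF3, per-pool VCF, truth TSV) go to results/study/.
"""

from mutmapkit.simulate import SimulationConfig, simulate_study, write_study

SEED = 1


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    genome, genes, truth, pools = simulate_study(cfg)
    paths = write_study(genome, genes, truth, pools, "results/study", seed=SEED)
    print(f"simulated {len(genes)} genes on {len(genome)} chromosomes "
          f"({sum(len(s) for s in genome.values()):,} bp)")
    print(f"planted causal gene: {truth.causal_gene}")
    for pool in pools:
        causal = truth.causal_variant_per_population[pool.pop_id]
        print(f"  {pool.pop_id}: {len(pool.records)} variant-level calls; causal "
              f"allele {causal.chrom}:{causal.pos} {causal.ref}>{causal.alt}")
    print("wrote:", ", ".join(str(p) for p in paths.values()))


if __name__ == "__main__":
    main()
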