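"""Synthetic study generator: reference integrity, EMS spectrum, cross genetics."""

import dataclasses

import numpy as np
import pytest

from mutmapkit.filtering import Genotype
from mutmapkit.genes import read_fasta, read_gff3, write_fasta, write_gff3
from mutmapkit.simulate import (
    COMPLEMENT,
    GermlineVariant,
    SimulationConfig,
    apply_ems_mutations,
    build_truth,
    read_truth,
    recombination_fraction,
    simulate_cross_and_bulk,
    simulate_reference,
    simulate_study,
    site_quality,
    write_truth,
)
from mutmapkit.stats import chi_square_ratio

TINY = SimulationConfig(
    n_chromosomes=2, chromosome_length=30_000, n_genes=4, ems_rate=2e-3, seed=5
)


def _coding_strand_intron(genome, gene, iv):
    s, e = iv
    seq = genome[gene.chrom][s - 1 : e]
    return seq if gene.strand == "+" else seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------

def test_reference_seeded_determinism(tmp_path):
    g1, m1 = simulate_reference(TINY)
    g2, m2 = simulate_reference(TINY)
    assert g1 == g2 and m1 == m2
    write_fasta(g1, tmp_path / "a.fa")
    write_fasta(g2, tmp_path / "b.fa")
    write_gff3(m1, tmp_path / "a.gff3")
    write_gff3(m2, tmp_path / "b.gff3")
    assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
    assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()


def test_reference_gene_structure():
    genome, genes = simulate_reference(TINY)
    assert len(genes) == TINY.n_genes
    from Bio.Seq import Seq

    for gene in genes:
        assert len(gene.exons) >= 2
        assert gene.cds_length % 3 == 0
        for iv in gene.introns:
            intron = _coding_strand_intron(genome, gene, iv)
            assert intron[:2] == "GT" and intron[-2:] == "AG"
        cds = gene.coding_sequence(genome)
        assert cds.startswith("ATG")
        assert cds[-3:] in {"TAA", "TAG", "TGA"}
        prot = str(Seq(cds).translate())
        assert prot.endswith("*") and "*" not in prot[:-1]
    # non-overlapping within a chromosome
    by_chrom = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    for ivs in by_chrom.values():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert s2 > e1


def test_reference_sizing_error():
    with pytest.raises(ValueError, match="cannot fit"):
        simulate_reference(
            dataclasses.replace(TINY, chromosome_length=2_000, n_genes=10)
        )


def test_fasta_gff3_round_trip(tmp_path):
    genome, genes = simulate_reference(TINY)
    write_fasta(genome, tmp_path / "g.fa")
    write_gff3(genes, tmp_path / "g.gff3")
    assert read_fasta(tmp_path / "g.fa") == genome
    back = read_gff3(tmp_path / "g.gff3")
    assert back == sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))


# ---------------------------------------------------------------------------
# EMS mutagenesis
# ---------------------------------------------------------------------------

def test_ems_zero_rate_and_no_targets():
    genome, _ = simulate_reference(TINY)
    assert apply_ems_mutations(genome, 0.0, seed=1) == []
    assert apply_ems_mutations({"x": "ATATATAT"}, 0.9, seed=1) == []


def test_ems_rate_one_enumerated():
    """ems_rate=1 on ATGCATGCAT hits exactly the G/C sites: positions 3,4,7,8."""
    variants = apply_ems_mutations({"x": "ATGCATGCAT"}, 1.0, seed=0)
    assert [(v.pos, v.ref, v.alt) for v in variants] == [
        (3, "G", "A"), (4, "C", "T"), (7, "G", "A"), (8, "C", "T"),
    ]


def test_ems_spectrum_invariant():
    genome, genes = simulate_reference(TINY)
    variants = apply_ems_mutations(genome, 5e-3, seed=3, genes=genes)
    assert variants  # non-degenerate draw
    for v in variants:
        assert (v.ref, v.alt) in {("G", "A"), ("C", "T")}
        assert genome[v.chrom][v.pos - 1] == v.ref


def test_ems_count_matches_binomial_expectation():
    genome, _ = simulate_reference(TINY)
    n_gc = sum(seq.count("G") + seq.count("C") for seq in genome.values())
    rate = 5e-3
    counts = [
        len(apply_ems_mutations(genome, rate, seed=s)) for s in range(30)
    ]
    mean = np.mean(counts)
    expected = n_gc * rate
    sd = np.sqrt(n_gc * rate * (1 - rate) / 30)
    assert abs(mean - expected) < 4 * sd


# ---------------------------------------------------------------------------
# Cross, selection, pooled counts
# ---------------------------------------------------------------------------

def test_causal_site_homozygous_alt_in_every_pool():
    genome, genes, truth, pools = simulate_study(TINY)
    for pool in pools:
        causal = truth.causal_variant_per_population[pool.pop_id]
        rec = next(
            r for r in pool.records if (r.chrom, r.pos) == (causal.chrom, causal.pos)
        )
        assert rec.genotype == Genotype.HOM_ALT
        assert rec.alt_fraction >= 0.95


def test_complete_linkage_when_recomb_zero():
    cfg = dataclasses.replace(TINY, recomb_rate=0.0, seed=11)
    genome, genes = simulate_reference(cfg)
    truth = build_truth(genome, genes, cfg)
    pool = simulate_cross_and_bulk(truth, cfg, "pool1")
    causal = truth.causal_variant_per_population["pool1"]
    for i, ((chrom, pos), v) in enumerate(sorted(pool.truth.items())):
        if chrom == causal.chrom:
            assert np.all(pool.plant_alt_copies[i] == 2)


def test_unlinked_sites_segregate_mendelian():
    """Aggregated unlinked-site genotypes in the bulk fit 1:2:1 (chi-square,
    alpha=0.01) in >= 98% of 200 seeded replicates."""
    passes = total = 0
    for seed in range(200):
        cfg = dataclasses.replace(TINY, seed=seed)
        genome, genes = simulate_reference(cfg)
        truth = build_truth(genome, genes, cfg)
        pool = simulate_cross_and_bulk(truth, cfg, "pool1")
        causal = truth.causal_variant_per_population["pool1"]
        keys = sorted(pool.truth)
        counts = np.zeros(3, dtype=int)
        for i, key in enumerate(keys):
            v = pool.truth[key]
            if v.origin == "background" and v.chrom != causal.chrom:
                geno = pool.plant_alt_copies[i]
                counts += np.bincount(geno, minlength=3)
        if counts.sum() == 0:
            continue
        total += 1
        _, _, p = chi_square_ratio(counts, (1, 2, 1))
        passes += p > 0.01
    assert total >= 150
    assert passes / total >= 0.98


def test_unlinked_mean_alt_fraction_near_half():
    """Unlinked surviving background sites average a pooled alt fraction of 0.5."""
    fracs = []
    for seed in range(40):
        cfg = dataclasses.replace(TINY, seed=seed)
        genome, genes = simulate_reference(cfg)
        truth = build_truth(genome, genes, cfg)
        pool = simulate_cross_and_bulk(truth, cfg, "pool1")
        causal = truth.causal_variant_per_population["pool1"]
        for i, key in enumerate(sorted(pool.truth)):
            v = pool.truth[key]
            if v.origin == "background" and v.chrom != causal.chrom:
                fracs.append(pool.plant_alt_copies[i].sum() / (2 * cfg.bulk_size))
    assert len(fracs) > 50
    # SE of the mean of Binomial(2n, 1/2)/2n fractions
    se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
    assert abs(np.mean(fracs) - 0.5) < 4 * se


def test_resampling_warning_when_bulk_exceeds_homozygotes():
    cfg = dataclasses.replace(TINY, bulk_size=30, f2_population_size=40, seed=2)
    genome, genes = simulate_reference(cfg)
    truth = build_truth(genome, genes, cfg)
    with pytest.warns(UserWarning, match="resampling"):
        simulate_cross_and_bulk(truth, cfg, "pool1")


def test_shared_causal_pair_and_distinct_alleles():
    genome, genes, truth, pools = simulate_study(TINY)
    pops = TINY.pop_ids()
    alleles = {
        p: truth.causal_variant_per_population[p] for p in pops
    }
    last, second_last = alleles[pops[-1]], alleles[pops[-2]]
    assert (last.chrom, last.pos) == (second_last.chrom, second_last.pos)
    others = [alleles[p].pos for p in pops[:-1]]
    assert len(set(others)) == len(others)
    # every causal variant lies within the causal gene's model
    causal_gene = next(g for g in genes if g.gene_id == truth.causal_gene)
    for v in alleles.values():
        assert causal_gene.contains(v.pos) and v.chrom == causal_gene.chrom


def test_haldane_map_function():
    assert recombination_fraction(0, 1e-8) == 0.0
    # small distance: r ~ d
    assert recombination_fraction(10_000, 1e-8) == pytest.approx(1e-4, rel=1e-3)
    # unbounded distance: r -> 1/2
    assert recombination_fraction(10**12, 1e-8) == pytest.approx(0.5)


def test_site_quality_monotone_in_alt_reads():
    quals = [site_quality(k, 20, 0.001) for k in range(0, 21)]
    assert quals == sorted(quals)
    assert quals[0] < 1.0 and quals[-1] == 60.0


def test_truth_tsv_round_trip(tmp_path):
    genome, genes, truth, pools = simulate_study(TINY)
    path = tmp_path / "truth.tsv"
    write_truth(truth, path, seed=TINY.seed)
    assert f"seed={TINY.seed}" in path.read_text().splitlines()[0]
    back = read_truth(path)
    assert back.causal_gene == truth.causal_gene
    assert back.causal_variant_per_population == truth.causal_variant_per_population
    assert {k: sorted(v, key=lambda x: (x.chrom, x.pos))
            for k, v in back.background_variants.items()} == {
        k: sorted(v, key=lambda x: (x.chrom, x.pos))
        for k, v in truth.background_variants.items()
    }


def test_study_bit_reproducible():
    a = simulate_study(TINY)
    b = simulate_study(TINY)
    assert a[0] == b[0] and a[1] == b[1]
    assert a[2] == b[2]
    for pa, pb in zip(a[3], b[3]):
        assert pa.records == pb.records
        assert np.array_equal(pa.plant_alt_copies, pb.plant_alt_copies)
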