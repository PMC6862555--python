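"""Variant effect prediction against gene models, with a translate-and-diff oracle."""

import numpy as np
import pytest

from mutmapkit.consequence import (
    Consequence,
    Kind,
    annotate_variant,
    is_deleterious,
    map_genomic_to_cds,
    protein_length_from_cds,
)
from mutmapkit.filtering import Genotype, VariantRecord
from mutmapkit.genes import GeneModel, to_one_based, to_zero_based
from mutmapkit.simulate import COMPLEMENT, SimulationConfig, simulate_reference
from oracles import splice_window_class, translate_and_diff


def _variant(genome, chrom, pos, alt):
    ref = genome[chrom][pos - 1]
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, ref_count=0, alt_count=20,
        qual=60.0, genotype=Genotype.HOM_ALT,
    )


# ---------------------------------------------------------------------------
# Coordinate mapping
# ---------------------------------------------------------------------------

def test_coordinate_converters_round_trip():
    for start, end in [(1, 1), (1, 100), (37, 42)]:
        assert to_one_based(*to_zero_based(start, end)) == (start, end)
    with pytest.raises(ValueError):
        to_zero_based(0, 5)
    with pytest.raises(ValueError):
        to_one_based(5, 5)


def test_map_genomic_to_cds_plus(toy_plus):
    genome, gene = toy_plus
    first_cds = gene.cds[0][0]
    assert map_genomic_to_cds(first_cds, gene) == 1  # first base of ATG
    intron_mid = (gene.introns[0][0] + gene.introns[0][1]) // 2
    assert map_genomic_to_cds(intron_mid, gene) == "intronic"
    assert map_genomic_to_cds(gene.exons[0][0], gene) == "utr"  # 5' UTR base
    assert map_genomic_to_cds(1, gene) == "intergenic"


def test_map_genomic_to_cds_minus(toy_minus):
    genome, gene = toy_minus
    # on the minus strand the genomically-last CDS base is CDS position 1
    assert map_genomic_to_cds(gene.cds[-1][1], gene) == 1
    assert map_genomic_to_cds(gene.cds[0][0], gene) == gene.cds_length


# ---------------------------------------------------------------------------
# Worked classifications on the toy gene (CDS: ATG CGG TGG TAA)
# ---------------------------------------------------------------------------

def test_missense_r2w(toy_plus):
    """C->T at codon-2 base-1 turns CGG (Arg) into TGG (Trp): R2W."""
    genome, gene = toy_plus
    pos = gene.cds[0][0] + 3  # codon 2, base 1
    c = annotate_variant(_variant(genome, gene.chrom, pos, "T"), gene, genome)
    assert c.kind == Kind.MISSENSE and c.protein_change == "R2W"
    assert c.cds_pos == 4


def test_stop_gained_w3(toy_plus):
    """G->A at codon-3 base-2 turns TGG (Trp) into TAG (stop): W3*."""
    genome, gene = toy_plus
    pos = gene.cds[1][0] + 1  # second CDS chunk starts TGG; base 2 of codon 3
    c = annotate_variant(_variant(genome, gene.chrom, pos, "A"), gene, genome)
    assert c.kind == Kind.STOP_GAINED and c.protein_change == "W3*"


def test_splice_donor_gt_disruption(toy_plus):
    """G->A at intron base 1 (GT -> AT) disrupts the canonical donor."""
    genome, gene = toy_plus
    pos = gene.introns[0][0]
    c = annotate_variant(_variant(genome, gene.chrom, pos, "A"), gene, genome)
    assert c.kind == Kind.SPLICE_DONOR
    assert c.protein_change == ""


def test_splice_acceptor(toy_plus):
    genome, gene = toy_plus
    pos = gene.introns[0][1]  # last intron base (the G of AG)
    c = annotate_variant(_variant(genome, gene.chrom, pos, "A"), gene, genome)
    assert c.kind == Kind.SPLICE_ACCEPTOR


def test_minus_strand_mirror(toy_minus):
    """The same codon-level events annotate identically on the minus strand."""
    genome, gene = toy_minus
    # genomic position of CDS position 4 (codon 2 base 1) on a minus-strand gene
    pos = gene.cds[-1][1] - 3
    ref = genome[gene.chrom][pos - 1]
    alt = "T".translate(COMPLEMENT)  # coding-strand C->T is genomic G->A here
    c = annotate_variant(_variant(genome, gene.chrom, pos, alt), gene, genome)
    assert c.kind == Kind.MISSENSE and c.protein_change == "R2W"


def test_reference_mismatch_raises(toy_plus):
    genome, gene = toy_plus
    pos = gene.cds[0][0]
    actual = genome[gene.chrom][pos - 1]
    wrong = "C" if actual != "C" else "G"
    v = VariantRecord(
        chrom=gene.chrom, pos=pos, ref=wrong, alt="T" if wrong != "T" else "A",
        ref_count=0, alt_count=5, qual=60.0, genotype=Genotype.HOM_ALT,
    )
    with pytest.raises(ValueError, match="reference mismatch"):
        annotate_variant(v, gene, genome)


# ---------------------------------------------------------------------------
# Protein length, deleteriousness
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("cds_length,expected", [(1356, 451), (6, 1), (303, 100)])
def test_protein_length(cds_length, expected):
    assert protein_length_from_cds(cds_length) == expected


def test_protein_length_frame_violation():
    with pytest.raises(ValueError):
        protein_length_from_cds(1357)
    with pytest.raises(ValueError):
        protein_length_from_cds(3)


@pytest.mark.parametrize(
    "kind,expected",
    [
        (Kind.STOP_GAINED, True),
        (Kind.SPLICE_DONOR, True),
        (Kind.SPLICE_ACCEPTOR, True),
        (Kind.MISSENSE, True),
        (Kind.START_LOST, True),
        (Kind.STOP_LOST, True),
        (Kind.SYNONYMOUS, False),
        (Kind.INTRONIC, False),
        (Kind.UTR, False),
        (Kind.INTERGENIC, False),
    ],
)
def test_deleterious_set(kind, expected):
    change = "X1Y" if kind in {
        Kind.SYNONYMOUS, Kind.MISSENSE, Kind.STOP_GAINED, Kind.STOP_LOST, Kind.START_LOST
    } else ""
    assert is_deleterious(Consequence(kind, protein_change=change)) is expected


# ---------------------------------------------------------------------------
# Oracle equivalence on random gene models, both strands
# ---------------------------------------------------------------------------

def _random_gene_snvs(n_snvs, seed):
    cfg = SimulationConfig(
        n_chromosomes=2, chromosome_length=30_000, n_genes=8, seed=seed
    )
    genome, genes = simulate_reference(cfg)
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    for _ in range(n_snvs):
        gene = genes[rng.integers(len(genes))]
        pos = int(rng.integers(gene.start, gene.end + 1))
        ref = genome[gene.chrom][pos - 1]
        alt = bases[(bases.index(ref) + rng.integers(1, 4)) % 4]
        yield genome, gene, pos, ref, alt


def test_translate_and_diff_oracle_500_snvs():
    """Codon-level annotation agrees with whole-protein translate-and-diff."""
    n_coding = 0
    for genome, gene, pos, ref, alt in _random_gene_snvs(1300, seed=2024):
        v = VariantRecord(
            chrom=gene.chrom, pos=pos, ref=ref, alt=alt, ref_count=0,
            alt_count=20, qual=60.0, genotype=Genotype.HOM_ALT,
        )
        got = annotate_variant(v, gene, genome)
        splice = splice_window_class(pos, gene)
        if splice is not None:
            assert got.kind.value == splice
            continue
        expected = translate_and_diff(pos, ref, alt, gene, genome)
        if expected is None:
            assert got.kind in (Kind.UTR, Kind.INTRONIC)
            continue
        n_coding += 1
        assert (got.kind.value, got.protein_change) == expected
    assert n_coding >= 500  # the oracle actually exercised the coding path


def test_reference_amino_acid_matches_translation(small_study):
    """Every coding call's reference residue equals the unmutated protein's."""
    from Bio.Seq import Seq

    genome, genes, truth, pools = small_study
    checked = 0
    for gene in genes:
        prot = str(Seq(gene.coding_sequence(genome)).translate())
        for s, e in gene.cds:
            for pos in range(s, min(s + 6, e + 1)):
                ref = genome[gene.chrom][pos - 1]
                alt = "A" if ref != "A" else "G"
                v = VariantRecord(
                    chrom=gene.chrom, pos=pos, ref=ref, alt=alt, ref_count=0,
                    alt_count=9, qual=60.0, genotype=Genotype.HOM_ALT,
                )
                c = annotate_variant(v, gene, genome)
                if c.protein_change:
                    residue = int(c.protein_change[1:-1])
                    assert c.protein_change[0] == prot[residue - 1]
                    checked += 1
    assert checked > 20


def test_strand_symmetry():
    """Reverse-complementing the genome and flipping strands keeps consequences."""
    from mutmapkit.genes import GeneModel

    for genome, gene, pos, ref, alt in _random_gene_snvs(150, seed=99):
        chrom_len = len(genome[gene.chrom])
        rc_genome = {gene.chrom: genome[gene.chrom].translate(COMPLEMENT)[::-1]}

        def flip(iv):
            return (chrom_len - iv[1] + 1, chrom_len - iv[0] + 1)

        rc_gene = GeneModel(
            gene_id=gene.gene_id, chrom=gene.chrom,
            strand="-" if gene.strand == "+" else "+",
            exons=tuple(sorted(flip(iv) for iv in gene.exons)),
            cds=tuple(sorted(flip(iv) for iv in gene.cds)),
        )
        rc_pos = chrom_len - pos + 1
        v = VariantRecord(
            chrom=gene.chrom, pos=pos, ref=ref, alt=alt, ref_count=0,
            alt_count=20, qual=60.0, genotype=Genotype.HOM_ALT,
        )
        rc_v = VariantRecord(
            chrom=gene.chrom, pos=rc_pos, ref=ref.translate(COMPLEMENT),
            alt=alt.translate(COMPLEMENT), ref_count=0, alt_count=20,
            qual=60.0, genotype=Genotype.HOM_ALT,
        )
        c1 = annotate_variant(v, gene, genome)
        c2 = annotate_variant(rc_v, rc_gene, rc_genome)
        assert (c1.kind, c1.protein_change, c1.cds_pos) == (
            c2.kind, c2.protein_change, c2.cds_pos
        )
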