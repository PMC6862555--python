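"""Independent brute-force oracles used by the property and acceptance tests.

Each oracle re-derives the expected answer by a different route than the
implementation: plain per-predicate evaluation for the variant filter,
whole-protein translate-and-diff for consequence calls, and exhaustive
alignment enumeration for the global aligner.
"""

from __future__ import annotations

from Bio.Seq import Seq

from mutmapkit.filtering import Genotype, VariantRecord
from mutmapkit.genes import GeneModel


def brute_force_filter(records, params):
    """Evaluate each filter predicate independently, from raw fields."""
    out = []
    for r in records:
        ems = (r.ref, r.alt) in {("G", "A"), ("C", "T")}
        hom = r.genotype == Genotype.HOM_ALT
        depth_ok = params.min_depth <= r.depth <= params.max_depth
        qual_ok = r.qual > params.min_qual
        if ems and hom and depth_ok and qual_ok:
            out.append(r)
    return out


def translate_and_diff(
    variant_pos: int, ref: str, alt: str, gene: GeneModel, genome: dict[str, str]
):
    """Consequence of a coding SNV by rebuilding and translating the mutant CDS.

    Returns (kind_name, protein_change) for positions inside the CDS, or None
    if the position is not coding. Completely independent of the codon-level
    annotator: it diffs the two full protein strings.
    """
    chrom_seq = genome[gene.chrom]
    assert chrom_seq[variant_pos - 1] == ref
    in_cds = any(s <= variant_pos <= e for s, e in gene.cds)
    if not in_cds:
        return None
    mutant = chrom_seq[: variant_pos - 1] + alt + chrom_seq[variant_pos:]
    ref_cds = gene.coding_sequence(genome)
    alt_cds = gene.coding_sequence({gene.chrom: mutant})
    prot_ref = str(Seq(ref_cds).translate())
    prot_alt = str(Seq(alt_cds).translate())
    if prot_ref == prot_alt:
        diffs = []
    else:
        diffs = [i for i, (x, y) in enumerate(zip(prot_ref, prot_alt)) if x != y]
    if not diffs:
        return ("synonymous", _change_at(prot_ref, prot_ref, variant_pos, gene))
    i = diffs[0]
    ref_aa, alt_aa = prot_ref[i], prot_alt[i]
    change = f"{ref_aa}{i + 1}{alt_aa}"
    if i == 0 and ref_aa == "M":
        kind = "start_lost"
    elif ref_aa == "*":
        kind = "stop_lost"
    elif alt_aa == "*":
        kind = "stop_gained"
    else:
        kind = "missense"
    return (kind, change)


def _change_at(prot_ref, prot_alt, variant_pos, gene):
    """Synonymous notation: residue index from the CDS offset of the variant."""
    offset = 0
    for s, e in gene.cds:
        if s <= variant_pos <= e:
            offset += variant_pos - s
            break
        offset += e - s + 1
    cds_pos = offset + 1 if gene.strand == "+" else gene.cds_length - offset
    i = (cds_pos - 1) // 3
    return f"{prot_ref[i]}{i + 1}{prot_ref[i]}"


def splice_window_class(pos: int, gene: GeneModel):
    """Donor/acceptor/intron label by direct interval arithmetic, or None."""
    for s, e in gene.introns:
        if not s <= pos <= e:
            continue
        if gene.strand == "+":
            if pos <= s + 1:
                return "splice_donor"
            if pos >= e - 1:
                return "splice_acceptor"
        else:
            if pos >= e - 1:
                return "splice_donor"
            if pos <= s + 1:
                return "splice_acceptor"
        return "intronic"
    return None


def enumerate_alignment_score(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0):
    """Optimal global alignment score by exhaustive recursion (no DP table reuse)."""

    def best(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            sub = match if a[i] == b[j] else mismatch
            options.append(sub + best(i + 1, j + 1))
        if i < len(a):
            options.append(gap + best(i + 1, j))
        if j < len(b):
            options.append(gap + best(i, j + 1))
        return max(options)

    return best(0, 0)


def hand_chi_square(observed, ratio):
    """Pearson chi-square by the plain summation formula."""
    total = sum(observed)
    wsum = sum(ratio)
    stat = 0.0
    for o, w in zip(observed, ratio):
        e = total * w / wsum
        stat += (o - e) ** 2 / e
    return stat
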