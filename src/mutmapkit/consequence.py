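"""Gene-model-based variant effect prediction.

Classifies SNVs against single-isoform gene models into the classes relevant
to a recessive loss-of-function screen — missense (e.g. R240W), stop gained
(e.g. W321*), canonical splice-site disruption, and the neutral classes — with
protein notation in 1-letter amino-acid code and ``*`` for stop.

The splice window is the canonical 2 bp at each intron end (GT donor / AG
acceptor on the coding strand); UTRs are collapsed into one class; the
standard nuclear genetic code is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .filtering import VariantRecord
from .genes import GeneModel

COMPLEMENT = str.maketrans("ACGT", "TGCA")


class Kind(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    STOP_GAINED = "stop_gained"
    STOP_LOST = "stop_lost"
    START_LOST = "start_lost"
    SPLICE_DONOR = "splice_donor"
    SPLICE_ACCEPTOR = "splice_acceptor"
    INTRONIC = "intronic"
    UTR = "utr"
    INTERGENIC = "intergenic"


PROTEIN_CHANGING = frozenset(
    {Kind.SYNONYMOUS, Kind.MISSENSE, Kind.STOP_GAINED, Kind.STOP_LOST, Kind.START_LOST}
)
DELETERIOUS_KINDS = frozenset(
    {
        Kind.MISSENSE,
        Kind.STOP_GAINED,
        Kind.STOP_LOST,
        Kind.START_LOST,
        Kind.SPLICE_DONOR,
        Kind.SPLICE_ACCEPTOR,
    }
)


@dataclass(frozen=True)
class Consequence:
    kind: Kind
    protein_change: str = ""  # "<refAA><residue><altAA>", '*' for stop
    cds_pos: int | None = None
    gene_id: str = ""

    def __post_init__(self) -> None:
        if (self.kind in PROTEIN_CHANGING) != bool(self.protein_change):
            raise ValueError(
                f"protein_change must be set iff kind is protein-level, got "
                f"{self.kind.value}/{self.protein_change!r}"
            )


def protein_length_from_cds(cds_length: int) -> int:
    """Protein residues encoded by a CDS of ``cds_length`` nt, stop codon excluded."""
    if cds_length % 3 != 0:
        raise ValueError(f"CDS length {cds_length} not divisible by 3")
    if cds_length < 6:
        raise ValueError("CDS must hold at least a start and a stop codon")
    return cds_length // 3 - 1


def is_deleterious(consequence: Consequence) -> bool:
    """Protein-changing or canonical-splice-disrupting (moderate/high-impact analogue)."""
    return consequence.kind in DELETERIOUS_KINDS


def map_genomic_to_cds(pos: int, gene: GeneModel) -> int | str:
    """1-based CDS offset (5'->3' on the coding strand) or a region label.

    Returns an ``int`` for coding positions, else one of ``"intronic"``,
    ``"utr"``, ``"intergenic"``.
    """
    if pos < 1:
        raise ValueError(f"position {pos} outside chromosome")
    if not gene.contains(pos):
        return Kind.INTERGENIC.value
    forward_offset = 0  # CDS bases strictly before pos in genomic order
    inside = False
    for s, e in gene.cds:
        if pos > e:
            forward_offset += e - s + 1
        elif pos >= s:
            forward_offset += pos - s
            inside = True
            break
    if not inside:
        for s, e in gene.introns:
            if s <= pos <= e:
                return Kind.INTRONIC.value
        return Kind.UTR.value
    if gene.strand == "+":
        return forward_offset + 1
    return gene.cds_length - forward_offset


def _splice_class(pos: int, gene: GeneModel) -> Kind | None:
    """Donor/acceptor if pos hits the canonical 2 bp window of an intron end."""
    for s, e in gene.introns:
        if not (s <= pos <= e):
            continue
        first_two = pos in (s, s + 1) and s + 1 <= e
        last_two = pos in (e - 1, e) and e - 1 >= s
        if gene.strand == "+":
            if first_two:
                return Kind.SPLICE_DONOR
            if last_two:
                return Kind.SPLICE_ACCEPTOR
        else:  # transcription right-to-left: genomic intron end is the donor side
            if last_two:
                return Kind.SPLICE_DONOR
            if first_two:
                return Kind.SPLICE_ACCEPTOR
        return Kind.INTRONIC
    return None


def annotate_variant(
    variant: VariantRecord, gene: GeneModel, genome: Mapping[str, str]
) -> Consequence:
    """Classify one SNV against one gene model.

    Raises if the variant's reference allele disagrees with the genome — that
    always indicates mismatched inputs, never biology.
    """
    chrom_seq = genome[variant.chrom]
    if not 1 <= variant.pos <= len(chrom_seq):
        raise ValueError(f"position {variant.pos} outside {variant.chrom}")
    if chrom_seq[variant.pos - 1] != variant.ref:
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: variant says "
            f"{variant.ref}, genome has {chrom_seq[variant.pos - 1]}"
        )
    if variant.chrom != gene.chrom or not gene.contains(variant.pos):
        return Consequence(Kind.INTERGENIC, gene_id=gene.gene_id)

    splice = _splice_class(variant.pos, gene)
    if splice is not None:
        return Consequence(splice, gene_id=gene.gene_id)

    cds_pos = map_genomic_to_cds(variant.pos, gene)
    if isinstance(cds_pos, str):
        return Consequence(Kind(cds_pos), gene_id=gene.gene_id)

    cds = gene.coding_sequence(genome)
    codon_index = (cds_pos - 1) // 3
    offset = (cds_pos - 1) % 3
    ref_codon = cds[codon_index * 3 : codon_index * 3 + 3]
    alt_base = variant.alt if gene.strand == "+" else variant.alt.translate(COMPLEMENT)
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    residue = codon_index + 1
    change = f"{ref_aa}{residue}{alt_aa}"

    if ref_aa == alt_aa:
        kind = Kind.SYNONYMOUS
    elif codon_index == 0 and ref_aa == "M":
        kind = Kind.START_LOST
    elif ref_aa == "*":
        kind = Kind.STOP_LOST
    elif alt_aa == "*":
        kind = Kind.STOP_GAINED
    else:
        kind = Kind.MISSENSE
    return Consequence(kind, protein_change=change, cds_pos=cds_pos, gene_id=gene.gene_id)


def annotate_against_genes(
    variant: VariantRecord, genes: Sequence[GeneModel], genome: Mapping[str, str]
) -> Consequence:
    """Annotate against the gene containing the variant (intergenic if none).

    Gene models are non-overlapping here, so at most one gene applies.
    """
    for gene in genes:
        if gene.chrom == variant.chrom and gene.contains(variant.pos):
            return annotate_variant(variant, gene, genome)
    return Consequence(Kind.INTERGENIC)
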