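"""Gene models and reference-genome IO.

A :class:`GeneModel` is the minimal single-isoform gene structure needed for
variant-consequence annotation: ordered exons, a CDS contained in them, and a
strand. Coordinates follow the field convention — 1-based inclusive in every
file interface (FASTA/GFF3/VCF) and 0-based half-open internally; the two
converters below are bijective and round-trip tested.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Interval = tuple[int, int]  # 1-based inclusive


def to_zero_based(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive [start, end] -> 0-based half-open [start0, end0)."""
    if start < 1 or end < start:
        raise ValueError(f"invalid 1-based interval [{start}, {end}]")
    return start - 1, end


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open [start0, end0) -> 1-based inclusive [start, end]."""
    if start0 < 0 or end0 <= start0:
        raise ValueError(f"invalid 0-based interval [{start0}, {end0})")
    return start0 + 1, end0


@dataclass(frozen=True)
class GeneModel:
    """Exon/CDS structure of one gene on one strand.

    ``exons`` and ``cds`` are ordered, non-overlapping 1-based inclusive
    intervals sorted by genomic coordinate regardless of strand; the total CDS
    length must be divisible by 3 and every CDS interval must lie inside an
    exon.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            for (s, e) in ivs:
                if s < 1 or e < s:
                    raise ValueError(f"bad {name} interval [{s}, {e}]")
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"{name} intervals overlap or are unsorted")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"CDS length {self.cds_length} of {self.gene_id} not divisible by 3"
            )
        for (cs, ce) in self.cds:
            if not any(es <= cs and ce <= ee for (es, ee) in self.exons):
                raise ValueError(f"CDS interval [{cs}, {ce}] not inside an exon")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def introns(self) -> tuple[Interval, ...]:
        """Intron intervals (1-based inclusive), in genomic coordinate order."""
        return tuple(
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def coding_sequence(self, genome: Mapping[str, str]) -> str:
        """Spliced CDS 5'->3' on the coding strand."""
        seq = self.cds_forward_sequence(genome)
        return str(Seq(seq).reverse_complement()) if self.strand == "-" else seq

    def cds_forward_sequence(self, genome: Mapping[str, str]) -> str:
        chrom_seq = genome[self.chrom]
        parts = []
        for s, e in self.cds:
            s0, e0 = to_zero_based(s, e)
            parts.append(chrom_seq[s0:e0])
        return "".join(parts)


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------

def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")  # wraps at 60 columns


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(
    genes: Iterable[GeneModel], path: str | Path, *, source: str = "mutmapkit"
) -> None:
    """Write gene/mRNA/exon/CDS features with CDS phase, GFF3 v1.23 layout."""
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
        col9 = f"ID={g.gene_id}"
        lines.append(
            "\t".join(
                [g.chrom, source, "gene", str(g.start), str(g.end), ".", g.strand, ".", col9]
            )
        )
        mrna_id = f"{g.gene_id}.1"
        lines.append(
            "\t".join(
                [
                    g.chrom, source, "mRNA", str(g.start), str(g.end), ".", g.strand,
                    ".", f"ID={mrna_id};Parent={g.gene_id}",
                ]
            )
        )
        for i, (s, e) in enumerate(g.exons, 1):
            lines.append(
                "\t".join(
                    [
                        g.chrom, source, "exon", str(s), str(e), ".", g.strand, ".",
                        f"ID={mrna_id}.exon{i};Parent={mrna_id}",
                    ]
                )
            )
        # phase runs 5'->3' on the coding strand
        ordered = list(g.cds) if g.strand == "+" else list(reversed(g.cds))
        consumed = 0
        phases: dict[Interval, int] = {}
        for s, e in ordered:
            phases[(s, e)] = (3 - consumed % 3) % 3
            consumed += e - s + 1
        for i, (s, e) in enumerate(g.cds, 1):
            lines.append(
                "\t".join(
                    [
                        g.chrom, source, "CDS", str(s), str(e), ".", g.strand,
                        str(phases[(s, e)]), f"ID={mrna_id}.cds{i};Parent={mrna_id}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load single-isoform gene models from a GFF3 file via gffutils."""
    with tempfile.NamedTemporaryFile(suffix=".db") as tmp:
        db = gffutils.create_db(
            str(path), tmp.name, force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        models = []
        for gene in db.features_of_type("gene"):
            mrnas = list(db.children(gene, featuretype="mRNA"))
            parent = mrnas[0] if mrnas else gene
            exons = tuple(
                sorted((f.start, f.end) for f in db.children(parent, featuretype="exon"))
            )
            cds = tuple(
                sorted((f.start, f.end) for f in db.children(parent, featuretype="CDS"))
            )
            if not exons:
                exons = ((gene.start, gene.end),)
            models.append(
                GeneModel(
                    gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
                    exons=exons, cds=cds,
                )
            )
    return sorted(models, key=lambda g: (g.chrom, g.start, g.gene_id))
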