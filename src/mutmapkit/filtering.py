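"""Candidate-SNP filtering for EMS bulked-segregant pools.

An EMS-mutagenized line carries almost exclusively G/C->A/T transitions, and a
phenotype-selected recessive bulk is homozygous for the causal allele, so the
candidate filter keeps only homozygous EMS-type SNVs whose site quality
exceeds Q20 and whose read depth lies in the trusted [3, 50] window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

BASES = frozenset("ACGT")
EMS_TRANSITIONS = frozenset({("G", "A"), ("C", "T")})


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNV call in one bulk pool."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    ref_count: int
    alt_count: int
    qual: float
    genotype: Genotype
    pop_id: str = ""
    depth: int | None = None  # defaults to ref_count + alt_count

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        if self.pos < 1 or self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("negative counts or non-positive position")
        if self.depth is None:
            object.__setattr__(self, "depth", self.ref_count + self.alt_count)

    @property
    def alt_fraction(self) -> float:
        total = self.ref_count + self.alt_count
        return self.alt_count / total if total else float("nan")


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the candidate filter (depth window inclusive, quality strict)."""

    min_qual: float = 20.0
    min_depth: int = 3
    max_depth: int = 50
    hom_alt_min_fraction: float = 0.9
    het_band: tuple[float, float] = (0.25, 0.75)

    def __post_init__(self) -> None:
        if not (0 < self.min_depth <= self.max_depth):
            raise ValueError("need 0 < min_depth <= max_depth")
        for f in (self.hom_alt_min_fraction, *self.het_band):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


def is_ems_type(ref: str, alt: str) -> bool:
    """True iff (ref, alt) is an EMS transition: G->A or C->T on the reference strand."""
    if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
        raise ValueError(f"alleles must be single bases, got {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    return (ref, alt) in EMS_TRANSITIONS


def call_pool_genotype(
    ref_count: int, alt_count: int, params: FilterParams = FilterParams()
) -> Genotype:
    """Call the pooled genotype from allele-supporting read counts.

    hom_alt if the alt fraction reaches ``hom_alt_min_fraction``; hom_ref if it
    is at most the mirror threshold; het inside ``het_band``; otherwise (zero
    reads, or a fraction between the bands) missing.
    """
    total = ref_count + alt_count
    if total == 0:
        return Genotype.MISSING
    frac = alt_count / total
    if frac >= params.hom_alt_min_fraction:
        return Genotype.HOM_ALT
    if frac <= 1.0 - params.hom_alt_min_fraction:
        return Genotype.HOM_REF
    if params.het_band[0] <= frac <= params.het_band[1]:
        return Genotype.HET
    return Genotype.MISSING


def passes_depth_quality(
    record: VariantRecord, params: FilterParams = FilterParams()
) -> bool:
    """Depth within [min_depth, max_depth] inclusive and quality strictly above Q20."""
    return (
        params.min_depth <= record.depth <= params.max_depth
        and record.qual > params.min_qual
    )


def filter_candidate_variants(
    records: Sequence[VariantRecord], params: FilterParams = FilterParams()
) -> list[VariantRecord]:
    """Retain homozygous-alt EMS-type SNVs passing depth and quality; order preserved."""
    return [
        r
        for r in records
        if is_ems_type(r.ref, r.alt)
        and r.genotype == Genotype.HOM_ALT
        and passes_depth_quality(r, params)
    ]


def filter_summary(
    records: Sequence[VariantRecord], params: FilterParams = FilterParams()
) -> pd.DataFrame:
    """Per-predicate pass counts, as written to the filter-summary TSV."""
    n = len(records)
    rows = [
        ("input", n),
        ("ems_type", sum(is_ems_type(r.ref, r.alt) for r in records)),
        ("hom_alt", sum(r.genotype == Genotype.HOM_ALT for r in records)),
        ("depth_quality", sum(passes_depth_quality(r, params) for r in records)),
        ("passing_all", len(filter_candidate_variants(records, params))),
    ]
    return pd.DataFrame(rows, columns=["predicate", "count"])


# ---------------------------------------------------------------------------
# VCF IO (pysam; VCF v4.2, one sample per pool; INFO DP, FORMAT GT/AD/DP)
# ---------------------------------------------------------------------------

_GT_CODES = {
    Genotype.HOM_REF: (0, 0),
    Genotype.HET: (0, 1),
    Genotype.HOM_ALT: (1, 1),
    Genotype.MISSING: (None, None),
}
_GT_FROM_CODES = {v: k for k, v in _GT_CODES.items()}


def _vcf_header(sample: str, contigs: dict[str, int] | None = None) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic read depths">'
    )
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    for name, length in (contigs or {}).items():
        header.contigs.add(name, length=length)
    header.add_sample(sample)
    return header


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    *,
    sample: str | None = None,
    contigs: dict[str, int] | None = None,
) -> None:
    sample = sample or (records[0].pop_id if records else "pool")
    if contigs is None:
        contigs = {}
        for r in records:
            contigs[r.chrom] = max(contigs.get(r.chrom, 0), r.pos + 1)
    header = _vcf_header(sample, contigs)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            rec = vcf.new_record(
                contig=r.chrom, start=r.pos - 1, stop=r.pos,
                alleles=(r.ref, r.alt), qual=round(r.qual, 2),
            )
            rec.info["DP"] = r.depth
            rec.samples[sample]["GT"] = _GT_CODES[r.genotype]
            rec.samples[sample]["AD"] = (r.ref_count, r.alt_count)
            rec.samples[sample]["DP"] = r.depth
            vcf.write(rec)


def read_vcf(path: str | Path, *, pop_id: str | None = None) -> list[VariantRecord]:
    """Load biallelic SNVs; multi-allelic records and indels are skipped with a log."""
    records: list[VariantRecord] = []
    n_multi = n_indel = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError(f"{path}: VCF has no sample column")
        sample = samples[0]
        if pop_id is None:
            pop_id = sample
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                n_multi += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                n_indel += 1
                continue
            fmt = rec.samples[sample]
            ad = fmt.get("AD")
            ref_count, alt_count = (int(ad[0]), int(ad[1])) if ad and ad[0] is not None else (0, 0)
            gt = _GT_FROM_CODES.get(tuple(fmt.get("GT") or (None, None)), Genotype.MISSING)
            depth = fmt.get("DP")
            records.append(
                VariantRecord(
                    chrom=rec.chrom, pos=rec.pos, ref=ref, alt=alt,
                    ref_count=ref_count, alt_count=alt_count,
                    qual=float(rec.qual) if rec.qual is not None else 0.0,
                    genotype=gt, pop_id=pop_id,
                    depth=int(depth) if depth is not None else None,
                )
            )
    if n_multi:
        logger.info("%s: skipped %d multi-allelic records", path, n_multi)
    if n_indel:
        logger.info("%s: skipped %d indel records", path, n_indel)
    return records
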