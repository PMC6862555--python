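"""Per-population candidate gene sets and the multi-population intersection.

Each independently mutagenized population contributes the set of genes that
carry at least one filtered, homozygous, deleterious EMS variant in its bulk;
the causal gene is the one common to all populations. Allelism reporting
groups populations by the exact (chrom, pos, ref, alt) of their allele in a
shared gene, so independent isolates of the same base change are visible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import consequence as csq
from .filtering import VariantRecord
from .genes import GeneModel
from .simulate import BulkPool, TruthSet

AlleleKey = tuple[str, int, str, str]  # (chrom, pos, ref, alt)


@dataclass(frozen=True)
class CandidateReport:
    per_population: dict[str, frozenset[str]]
    intersection: tuple[str, ...]  # sorted gene ids
    allelism: dict[str, dict[str, AlleleKey]]  # gene -> pop -> allele

    def __post_init__(self) -> None:
        expected = set.intersection(*(set(s) for s in self.per_population.values()))
        if set(self.intersection) != expected:
            raise ValueError("intersection field disagrees with per-population sets")


def genes_with_homozygous_deleterious(
    records: Sequence[VariantRecord],
    gene_models: Sequence[GeneModel],
    genome: Mapping[str, str],
) -> set[str]:
    """Genes hit by >= 1 deleterious variant among already-filtered records."""
    hit: set[str] = set()
    for rec in records:
        c = csq.annotate_against_genes(rec, gene_models, genome)
        if c.gene_id and csq.is_deleterious(c):
            hit.add(c.gene_id)
    return hit


def deleterious_variants_by_gene(
    records: Sequence[VariantRecord],
    gene_models: Sequence[GeneModel],
    genome: Mapping[str, str],
) -> dict[str, list[tuple[VariantRecord, csq.Consequence]]]:
    out: dict[str, list[tuple[VariantRecord, csq.Consequence]]] = {}
    for rec in records:
        c = csq.annotate_against_genes(rec, gene_models, genome)
        if c.gene_id and csq.is_deleterious(c):
            out.setdefault(c.gene_id, []).append((rec, c))
    return out


def intersect_populations(per_population: Mapping[str, set[str]]) -> tuple[str, ...]:
    """Sorted gene ids present in every population's candidate set."""
    if len(per_population) < 2:
        raise ValueError("need candidate sets from at least 2 populations")
    common = set.intersection(*(set(s) for s in per_population.values()))
    return tuple(sorted(common))


def allelism_check(
    per_pool_variants: Mapping[str, Sequence[VariantRecord]], gene_id: str
) -> dict[AlleleKey, list[str]]:
    """Group pools by identical allele in ``gene_id``'s variant lists.

    ``per_pool_variants`` maps pop id -> that pool's (already gene-assigned)
    variants in the gene; pools sharing (chrom, pos, ref, alt) fall into one
    allele class.
    """
    classes: dict[AlleleKey, list[str]] = {}
    for pop, variants in per_pool_variants.items():
        if not variants:
            raise ValueError(f"gene {gene_id} has no variant in pool {pop}")
        for v in variants:
            key = (v.chrom, v.pos, v.ref, v.alt)
            pops = classes.setdefault(key, [])
            if pop not in pops:
                pops.append(pop)
    return classes


STOP_SPLICE = frozenset(
    {csq.Kind.STOP_GAINED, csq.Kind.SPLICE_DONOR, csq.Kind.SPLICE_ACCEPTOR}
)


def build_candidate_report(
    pools_records: Mapping[str, Sequence[VariantRecord]],
    gene_models: Sequence[GeneModel],
    genome: Mapping[str, str],
) -> CandidateReport:
    """Filterd per-pool records -> candidate sets, intersection, allelism.

    If the intersection holds more than one gene, genes are ranked by the
    number of pools carrying a stop/splice (clearly truncating) allele, then
    by gene id; a unique hit is unaffected by the rule.
    """
    per_gene: dict[str, dict[str, list[tuple[VariantRecord, csq.Consequence]]]] = {}
    per_population: dict[str, frozenset[str]] = {}
    for pop, records in pools_records.items():
        by_gene = deleterious_variants_by_gene(records, gene_models, genome)
        per_population[pop] = frozenset(by_gene)
        for gene_id, hits in by_gene.items():
            per_gene.setdefault(gene_id, {})[pop] = hits
    common = intersect_populations(per_population)

    def rank(gene_id: str) -> tuple[int, str]:
        n_truncating = sum(
            any(c.kind in STOP_SPLICE for _, c in hits)
            for hits in per_gene[gene_id].values()
        )
        return (-n_truncating, gene_id)

    ordered = tuple(sorted(common, key=rank))
    allelism: dict[str, dict[str, AlleleKey]] = {}
    for gene_id in ordered:
        allelism[gene_id] = {
            pop: (hits[0][0].chrom, hits[0][0].pos, hits[0][0].ref, hits[0][0].alt)
            for pop, hits in per_gene[gene_id].items()
        }
    return CandidateReport(
        per_population=per_population, intersection=ordered, allelism=allelism
    )


# ---------------------------------------------------------------------------
# Serialization and truth-aware evaluation
# ---------------------------------------------------------------------------

def report_to_json(report: CandidateReport) -> str:
    payload = {
        "per_population": {
            pop: sorted(genes) for pop, genes in sorted(report.per_population.items())
        },
        "intersection": list(report.intersection),
        "allelism": {
            gene: {pop: list(key) for pop, key in sorted(pops.items())}
            for gene, pops in report.allelism.items()
        },
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def write_report(report: CandidateReport, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    json_path = outdir / "candidates.json"
    json_path.write_text(report_to_json(report) + "\n")
    rows = [
        {"pop_id": pop, "gene_id": g}
        for pop, genes in sorted(report.per_population.items())
        for g in sorted(genes)
    ]
    tsv_path = outdir / "candidates.tsv"
    pd.DataFrame(rows, columns=["pop_id", "gene_id"]).to_csv(
        tsv_path, sep="\t", index=False
    )
    return {"json": json_path, "tsv": tsv_path}


def evaluate_report(report: CandidateReport, truth: TruthSet) -> dict:
    """Recovery metrics of a report against the simulator's truth."""
    return {
        "causal_gene": truth.causal_gene,
        "causal_in_intersection": truth.causal_gene in report.intersection,
        "intersection_size": len(report.intersection),
        "exact_single_hit": report.intersection == (truth.causal_gene,),
    }
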