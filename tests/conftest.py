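import numpy as np
import pytest
from hypothesis import settings

from mutmapkit.candidates import build_candidate_report, evaluate_report
from mutmapkit.filtering import filter_candidate_variants
from mutmapkit.genes import GeneModel
from mutmapkit.simulate import SimulationConfig, simulate_study

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_genome_and_gene(
    *,
    strand: str = "+",
    utr5: str = "TTTTTT",
    cds_chunks: tuple[str, ...] = ("ATGCGG", "TGGTAA"),
    introns: tuple[str, ...] = ("GTAAAAAG",),
    utr3: str = "TTTTTT",
    flank: str = "AAAAAAAAAA",
    chrom: str = "toy",
    gene_id: str = "g1",
):
    """Hand-assembled toy gene: coding-strand regions -> genome + GeneModel."""
    from mutmapkit.simulate import COMPLEMENT

    regions = [("utr", utr5)]
    for i, chunk in enumerate(cds_chunks):
        regions.append(("cds", chunk))
        if i < len(introns):
            regions.append(("intron", introns[i]))
    regions.append(("utr", utr3))
    if strand == "-":
        regions = [(k, s.translate(COMPLEMENT)[::-1]) for k, s in reversed(regions)]
    pos = len(flank) + 1
    exons, cds = [], []
    exon_start = None
    parts = [flank]
    for kind, seq in regions:
        s, e = pos, pos + len(seq) - 1
        if kind == "intron":
            exons.append((exon_start, s - 1))
            exon_start = None
        else:
            if exon_start is None:
                exon_start = s
            if kind == "cds":
                cds.append((s, e))
        parts.append(seq)
        pos = e + 1
    exons.append((exon_start, pos - 1))
    parts.append(flank)
    gene = GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand,
        exons=tuple(exons), cds=tuple(cds),
    )
    return {chrom: "".join(parts)}, gene


@pytest.fixture(scope="session")
def toy_plus():
    """Plus-strand two-exon gene; CDS = ATG CGG TGG TAA (M R W *)."""
    return make_genome_and_gene(strand="+")


@pytest.fixture(scope="session")
def toy_minus():
    """Same gene on the minus strand."""
    return make_genome_and_gene(strand="-")


SMALL_CONFIG = SimulationConfig(
    n_chromosomes=2, chromosome_length=40_000, n_genes=6, ems_rate=2e-3, seed=0
)


@pytest.fixture(scope="session")
def small_study():
    """A fast, fully simulated study on a 80 kb genome."""
    return simulate_study(SMALL_CONFIG)


def run_recovery(seed: int, config: SimulationConfig = SimulationConfig()):
    """One simulate -> filter -> annotate -> intersect run scored against truth."""
    import dataclasses

    cfg = dataclasses.replace(config, seed=seed)
    genome, genes, truth, pools = simulate_study(cfg)
    filtered = {p.pop_id: filter_candidate_variants(p.records) for p in pools}
    report = build_candidate_report(filtered, genes, genome)
    return evaluate_report(report, truth)


@pytest.fixture(scope="session")
def recovery_50_runs():
    """Recovery metrics of 50 seeded default-condition runs (shared across tests)."""
    return [run_recovery(seed) for seed in range(1, 51)]
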