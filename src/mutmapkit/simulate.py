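"""Synthetic EMS bulked-segregant study generator.

Emulates the genetic structure of a MutMap experiment on a toy genome: an EMS
mutagen lays down G/C->A/T transitions; each mutant line is backcrossed to the
wild-type recurrent parent for several generations (each backcross halves the
expected retention of unlinked mutant-origin heterozygosity, while loci linked
to the phenotype-selected causal allele survive according to their
recombination fraction); an F2 is selfed from the final backcross and a bulk
of plants homozygous for the recessive causal allele is pooled and
"sequenced" at the variant level — per retained site the pool's read depth is
Poisson, alt-supporting reads are binomial in the pooled allele frequency
perturbed by the per-base error rate, and a phred-scaled site quality is
derived from the counts.

No read-level artefacts (FASTQ, alignment, mapping error) are simulated;
output is variant-level, serialized as FASTA + GFF3 + one VCF per pool + a
truth TSV.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from . import consequence as csq
from .filtering import FilterParams, Genotype, VariantRecord, call_pool_genotype
from .genes import GeneModel, write_fasta, write_gff3

COMPLEMENT = str.maketrans("ACGT", "TGCA")
EMS_ALT = {"G": "A", "C": "T"}
STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs of the synthetic experiment.

    Defaults mirror the experimental design being emulated: three backcross
    generations, F2 bulks of 20 phenotype-selected homozygous mutants, ~20x
    pooled depth, four independent mutant populations sharing one causal gene.
    """

    n_chromosomes: int = 2
    chromosome_length: int = 500_000  # bp per chromosome
    n_genes: int = 100
    gc_fraction: float = 0.44
    ems_rate: float = 2e-4  # mutation probability per G/C site
    bc_generations: int = 3
    bulk_size: int = 20  # plants per F2 bulk
    mean_depth: float = 20.0  # reads per site in the pool
    base_error_rate: float = 0.001
    recomb_rate: float = 2e-8  # Morgans per bp
    n_populations: int = 4
    seed: int = 0
    f2_population_size: int | None = None  # default 8 x bulk_size
    shared_causal_pair: bool = True  # last two pools share an identical causal allele

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chromosome_length", "n_genes",
                     "bc_generations", "bulk_size", "n_populations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("gc_fraction", "ems_rate", "base_error_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mean_depth <= 0 or self.recomb_rate < 0:
            raise ValueError("mean_depth must be > 0 and recomb_rate >= 0")
        if self.f2_population_size is not None and self.f2_population_size < 1:
            raise ValueError("f2_population_size must be >= 1")

    @property
    def f2_size(self) -> int:
        return self.f2_population_size or 8 * self.bulk_size

    def pop_ids(self) -> list[str]:
        return [f"pool{i + 1}" for i in range(self.n_populations)]


@dataclass(frozen=True)
class GermlineVariant:
    """A mutagen-induced germline SNV with its truth label."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    origin: str  # 'causal' or 'background'
    linked_gene: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref == alt")
        if self.ref not in EMS_ALT or self.alt != EMS_ALT[self.ref]:
            raise ValueError(
                f"EMS variant must be G->A or C->T, got {self.ref}->{self.alt}"
            )


@dataclass(frozen=True)
class TruthSet:
    """Machine-readable ground truth of one simulated study."""

    causal_gene: str
    causal_variant_per_population: dict[str, GermlineVariant]
    background_variants: dict[str, list[GermlineVariant]]


@dataclass
class BulkPool:
    """One phenotype-selected F2 bulk with its variant-level 'sequencing' output."""

    pop_id: str
    bulk_size: int
    records: list[VariantRecord]
    truth: dict[tuple[str, int], GermlineVariant]
    plant_alt_copies: np.ndarray  # (n_records, bulk_size) causal-selected genotypes
    f2_causal_genotype_counts: tuple[int, int, int]  # (hom_ref, het, hom_alt), unselected


# ---------------------------------------------------------------------------
# Reference genome and gene models
# ---------------------------------------------------------------------------

def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n random sense codons (no in-frame stops)."""
    codons = []
    bases = np.array(list("ACGT"))
    while len(codons) < n:
        draw = ["".join(bases[rng.integers(0, 4, size=3)]) for _ in range(n - len(codons))]
        codons.extend(c for c in draw if c not in STOP_CODONS)
    return "".join(codons[:n])


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _build_gene_regions(rng: np.random.Generator, gc: float) -> list[tuple[str, str]]:
    """Transcription-order (kind, sequence) regions on the coding strand."""
    n_residues = int(rng.integers(80, 200))
    cds = "ATG" + _random_codons(rng, n_residues - 1) + "TAA"
    n_exons = int(rng.integers(2, 9))
    # split the CDS into n_exons chunks, each >= 3 nt
    cuts = sorted(rng.choice(np.arange(3, len(cds) - 2, 3), size=n_exons - 1, replace=False))
    chunks, prev = [], 0
    for c in [*cuts, len(cds)]:
        chunks.append(cds[prev:c])
        prev = c
    regions: list[tuple[str, str]] = [("utr", _random_seq(rng, int(rng.integers(20, 60)), gc))]
    for i, chunk in enumerate(chunks):
        regions.append(("cds", chunk))
        if i < len(chunks) - 1:
            interior = _random_seq(rng, int(rng.integers(56, 196)), gc)
            regions.append(("intron", "GT" + interior + "AG"))
    regions.append(("utr", _random_seq(rng, int(rng.integers(20, 60)), gc)))
    return regions


def _place_gene(
    gene_id: str, chrom: str, strand: str, start: int, regions: list[tuple[str, str]]
) -> tuple[GeneModel, str]:
    """Lay regions onto the genome from 1-based ``start``; returns model + sequence."""
    if strand == "-":
        regions = [(k, s.translate(COMPLEMENT)[::-1]) for k, s in reversed(regions)]
    exons: list[tuple[int, int]] = []
    cds: list[tuple[int, int]] = []
    pos = start
    exon_start: int | None = None
    for kind, seq in regions:
        s, e = pos, pos + len(seq) - 1
        if kind == "intron":
            if exon_start is not None:
                exons.append((exon_start, s - 1))
                exon_start = None
        else:
            if exon_start is None:
                exon_start = s
            if kind == "cds":
                cds.append((s, e))
        pos = e + 1
    if exon_start is not None:
        exons.append((exon_start, pos - 1))
    model = GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand,
        exons=tuple(exons), cds=tuple(cds),
    )
    return model, "".join(seq for _, seq in regions)


def simulate_reference(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Toy genome + non-overlapping multi-exon gene models.

    Every gene has >= 2 exons, canonical GT/AG introns on the coding strand,
    and a CDS that starts with ATG, ends with a stop, and is a multiple of 3.
    Deterministic for a given config (including its seed).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EF]))
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1

    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    gene_no = 0
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1:02d}"
        bodies = []
        for _ in range(per_chrom[ci]):
            regions = _build_gene_regions(rng, config.gc_fraction)
            bodies.append(regions)
        total = sum(sum(len(s) for _, s in r) for r in bodies)
        n_gaps = len(bodies) + 1
        min_gap = 50
        slack = config.chromosome_length - total - n_gaps * min_gap
        if slack < 0:
            raise ValueError(
                f"{chrom}: {per_chrom[ci]} genes ({total} bp) cannot fit in "
                f"{config.chromosome_length} bp"
            )
        extra = rng.multinomial(slack, np.ones(n_gaps) / n_gaps) if n_gaps else []
        seq_parts: list[str] = []
        cursor = 1
        for gi, regions in enumerate(bodies):
            gap = min_gap + int(extra[gi])
            seq_parts.append(_random_seq(rng, gap, config.gc_fraction))
            cursor += gap
            gene_no += 1
            strand = "+" if rng.random() < 0.5 else "-"
            model, gene_seq = _place_gene(
                f"gene{gene_no:04d}", chrom, strand, cursor, regions
            )
            genes.append(model)
            seq_parts.append(gene_seq)
            cursor += len(gene_seq)
        tail = config.chromosome_length - (cursor - 1)
        seq_parts.append(_random_seq(rng, tail, config.gc_fraction))
        genome[chrom] = "".join(seq_parts)
        assert len(genome[chrom]) == config.chromosome_length
    return genome, genes


# ---------------------------------------------------------------------------
# EMS mutagenesis and truth
# ---------------------------------------------------------------------------

def apply_ems_mutations(
    genome: Mapping[str, str],
    ems_rate: float,
    seed: int | np.random.Generator,
    *,
    genes: Sequence[GeneModel] = (),
) -> list[GermlineVariant]:
    """Draw EMS-induced G->A / C->T transitions, Bernoulli(ems_rate) per G/C site."""
    if not 0.0 <= ems_rate <= 1.0:
        raise ValueError("ems_rate must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_gene = {(g.chrom): [] for g in genes}
    for g in genes:
        by_gene[g.chrom].append(g)
    variants: list[GermlineVariant] = []
    for chrom in sorted(genome):
        arr = np.frombuffer(genome[chrom].encode(), dtype="S1")
        gc_pos = np.flatnonzero((arr == b"G") | (arr == b"C"))
        if gc_pos.size == 0 or ems_rate == 0.0:
            continue
        hit = gc_pos[rng.random(gc_pos.size) < ems_rate]
        for p0 in hit:
            ref = genome[chrom][p0]
            gene_id = next(
                (g.gene_id for g in by_gene.get(chrom, []) if g.contains(int(p0) + 1)),
                None,
            )
            variants.append(
                GermlineVariant(
                    chrom=chrom, pos=int(p0) + 1, ref=ref, alt=EMS_ALT[ref],
                    origin="background", linked_gene=gene_id,
                )
            )
    return variants


def _pick_causal_variant(
    gene: GeneModel,
    genome: Mapping[str, str],
    rng: np.random.Generator,
    forbidden: set[int],
) -> GermlineVariant:
    """An EMS-type SNV in the causal gene whose consequence is deleterious."""
    chrom_seq = genome[gene.chrom]
    candidates = [
        p
        for p in range(gene.start, gene.end + 1)
        if chrom_seq[p - 1] in EMS_ALT and p not in forbidden
    ]
    rng.shuffle(candidates)
    for pos in candidates:
        ref = chrom_seq[pos - 1]
        rec = VariantRecord(
            chrom=gene.chrom, pos=pos, ref=ref, alt=EMS_ALT[ref],
            ref_count=0, alt_count=1, qual=60.0, genotype=Genotype.HOM_ALT,
        )
        if csq.is_deleterious(csq.annotate_variant(rec, gene, genome)):
            return GermlineVariant(
                chrom=gene.chrom, pos=pos, ref=ref, alt=EMS_ALT[ref],
                origin="causal", linked_gene=gene.gene_id,
            )
    raise ValueError(f"no deleterious EMS site available in {gene.gene_id}")


def build_truth(
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    config: SimulationConfig,
) -> TruthSet:
    """Pick one causal gene shared by all populations and per-population alleles.

    Causal positions are distinct across populations except that, when
    ``shared_causal_pair`` is set, the last two populations carry an identical
    allele — the situation of two independent isolates hitting the same base.
    Background mutations are drawn independently per population (independent
    mutagenesis events) and never collide with that population's causal site.
    """
    ss_pick, ss_bg = np.random.SeedSequence([config.seed, 0x7121]).spawn(2)
    rng_pick = np.random.default_rng(ss_pick)
    causal_gene = genes[int(rng_pick.integers(0, len(genes)))]
    pops = config.pop_ids()
    causal: dict[str, GermlineVariant] = {}
    used: set[int] = set()
    for i, pop in enumerate(pops):
        share = (
            config.shared_causal_pair
            and config.n_populations >= 2
            and i == len(pops) - 1
        )
        if share:
            causal[pop] = replace(causal[pops[-2]])
        else:
            v = _pick_causal_variant(causal_gene, genome, rng_pick, used)
            used.add(v.pos)
            causal[pop] = v
    backgrounds: dict[str, list[GermlineVariant]] = {}
    for pop, bg_ss in zip(pops, ss_bg.spawn(len(pops))):
        bg = apply_ems_mutations(
            genome, config.ems_rate, np.random.default_rng(bg_ss), genes=genes
        )
        backgrounds[pop] = [v for v in bg if v.pos != causal[pop].pos or v.chrom != causal[pop].chrom]
    return TruthSet(
        causal_gene=causal_gene.gene_id,
        causal_variant_per_population=causal,
        background_variants=backgrounds,
    )


# ---------------------------------------------------------------------------
# Backcrossing, F2 selection, pooled read counts
# ---------------------------------------------------------------------------

def recombination_fraction(distance_bp: int, recomb_rate: float) -> float:
    """Haldane map function: r = (1 - exp(-2d)) / 2 with d in Morgans."""
    d = recomb_rate * abs(distance_bp)
    return 0.5 * (1.0 - math.exp(-2.0 * d))


def site_quality(alt_count: int, depth: int, base_error_rate: float) -> float:
    """Phred-scaled evidence against hom-ref: min(60, -10*log10 P(counts | hom-ref)).

    The hom-ref error model is Binomial(depth, base_error_rate) alt reads.
    """
    if depth == 0:
        return 0.0
    e = max(base_error_rate, 1e-10)
    logp = stats.binom.logpmf(alt_count, depth, e)
    return float(min(60.0, -10.0 * logp / math.log(10.0)))


def simulate_cross_and_bulk(
    truth: TruthSet,
    config: SimulationConfig,
    pop_id: str,
    seed: int | np.random.Generator | None = None,
) -> BulkPool:
    """Backcross, self, select a homozygous-mutant bulk, and emit pooled counts.

    The causal allele is recessive and retained through every backcross; an
    unlinked background heterozygous variant survives each backcross with
    probability 1/2, a linked one with probability (1 - r) per generation
    (coupling phase, r from the Haldane map). In the selected bulk the causal
    site is homozygous alt in every plant, a linked survivor contributes
    Binomial(2, 1-r) alt copies per plant, and an unlinked survivor segregates
    1:2:1 (Binomial(2, 1/2)). Per site: depth ~ Poisson(mean_depth),
    alt reads ~ Binomial(depth, f(1-e) + (1-f)e) with f the pooled alt
    frequency and e the base error rate.
    """
    if seed is None:
        seed = np.random.default_rng(
            np.random.SeedSequence([config.seed, 0xB1C, config.pop_ids().index(pop_id)])
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    causal = truth.causal_variant_per_population[pop_id]
    background = truth.background_variants[pop_id]

    survivors: list[GermlineVariant] = []
    surv_r: list[float] = []  # recombination fraction to the causal site (0.5 if unlinked)
    for v in background:
        if v.chrom == causal.chrom:
            r = recombination_fraction(v.pos - causal.pos, config.recomb_rate)
            p_keep = (1.0 - r) ** config.bc_generations
        else:
            r = 0.5
            p_keep = 0.5 ** config.bc_generations
        if rng.random() < p_keep:
            survivors.append(v)
            surv_r.append(r)

    # F2 from the selfed BC_nF1: genotype at the causal locus segregates 1:2:1
    f2 = rng.binomial(2, 0.5, size=config.f2_size)
    counts = (int(np.sum(f2 == 0)), int(np.sum(f2 == 1)), int(np.sum(f2 == 2)))
    if counts[2] < config.bulk_size:
        warnings.warn(
            f"{pop_id}: only {counts[2]} of {config.f2_size} simulated F2 plants are "
            f"homozygous mutant; resampling to reach bulk_size={config.bulk_size}",
            stacklevel=2,
        )

    variants = [causal, *survivors]
    rs = [0.0, *surv_r]
    n_var = len(variants)
    plant_alt = np.empty((n_var, config.bulk_size), dtype=np.int64)
    plant_alt[0, :] = 2  # selection: every bulk plant homozygous for the causal allele
    for i, r in enumerate(rs[1:], start=1):
        # alt allele co-transmits with the selected causal allele w.p. (1 - r)
        plant_alt[i, :] = rng.binomial(2, 1.0 - r, size=config.bulk_size)

    pooled_f = plant_alt.sum(axis=1) / (2.0 * config.bulk_size)
    e = config.base_error_rate
    p_alt_read = pooled_f * (1.0 - e) + (1.0 - pooled_f) * e
    depth = rng.poisson(config.mean_depth, size=n_var)
    alt_reads = rng.binomial(depth, p_alt_read)
    ref_reads = depth - alt_reads

    records: list[VariantRecord] = []
    for i, v in enumerate(variants):
        records.append(
            VariantRecord(
                chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                ref_count=int(ref_reads[i]), alt_count=int(alt_reads[i]),
                qual=site_quality(int(alt_reads[i]), int(depth[i]), e),
                genotype=call_pool_genotype(int(ref_reads[i]), int(alt_reads[i])),
                pop_id=pop_id,
            )
        )
    order = sorted(range(n_var), key=lambda i: (variants[i].chrom, variants[i].pos))
    return BulkPool(
        pop_id=pop_id,
        bulk_size=config.bulk_size,
        records=[records[i] for i in order],
        truth={(variants[i].chrom, variants[i].pos): variants[i] for i in order},
        plant_alt_copies=plant_alt[order, :],
        f2_causal_genotype_counts=counts,
    )


def simulate_study(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel], TruthSet, list[BulkPool]]:
    """Full study: reference, truth, and one selected bulk per population."""
    genome, genes = simulate_reference(config)
    truth = build_truth(genome, genes, config)
    pools = [
        simulate_cross_and_bulk(truth, config, pop) for pop in config.pop_ids()
    ]
    return genome, genes, truth, pools


# ---------------------------------------------------------------------------
# Truth TSV
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ["pop_id", "chrom", "pos", "ref", "alt", "origin", "linked_gene"]


def write_truth(truth: TruthSet, path: str | Path, *, seed: int) -> None:
    lines = [
        f"# mutmapkit truth file; seed={seed}",
        f"# causal_gene={truth.causal_gene}",
        "\t".join(TRUTH_COLUMNS),
    ]
    for pop in sorted(truth.causal_variant_per_population):
        rows = [truth.causal_variant_per_population[pop]] + sorted(
            truth.background_variants.get(pop, []), key=lambda v: (v.chrom, v.pos)
        )
        for v in rows:
            lines.append(
                "\t".join(
                    [pop, v.chrom, str(v.pos), v.ref, v.alt, v.origin,
                     v.linked_gene or "."]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth(path: str | Path) -> TruthSet:
    causal_gene = ""
    causal: dict[str, GermlineVariant] = {}
    backgrounds: dict[str, list[GermlineVariant]] = {}
    header: list[str] | None = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            if line.startswith("# causal_gene="):
                causal_gene = line.split("=", 1)[1].strip()
            continue
        if header is None:
            header = line.split("\t")
            if header != TRUTH_COLUMNS:
                raise ValueError(f"unexpected truth header: {header}")
            continue
        pop, chrom, pos, ref, alt, origin, linked = line.split("\t")
        v = GermlineVariant(
            chrom=chrom, pos=int(pos), ref=ref, alt=alt, origin=origin,
            linked_gene=None if linked == "." else linked,
        )
        if origin == "causal":
            causal[pop] = v
        else:
            backgrounds.setdefault(pop, []).append(v)
    return TruthSet(
        causal_gene=causal_gene,
        causal_variant_per_population=causal,
        background_variants=backgrounds,
    )


def write_study(
    genome: dict[str, str],
    genes: Sequence[GeneModel],
    truth: TruthSet,
    pools: Sequence[BulkPool],
    outdir: str | Path,
    *,
    seed: int,
) -> dict[str, Path]:
    """Serialize a simulated study as FASTA + GFF3 + per-pool VCF + truth TSV."""
    from .filtering import write_vcf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["fasta"] = outdir / "genome.fa"
    write_fasta(genome, paths["fasta"])
    paths["gff3"] = outdir / "genes.gff3"
    write_gff3(genes, paths["gff3"])
    paths["truth"] = outdir / "truth.tsv"
    write_truth(truth, paths["truth"], seed=seed)
    contigs = {name: len(seq) for name, seq in genome.items()}
    for pool in pools:
        p = outdir / f"{pool.pop_id}.vcf"
        write_vcf(pool.records, p, sample=pool.pop_id, contigs=contigs)
        paths[pool.pop_id] = p
    return paths
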