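"""End-to-end orchestration: simulate -> filter -> annotate -> intersect -> evaluate.

A run is driven by a :class:`RunConfig` (inputs either a simulation config or
paths to an existing FASTA/GFF3/VCF set), is deterministic given its seed, and
leaves every intermediate artifact plus a manifest (versions, seed,
parameters) in the output directory, so a run is reconstructible from the
manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import scipy
import yaml

from . import __version__
from . import candidates as cand
from . import consequence as csq
from .filtering import FilterParams, VariantRecord, filter_candidate_variants, \
    filter_summary, read_vcf, write_vcf
from .genes import GeneModel, read_fasta, read_gff3
from .simulate import SimulationConfig, read_truth, simulate_study, write_study

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage name and context."""


@dataclass(frozen=True)
class RunConfig:
    outdir: str
    seed: int = 0
    simulation: SimulationConfig | None = None
    fasta: str | None = None
    gff3: str | None = None
    vcfs: dict[str, str] = field(default_factory=dict)  # pop id -> path
    truth: str | None = None
    filter_params: FilterParams = field(default_factory=FilterParams)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.simulation is None:
            if not (self.fasta and self.gff3 and self.vcfs):
                raise ValueError("need either a simulation config or fasta+gff3+vcfs")
            for label, p in [("fasta", self.fasta), ("gff3", self.gff3),
                             *[(f"vcf[{k}]", v) for k, v in self.vcfs.items()]]:
                if not Path(p).exists():
                    raise FileNotFoundError(f"{label} input does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "simulation" in raw and isinstance(raw["simulation"], dict):
            raw["simulation"] = SimulationConfig(**raw["simulation"])
        if "filter_params" in raw and isinstance(raw["filter_params"], dict):
            fp = dict(raw["filter_params"])
            if "het_band" in fp:
                fp["het_band"] = tuple(fp["het_band"])
            raw["filter_params"] = FilterParams(**fp)
        return cls(**raw)


def consequence_table(
    annotated: Sequence[tuple[VariantRecord, csq.Consequence]]
) -> pd.DataFrame:
    rows = [
        {
            "pop_id": r.pop_id, "chrom": r.chrom, "pos": r.pos, "ref": r.ref,
            "alt": r.alt, "gene_id": c.gene_id or ".", "kind": c.kind.value,
            "protein_change": c.protein_change or ".",
            "cds_pos": c.cds_pos if c.cds_pos is not None else ".",
        }
        for r, c in annotated
    ]
    return pd.DataFrame(
        rows,
        columns=["pop_id", "chrom", "pos", "ref", "alt", "gene_id", "kind",
                 "protein_change", "cds_pos"],
    )


def write_annotated_vcf(
    annotated: Sequence[tuple[VariantRecord, csq.Consequence]],
    path: str | Path,
    *,
    sample: str,
    contigs: dict[str, int],
) -> None:
    """VCF with INFO key ``CSQ=kind|protein_change|gene_id``."""
    from .filtering import _GT_CODES, _vcf_header  # shared header layout

    header = _vcf_header(sample, contigs)
    header.add_line(
        '##INFO=<ID=CSQ,Number=1,Type=String,Description='
        '"Consequence: kind|protein_change|gene_id">'
    )
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r, c in sorted(annotated, key=lambda t: (t[0].chrom, t[0].pos)):
            rec = vcf.new_record(
                contig=r.chrom, start=r.pos - 1, stop=r.pos,
                alleles=(r.ref, r.alt), qual=round(r.qual, 2),
            )
            rec.info["DP"] = r.depth
            rec.info["CSQ"] = f"{c.kind.value}|{c.protein_change or '.'}|{c.gene_id or '.'}"
            rec.samples[sample]["GT"] = _GT_CODES[r.genotype]
            rec.samples[sample]["AD"] = (r.ref_count, r.alt_count)
            rec.samples[sample]["DP"] = r.depth
            vcf.write(rec)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-labelled with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_end_to_end(config: RunConfig) -> dict:
    """Run the full pipeline; returns the evaluation/summary dict.

    When driven by a simulation config, artifacts are written to disk and read
    back through the package's own FASTA/GFF3/VCF readers, so every run also
    exercises the file round trip.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    truth = None
    if config.simulation is not None:
        sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
        genome_mem, genes_mem, truth, pools = _stage("simulate")(simulate_study)(sim_cfg)
        sim_dir = outdir / "sim"
        paths = _stage("simulate")(write_study)(
            genome_mem, genes_mem, truth, pools, sim_dir, seed=config.seed
        )
        fasta, gff3 = paths["fasta"], paths["gff3"]
        vcfs = {p.pop_id: paths[p.pop_id] for p in pools}
    else:
        fasta, gff3 = Path(config.fasta), Path(config.gff3)
        vcfs = {k: Path(v) for k, v in config.vcfs.items()}
        if config.truth:
            truth = _stage("load-truth")(read_truth)(config.truth)

    genome = _stage("load-reference")(read_fasta)(fasta)
    genes = _stage("load-reference")(read_gff3)(gff3)
    contigs = {name: len(seq) for name, seq in genome.items()}

    filtered: dict[str, list[VariantRecord]] = {}
    annotated_all: list[tuple[VariantRecord, csq.Consequence]] = []
    for pop in sorted(vcfs):
        records = _stage("load-vcf")(read_vcf)(vcfs[pop], pop_id=pop)
        kept = _stage("filter")(filter_candidate_variants)(records, config.filter_params)
        filtered[pop] = kept
        filter_summary(records, config.filter_params).to_csv(
            outdir / f"{pop}.filter_summary.tsv", sep="\t", index=False
        )
        write_vcf(kept, outdir / f"{pop}.filtered.vcf", sample=pop, contigs=contigs)
        ann = [
            (r, _stage("annotate")(csq.annotate_against_genes)(r, genes, genome))
            for r in kept
        ]
        annotated_all.extend(ann)
        write_annotated_vcf(
            ann, outdir / f"{pop}.annotated.vcf", sample=pop, contigs=contigs
        )

    consequence_table(annotated_all).to_csv(
        outdir / "consequences.tsv", sep="\t", index=False
    )

    report = _stage("map-candidates")(cand.build_candidate_report)(
        filtered, genes, genome
    )
    cand.write_report(report, outdir)

    summary: dict = {
        "seed": config.seed,
        "populations": sorted(vcfs),
        "intersection": list(report.intersection),
        "per_population_candidates": {
            pop: sorted(genes_) for pop, genes_ in sorted(report.per_population.items())
        },
    }
    if truth is not None:
        summary["evaluation"] = _stage("evaluate")(cand.evaluate_report)(report, truth)

    manifest = {
        "tool": "mutmapkit",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pysam": pysam.__version__,
        "seed": config.seed,
        "filter_params": dataclasses.asdict(config.filter_params),
        "simulation": dataclasses.asdict(config.simulation) if config.simulation else None,
        "inputs": {"fasta": str(fasta), "gff3": str(gff3),
                   "vcfs": {k: str(v) for k, v in vcfs.items()}},
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
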