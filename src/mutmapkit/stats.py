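"""Downstream validation statistics.

Two families of checks used to confirm a mapped candidate gene:

* co-segregation of a recessive allele with the mutant phenotype in an F2
  genotyping panel, with a Pearson chi-square goodness-of-fit against the
  Mendelian 1:2:1 expectation, and
* qPCR relative quantification under the Livak assumption of a perfect
  doubling per cycle: a between-gene fold change ``2^(Ct_b - Ct_a)`` and the
  classic ddCt fold change ``2^-ddCt`` against a reference gene and a control
  sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

GENOTYPE_CODES = ("AA", "GA", "GG")  # hom mutant, het, hom wild type
PHENOTYPE_CODES = ("msd", "WT")


def chi_square_ratio(
    observed: Sequence[float], expected_ratio: Sequence[float]
) -> tuple[float, int, float]:
    """Pearson chi-square of observed counts against a ratio, no continuity correction.

    Returns (chi2, df, p) with df = number of classes - 1.
    """
    obs = np.asarray(observed, dtype=float)
    weights = np.asarray(expected_ratio, dtype=float)
    if obs.size < 2 or obs.size != weights.size:
        raise ValueError("need >= 2 classes and matching ratio weights")
    if obs.sum() < 1:
        raise ValueError("total observed count must be >= 1")
    if np.any(weights <= 0):
        raise ValueError("expected ratio weights must be positive")
    expected = obs.sum() * weights / weights.sum()
    chi2, p = sps.chisquare(obs, f_exp=expected)
    return float(chi2), obs.size - 1, float(p)


@dataclass(frozen=True)
class CosegregationResult:
    n: int
    genotype_counts: dict[str, int]  # AA / GA / GG
    concordant_mutant_count: int
    discordant_count: int
    chi2_1_2_1: float
    df: int
    p: float
    cosegregates: bool


def cosegregation_test(table: pd.DataFrame) -> CosegregationResult:
    """Recessive-model co-segregation on a plant genotype/phenotype table.

    ``table`` needs columns ``genotype`` (AA het-coded GA / GG) and
    ``phenotype`` (msd / WT). Concordance under the recessive model requires
    phenotype == msd exactly for AA plants; the chi-square tests genotype
    counts against 1:2:1.
    """
    if table.empty:
        raise ValueError("genotype/phenotype table is empty")
    for col in ("genotype", "phenotype"):
        if col not in table.columns:
            raise ValueError(f"missing required column {col!r}")
        if table[col].isna().any():
            raise ValueError(f"column {col!r} has missing values")
    bad_g = set(table["genotype"]) - set(GENOTYPE_CODES)
    bad_p = set(table["phenotype"]) - set(PHENOTYPE_CODES)
    if bad_g or bad_p:
        raise ValueError(f"unknown codes: genotypes {bad_g or '{}'}, phenotypes {bad_p or '{}'}")

    counts = {g: int((table["genotype"] == g).sum()) for g in GENOTYPE_CODES}
    is_mut_geno = table["genotype"] == "AA"
    is_mut_pheno = table["phenotype"] == "msd"
    concordant_mutant = int((is_mut_geno & is_mut_pheno).sum())
    discordant = int((is_mut_geno != is_mut_pheno).sum())
    chi2, df, p = chi_square_ratio(
        [counts["AA"], counts["GA"], counts["GG"]], (1, 2, 1)
    )
    return CosegregationResult(
        n=len(table),
        genotype_counts=counts,
        concordant_mutant_count=concordant_mutant,
        discordant_count=discordant,
        chi2_1_2_1=chi2,
        df=df,
        p=p,
        cosegregates=(discordant == 0),
    )


def fold_change_between_genes(ct_gene_a: float, ct_gene_b: float) -> float:
    """Relative abundance of gene a over gene b from their Ct values: 2^(Ct_b - Ct_a).

    Assumes 100% amplification efficiency, so one cycle = one doubling; the
    lower-Ct gene is the more abundant one.
    """
    if ct_gene_a <= 0 or ct_gene_b <= 0:
        raise ValueError("Ct values must be positive")
    return float(2.0 ** (ct_gene_b - ct_gene_a))


def ddct_relative_expression(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Livak 2^-ddCt fold change of the target gene in sample vs control."""
    for ct in (ct_target_sample, ct_ref_sample, ct_target_control, ct_ref_control):
        if ct <= 0:
            raise ValueError("Ct values must be positive")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_control - ct_ref_control)
    return float(2.0 ** -ddct)


# ---------------------------------------------------------------------------
# Table IO
# ---------------------------------------------------------------------------

def read_genotype_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns plant_id, genotype, phenotype."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"plant_id", "genotype", "phenotype"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns sample, gene, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "gene", "replicate", "ct"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise ValueError(f"{path}: Ct values must be positive")
    return df


def mean_ct(ct_table: pd.DataFrame, sample: str, gene: str) -> float:
    sel = ct_table[(ct_table["sample"] == sample) & (ct_table["gene"] == gene)]
    if sel.empty:
        raise ValueError(f"no Ct rows for sample={sample!r}, gene={gene!r}")
    return float(sel["ct"].mean())


def ddct_table(
    ct_table: pd.DataFrame, *, ref_gene: str, control_sample: str
) -> pd.DataFrame:
    """Per sample x target gene 2^-ddCt folds relative to the control sample."""
    genes = [g for g in ct_table["gene"].unique() if g != ref_gene]
    samples = list(ct_table["sample"].unique())
    rows = []
    for gene in genes:
        tc = mean_ct(ct_table, control_sample, gene)
        rc = mean_ct(ct_table, control_sample, ref_gene)
        for sample in samples:
            fold = ddct_relative_expression(
                mean_ct(ct_table, sample, gene), mean_ct(ct_table, sample, ref_gene),
                tc, rc,
            )
            rows.append({"sample": sample, "gene": gene, "fold_vs_control": round(fold, 1)})
    return pd.DataFrame(rows)
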