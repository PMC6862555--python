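# Methods

## The genetic model behind the simulator

The synthetic-data module emulates the structure of a MutMap experiment on a
recessive EMS mutant, at the **variant level** — no reads, alignment, or
mapping error are simulated; what exists is the set of germline variants a
mutant line carries and, per variant, the pooled read counts a bulk would
produce.

**Mutagenesis.** EMS alkylates guanine, so induced mutations are modelled as
exclusively G→A / C→T transitions on the reference strand. Each G/C site
mutates independently with probability `ems_rate` (default 2×10⁻⁴ per G/C
site, ≈ 90 mutations on the default 1 Mb toy genome). This density is
deliberately higher than a real EMS line scaled to 1 Mb would carry: the
point of the toy genome is to stress the intersection logic with a rich
background, not to miniaturize a 730 Mb genome faithfully. Each population is
mutagenized independently.

**Backcrossing.** The causal allele is retained through every backcross
(phenotype/genotype selection is assumed perfect). A background heterozygous
variant survives one backcross with probability 1/2 if unlinked, and with
probability (1−r) per generation if on the causal chromosome, where r is the
Haldane recombination fraction r = (1−e^(−2d))/2 at map distance
d = `recomb_rate` × bp separation (default 2×10⁻⁸ Morgans/bp ≈ 2 cM/Mb,
a typical plant genome average). Default `bc_generations` = 3, so unlinked
background heterozygosity is purged to 1/8 in expectation. Whole-genome
gamete simulation is intentionally avoided: per-locus survival probabilities
reproduce the relevant marginal genetics at a fraction of the cost.

**F2 selection and the bulk.** The final backcross F1 is selfed; genotypes at
the causal locus segregate 1:2:1 in a finite F2 (`f2_population_size`,
default 8× the bulk). A bulk of `bulk_size` (default 20) homozygous-mutant
plants is selected; if the F2 holds fewer homozygotes than the bulk needs,
plants are resampled with a warning. Conditional on selection, a surviving
background variant contributes per plant Binomial(2, 1−r) alt alleles if
linked in coupling, Binomial(2, 1/2) if unlinked — so unlinked sites stay
1:2:1 in the bulk while tightly linked sites ride to homozygosity, which is
exactly the hitchhiking the multi-population intersection must defeat.

**Pooled sequencing.** Per site, depth ~ Poisson(`mean_depth`, default 20);
alt reads ~ Binomial(depth, f(1−e) + (1−f)e) with f the pooled alt-allele
frequency and e = `base_error_rate` (default 0.001, i.e. Q30-grade post-filter
base error typical of the sequencing platforms used for bulk-segregant
studies). Site quality is defined as
`qual = min(60, −10·log₁₀ P(alt_count | hom-ref))` under a
Binomial(depth, e) error model — a phred-scaled evidence score chosen so the
Q20 filter has something real to act on; variant callers use likelihood
ratios of the same flavor.

What the simulator does **not** emulate: mapping artefacts and repeat-induced
false calls, indels and multi-allelic sites, segregation distortion,
incomplete penetrance, and contamination between bulks. Passing tests
therefore demonstrate that the filtering/intersection logic is correct under
clean Mendelian genetics with realistic counting noise — not that it is
robust to alignment pathology, which is upstream of this package's scope.

## Candidate filter

A record passes iff it is an EMS-type transition, called homozygous-alt, with
depth in [3, 50] **inclusive** and quality **strictly** greater than 20 —
"from 3 to 50" reads most naturally as closed bounds, "greater than Q20" as
strict. The pooled genotype call is threshold-based: hom-alt at alt fraction
≥ 0.9, hom-ref at ≤ 0.1, het inside [0.25, 0.75], missing otherwise (zero
reads included). Multi-allelic VCF records and indels are skipped with a
logged count rather than split: the EMS model is biallelic-SNV-only.

## Consequence annotation

Single-isoform gene models (ordered exons, CDS ⊆ exons, CDS length divisible
by 3) are read from GFF3. Classification precedence: canonical splice window
first (2 bp at each intron end, strand-aware: donor at the transcription-side
start of the intron), then CDS translation via the standard nuclear code —
synonymous / missense / stop gained / stop lost, with start-lost taking
precedence over missense at codon 1 and stop-lost over missense at the
terminal codon. Protein notation is 1-letter code with `*` for stop
(`R2W`, `W3*`). "Deleterious" = protein-changing or splice-disrupting
(missense, stop gained/lost, start lost, splice donor/acceptor) — the
moderate/high-impact set of a standard effect predictor; synonymous,
UTR, and interior-intronic changes are not. Coordinates are 1-based inclusive
in all file interfaces and 0-based half-open internally, with round-trip
tested converters.

## Candidate intersection

Intersection happens at **gene** level, not position level: independent
allelic lines carry different base changes in the same gene, which is the
signal. If the intersection ever holds more than one gene, genes are ranked
by the number of pools carrying a clearly truncating (stop/splice) allele,
then gene id; with one planted causal gene and the default background density
the intersection is a single gene in practice (50/50 seeded replicates in the
benchmark). Allelism classes group pools by exact (chrom, pos, ref, alt), so
two lines sharing one identical allele — a configuration the simulator plants
by default — appear as one class.

## Validation statistics

The co-segregation test is a recessive-model concordance check (mutant
phenotype iff homozygous-mutant genotype; `cosegregates` = zero discordant
plants) plus a Pearson chi-square of genotype counts against 1:2:1, df = 2,
no continuity correction (three classes; Yates applies to 2×2 tables).
qPCR folds assume 100% amplification efficiency (Livak): between genes,
fold = 2^(Ct_b − Ct_a); between samples, fold = 2^−ΔΔCt with the reference
gene and control sample subtracted. Output tables round folds to one
decimal; the between-gene comparison is additionally reported at integer
rounding because whole-fold statements are how such numbers are quoted.

## Lipid decomposition

36-carbon diacyl species split their double bonds across two 18-carbon chains
as evenly as the {18:3, 18:2, 18:1, 18:0} inventory allows with ≤ 3 bonds per
chain: 36:6 → 18:3+18:3, 36:5 → 18:3+18:2, 36:4 → 18:2+18:2, 36:3 →
18:2+18:1 (never 18:3+18:0). 34-carbon species decompose as 16:0 + 18:D
because 16-carbon chains carry no double bonds in this system (16:3 is not
detectable in sorghum tissue). Single-chain 16/18-carbon (lyso) labels are
decomposed directly under the same cap. Anything else is flagged
undecomposable and excluded from ratios with a logged count. The 18:3/18:2
ratio is the molar-percent-weighted chain count quotient over **all**
decomposable species of a profile, including minor (< 1%) species — ratios
are totals even when plots only show major species. A profile that is meant
to be complete must sum to 100 ± 0.5 molar %; partial profiles can skip the
check. The demo profiles in `analysis/05_lipid_ratios.py` are synthetic
shapes, not measurements.

## Homology

Needleman–Wunsch with linear gap scores (match +1, mismatch −1, gap −2 by
default) and a fixed tie-break (diagonal, then up) so alignments are
deterministic. Percent identity = 100 × matches / alignment columns with
terminal-gap columns excluded — identity conventions differ between tools,
so this one is stated rather than assumed, and published identity values
computed under unknown conventions are treated as method-dependent.
Paralog classification assigns the reference label with maximal identity and
reports the margin over the runner-up; margins below 0.05 points are called
ambiguous. Protein-level comparison is the intended default use.

## Problem sizes and determinism

The default study is 4 populations on a 1 Mb, 100-gene, 2-chromosome toy
genome — large enough that each pool carries a realistic mix of linked and
unlinked background candidates, small enough that a full
simulate→filter→annotate→intersect run takes well under a second and the
50-replicate benchmark under half a minute. All randomness flows from one
integer seed through `numpy.random.SeedSequence` spawning (separate streams
for reference construction, per-population mutagenesis, and per-population
crossing), and seeded runs are bit-reproducible; the end-to-end pipeline
writes byte-identical reports for identical seeds.

## Known limitations

- One isoform per gene; no indel or extended splice-region consequences, no
  impact scores.
- The pooled genotype caller is threshold-based, not likelihood-based; at
  very low depth (3–5 reads) hom/het discrimination is weak, which is why the
  depth floor exists.
- Linked-survivor genetics assume coupling phase throughout backcrossing and
  perfect causal-allele retention each generation.
- The identity convention (terminal-gap-excluded, linear gaps) will not
  numerically match published identity matrices produced by other aligners.
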