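# Methods

This note records the models, conventions and numerical choices behind
`avigut`, and what the synthetic data does and does not establish.

## Study design and data model

The unit of analysis is a pooled sample: one pen × intestine segment × age
cell (three birds pooled before DNA extraction), giving 4 segments × 4 ages
× 3 pens = 48 samples. The pipeline's central object is an integer ASV ×
sample count table paired with a seven-rank taxonomy and per-sample design
factors. Count tables travel as TSV with taxa as rows; the transposed
orientation is accepted only behind an explicit flag because silent
transposition is a classic microbiome-pipeline bug. All identifiers are
opaque, case-sensitive strings.

Ages are 11/25/34/46 days (the sampling coincided with feed changes); both
the segment and age level sets are configurable on the metadata reader and
the community template.

## Species refinement

DADA2-style species assignment requires exact sequence matches, so many
ASVs carry a genus but no species. The refinement rule fills these in from
BLAST hits: hits below 95% identity or below 100% query coverage are
discarded (coverage compared after rounding to one decimal); the remainder
are ranked by identity, ties broken by bitscore then subject id; the best
hit's species is adopted iff its identity is ≥ 97% and exceeds the best
hit of a *different* species by more than 2 points. Three edge cases the
rule's verbal statement leaves open are resolved as follows:

- the runner-up is the best *different-species* hit, not the literal
  second alignment — two alignments to the same species should not block
  assignment (`gap_vs_second_alignment=True` restores the literal
  reading);
- a single passing hit at ≥ 97% identity is assigned (nothing contests it);
- two species tied at the best identity give a gap of 0 and block
  assignment.

Query coverage comes from a qcovs-style 13th column when the hit file has
one, else it is computed as alignment length / query length × 100 with
query lengths taken from the ASV FASTA. Species text is resolved from a
`subject_id` convention (`accession|Genus_species`) or an explicit
subject → species mapping, since tabular BLAST output itself carries no
species column.

## Abundance

Counts are aggregated to a rank by summing ASV rows; ASVs lacking the rank
go to an explicit `Unclassified` row so column totals are conserved
exactly and aggregation commutes with closure (normalization). Relative
abundances divide each sample column by its total; a zero-total sample is
an error, never a silent NaN. `top_k_with_others` pools everything outside
the k most abundant taxa (by overall mean) into `Others`, keeping columns
on the simplex; k is a free display parameter.

## Alpha diversity

Shannon uses the natural log by default (base 2 behind a flag — the
upstream tools this mirrors do not state their base). Chao1 defaults to
the bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)), which is defined even
without doubletons; the classic form is available and errors when F₂ = 0.
Chao1 refuses non-integer input: it is undefined on relative abundances.

Rarefaction is an exact multivariate-hypergeometric draw (sampling without
replacement), so the subsampled total equals the requested depth exactly
and per-taxon means are depth·nᵢ/n. The default depth is 37,761 reads with
1,000 iterations; per-sample random substreams are derived from the master
seed and a CRC32 of the sample id, so results are independent of sample
order and of which other samples are present. Samples below the depth
abort with a listing by default (`on_shallow="drop"` excludes them
instead).

Group contrasts use the paired two-sided t-test or Wilcoxon signed-rank
(scipy). Identical paired vectors give (0, 1) for the t-test by
convention; constant non-zero differences (sd = 0) and all-zero Wilcoxon
differences raise errors rather than returning NaN.

## Beta diversity

Bray–Curtis is computed over sample columns via scipy's pdist. PCoA is
classical scaling: Gower double-centering of −d²/2, symmetric
eigendecomposition, coordinates scaled by √λ. Negative eigenvalues (normal
for non-Euclidean dissimilarities like Bray–Curtis) are reported but their
axes dropped; no Lingoes/Cailliez correction is applied — a documented
limitation.

PERMANOVA is one-factor: SS_total = Σ_{i<j} d²ᵢⱼ/n, SS_within summed over
within-group pairs (each divided by group size), pseudo-F =
(SS_between/(a−1))/(SS_within/(n−a)), R² = SS_between/SS_total. The
permutation p-value counts the observed labeling (+1 convention). When the
number of distinct relabelings (multinomial coefficient) is no larger than
the requested permutation count, the null distribution is enumerated
exhaustively and the p-value is exact. F-comparisons in the permutation
count use a 1e-12 slack so the identity permutation is never lost to float
round-off. The default 999 permutations is a package convention.

## Core microbiota

The rare-taxon threshold is 5 × the minimum non-zero relative abundance
taken **globally** over the whole matrix (not per group or per sample,
which the defining phrase supports). "Above the threshold" is strict and
the 50%-of-a-group quota is inclusive at exact halves; both are exposed as
flags. Cores (taxa present in every sample of a group) are computed on the
filtered taxon set. The Venn partition assigns each taxon in the union of
2–4 cores to exactly one of the 2^k − 1 regions; region sizes therefore
always sum to the size of the union.

## Variable network

Each of the 8 design variables gets an unweighted arithmetic mean of its
samples' compositions (the design is balanced, so weighting is moot; a
16-cell segment × age mode exists behind a flag). Pairs with Bray–Curtis
strictly below the cutoff (default 0.6) are connected; edges carry the
dissimilarity as an attribute but are topologically unweighted. Node
coordinates are fixed by the first two PCoA axes of the variable
dissimilarity matrix — no force-directed layout.

## qPCR

The standard curve is OLS of Ct on log₁₀ copies over ≥ 3 distinct dilution
levels; efficiency is 10^(−1/slope) − 1 (slope −3.3219 ⇔ 100%), dynamic
range is the log₁₀ span of the dilution series. Technical duplicates are
averaged on the Ct scale (standard qPCR practice). Unknowns are
interpolated as 10^((Ct − intercept)/slope); Ct values outside the curve's
span are flagged, not dropped, as are values above an optional
negative-control Ct floor. Copies per ng of input DNA divide by a
configurable input mass.

## Synthetic-data generator

Counts are Dirichlet-multinomial: per sample, a composition is drawn from
Dirichlet(θ · m) over the non-zero support of the cell mean m (θ = 75 by
default — visible pen-to-pen scatter without swamping the design signal)
and counts are multinomial at a log-normal library size (median ≈ 6 × 10⁴,
σ = 0.25, floored at 45,000 so the default rarefaction depth of 37,761 is
always reachable).

The default template encodes the system's known biology as generator
defaults, not as claims to reproduce: Lactobacillus-dominated proximal
segments rising with age (duodenum → ~0.97 by day 46), an early
Enterococcus bloom vanishing after day 11, Escherichia/Shigella expanding
in the ileum to ~0.40, and a caecum anchored by Lachnoclostridium (~0.20)
with Bacteroides, Alistipes and Faecalibacterium varying by age over a
pool of 38 genera — of which only the caecum uses all, making caecal
richness a structural property of the template. Each genus contributes two
ASVs with a fixed within-genus Dirichlet split; a configurable fraction
(default 0.3) of ASVs lacks a species, feeding the refinement stage.

`segment_effect` and `age_effect` scale between-cell differences on the
log scale: cell mean = global mean + segment_effect · (segment deviation)
+ age_effect · (within-segment age deviation), renormalized. At (0, 0)
every cell shares one mean (a pure null model); at (1, 1) — the default —
the template is reproduced exactly; larger values exaggerate the
structure.

The BLAST-hit generator constructs, for every genus-only ASV, a hit set
that lands in a prescribed branch of the refinement rule (assignable /
ambiguous gap / sub-97 best / coverage-filtered) and records the intended
label, so rule behavior is testable against known ground truth. The qPCR
generator draws Ct = intercept + slope·log₁₀(copies) + N(0, sd) over a
7-log dilution series (default slope −3.4, intercept 38, sd 0.2, 2
replicates per level) and hides true copy numbers with the unknowns.

**What the synthetic data does not show.** The generator emulates
compositional structure, overdispersion and library-size variation; it
does not emulate sequencing error, chimeras, contamination, copy-number
variation of the 16S gene, phylogenetic correlation between taxa, or pen
effects beyond sampling noise. Passing tests therefore establish that the
statistics are computed correctly and that design-level signals of the
modeled kind are recovered — not that any particular real dataset would
yield particular values.

## Problem sizes and runtime choices

The test and acceptance workloads are sized for a single CPU: the
PERMANOVA calibration check uses 500 null datasets of 12 samples × 10 taxa
with 199 permutations; replicate-rate checks use 20 datasets at the full
48-sample design; the caecum-vs-duodenum Shannon contrast in replicate
runs uses 100 rarefaction iterations (the per-sample mean it compares
stabilizes well before that; the library default remains 1,000). The
qPCR slope-recovery simulation checks the estimate against the exact
sampling standard error of the OLS slope under the generating model
(σ/√Sxx), for which the standardized deviation is exactly standard normal.

## Known limitations

- PERMANOVA is one-factor only; no stratified or multi-factor designs,
  and no interaction tests.
- No phylogeny-aware metrics (UniFrac, Faith PD) — there is no tree.
- Negative PCoA eigenvalues are reported but uncorrected.
- The core definition is presence-based; no abundance-weighted variant.
- BIOM/HDF5, FASTQ and any read-level processing are out of scope: the
  pipeline starts from an ASV table.
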