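# avigut

Downstream analysis of 16S rRNA amplicon-sequence-variant (ASV) data from
the broiler-chicken intestinal tract, built around a 4 × 4 factorial
design: four gut segments (duodenum, jejunum, ileum, caecum) sampled at
four ages (11, 25, 34, 46 days) in three pens, i.e. 48 pooled samples.

It is aimed at microbiome researchers who have an ASV count table,
taxonomy and BLAST hits in hand (e.g. from a DADA2 + SILVA workflow) and
want the downstream statistics as a tested, scriptable library rather than
a pile of one-off R snippets. A synthetic-data generator emulates the full
design, so every stage runs and is testable without any sequencing data.

## What it computes

- **Species refinement.** ASVs with a genus but no species are assigned a
  species from BLAST hits when, among hits with identity ≥ 95% and query
  coverage = 100%, the best hit has identity ≥ 97% and beats the best hit
  of any *other* species by more than 2 identity points.
- **Alpha diversity.** Shannon entropy H = −Σ pᵢ ln pᵢ and the Chao1
  richness estimate S_obs + F₁(F₁−1)/(2(F₂+1)) (bias-corrected; classic
  F₁²/2F₂ behind a flag), averaged over repeated rarefaction — exact
  multivariate-hypergeometric subsampling without replacement to a common
  depth (default 37,761 reads, 1,000 iterations).
- **Beta diversity.** Bray–Curtis dissimilarity d(x,y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ),
  principal-coordinate analysis (Gower double-centering + eigendecomposition),
  and one-factor PERMANOVA (ADONIS): pseudo-F from the between/within
  partition of squared dissimilarities, permutation p-value with the
  standard +1 convention, exhaustive enumeration when feasible.
- **Core microbiota.** Adaptive rare-taxon filter (threshold = 5 × the
  smallest non-zero relative abundance, retained if above threshold in
  ≥ 50% of the samples of at least one group), per-group cores (taxa
  present in every sample of the group), and the Venn partition of the
  cores.
- **Dissimilarity network.** The 8 design variables (4 segments + 4 ages)
  as nodes with mean composition profiles; edges where Bray–Curtis < 0.6;
  node positions from PCoA of the 8 × 8 variable dissimilarity matrix.
- **qPCR quantification.** Standard curve Ct = a + b·log₁₀(copies) by OLS,
  amplification efficiency 10^(−1/b) − 1, r², dynamic range, and absolute
  16S copy numbers for unknowns by interpolation.

## Worked example

```python
from avigut import *

counts, taxonomy, meta = generate_dataset(default_template(), GeneratorConfig(seed=7))
genus = aggregate_by_rank(counts, taxonomy, "genus")
rel = to_relative(genus)

dm = bray_curtis(rel)
res = permanova(dm, meta.groups(["segment"]), n_permutations=999, seed=7)
print(f"PERMANOVA by segment: F = {res.pseudo_f:.2f}, R2 = {res.r_squared:.3f}, p = {res.p_value:.4f}")

alpha = rarefied_alpha(genus, depth=37761, iterations=100, seed=7)
seg = alpha.table.join(meta.df).groupby("segment")["shannon_mean"].mean()
print("mean rarefied Shannon:", ", ".join(f"{s} {v:.2f}" for s, v in seg.items()))

net = build_network(variable_profiles(rel, meta), cutoff=0.6)
print(f"network: {net.graph.number_of_edges()} edges; caecum-duodenum edge: "
      f"{net.graph.has_edge('caecum', 'duodenum')}")
```

prints

```
PERMANOVA by segment: F = 20.44, R2 = 0.582, p = 0.0010
mean rarefied Shannon: caecum 2.86, duodenum 0.62, ileum 1.65, jejunum 0.95
network: 25 edges; caecum-duodenum edge: False
```

The intestine segment explains ~58% of the compositional variance (far
more than age on the same data), the caecum carries the highest rarefied
diversity of the four segments, and in the variable network the caecum
node is not connected to the proximal duodenum/jejunum cluster at the 0.6
cutoff — the qualitative structure the generator's default template
encodes.

The same stages are available from the shell:

```sh
avigut simulate --seed 7 --out sim/
avigut beta --counts sim/counts.tsv --metadata sim/metadata.csv --factor segment
avigut run --seed 7 --out full_run/     # the whole pipeline at once
```

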