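# pancestor

Comparative pan-genome analysis of bacterial genomes on a phylogeny:
core/relaxed-core ortholog sets, phenotype- and clade-exclusive gene
signatures, in-paralog profiles, genome-composition bias testing, parsimony
reconstruction of ancestral gene content and genome size, and
phylogenetically independent contrasts with clade rate tests.

The package is aimed at microbial comparative genomicists who have (i) an
ortholog clustering of many genomes (OrthoMCL-style groups file), (ii) a
genome metadata table (assembly status, nucleotide partition into coding /
non-coding / pseudogene regions, phenotype flags, clade labels), (iii) a
rooted phylogeny with branch lengths, and optionally a pseudogene list and
per-gene COG best hits — and who want to ask questions such as: which
ortholog groups form the core of the collection? Which groups track a
phenotype like heterocyst differentiation or plant symbiosis? How many genes
did the most recent common ancestor (MRCA) carry, and how large was its
genome? Do genome sizes evolve faster in one clade than another?

## Methods at a glance

* **Core sets.** The strict core contains groups present in every genome.
  Relaxed cores (RCF, RCF1–RCF3) treat draft genomes as wildcards and allow
  absence from up to *k* = 0…3 finished genomes. Presence can be counted
  with or without pseudogene copies; pseudogene-only members are annotated
  as functional losses rather than silently dropped.
* **Signatures.** A phenotype signature is the set of groups with gene
  copies in every (finished) flag-positive genome and zero functional copies
  in every flag-negative genome; clade signatures are the analogous
  contrast between the two major clades.
* **Ancestral reconstruction.** Discrete characters (presence/absence,
  phenotypes) by Fitch parsimony with exact most-parsimonious state sets at
  every node; gene copy numbers by Sankoff parsimony with linear cost
  |i − j|; continuous characters (genome size, gene counts) by
  squared-change parsimony, minimising Σ (x_parent − x_child)²/w_e, solved
  exactly as a linear system. Summing per-group root sets gives the MRCA
  gene-content interval [min, max]: groups surely present at the root count
  toward both bounds, ambiguous groups toward the maximum only.
* **Composition test.** A Pearson chi-squared statistic on the per-genome
  coding/non-coding nucleotide table with a Monte-Carlo p-value
  (multinomial resampling under independence, p = (1 + #{χ²* ≥ χ²})/(B+1))
  and per-genome Pearson residuals that call coding/non-coding bias.
* **Independent contrasts.** Felsenstein's PIC turns n tip values into
  n − 1 standardized contrasts that are iid N(0, σ²) under Brownian motion.
  Rates between the two clades are compared by a Wilcoxon rank-sum test on
  contrast magnitudes (exact by enumeration for small samples); trait
  co-evolution by correlation/regression through the origin of positivized
  contrast pairs, r = Σxy/√(Σx²Σy²).
* **Synthetic data.** A Yule tree whose root bipartition defines the two
  clades, gene families evolving by a two-state gain/loss chain with
  within-lineage duplication, genome metadata derived from gene content, a
  heavily pseudogenized target tip emulating an eroding obligate-symbiont
  genome, binary phenotypes on the tree, and noisy COG hits — all with
  recorded ground truth at every node.

## Worked example

```python
import pancestor as pc

cfg = pc.SimulationConfig(n_tips=12, n_families=300, seed=42)
ds = pc.simulate_dataset(cfg)

strict = pc.compute_core(ds.matrix, pc.CoreSpec.strict())
rcf1 = pc.compute_core(ds.matrix, pc.CoreSpec.relaxed(1))
print("strict core:", len(strict), " RCF1:", len(rcf1))

iv = pc.root_content_interval(ds.matrix, ds.tree)
print("MRCA gene content:", iv.min_genes, "-", iv.max_genes,
      "(true:", ds.truth.true_root_gene_count, ")")

sizes = {r.id: float(r.genome_size_bp) for r in ds.genomes}
clades = {r.id: r.clade for r in ds.genomes}
ct = pc.pic(ds.tree, sizes, clade_map=clades)
rate = pc.clade_rate_test(ct)
print("rate test: W=%.1f p=%.3f (%s)" % (rate.statistic, rate.p_value, rate.method))
```

prints

```
strict core: 27  RCF1: 41
MRCA gene content: 69 - 118 (true: 86 )
rate test: W=40.0 p=0.400 (exact)
```

Of the 180 ortholog groups observable at the tips, 27 are present in all 12
genomes; relaxing the definition to allow one missing finished genome (with
drafts as wildcards) grows the core to 41. Presence/absence parsimony bounds
the root ancestor's gene content at 69–118 groups, bracketing the true
simulated count of 86. The clade rate test finds no rate difference
(p = 0.4), as expected here since both clades evolved under the same
process.

The same stages are available from the shell via the `pancestor` console
script (`simulate`, `core`, `signature`, `paralogs`, `cogdist`,
`composition`, `ancestral`, `contrasts`, and `run` for the full pipeline
driven by a YAML config that writes per-stage TSVs plus a `report.json`).

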