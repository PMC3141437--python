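# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic-data tests do and do not demonstrate.

## Data model

The central object is the ortholog matrix: for every ortholog group and
genome, the number of *functional* and *pseudogene* gene copies. Pseudogene
status comes from a separate per-gene list (one id per line) rather than
inline markers in the groups file, because pseudogene calls are a per-gene
annotation produced independently of clustering; this also keeps the groups
file in the standard OrthoMCL dialect. Two presence conventions are used
everywhere presence is evaluated and are an explicit parameter:

* `any_copy` — a group is present if it has any copy, functional or
  pseudogenized. Default for core computations: a genome that still carries
  a (broken) copy has not lost the locus, and the loss of function is
  annotated per group instead.
* `functional_only` — only functional copies count. Default for the
  *negative* side of signature sets: a genome whose only copy is a
  pseudogene is counted as lacking the working gene.

Signature sets require `any_copy` presence in the positive genomes and zero
functional copies in the negatives, with pseudogene-only positives reported
alongside the set. The asymmetry is deliberate: a pseudogenized member in a
positive genome weakens, but does not formally break, the association
between group and phenotype, so it is kept and flagged; a functional copy in
a negative genome breaks it outright.

Genome records enforce the nucleotide partition exactly:
`coding + noncoding + pseudogene == genome_size`. Draft genomes are
wildcards for relaxed cores (absence from a draft is never evidence of
loss), while outgroup-labelled genomes participate in cores but are ignored
by clade signatures.

## Parsimony reconstruction

**Discrete characters.** Unit-cost (Fitch) parsimony is computed by a
down/up dynamic program over the tree. The down pass gives, for every node
and state, the minimal cost of the subtree; the up pass the minimal cost of
the rest of the tree; a state belongs to a node's MPR set iff the two sum to
the global minimum. This yields exact most-parsimonious state sets on
polytomies as well, where the classic one-pass Fitch top-down refinement is
only an approximation; on binary trees the total cost equals the number of
union operations in the classic bottom-up pass (verified by a property
test). A branch is flagged *equivocal* when either endpoint has an
ambiguous (multi-state) MPR set — the situation drawn as a bi-coloured
branch in trait-history figures.

**Copy numbers.** Sankoff parsimony with cost |i − j| over states
0…max(observed copy number). Restricting the alphabet to the observed
maximum loses nothing: with linear cost, any assignment using a state above
every tip value can be improved by moving it down to the largest tip value
on the relevant side, so such assignments are never optimal.

**Root content intervals.** Each group contributes a 0/1 (or copy-number)
character. `min_genes` counts groups whose root MPR set is exactly
{present}; groups with ambiguous root sets {absent, present} count toward
`max_genes` only. The min is therefore strict and the max generous — the
natural reading of a min–max gene-content range. For copy numbers the
bounds sum the smallest/largest root states across groups.

**Continuous characters.** Squared-change parsimony minimises
Σ_e (x_parent − x_child)² / w_e over internal-node values, with w_e = 1
(default) or the branch length (`weighted=True`). The objective is strictly
convex, so the stationary linear system has a unique solution; it is solved
exactly with a dense solver (trees of this scale have at most a few hundred
internal nodes). Unweighted is the default because reconstruction software
commonly defaults to ignoring branch lengths for squared-change
optimisation and the choice is not otherwise determined; both modes are
exposed and can be reported side by side. Weighted mode refuses zero-length
branches (the weight would be infinite) and names the offending branch.

## Composition test

The test statistic is Pearson's χ² on the 2 × G coding/non-coding table
(pseudogene nucleotides fold into the non-coding row by default, since
pseudogenes are no longer coding sequence; `separate` and `merge_coding`
modes exist). Several resampling schemes are defensible for a Monte-Carlo
chi-squared test on such a table; we use multinomial resampling
of the table total with cell probabilities from the independence expectation
— a parametric bootstrap of the null. Each replicate's statistic is
computed against *its own* margins, so the replicate statistics follow the
same null law as the observed one; the p-value uses the add-one convention
p = (1 + #{χ²* ≥ χ²})/(B + 1), making 1/(B+1) the smallest attainable value
(≈ 0.0005 at the conventional B = 2000). Per-genome bias calls use the
signed Pearson residual of the non-coding row with a ±2 threshold
(configurable). Nucleotide counts are huge, so on real-scale data the test
is essentially always significant; the interesting output is the residual
pattern. χ² scales linearly with the counts (doubling every cell doubles
the statistic), which is why a kbp counting unit is offered at the CLI.

## Independent contrasts

Standard Felsenstein pruning: contrast = difference of daughter working
values, sd = √(sum of corrected daughter branch lengths), working value =
precision-weighted daughter mean, and the node's branch is inflated by
v_a·v_b/(v_a+v_b). Polytomies and non-positive branch lengths are errors
(resolve or re-estimate the tree first). A contrast belongs to a clade iff
*every* descendant tip of its node carries that clade label; the basal
contrast between the clades and any contrast touching outgroup or
unassigned tips is excluded from the rate test — the natural generalisation
of excluding the single between-clade contrast.

The clade rate test is a two-sample Wilcoxon rank-sum on the magnitudes of
standardized contrasts. With both groups ≤ 12 the two-tailed p-value is
exact by full enumeration: the null distribution of the group-1 midrank sum
is built by dynamic programming over all C(n1+n2, n1) splits, which handles
ties exactly (and gives p = 1 for identical magnitude multisets, as
symmetry demands). Larger samples use the normal approximation with tie
correction and a 0.5 continuity correction.

Regression of one set of contrasts on another is through the origin — under
Brownian motion contrasts have mean zero, so no intercept exists — after
positivizing pairs (flip signs so x ≥ 0; the through-origin r is invariant
to pairwise sign flips). Significance uses t = r√((n−1)/(1−r²)) on n − 1
degrees of freedom: only the slope is estimated, so a single degree of
freedom is lost.

## Synthetic data generator

The generator emulates a ~58-genome comparative dataset:

* **Tree**: Yule with birth rate 1 per unit time, stopped at n tips plus
  one extra exponential waiting time (so pendant branches are positive).
  The two root subtrees define clade1 (the larger) and clade2.
* **Gene content**: each family evolves presence independently by a
  two-state chain with gain 0.03 and loss 0.06 per unit branch length from
  a Bernoulli(0.30) root. On a Yule tree of 58 tips (total length ≈ 57)
  this yields roughly two presence flips per family across the whole tree —
  the low-homoplasy regime parsimony assumes, and a strict core that is a
  small percentage of all families, as in real pan-genomes. Present
  lineages duplicate at rate 0.05 (each copy leaves a geometric number of
  descendants per branch; duplication is within-lineage only, i.e.
  in-paralogs). Families extinct at every tip leave no genes and are
  dropped from the emitted dataset; the recorded truth keeps them, so
  coverage statements are honest about unobservable families. 2000 families
  are generated by default — enough for stable set statistics while keeping
  a full pipeline run in seconds.
* **Genome metadata**: coding nucleotides = functional gene count × a
  per-genome gene length (lognormal around 1000 bp); non-coding nucleotides
  a per-tip lognormal fraction (mean 0.15) of genic nucleotides; the
  partition invariant holds exactly by construction. One target tip (by
  default the first clade1 tip, always marked finished) has each functional
  copy independently pseudogenized with probability 0.64 — an eroding
  obligate-symbiont genome whose paralogs are mostly pseudogenes and whose
  non-coding compartment is strongly biased. 39/58 of genomes are finished.
* **Phenotypes**: four binary flags evolve as independent gain/loss chains
  (rates 0.05/0.05, root probability 0.5); nesting is imposed afterwards
  (heterocystous ⊆ filamentous, plant_symbiont ⊆ heterocystous). Planted
  signature families whose presence exactly tracks a flag can be added to
  give downstream signature recovery a known answer.
* **COG hits**: each family draws a true category; per gene the emitted
  best hit is missing (failing e-value) with probability 0.2 and wrong with
  probability 0.1, exercising the majority-with-fallback assignment rule.

What the generator does *not* emulate: lateral transfer (gains are
independent re-gains, not transfers with donors), rate heterogeneity across
families (available as an option but off by default), sequence-level
divergence, assembly artefacts in drafts, and correlated evolution between
gene content and the continuous traits. Passing tests therefore show the
algorithms are correct under their own model assumptions, not that those
assumptions hold for any particular real dataset.

## Test and acceptance problem sizes

Oracle-equivalence checks run on hundreds of random instances small enough
for exhaustive enumeration (≤ 7 tips, ≤ 200 groups). Brownian-motion
calibration pools contrasts from 2000 replicates on a 16-tip tree; slope
recovery uses 500 replicates on 32 tips. The rate-test size check uses 1000
equal-rate replicates on 16 tips. For the 4:1 variance-ratio power check
the tree size is a design choice: the rank-sum AUC for |N(0,4)| vs |N(0,1)|
is (2/π)·arctan 2 ≈ 0.705, which by the normal approximation gives only
~75% power at 28 + 28 contrasts but > 95% at 63 + 63, so the power
replicates run on a 128-tip two-clade tree. Root-interval coverage uses
100 replicates of 500 families at the default rates on 58 tips.

## Known limitations

* Fitch on polytomies reports exact MPR sets, but the equivocality flag is
  a per-branch summary and does not enumerate full reconstructions.
* The copy-number interval treats groups independently; co-amplified
  families violate that.
* The composition test's multinomial null ignores spatial genome structure;
  it answers "are non-coding nucleotides distributed proportionally", not
  "why".
* Exact rank-sum enumeration is limited to 12 + 12 contrasts (the DP is
  quadratic in the doubled rank total); beyond that the corrected normal
  approximation is used automatically.
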