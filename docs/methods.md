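# Methods

`podovirome` re-implements, as one tested package, the computational chain
used to characterize a clade of marine cyanopodoviruses (T7-like phages of
*Prochlorococcus*/*Synechococcus*) and to quantify its abundance in ocean
viromes: ANI-based population delineation, reciprocal-best-hit (RBH)
pan/core-genome analysis, KPKG fragment recruitment, and the ecological
statistics layered on top. A synthetic data generator supplies
clade-structured genomes, proteomes and viromes with known ground truth, so
every stage can be validated without downloading reference data.

## Pairwise alignment and e-values

All alignment is affine-gap Smith–Waterman (Gotoh), compiled with numba.
Scoring defaults:

| scheme     | match/matrix | mismatch | gap open | gap extend | λ     | K     |
|------------|--------------|----------|----------|------------|-------|-------|
| nucleotide | +2           | −3       | 5        | 2          | 0.625 | 0.41  |
| protein    | BLOSUM62     | —        | 11       | 1          | 0.267 | 0.041 |

A gap of length L costs `open + L·extend`. Bitscores follow the
Karlin–Altschul convention, `S' = (λS − ln K)/ln 2`, and
`E = m·n·2^(−S')` with n the total residue count of the search space. The
λ/K values are the published gapped-scoring constants for these parameter
sets; they are calibration metadata, not fitted quantities. The e-value
cutoff used downstream (10⁻⁵) sits far from the decision boundary for reads
at the 95% identity floor, so moderate calibration error is inconsequential.

Percent identity uses the alignment length including gap columns as its
denominator (the convention of the 12-column tabular format), so internally
computed hits are interchangeable with ingested tabular hits. `N` (and `X`
in proteins, scored 0) never count as identities. When every local score is
non-positive, `local_align` returns `None` rather than a zero-length
alignment. Co-optimal alignments are resolved deterministically: the DP max
scan keeps the smallest (q_end, s_end) cell and the traceback prefers
substitution over gap-in-subject over gap-in-query.

Read mapping is seed-and-extend: exact k-mers (k = 11) from the read and its
reverse complement are looked up in a sorted-array index of the genome set;
seeds voting for the same (genome, strand, diagonal) nominate a window of
±30 bp around the read's projection, which is aligned with the full kernel.
One best hit per genome is reported. Recruitment requires at least 8 seeds
on a diagonal before extending: a 150 bp read at the 95% identity filter
floor still carries ~80 exact 11-mers, while cross-clade homology (≥10%
divergence) and random background rarely reach 8, which removes most
alignment work without affecting which reads pass the filters. The general
mapper default is 2 seeds; ANI fragments use 2 as well.

## ANI and population delineation

The published analysis used whole-genome-alignment ANI; this package
implements fragment ANI instead, because it is self-contained and, on
substitution-only synthetic data, agrees with the analytic identity to
within alignment edge effects (validated at |ANI − 100(1−d)| ≤ 0.5 for
d ≤ 0.1). Genomes are cut into consecutive 1020 bp windows (a terminal
window is kept if ≥ 510 bp); each fragment is mapped to the partner genome
and accepted when the alignment covers ≥ 70% of the fragment at ≥ 30%
identity — a conventional acceptance rule, flagged here because the
whole-genome mode it replaces has none. Directed ANI is the mean identity
over accepted fragments; the reported ANI is the arithmetic mean of the two
directions. Pairs with no accepted fragments get NaN, never 0: absence of
alignment is not identity zero. Because exact 11-mer seeding loses
sensitivity beyond roughly 35% divergence, ANI values are only meaningful
well above that, which is also the only regime the 95% population threshold
interrogates.

Populations are single-linkage connected components of the ANI ≥ 95% graph,
the conventional viral population definition. Output ordering is
deterministic (lexicographic by smallest member); the partition is invariant
to genome input order.

## Orthology and pan/core genomes

Protein families are built from all-vs-all local alignments: a pair is an
ortholog candidate iff the two genes are reciprocal best hits between their
genomes (bitscore ties broken lexicographically), both directed hits have
e-value ≤ 10⁻⁵, and both alignments cover ≥ 75% of the shorter gene.
Families are connected components of the RBH graph. The component rule is a
package decision: at most one representative per genome per family; when a
genome contributes several genes, the one with the highest summed pair
bitscore to the rest of the component stays and the others become
singletons. This is the simplest rule under which "core = family present in
every genome" is well defined.

The profile-HMM rescue of divergent orthologs in the original workflow is
replaced by a deliberately simplified, clearly isolated stand-in: each
multi-member family defines an ungapped position-specific scoring matrix
(center-star layout around the member with the most total matches, counts
with +1 pseudocounts, log-odds in bits against a uniform 1/20 background).
A singleton joins the best family if its best ungapped offset achieves a
mean per-position log-odds above τ = 1.0 bits, the family lacks a member
from its genome, and it joins at most one family. Random sequences exceed τ
less than 1% of the time at this threshold.

Pan = number of families with at least one member in the genome set;
core = families present in every genome. Accumulation curves recompute both
after each genome along 100 random orderings (the original publication does
not state a replicate count; 100 gives stable standard deviations at this
scale) and report per-step mean and sd. The curve endpoint equals the
full-set counts for every ordering by construction, which the tests assert.

## KPKG fragment recruitment

Filters follow the printed inequality directions: e-value strictly
< 10⁻⁵, percent identity ≥ 95 (inclusive, no direction printed), and
aligned fraction of the read strictly > 0.90. The coverage filter is read
as per-read alignment coverage, distinct from the per-genome breadth rule —
the two rules govern reads and genomes respectively. A multi-mapped read
goes to the genome with the highest bitscore; exact ties break to the
lexicographically smallest genome id for cross-platform determinism.

Per (sample, genome): recruited kb is the sum of aligned read lengths
(q_end − q_start + 1, not the full read length — the most literal reading of
"recruited nucleotides", insensitive to unaligned tails), and

    KPKG = recruited kb / (genome kb × dataset Gb).

Coverage breadth is the merged-interval union of assigned reads' subject
intervals over the genome length; breadth < 40% marks the genome absent and
forces KPKG = 0. A sample whose best clade-level KPKG (sum over member
genomes) is below 0.001 is omitted from downstream analyses. Clade
abundance within a sample is the clade KPKG share; per-layer summaries pool
KPKG across the layer's samples before normalizing (an average of
per-sample proportions is available behind a flag). Depth contrasts report
log₁₀(KPKG + 1) pairs per (site, clade) for sites sampled at both the
surface and DCM/Mix depth.

## Statistics

The Mantel statistic is the Pearson correlation (Spearman behind a flag)
over upper-triangle distances; the null jointly permutes rows and columns of
the second matrix and the one-sided (greater) p is
(1 + #{r_perm ≥ r_obs})/(n_perm + 1) with 999 permutations by default, or
exact enumeration over all n! orderings on request. The abundance distance
is Euclidean on log₁₀(KPKG+1) clade vectors and the environmental distance
Euclidean on z-scored variables — the source workflow names neither metric,
so both are explicit package choices exposed as parameters. Paired t-tests
(surface vs deep, by site) and the genome-size contrast (Welch by default,
pooled available; the published claim p < 0.001 holds under both) use the
classical t formulas; zero-variance differences raise a degenerate-input
error rather than returning t = 0. Per-variable Mantel results are reported
without multiple-testing correction, matching the source analysis; a
Benjamini–Hochberg helper is provided but off by default.

## Synthetic data generator

The generator defines the study conditions for every test and for the
acceptance analyses:

* **Genomes** — one uniform-random root; one ancestor per clade at
  substitution rate `to_root_divergence` (default 0.15); members at
  `within_clade_divergence` (default 0.02). Substitution-only (no indels),
  linear (no wraparound). Defaults give within-clade pairwise divergence
  ~4% and between-clade ~26%, matching the intra-population (0–5%) and
  inter-clade (10–60%) structure of the real isolate collection. The
  population-delineation demo uses 17 members at 0.008 plus one outlier at
  0.06 to the root, reproducing the tight-population-plus-~88%-outlier
  geometry of the published isolates.
* **Proteomes** — core families present in every genome, clade-specific
  families, Poisson-distributed strain-specific genes; family copies are
  mutated hierarchically (default 10% amino-acid divergence between clade
  copies, 2% within), keeping within-family divergence well inside RBH
  sensitivity (validated up to ~20%).
* **Viromes** — reads drawn per clade at stated proportions, uniform genome
  and position within clade, either strand, per-base substitution errors
  (default 1%); background reads are uniform random, which guarantees they
  fail the 95% identity filter and act as a clean negative control. The
  default sample is 50,000 × 150 bp with 5% background at clade proportions
  0.50/0.30/0.15.
* **Environment** — each variable is slope × (a clade's true abundance) +
  Gaussian noise; slope 0 gives a null variable with a known answer for
  Mantel calibration.

What the generator does **not** emulate — indels, GC skew, quality-score
error profiles, amplification bias, host-derived background, circular
genomes — bounds what passing tests show: they validate the statistical
machinery and rule implementations under the stated substitution-only
model, not robustness to real sequencing artifacts.

## Problem sizes and numerical choices

The acceptance analyses run at desk scale by choice: 12 synthetic genomes of
30 kb and 50,000 reads for parameter recovery; 18 genomes of 10 kb for the
population split; 9 genomes for pan/core recovery; 16 samples × 1500 reads
for the depth/environment survey. The published global-ocean percentages
(which require multi-terabyte viromes) and the accession-based 39-genome
counts are out of desk-scale reach; parameter-recovery properties on the
generator stand in for them. Degenerate inputs are contracts, not crashes:
undefined ANI is NaN, zero-recruitment samples carry NaN proportions,
constant distance matrices and zero-variance differences raise typed
errors. All randomness flows from explicit seeds through
`numpy.random.default_rng`; equal seeds give byte-identical outputs.

## Known limitations

* Fragment ANI deviates by construction from whole-genome-alignment ANI on
  real (indel-containing) genomes; on substitution-only data they agree.
* The PSSM rescue is ungapped and much weaker than a profile HMM for
  remote orthologs; it is isolated behind one function so it can be
  swapped.
* Exact k-mer seeding (k = 11) bounds mapper sensitivity at roughly 35%
  divergence; irrelevant at the 95% recruitment threshold but a caveat for
  other uses.
* The 12-column hit ingestion route cannot know true read lengths; absent
  the reads themselves, read length is taken as the largest aligned query
  coordinate, making the coverage filter permissive.
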