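# Methods

## Scope and model

The package treats a complete organellar genome (or a concatenated set of
clean fragments) as a species-identification marker and asks three
questions: which parts of a mitogenome are unusable for barcoding (plastid
transfers, repeats), how much species-diagnostic signal the usable parts
carry, and how organellar data sets compare (diversity, codon usage,
phylogeny). Everything operates on standard formats — FASTA/aligned FASTA,
GFF3, BED, Newick, TSV sample sheets — with one internal coordinate
convention: 0-based half-open everywhere, converted at the I/O boundary
(GFF3 1-based inclusive, BED 0-based half-open). Circular genomes are
linearized at position 0; features and hits crossing the origin are stored
split into two intervals sharing a name.

## Homology scanning

`homology.find_hits` is a classic seed-and-extend scanner:

* every exact shared k-mer (default `seed_len = 12`) between the query and
  either strand of the subject seeds an extension;
* seeds are extended ungapped along the diagonal with an X-drop rule
  (default drop 100) to the maximal-scoring segment; seeds landing on an
  already-extended diagonal are skipped;
* the candidate segment is refined by gapped affine local alignment
  (Smith–Waterman) on a padded window, implemented via Biopython's
  `PairwiseAligner` (C implementation); scoring defaults are blastn-like:
  match +2, mismatch −3, gap open 5, gap extend 2;
* hits below the raw-score threshold (default 100, used as ≥ 100) or above
  the e-value cutoff (default 10⁻⁵) are discarded; overlapping hits on the
  same diagonal collapse to the best-scoring one.

E-values use the Karlin–Altschul formula E = K·m·n·e^(−λS) with m, n the
genome lengths. λ is solved exactly for the scoring scheme from
Σᵢⱼ pᵢpⱼ e^(λsᵢⱼ) = 1 at uniform base composition; K is shipped for the
common schemes ((2,−3): 0.41; (1,−2): 0.46; (1,−1): 0.35) and must be
supplied for others. These are ungapped parameters applied to gapped
scores — the standard approximation — so the e-value cutoff should be read
as configurable rather than exact. A scheme with non-negative expected
pair score has no λ and is rejected.

Duplicate transfers are resolved by `dedupe_hits`: hits whose query *or*
subject intervals reciprocally overlap by ≥ 50% (configurable) are
clustered by transitive closure into region pairs with merged spans.
`classify_gene_content` marks an annotated gene "complete" when its full
interval lies inside a merged subject region and "fragment" on partial
overlap. `self_repeats` runs the scanner on a genome against itself,
drops the trivial self-diagonal, and returns the merged union of query and
subject intervals of qualifying hits (defaults: aligned length ≥ 100 bp,
identity ≥ 90%).

Hits with identity below 80% (configurable) are flagged `low_identity` in
reports but never removed automatically: similarity between analogous
genes (e.g. ribosomal RNAs of the two organelles) can qualify as a hit
without being evidence of transfer, and that judgement is editorial.

## Fragment selection

`select_fragments` takes the complement of the union of masks, drops
intervals shorter than `min_len` (default 1000 bp), and applies a
per-species presence criterion (default: present in ≥ 90% of species; a
species is present when one of its samples covers ≥ 50% of the fragment's
reference length with non-gap characters). Presence is deliberately a
soft criterion — a fragment missing in a couple of taxa can still be
worth keeping — so both thresholds are configurable. Surviving intervals
are numbered c1, c2, … in genome order.

## Molecular diagnostic characters

A column is an MDC for a query species iff (i) all query samples carry
the same unambiguous base, (ii) no reference sample's state is compatible
with that base, and (iii) no query sample has a gap or ambiguity there.
Reference-side compatibility is a pluggable policy:

* `conservative` (default): any reference gap, N, or ambiguity code whose
  expansion contains the query base disqualifies the column. This policy
  can only under-count.
* `strict_acgt`: non-ACGT reference characters are ignored.

`discrimination` scores each species against all samples of the other
species of its genus (`scope="genus"`, the default) or against the whole
panel. A species that is its genus's sole member cannot be evaluated
under genus scope; it is flagged and excluded from the efficiency
denominator, which is always reported. Efficiency = 100 × (species with
≥ 1 MDC)/(evaluable species). Subspecies are merged into their species in
the panel sheet; subspecies-level contrasts go through `compare_taxa`,
which returns the two asymmetric counts. Hybrid taxa receive no special
handling — a hybrid sharing a parental haplotype simply yields zero MDCs,
which is an outcome, not a rule.

## Diversity statistics

Gap/ambiguity handling is pairwise deletion throughout: a column enters a
pairwise comparison only when both rows carry an unambiguous base. π is
the mean over unordered pairs of differences/compared sites; for gap-free
alignments this equals the mean per-column pairwise heterozygosity, which
the tests exploit as an algebraic oracle. Window tracks slide on
alignment columns (π: 600 bp window, 100 bp step) or genome positions
(GC: 100 bp tiling); MDC density uses a non-overlapping 1000 bp tiling
whose trailing partial window is counted and flagged, so window counts
always sum to the total. Windows with no compared sites are NaN.
`divergent_block_scan` finds maximal positive-scoring runs of columns
where a focal sample differs from the column majority (scores
1−f/−f for a divergence fraction threshold f), the device used to flag
hypervariable inserts confined to one taxon.

## Codon usage

RSCU_c = r·n_c/Σ_family n with r the family degeneracy; families with zero
counts give NA, and Σ RSCU = r holds for every nonzero family (tested to
1e-12). Six-fold families (Leu, Ser, Arg) are kept whole by default — the
common RSCU convention — with an option to split them 2+4. Methionine and
tryptophan (r = 1) admit no within-family contrast and are excluded from
testing. The statistical procedure is two-level: per amino acid, a
Kruskal–Wallis test across the family's codons with rows (genomes or
genes) as replicates, mid-ranks and tie correction, α = 0.05; then Dunn's
z post hoc tests with Bonferroni correction over that family's
C(r,2) pairs. The organelle contrast applies the same rank test per codon
between mitochondrial and plastid rows, Bonferroni-corrected over all
tested codons, and reports the direction as the sign of the median
difference. All rank statistics are invariant under monotone transforms
of the values.

MILC for a gene of L codons is Σ_a M_a/L − C with
M_a = 2 Σ_c o_c ln(f_c/g_c) (observed counts o, observed within-family
frequencies f, expected within-family frequencies g) and the small-sample
correction C = (Σ_a (r_a − 1))/L − 0.5 over amino acids present in the
gene. Genes shorter than 80 sense codons are excluded (hard filter,
configurable). An expected model assigning zero mass to an observed codon
is a misspecification error, not a silent zero. Both organelles use the
standard genetic code by default (plant mitochondria and plastids
translate with it); any NCBI table id can be configured.

## Tree comparison

Trees are compared unrooted. Robinson–Foulds is the symmetric difference
of nontrivial bipartitions (via dendropy), normalized by 2(n−3). The
tanglegram heuristic repeatedly flips child orders in either tree when a
flip reduces the leaf-line crossing count — deterministic given input
order, and never worse than the input embedding. Polytomies are internal
nodes with more than two children, except at the root of an unrooted
tree where three children are the resolved convention; low-support clades
are internal edges with support below 60% (configurable). An optional
outgroup reroot is provided for rooted summaries. Neighbor joining is
included only to validate synthetic data: it recovers additive matrices
exactly, and negative branch lengths are clamped to zero with the deficit
shifted to the sister edge. Maximum-likelihood inference is out of scope;
the module consumes externally inferred Newick trees.

## Synthetic data: what it emulates, and what it does not

`sim_tree` is a Gillespie birth–death simulation run forward from one
lineage until the target extant count, extinct branches pruned, leaves
ultrametric; for the pure-birth case the expected height has the closed
form Σ_{k=2}^{n−1} 1/(λk), used as a simulation oracle. All generators
draw from a single `numpy.random.default_rng(seed)` stream, so output is
platform-reproducible for a fixed seed.

`sim_panel` evolves fragment sequences along the tree under a
Jukes–Cantor-type process (Poisson substitution events, uniform base
exchange; default rate 0.001 substitutions/site per unit branch length,
giving π in the 10⁻³–10⁻⁴ range typical of conspecific organellar data).
Species-diagnostic sites are planted post hoc at columns invariant across
the whole panel and verified absent in every other species, so planted
counts are exact — no homoplasy enters recovery tests. Intra-species
polymorphism is placed only at diagnostic-free columns; hybrids copy
their donor's haplotype before planting; missing (species, fragment)
pairs become all-gap rows. `study_panel` packages the study-scale
configuration: 33 species in six genera over 29 fragments (~250 kb
total), 25 species with ≥ 1 planted diagnostic, the eight species without
diagnostics gathered in the largest genus and including one hybrid/donor
pair, and one fragment absent from two species; between-species background
substitution is off in this configuration so the discrimination report
equals the planted truth exactly (25/33 = 75.76%).

`sim_organelles` builds a random-backbone mitogenome (default 424,370 bp,
44% GC) and plastome (135,000 bp) and overwrites disjoint mitogenome
slots with copies of 20 plastid source regions, the ten smallest inserted
twice (30 insertions total), each substituted at 3% divergence and placed
on a random strand. Source lengths follow a skewed log-spaced series over
64–4310 bp calibrated so the planted total is ~19.3 kb, 4.55% of the
mitogenome. Gene annotations are laid out so that exactly five plastid
genes lie fully inside source regions and four straddle a boundary.
Two 1 kb exact repeats are planted separately. `sim_cds` draws coding
sequences codon-by-codon from a configurable usage profile.

The generators do **not** emulate: indels and alignment error (divergence
is substitution-only, so alignments are trivially correct), recombination
or structural rearrangement, rate heterogeneity across sites or lineages,
GC skew and compositional gradients, or sequencing/assembly artefacts.
Passing recovery tests therefore shows the algorithms are correct under a
clean substitution model, not that real-data preprocessing (assembly,
alignment, trimming) is solved — those stages are accepted as given
inputs.

## Numerical choices and degenerate inputs

* Thresholds are applied as: raw score ≥ min (the cutoff value 100 is
  kept), e-value ≤ max, adjusted p < α.
* Bonferroni is min(1, p·k); the within-family factor is the family's
  pair count, the organelle-contrast factor the number of tested codons.
* Kruskal–Wallis on all-equal data returns p = 1 (the test statistic is
  undefined; no evidence of difference).
* Pairs with zero compared columns are excluded from identity/π means
  with a warning; a pair with zero compared sites in a distance matrix is
  an error (the tree would be undefined).
* NJ pair selection breaks ties by first index (deterministic); Q-value
  comparisons use a 1e-12 slack.
* Interval deduplication and masking are exact integer interval algebra;
  merged masks are sorted, disjoint, in bounds by construction.

## Problem sizes

The test suite runs synthetic fixtures from toy (4 × 10 alignments) up to
full study scale (424 kb genome scans, 33 species × 250 kb panels); the
acceptance script uses the full-scale generator defaults throughout and
completes in well under a minute on one CPU. Property tests
(MDC-vs-brute-force equivalence, RSCU normalization, window-count
formula) run 100–200 randomized replicates each.

## Known limitations

* Gapped e-values reuse ungapped Karlin–Altschul parameters; absolute
  e-values near the cutoff can differ from NCBI BLAST's (which also
  applies length and composition corrections). Hit coordinates and scores
  agree with blastn on planted fixtures (cross-checked in the tests).
* The scanner indexes exact k-mers: homology below roughly 75% identity
  with no conserved 12-mer stretch can be missed; lower `seed_len` for
  more sensitivity at quadratic cost in seed density.
* π on gappy alignments depends on the deletion convention; pairwise
  deletion is used throughout, which can differ in the third decimal from
  complete-deletion implementations.
* The tanglegram heuristic is greedy; it guarantees improvement, not the
  global crossing minimum (exhaustive rotation is exponential).
* `study_panel` fixes the identifiable-species count by construction;
  with background substitution enabled, terminal-branch mutations add
  genuine diagnostics on top of the planted ones, so exact-count
  recovery holds only at substitution rate 0.
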