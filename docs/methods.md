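# Methods

## Scope and data model

The package scores somatic framework (FR) mutations of antibody heavy
chains against germline-specific substitution profiles estimated from
IgG repertoires. A `GermlineReference` carries the germline V-segment
nucleotide sequence (in frame, trimmed at the conserved FR3 cysteine so
the highly variable CDR3/D/J region is excluded), its translation, and
region windows labelling every amino-acid position FR1/CDR1/FR2/CDR2/FR3
exactly once. Windows are stated in ungapped 1-based coordinates of the
reference itself and are configurable per germline, because FR1
boundaries differ between V<sub>H</sub> genes in unique-numbering
schemes; for the bundled VH3-23 reference (96 aa) the defaults are
FR1 1–25, CDR1 26–33, FR2 34–50, CDR2 51–58, FR3 59–96. Only FR1/FR2/FR3
columns are scored; FR4 is J-encoded and out of scope.

## Alignment strategy

Repertoire reads are anchored on their germline by global pairwise
alignment (Needleman–Wunsch, affine gaps; Biopython's `PairwiseAligner`)
instead of a progressive multiple alignment of the whole repertoire.
Because every read is compared to the same reference, the column
semantics are identical at a fraction of the cost, and an externally
produced MSA can be ingested instead (`build_column_map` /
`msa_to_matrix`). Insertion columns — columns where the germline row is
gapped — are dropped when their occupancy is strictly below 10% (an MSA
column with "more than 90% gaps"); in the pairwise path an insertion is
private to one read, i.e. occupancy ~1/N, and is dropped directly.
Reads whose length equals the reference take a fast vectorised path
(direct in-frame translation). Codons that are deleted, partially
covered, ambiguous, or stop codons are excluded from the per-position
totals. Gap penalties are positive magnitudes with the convention that a
run of length g costs `open + (g-1)·extend`; defaults open 5.0,
extend 1.0, match +1, mismatch −1. Germline assignment picks the
reference with the highest nucleotide identity over reference positions,
ties broken lexicographically, with a 60% identity floor below which a
query is reported unassigned.

## Score matrix

Counts `N_ij` of amino acid j at FR position i are tallied over aligned,
translated reads; `T_i = Σ_j N_ij` is the number of gap-free sequences
at the position. Wild-type residues and allelic-variant residues of the
same gene are *masked*: they are germline variation, not somatic
mutation, so they receive no score — but their observations remain in
`T_i`, keeping `N_ij / T_i` a true per-sequence mutation frequency.
Unobserved, unmasked substitutions receive a pseudocount of one, which
acts as the score floor at each position. Scores are

    S_ij = log_1.26(α · N_ij / T_i),

the log base following the Dayhoff log-odds convention. α centres the
mean of the unmasked FR scores at zero; because the mean of
`log(α·f_ij)` is linear in `log α`, the centring constant has the closed
form α = 1 / geomean(f_ij), which the tests verify against a numeric
root-finder. The set over which the mean is centred includes
pseudocounted entries; correlation analyses expose an `observed_only`
flag to drop them when comparing matrices. A depth warning (not an
error) is emitted below 100,000 sequences, the depth at which score
displacements under subsampling stop shrinking appreciably; the warning
threshold is configurable and disabled in the bundled desk-scale
analyses.

Structural properties the construction guarantees (and the suite
checks): mean of unmasked scores is zero to 1e-6; scores are strictly
increasing in `N_ij` at fixed `T_i` and α; scaling all counts and totals
by a constant leaves every score unchanged; the position minimum is
attained by a pseudocounted cell whenever one exists.

## FR score

For a query antibody aligned to its germline, one `MutationRecord` is
produced per FR position where residues differ (CDR differences and
gapped positions are skipped; a residue that is masked as an allelic
variant is not counted as a mutation, mirroring its removal from the
count table). The antibody-level score is

    FR = 1 for m = 0;   FR = Σ S_ijk / (c0·m + c1·m²) for m > 0.

`c0`/`c1` are fitted by ordinary least squares without an intercept on
individual repertoire antibodies (simple random sample with replacement,
default 1,000, seedable), using only antibodies with m ≥ 1 since m = 0
contributes no constraint. Fitting on per-m means instead is exposed as
`on_means=True`; with balanced data the two fits coincide, and the
raw-antibody default is the simplest reading of a least-squares estimate
of the typical score sum at a given mutation load. The fit is exact on
noiseless quadratic data; a non-positive denominator at some m is
reported as an error naming the model unusable at that load. Mutation
effects are treated as additive and independent — no epistasis.

## Codon distances

The minimum number of nucleotide substitutions converting a source codon
into any sense codon of a target residue is a direct Hamming minimum;
stop codons are excluded as targets and intermediates are not modelled
(pathways are not scored). When the germline codon is unknown, the
amino-acid-level distance minimises over all source-residue codons.
`class_score_summary` partitions a PSSM's unmasked entries by the
distance from the germline codon and reports per-class means, counts,
and one-tailed Welch t-tests; on repertoires generated by single-
nucleotide events the class means are strictly ordered 1 > 2 > 3.

## Repertoire statistics

- **Per-position frequency**: fraction of gap-free reads differing from
  germline per position, plus FR/CDR region means.
- **Identity summary**: percent of reads above 98% germline nucleotide
  identity (strict) and percent unmutated.
- **dN/dS**: events are counted per codon against the germline — a
  changed codon is one nonsynonymous event if its translation changes,
  else one synonymous event; the ratio is total N over total S, NA when
  no synonymous events exist. The per-codon rule is pinned by an
  enumeration oracle over all single-nucleotide changes of the germline.
- **PSSM correlation**: Pearson r over the intersection of unmasked
  entries, optionally restricted to positions where both germlines share
  an identical codon, to substitutions one nucleotide from the germline
  codon, or to observed (non-pseudocount) entries. Same-donor basal
  noise is obtained by correlating PSSMs built from two disjoint
  subsamples.
- **UPGMA clustering**: average-linkage agglomeration (SciPy) of the
  distance 1 − r, exported as Newick with branch lengths via scikit-bio.
- **Subsampling convergence**: for each depth and repetition, a uniform
  subsample without replacement is scored and |S_sub − S_full| pooled
  over repetitions; the report gives the median and the 97.5th
  percentile (the upper tail of a 95% band) per depth.

## MHC-II epitope binning

Peptides are all 15-mer windows of a sequence; a window starting at s
covers a mutation at p iff s ≤ p ≤ s+14. Mutant windows are paired to
germline windows at the same start position in germline coordinates (the
simplest well-defined pairing; predictors report per-peptide affinities,
so pairing by offset keeps the mutated and unmutated content aligned).
Mutant peptides whose germline partner binds with K<sub>D</sub> < 1,000
nM are binned by the fold-change mutant/germline K<sub>D</sub> for the
same allele: < 0.5, [0.5, 2] (closed), > 2. K<sub>D</sub> exactly 1,000
nM does not pass the strict high-affinity gate and is tagged
low-affinity. A peptide covering several mutations contributes the mean
of their PSSM scores by default (per-mutation expansion available).
Scores are averaged per allele × bin to remove redundancy from the same
peptide binding multiple alleles; bins are compared by Welch two-sample
t-tests over allele-level means with Benjamini–Hochberg adjustment.
Affinity prediction itself is out of scope: any TSV with (peptide,
allele, kd_nM) is accepted.

## Synthetic repertoires

The simulator emulates the *mechanistic* structure of somatic
hypermutation: per sequence, a mutation load k is drawn and k
single-nucleotide substitutions are placed at sites drawn from
per-site weights, with the replacement base drawn from a 4×4 bias
matrix conditioned on the germline base (default transitions:transversions
2:1, the dominant point-mutation bias of AID, without modelling WRC/GYW
hotspot motifs). Repeated hits on a site overwrite, so every mutated
site is exactly one substitution from germline and the closed-form
single-hit expectation (`true_aa_profile`: each codon's nine
single-nucleotide neighbours weighted by site weight × bias × mean load)
is exact up to multi-hit collisions; a Monte-Carlo profile at 10× depth
covers the multi-hit regime. The default load is negative binomial with
mean 8 substitutions per 288-nt segment and shape 2 — an overdispersed
mix of lightly and heavily matured sequences leaving a few percent
unmutated, qualitatively matching IgG repertoires.

**What passing tests do and do not show.** The simulator has no
selection step and no clonal structure, so it reproduces the
single-nucleotide enrichment and sampling behaviour of real repertoires
but not their selected score magnitudes, hotspot concentration, or
lineage correlations; tests against it validate the estimator machinery
(centring, recovery, convergence, class ordering), not biological
effect sizes. Whole-dataset magnitudes published for real repertoires
require the original multi-hundred-million-sequence data and are
documented as out of desk scope.

## Problem sizes and numerical choices

Bundled analyses run at desk scale: 10,000–50,000 simulated sequences
for matrix construction and recovery checks, 1,000-antibody samples for
the c0/c1 fit and FR-score centring, 3 repetitions for subsampling.
Deterministic seeds are threaded through every stochastic step
(NumPy `default_rng`). Ties in germline assignment break
lexicographically; alignment ambiguity resolves to the aligner's
first-reported optimum; degenerate inputs (empty classes, bins with
fewer than two allele means, zero synonymous events, all-identical
mutation loads) are reported as NA/skipped/errors rather than silently
patched. PSSM files round-trip scores at six decimals with metadata
exact; a format-version mismatch is an explicit error.

## Known limitations

- Pairwise germline anchoring cannot represent shared insertions across
  reads; ingest a pre-computed MSA if insertions matter.
- Allelic variants are masked rather than modelled per-allele, so
  genuinely allele-specific substitution preferences are averaged.
- The FR score assumes additivity and independence of mutations.
- The bundled reference set is a single real germline plus synthetic
  derivatives; multi-germline analyses on real data require user-supplied
  references.
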