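# Methods

This note documents the statistical machinery, the defaults and the design
choices in pavkit, and what the synthetic-data experiments do and do not
demonstrate.

## Data model and conventions

Internal coordinates are 0-based half-open; VCF and GFF3 (1-based,
inclusive end) are converted at the boundary, so POS=101/END=200 becomes
[100, 200) with length 100. This makes every base-count identity exact:
partition spans sum to the genome length, and covered-base unions never
double-count.

Presence genotypes are ternary: 0 (reference state), 1 (non-reference /
variant present), MISSING. Diploid heterozygous calls are collapsed to
MISSING on input: the intended organisms are highly selfing, so residual
heterozygous SV genotype calls are far more likely genotyping artifacts
than true heterozygotes, and no published rule exists for using them.
"PAV" throughout means deletion-type records relative to the reference;
the analysis set used by the higher-level statistics is
`filter_catalog(cat, svtypes={"DEL"}, max_len=10_000, polymorphic_only=True)`
(1 bp to 10 kb; a 50 bp floor is only a benchmarking convention for
long-read comparisons, not an analysis filter).

When reading SV VCFs we derive the record end from |SVLEN| when present
(falling back to the END-derived stop): htslib infers the stop coordinate
from SVLEN with symbolic alleles in a way that is off by one for this
encoding, and SVLEN is unambiguous for DEL/DUP/INV.

## Benchmarking by reciprocal overlap

Truth sets are simulated by placing non-overlapping events (uniform
lengths in [min_len, max_len], uniform positions, bounded rejection
sampling) and applying them right-to-left so coordinates stay valid; point
substitutions are applied outside event bases at a per-base rate. The
substitution rate defaults to 1e-3 per base: the upstream simulator
parameter this emulates has an unstated unit, and 10% divergence would be
unrealistic for intraspecific data, so a typical intraspecific divergence
was chosen.

Matching requires overlap/len(call) ≥ r and overlap/len(truth) ≥ r (r =
0.5 default), optionally type-strict (default on; DEL≠DUP≠INV). Assignment
is one-to-one and greedy by descending overlap bases with deterministic
lexicographic tie-breaks. Greedy was chosen over optimal bipartite
matching for determinism and speed; the test suite verifies that on
sparse, well-separated instances (the regime of simulated benchmarks) the
greedy assignment attains the exact maximum-cardinality matching computed
by an independent graph-matching oracle. Breakpoint tolerance is expressed
solely through the reciprocal-overlap fraction — no fixed ±bp slack.
Precision and sensitivity return NaN (never raise) on empty denominators.

## Genome partition and base-count enrichment

Genic = union of merged gene intervals; intergenic = per-chromosome
complement; the two are disjoint and exhaustive by construction. A PAV
counts toward each partition it overlaps by ≥1 base (so the two rows'
record counts can sum to more than the catalog size), while covered bases
are unions, never sums of lengths.

The enrichment test is a Pearson χ² without continuity correction on the
2×2 table {genic, intergenic} × {PAV-covered, uncovered} **base counts**,
not record counts: the observed/expected quantities of interest are base
totals, and only base counts give the test the genome-scale sensitivity
that makes a several-fold coverage difference astronomically significant.
Fold = intergenic covered proportion / genic covered proportion. p values
below 1e-16 are displayed as "< 1E-16"; χ² display uses *truncation* to
two significant figures (18,622,228 → "1.8E7"), which is the convention
the reference accounting is consistent with. Full precision is retained in
all objects and verified in tests against the direct Σ(O−E)²/E formula.

## Polarization and unfolded SFS

Ancestral states come from a consensus over a designated polarizer panel
(five deeply diverged accessions in the emulated design): the majority
allele among the panel's non-missing calls is ancestral; the state is NA
when more than one panel member is missing or when the panel allele
frequency is exactly 0.5. The 0.5 rule is evaluated over the *informative*
(non-missing) panel members — the alternative (counting missing members in
the denominator) is not well defined; this choice is flagged for
sensitivity testing via the recorded per-record panel counts.

The unfolded SFS of a population bins loci by raw derived-allele count k =
1..n−1 (no projection to a common sample size; populations are compared on
proportions). Derived counts are taken over non-missing calls; loci are
dropped and tallied when ancestral state is NA, when the within-population
call rate falls below 80% (configurable; the source design is silent), or
when the locus is monomorphic within the population. Class membership
(genic, defense) is ≥1 bp overlap with a gene / a gene bearing the defense
term, consistent with the partition rules.

## Tajima's D and the matched-resampling test

For a sites × samples presence matrix, each site contributes
2p(1−p)·m/(m−1) to θ̂π, where p is the allele frequency and m the
non-missing count at that site (the unbiased small-sample factor). S is
the number of polymorphic sites, and the sample size plugged into the
normalizing constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂) is the median
informative count across sites, floored to an integer. D is NA (never an
exception) when S = 0 or n < 4. With complete data this reduces exactly to
the classical pairwise-difference definition, which the tests verify
against a from-scratch enumeration oracle.

The significance test for a focal class draws, per replicate, |focal|
sites uniformly without replacement from the genic variant universe and
recomputes D from per-site sufficient statistics (vectorized, chunked to
bound memory). The empirical p is one-sided upper-tail with add-one
correction, p = (1 + #{D_null ≥ D_obs})/(1 + R): the hypothesis is
directional (intermediate-frequency excess) and add-one avoids p = 0.
Variants, not genes, are the resampling unit — matching the design being
emulated — which leaves per-gene clustering of the focal class as a known
caveat (clustered focal variants are not independent draws). Replicates
with no segregating sites yield NaN and never count as exceedances.

The tail-enrichment helper consumes any per-SNP score table, takes the top
tail (default 5%), maps tail SNPs to genes, and runs a one-tailed
hypergeometric test of focal-gene membership among tail genes against the
gene universe. Computation of the scores themselves is out of scope.

## Gene-set enrichment

Fisher route: per term, hypergeometric upper-tail p for the study set's
term count, enrichment score (k/n)/(K/N), Benjamini–Hochberg adjustment
across terms (step-up with monotone enforcement, input order preserved).
Term maps are taken as-is — no ontology-graph propagation.

Permutation route (gene mode): the observed statistic per term is the
number of *distinct* term genes overlapped by candidate variants — a long
gene hit by many variants counts once — and the null redraws |candidate|
variants from the full variant set. Because the null inherits the
variant pool's spatial structure, terms whose genes are long or clustered
get conservative p values exactly where the Fisher test is
anti-conservative; the suite asserts this ordering on a constructed
clustered fixture. Gene mode (rather than variant-hit counting) is the
conservative reading of the emulated tool's behavior.

## Distances, neighbor joining, tag SNPs

The accession distance is the allele-sharing mismatch proportion over
pairwise-complete presence calls (pairwise deletion), the standard choice
for binary presence data; the metric is configurable in the sense that the
matrix computation is exposed and any matrix can be fed to the tree
builder. Neighbor joining implements the classical Q-criterion
agglomeration with deterministic first-minimum (lexicographic) tie-breaks;
branch lengths may be negative on non-additive inputs and are retained raw
on the tree object, clamped to zero at Newick export by default. On
additive inputs NJ provably recovers the generating topology, which the
tests exercise over random 6-taxon trees and verify with an independent
tree library.

Tag-SNP r² is the squared Pearson correlation of presence vectors over
pairwise-complete samples, maximized over SNPs within a window (default
10 kb) of the PAV **midpoint** (the anchor choice — start, midpoint, or
breakpoint — is otherwise arbitrary; midpoint is symmetric). PAVs without
any window SNP are reported NA and excluded from the summary mean/SD with
a count. Association mapping itself is out of scope; focal PAV lists are
inputs.

## Synthetic data generator

Defaults describe a deliberately small but structurally faithful study:
two 600 kb chromosomes; ~300 genes (gamma lengths, mean 2 kb, exponential
gaps) giving an ~50% genic genome; nine clusters of four consecutive
defense genes carrying GO:0006952 plus random background terms; three
populations of 24/20/16 accessions plus five polarizer accessions; 5%
missing calls. PAV lengths are lognormal (median ≈ 90 bp, capped at
10 kb). Placement targets a 3.5-fold intergenic/genic per-base coverage
ratio by filling each compartment to its coverage budget (defense genes
receive two PAVs each first), so the realized ratio tracks the target
within a few percent.

Genotypes: a global derived-allele frequency per locus — 1/k-shaped for
neutral loci, Beta(κ, κ) with κ = 20 around 0.5 for defense loci — is
propagated to populations through a Balding–Nichols Beta with Fst = 0.12,
then sampled per accession. Ancestral state is the reference allele with
probability 0.9; polarizers carry the derived allele independently with
probability 0.1. Each defense PAV gets a tag SNP nearby whose genotypes
are the PAV's with symmetric flips at rate ε = (1 − √r²_target)/2, which
for frequencies near 0.5 yields the target r² (0.75 default) in
expectation; background SNPs are unlinked.

What the generator does *not* emulate: genuine coalescent histories and
LD beyond the single tag-SNP knob, recombination, reference bias, read-level
genotyping error structure, gene length/expression correlations, or the
real data's sample sizes (three populations of ~20 vs. sixteen populations
from 1,301 accessions). Passing end-to-end tests therefore demonstrate
that the estimators recover planted signals of realistic shape and size —
not that the pipeline's numerical outputs on real data would match any
published value. One visible consequence: under Balding–Nichols sampling
with within-population polymorphism conditioning, even "neutral" loci show
positive within-population D, so the defense signal is assessed *relative*
to the genic background, exactly as the matched-resampling test does.

## Problem sizes and determinism

All stochastic procedures take explicit seeds and are reproducible
bit-for-bit (the suite checks byte-identical regenerated file sets). The
shipped experiment sizes — 1,000–10,000 resampling replicates, 200-trial
calibrations, 50-instance matching and tree-recovery sweeps — were chosen
so the entire suite completes in well under a minute of compute while
keeping Monte-Carlo error far below the asserted margins; the resampling
test itself scales to the 100,000 replicates used in production analyses
(vectorized subset-D evaluation, ~seconds for catalog-scale universes).

## Known limitations

* The matching assignment is greedy; a certificate of optimality exists
  only for sparse instances (verified in tests), not adversarial ones.
* Tajima constants use a single n (median informative count); heavily
  heterogeneous missingness across sites is better served by per-site
  projection, which is not implemented.
* The permutation enrichment redraws variants marginally (no preservation
  of per-sample genotype structure); it corrects for gene length and
  clustering, not for frequency spectra differences between candidate and
  background variants.
* `best_tag_snp` computes r² on collapsed presence states; diploid
  dosage-based r² would differ for outcrossing data.
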