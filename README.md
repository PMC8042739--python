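# pavkit

Population genetics of presence/absence variants (PAVs) in selfing plant
genomes.

Whole-genome short-read studies of species like *Arabidopsis thaliana*
yield catalogs of structural variants — deletions (PAVs), tandem
duplications, inversions — genotyped across hundreds or thousands of
accessions. Two evolutionary questions dominate the analysis of such
catalogs: is there purifying selection keeping PAVs out of genes (a "core"
genome), and do particular gene classes — disease-resistance and other
defense-response genes above all — instead *accumulate* PAVs and hold them
at intermediate frequencies, the footprint of balancing selection? pavkit
implements the full analysis chain for these questions, plus a synthetic
data generator so every stage can be exercised and validated without any
external data.

## What it computes

* **Call-set benchmarking** — plant non-overlapping DEL/DUP/INV events into
  a reference, then score any call set against a truth set by *reciprocal
  overlap*: call *c* matches truth *t* only if their shared bases cover at
  least a fraction *r* (default 0.5) of **each** interval. Assignment is
  one-to-one; precision = TP/(TP+FP), sensitivity = TP/(TP+FN).
* **Genic/intergenic partition** — merge gene annotations, count PAV-covered
  bases in each partition, and test the genic deficit with a Pearson χ² on
  the 2×2 base-count table; the fold enrichment is the ratio of covered
  proportions.
* **Polarized unfolded SFS** — ancestral states from a consensus over a
  small panel of deeply diverged accessions (majority allele; NA if >1
  panel member missing or the panel frequency is exactly 0.5), then
  derived-allele-count spectra per population and genomic class.
* **Tajima's D with a matched-resampling test** —

  D = (θ̂π − θ̂W) / √(e₁S + e₂S(S−1)),  θ̂W = S/a₁,

  with missing-data handling on presence matrices. Significance of a focal
  class (defense PAVs) comes from redrawing size-matched genic variant sets
  and recomputing D, giving an add-one-corrected upper-tail empirical p.
* **Gene-set enrichment** — one-tailed Fisher (hypergeometric) tests with
  Benjamini–Hochberg correction, and a conservative gene-mode permutation
  test that redraws variants and therefore respects gene length and
  clustering.
* **Trees and LD** — allele-sharing distances with pairwise deletion,
  neighbor-joining with deterministic tie-breaks and Newick output, and
  best tag-SNP r² (squared Pearson correlation) within a window of each
  focal PAV.
* **Synthetic data** — genomes, clustered defense genes, multi-population
  genotypes (neutral 1/k spectra vs. Beta-distributed intermediate
  frequencies), polarizer accessions, missingness, and an engineered
  tag-SNP panel; every planted signal is recoverable by the pipeline.

## Worked example

```python
from pavkit import simulate as sim
from pavkit.partition import build_partition, summarize_partition, enrichment_chisq
from pavkit.sfs import class_intervals_from_annotation, classify_records
from pavkit.tajima import matched_resampling_test, tajimas_d

out = sim.generate(sim.SimConfig(seed=1))
cat = out.pav_catalog          # polymorphic deletions <= 10 kb

partition = build_partition(out.genes, out.config.chrom_lengths)
summary = summarize_partition(partition, cat)
test = enrichment_chisq(summary)

classes = class_intervals_from_annotation(out.genes, out.terms, out.defense_term)
masks = classify_records(cat, classes)
geno = cat.genotype_matrix()[:, cat.sample_index(out.popmap.samples_of("P1"))]
res = matched_resampling_test(geno[masks["genic"]], geno[masks["defense"]],
                              n_reps=10_000, seed=7)
```

which prints, when the pieces above are reported:

```
catalog: 1487 SVs -> 1256 polymorphic PAVs (<= 10 kb)
whole_genome  span=1,200,000 n_pavs= 1256 covered= 167,317 proportion=0.139
intergenic    span=  588,960 n_pavs= 1036 covered= 129,056 proportion=0.219
genic         span=  611,040 n_pavs=  220 covered=  38,261 proportion=0.063
fold = 3.50, chi2 = 6.1E4 (full 61222.1), p < 1E-16
Tajima's D: genic +1.467 (S=168), defense +2.415 (S=72)
matched resampling: p = 9.999e-05 over 10,000 draws
```

Reading: PAVs cover 21.9% of intergenic but only 6.3% of genic sequence —
a 3.5-fold deficit inside genes (the generator's target), overwhelmingly
significant on base counts. Within population P1, defense-gene PAVs sit at
more intermediate frequencies than genic PAVs overall (D +2.42 vs +1.47),
and no random size-matched genic subset out of 10,000 reaches the defense
value (p ≈ 1e-4): the planted balancing-selection signal is recovered.

The same steps are available from the shell:

```sh
pavkit simulate --seed 1 --out sim/
pavkit catalog filter --vcf sim/svs.vcf --genome sim/chrom.sizes \
    --types DEL --max-len 10000 --polymorphic --out pavs.vcf
pavkit partition --gff sim/genes.gff3 --vcf pavs.vcf --genome sim/chrom.sizes
pavkit tajima --vcf pavs.vcf --genome sim/chrom.sizes --gff sim/genes.gff3 \
    --terms sim/terms.tsv --popmap sim/popmap.tsv --population P1 \
    --reps 100000 --seed 7
```

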