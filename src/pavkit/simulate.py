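"""Synthetic multi-population PAV data with planted selection signals.

The generator emulates the structure of a selfing plant pan-genome study:

* a small random genome with a gene-dense annotation, a fraction of genes
  being clustered "defense" genes (tandem R-gene-like clusters) carrying a
  defense-response term;
* presence/absence variants placed so that the per-base PAV coverage of
  intergenic sequence exceeds genic coverage by a target fold (purifying
  selection against gene-disrupting PAVs);
* genotypes for several populations drawn from a Balding–Nichols model
  around a global derived-allele frequency, where neutral loci have a
  1/k-shaped frequency spectrum and defense-gene loci draw frequencies
  from a symmetric Beta around 0.5 (balancing-selection-like
  intermediate-frequency excess, concentration ``balanced_kappa``);
* five divergent "polarizer" accessions that carry the ancestral allele
  except at a small divergence rate, supporting consensus polarization;
* per-call missingness, and a SNP panel in which each defense PAV has a
  nearby tag SNP engineered to a target r² plus unlinked background SNPs.

Everything is deterministic given the config seed, and every emitted file
round-trips through the package readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .catalog import (
    MISSING,
    PopulationMap,
    SVCatalog,
    SVRecord,
    write_sv_vcf,
)
from .intervals import GenomicInterval, complement_spans, merge_spans

DEFENSE_TERM = "GO:0006952"  # defense response


@dataclass
class SimConfig:
    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 600_000, "chr2": 600_000}
    )
    # annotation
    n_genes: int = 300
    gene_length_mean: float = 2_000.0
    gene_gap_mean: float = 2_000.0
    n_defense_clusters: int = 9
    genes_per_cluster: int = 4
    n_background_terms: int = 20
    # populations (polarizers are extra, on top of these)
    populations: dict[str, int] = field(
        default_factory=lambda: {"P1": 24, "P2": 20, "P3": 16}
    )
    n_polarizers: int = 5
    fst: float = 0.12
    # PAV placement
    intergenic_coverage: float = 0.25
    density_ratio: float = 3.5          # intergenic/genic per-base coverage
    defense_pavs_per_gene: int = 2
    pav_log_len_mean: float = 4.5       # lognormal length, median ~90 bp
    pav_log_len_sd: float = 1.2
    pav_min_len: int = 20
    pav_max_len: int = 10_000
    n_dup: int = 40
    n_inv: int = 20
    # genotype model
    balanced_kappa: float = 20.0
    missing_rate: float = 0.05
    ancestral_ref_prob: float = 0.9
    polarizer_divergence: float = 0.1
    # SNP panel
    snp_target_r2: float = 0.75
    tag_window: int = 4_000             # tag SNP within this distance of PAV midpoint
    n_background_snps: int = 300

    def validate(self) -> None:
        for name, value in (
            ("fst", self.fst),
            ("intergenic_coverage", self.intergenic_coverage),
            ("missing_rate", self.missing_rate),
            ("ancestral_ref_prob", self.ancestral_ref_prob),
            ("polarizer_divergence", self.polarizer_divergence),
            ("snp_target_r2", self.snp_target_r2),
        ):
            if not 0 <= value <= 1:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if any(n < 4 for n in self.populations.values()):
            raise ValueError("population sizes must be >= 4")
        if self.intergenic_coverage / self.density_ratio > 0.6:
            raise ValueError("infeasible PAV density: genic coverage target > 0.6")


@dataclass
class SimOutput:
    config: SimConfig
    reference: dict[str, str]
    genes: dict[str, GenomicInterval]
    terms: dict[str, set[str]]
    defense_term: str
    catalog: SVCatalog
    popmap: PopulationMap
    polarizers: list[str]
    truth: pd.DataFrame
    snp_matrix: np.ndarray
    snp_positions: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {k: outdir / v for k, v in {
            "genome": "genome.fa", "sizes": "chrom.sizes",
            "gff": "genes.gff3", "terms": "terms.tsv",
            "svs": "svs.vcf", "snps": "snps.vcf",
            "popmap": "popmap.tsv", "polarizers": "polarizers.txt",
            "truth": "truth.tsv",
        }.items()}
        with open(paths["genome"], "w") as fh:
            for chrom, seq in self.reference.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        with open(paths["sizes"], "w") as fh:
            for chrom, n in self.config.chrom_lengths.items():
                fh.write(f"{chrom}\t{n}\n")
        with open(paths["gff"], "w") as fh:
            fh.write("##gff-version 3\n")
            for gene, iv in self.genes.items():
                fh.write(
                    f"{iv.chrom}\tpavkit_sim\tgene\t{iv.start + 1}\t{iv.end}"
                    f"\t.\t+\t.\tID={gene}\n"
                )
        with open(paths["terms"], "w") as fh:
            for gene in self.genes:
                for term in sorted(self.terms.get(gene, ())):
                    fh.write(f"{gene}\t{term}\n")
        write_sv_vcf(self.catalog, paths["svs"])
        self._write_snp_vcf(paths["snps"])
        with open(paths["popmap"], "w") as fh:
            for sample, pop in self.popmap.sample_to_pop.items():
                fh.write(f"{sample}\t{pop}\n")
        paths["polarizers"].write_text("\n".join(self.polarizers) + "\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths

    def _write_snp_vcf(self, path: Path) -> None:
        header = pysam.VariantHeader()
        header.add_line("##fileformat=VCFv4.2")
        for chrom, length in self.config.chrom_lengths.items():
            header.contigs.add(chrom, length=length)
        header.formats.add("GT", 1, "String", "Genotype")
        for s in self.catalog.samples:
            header.add_sample(s)
        vf = pysam.VariantFile(str(path), "w", header=header)
        for i, row in self.snp_positions.iterrows():
            rec = vf.new_record(
                contig=row["chrom"], start=int(row["pos"]) - 1,
                stop=int(row["pos"]), alleles=("A", "T"), id=row["id"],
            )
            for j, s in enumerate(self.catalog.samples):
                g = int(self.snp_matrix[i, j])
                rec.samples[s]["GT"] = (None, None) if g == MISSING else (g, g)
            vf.write(rec)
        vf.close()

    @property
    def pav_catalog(self) -> SVCatalog:
        from .catalog import filter_catalog

        return filter_catalog(self.catalog, svtypes={"DEL"},
                              max_len=self.config.pav_max_len,
                              polymorphic_only=True)


def _random_genome(rng: np.random.Generator, chrom_lengths: dict[str, int]) -> dict[str, str]:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return {
        chrom: bases[rng.integers(0, 4, size=n)].tobytes().decode()
        for chrom, n in chrom_lengths.items()
    }


def _place_genes(rng: np.random.Generator, cfg: SimConfig) -> dict[str, GenomicInterval]:
    genes: dict[str, GenomicInterval] = {}
    chroms = list(cfg.chrom_lengths)
    ci = 0
    pos = 0
    for gi in range(cfg.n_genes):
        gap = int(rng.exponential(cfg.gene_gap_mean)) + 50
        length = int(np.clip(rng.gamma(4.0, cfg.gene_length_mean / 4.0), 400, 8_000))
        while ci < len(chroms) and pos + gap + length > cfg.chrom_lengths[chroms[ci]]:
            ci += 1
            pos = 0
        if ci >= len(chroms):
            break
        start = pos + gap
        genes[f"g{gi:04d}"] = GenomicInterval(chroms[ci], start, start + length)
        pos = start + length
    return genes


def _assign_defense(rng: np.random.Generator, cfg: SimConfig, gene_names: list[str]) -> set[str]:
    """Defense genes as runs of consecutive genes: genomic clustering."""
    run = cfg.genes_per_cluster
    stride = max(run * 3, run + 1)
    block_starts = np.arange(0, max(len(gene_names) - run, 1), stride)
    chosen = rng.choice(
        block_starts, size=min(cfg.n_defense_clusters, len(block_starts)),
        replace=False,
    )
    defense: set[str] = set()
    for b in chosen:
        defense.update(gene_names[b:b + run])
    return defense


def _pav_length(rng: np.random.Generator, cfg: SimConfig, cap: int) -> int:
    L = int(rng.lognormal(cfg.pav_log_len_mean, cfg.pav_log_len_sd))
    return int(np.clip(L, cfg.pav_min_len, min(cfg.pav_max_len, cap)))


def generate(config: SimConfig | None = None) -> SimOutput:
    """Build one full synthetic data set from a config (see module docs)."""
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    reference = _random_genome(rng, cfg.chrom_lengths)
    genes = _place_genes(rng, cfg)
    gene_names = list(genes)
    defense_genes = _assign_defense(rng, cfg, gene_names)

    background = [f"GO:TERM{i:02d}" for i in range(cfg.n_background_terms)]
    terms: dict[str, set[str]] = {}
    for gene in gene_names:
        assigned = set(
            rng.choice(background, size=int(rng.integers(0, 4)), replace=False)
        )
        if gene in defense_genes:
            assigned.add(DEFENSE_TERM)
        if assigned:
            terms[gene] = assigned

    # ---- PAV placement ---------------------------------------------------
    pav_intervals: list[tuple[GenomicInterval, str]] = []  # (interval, class)
    genic_bases = 0
    occupied_per_gene: dict[str, list[tuple[int, int]]] = {}

    def place_in_gene(gene: str, n_pavs: int, tag: str) -> int:
        nonlocal genic_bases
        iv = genes[gene]
        placed = 0
        seg = iv.length // max(n_pavs, 1)
        for s_i in range(n_pavs):
            lo = iv.start + s_i * seg
            hi = min(iv.start + (s_i + 1) * seg, iv.end)
            cap = hi - lo - 2
            if cap < cfg.pav_min_len:
                continue
            L = _pav_length(rng, cfg, cap)
            start = int(rng.integers(lo, hi - L))
            pav_intervals.append((GenomicInterval(iv.chrom, start, start + L), tag))
            occupied_per_gene.setdefault(gene, []).append((start, start + L))
            genic_bases += L
            placed += 1
        return placed

    for gene in (g for g in gene_names if g in defense_genes):
        place_in_gene(gene, cfg.defense_pavs_per_gene, "defense")

    genic_span = sum(iv.length for iv in genes.values())
    genome_total = sum(cfg.chrom_lengths.values())
    intergenic_span = genome_total - _merged_genic_span(genes, cfg)
    genic_target = int(cfg.intergenic_coverage / cfg.density_ratio * genic_span)
    nondefense = [g for g in gene_names if g not in defense_genes]
    tries = 0
    while genic_bases < genic_target and tries < 50_000:
        tries += 1
        gene = nondefense[int(rng.integers(len(nondefense)))]
        iv = genes[gene]
        cap = iv.length - 2
        if cap < cfg.pav_min_len:
            continue
        L = _pav_length(rng, cfg, cap)
        start = int(rng.integers(iv.start, iv.end - L))
        if any(start < e and s < start + L for s, e in occupied_per_gene.get(gene, [])):
            continue
        pav_intervals.append((GenomicInterval(iv.chrom, start, start + L), "genic"))
        occupied_per_gene.setdefault(gene, []).append((start, start + L))
        genic_bases += L

    # intergenic placement until realized coverage matches the fold target
    intergenic_spans: list[tuple[str, int, int]] = []
    per_chrom_genic: dict[str, list[tuple[int, int]]] = {c: [] for c in cfg.chrom_lengths}
    for iv in genes.values():
        per_chrom_genic[iv.chrom].append((iv.start, iv.end))
    for chrom, n in cfg.chrom_lengths.items():
        for s, e in complement_spans(merge_spans(per_chrom_genic[chrom]), n):
            if e - s > cfg.pav_min_len + 4:
                intergenic_spans.append((chrom, s, e))
    span_lens = np.array([e - s for _, s, e in intergenic_spans], dtype=float)
    intergenic_target = int(
        cfg.density_ratio * (genic_bases / genic_span) * intergenic_span
    )
    occupied_per_span: dict[int, list[tuple[int, int]]] = {}
    inter_bases = 0
    tries = 0
    while inter_bases < intergenic_target and tries < 200_000:
        tries += 1
        si = int(rng.choice(len(intergenic_spans), p=span_lens / span_lens.sum()))
        chrom, s0, e0 = intergenic_spans[si]
        cap = e0 - s0 - 4
        if cap < cfg.pav_min_len:
            continue
        L = _pav_length(rng, cfg, cap)
        start = int(rng.integers(s0 + 1, e0 - L - 1))
        if any(start < e and s < start + L for s, e in occupied_per_span.get(si, [])):
            continue
        pav_intervals.append((GenomicInterval(chrom, start, start + L), "intergenic"))
        occupied_per_span.setdefault(si, []).append((start, start + L))
        inter_bases += L

    # ---- samples and genotypes ------------------------------------------
    pop_samples: list[str] = []
    sample_pop: dict[str, str] = {}
    for pop, size in cfg.populations.items():
        for i in range(size):
            name = f"{pop}_{i:03d}"
            pop_samples.append(name)
            sample_pop[name] = pop
    polarizers = [f"pol{i}" for i in range(cfg.n_polarizers)]
    samples = pop_samples + polarizers
    n_pop_total = len(pop_samples)

    def draw_genotypes(model: str) -> tuple[np.ndarray, float, int]:
        """Presence genotypes for all samples; returns (genotypes, f, ancestral)."""
        if model == "balanced":
            f = float(rng.beta(cfg.balanced_kappa, cfg.balanced_kappa))
        else:
            ks = np.arange(1, n_pop_total)
            w = 1.0 / ks
            f = float(rng.choice(ks, p=w / w.sum()) / n_pop_total)
        a = max(f * (1 - cfg.fst) / cfg.fst, 1e-3)
        b = max((1 - f) * (1 - cfg.fst) / cfg.fst, 1e-3)
        derived = np.empty(len(samples), dtype=np.int8)
        pos = 0
        for pop, size in cfg.populations.items():
            f_pop = rng.beta(a, b)
            derived[pos:pos + size] = rng.random(size) < f_pop
            pos += size
        derived[pos:] = rng.random(cfg.n_polarizers) < cfg.polarizer_divergence
        ancestral = 0 if rng.random() < cfg.ancestral_ref_prob else 1
        genotypes = derived if ancestral == 0 else (1 - derived).astype(np.int8)
        return genotypes, f, ancestral

    records: list[SVRecord] = []
    truth_rows = []
    clean_genotypes: dict[str, np.ndarray] = {}
    for i, (iv, klass) in enumerate(
        sorted(pav_intervals, key=lambda x: (x[0].chrom, x[0].start))
    ):
        model = "balanced" if klass == "defense" else "neutral"
        g, f, anc = draw_genotypes(model)
        rid = f"pav{i:05d}"
        clean_genotypes[rid] = g.copy()
        miss = rng.random(len(samples)) < cfg.missing_rate
        g = np.where(miss, MISSING, g).astype(np.int8)
        records.append(SVRecord(iv, "DEL", g, record_id=rid))
        truth_rows.append(
            {"record_id": rid, "chrom": iv.chrom, "start": iv.start,
             "end": iv.end, "svtype": "DEL", "class": klass, "model": model,
             "derived_freq": f, "ancestral_allele": anc}
        )

    # a sprinkling of DUP/INV records so type filtering is exercisable
    for svtype, count in (("DUP", cfg.n_dup), ("INV", cfg.n_inv)):
        for i in range(count):
            chrom = list(cfg.chrom_lengths)[int(rng.integers(len(cfg.chrom_lengths)))]
            L = _pav_length(rng, cfg, cfg.chrom_lengths[chrom] - 2)
            start = int(rng.integers(0, cfg.chrom_lengths[chrom] - L))
            g, f, anc = draw_genotypes("neutral")
            miss = rng.random(len(samples)) < cfg.missing_rate
            g = np.where(miss, MISSING, g).astype(np.int8)
            rid = f"{svtype.lower()}{i:04d}"
            records.append(
                SVRecord(GenomicInterval(chrom, start, start + L), svtype, g,
                         record_id=rid)
            )
            truth_rows.append(
                {"record_id": rid, "chrom": chrom, "start": start,
                 "end": start + L, "svtype": svtype, "class": "any",
                 "model": "neutral", "derived_freq": f, "ancestral_allele": anc}
            )

    records.sort(key=lambda r: (r.chrom, r.interval.start, r.interval.end))
    catalog = SVCatalog(samples=samples, records=records,
                        genome=dict(cfg.chrom_lengths))
    truth = pd.DataFrame(truth_rows).set_index("record_id").loc[
        [r.record_id for r in records]
    ].reset_index()

    # ---- SNP panel -------------------------------------------------------
    eps = (1.0 - np.sqrt(cfg.snp_target_r2)) / 2.0
    snp_rows = []
    snp_genos = []
    snp_i = 0
    for rec in records:
        if rec.svtype != "DEL":
            continue
        row = truth.loc[truth["record_id"] == rec.record_id].iloc[0]
        if row["class"] != "defense":
            continue
        base = clean_genotypes[rec.record_id]
        flips = rng.random(len(samples)) < eps
        g = np.where(flips, 1 - base, base).astype(np.int8)
        miss = rng.random(len(samples)) < cfg.missing_rate
        g = np.where(miss, MISSING, g).astype(np.int8)
        offset = int(rng.integers(-cfg.tag_window, cfg.tag_window + 1))
        pos = int(np.clip(rec.interval.midpoint + offset, 1,
                          cfg.chrom_lengths[rec.chrom]))
        snp_rows.append({"chrom": rec.chrom, "pos": pos,
                         "id": f"snp{snp_i:05d}", "tag_of": rec.record_id})
        snp_genos.append(g)
        snp_i += 1
    for _ in range(cfg.n_background_snps):
        chrom = list(cfg.chrom_lengths)[int(rng.integers(len(cfg.chrom_lengths)))]
        pos = int(rng.integers(1, cfg.chrom_lengths[chrom] + 1))
        f = rng.uniform(0.1, 0.9)
        g = (rng.random(len(samples)) < f).astype(np.int8)
        miss = rng.random(len(samples)) < cfg.missing_rate
        g = np.where(miss, MISSING, g).astype(np.int8)
        snp_rows.append({"chrom": chrom, "pos": pos,
                         "id": f"snp{snp_i:05d}", "tag_of": ""})
        snp_genos.append(g)
        snp_i += 1
    snp_positions = pd.DataFrame(snp_rows)
    order = np.lexsort(
        (snp_positions["pos"].to_numpy(), snp_positions["chrom"].to_numpy())
    )
    snp_positions = snp_positions.iloc[order].reset_index(drop=True)
    snp_matrix = np.stack([snp_genos[i] for i in order]) if snp_genos else np.empty((0, len(samples)), dtype=np.int8)

    return SimOutput(
        config=cfg,
        reference=reference,
        genes=genes,
        terms=terms,
        defense_term=DEFENSE_TERM,
        catalog=catalog,
        popmap=PopulationMap(sample_pop),
        polarizers=polarizers,
        truth=truth,
        snp_matrix=snp_matrix,
        snp_positions=snp_positions,
    )


def _merged_genic_span(genes: dict[str, GenomicInterval], cfg: SimConfig) -> int:
    per_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in cfg.chrom_lengths}
    for iv in genes.values():
        per_chrom[iv.chrom].append((iv.start, iv.end))
    return sum(
        e - s for spans in per_chrom.values() for s, e in merge_spans(spans)
    )


def realized_coverage_ratio(output: SimOutput) -> float:
    """Intergenic / genic per-base PAV coverage of an output, from scratch."""
    from .partition import build_partition, summarize_partition

    partition = build_partition(output.genes, output.config.chrom_lengths)
    summary = summarize_partition(partition, output.pav_catalog)
    return (
        summary.rows["intergenic"].proportion / summary.rows["genic"].proportion
    )


def make_worked_fixtures() -> dict:
    """Hand-checkable micro-fixtures used in docs and unit tests."""
    three_record_vcf = "\n".join([
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1,length=100000>",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampleA\tsampleB",
        "chr1\t101\tdel1\tN\t<DEL>\t.\t.\tSVTYPE=DEL;END=200;SVLEN=-100\tGT\t0/0\t1/1",
        "chr1\t501\tdup1\tN\t<DUP>\t.\t.\tSVTYPE=DUP;END=750;SVLEN=250\tGT\t1/1\t0/1",
        "chr1\t1001\tinv1\tN\t<INV>\t.\t.\tSVTYPE=INV;END=1400;SVLEN=400\tGT\t./.\t0/0",
    ]) + "\n"
    # additive distances from the tree ((A:1,B:2):1,(C:3,D:1));
    four_taxon = pd.DataFrame(
        [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]],
        index=list("ABCD"), columns=list("ABCD"), dtype=float,
    )
    enrichment_2x2 = {"k": 8, "n": 10, "K": 10, "N": 100}
    return {
        "three_record_vcf": three_record_vcf,
        "four_taxon_distances": four_taxon,
        "enrichment_2x2": enrichment_2x2,
    }
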