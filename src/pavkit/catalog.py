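"""SV catalog data model and readers/writers.

A catalog holds typed structural variants (DEL/DUP/INV) with one presence
genotype per sample. Presence states are coded 0 (reference), 1
(non-reference) and MISSING (-1). Heterozygous diploid calls are collapsed
to MISSING: the target species is highly selfing, so residual heterozygous
genotype calls are treated as unreliable rather than as half-presence.

Coordinates are 0-based half-open internally; VCF POS/END (1-based
inclusive) are converted on the way in and out, so a record read from
POS=101, END=200 has interval [100, 200) and length 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

MISSING: int = -1
SV_TYPES = ("DEL", "DUP", "INV")

#: FORMAT keys probed (in order) for read-support counts when reading VCFs.
DEFAULT_SUPPORT_KEYS = ("SU", "PE", "SR")


@dataclass
class SVRecord:
    interval: GenomicInterval
    svtype: str
    genotypes: np.ndarray  # int8, one entry per catalog sample
    support: dict = field(default_factory=dict)
    record_id: str = "."

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    def non_missing(self) -> np.ndarray:
        return self.genotypes[self.genotypes != MISSING]

    def is_polymorphic(self) -> bool:
        g = self.non_missing()
        return g.size > 0 and bool(g.min() == 0 and g.max() == 1)


@dataclass
class SVCatalog:
    samples: list[str]
    records: list[SVRecord]
    genome: dict[str, int]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = len(self.samples)
        for rec in self.records:
            if rec.chrom not in self.genome:
                raise ValueError(f"record on unknown chromosome {rec.chrom!r}")
            if rec.interval.end > self.genome[rec.chrom]:
                raise ValueError(
                    f"record {rec.record_id} at {rec.interval} exceeds "
                    f"chromosome length {self.genome[rec.chrom]}"
                )
            if rec.genotypes.shape != (n,):
                raise ValueError(
                    f"record {rec.record_id}: {rec.genotypes.shape[0]} genotypes "
                    f"for {n} samples"
                )

    def __len__(self) -> int:
        return len(self.records)

    def genotype_matrix(self) -> np.ndarray:
        """Records x samples matrix of presence states (int8, -1 missing)."""
        if not self.records:
            return np.empty((0, len(self.samples)), dtype=np.int8)
        return np.stack([r.genotypes for r in self.records]).astype(np.int8)

    def class_counts(self) -> dict[str, int]:
        counts = {t: 0 for t in SV_TYPES}
        for rec in self.records:
            counts[rec.svtype] = counts.get(rec.svtype, 0) + 1
        return counts

    def total_count(self) -> int:
        """Sum of per-class counts; equals len(self) by construction."""
        return sum(self.class_counts().values())

    def sample_index(self, names: Sequence[str]) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([idx[n] for n in names], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in catalog") from None


@dataclass
class PopulationMap:
    sample_to_pop: dict[str, str]

    @property
    def populations(self) -> dict[str, list[str]]:
        pops: dict[str, list[str]] = {}
        for sample, pop in self.sample_to_pop.items():
            pops.setdefault(pop, []).append(sample)
        return pops

    def samples_of(self, population: str) -> list[str]:
        pops = self.populations
        if population not in pops:
            raise KeyError(f"population {population!r} not in population map")
        return pops[population]


def _collapse_gt(gt: tuple) -> int:
    """Diploid GT -> presence state. 0/0 -> 0, 1/1 -> 1, ./., 0/1 -> MISSING."""
    alleles = [a for a in gt if a is not None]
    if len(alleles) < len(gt) or not alleles:
        return MISSING
    first = alleles[0]
    if any(a != first for a in alleles):
        return MISSING  # heterozygous: unreliable in a selfing species
    return 1 if first >= 1 else 0


def read_sv_vcf(
    path: str | Path,
    genome: Mapping[str, int],
    support_keys: Sequence[str] = DEFAULT_SUPPORT_KEYS,
) -> SVCatalog:
    """Read an SV VCF (SVTYPE/END INFO, per-sample GT) into a catalog.

    Records whose SVTYPE is not DEL/DUP/INV are skipped; the skipped count
    is logged. Malformed records raise with the offending position named.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    records: list[SVRecord] = []
    skipped = 0
    for rec in vf:
        svtype = rec.info.get("SVTYPE")
        if svtype not in SV_TYPES:
            skipped += 1
            continue
        # htslib infers rec.stop from SVLEN (not END) when both are present,
        # off by one for symbolic alleles; trust SVLEN's magnitude directly.
        svlen = rec.info.get("SVLEN")
        if isinstance(svlen, tuple):
            svlen = svlen[0]
        end = rec.start + abs(int(svlen)) if svlen is not None else rec.stop
        try:
            interval = GenomicInterval(rec.chrom, rec.start, end)
        except ValueError as exc:
            raise ValueError(f"malformed record at {rec.chrom}:{rec.pos}: {exc}") from exc
        gts = np.array(
            [_collapse_gt(rec.samples[s].get("GT", (None,))) for s in samples],
            dtype=np.int8,
        )
        support: dict = {}
        for key in support_keys:
            vals = [rec.samples[s].get(key) for s in samples]
            if any(v is not None for v in vals):
                support[key] = [
                    (v[0] if isinstance(v, tuple) else v) for v in vals
                ]
        records.append(
            SVRecord(interval, svtype, gts, support, rec.id or ".")
        )
    vf.close()
    if skipped:
        logger.info("skipped %d records with unknown SVTYPE", skipped)
    return SVCatalog(samples=samples, records=records, genome=dict(genome))


def write_sv_vcf(catalog: SVCatalog, path: str | Path) -> None:
    """Write a catalog as VCF 4.2 with symbolic ALT alleles.

    Presence states map back to diploid GT: 0 -> 0/0, 1 -> 1/1,
    MISSING -> ./.; SVLEN is negative for deletions by convention.
    """
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for chrom, length in catalog.genome.items():
        header.contigs.add(chrom, length=length)
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("END", 1, "Integer", "End position of the variant")
    header.info.add("SVLEN", 1, "Integer", "Length of the variant")
    header.formats.add("GT", 1, "String", "Genotype")
    for key in DEFAULT_SUPPORT_KEYS:
        header.formats.add(key, 1, "Integer", f"{key} support count")
    for s in catalog.samples:
        header.add_sample(s)
    vf = pysam.VariantFile(str(path), "w", header=header)
    for i, rec in enumerate(catalog.records):
        out = vf.new_record(
            contig=rec.chrom,
            start=rec.interval.start,
            stop=rec.interval.end,
            alleles=("N", f"<{rec.svtype}>"),
            id=rec.record_id if rec.record_id != "." else f"sv{i}",
        )
        out.info["SVTYPE"] = rec.svtype
        out.info["SVLEN"] = -rec.length if rec.svtype == "DEL" else rec.length
        for j, s in enumerate(catalog.samples):
            g = int(rec.genotypes[j])
            out.samples[s]["GT"] = (
                (None, None) if g == MISSING else (g, g)
            )
            for key, vals in rec.support.items():
                if vals[j] is not None:
                    out.samples[s][key] = int(vals[j])
        vf.write(out)
    vf.close()


def filter_catalog(
    catalog: SVCatalog,
    svtypes: Iterable[str] | None = None,
    min_len: int = 1,
    max_len: int | None = None,
    polymorphic_only: bool = False,
) -> SVCatalog:
    """Subset a catalog by SV type, length window and polymorphism.

    The published analysis set corresponds to
    ``filter_catalog(cat, svtypes={"DEL"}, max_len=10_000, polymorphic_only=True)``:
    polymorphic presence/absence variants from 1 bp to 10 kb.
    """
    if max_len is not None and min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    type_set = set(svtypes) if svtypes is not None else None
    kept = []
    for rec in catalog.records:
        if type_set is not None and rec.svtype not in type_set:
            continue
        if rec.length < min_len:
            continue
        if max_len is not None and rec.length > max_len:
            continue
        if polymorphic_only and not rec.is_polymorphic():
            continue
        kept.append(rec)
    return SVCatalog(samples=list(catalog.samples), records=kept, genome=dict(catalog.genome))


def read_genome(path: str | Path) -> dict[str, int]:
    """Chromosome lengths from a FAI-style table (name, length, ...)."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1])
    return dict(zip(df[0].astype(str), df[1].astype(int)))


def read_annotation(gff_path: str | Path) -> dict[str, GenomicInterval]:
    """Gene intervals (0-based half-open) from GFF3 ``gene`` features."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, GenomicInterval] = {}
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        genes[feat.id] = GenomicInterval(feat.seqid, feat.start - 1, feat.end)
    return genes


def read_terms(
    table_path: str | Path,
    annotation: Mapping[str, GenomicInterval] | None = None,
) -> dict[str, set[str]]:
    """gene_id<TAB>term_id lines -> gene -> set of terms.

    Genes absent from the annotation are retained (they still belong to the
    enrichment universe) but warned about.
    """
    df = pd.read_csv(table_path, sep="\t", header=None, names=["gene", "term"])
    terms: dict[str, set[str]] = {}
    unknown = 0
    for gene, term in zip(df["gene"].astype(str), df["term"].astype(str)):
        if annotation is not None and gene not in annotation:
            unknown += 1
        terms.setdefault(gene, set()).add(term)
    if unknown:
        logger.warning("%d term assignments name genes absent from the annotation", unknown)
    return terms


def read_popmap(tsv_path: str | Path) -> PopulationMap:
    """sample<TAB>population lines -> PopulationMap."""
    df = pd.read_csv(tsv_path, sep="\t", header=None, names=["sample", "pop"])
    mapping: dict[str, str] = {}
    for sample, pop in zip(df["sample"].astype(str), df["pop"].astype(str)):
        if sample in mapping and mapping[sample] != pop:
            raise ValueError(f"sample {sample!r} assigned to two populations")
        mapping[sample] = pop
    return PopulationMap(mapping)
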