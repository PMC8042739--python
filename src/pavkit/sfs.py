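"""Ancestral-state polarization and unfolded site-frequency spectra.

Polarization uses a consensus over a small panel of deeply diverged
"polarizer" accessions (relict lineages): at each locus the majority allele
among the panel's non-missing presence calls is taken as ancestral. The
state is NA when more than one panel member is missing or when the panel
allele frequency is exactly 0.5 (evaluated over the informative members).

The unfolded SFS of a population counts, per polymorphic locus, how many
population members carry the derived (non-ancestral) allele; spectra are
reported per genomic class (whole genome / intergenic / genic / defense).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .catalog import MISSING, PopulationMap, SVCatalog
from .intervals import GenomicInterval

ANCESTRAL_NA: int = -9


@dataclass
class PolarizedCatalog:
    catalog: SVCatalog
    polarizer_samples: list[str]
    #: per record: 0 = reference allele ancestral, 1 = alternate ancestral,
    #: ANCESTRAL_NA = unassigned
    ancestral: np.ndarray
    #: per record: (n_ref, n_alt, n_missing) among polarizers
    polarizer_counts: np.ndarray

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "record_id": [r.record_id for r in self.catalog.records],
                "ancestral": self.ancestral,
                "polarizer_ref": self.polarizer_counts[:, 0],
                "polarizer_alt": self.polarizer_counts[:, 1],
                "polarizer_missing": self.polarizer_counts[:, 2],
            }
        )


@dataclass
class SpectrumTable:
    population: str
    class_name: str
    n: int                     # population sample size
    counts: np.ndarray         # index k-1 holds count of sites with k derived copies
    sites_used: int
    sites_dropped: int
    drop_reasons: dict[str, int] = field(default_factory=dict)

    @property
    def proportions(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total

    def to_frame(self) -> pd.DataFrame:
        ks = np.arange(1, self.n)
        return pd.DataFrame(
            {
                "population": self.population,
                "class": self.class_name,
                "k": ks,
                "count": self.counts,
                "proportion": self.proportions,
            }
        )


def polarize(catalog: SVCatalog, polarizer_samples: Sequence[str]) -> PolarizedCatalog:
    """Assign per-record ancestral states from the polarizer consensus."""
    idx = catalog.sample_index(polarizer_samples)
    n_rec = len(catalog.records)
    ancestral = np.full(n_rec, ANCESTRAL_NA, dtype=np.int8)
    counts = np.zeros((n_rec, 3), dtype=int)
    max_missing = 1
    for r, rec in enumerate(catalog.records):
        g = rec.genotypes[idx]
        n_miss = int((g == MISSING).sum())
        n_alt = int((g == 1).sum())
        n_ref = int((g == 0).sum())
        counts[r] = (n_ref, n_alt, n_miss)
        if n_miss > max_missing:
            continue
        informative = n_ref + n_alt
        if informative == 0 or n_ref == n_alt:  # frequency exactly 0.5 -> NA
            continue
        ancestral[r] = 0 if n_ref > n_alt else 1
    return PolarizedCatalog(
        catalog=catalog,
        polarizer_samples=list(polarizer_samples),
        ancestral=ancestral,
        polarizer_counts=counts,
    )


def class_intervals_from_annotation(
    genes: Mapping[str, GenomicInterval],
    terms: Mapping[str, set[str]] | None = None,
    defense_term: str | None = None,
) -> dict[str, list[GenomicInterval] | None]:
    """Class -> interval set used for SFS/record classification.

    ``whole_genome`` is encoded as None (no restriction); ``genic`` is all
    gene intervals; ``defense`` is the genes carrying ``defense_term``.
    Intergenic membership is the complement (no genic overlap) and is
    resolved per record by :func:`classify_records`.
    """
    classes: dict[str, list[GenomicInterval] | None] = {
        "whole_genome": None,
        "genic": list(genes.values()),
    }
    if terms is not None and defense_term is not None:
        classes["defense"] = [
            iv for gene, iv in genes.items()
            if defense_term in terms.get(gene, set())
        ]
    return classes


def _overlap_mask(catalog: SVCatalog, intervals: Sequence[GenomicInterval]) -> np.ndarray:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    mask = np.zeros(len(catalog.records), dtype=bool)
    for i, rec in enumerate(catalog.records):
        tree = trees.get(rec.chrom)
        if tree is not None and tree.overlap(rec.interval.start, rec.interval.end):
            mask[i] = True
    return mask


def classify_records(
    catalog: SVCatalog,
    class_intervals: Mapping[str, Sequence[GenomicInterval] | None],
) -> dict[str, np.ndarray]:
    """Boolean record mask per class; membership is >= 1 bp overlap.

    If the mapping contains ``genic``, an ``intergenic`` mask (its
    complement) is added automatically.
    """
    masks: dict[str, np.ndarray] = {}
    for name, intervals in class_intervals.items():
        if intervals is None:
            masks[name] = np.ones(len(catalog.records), dtype=bool)
        else:
            masks[name] = _overlap_mask(catalog, intervals)
    if "genic" in masks and "intergenic" not in masks:
        masks["intergenic"] = ~masks["genic"]
    return masks


def unfolded_sfs(
    polarized: PolarizedCatalog,
    popmap: PopulationMap,
    population: str,
    record_mask: np.ndarray | None = None,
    class_name: str = "whole_genome",
    min_call_rate: float = 0.8,
) -> SpectrumTable:
    """Unfolded SFS for one population over one record class.

    Per locus the derived count is the number of population samples whose
    non-missing call differs from the ancestral state. Loci are dropped
    (and tallied) when the ancestral state is NA, the within-population
    call rate falls below ``min_call_rate``, or the locus is monomorphic
    within the population (derived count 0 or equal to the informative
    sample count). Bins are raw derived counts k = 1..n-1.
    """
    samples = popmap.samples_of(population)
    idx = polarized.catalog.sample_index(samples)
    n = len(samples)
    counts = np.zeros(max(n - 1, 0), dtype=int)
    used = 0
    reasons = {"ancestral_na": 0, "low_call_rate": 0, "monomorphic": 0}
    geno = polarized.catalog.genotype_matrix()[:, idx] if len(polarized.catalog.records) else np.empty((0, n), dtype=np.int8)
    records_iter = range(geno.shape[0])
    if record_mask is not None:
        records_iter = np.flatnonzero(record_mask)
    for r in records_iter:
        anc = polarized.ancestral[r]
        if anc == ANCESTRAL_NA:
            reasons["ancestral_na"] += 1
            continue
        g = geno[r]
        informative = g != MISSING
        m = int(informative.sum())
        if m < min_call_rate * n:
            reasons["low_call_rate"] += 1
            continue
        derived = int((g[informative] != anc).sum())
        if derived == 0 or derived == m:
            reasons["monomorphic"] += 1
            continue
        counts[derived - 1] += 1
        used += 1
    return SpectrumTable(
        population=population,
        class_name=class_name,
        n=n,
        counts=counts,
        sites_used=used,
        sites_dropped=sum(reasons.values()),
        drop_reasons=reasons,
    )


def sfs_tables(
    polarized: PolarizedCatalog,
    popmap: PopulationMap,
    class_intervals: Mapping[str, Sequence[GenomicInterval] | None],
    min_call_rate: float = 0.8,
) -> pd.DataFrame:
    """All populations x classes, as one long-format table."""
    masks = classify_records(polarized.catalog, class_intervals)
    frames = []
    for population in popmap.populations:
        for class_name, mask in masks.items():
            table = unfolded_sfs(
                polarized, popmap, population,
                record_mask=mask, class_name=class_name,
                min_call_rate=min_call_rate,
            )
            frames.append(table.to_frame())
    return pd.concat(frames, ignore_index=True)
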