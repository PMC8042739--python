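"""Genic/intergenic genome partition and PAV base-count enrichment.

Any base covered by at least one annotated gene is genic; everything else
is intergenic, so the two partitions are disjoint and jointly cover the
genome. PAV coverage is counted on bases, not records: the enrichment test
is a Pearson chi-square on the 2x2 table of {genic, intergenic} x
{PAV-covered, not covered} base totals, which is the scale on which a
genome-sized deficit of genic PAVs becomes a ~1e7 statistic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .catalog import SVCatalog
from .intervals import (
    GenomicInterval,
    Span,
    complement_spans,
    intersect_spans,
    merge_spans,
)


@dataclass
class GenomePartition:
    genome: dict[str, int]
    genic: dict[str, list[Span]]       # merged, non-overlapping
    intergenic: dict[str, list[Span]]  # complement within chromosome bounds

    @property
    def genic_bases(self) -> int:
        return sum(e - s for spans in self.genic.values() for s, e in spans)

    @property
    def intergenic_bases(self) -> int:
        return sum(e - s for spans in self.intergenic.values() for s, e in spans)

    @property
    def total_bases(self) -> int:
        return sum(self.genome.values())


@dataclass
class PartitionRow:
    partition: str
    span: int
    n_pavs: int
    mean_length: float
    median_length: float
    pav_bases: int
    proportion: float


@dataclass
class PartitionSummary:
    rows: dict[str, PartitionRow] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [vars(r) for r in self.rows.values()]
        ).set_index("partition")


@dataclass
class EnrichmentTest:
    table: np.ndarray  # rows {genic, intergenic} x cols {covered, not covered}
    chi2: float
    df: int
    p: float
    fold: float

    def p_display(self, floor: float = 1e-16) -> str:
        """p for reporting; values below the floor print as '< 1E-16'."""
        return f"< {floor:.0E}" if self.p < floor else f"{self.p:.2E}"

    def chi2_display(self, sig: int = 2) -> str:
        """chi2 truncated to `sig` significant figures, e.g. '1.8E7'."""
        return truncate_sig(self.chi2, sig)


def truncate_sig(x: float, sig: int = 2) -> str:
    """Format ``x`` truncated (not rounded) to ``sig`` significant figures."""
    if x == 0 or not math.isfinite(x):
        return str(x)
    exp = math.floor(math.log10(abs(x)))
    scaled = abs(x) / 10 ** exp
    trunc = math.floor(scaled * 10 ** (sig - 1)) / 10 ** (sig - 1)
    mantissa = f"{trunc:.{sig - 1}f}".rstrip("0").rstrip(".")
    sign = "-" if x < 0 else ""
    return f"{sign}{mantissa}E{exp}"


def build_partition(
    genes: Mapping[str, GenomicInterval] | list[GenomicInterval],
    genome: Mapping[str, int],
) -> GenomePartition:
    """Merge gene intervals per chromosome and complement into intergenic."""
    intervals = list(genes.values()) if isinstance(genes, Mapping) else list(genes)
    per_chrom: dict[str, list[Span]] = {c: [] for c in genome}
    for iv in intervals:
        if iv.chrom not in genome:
            raise ValueError(f"gene on unknown chromosome {iv.chrom!r}")
        if iv.end > genome[iv.chrom]:
            raise ValueError(f"gene {iv} exceeds chromosome bounds")
        per_chrom[iv.chrom].append((iv.start, iv.end))
    genic = {c: merge_spans(spans) for c, spans in per_chrom.items()}
    intergenic = {
        c: complement_spans(genic[c], genome[c]) for c in genome
    }
    return GenomePartition(genome=dict(genome), genic=genic, intergenic=intergenic)


def _summarize_one(
    name: str,
    part_spans: dict[str, list[Span]],
    catalog: SVCatalog,
) -> PartitionRow:
    span = sum(e - s for spans in part_spans.values() for s, e in spans)
    lengths: list[int] = []
    covered: dict[str, list[Span]] = {c: [] for c in part_spans}
    for rec in catalog.records:
        hits = intersect_spans(
            [(rec.interval.start, rec.interval.end)],
            part_spans.get(rec.chrom, []),
        )
        if hits:
            lengths.append(rec.length)
            covered[rec.chrom].extend(hits)
    pav_bases = sum(
        e - s for c in covered for s, e in merge_spans(covered[c])
    )
    return PartitionRow(
        partition=name,
        span=span,
        n_pavs=len(lengths),
        mean_length=float(np.mean(lengths)) if lengths else float("nan"),
        median_length=float(np.median(lengths)) if lengths else float("nan"),
        pav_bases=pav_bases,
        proportion=pav_bases / span if span else float("nan"),
    )


def summarize_partition(partition: GenomePartition, catalog: SVCatalog) -> PartitionSummary:
    """Per-partition PAV accounting.

    A record counts toward every partition it overlaps by >= 1 base (so a
    boundary-spanning PAV appears in both rows and row counts may exceed the
    catalog size); ``pav_bases`` is the union of covered bases, not a sum of
    record lengths.
    """
    whole = {c: [(0, n)] for c, n in partition.genome.items()}
    summary = PartitionSummary()
    for name, spans in (
        ("whole_genome", whole),
        ("intergenic", partition.intergenic),
        ("genic", partition.genic),
    ):
        summary.rows[name] = _summarize_one(name, spans, catalog)
    return summary


def enrichment_chisq(summary: PartitionSummary) -> EnrichmentTest:
    """Pearson chi-square (no continuity correction) on base counts.

    fold = intergenic covered proportion / genic covered proportion; > 1
    means PAVs concentrate outside genes, the purifying-selection signature.
    """
    g = summary.rows["genic"]
    i = summary.rows["intergenic"]
    table = np.array(
        [[g.pav_bases, g.span - g.pav_bases], [i.pav_bases, i.span - i.pav_bases]],
        dtype=float,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        import warnings

        warnings.warn("degenerate 2x2 margin; chi-square undefined")
        return EnrichmentTest(table, float("nan"), 1, float("nan"), float("nan"))
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    chi2 = float(((table - expected) ** 2 / expected).sum())
    p = float(chi2_dist.sf(chi2, 1))
    fold = (
        (i.proportion / g.proportion) if g.proportion > 0 else float("inf")
    )
    return EnrichmentTest(table=table, chi2=chi2, df=1, p=p, fold=fold)


def density_track(catalog: SVCatalog, window: int = 100_000) -> pd.DataFrame:
    """Per-window PAV covered-base density, for plotting only."""
    rows = []
    per_chrom: dict[str, list[Span]] = {}
    for rec in catalog.records:
        per_chrom.setdefault(rec.chrom, []).append(
            (rec.interval.start, rec.interval.end)
        )
    for chrom, length in catalog.genome.items():
        merged = merge_spans(per_chrom.get(chrom, []))
        for start in range(0, length, window):
            end = min(start + window, length)
            cov = sum(
                e - s for s, e in intersect_spans(merged, [(start, end)])
            )
            rows.append(
                {"chrom": chrom, "start": start, "end": end,
                 "density": cov / (end - start)}
            )
    return pd.DataFrame(rows)


def enrichment_to_json(test: EnrichmentTest) -> str:
    return json.dumps(
        {
            "table": test.table.astype(int).tolist(),
            "chi2": test.chi2,
            "chi2_display": test.chi2_display(),
            "df": test.df,
            "p": test.p,
            "p_display": test.p_display(),
            "fold": test.fold,
        },
        indent=2,
    )
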