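"""Term enrichment for PAV-bearing (or PAV-free) gene sets.

Two routes with different null models:

* :func:`fisher_enrichment` — one-tailed Fisher's exact test per term
  (hypergeometric upper tail) over genes, with Benjamini–Hochberg
  correction. Treats genes as exchangeable units.
* :func:`permutation_enrichment` — a variant-resampling test in the style
  of Gowinda: the statistic is the number of distinct term genes hit by the
  candidate variants, and the null redraws equally many variants from the
  full variant set. Long genes and clustered gene families soak up more
  random variants, so the permutation p is conservative exactly where the
  Fisher test is anti-conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .catalog import SVRecord
from .intervals import GenomicInterval


@dataclass
class TermUniverse:
    gene_terms: dict[str, set[str]]
    universe: list[str]
    term_genes: dict[str, set[str]] = field(init=False)

    def __post_init__(self) -> None:
        in_universe = set(self.universe)
        missing = set(self.gene_terms) - in_universe
        if missing:
            # genes with terms but outside the universe are ignored
            self.gene_terms = {
                g: t for g, t in self.gene_terms.items() if g in in_universe
            }
        index: dict[str, set[str]] = {}
        for gene, terms in self.gene_terms.items():
            for term in terms:
                index.setdefault(term, set()).add(gene)
        self.term_genes = index


def benjamini_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up, monotone, input order preserved."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def fisher_enrichment(
    study_genes: Iterable[str],
    universe: TermUniverse,
) -> pd.DataFrame:
    """One-tailed Fisher enrichment of every term in the study gene set.

    Columns: term, k (study genes with term), n (study genes), K (universe
    genes with term), N (universe size), enrichment_score = (k/n)/(K/N),
    p (hypergeometric upper tail), p_adjusted (BH across terms).
    """
    study = set(study_genes) & set(universe.universe)
    n = len(study)
    N = len(universe.universe)
    rows = []
    for term in sorted(universe.term_genes):
        genes = universe.term_genes[term]
        K = len(genes)
        k = len(genes & study)
        score = (k / n) / (K / N) if n and K else 0.0
        p = float(hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        rows.append(
            {"term": term, "k": k, "n": n, "K": K, "N": N,
             "enrichment_score": score, "p": p}
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_adjusted"] = benjamini_adjust(df["p"].to_numpy())
    return df


def _variant_gene_hits(
    variants: Sequence[SVRecord] | Sequence[GenomicInterval],
    gene_intervals: Mapping[str, GenomicInterval],
) -> list[list[int]]:
    """Per-variant list of gene indices overlapped (>= 1 bp)."""
    gene_names = list(gene_intervals)
    trees: dict[str, IntervalTree] = {}
    for gi, gene in enumerate(gene_names):
        iv = gene_intervals[gene]
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, gi)
    hits: list[list[int]] = []
    for v in variants:
        iv = v.interval if isinstance(v, SVRecord) else v
        tree = trees.get(iv.chrom)
        if tree is None:
            hits.append([])
        else:
            hits.append(sorted(h.data for h in tree.overlap(iv.start, iv.end)))
    return hits


def permutation_enrichment(
    candidate_variants: Sequence[SVRecord] | Sequence[GenomicInterval],
    all_variants: Sequence[SVRecord] | Sequence[GenomicInterval],
    gene_intervals: Mapping[str, GenomicInterval],
    universe: TermUniverse,
    n_perms: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-mode permutation enrichment over terms.

    Observed statistic per term: distinct genes carrying the term that are
    overlapped by >= 1 candidate variant. Each permutation redraws
    ``len(candidate_variants)`` variants from ``all_variants`` without
    replacement and recomputes; empirical p is add-one corrected and BH
    adjusted across testable terms. Terms with no gene in the universe are
    skipped.
    """
    gene_names = list(gene_intervals)
    gene_pos = {g: i for i, g in enumerate(gene_names)}
    terms = [t for t in sorted(universe.term_genes) if universe.term_genes[t]]
    # gene index -> term indices
    term_pos = {t: i for i, t in enumerate(terms)}
    gene_term_idx: list[list[int]] = [[] for _ in gene_names]
    for t in terms:
        for g in universe.term_genes[t]:
            if g in gene_pos:
                gene_term_idx[gene_pos[g]].append(term_pos[t])
    all_hits = _variant_gene_hits(all_variants, gene_intervals)
    cand_hits = _variant_gene_hits(candidate_variants, gene_intervals)
    n_cand = len(cand_hits)
    if n_cand > len(all_hits):
        raise ValueError("candidate set larger than the variant universe")

    def term_counts(hit_lists: Iterable[list[int]]) -> np.ndarray:
        genes_hit: set[int] = set()
        for h in hit_lists:
            genes_hit.update(h)
        counts = np.zeros(len(terms), dtype=int)
        for g in genes_hit:
            for ti in gene_term_idx[g]:
                counts[ti] += 1
        return counts

    observed = term_counts(cand_hits)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms), dtype=int)
    n_all = len(all_hits)
    for _ in range(n_perms):
        draw = rng.choice(n_all, size=n_cand, replace=False)
        perm = term_counts(all_hits[i] for i in draw)
        exceed += perm >= observed
    pvals = (1 + exceed) / (1 + n_perms)
    df = pd.DataFrame(
        {
            "term": terms,
            "observed_genes": observed,
            "K": [len(universe.term_genes[t]) for t in terms],
            "p": pvals,
        }
    )
    df["p_adjusted"] = benjamini_adjust(df["p"].to_numpy())
    return df


def pav_bearing_genes(
    variants: Sequence[SVRecord] | Sequence[GenomicInterval],
    gene_intervals: Mapping[str, GenomicInterval],
) -> set[str]:
    """Genes overlapped by >= 1 variant."""
    gene_names = list(gene_intervals)
    hits = _variant_gene_hits(variants, gene_intervals)
    out: set[str] = set()
    for h in hits:
        out.update(gene_names[i] for i in h)
    return out


def pav_free_genes(
    variants: Sequence[SVRecord] | Sequence[GenomicInterval],
    gene_intervals: Mapping[str, GenomicInterval],
) -> set[str]:
    """Genes never overlapped by any variant (the 'core genome' study set)."""
    return set(gene_intervals) - pav_bearing_genes(variants, gene_intervals)
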