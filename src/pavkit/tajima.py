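"""Tajima's D on presence/absence genotype matrices and the
matched-resampling test for intermediate-frequency excess.

D contrasts two estimators of the population mutation rate: mean pairwise
diversity (theta_pi) and the normalized segregating-site count (theta_W =
S/a1). An excess of intermediate-frequency variants — the footprint of
balancing selection — pushes D positive; an excess of rare variants pushes
it negative.

Genotype matrices are sites x samples with entries 0/1 and MISSING (-1).
With missing data, each site's heterozygosity term uses its own informative
sample count m with the unbiased m/(m-1) factor, and the sample size
plugged into the normalizing constants is the median informative count
across sites.

The significance test for a focal gene class (e.g. defense-response PAVs)
draws size-matched subsets of the genic variant universe, recomputes D for
each, and reports an add-one-corrected upper-tail empirical p — a direct
Monte Carlo analogue of asking how often a random genic subset looks as
shifted toward intermediate frequencies as the focal class does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .catalog import MISSING
from .intervals import GenomicInterval


@dataclass(frozen=True)
class TajimaConstants:
    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


@lru_cache(maxsize=None)
def tajima_constants(n: int) -> TajimaConstants:
    """Normalizing constants of Tajima's D for sample size n (n >= 2)."""
    if n < 2:
        raise ValueError("constants require n >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


@dataclass
class TajimaResult:
    n: int
    S: int
    theta_pi: float
    theta_w: float
    D: float

    @property
    def is_na(self) -> bool:
        return not np.isfinite(self.D)


@dataclass
class SiteStats:
    """Per-site sufficient statistics for fast subset D computation."""

    pi_contrib: np.ndarray   # 2 p (1-p) m/(m-1) per site (0 if monomorphic)
    polymorphic: np.ndarray  # bool
    m: np.ndarray            # informative sample count per site

    def __len__(self) -> int:
        return self.pi_contrib.shape[0]


def site_stats(matrix: np.ndarray) -> SiteStats:
    """Sufficient statistics from a sites x samples 0/1/MISSING matrix."""
    matrix = np.asarray(matrix)
    informative = matrix != MISSING
    m = informative.sum(axis=1)
    ones = np.where(informative, matrix, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(m > 0, ones / np.maximum(m, 1), 0.0)
        contrib = 2.0 * p * (1.0 - p) * m / np.maximum(m - 1, 1)
    polymorphic = (ones > 0) & (ones < m) & (m >= 2)
    contrib = np.where(polymorphic, contrib, 0.0)
    return SiteStats(pi_contrib=contrib, polymorphic=polymorphic, m=m.astype(int))


def _d_from_sums(theta_pi: float, S: int, n: int) -> TajimaResult:
    if S == 0 or n < 4:
        return TajimaResult(n=n, S=S, theta_pi=theta_pi,
                            theta_w=float("nan"), D=float("nan"))
    c = tajima_constants(n)
    theta_w = S / c.a1
    var = c.e1 * S + c.e2 * S * (S - 1)
    D = (theta_pi - theta_w) / np.sqrt(var)
    return TajimaResult(n=n, S=S, theta_pi=theta_pi, theta_w=theta_w, D=float(D))


def tajimas_d(matrix: np.ndarray) -> TajimaResult:
    """Tajima's D for a sites x samples presence matrix.

    Returns an NA result (D = nan) rather than raising when there are no
    segregating sites or fewer than 4 informative samples.
    """
    stats = site_stats(matrix)
    S = int(stats.polymorphic.sum())
    theta_pi = float(stats.pi_contrib.sum())
    if S == 0:
        return _d_from_sums(theta_pi, 0, 0)
    n = int(np.median(stats.m))
    return _d_from_sums(theta_pi, S, n)


@dataclass
class ResamplingResult:
    observed_D: float
    null_Ds: np.ndarray
    n_reps: int
    empirical_p: float
    seed: int

    def null_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rep": np.arange(self.n_reps), "D": self.null_Ds})


def _subset_Ds(stats: SiteStats, draws: np.ndarray) -> np.ndarray:
    """D per row of ``draws`` (reps x k site-index matrix), vectorized."""
    pi = stats.pi_contrib[draws].sum(axis=1)
    S = stats.polymorphic[draws].sum(axis=1)
    n = np.median(stats.m[draws], axis=1)
    n = np.floor(n).astype(int)  # median of ints may be x.5; floor keeps it an int n
    Ds = np.full(draws.shape[0], np.nan)
    for n_val in np.unique(n):
        sel = (n == n_val) & (S > 0) & (n >= 4)
        if not sel.any():
            continue
        c = tajima_constants(int(n_val))
        S_sel = S[sel].astype(float)
        var = c.e1 * S_sel + c.e2 * S_sel * (S_sel - 1)
        Ds[sel] = (pi[sel] - S_sel / c.a1) / np.sqrt(var)
    return Ds


def matched_resampling_test(
    genic_matrix: np.ndarray,
    focal_matrix: np.ndarray,
    n_reps: int = 100_000,
    seed: int = 0,
) -> ResamplingResult:
    """Empirical upper-tail p for the focal class's Tajima's D.

    Each replicate draws ``focal`` many sites uniformly without replacement
    from the genic universe and recomputes D; the p value is
    (1 + #{null D >= observed}) / (1 + n_reps), one-sided in the direction
    of intermediate-frequency excess. nan replicates (no segregating sites
    in a draw) never count as exceedances.
    """
    if n_reps < 100:
        warnings.warn("fewer than 100 replicates: empirical p is unstable")
    k = np.asarray(focal_matrix).shape[0]
    universe = np.asarray(genic_matrix)
    if universe.shape[0] < k:
        raise ValueError(
            f"genic universe ({universe.shape[0]} sites) smaller than focal set ({k})"
        )
    observed = tajimas_d(focal_matrix).D
    stats = site_stats(universe)
    rng = np.random.default_rng(seed)
    # vectorized without-replacement draws: argpartition of uniform keys,
    # chunked to bound memory at ~chunk x universe floats
    chunk = max(1, min(n_reps, 20_000_000 // max(len(stats), 1)))
    parts = []
    done = 0
    while done < n_reps:
        b = min(chunk, n_reps - done)
        keys = rng.random((b, len(stats)))
        draws = np.argpartition(keys, k - 1, axis=1)[:, :k]
        parts.append(_subset_Ds(stats, draws))
        done += b
    null_Ds = np.concatenate(parts)
    exceed = int(np.nansum(null_Ds >= observed)) if np.isfinite(observed) else n_reps
    p = (1 + exceed) / (1 + n_reps)
    return ResamplingResult(
        observed_D=float(observed),
        null_Ds=null_Ds,
        n_reps=n_reps,
        empirical_p=float(p),
        seed=seed,
    )


@dataclass
class TailEnrichmentResult:
    table: np.ndarray  # rows {tail genes, non-tail genes} x cols {focal, other}
    odds_ratio: float
    p: float
    tail_fraction: float
    n_tail_snps: int


def tail_enrichment(
    score_table: pd.DataFrame,
    gene_intervals: dict[str, GenomicInterval],
    focal_genes: set[str],
    tail_fraction: float = 0.05,
) -> TailEnrichmentResult:
    """Focal-gene enrichment in the extreme upper tail of a per-SNP score.

    ``score_table`` needs columns chrom, pos (1-based), score. SNPs in the
    top ``tail_fraction`` by score are intersected with genes; the test is
    a one-tailed Fisher (hypergeometric upper tail) of focal-gene
    membership among tail genes against the full gene universe.
    """
    if not 0 < tail_fraction < 1:
        raise ValueError("tail_fraction must be in (0, 1)")
    df = score_table.sort_values("score", ascending=False)
    n_tail = max(1, int(round(tail_fraction * len(df))))
    tail = df.head(n_tail)
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for gene, iv in gene_intervals.items():
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, gene)
    tail_genes: set[str] = set()
    for chrom, pos in zip(tail["chrom"], tail["pos"]):
        tree = trees.get(str(chrom))
        if tree is None:
            continue
        for hit in tree.at(int(pos) - 1):
            tail_genes.add(hit.data)
    universe = set(gene_intervals)
    focal = focal_genes & universe
    k = len(tail_genes & focal)
    n = len(tail_genes)
    K = len(focal)
    N = len(universe)
    p = float(hypergeom.sf(k - 1, N, K, n)) if n else 1.0
    a, b = k, n - k
    c_, d_ = K - k, (N - K) - (n - k)
    odds = (a * d_) / (b * c_) if b * c_ > 0 else float("inf")
    table = np.array([[a, b], [c_, d_]])
    return TailEnrichmentResult(
        table=table, odds_ratio=float(odds), p=p,
        tail_fraction=tail_fraction, n_tail_snps=n_tail,
    )
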