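"""PAV distance matrices, neighbor-joining trees, and tag-SNP r².

The distance between two accessions is the allele-sharing mismatch
proportion over pairwise-complete presence calls. Neighbor joining follows
the classical Saitou–Nei/Studier–Keppler agglomeration with the Q
criterion, deterministic tie-break by first (row-major) minimum, so the
same matrix always yields the same tree. r² between a PAV and a SNP is the
squared Pearson correlation of their presence vectors over samples where
both are called; a PAV's tag SNP is the r²-maximizing SNP within a window
around the PAV midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import MISSING, SVCatalog


@dataclass
class DistanceMatrix:
    samples: list[str]
    matrix: np.ndarray           # symmetric, zero diagonal, entries in [0,1] or nan
    informative: np.ndarray      # pairwise informative-site counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.samples, columns=self.samples)


def pav_distance(
    catalog_or_matrix: SVCatalog | np.ndarray,
    samples: list[str] | None = None,
) -> DistanceMatrix:
    """Allele-sharing distance with pairwise deletion.

    d(i, j) = (# sites with differing presence states) / (# sites where
    both are non-missing); nan when no site is informative for a pair.
    """
    if isinstance(catalog_or_matrix, SVCatalog):
        mat = catalog_or_matrix.genotype_matrix()
        names = list(catalog_or_matrix.samples)
        if samples is not None:
            idx = catalog_or_matrix.sample_index(samples)
            mat = mat[:, idx]
            names = list(samples)
    else:
        mat = np.asarray(catalog_or_matrix)
        names = samples if samples is not None else [f"s{i}" for i in range(mat.shape[1])]
    called = (mat != MISSING).astype(np.float64)       # sites x samples
    vals = np.where(mat != MISSING, mat, 0).astype(np.float64)
    # informative(i,j) = sum_s called_i called_j ; mismatches via xor on called sites
    informative = called.T @ called
    agree_ones = vals.T @ vals
    agree_zeros = (called - vals).T @ (called - vals)
    mism = informative - agree_ones - agree_zeros
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(informative > 0, mism / informative, np.nan)
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(
        samples=names,
        matrix=dist,
        informative=informative.astype(int),
    )


class _Node:
    __slots__ = ("name", "children")

    def __init__(self, name=None, children=None):
        self.name = name
        self.children = children or []  # list of (node, branch_length)

    def newick(self, clamp_negative: bool = True) -> str:
        def fmt(node: "_Node", length: float | None) -> str:
            if node.children:
                inner = ",".join(fmt(c, bl) for c, bl in node.children)
                s = f"({inner})"
            else:
                s = node.name
            if length is not None:
                bl = max(length, 0.0) if clamp_negative else length
                s += f":{bl:.6g}"
            return s

        return fmt(self, None) + ";"


@dataclass
class UnrootedTree:
    root: _Node
    samples: list[str]
    raw_branch_lengths: dict[tuple[str, ...], float]

    def newick(self, clamp_negative: bool = True) -> str:
        return self.root.newick(clamp_negative=clamp_negative)

    def write(self, path: str | Path, clamp_negative: bool = True) -> None:
        Path(path).write_text(self.newick(clamp_negative=clamp_negative) + "\n")


def neighbor_joining(distances: DistanceMatrix) -> UnrootedTree:
    """Neighbor joining on a distance matrix (>= 3 samples).

    Iteratively joins the pair minimizing
    Q(i, j) = (N - 2) d(i, j) - r_i - r_j; ties resolve to the first pair
    in row-major (lexicographic index) order. Branch lengths may come out
    negative on non-additive data; they are retained raw on the tree and
    clamped to zero at Newick export by default.
    """
    names = list(distances.samples)
    if len(names) < 3:
        raise ValueError("neighbor joining needs at least 3 samples")
    D = np.array(distances.matrix, dtype=float)
    if np.isnan(D).any():
        raise ValueError("distance matrix contains undefined (nan) entries")
    nodes: list[_Node] = [_Node(name=n) for n in names]
    raw: dict[tuple[str, ...], float] = {}

    def leaf_set(node: _Node) -> tuple[str, ...]:
        if not node.children:
            return (node.name,)
        out: list[str] = []
        for c, _ in node.children:
            out.extend(leaf_set(c))
        return tuple(sorted(out))

    while len(nodes) > 3:
        N = len(nodes)
        r = D.sum(axis=1)
        Q = (N - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)  # first minimum = lexicographic
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (N - 2))
        lj = D[i, j] - li
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        raw[leaf_set(nodes[i])] = li
        raw[leaf_set(nodes[j])] = lj
        d_new = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(N) if k not in (i, j)]
        D2 = np.empty((N - 1, N - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = d_new[keep]
        D2[:-1, -1] = d_new[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
    # resolve the final three nodes around an unrooted center
    a, b, c = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    for node, length in ((a, la), (b, lb), (c, lc)):
        raw[leaf_set(node)] = length
    center = _Node(children=[(a, la), (b, lb), (c, lc)])
    return UnrootedTree(root=center, samples=names, raw_branch_lengths=raw)


@dataclass
class TagReport:
    table: pd.DataFrame     # per focal PAV: best SNP index/id, best r², n SNPs in window
    window_bp: int
    mean_r2: float
    sd_r2: float
    n_without_snp: int


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 3:
        return float("nan")
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    if xv.std() == 0 or yv.std() == 0:
        return float("nan")
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def best_tag_snp(
    pav_genotypes: np.ndarray,
    pav_positions: pd.DataFrame,
    snp_genotypes: np.ndarray,
    snp_positions: pd.DataFrame,
    window_bp: int = 10_000,
) -> TagReport:
    """Best-r² SNP within ``window_bp`` of each focal PAV's midpoint.

    Position frames need columns chrom and pos (PAV pos = midpoint);
    genotype arrays are sites x samples over the same sample ordering.
    PAVs with no SNP in the window get a nan entry and are excluded from
    the summary mean/SD, with the count reported.
    """
    rows = []
    snp_by_chrom: dict[str, np.ndarray] = {
        chrom: np.flatnonzero((snp_positions["chrom"] == chrom).to_numpy())
        for chrom in snp_positions["chrom"].unique()
    }
    snp_pos = snp_positions["pos"].to_numpy()
    for i in range(pav_genotypes.shape[0]):
        chrom = pav_positions["chrom"].iloc[i]
        mid = pav_positions["pos"].iloc[i]
        cand = snp_by_chrom.get(chrom, np.empty(0, dtype=int))
        cand = cand[np.abs(snp_pos[cand] - mid) <= window_bp]
        best_r2 = float("nan")
        best_snp = -1
        for si in cand:
            r2 = _pairwise_r2(pav_genotypes[i], snp_genotypes[si])
            if np.isnan(r2):
                continue
            if np.isnan(best_r2) or r2 > best_r2:
                best_r2 = r2
                best_snp = int(si)
        rows.append(
            {"pav": i, "chrom": chrom, "pos": mid,
             "best_snp": best_snp, "best_r2": best_r2,
             "n_snps_in_window": int(cand.size)}
        )
    table = pd.DataFrame(rows)
    valid = table["best_r2"].dropna()
    return TagReport(
        table=table,
        window_bp=window_bp,
        mean_r2=float(valid.mean()) if len(valid) else float("nan"),
        sd_r2=float(valid.std(ddof=1)) if len(valid) > 1 else float("nan"),
        n_without_snp=int(table["best_r2"].isna().sum()),
    )
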