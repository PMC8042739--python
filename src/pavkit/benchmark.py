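"""SV truth-set simulation and reciprocal-overlap benchmarking.

The simulator plants non-overlapping deletions, tandem duplications and
inversions into a reference sequence (plus optional background point
substitutions) and emits the mutated sequence together with the truth
records in reference coordinates. A call set is scored against a truth set
by requiring reciprocal overlap: call c matches truth t only if their
shared bases cover at least ``min_ro`` of *each* interval. Assignment is
one-to-one, greedy by descending overlap, so one oversized call cannot
absorb several truths. Precision = TP/(TP+FP), sensitivity = TP/(TP+FN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import SVCatalog, SVRecord
from .intervals import GenomicInterval

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class TruthSet:
    reference: dict[str, str]
    mutated: dict[str, str]
    records: list[SVRecord]
    snp_positions: dict[str, np.ndarray] = field(default_factory=dict)

    def to_catalog(self) -> SVCatalog:
        genome = {c: len(s) for c, s in self.reference.items()}
        return SVCatalog(samples=[], records=list(self.records), genome=genome)

    def write(self, fasta_path: str | Path, bed_path: str | Path | None = None) -> None:
        SeqIO.write(
            [SeqRecord(Seq(s), id=c, description="") for c, s in self.mutated.items()],
            str(fasta_path),
            "fasta",
        )
        if bed_path is not None:
            with open(bed_path, "w") as fh:
                for rec in self.records:
                    fh.write(
                        f"{rec.chrom}\t{rec.interval.start}\t{rec.interval.end}"
                        f"\t{rec.svtype}\n"
                    )


@dataclass
class MatchReport:
    assignment: list[tuple[int, int]]  # (call index, truth index)
    tp: int
    fp: int
    fn: int
    n_calls: int
    n_truth: int
    per_svtype: pd.DataFrame | None = None

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def simulate_svs(
    reference: Mapping[str, str] | str | Path,
    n_per_type: int = 1000,
    min_len: int = 50,
    max_len: int = 10_000,
    snp_rate: float = 0.001,
    seed: int = 0,
    max_tries: int = 10_000,
) -> TruthSet:
    """Plant ``n_per_type`` DEL, DUP (tandem) and INV events per genome.

    Events are placed uniformly at random without overlap, with lengths
    uniform on [min_len, max_len]; point substitutions hit non-event bases
    at per-base probability ``snp_rate``. Deterministic under a fixed seed.
    Raises if placement cannot finish within ``max_tries`` rejections.
    """
    if isinstance(reference, (str, Path)):
        reference = read_fasta(reference)
    rng = np.random.default_rng(seed)
    chroms = list(reference)
    lengths = np.array([len(reference[c]) for c in chroms], dtype=float)
    records: list[SVRecord] = []
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    total = {"DEL": n_per_type, "DUP": n_per_type, "INV": n_per_type}
    for svtype, n_events in total.items():
        done = 0
        tries = 0
        while done < n_events:
            if tries > max_tries + 10 * n_events:
                raise RuntimeError(
                    f"could not place {svtype} events: placed {done}/{n_events}"
                )
            tries += 1
            ci = int(rng.choice(len(chroms), p=lengths / lengths.sum()))
            chrom = chroms[ci]
            L = int(rng.integers(min_len, max_len + 1))
            if L + 2 > len(reference[chrom]):
                continue
            start = int(rng.integers(1, len(reference[chrom]) - L))
            end = start + L
            if any(start < e and s < end for s, e in placed[chrom]):
                continue
            placed[chrom].append((start, end))
            records.append(
                SVRecord(
                    GenomicInterval(chrom, start, end),
                    svtype,
                    np.empty(0, dtype=np.int8),
                    record_id=f"{svtype.lower()}{done}_{chrom}",
                )
            )
            done += 1
    records.sort(key=lambda r: (r.chrom, r.interval.start))

    mutated: dict[str, str] = {}
    snp_positions: dict[str, np.ndarray] = {}
    for chrom in chroms:
        seq = np.frombuffer(reference[chrom].encode(), dtype=np.uint8).copy()
        event_mask = np.zeros(len(seq), dtype=bool)
        for s, e in placed[chrom]:
            event_mask[s:e] = True
        if snp_rate > 0:
            candidates = np.flatnonzero(~event_mask)
            hit = candidates[rng.random(candidates.size) < snp_rate]
            for pos in hit:
                alternatives = _BASES[_BASES != seq[pos]]
                seq[pos] = alternatives[rng.integers(len(alternatives))]
            snp_positions[chrom] = hit
        else:
            snp_positions[chrom] = np.empty(0, dtype=int)
        # apply SVs right-to-left so earlier coordinates stay valid
        pieces = seq
        for rec in sorted(
            (r for r in records if r.chrom == chrom),
            key=lambda r: -r.interval.start,
        ):
            s, e = rec.interval.start, rec.interval.end
            if rec.svtype == "DEL":
                pieces = np.concatenate([pieces[:s], pieces[e:]])
            elif rec.svtype == "DUP":
                pieces = np.concatenate([pieces[:e], pieces[s:e], pieces[e:]])
            elif rec.svtype == "INV":
                pieces = np.concatenate([pieces[:s], pieces[s:e][::-1], pieces[e:]])
        mutated[chrom] = pieces.tobytes().decode()
    return TruthSet(
        reference={c: reference[c] for c in chroms},
        mutated=mutated,
        records=records,
        snp_positions=snp_positions,
    )


def match_reciprocal(
    calls: Sequence[SVRecord],
    truth: Sequence[SVRecord],
    min_ro: float = 0.5,
    type_strict: bool = True,
) -> MatchReport:
    """One-to-one reciprocal-overlap matching of calls against truth.

    Compatibility: same svtype (if ``type_strict``) and
    overlap/len(call) >= min_ro and overlap/len(truth) >= min_ro.
    Pairs are assigned greedily by descending overlap bases, ties broken by
    (chrom, start, end) of call then truth; leftovers are FP/FN.
    """
    if not 0 < min_ro <= 1:
        raise ValueError("min_ro must be in (0, 1]")
    pairs: list[tuple[int, tuple, int, int]] = []
    for ti, t in enumerate(truth):
        for ci, c in enumerate(calls):
            if type_strict and c.svtype != t.svtype:
                continue
            ov = c.interval.overlap(t.interval)
            if ov == 0:
                continue
            if ov / c.length >= min_ro and ov / t.length >= min_ro:
                key = (
                    c.chrom, c.interval.start, c.interval.end,
                    t.chrom, t.interval.start, t.interval.end,
                )
                pairs.append((ov, key, ci, ti))
    pairs.sort(key=lambda x: (-x[0], x[1]))
    used_c: set[int] = set()
    used_t: set[int] = set()
    assignment: list[tuple[int, int]] = []
    for _, _, ci, ti in pairs:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        assignment.append((ci, ti))
    tp = len(assignment)
    report = MatchReport(
        assignment=assignment,
        tp=tp,
        fp=len(calls) - tp,
        fn=len(truth) - tp,
        n_calls=len(calls),
        n_truth=len(truth),
    )
    rows = []
    for svtype in sorted({r.svtype for r in list(calls) + list(truth)}):
        t_idx = {i for i, r in enumerate(truth) if r.svtype == svtype}
        c_idx = {i for i, r in enumerate(calls) if r.svtype == svtype}
        tp_t = sum(1 for ci, ti in assignment if ti in t_idx)
        fp_t = len(c_idx) - sum(1 for ci, _ in assignment if ci in c_idx)
        fn_t = len(t_idx) - tp_t
        rows.append(
            {"svtype": svtype, "tp": tp_t, "fp": fp_t, "fn": fn_t,
             "precision": tp_t / (tp_t + fp_t) if tp_t + fp_t else float("nan"),
             "sensitivity": tp_t / (tp_t + fn_t) if tp_t + fn_t else float("nan")}
        )
    report.per_svtype = pd.DataFrame(rows)
    return report


def precision_sensitivity(report: MatchReport) -> tuple[float, float]:
    """(precision, sensitivity); nan (never an exception) on zero denominators."""
    return report.precision, report.sensitivity


def jitter_calls(
    truth: Sequence[SVRecord],
    genome: Mapping[str, int],
    shift_sd: float = 20.0,
    drop_rate: float = 0.0,
    fp_rate: float = 0.0,
    seed: int = 0,
) -> list[SVRecord]:
    """Perturbed copy of a truth set, for benchmarking exercises.

    Shifts both breakpoints by ~N(0, shift_sd), drops records at
    ``drop_rate`` (future FNs) and appends spurious records at ``fp_rate``
    per true record (future FPs).
    """
    rng = np.random.default_rng(seed)
    calls: list[SVRecord] = []
    for rec in truth:
        if rng.random() < drop_rate:
            continue
        shift = int(np.round(rng.normal(0, shift_sd)))
        s = max(0, rec.interval.start + shift)
        e = min(genome[rec.chrom], rec.interval.end + shift)
        if e <= s:
            continue
        calls.append(
            SVRecord(GenomicInterval(rec.chrom, s, e), rec.svtype,
                     np.empty(0, dtype=np.int8), record_id=f"call_{rec.record_id}")
        )
    n_fp = int(round(fp_rate * len(truth)))
    chroms = list(genome)
    for i in range(n_fp):
        chrom = chroms[int(rng.integers(len(chroms)))]
        L = int(rng.integers(50, 2000))
        if genome[chrom] <= L + 1:
            continue
        s = int(rng.integers(0, genome[chrom] - L))
        calls.append(
            SVRecord(GenomicInterval(chrom, s, s + L), "DEL",
                     np.empty(0, dtype=np.int8), record_id=f"fp{i}")
        )
    return calls
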