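"""Quadripartite structure: inverted-repeat detection, partitioning, metrics.

The plastome's two inverted repeats (IRa/IRb) are located as the longest pair
of disjoint intervals whose sequences are reverse complements of one another,
within an allowed mismatch budget.  Detection is seed-and-extend: k-mer seeds
against the reverse-complemented sequence collapse onto anti-diagonals, and on
each diagonal the longest run with at most ``max_mismatches`` mismatches is
found with a sliding window.  Circular genomes are searched on the doubled
sequence so repeats spanning the linearization origin are not missed.

After detection the genome is rotated to a canonical origin — the first base
of the LSC, immediately following IRa (the junction that in Cornales plastomes
sits between rpl2 and trnH) — giving the linear region order LSC-IRb-SSC-IRa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    AlignmentMatrix,
    GAP,
    PlastomeRecord,
    PlastcompError,
    normalize_gene_name,
    revcomp,
    round2,
)

Interval = tuple[int, int]


class IRNotFoundError(PlastcompError):
    pass


class AmbiguousStructureError(PlastcompError):
    pass


@dataclass
class QuadripartiteStructure:
    """Coordinates and metrics of the four plastome regions.

    Intervals are 0-based half-open in the canonically rotated frame
    (LSC starts at 0; region order LSC, IRb, SSC, IRa).  Metrics are filled
    by :func:`region_metrics`.
    """

    lsc: Interval
    irb: Interval
    ssc: Interval
    ira: Interval
    total_length: int
    ir_mismatches: int = 0
    region_gc: dict = field(default_factory=dict)  # region -> GC %
    coding_length: int = 0
    noncoding_length: int = 0
    coding_gc: float = 0.0
    noncoding_gc: float = 0.0

    @property
    def lsc_length(self) -> int:
        return self.lsc[1] - self.lsc[0]

    @property
    def ssc_length(self) -> int:
        return self.ssc[1] - self.ssc[0]

    @property
    def ir_length(self) -> int:
        return self.ira[1] - self.ira[0]

    @property
    def junctions(self) -> dict[str, int]:
        """The four region boundaries: JLB=LSC/IRb, JSB=IRb/SSC, JSA=SSC/IRa,
        JLA=IRa/LSC (at the origin, coordinate ``total_length`` = 0)."""
        return {
            "JLB": self.lsc[1],
            "JSB": self.irb[1],
            "JSA": self.ssc[1],
            "JLA": self.total_length,
        }

    def region_of(self, pos: int) -> str:
        pos %= self.total_length
        for name, (s, e) in (
            ("LSC", self.lsc),
            ("IRb", self.irb),
            ("SSC", self.ssc),
            ("IRa", self.ira),
        ):
            if s <= pos < e:
                return name
        raise ValueError(f"position {pos} outside genome")


def _longest_window(match: np.ndarray, max_mismatches: int) -> tuple[int, int]:
    """Longest [l, r) window of a boolean array with <= max_mismatches False,
    not starting or ending on a mismatch.  Returns (l, r), possibly empty."""
    def _trim(l: int, r: int) -> tuple[int, int]:
        while l < r and not match[l]:
            l += 1
        while r > l and not match[r - 1]:
            r -= 1
        return l, r

    mm = np.flatnonzero(~match)
    if len(mm) <= max_mismatches:
        return _trim(0, len(match))
    # each candidate window spans from just after one mismatch to just before
    # the (max_mismatches+1)-th following one
    best = (0, 0)
    bounds = np.concatenate(([-1], mm, [len(match)]))
    for i in range(1, len(bounds) - max_mismatches):
        l, r = _trim(int(bounds[i - 1]) + 1, int(bounds[i + max_mismatches]))
        if r - l > best[1] - best[0]:
            best = (l, r)
    return best


def detect_inverted_repeats(
    rec: PlastomeRecord | str,
    min_len: int = 1000,
    max_mismatches: int = 0,
    circular: bool | None = None,
) -> tuple[Interval, Interval]:
    """Find the longest pair of disjoint reverse-complementary intervals.

    Returns two intervals sorted by start, as (start, end) with start in
    [0, n); end may exceed n for a repeat wrapping the origin of a circular
    genome.  Raises :class:`IRNotFoundError` if no pair of length >= min_len
    exists.
    """
    if isinstance(rec, PlastomeRecord):
        seq = rec.sequence
        if circular is None:
            circular = rec.circular
    else:
        seq = rec.upper()
        circular = bool(circular)
    n = len(seq)
    if n < 2 * min_len:
        raise IRNotFoundError(f"sequence ({n} bp) shorter than 2*min_len")

    s2 = seq + seq if circular else seq
    n2 = len(s2)
    rc2 = revcomp(s2)
    k = max(4, min(31, min_len // (max_mismatches + 1)))

    index: dict[str, list[int]] = {}
    for p in range(n2 - k + 1):
        index.setdefault(rc2[p : p + k], []).append(p)

    diagonals: dict[int, list[int]] = {}
    for i in range(n2 - k + 1):
        for p in index.get(s2[i : i + k], ()):
            diagonals.setdefault(i - p, []).append(i)

    a1 = np.frombuffer(s2.encode(), dtype="S1")
    a2 = np.frombuffer(rc2.encode(), dtype="S1")
    margin = (max_mismatches + 1) * k
    candidates: dict[tuple, int] = {}
    for d, seeds in diagonals.items():
        lo = max(min(seeds) - margin, 0, d)
        hi = min(max(seeds) + k + margin, n2, n2 + d)
        t = np.arange(lo, hi)
        match = (a1[t] == a2[t - d]) & (a1[t] != b"N")
        wl, wr = _longest_window(match, max_mismatches)
        L = wr - wl
        if L < min_len:
            continue
        i0 = lo + wl
        p0 = i0 - d
        L = min(L, n)
        b0 = n2 - p0 - L
        arm_a, arm_b = (i0 % n, L), (b0 % n, L)
        # disjoint arcs on the circle (also rejects palindromic self-matches)
        rel = (arm_b[0] - arm_a[0]) % n
        if rel < L or rel + L > n:
            continue
        key = tuple(sorted((arm_a, arm_b)))
        candidates[key] = max(candidates.get(key, 0), L)

    if not candidates:
        raise IRNotFoundError(f"no inverted repeat of length >= {min_len}")
    best_key = min(candidates, key=lambda key: (-key[0][1], key))
    (sa, L), (sb, _) = best_key
    return ((sa, sa + L), (sb, sb + L))


def partition_genome(
    rec: PlastomeRecord,
    ir_pair: tuple[Interval, Interval],
    check_orientation: bool = True,
    max_mismatches: int = 0,
) -> tuple[PlastomeRecord, QuadripartiteStructure]:
    """Label single-copy regions and rotate to the canonical origin.

    The longer inter-IR segment is the LSC, the shorter the SSC; the rotated
    record starts at the first LSC base and runs LSC-IRb-SSC-IRa.  If a trnH
    annotation is present and sits nearer the far (JLB) end of the LSC, the
    genome is reverse-complemented first so that trnH abuts the origin, as at
    the rpl2-trnH IRa/LSC junction.  Returns (rotated record, structure).
    """
    n = len(rec)
    (a0, a1), (b0, b1) = sorted(ir_pair)
    La, Lb = a1 - a0, b1 - b0
    if La != Lb:
        raise AmbiguousStructureError("IR intervals have unequal lengths")
    gap_ab = (b0 - a1) % n  # arc from A end to B start
    gap_ba = (a0 - b1) % n  # arc from B end to A start
    if gap_ab == gap_ba:
        raise AmbiguousStructureError(
            f"inter-IR segments of equal length ({gap_ab} bp): LSC/SSC ambiguous"
        )
    if gap_ab > gap_ba:
        origin, lsc_len, ssc_len = a1 % n, gap_ab, gap_ba
    else:
        origin, lsc_len, ssc_len = b1 % n, gap_ba, gap_ab
    ir_len = La

    rotated = rec.rotated(origin) if rec.circular else rec
    qs = QuadripartiteStructure(
        lsc=(0, lsc_len),
        irb=(lsc_len, lsc_len + ir_len),
        ssc=(lsc_len + ir_len, lsc_len + ir_len + ssc_len),
        ira=(lsc_len + ir_len + ssc_len, n),
        total_length=n,
    )

    if check_orientation:
        trnh = next(
            (
                f
                for f in rotated.features
                if normalize_gene_name(f.name).startswith("trnH")
            ),
            None,
        )
        if trnh is not None and not trnh.wraps_origin:
            mid = (trnh.start + trnh.end) // 2
            if qs.lsc[0] <= mid < qs.lsc[1] and mid > lsc_len // 2:
                flipped = rec.reverse_complemented()
                starts = sorted(((n - a1) % n, (n - b1) % n))
                return partition_genome(
                    flipped,
                    ((starts[0], starts[0] + La), (starts[1], starts[1] + Lb)),
                    check_orientation=False,
                    max_mismatches=max_mismatches,
                )

    ira_seq = rotated.sequence[qs.ira[0] : qs.ira[1]]
    irb_seq = rotated.sequence[qs.irb[0] : qs.irb[1]]
    qs.ir_mismatches = sum(x != y for x, y in zip(ira_seq, revcomp(irb_seq)))
    if qs.ir_mismatches > max_mismatches:
        raise AmbiguousStructureError(
            f"IRa is not the reverse complement of IRb "
            f"({qs.ir_mismatches} mismatches > budget {max_mismatches})"
        )
    return rotated, qs


def gc_percent(seq: str) -> float:
    """GC as a percentage of unambiguous bases, half-up to 2 decimals."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return round2(100.0 * (seq.count("G") + seq.count("C")) / acgt)


def _merge_intervals(ivs: list[Interval]) -> list[Interval]:
    merged: list[Interval] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def region_metrics(rec: PlastomeRecord, qs: QuadripartiteStructure) -> QuadripartiteStructure:
    """Fill per-region length/GC and coding vs non-coding accounting.

    Coding length is the union of all exon intervals (both IR copies count);
    non-coding is its complement, so the two always sum to the genome length.
    """
    seq = rec.sequence
    qs.region_gc = {
        "total": gc_percent(seq),
        "LSC": gc_percent(seq[qs.lsc[0] : qs.lsc[1]]),
        "SSC": gc_percent(seq[qs.ssc[0] : qs.ssc[1]]),
        "IR": gc_percent(seq[qs.irb[0] : qs.irb[1]] + seq[qs.ira[0] : qs.ira[1]]),
    }
    exon_union = _merge_intervals([iv for f in rec.features for iv in f.exons])
    qs.coding_length = sum(e - s for s, e in exon_union)
    qs.noncoding_length = qs.total_length - qs.coding_length
    coding_seq = "".join(seq[s:e] for s, e in exon_union)
    qs.coding_gc = gc_percent(coding_seq)
    mask = np.ones(len(seq), dtype=bool)
    for s, e in exon_union:
        mask[s:e] = False
    qs.noncoding_gc = gc_percent("".join(np.array(list(seq))[mask]))
    return qs


def windowed_identity(
    aln: AlignmentMatrix, reference: str, window: int = 600, step: int = 200
) -> pd.DataFrame:
    """Sliding-window percent identity of every taxon against a reference.

    Windows tile the reference's own (ungapped) coordinates; identity within
    a window is the fraction of reference positions where the taxon carries
    the same base (a gap or N in the taxon counts as a difference).
    """
    ref_row = aln.row(reference)
    ref_cols = np.flatnonzero(np.frombuffer(ref_row.encode(), dtype="S1") != GAP.encode())
    n_ref = len(ref_cols)
    ref_arr = aln.matrix[aln.taxa.index(reference)]
    rows = []
    for taxon in aln.taxa:
        if taxon == reference:
            continue
        taxon_arr = aln.matrix[aln.taxa.index(taxon)]
        eq = (taxon_arr[ref_cols] == ref_arr[ref_cols]) & (ref_arr[ref_cols] != b"N")
        for start in range(0, max(n_ref - window, 0) + 1, step):
            w = eq[start : start + window]
            rows.append(
                {
                    "taxon": taxon,
                    "window_start": start,
                    "window_end": start + len(w),
                    "identity_pct": round2(100.0 * float(w.mean())) if len(w) else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["taxon", "window_start", "window_end", "identity_pct"])
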