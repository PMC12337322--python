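"""Converted-space alignment, deduplication and per-site state compilation.

Reads in deaminated space have lost most cytosines to thymine, so matching
uses the asymmetric three-letter rule of bisulfite-style aligners: a read T
matches reference C or T, a read C matches only reference C, and A/G must
match exactly.  The aligner is a k-mer-seeded exact-verification scanner on
the C->T-collapsed alphabet -- deliberately index-light, adequate for the
desk-scale genomes this package simulates (documented limitation; it is not
a general-purpose read mapper).

Insert a seeds the plus strand and insert b the minus strand; they must
agree on one fragment interval.  The copy-strand inserts d and c are then
verified against the opposite strands at the same locus but never seed
alignment themselves.  A unique best full-length match is required; ties
leave the quad unaligned.  Duplicates are collapsed on the fragment
interval, keeping the lexicographically smallest read name, and per-site
tallies record each decoded duplex state plus a count of implausible call
combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._tsv import write_table
from .extract import InsertQuad
from .genome import cpg_positions, revcomp
from .model import (
    IMPLAUSIBLE,
    CallQuad,
    CpGState,
    STATE_ORDER,
    decode_state,
)

_C, _T = 67, 84


@dataclass(frozen=True)
class FragmentAlignment:
    name: str
    contig: str
    start: int
    end: int
    mismatches: int  # summed over all four inserts
    unique: bool = True


class ReferenceIndex:
    """k-mer index of both strands of a reference in C->T-collapsed space."""

    def __init__(self, reference: Mapping[str, str], k: int = 16):
        if k < 8:
            raise ValueError("seed length k must be >= 8")
        self.k = k
        self.contigs = dict(reference)
        self.sizes = {c: len(s) for c, s in self.contigs.items()}
        # raw and collapsed byte arrays per strand; minus = reverse complement
        self._raw: dict[tuple[str, str], np.ndarray] = {}
        self._index: dict[bytes, list[tuple[str, str, int]]] = {}
        for contig, seq in self.contigs.items():
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                raw = np.frombuffer(s.encode(), dtype=np.uint8).copy()
                self._raw[(contig, strand)] = raw
                coll = raw.copy()
                coll[coll == _C] = _T
                cb = coll.tobytes()
                for pos in range(len(cb) - k + 1):
                    self._index.setdefault(cb[pos:pos + k], []).append(
                        (contig, strand, pos))

    def candidates(self, read_collapsed: bytes, strand: str) -> set[tuple[str, int]]:
        """Candidate (contig, start) positions for a read on one strand."""
        k = self.k
        n = len(read_collapsed)
        if n < k:
            return set()
        offsets = sorted({0, (n - k) // 2, n - k})
        out: set[tuple[str, int]] = set()
        for off in offsets:
            for contig, s, pos in self._index.get(read_collapsed[off:off + k], ()):
                if s == strand:
                    out.add((contig, pos - off))
        return out

    def mismatch_count(self, read: np.ndarray, contig: str, strand: str,
                       start: int) -> int | None:
        """Asymmetric-rule mismatches of a read at one position, or None if
        it does not fit inside the contig."""
        ref = self._raw[(contig, strand)]
        if start < 0 or start + len(read) > len(ref):
            return None
        w = ref[start:start + len(read)]
        ok = (read == w) | ((read == _T) & (w == _C))
        return int(len(read) - np.count_nonzero(ok))


def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _collapse(seq: str) -> bytes:
    arr = _as_bytes(seq).copy()
    arr[arr == _C] = _T
    return arr.tobytes()


def _best_unique(index: ReferenceIndex, seq: str, strand: str,
                 max_mismatch: int):
    """Best unique placement of one insert on one strand, or (None, reason)."""
    read = _as_bytes(seq)
    cands = index.candidates(_collapse(seq), strand)
    best = None
    best_mm = max_mismatch + 1
    tie = False
    for contig, start in sorted(cands):
        mm = index.mismatch_count(read, contig, strand, start)
        if mm is None:
            continue
        if mm < best_mm:
            best, best_mm, tie = (contig, start), mm, False
        elif mm == best_mm and best is not None:
            tie = True
    if best is None or best_mm > max_mismatch:
        return None, "unmapped"
    if tie:
        return None, "ambiguous"
    return (best[0], best[1], best_mm), None


def align_quad(quad: InsertQuad, index: ReferenceIndex,
               max_mismatch: int = 5):
    """Place one insert quad on the reference.

    Returns (FragmentAlignment, None) or (None, reason).  Reasons:
    ``unmapped`` / ``ambiguous`` (from the a or b seed), ``pair_mismatch``
    (a and b disagree on the fragment interval), ``copy_inconsistent``
    (d or c does not verify at the locus).
    """
    hit_a, why = _best_unique(index, quad.a, "+", max_mismatch)
    if hit_a is None:
        return None, why
    hit_b, why = _best_unique(index, quad.b, "-", max_mismatch)
    if hit_b is None:
        return None, why
    contig, start, mm_a = hit_a
    contig_b, minus_off, mm_b = hit_b
    size = index.sizes[contig]
    # b spans the same duplex fragment read from the minus strand
    b_start = size - minus_off - len(quad.b)
    if contig_b != contig or b_start != start or len(quad.b) != len(quad.a):
        return None, "pair_mismatch"
    end = start + len(quad.a)
    # copy strands verify against the opposite strands at the same locus:
    # d (copy of plus) runs along the minus orientation, c along plus
    mm_d = index.mismatch_count(_as_bytes(quad.d), contig, "-", minus_off)
    mm_c = index.mismatch_count(_as_bytes(quad.c), contig, "+", start)
    if mm_d is None or mm_c is None or mm_d > max_mismatch or mm_c > max_mismatch:
        return None, "copy_inconsistent"
    return FragmentAlignment(quad.name, contig, start, end,
                             mm_a + mm_b + mm_c + mm_d), None


def deduplicate(alignments: Sequence[FragmentAlignment]) -> list[FragmentAlignment]:
    """One representative per fragment interval: smallest read name wins.

    Coordinate-based duplicate marking; idempotent by construction.
    """
    best: dict[tuple[str, int, int], FragmentAlignment] = {}
    for aln in alignments:
        key = (aln.contig, aln.start, aln.end)
        cur = best.get(key)
        if cur is None or aln.name < cur.name:
            best[key] = aln
    return [best[k] for k in sorted(best)]


def call_quads(alignment: FragmentAlignment, quad: InsertQuad,
               reference: Mapping[str, str]):
    """Four-call extraction at every CpG dyad fully inside the fragment.

    In plus coordinates a dyad at i reads: a and c at offset i-start, b and
    d at the mirrored offset (length-1)-(i+1-start).  C -> call 1, T -> call
    0; any other base at a dyad position (sequencing error) skips the site
    for this fragment.  Returns (calls, n_skipped).
    """
    seq = reference[alignment.contig][alignment.start:alignment.end]
    length = len(seq)
    calls: list[tuple[int, CallQuad]] = []
    skipped = 0
    for i_rel in map(int, cpg_positions(seq)):
        fwd = i_rel
        rev = length - i_rel - 2
        bases = (quad.a[fwd], quad.d[rev], quad.b[rev], quad.c[fwd])
        if any(b not in "CT" for b in bases):
            skipped += 1
            continue
        calls.append((alignment.start + i_rel,
                      CallQuad(*(1 if b == "C" else 0 for b in bases))))
    return calls, skipped


SITE_COLUMNS = ["contig", "pos0", *STATE_ORDER, "implausible", "depth"]


def compile_sites(calls: Iterable[tuple[str, int, CallQuad]]) -> pd.DataFrame:
    """Tally decoded states per CpG site.

    Valid states increment their state counter; implausible quads increment
    ``implausible`` (kept for QC, excluded from state fractions downstream).
    ``depth`` is the double-stranded depth: each deduplicated fragment
    contributes one count at each dyad it fully covers.
    """
    acc: dict[tuple[str, int], np.ndarray] = {}
    for contig, pos0, quad in calls:
        row = acc.get((contig, pos0))
        if row is None:
            row = acc[(contig, pos0)] = np.zeros(10, dtype=int)
        state = decode_state(quad)
        if state is IMPLAUSIBLE:
            row[9] += 1
        else:
            row[STATE_ORDER.index(state.name)] += 1
    records = [(c, p, *row, int(row.sum())) for (c, p), row in sorted(acc.items())]
    return pd.DataFrame(records, columns=SITE_COLUMNS)


# ---------------------------------------------------------------------------
# Stage driver
# ---------------------------------------------------------------------------

def call_sites(quads: Sequence[InsertQuad], reference: Mapping[str, str],
               k: int = 16, max_mismatch: int = 5):
    """align -> deduplicate -> call -> compile, returning (sites, stats).

    ``stats`` counts aligned/unaligned quads by reason, duplicates removed,
    and dyad positions skipped for sequencing errors.
    """
    index = ReferenceIndex(reference, k)
    by_name: dict[str, InsertQuad] = {}
    alignments: list[FragmentAlignment] = []
    stats: dict[str, int] = {"input": len(quads), "aligned": 0}
    for quad in quads:
        aln, reason = align_quad(quad, index, max_mismatch)
        if aln is None:
            stats[reason] = stats.get(reason, 0) + 1
            continue
        alignments.append(aln)
        by_name[quad.name] = quad
        stats["aligned"] += 1
    deduped = deduplicate(alignments)
    stats["duplicates_removed"] = len(alignments) - len(deduped)
    all_calls: list[tuple[str, int, CallQuad]] = []
    skipped = 0
    for aln in deduped:
        calls, n_skip = call_quads(aln, by_name[aln.name], reference)
        skipped += n_skip
        all_calls.extend((aln.contig, pos, q) for pos, q in calls)
    stats["sites_skipped_seq_error"] = skipped
    return compile_sites(all_calls), stats


def write_sites(df: pd.DataFrame, path, comments: Sequence[str] = ()):
    write_table(df, path, comments)
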