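"""Adapter-configuration filtering and four-insert extraction.

A target read pair shows the intact (noncleavable) hairpin once in Read 1
and the cleaved-adapter remnant once in Read 2; everything else -- ligation
side products, adapter-less junk, ambiguous multi-hit reads -- is rejected
with a logged reason.  From each retained pair the four inserts are cut
out: a (R1 before the hairpin), b (R1 after it), c (R2 before the remnant)
and d (R2 after it).  By construction all four inserts of one fragment have
equal length, so b and d are trimmed to the length of their complementary
partners, which also disposes of any trailing adapter carry-over; pairs
that cannot yield four complete inserts are discarded, never crashed on.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._tsv import read_table, write_table
from .simulate import AdapterConfig


class InsertQuad(NamedTuple):
    """The four converted insert sequences of one read pair."""

    name: str
    a: str
    b: str
    c: str
    d: str


def _open_text(path):
    path = Path(path)
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_read_pairs(fastq_r1, fastq_r2) -> Iterator[tuple[str, str, str]]:
    """Yield (name, r1, r2) from paired FASTQ files; names must agree."""
    with _open_text(fastq_r1) as f1, _open_text(fastq_r2) as f2:
        it2 = FastqGeneralIterator(f2)
        for (t1, s1, _q1) in FastqGeneralIterator(f1):
            try:
                t2, s2, _q2 = next(it2)
            except StopIteration:
                raise ValueError("R2 file ended before R1") from None
            n1 = t1.split()[0]
            n2 = t2.split()[0]
            if n1 != n2:
                raise ValueError(f"read name mismatch: {n1!r} vs {n2!r}")
            yield n1, s1.upper(), s2.upper()
        try:
            next(it2)
        except StopIteration:
            pass
        else:
            raise ValueError("R1 file ended before R2")


def adapter_hits(read: str, adapter: str, max_mismatch: int) -> np.ndarray:
    """Offsets where ``adapter`` matches ``read`` within ``max_mismatch``
    substitutions (Hamming distance; no indels)."""
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    a = np.frombuffer(adapter.encode(), dtype=np.uint8)
    if len(r) < len(a):
        return np.empty(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(r, len(a))
    return np.where((windows != a).sum(axis=1) <= max_mismatch)[0]


def filter_target_pairs(pairs: Iterable[tuple[str, str, str]],
                        adapters: AdapterConfig,
                        max_mismatch: int = 2):
    """Keep pairs with the target adapter configuration.

    Retained: exactly one intact-hairpin hit in R1 AND exactly one remnant
    hit in R2.  Returns (retained [(name, r1, r2, r1_hit, r2_hit)], rejection
    reason counts).
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    retained = []
    rejected: Counter[str] = Counter()
    for name, r1, r2 in pairs:
        h1 = adapter_hits(r1, adapters.intact, max_mismatch)
        h2 = adapter_hits(r2, adapters.remnant, max_mismatch)
        if len(h1) == 0 or len(h2) == 0:
            rejected["no_adapter"] += 1
        elif len(h1) > 1 or len(h2) > 1:
            rejected["ambiguous"] += 1
        else:
            retained.append((name, r1, r2, int(h1[0]), int(h2[0])))
    return retained, dict(rejected)


def extract_inserts(name: str, r1: str, r2: str, r1_hit: int, r2_hit: int,
                    adapters: AdapterConfig):
    """Cut the four inserts out of a retained pair.

    Returns (InsertQuad, None) on success or (None, reason).  All four
    inserts of a fragment are equal-length; b and d are trimmed to that
    length, removing trailing adapter remnants in truncated reads.
    """
    a = r1[:r1_hit]
    c = r2[:r2_hit]
    length = len(a)
    if length == 0 or len(c) == 0:
        return None, "incomplete_quad"
    if len(c) != length:
        return None, "inconsistent_pair"
    b = r1[r1_hit + len(adapters.intact):][:length]
    d = r2[r2_hit + adapters.remnant_len:][:length]
    if len(b) < length or len(d) < length:
        return None, "incomplete_quad"
    return InsertQuad(name, a, b, c, d), None


def extract_quads(pairs: Iterable[tuple[str, str, str]],
                  adapters: AdapterConfig | None = None,
                  max_mismatch: int = 2):
    """Filter + extract in one pass.

    Returns (quads, summary) where summary counts retained quads and every
    rejection reason; reasons partition the non-retained pairs.
    """
    adapters = adapters or AdapterConfig()
    retained, rejected = filter_target_pairs(pairs, adapters, max_mismatch)
    quads: list[InsertQuad] = []
    for name, r1, r2, h1, h2 in retained:
        quad, reason = extract_inserts(name, r1, r2, h1, h2, adapters)
        if quad is None:
            rejected[reason] = rejected.get(reason, 0) + 1
        else:
            quads.append(quad)
    summary = {"retained": len(quads), "rejected": rejected,
               "total": len(quads) + sum(rejected.values())}
    return quads, summary


# ---------------------------------------------------------------------------
# File-level driver and serialization
# ---------------------------------------------------------------------------

def extract_fastq(fastq_r1, fastq_r2, quads_path, summary_path=None,
                  adapters: AdapterConfig | None = None, max_mismatch: int = 2,
                  comments: Sequence[str] = ()):
    quads, summary = extract_quads(iter_read_pairs(fastq_r1, fastq_r2),
                                   adapters, max_mismatch)
    write_quads(quads, quads_path, comments)
    if summary_path is not None:
        Path(summary_path).parent.mkdir(parents=True, exist_ok=True)
        Path(summary_path).write_text(json.dumps(summary, indent=2) + "\n")
    return quads, summary


def write_quads(quads: Sequence[InsertQuad], path, comments: Sequence[str] = ()):
    df = pd.DataFrame(quads, columns=["name", "a", "b", "c", "d"])
    write_table(df, path, comments)


def read_quads(path) -> list[InsertQuad]:
    df = read_table(path, dtype=str)
    return [InsertQuad(*row) for row in df[["name", "a", "b", "c", "d"]].itertuples(index=False)]
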