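"""Converted-space alignment, deduplication, calling and compilation."""

import numpy as np
import pandas as pd
import pytest

import duplexmeth as dm
from duplexmeth.align import (
    FragmentAlignment,
    ReferenceIndex,
    align_quad,
    call_quads,
    call_sites,
    compile_sites,
    deduplicate,
)
from duplexmeth.extract import InsertQuad, extract_quads
from duplexmeth.genome import revcomp
from duplexmeth.model import CallQuad, STATE_ORDER
from duplexmeth.simulate import ChemistryErrorModel, simulate_reads


def brute_force_locate(insert: str, reference: dict, strand: str):
    """Oracle: scan every offset of every contig under the asymmetric rule
    (read T matches ref C or T; read C matches only ref C; A/G exact)."""
    def mismatches(read, ref_window):
        return sum(0 if r == w or (r == "T" and w == "C") else 1
                   for r, w in zip(read, ref_window))

    hits = []
    for contig, seq in reference.items():
        s = seq if strand == "+" else revcomp(seq)
        for off in range(len(s) - len(insert) + 1):
            mm = mismatches(insert, s[off:off + len(insert)])
            hits.append((mm, contig, off))
    if not hits:
        return None
    best = min(h[0] for h in hits)
    winners = [h for h in hits if h[0] == best]
    if best > 5 or len(winners) > 1:
        return None
    return winners[0][1], winners[0][2], best


@pytest.fixture(scope="module")
def small_genome_quads():
    """Zero-error quads over a <=5 kb genome, with truth coordinates."""
    ref = dm.generate_reference(1, 4000, 0.02, seed=31)
    meth = dm.assign_states(ref, dm.DEFAULT_STATE_FRACTIONS, seed=32)
    pairs, tp, tc = simulate_reads(meth, 150, ChemistryErrorModel.zero(), seed=33)
    quads, _ = extract_quads([(p.name, p.r1, p.r2) for p in pairs])
    return meth, quads, tp.set_index("name")


class TestAlignQuad:
    def test_zero_error_alignment_at_true_coordinates(self, small_genome_quads):
        meth, quads, truth = small_genome_quads
        index = ReferenceIndex(meth.reference)
        aligned = 0
        for quad in quads:
            aln, reason = align_quad(quad, index)
            assert aln is not None, reason
            row = truth.loc[quad.name]
            assert (aln.contig, aln.start, aln.end) == (row.contig, row.start, row.end)
            aligned += 1
        assert aligned == len(quads)

    def test_agrees_with_brute_force_scan(self, small_genome_quads):
        meth, quads, _ = small_genome_quads
        index = ReferenceIndex(meth.reference)
        for quad in quads[:60]:
            oracle = brute_force_locate(quad.a, meth.reference, "+")
            aln, _ = align_quad(quad, index)
            if oracle is None:
                assert aln is None
            else:
                assert aln is not None
                assert (aln.contig, aln.start) == (oracle[0], oracle[1])

    def test_duplicated_fragment_is_a_tie(self, zero_errors):
        # reference with the same 400 bp block at two loci
        base = dm.generate_reference(1, 2000, 0.02, seed=34)["contig1"]
        block = base[300:700]
        ref = {"contig1": base[:1200] + block + base[1200:]}
        meth = dm.DuplexMethylome(ref, {})
        from duplexmeth.genome import cpg_positions
        meth.states = {("contig1", int(p)): dm.CpGState.from_name("CC")
                       for p in cpg_positions(ref["contig1"])}
        from duplexmeth.simulate import Fragment, build_construct
        rng = np.random.default_rng(0)
        con = build_construct(Fragment("contig1", 400, 500), meth, zero_errors, rng)
        quad = InsertQuad("dup", con.a, con.b, con.c, con.d)
        aln, reason = align_quad(quad, ReferenceIndex(ref))
        assert aln is None and reason == "ambiguous"


class TestDeduplicate:
    def test_idempotent_and_name_deterministic(self):
        alns = [FragmentAlignment("b", "c1", 10, 110, 0),
                FragmentAlignment("a", "c1", 10, 110, 0),
                FragmentAlignment("z", "c1", 200, 300, 0)]
        once = deduplicate(alns)
        assert [a.name for a in once] == ["a", "z"]
        assert deduplicate(once) == once
        assert deduplicate([]) == []

    def test_post_dedup_count_matches_unique_truth_fragments(self, small_methylome):
        em = ChemistryErrorModel(p_fail_deam=0, p_overdeam_m=0, p_overdeam_h=0,
                                 p_copy_fail=0, p_copy_spurious=0, p_seq_err=0,
                                 dup_rate=0.1, side_product_rate=0)
        pairs, tp, _ = simulate_reads(small_methylome, 1500, em, seed=35)
        quads, _ = extract_quads([(p.name, p.r1, p.r2) for p in pairs])
        index = ReferenceIndex(small_methylome.reference)
        alns = [align_quad(q, index)[0] for q in quads]
        alns = [a for a in alns if a is not None]
        deduped = deduplicate(alns)
        aligned_names = {a.name for a in alns}
        unique_truth = tp[tp.name.isin(aligned_names)][
            ["contig", "start", "end"]].drop_duplicates()
        assert len(deduped) == len(unique_truth)


class TestCallQuads:
    def test_truncated_dyad_not_called(self):
        # dyad C at the last base of the fragment: G falls outside
        ref = {"c": "ATATATATAT" + "CG" + "ATATATATAT"}
        quad = InsertQuad("x", "ATATATATATC", "TATATATATAT"[:11], "ATATATATATT", "ATATATATATT")
        aln = FragmentAlignment("x", "c", 0, 11, 0)
        calls, skipped = call_quads(aln, quad, ref)
        assert calls == [] and skipped == 0

    def test_sequencing_error_base_skips_site(self):
        ref = {"c": "ATATA" + "CG" + "ATATA"}
        # insert a carries a G at the dyad C position
        quad = InsertQuad("x", "ATATAGGATATA", "TATATTCTATAT",
                          "ATATACGATATA"[:12], "TATATCGTATAT")
        aln = FragmentAlignment("x", "c", 0, 12, 0)
        calls, skipped = call_quads(aln, quad, ref)
        assert calls == [] and skipped == 1

    def test_zero_error_calls_decode_to_truth(self, small_genome_quads):
        meth, quads, truth = small_genome_quads
        index = ReferenceIndex(meth.reference)
        n_checked = 0
        for quad in quads[:80]:
            aln, _ = align_quad(quad, index)
            calls, skipped = call_quads(aln, quad, meth.reference)
            assert skipped == 0
            for pos, cq in calls:
                true_state = meth.states[(aln.contig, pos)]
                assert dm.decode_state(cq) == true_state
                n_checked += 1
        assert n_checked > 50


class TestCompileSites:
    def test_zero_error_no_implausible(self, zero_sites):
        sites, stats = zero_sites
        assert (sites["implausible"] == 0).all()
        assert (sites["depth"] == sites[list(STATE_ORDER)].sum(axis=1)).all()

    def test_spurious_copy_methylation_on_unmodified_genome(self):
        """p_copy_spurious=1 on an all-CC genome methylates every copy
        strand over an unmodified original: every quad is implausible."""
        ref = dm.generate_reference(1, 3000, 0.02, seed=36)
        from duplexmeth.model import StateFractions
        meth = dm.assign_states(ref, StateFractions.from_counts({"CC": 1}), seed=37)
        em = ChemistryErrorModel(p_fail_deam=0, p_overdeam_m=0, p_overdeam_h=0,
                                 p_copy_fail=0, p_copy_spurious=1.0, p_seq_err=0,
                                 dup_rate=0, side_product_rate=0)
        pairs, _, _ = simulate_reads(meth, 200, em, seed=38)
        quads, _ = extract_quads([(p.name, p.r1, p.r2) for p in pairs])
        sites, stats = call_sites(quads, meth.reference)
        assert len(sites) > 0
        assert (sites[list(STATE_ORDER)].to_numpy() == 0).all()
        assert (sites["implausible"] > 0).all()

    def test_depth_is_per_fragment_duplex_depth(self, zero_sites, zero_sim, small_methylome):
        """One deduplicated fragment contributes exactly 1 to depth at each
        dyad it fully covers (duplex depth: both strands in one count)."""
        sites, _ = zero_sites
        _, tp, _ = zero_sim
        # recompute expected coverage from unique truth fragments
        unique = tp[["contig", "start", "end"]].drop_duplicates()
        import collections
        expected = collections.Counter()
        positions = {(c, p) for c, p in small_methylome.states}
        for row in unique.itertuples():
            seq = small_methylome.reference[row.contig][row.start:row.end]
            from duplexmeth.genome import cpg_positions
            for i in cpg_positions(seq):
                if row.start + i + 1 < row.end:
                    expected[(row.contig, row.start + int(i))] += 1
        observed = {(r.contig, r.pos0): r.depth for r in sites.itertuples()}
        # quads lost to read-length truncation can only lower depth
        missing = {k: v for k, v in expected.items() if observed.get(k, 0) != v}
        assert len(missing) <= 0.02 * len(expected)

    def test_end_to_end_zero_error_identity(self, zero_sites, small_methylome):
        """Core recovery property: simulate -> extract -> align -> dedup ->
        call -> compile returns the true state for 100% of called sites."""
        sites, _ = zero_sites
        assert len(sites) > 300
        for row in sites.itertuples():
            true = small_methylome.states[(row.contig, row.pos0)].name
            for name in STATE_ORDER:
                count = getattr(row, name)
                assert count == (row.depth if name == true else 0)
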