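"""Forward chemistry model: fragmentation, construct assembly, read emission."""

import numpy as np
import pytest

import duplexmeth as dm
from duplexmeth.genome import DuplexMethylome
from duplexmeth.model import CpGState, STATE_ORDER, encode_calls
from duplexmeth.simulate import (
    AdapterConfig,
    ChemistryErrorModel,
    Fragment,
    _sample_strand,
    analytic_confusion,
    build_construct,
    emit_reads,
    fragmentize,
    strand_outcome_probs,
)


def one_site_methylome(state_name: str, length: int = 120, pos: int = 60):
    """A single CpG dyad of a chosen state in otherwise CpG-free sequence."""
    ref = dm.generate_reference(1, max(200, length), 0.001, seed=13)
    seq = list(ref["contig1"][:length])
    # clear any dyads the generator placed, then plant one
    from duplexmeth.genome import cpg_positions
    for p in cpg_positions("".join(seq)):
        seq[p + 1] = "A"
    seq[pos], seq[pos + 1] = "C", "G"
    s = "".join(seq)
    assert list(cpg_positions(s)) == [pos]
    return DuplexMethylome({"contig1": s},
                           {("contig1", pos): CpGState.from_name(state_name)})


class TestFragmentize:
    def test_mean_length_clt(self, small_methylome):
        frags = fragmentize(small_methylome, 1000, mean_len=100, sd_len=10, seed=1)
        lengths = np.array([f.end - f.start for f in frags])
        assert abs(lengths.mean() - 100) < 2  # ~6 s.e. of the mean
        assert lengths.min() >= 40 and lengths.max() <= 200

    def test_deterministic(self, small_methylome):
        a = fragmentize(small_methylome, 50, seed=7)
        b = fragmentize(small_methylome, 50, seed=7)
        assert a == b

    def test_empty_methylome(self):
        empty = DuplexMethylome({}, {})
        assert fragmentize(empty, 100, seed=1) == []

    def test_short_contig_skipped_with_warning(self):
        meth = DuplexMethylome({"tiny": "ACGT" * 10, "big": "ACGT" * 100}, {})
        with pytest.warns(UserWarning, match="tiny"):
            frags = fragmentize(meth, 50, mean_len=100, seed=1)
        assert {f.contig for f in frags} == {"big"}

    def test_rejects_tiny_mean(self, small_methylome):
        with pytest.raises(ValueError):
            fragmentize(small_methylome, 10, mean_len=20)


class TestBuildConstruct:
    @pytest.mark.parametrize("state_name", STATE_ORDER)
    def test_zero_error_truth_equals_encoded_calls(self, state_name, zero_errors):
        meth = one_site_methylome(state_name)
        rng = np.random.default_rng(0)
        con = build_construct(Fragment("contig1", 10, 110), meth, zero_errors, rng)
        assert con.truth_calls == [
            (60, state_name, encode_calls(CpGState.from_name(state_name)))]
        # all four inserts span the fragment
        assert len(con.a) == len(con.b) == len(con.c) == len(con.d) == 100

    def test_zero_error_no_cytosine_outside_protected_sites(self, zero_errors):
        meth = one_site_methylome("CC")
        rng = np.random.default_rng(0)
        con = build_construct(Fragment("contig1", 0, 120), meth, zero_errors, rng)
        for insert in (con.a, con.b, con.c, con.d):
            assert "C" not in insert  # fully unmodified: everything deaminates

    def test_fail_deam_one_retains_every_c(self):
        meth = one_site_methylome("MM")
        em = ChemistryErrorModel.zero()
        em = ChemistryErrorModel(**{**{f: 0.0 for f in em.__dataclass_fields__},
                                    "p_fail_deam": 1.0})
        rng = np.random.default_rng(0)
        con = build_construct(Fragment("contig1", 0, 120), meth, em, rng)
        seq = meth.reference["contig1"][:120]
        # every plus-strand C is retained in insert a
        assert all(con.a[i] == "C" for i, b in enumerate(seq) if b == "C")
        # every minus-strand C (plus-strand G) is retained in insert b
        minus_cs = [i for i, b in enumerate(seq) if b == "G"]
        assert all(con.b[len(seq) - 1 - i] == "C" for i in minus_cs)

    def test_out_of_bounds_fragment_raises(self, small_methylome, zero_errors):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            build_construct(Fragment("contig1", 19_990, 20_090),
                            small_methylome, zero_errors, rng)


class TestStrandChemistry:
    @pytest.mark.parametrize("mark", ["C", "M", "H"])
    def test_sampler_matches_enumeration(self, mark):
        """The per-strand sampler agrees with an explicit enumeration of the
        latent chemistry events (copy-methylation decision, then independent
        deamination outcomes on original and copy)."""
        from duplexmeth.model import StrandMark
        em = ChemistryErrorModel(p_fail_deam=0.03, p_overdeam_m=0.04,
                                 p_overdeam_h=0.08, p_copy_fail=0.05,
                                 p_copy_spurious=0.02, p_seq_err=0.0,
                                 dup_rate=0.0, side_product_rate=0.0)
        expected: dict[tuple[int, int], float] = {}
        p_cm = {"M": 1 - em.p_copy_fail, "H": em.p_copy_spurious,
                "C": em.p_copy_spurious}[mark]
        p_o1 = {"C": em.p_fail_deam, "M": 1 - em.p_overdeam_m,
                "H": 1 - em.p_overdeam_h}[mark]
        for cm, pcm in ((1, p_cm), (0, 1 - p_cm)):
            p_c1 = (1 - em.p_overdeam_m) if cm else em.p_fail_deam
            for o in (0, 1):
                for c in (0, 1):
                    expected[(o, c)] = expected.get((o, c), 0.0) + (
                        pcm * (p_o1 if o else 1 - p_o1) * (p_c1 if c else 1 - p_c1))
        assert strand_outcome_probs(StrandMark(mark), em) == pytest.approx(expected)

        rng = np.random.default_rng(99)
        n = 20_000
        counts: dict[tuple[int, int], int] = {}
        for _ in range(n):
            oc = _sample_strand(StrandMark(mark), em, rng)
            counts[oc] = counts.get(oc, 0) + 1
        for oc, p in expected.items():
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(counts.get(oc, 0) / n - p) < 4 * sd + 1e-4

    def test_single_overdeamination_error_mass(self):
        """With p_overdeam_m = eps as the only error, a true MM site is
        miscalled MH or HM (copy-strand 5mC deaminated) with total analytic
        mass 2*eps*(1-eps) to within the valid-call renormalization."""
        eps = 0.05
        em = ChemistryErrorModel(p_fail_deam=0, p_overdeam_m=eps, p_overdeam_h=0,
                                 p_copy_fail=0, p_copy_spurious=0, p_seq_err=0,
                                 dup_rate=0, side_product_rate=0)
        cm = analytic_confusion(em)
        j = STATE_ORDER.index("MM")
        mass = cm.matrix[STATE_ORDER.index("MH"), j] + cm.matrix[STATE_ORDER.index("HM"), j]
        assert mass == pytest.approx(2 * eps * (1 - eps), rel=0.02)

    def test_zero_error_confusion_is_identity(self, zero_errors):
        cm = analytic_confusion(zero_errors)
        assert np.allclose(cm.matrix, np.eye(9))
        assert np.allclose(cm.implausible_rate, 0)


class TestAdapterConfig:
    def test_default_valid(self):
        cfg = AdapterConfig()
        assert cfg.remnant == cfg.cleavable[-10:]

    def test_shared_substring_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            AdapterConfig(intact="CATCTATATCCATGACCACTGTCAC",
                          cleavable="TTCATCTATATCCATGAGGGAGGAA")

    def test_error_model_bounds(self):
        with pytest.raises(ValueError):
            ChemistryErrorModel(p_seq_err=1.5)


class TestEmitReads:
    def test_layout_single_intact_hit(self, zero_errors):
        meth = one_site_methylome("MM")
        rng = np.random.default_rng(0)
        con = build_construct(Fragment("contig1", 10, 110), meth, zero_errors, rng)
        adapters = AdapterConfig()
        pairs, tp, tc = emit_reads([con], adapters, errors=zero_errors, seed=1)
        (pair,) = pairs
        assert pair.r1.count(adapters.intact) == 1
        assert pair.r1.startswith(con.a)
        assert pair.r2.startswith(con.c + adapters.remnant + con.d)
        assert len(pair.q1) == len(pair.r1)

    def test_no_duplicates_means_unique_names(self, small_methylome, zero_errors):
        pairs, _, _ = dm.simulate_reads(small_methylome, 500, zero_errors, seed=5)
        names = [p.name for p in pairs]
        assert len(names) == len(set(names))

    def test_duplication_marked_in_truth(self, small_methylome):
        em = ChemistryErrorModel(p_fail_deam=0, p_overdeam_m=0, p_overdeam_h=0,
                                 p_copy_fail=0, p_copy_spurious=0, p_seq_err=0,
                                 dup_rate=0.3, side_product_rate=0)
        pairs, tp, _ = dm.simulate_reads(small_methylome, 400, em, seed=6)
        dups = tp[tp.duplicate_of != "."]
        assert len(dups) > 0
        assert set(dups.duplicate_of) <= set(tp.name)
        assert len(tp) == len(pairs)

    def test_side_product_fraction_small_scale(self, small_methylome):
        em = ChemistryErrorModel(p_fail_deam=0, p_overdeam_m=0, p_overdeam_h=0,
                                 p_copy_fail=0, p_copy_spurious=0, p_seq_err=0,
                                 dup_rate=0, side_product_rate=0.2)
        pairs, tp, _ = dm.simulate_reads(small_methylome, 20_000, em, seed=7)
        frac = tp.side_product.mean()
        sd = np.sqrt(0.2 * 0.8 / len(tp))
        assert abs(frac - 0.2) < 4 * sd

    def test_read_len_guard(self, small_methylome, zero_errors):
        meth = one_site_methylome("MM")
        rng = np.random.default_rng(0)
        con = build_construct(Fragment("contig1", 10, 110), meth, zero_errors, rng)
        with pytest.raises(ValueError):
            emit_reads([con], AdapterConfig(), read_len=50, errors=zero_errors)
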