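"""Forward model of the hairpin duplex-methylation library chemistry.

The simulated workflow mirrors the laboratory one: duplex fragments are
capped with a 1:1 mixture of a cleavable and a noncleavable hairpin adapter;
cleavage of the dU-containing adapter yields a self-priming construct whose
extension synthesizes a "copy" strand for each original strand; a
maintenance methyltransferase copy-methylates copy-strand CpGs only opposite
5mC on the original (glucosylated 5hmC blocks it); unmodified cytosines are
then deaminated and read as T.  Both original strands appear in Read 1,
both copy strands in Read 2:

    R1 = a + <intact hairpin> + b (+ trailing cleaved-adapter remnant)
    R2 = c + <remnant>        + d (+ trailing intact hairpin)

with inserts named a (original plus), b (original minus), c (copy of
minus) and d (copy of plus), so that a&d and b&c are the complementary
pairs.  Ligation side products carry two adapters of the same type, contain
only single-stranded information, and lack the target adapter
configuration; the parser removes them.

All stochastic failure modes of the chemistry are collected in
:class:`ChemistryErrorModel`; with every probability at zero the emitted
reads decode each CpG site to its true duplex state exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .genome import COMPLEMENT, DuplexMethylome, SpikeInPanel, revcomp
from .model import CallQuad, CpGState, StrandMark, STATE_ORDER, decode_state

_COMP_BASE = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdapterConfig:
    """Hairpin adapter sequences shared by simulator and parser.

    Default sequences are synthetic.  Adapter cytosines are treated as
    deamination-resistant (as for methylated or otherwise protected adapter
    bases), so adapters read through the conversion chemistry unchanged --
    their C content is what makes spurious matches inside converted,
    C-depleted inserts vanishingly rare.  The remnant left after dU cleavage
    is modeled as a fixed-length suffix of the cleavable adapter.
    """

    intact: str = "CATCTATATCCATGACCACTGTCAC"
    cleavable: str = "GGATCTACTAATGAAGGGCTCCAAG"
    remnant_len: int = 10

    @property
    def remnant(self) -> str:
        return self.cleavable[-self.remnant_len:]

    def __post_init__(self) -> None:
        for name in ("intact", "cleavable"):
            seq = getattr(self, name)
            if len(seq) < 15 or set(seq) - set("ACGT"):
                raise ValueError(f"{name} adapter must be >=15 nt of ACGT")
        if not 4 <= self.remnant_len <= len(self.cleavable):
            raise ValueError("remnant_len out of range")
        k = 12
        intact_kmers = {self.intact[i:i + k] for i in range(len(self.intact) - k + 1)}
        for i in range(len(self.cleavable) - k + 1):
            if self.cleavable[i:i + k] in intact_kmers:
                raise ValueError(
                    "adapters share a >=12 nt substring: parsing would be ambiguous")
        rem = self.remnant
        for i in range(len(self.intact) - len(rem) + 1):
            ham = sum(x != y for x, y in zip(rem, self.intact[i:i + len(rem)]))
            if ham < 4:
                raise ValueError(
                    "cleaved-adapter remnant resembles the intact adapter: "
                    "parsing would be ambiguous")


@dataclass(frozen=True)
class ChemistryErrorModel:
    """Stochastic failure modes of the chemistry, PCR and sequencing.

    Rates are per event.  ``side_product_rate`` and ``dup_rate`` defaults
    reproduce library-level statistics typical of real runs of this
    chemistry (16.5% non-target read pairs; 12.2% PCR/cluster duplication);
    the enzymatic failure rates are free parameters chosen so that every
    duplex state is still called with well over 94% accuracy.
    """

    p_fail_deam: float = 0.005     # unmodified C escapes deamination
    p_overdeam_m: float = 0.005    # protected 5mC deaminated anyway
    p_overdeam_h: float = 0.01     # protected 5hmC deaminated anyway
    p_copy_fail: float = 0.01      # DNMT5 misses a copy-methylation
    p_copy_spurious: float = 0.002 # copy-methylation opposite C or hmC
    p_seq_err: float = 0.001       # per-base substitution in sequencing
    dup_rate: float = 0.122        # PCR/cluster duplication probability
    side_product_rate: float = 0.165  # fraction of pairs that are side products

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f.name}={v} outside [0, 1]")

    @classmethod
    def zero(cls) -> "ChemistryErrorModel":
        return cls(**{f.name: 0.0 for f in fields(cls)})


class Fragment(NamedTuple):
    contig: str
    start: int
    end: int


class ReadPair(NamedTuple):
    name: str
    r1: str
    q1: str
    r2: str
    q2: str


@dataclass
class Construct:
    """One target library molecule: four converted inserts plus truth."""

    name: str
    contig: str
    start: int
    end: int
    a: str
    b: str
    c: str
    d: str
    # (pos0, true state name, realized pre-sequencing-error CallQuad)
    truth_calls: list[tuple[int, str, CallQuad]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Fragmentation
# ---------------------------------------------------------------------------

def fragmentize(methylome: DuplexMethylome, n_fragments: int,
                mean_len: int = 100, sd_len: int = 10,
                seed: int = 0) -> list[Fragment]:
    """Sonication model: clipped-normal lengths, uniform positions.

    Lengths are normal(mean, sd) clipped to [40, 2*mean]; contigs shorter
    than ``mean_len`` are skipped with a warning.  Deterministic given seed.
    """
    if mean_len < 40:
        raise ValueError("mean fragment length must be >= 40 bp")
    sizes = methylome.contig_sizes()
    eligible = sorted(c for c, n in sizes.items() if n >= mean_len)
    for c in sorted(set(sizes) - set(eligible)):
        warnings.warn(f"contig {c} shorter than mean fragment length; skipped")
    if not eligible or n_fragments <= 0:
        return []
    rng = np.random.default_rng(seed)
    weights = np.array([sizes[c] for c in eligible], dtype=float)
    weights /= weights.sum()
    picks = rng.choice(len(eligible), size=n_fragments, p=weights)
    lengths = np.clip(np.rint(rng.normal(mean_len, sd_len, n_fragments)),
                      40, 2 * mean_len).astype(int)
    out = []
    for k, li in zip(picks, lengths):
        contig = eligible[k]
        csize = sizes[contig]
        li = min(int(li), csize)
        start = int(rng.integers(0, csize - li + 1))
        out.append(Fragment(contig, start, start + li))
    return out


# ---------------------------------------------------------------------------
# Per-strand chemistry
# ---------------------------------------------------------------------------

def _sample_strand(mark: StrandMark, em: ChemistryErrorModel, rng) -> tuple[int, int]:
    """Realize one strand's (original, copy) call pair under the error model."""
    if mark is StrandMark.M:
        copy_meth = not (em.p_copy_fail and rng.random() < em.p_copy_fail)
        orig = 0 if (em.p_overdeam_m and rng.random() < em.p_overdeam_m) else 1
    elif mark is StrandMark.H:
        copy_meth = bool(em.p_copy_spurious and rng.random() < em.p_copy_spurious)
        orig = 0 if (em.p_overdeam_h and rng.random() < em.p_overdeam_h) else 1
    else:
        copy_meth = bool(em.p_copy_spurious and rng.random() < em.p_copy_spurious)
        orig = 1 if (em.p_fail_deam and rng.random() < em.p_fail_deam) else 0
    if copy_meth:
        copy = 0 if (em.p_overdeam_m and rng.random() < em.p_overdeam_m) else 1
    else:
        copy = 1 if (em.p_fail_deam and rng.random() < em.p_fail_deam) else 0
    return orig, copy


def strand_outcome_probs(mark: StrandMark, em: ChemistryErrorModel) -> dict[tuple[int, int], float]:
    """Exact probabilities of the four (original, copy) call outcomes.

    Original and copy calls are conditionally independent given the mark:
    copy-methylation is decided by the template mark before deamination.
    """
    if mark is StrandMark.M:
        p_copy_meth = 1.0 - em.p_copy_fail
        p_orig1 = 1.0 - em.p_overdeam_m
    elif mark is StrandMark.H:
        p_copy_meth = em.p_copy_spurious
        p_orig1 = 1.0 - em.p_overdeam_h
    else:
        p_copy_meth = em.p_copy_spurious
        p_orig1 = em.p_fail_deam
    p_copy1 = p_copy_meth * (1.0 - em.p_overdeam_m) + (1.0 - p_copy_meth) * em.p_fail_deam
    return {
        (o, c): (p_orig1 if o else 1.0 - p_orig1) * (p_copy1 if c else 1.0 - p_copy1)
        for o in (0, 1) for c in (0, 1)
    }


def analytic_confusion(em: ChemistryErrorModel):
    """Expected call-rate matrix of the chemistry error model (no sequencing
    error, no alignment loss).  Returns a :class:`~duplexmeth.correct.ConfusionMatrix`."""
    from .correct import ConfusionMatrix  # local: avoids import cycle
    from .model import IMPLAUSIBLE

    mat = np.zeros((9, 9))
    implaus = np.zeros(9)
    for j, true_name in enumerate(STATE_ORDER):
        st = CpGState.from_name(true_name)
        probs_plus = strand_outcome_probs(st.plus, em)
        probs_minus = strand_outcome_probs(st.minus, em)
        for (a, d), pp in probs_plus.items():
            for (b, c), pm in probs_minus.items():
                called = decode_state(CallQuad(a, d, b, c))
                if called is IMPLAUSIBLE:
                    implaus[j] += pp * pm
                else:
                    mat[STATE_ORDER.index(called.name), j] += pp * pm
    valid = mat.sum(axis=0)
    return ConfusionMatrix(mat / valid, implaus)


# ---------------------------------------------------------------------------
# Construct assembly
# ---------------------------------------------------------------------------

def build_construct(fragment: Fragment, methylome: DuplexMethylome,
                    errors: ChemistryErrorModel, rng,
                    name: str = "frag") -> Construct:
    """Run the conversion chemistry over one fragment.

    Emits the four inserts in deaminated space.  In plus-strand coordinates
    a dyad at position i places its four cytosines at: a and c at i
    (original plus C; copy-of-minus C), b and d at i+1 (original minus C;
    copy-of-plus C, both written on the complementary alphabet).  b and d
    are reversed at the end to give their own 5'->3' orientation.
    """
    contig, start, end = fragment
    seq = methylome.reference[contig]
    if not (0 <= start < end <= len(seq)):
        raise ValueError(f"fragment {fragment} outside contig bounds")
    P = list(seq[start:end])
    comp = [_COMP_BASE[b] for b in P]
    A = P.copy()
    Cc = P.copy()
    B = comp.copy()
    D = comp.copy()
    states = methylome.states
    pf = errors.p_fail_deam
    outcomes: dict[int, tuple[CpGState, tuple[int, int], tuple[int, int]]] = {}

    def dyad(i: int):
        o = outcomes.get(i)
        if o is None:
            st = states[(contig, i)]
            o = (st, _sample_strand(st.plus, errors, rng),
                 _sample_strand(st.minus, errors, rng))
            outcomes[i] = o
        return o

    for idx, base in enumerate(P):
        p = start + idx
        if base == "C":
            if (contig, p) in states:
                _, (a_call, _d), (_b, c_call) = dyad(p)
                A[idx] = "C" if a_call else "T"
                Cc[idx] = "C" if c_call else "T"
            else:
                A[idx] = "C" if (pf and rng.random() < pf) else "T"
                Cc[idx] = "C" if (pf and rng.random() < pf) else "T"
        elif base == "G":
            if (contig, p - 1) in states:
                _, (_a, d_call), (b_call, _c) = dyad(p - 1)
                B[idx] = "C" if b_call else "T"
                D[idx] = "C" if d_call else "T"
            else:
                B[idx] = "C" if (pf and rng.random() < pf) else "T"
                D[idx] = "C" if (pf and rng.random() < pf) else "T"

    truth = [
        (i, st.name, CallQuad(plus[0], plus[1], minus[0], minus[1]))
        for i, (st, plus, minus) in sorted(outcomes.items())
        if start <= i and i + 1 < end  # dyad fully inside the fragment
    ]
    return Construct(name, contig, start, end,
                     a="".join(A), b="".join(reversed(B)),
                     c="".join(Cc), d="".join(reversed(D)),
                     truth_calls=truth)


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------

_OTHER_BASES = {65: (67, 71, 84), 67: (65, 71, 84), 71: (65, 67, 84), 84: (65, 67, 71)}


def _sequencing_errors(s: str, p: float, rng) -> str:
    if not p:
        return s
    arr = np.frombuffer(s.encode(), dtype=np.uint8).copy()
    hits = np.where(rng.random(len(arr)) < p)[0]
    for i in hits:
        alts = _OTHER_BASES.get(int(arr[i]))
        if alts:
            arr[i] = alts[int(rng.integers(3))]
    return arr.tobytes().decode()


def emit_reads(constructs: Sequence[Construct], adapters: AdapterConfig,
               read_len: int = 300,
               errors: ChemistryErrorModel | None = None,
               seed: int = 0) -> tuple[list[ReadPair], pd.DataFrame, pd.DataFrame]:
    """Turn constructs into paired reads with truth tables.

    Each construct becomes a target pair, or -- with probability
    ``side_product_rate`` -- a same-adapter side product carrying only the
    original strands.  After each emitted pair, duplicates follow with
    probability ``dup_rate`` each (geometric tail), and per-base substitution
    errors are applied independently to every emitted read.

    Returns (pairs, pair truth table, per-CpG call truth table).
    """
    if errors is None:
        errors = ChemistryErrorModel()
    min_layout = 80 + len(adapters.intact) + adapters.remnant_len
    if read_len < min_layout:
        raise ValueError(f"read_len must be >= {min_layout} for the default layout")
    rng = np.random.default_rng(seed)
    pairs: list[ReadPair] = []
    truth_pairs: list[tuple] = []
    truth_calls: list[tuple] = []
    p_seq = errors.p_seq_err

    def push(name: str, r1: str, r2: str, base: Construct, is_side: int, dup_of: str):
        r1 = _sequencing_errors(r1, p_seq, rng)
        r2 = _sequencing_errors(r2, p_seq, rng)
        pairs.append(ReadPair(name, r1, "F" * len(r1), r2, "F" * len(r2)))
        truth_pairs.append((name, base.contig, base.start, base.end, is_side, dup_of))

    for serial, con in enumerate(constructs):
        name = f"frag{serial:07d}"
        is_side = int(rng.random() < errors.side_product_rate)
        if is_side:
            ad = adapters.intact if rng.random() < 0.5 else adapters.cleavable
            molecule = con.a + ad + con.b
            r1 = molecule[:read_len]
            r2 = revcomp(molecule)[:read_len]
        else:
            r1 = (con.a + adapters.intact + con.b + adapters.remnant)[:read_len]
            r2 = (con.c + adapters.remnant + con.d + adapters.intact)[:read_len]
            for pos0, state_name, quad in con.truth_calls:
                truth_calls.append((name, con.contig, pos0, state_name, *quad))
        push(name, r1, r2, con, is_side, ".")
        k = 0
        while errors.dup_rate and rng.random() < errors.dup_rate:
            k += 1
            push(f"{name}:d{k}", r1, r2, con, is_side, name)

    pair_df = pd.DataFrame(truth_pairs, columns=[
        "name", "contig", "start", "end", "side_product", "duplicate_of"])
    call_df = pd.DataFrame(truth_calls, columns=[
        "name", "contig", "pos0", "true_state", "a", "d", "b", "c"])
    return pairs, pair_df, call_df


def write_fastq(pairs: Iterable[ReadPair], r1_path, r2_path) -> None:
    import gzip

    def opener(path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        return gzip.open(path, "wt") if str(path).endswith(".gz") else open(path, "w")

    with opener(r1_path) as f1, opener(r2_path) as f2:
        for p in pairs:
            f1.write(f"@{p.name}\n{p.r1}\n+\n{p.q1}\n")
            f2.write(f"@{p.name}\n{p.r2}\n+\n{p.q2}\n")


# ---------------------------------------------------------------------------
# Convenience drivers
# ---------------------------------------------------------------------------

def simulate_reads(methylome: DuplexMethylome, n_fragments: int,
                   errors: ChemistryErrorModel | None = None,
                   adapters: AdapterConfig | None = None,
                   read_len: int = 300, mean_len: int = 100, sd_len: int = 10,
                   seed: int = 0):
    """Fragment, convert and sequence a methylome in one call."""
    errors = errors or ChemistryErrorModel()
    adapters = adapters or AdapterConfig()
    rng = np.random.default_rng(seed + 1)
    frags = fragmentize(methylome, n_fragments, mean_len, sd_len, seed)
    constructs = [build_construct(f, methylome, errors, rng) for f in frags]
    return emit_reads(constructs, adapters, read_len, errors, seed + 2)


def simulate_spikein_reads(panel: SpikeInPanel, pairs_per_duplex: int | None = None,
                           errors: ChemistryErrorModel | None = None,
                           adapters: AdapterConfig | None = None,
                           read_len: int = 300, seed: int = 0):
    """Simulate reads duplex-by-duplex so every control gets equal coverage."""
    errors = errors or ChemistryErrorModel()
    adapters = adapters or AdapterConfig()
    if pairs_per_duplex is None:
        pairs_per_duplex = panel.coverage_target
    meth = panel.as_methylome()
    all_pairs: list[ReadPair] = []
    pair_tables = []
    call_tables = []
    for j, dup in enumerate(panel.duplexes):
        sub = DuplexMethylome({dup.name: dup.sequence},
                              {(dup.name, p): st for p, st in dup.states.items()})
        rng = np.random.default_rng((seed, 101, j))
        frags = fragmentize(sub, pairs_per_duplex, mean_len=100, sd_len=10,
                            seed=int(rng.integers(2**31)))
        constructs = [build_construct(f, sub, errors, rng, name=dup.name)
                      for f in frags]
        pairs, pdf, cdf = emit_reads(constructs, adapters, read_len, errors,
                                     seed=int(rng.integers(2**31)))
        prefix = f"{dup.name}_"
        pairs = [p._replace(name=prefix + p.name) for p in pairs]
        for df in (pdf, cdf):
            df["name"] = prefix + df["name"]
        pdf["duplicate_of"] = np.where(pdf["duplicate_of"] == ".", ".",
                                       prefix + pdf["duplicate_of"])
        all_pairs.extend(pairs)
        pair_tables.append(pdf)
        call_tables.append(cdf)
    return (all_pairs,
            pd.concat(pair_tables, ignore_index=True),
            pd.concat(call_tables, ignore_index=True))
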