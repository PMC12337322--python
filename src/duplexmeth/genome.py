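"""Synthetic references, duplex methylomes, and spike-in control panels.

Everything downstream of this module is testable without any external data:
:func:`generate_reference` emits random contigs with a controlled CpG-dyad
density, :func:`assign_states` draws a duplex state for every dyad from a
target composition, and :func:`build_spikein_panel` constructs synthetic
control duplexes of known state (the analogue of the spike-in oligos used to
measure call-rate accuracy on real libraries).

Conventions: a CpG site is identified by the 0-based position of the C on
the plus strand; ground truth serializes as FASTA plus a TSV sidecar with
columns (contig, pos0, state).  Non-CpG cytosines are always unmodified --
they act only as deamination substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._tsv import read_table, write_table
from .model import DEFAULT_STATE_FRACTIONS, CpGState, StateFractions, STATE_ORDER

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 65, 67, 71, 84

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def cpg_positions(seq: str) -> np.ndarray:
    """0-based plus-strand C positions of every CpG dyad in ``seq``."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return np.where((arr[:-1] == _C) & (arr[1:] == _G))[0]


def _random_cg_free(rng: np.random.Generator, length: int) -> np.ndarray:
    """Random uint8 base array of given length containing no CpG dyad."""
    arr = _BASES[rng.integers(0, 4, size=length)].copy()
    # demote the G of every accidental C-G dyad; cannot create new dyads
    bad = np.where((arr[:-1] == _C) & (arr[1:] == _G))[0]
    arr[bad + 1] = _A
    return arr


def _inject_dyads(rng: np.random.Generator, arr: np.ndarray, n_target: int,
                  max_rounds: int = 12) -> None:
    """Plant CpG dyads in-place until their count reaches ``n_target``."""
    length = len(arr)
    for _ in range(max_rounds):
        current = int(np.count_nonzero((arr[:-1] == _C) & (arr[1:] == _G)))
        deficit = n_target - current
        if deficit <= 0:
            return
        cand = rng.choice(length - 3, size=min(length // 3, int(deficit * 1.5) + 8),
                          replace=False) + 1
        cand.sort()
        # injection at p writes C,G at (p, p+1); valid only if no existing
        # dyad overlaps p-1..p+2 and the previous accepted site is >=2 away
        ok = ~(((arr[cand - 1] == _C) & (arr[cand] == _G))
               | ((arr[cand] == _C) & (arr[cand + 1] == _G))
               | ((arr[cand + 1] == _C) & (arr[cand + 2] == _G)))
        cand = cand[ok]
        keep = np.ones(len(cand), dtype=bool)
        last = -10
        for i, p in enumerate(cand):
            if p - last < 2:
                keep[i] = False
            else:
                last = p
        cand = cand[keep][:deficit]
        arr[cand] = _C
        arr[cand + 1] = _G


def generate_reference(n_contigs: int, length: int, cpg_density: float,
                       seed: int) -> dict[str, str]:
    """Random contigs with a target CpG-dyad density (dyads per bp).

    Deterministic given ``seed``.  For contigs of >= 10 kb the realized
    density lands well within +/-20% of the target.
    """
    if length < 200:
        raise ValueError("contig length must be >= 200 bp")
    if not 0 < cpg_density < 0.25:
        raise ValueError("cpg_density must lie in (0, 0.25)")
    if n_contigs < 1:
        raise ValueError("need at least one contig")
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    for i in range(n_contigs):
        arr = _random_cg_free(rng, length)
        _inject_dyads(rng, arr, int(round(cpg_density * length)))
        out[f"contig{i + 1}"] = arr.tobytes().decode()
    return out


@dataclass
class DuplexMethylome:
    """A reference plus the true duplex state of every CpG dyad in it."""

    reference: dict[str, str]
    states: dict[tuple[str, int], CpGState]

    def contig_sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.reference.items()}

    def sites(self, contig: str) -> list[int]:
        return sorted(p for c, p in self.states if c == contig)

    def composition(self) -> StateFractions:
        counts: dict[str, int] = {}
        for st in self.states.values():
            counts[st.name] = counts.get(st.name, 0) + 1
        return StateFractions.from_counts(counts)

    def validate(self) -> None:
        keyed = set(self.states)
        for contig, seq in self.reference.items():
            dyads = {(contig, int(p)) for p in cpg_positions(seq)}
            extra = {k for k in keyed if k[0] == contig} - dyads
            missing = dyads - keyed
            if extra:
                raise ValueError(f"states keyed at non-CpG positions: {sorted(extra)[:3]}")
            if missing:
                raise ValueError(f"CpG dyads without a state: {sorted(missing)[:3]}")

    # ---- serialization -------------------------------------------------

    def write_fasta(self, path) -> None:
        write_fasta(self.reference, path)

    def write_states(self, path, comments: Iterable[str] = ()) -> None:
        rows = [(c, p, st.name) for (c, p), st in sorted(self.states.items())]
        df = pd.DataFrame(rows, columns=["contig", "pos0", "state"])
        write_table(df, path, comments)

    @classmethod
    def read(cls, fasta_path, states_path) -> "DuplexMethylome":
        reference = read_fasta(fasta_path)
        df = read_table(states_path)
        states = {
            (row.contig, int(row.pos0)): CpGState.from_name(row.state)
            for row in df.itertuples()
        }
        return cls(reference, states)


def write_fasta(reference: Mapping[str, str], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in reference.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def assign_states(reference: Mapping[str, str], fractions: StateFractions,
                  seed: int) -> DuplexMethylome:
    """Draw an i.i.d. duplex state for every CpG dyad of the reference."""
    fractions.validate_distribution(1e-9)
    rng = np.random.default_rng(seed)
    states: dict[tuple[str, int], CpGState] = {}
    from .model import STATES  # canonical order

    for contig in sorted(reference):
        pos = cpg_positions(reference[contig])
        draws = rng.choice(9, size=len(pos), p=fractions.values)
        for p, k in zip(pos, draws):
            states[(contig, int(p))] = STATES[k]
    return DuplexMethylome(dict(reference), states)


# ---------------------------------------------------------------------------
# Spike-in control panel
# ---------------------------------------------------------------------------

@dataclass
class SpikeInDuplex:
    name: str
    sequence: str
    states: dict[int, CpGState]  # pos0 of plus-strand C -> known state


@dataclass
class SpikeInPanel:
    """Synthetic control duplexes of known CpG state.

    Jointly covers all nine duplex states; decoded calls on these duplexes
    against the known truth yield the call-rate (confusion) matrix.
    """

    duplexes: list[SpikeInDuplex]
    coverage_target: int = 5000

    def state_coverage(self) -> set[str]:
        return {st.name for d in self.duplexes for st in d.states.values()}

    def as_methylome(self) -> DuplexMethylome:
        reference = {d.name: d.sequence for d in self.duplexes}
        states = {(d.name, p): st for d in self.duplexes for p, st in d.states.items()}
        return DuplexMethylome(reference, states)

    def write_fasta(self, path) -> None:
        write_fasta({d.name: d.sequence for d in self.duplexes}, path)

    def write_sidecar(self, path, comments: Iterable[str] = ()) -> None:
        self.as_methylome().write_states(path, comments)

    @classmethod
    def read(cls, fasta_path, sidecar_path, coverage_target: int = 5000) -> "SpikeInPanel":
        meth = DuplexMethylome.read(fasta_path, sidecar_path)
        duplexes = []
        for name, seq in meth.reference.items():
            states = {p: st for (c, p), st in meth.states.items() if c == name}
            duplexes.append(SpikeInDuplex(name, seq, states))
        return cls(duplexes, coverage_target)


def _contains_adapter(seq: str, adapters: Sequence[str], max_mismatch: int = 2) -> bool:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    for ad in adapters:
        ad_arr = np.frombuffer(ad.encode(), dtype=np.uint8)
        if len(arr) < len(ad_arr):
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr, len(ad_arr))
        if np.any((windows != ad_arr).sum(axis=1) <= max_mismatch):
            return True
    return False


def build_spikein_panel(seed: int = 0, duplex_length: int = 160,
                        cpgs_per_duplex: int = 4,
                        adapter_sequences: Sequence[str] | None = None,
                        coverage_target: int = 5000) -> SpikeInPanel:
    """One control duplex per duplex state, free of adapter-like substrings.

    Each duplex carries ``cpgs_per_duplex`` evenly spaced CpG dyads, all in
    the duplex's designated state, embedded in otherwise CpG-free random
    sequence.  Sequences that contain any configured hairpin-adapter
    sequence (within 2 substitutions) are rejected and redrawn.
    """
    if adapter_sequences is None:
        from .simulate import AdapterConfig  # lazy: avoids import cycle
        cfg = AdapterConfig()
        adapter_sequences = [cfg.intact, cfg.cleavable, cfg.remnant]
    rng = np.random.default_rng(seed)
    margin = 20
    span = duplex_length - 2 * margin
    offsets = [margin + round(i * span / (cpgs_per_duplex - 1)) if cpgs_per_duplex > 1
               else duplex_length // 2 for i in range(cpgs_per_duplex)]
    duplexes = []
    for state_name in STATE_ORDER:
        state = CpGState.from_name(state_name)
        for _ in range(100):
            arr = _random_cg_free(rng, duplex_length)
            for p in offsets:
                arr[p] = _C
                arr[p + 1] = _G
            seq = arr.tobytes().decode()
            if set(map(int, cpg_positions(seq))) != set(offsets):
                continue  # injection collided with itself; redraw
            if _contains_adapter(seq, adapter_sequences):
                continue
            if _contains_adapter(revcomp(seq), adapter_sequences):
                continue
            break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError(f"could not draw an adapter-free duplex for {state_name}")
        duplexes.append(SpikeInDuplex(
            f"spike_{state_name}", seq, {p: state for p in offsets}))
    panel = SpikeInPanel(duplexes, coverage_target)
    assert panel.state_coverage() == set(STATE_ORDER)
    return panel


def make_blacklist_free_methylome(seed: int = 0, length: int = 20_000,
                                  cpg_density: float = 0.02,
                                  fractions: StateFractions = DEFAULT_STATE_FRACTIONS,
                                  n_contigs: int = 1) -> DuplexMethylome:
    """Convenience: reference + states in one call (used by fixtures)."""
    ref = generate_reference(n_contigs, length, cpg_density, seed)
    return assign_states(ref, fractions, seed + 1)
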