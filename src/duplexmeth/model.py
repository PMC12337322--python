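"""Duplex CpG-state model and four-call decode logic.

A CpG dyad carries one of three cytosine marks on each strand -- unmodified
cytosine (C), 5-methylcytosine (M) or 5-hydroxymethylcytosine (H) -- giving
nine ordered duplex states.  Hairpin-linked library chemistry reads each
strand twice: once directly (the "original" strand, protected marks survive
enzymatic deamination and read as C) and once through an enzymatically
synthesized "copy" strand that is maintenance-methylated only opposite an
original 5mC (glucosylated 5hmC blocks copying).  Each dyad therefore yields
four binary methylation calls, written in the canonical order

    (a, d, b, c) = (original plus, copy of plus, original minus, copy of minus)

which decode to one of the nine states -- or to an implausible combination
that no chemistry path can produce (copy methylated over an unmodified
original).  This module is the single source of truth for that decode table;
the read simulator and the caller both import it.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, NamedTuple, Union

import numpy as np
import pandas as pd


class StrandMark(str, Enum):
    """Cytosine status of one strand of a CpG dyad."""

    C = "C"  # unmodified cytosine
    M = "M"  # 5-methylcytosine
    H = "H"  # 5-hydroxymethylcytosine


class _Implausible:
    """Sentinel for call combinations no chemistry path can produce."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "IMPLAUSIBLE"

    def __bool__(self) -> bool:
        return False


#: Returned by :func:`decode_strand` / :func:`decode_state` for the seven
#: call combinations that do not correspond to a plausible CpG state.
IMPLAUSIBLE = _Implausible()

#: Serialized label for implausible calls in tabular output.
IMPLAUSIBLE_LABEL = "implausible"


@dataclass(frozen=True)
class CpGState:
    """Ordered pair of strand marks at one CpG dyad (plus strand first)."""

    plus: StrandMark
    minus: StrandMark

    @property
    def name(self) -> str:
        return self.plus.value + self.minus.value

    def mirrored(self) -> "CpGState":
        """The state seen when the two strands are swapped (HC <-> CH etc.)."""
        return CpGState(self.minus, self.plus)

    @classmethod
    def from_name(cls, name: str) -> "CpGState":
        if len(name) != 2:
            raise ValueError(f"not a CpG state name: {name!r}")
        return cls(StrandMark(name[0]), StrandMark(name[1]))

    def __str__(self) -> str:
        return self.name


#: Canonical ordering of the nine duplex states.  Every vector, matrix and
#: TSV column block in the package follows this order.
STATE_ORDER: tuple[str, ...] = (
    "MM", "CC", "MC", "CM", "HC", "CH", "HM", "MH", "HH",
)

STATES: tuple[CpGState, ...] = tuple(CpGState.from_name(n) for n in STATE_ORDER)
STATE_INDEX: Mapping[str, int] = {n: i for i, n in enumerate(STATE_ORDER)}

#: Names of the three strand-asymmetric state groupings reported site-wise.
ASYMMETRIC_GROUPS: Mapping[str, tuple[str, str]] = {
    "MC+CM": ("MC", "CM"),
    "HC+CH": ("HC", "CH"),
    "HM+MH": ("HM", "MH"),
}


class CallQuad(NamedTuple):
    """The four binary methylation calls of one CpG dyad in one fragment.

    Order is (a, d, b, c): original plus strand, copy of plus strand,
    original minus strand, copy of minus strand.  A call of 1 means the
    cytosine survived deamination (read as C); 0 means it was deaminated
    (read as T).
    """

    a: int
    d: int
    b: int
    c: int


def decode_strand(original_call: int, copy_call: int) -> Union[StrandMark, _Implausible]:
    """Decode one strand's (original, copy) call pair to its cytosine mark.

    A protected original (5mC or 5hmC) reads 1; the copy strand reads 1 only
    when maintenance methylation fired, which requires 5mC on the original.
    Hence (1,1) -> M, (1,0) -> H, (0,0) -> C, and (0,1) is chemically
    impossible: a copy cannot be methylated opposite an unmodified original.
    """
    if original_call not in (0, 1) or copy_call not in (0, 1):
        raise ValueError("methylation calls must be 0 or 1")
    if original_call == 1:
        return StrandMark.M if copy_call == 1 else StrandMark.H
    return IMPLAUSIBLE if copy_call == 1 else StrandMark.C


def decode_state(quad: CallQuad) -> Union[CpGState, _Implausible]:
    """Decode a four-call quad to its duplex CpG state.

    The plus strand is read from (a, d) and the minus strand from (b, c);
    the quad is implausible if either strand pair is.
    """
    plus = decode_strand(quad.a, quad.d)
    minus = decode_strand(quad.b, quad.c)
    if plus is IMPLAUSIBLE or minus is IMPLAUSIBLE:
        return IMPLAUSIBLE
    return CpGState(plus, minus)


_ENCODE_STRAND: Mapping[StrandMark, tuple[int, int]] = {
    StrandMark.M: (1, 1),
    StrandMark.H: (1, 0),
    StrandMark.C: (0, 0),
}


def encode_calls(state: CpGState) -> CallQuad:
    """Inverse of :func:`decode_state`: the error-free quad of a state."""
    a, d = _ENCODE_STRAND[state.plus]
    b, c = _ENCODE_STRAND[state.minus]
    return CallQuad(a, d, b, c)


def all_quads() -> Iterable[CallQuad]:
    """All 16 possible four-call combinations, in lexicographic order."""
    for a in (0, 1):
        for d in (0, 1):
            for b in (0, 1):
                for c in (0, 1):
                    yield CallQuad(a, d, b, c)


@dataclass
class StateFractions:
    """Proportions of the nine duplex states, in :data:`STATE_ORDER`.

    Holds either a proper distribution (sums to 1) or an unnormalized
    non-negative vector (e.g. a clamped deconvolution estimate); use
    :meth:`validate_distribution` where a distribution is required.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (9,):
            raise ValueError("StateFractions requires exactly 9 entries")
        if np.any(self.values < 0):
            raise ValueError("state fractions must be non-negative")

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "StateFractions":
        missing = set(STATE_ORDER) - set(d)
        if missing:
            raise ValueError(f"missing states: {sorted(missing)}")
        return cls(np.array([d[n] for n in STATE_ORDER], dtype=float))

    @classmethod
    def from_counts(cls, counts: Mapping[str, float]) -> "StateFractions":
        v = np.array([counts.get(n, 0) for n in STATE_ORDER], dtype=float)
        total = v.sum()
        if total <= 0:
            raise ValueError("no counts to normalize")
        return cls(v / total)

    def __getitem__(self, state: str) -> float:
        return float(self.values[STATE_INDEX[state]])

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(STATE_ORDER, self.values)}

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(STATE_ORDER), name="fraction")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def validate_distribution(self, tol: float = 1e-9) -> "StateFractions":
        if abs(self.total - 1.0) > tol:
            raise ValueError(
                f"state fractions sum to {self.total!r}, not 1 (tol {tol})"
            )
        return self


#: A genome-wide duplex-state composition typical of primed mouse embryonic
#: stem cells: symmetric methylation dominates, followed by unmodified CpG
#: and hemimethylation; hydroxymethylation is rare and almost entirely
#: asymmetric.  Used as the simulator's default ground-truth composition.
DEFAULT_STATE_FRACTIONS = StateFractions(
    np.array([60.0, 22.0, 6.5, 6.5, 1.8, 1.8, 1.0, 1.0, 0.1]) / 100.7
)
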