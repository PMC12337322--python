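"""Spike-in confusion matrix and linear deconvolution of state fractions.

Decoded calls on the spike-in controls, whose true duplex state is known,
estimate the call-rate matrix P with entry p_ij = P(called state i | true
state j), column-stochastic over the nine called states after excluding
implausible calls.  Genome-wide observed fractions O then relate to the
true fractions T through the linear system

    O_i = sum_j p_ij * T_j,   i = 1..9

which is solved directly; any negative entries of the solution are clamped
to zero afterwards and the vector is deliberately NOT renormalized -- the
reported sum makes the clamping deficit visible instead of hiding it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._tsv import read_table, write_table
from .model import CpGState, STATE_ORDER, StateFractions


@dataclass
class ConfusionMatrix:
    """Call-rate matrix over the nine duplex states.

    ``matrix[i, j]`` is the probability that true state j (column) is called
    as state i (row), normalized over valid calls; ``implausible_rate[j]``
    is the fraction of calls on true state j that decoded to an implausible
    quad.  Rows and columns follow :data:`~duplexmeth.model.STATE_ORDER`.
    """

    matrix: np.ndarray
    implausible_rate: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.implausible_rate = np.asarray(self.implausible_rate, dtype=float)
        if self.matrix.shape != (9, 9) or self.implausible_rate.shape != (9,):
            raise ValueError("confusion matrix must be 9x9 with 9 implausible rates")
        if np.any(self.matrix < -1e-12) or np.any(self.matrix > 1 + 1e-12):
            raise ValueError("call rates must lie in [0, 1]")
        colsums = self.matrix.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-9):
            raise ValueError("confusion-matrix columns must sum to 1 over valid calls")

    def diagonal(self) -> np.ndarray:
        return np.diag(self.matrix).copy()

    def min_accuracy(self) -> float:
        """Worst per-state call rate (smallest diagonal entry)."""
        return float(self.diagonal().min())

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, index=[f"called_{s}" for s in STATE_ORDER],
                          columns=list(STATE_ORDER))
        df.loc["implausible"] = self.implausible_rate
        return df

    def write(self, path, comments: Sequence[str] = ()) -> None:
        frame = self.to_frame().reset_index(names="call")
        write_table(frame, path, comments)

    @classmethod
    def read(cls, path) -> "ConfusionMatrix":
        df = read_table(path).set_index("call")
        mat = df.loc[[f"called_{s}" for s in STATE_ORDER], list(STATE_ORDER)].to_numpy()
        implaus = df.loc["implausible", list(STATE_ORDER)].to_numpy()
        return cls(mat, implaus)


def build_confusion(site_counts: pd.DataFrame,
                    truth: Mapping[tuple[str, int], CpGState]) -> ConfusionMatrix:
    """Estimate the call-rate matrix from spike-in site tallies.

    ``site_counts`` is the compiled per-site table (one row per spike-in CpG
    with the nine state counts plus ``implausible``); ``truth`` maps each
    (contig, pos0) to its known state.  All CpG sites of the controls enter
    the estimate.  A true state with zero valid calls is an error: the
    matrix column would be undefined and more spike-in depth is needed.
    """
    counts = np.zeros((9, 9), dtype=float)
    implaus = np.zeros(9, dtype=float)
    for row in site_counts.itertuples():
        key = (row.contig, int(row.pos0))
        if key not in truth:
            raise KeyError(f"no known state for spike-in site {key}")
        j = STATE_ORDER.index(truth[key].name)
        for i, name in enumerate(STATE_ORDER):
            counts[i, j] += getattr(row, name)
        implaus[j] += row.implausible
    valid = counts.sum(axis=0)
    for j, name in enumerate(STATE_ORDER):
        if valid[j] == 0:
            raise ValueError(
                f"true state {name} has zero valid spike-in calls; "
                "increase spike-in coverage")
    total = valid + implaus
    return ConfusionMatrix(counts / valid, implaus / total)


def observed_fractions(site_counts: pd.DataFrame) -> StateFractions:
    """Genome-wide observed state fractions over all valid calls."""
    totals = {name: float(site_counts[name].sum()) for name in STATE_ORDER}
    return StateFractions.from_counts(totals)


@dataclass
class CorrectionResult:
    """Outcome of the linear deconvolution.

    ``estimate`` is the clamped solution (not renormalized; its ``total``
    exposes any clamping deficit), ``raw`` the pre-clamp solve,
    ``residual`` the norm of P @ raw - O, and ``condition`` the condition
    number of P.
    """

    estimate: StateFractions
    raw: np.ndarray
    residual: float
    condition: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "state": list(STATE_ORDER),
            "estimate": self.estimate.values,
            "raw_solution": self.raw,
        })


def correct_fractions(observed: StateFractions, p: ConfusionMatrix,
                      max_condition: float = 1e12) -> CorrectionResult:
    """Solve O = P T for the true state fractions T.

    Direct linear solve; negative solution entries are set to zero after
    solving.  A singular or numerically unusable P raises with advice to
    sequence the spike-ins deeper.
    """
    cond = p.condition_number()
    if not np.isfinite(cond) or cond > max_condition:
        raise ValueError(
            f"confusion matrix is singular or ill-conditioned (cond={cond:.3g}); "
            "more spike-in depth is needed to estimate the call rates")
    raw = np.linalg.solve(p.matrix, observed.values)
    residual = float(np.linalg.norm(p.matrix @ raw - observed.values))
    clamped = np.where(raw < 0, 0.0, raw)
    return CorrectionResult(StateFractions(clamped), raw, residual, cond)


def write_fractions(result: CorrectionResult, path, comments: Sequence[str] = ()):
    frame = result.as_frame()
    notes = list(comments) + [
        f"residual={result.residual:.3e} condition={result.condition:.6g} "
        f"estimate_sum={result.estimate.total:.9f}",
    ]
    write_table(frame, path, notes)
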