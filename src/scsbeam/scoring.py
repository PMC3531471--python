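"""Probabilistic scoring of partial solutions and the dominance relation.

The quality estimate for a partial supersequence follows the idea behind
the IBS beam search: rate a candidate by the probability that a uniform
random string would embed everything the candidate has not yet embedded.

For a fixed string of length ``i`` and a uniform random string of length
``j`` over an alphabet of size ``q``, the embedding probability ``P[i][j]``
satisfies the recurrence

    P[0][j] = 1
    P[i][j] = 0                                   for i > j
    P[i][j] = (1/q) P[i-1][j-1] + (1 - 1/q) P[i][j-1]   otherwise

(conditioning on whether the random string's first symbol matches the fixed
string's first symbol).  The heuristic value of a candidate is the product
over input strings of ``P[r_i][j]`` where ``r_i`` is the length of the
still-unembedded part of string ``i`` — the strings are treated as
independent.  Products over many strings underflow double precision, so
ranking uses the equivalent sum of logs.

Dominance: at equal constructed length, a candidate whose embedded-prefix
vector is componentwise <= another's can be discarded — anything the weaker
candidate can still reach, the stronger one can reach at least as cheaply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import CandidateSolution, Instance

__all__ = [
    "ProbabilityTable",
    "build_probability_table",
    "heuristic_value",
    "log_heuristic",
    "dominates",
]


@dataclass(frozen=True)
class ProbabilityTable:
    """DP table of embedding probabilities for a given alphabet size.

    ``P[i, j]`` = probability that a fixed string of length ``i`` is a
    subsequence of a uniform random string of length ``j``.  ``logP`` is a
    plain nested list mirror of ``log(P)`` (``-inf`` where ``P`` is 0),
    kept as Python floats because the beam search indexes it per candidate
    in a tight loop.
    """

    q: int
    imax: int
    jmax: int
    P: np.ndarray
    logP: list[list[float]]
    logP_np: np.ndarray


def build_probability_table(q: int, imax: int, jmax: int) -> ProbabilityTable:
    """Populate the embedding-probability table for alphabet size ``q``.

    Satisfies the base cases and recurrence exactly; the ``i = 1`` row
    equals the closed form ``1 - (1 - 1/q)**j`` (probability that at least
    one of ``j`` draws matches a given symbol).
    """
    if q < 1:
        raise ValueError("alphabet size q must be >= 1")
    if imax < 0 or jmax < 0:
        raise ValueError("table bounds must be nonnegative")
    P = np.zeros((imax + 1, jmax + 1))
    P[0, :] = 1.0
    p = 1.0 / q
    for i in range(1, imax + 1):
        for j in range(i, jmax + 1):
            P[i, j] = p * P[i - 1, j - 1] + (1.0 - p) * P[i, j - 1]
    with np.errstate(divide="ignore"):
        logP = np.log(P)
    return ProbabilityTable(q=q, imax=imax, jmax=jmax, P=P,
                            logP=logP.tolist(), logP_np=logP)


def _reference_length(r: tuple[int, ...], tab: ProbabilityTable,
                      length_mode: str, fixed_length: int | None) -> int:
    if length_mode == "max_remaining":
        return max(r) if r else 0
    if length_mode == "fixed":
        if fixed_length is None:
            raise ValueError("length_mode='fixed' requires fixed_length")
        return fixed_length
    raise ValueError(f"unknown length_mode {length_mode!r}")


def log_heuristic(lambdas: tuple[int, ...], lengths: tuple[int, ...],
                  tab: ProbabilityTable, length_mode: str = "max_remaining",
                  fixed_length: int | None = None) -> float:
    """Sum over strings of ``log P[r_i][j]`` — the ranking form of the heuristic."""
    r = tuple(n - l for l, n in zip(lambdas, lengths))
    j = _reference_length(r, tab, length_mode, fixed_length)
    if r and max(r) > tab.imax or j > tab.jmax:
        raise ValueError("probability table bounds exceeded")
    logP = tab.logP
    return sum(logP[ri][j] for ri in r)


def heuristic_value(c: CandidateSolution, inst: Instance, tab: ProbabilityTable,
                    length_mode: str = "max_remaining",
                    fixed_length: int | None = None) -> float:
    """Probability-scale heuristic: product of ``P[r_i][j]`` over input strings.

    ``j`` is the reference random-string length: the candidate's largest
    remaining length by default (``max_remaining``), or a user-set constant
    (``fixed``).  Equals 1 exactly when every string is fully embedded.
    May underflow for long remaining parts; use :func:`log_heuristic` for
    ranking.
    """
    return math.exp(
        log_heuristic(c.lambdas, inst.lengths, tab, length_mode, fixed_length)
    )


def dominates(a: CandidateSolution, b: CandidateSolution) -> bool:
    """True iff ``a``'s embedded-prefix vector is componentwise >= ``b``'s.

    Only meaningful between candidates of equal constructed length (the
    same beam level); comparing across levels is an error.  Non-strict, so
    a candidate dominates itself and exact duplicates of a dominator are
    pruned.
    """
    if len(a.seq) != len(b.seq):
        raise ValueError("dominance is defined only at equal constructed length")
    return all(x >= y for x, y in zip(a.lambdas, b.lambdas))
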