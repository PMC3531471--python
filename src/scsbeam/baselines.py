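"""Classical constructive heuristics and exact small-instance oracles.

Majority Merge (MM) appends, at each step, the symbol found at the front
of the most strings (counting their still-unembedded parts).  Weighted
Majority Merge (WMM) weights each front occurrence by the remaining
length of its string, so longer strings are shortened first.  Alphabet
Leftmost cycles a fixed permutation of the alphabet, skipping symbols
that sit at no string front.  All three produce valid supersequences and
serve as fast baselines.

The exact oracle searches the product state space (one embedded-prefix
counter per string) breadth-first; with unit edge costs BFS yields a
provably shortest common supersequence.  Memory is the number of states,
``prod(|s_i| + 1)``, hence the ``state_limit`` guard — the oracle is for
small instances and tests only.  ``lcs_length`` backs the classical
two-string identity |SCS| = |x| + |y| - |LCS|.
"""

from __future__ import annotations

import random
from math import prod

from .core import Instance

__all__ = [
    "majority_merge",
    "weighted_majority_merge",
    "alphabet_leftmost",
    "lcs_length",
    "exact_scs",
    "StateLimitExceeded",
]


class StateLimitExceeded(ValueError):
    """The product state space is too large for the exact oracle."""


def _greedy_merge(inst: Instance, score, tie_rng: random.Random | None) -> str:
    """Shared MM/WMM loop: repeatedly append the best-scoring front symbol."""
    strings = inst.strings
    lam = [0] * inst.m
    lengths = inst.lengths
    order = {a: i for i, a in enumerate(inst.alphabet.symbols)}
    out: list[str] = []
    while any(l < n for l, n in zip(lam, lengths)):
        scores: dict[str, float] = {}
        for i, s in enumerate(strings):
            if lam[i] < lengths[i]:
                a = s[lam[i]]
                scores[a] = scores.get(a, 0.0) + score(lengths[i] - lam[i])
        best = max(scores.values())
        tied = sorted((a for a, v in scores.items() if v == best),
                      key=order.__getitem__)
        a = tied[0] if tie_rng is None else tie_rng.choice(tied)
        out.append(a)
        for i, s in enumerate(strings):
            if lam[i] < lengths[i] and s[lam[i]] == a:
                lam[i] += 1
    return "".join(out)


def majority_merge(inst: Instance, tie_break: str = "alpha",
                   rng: random.Random | None = None) -> str:
    """Majority Merge: append the symbol at the most string fronts.

    ``tie_break="alpha"`` resolves ties by alphabet order (deterministic);
    ``"random"`` picks uniformly among the tied symbols using ``rng`` —
    the stochastic variant used in the literature.
    """
    if tie_break == "alpha":
        tie_rng = None
    elif tie_break == "random":
        tie_rng = rng if rng is not None else random.Random(0)
    else:
        raise ValueError(f"unknown tie_break {tie_break!r}")
    return _greedy_merge(inst, lambda _rem: 1.0, tie_rng)


def weighted_majority_merge(inst: Instance) -> str:
    """WMM: like MM but each front occurrence scores its string's remaining length."""
    return _greedy_merge(inst, lambda rem: float(rem), None)


def alphabet_leftmost(inst: Instance, perm: str | tuple[str, ...]) -> str:
    """Cycle a fixed alphabet permutation, appending only productive symbols."""
    perm = tuple(perm)
    if sorted(perm) != sorted(inst.alphabet.symbols):
        raise ValueError("perm must be a permutation of the instance alphabet")
    strings = inst.strings
    lam = [0] * inst.m
    lengths = inst.lengths
    out: list[str] = []
    while any(l < n for l, n in zip(lam, lengths)):
        for a in perm:
            hit = False
            for i, s in enumerate(strings):
                if lam[i] < lengths[i] and s[lam[i]] == a:
                    lam[i] += 1
                    hit = True
            if hit:
                out.append(a)
    return "".join(out)


def lcs_length(x: str, y: str) -> int:
    """Length of the longest common subsequence (rolling-row DP)."""
    if len(y) < len(x):
        x, y = y, x
    prev = [0] * (len(x) + 1)
    for cy in y:
        cur = [0]
        p0 = prev[0]
        for i, cx in enumerate(x, start=1):
            cur.append(prev[i - 1] + 1 if cx == cy
                       else max(prev[i], cur[i - 1]))
        prev = cur
    return prev[-1]


def exact_scs(inst: Instance, state_limit: int = 2_000_000) -> str:
    """A provably shortest common supersequence, by BFS over prefix-vectors.

    States are tuples of embedded-prefix lengths; each front symbol
    (taken in alphabet order, which fixes the tie-break) advances every
    string it fronts.  Raises :class:`StateLimitExceeded` when
    ``prod(|s_i| + 1)`` exceeds ``state_limit``.
    """
    strings = inst.strings
    lengths = inst.lengths
    if prod(n + 1 for n in lengths) > state_limit:
        raise StateLimitExceeded(
            f"state space larger than state_limit={state_limit}")
    goal = tuple(lengths)
    start = (0,) * inst.m
    if start == goal:
        return ""
    parent: dict[tuple[int, ...], tuple[tuple[int, ...], str]] = {start: None}
    frontier = [start]
    while frontier:
        nxt: list[tuple[int, ...]] = []
        for state in frontier:
            fronts = []
            seen = set()
            for l, s in zip(state, strings):
                if l < len(s) and s[l] not in seen:
                    seen.add(s[l])
            for a in inst.alphabet:
                if a in seen:
                    fronts.append(a)
            for a in fronts:
                child = tuple(
                    l + 1 if l < len(s) and s[l] == a else l
                    for l, s in zip(state, strings)
                )
                if child in parent:
                    continue
                parent[child] = (state, a)
                if child == goal:
                    out = []
                    cur = child
                    while parent[cur] is not None:
                        cur, sym = parent[cur]
                        out.append(sym)
                    return "".join(reversed(out))
                nxt.append(child)
        frontier = nxt
    raise RuntimeError("exhausted state space without reaching the goal")
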