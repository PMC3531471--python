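"""String primitives for the shortest common supersequence problem (SCSP).

A string ``t`` is a *supersequence* of ``s`` (equivalently, ``s`` embeds in
``t``) when every symbol of ``s`` occurs in ``t`` in the same order, not
necessarily contiguously.  An SCSP instance is a finite alphabet together
with a set of strings over it; solving it means finding a minimum-length
common supersequence of all of them.  The problem is NP-hard already for
binary alphabets, which is why everything above this module is heuristic.

The primitives here are the vocabulary every search layer is built from:
the embedding test, the progress function ``lambda_prefix`` (length of the
longest prefix of an input string embedded by a partial solution), its
complement ``remaining``, the suffix-split used by the reduction local
search, and incremental candidate bookkeeping (``advance``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

__all__ = [
    "Alphabet",
    "Instance",
    "CandidateSolution",
    "embeds",
    "lambda_prefix",
    "remaining",
    "longest_embedded_suffix_split",
    "advance",
    "is_supersequence_of_all",
]


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of distinct single-character symbols.

    Iteration order is fixed and reproducible; it defines the tie-break
    order used by deterministic heuristics.
    """

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        symbols = tuple(self.symbols)
        if len(symbols) < 1:
            raise ValueError("alphabet must contain at least one symbol")
        if any(len(a) != 1 for a in symbols):
            raise ValueError("alphabet symbols must be single characters")
        if len(set(symbols)) != len(symbols):
            raise ValueError("alphabet symbols must be pairwise distinct")
        object.__setattr__(self, "symbols", symbols)

    @classmethod
    def from_string(cls, s: str) -> "Alphabet":
        return cls(tuple(s))

    @property
    def size(self) -> int:
        return len(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def __contains__(self, a: str) -> bool:
        return a in self.symbols


@dataclass(frozen=True)
class Instance:
    """One SCSP problem: an alphabet plus the strings to cover.

    Empty input strings are dropped at construction (they are embedded by
    anything and carry no information); a warning is logged.  Duplicate
    strings are kept — they legitimately change Majority Merge counts and
    the probabilistic heuristic product.  Symbols are case-sensitive.
    """

    alphabet: Alphabet
    strings: tuple[str, ...]
    id: str | None = None

    def __post_init__(self) -> None:
        strings = tuple(self.strings)
        if len(strings) < 1:
            raise ValueError("instance must contain at least one string")
        kept = tuple(s for s in strings if s)
        if len(kept) < len(strings):
            logger.warning(
                "dropped %d empty string(s) from instance %s",
                len(strings) - len(kept), self.id,
            )
        for s in kept:
            for ch in s:
                if ch not in self.alphabet:
                    raise ValueError(
                        f"character {ch!r} not in alphabet {self.alphabet.symbols!r}"
                    )
        object.__setattr__(self, "strings", kept)

    @property
    def m(self) -> int:
        """Number of (non-empty) strings."""
        return len(self.strings)

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.strings)


@dataclass(slots=True)
class CandidateSolution:
    """A partial supersequence plus per-string embedded-prefix lengths.

    ``lambdas[i]`` is the length of the longest prefix of ``strings[i]``
    embedded by ``seq`` — the search's progress measure.  ``logh`` caches
    the log-space heuristic value once a scorer has computed it.
    """

    seq: str
    lambdas: tuple[int, ...]
    logh: float | None = field(default=None, compare=False)

    @classmethod
    def empty(cls, inst: Instance) -> "CandidateSolution":
        return cls("", (0,) * inst.m)

    def is_complete(self, inst: Instance) -> bool:
        return all(l == n for l, n in zip(self.lambdas, inst.lengths))


def embeds(t: str, s: str) -> bool:
    """True iff ``s`` is a subsequence of ``t`` (greedy left-to-right scan)."""
    if not s:
        return True
    it = iter(t)
    return all(ch in it for ch in s)


def lambda_prefix(y: str, s: str) -> int:
    """Length of the longest prefix of ``s`` embedded by ``y``.

    Greedy left-to-right matching attains the maximum: skipping an
    available match can never embed a longer prefix.
    """
    k = 0
    n = len(s)
    if n == 0:
        return 0
    nxt = s[0]
    for ch in y:
        if ch == nxt:
            k += 1
            if k == n:
                return k
            nxt = s[k]
    return k


def remaining(y: str, s: str) -> str:
    """The part of ``s`` not embedded by ``y`` (its suffix past the matched prefix)."""
    return s[lambda_prefix(y, s):]


def longest_embedded_suffix_split(s: str, y: str) -> str:
    """Prefix of ``s`` left over after removing its longest suffix embeddable in ``y``.

    Computed by a right-to-left greedy scan; returns ``s[:k]`` where
    ``s[k:]`` is the longest suffix of ``s`` that is a subsequence of
    ``y``.  Used by the reduction local search to build sub-instances.
    """
    i = len(s) - 1
    for ch in reversed(y):
        if i < 0:
            break
        if ch == s[i]:
            i -= 1
    return s[: i + 1]


def advance(c: CandidateSolution, a: str, inst: Instance) -> CandidateSolution:
    """Candidate for ``c.seq + a``: each lambda whose next unembedded symbol is ``a`` gains 1."""
    if a not in inst.alphabet:
        raise ValueError(f"symbol {a!r} not in instance alphabet")
    new = tuple(
        l + 1 if l < len(s) and s[l] == a else l
        for l, s in zip(c.lambdas, inst.strings)
    )
    return CandidateSolution(c.seq + a, new)


def is_supersequence_of_all(t: str, inst: Instance) -> bool:
    """True iff ``t`` embeds every string of the instance (vacuously true for none)."""
    return all(embeds(t, s) for s in inst.strings)
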