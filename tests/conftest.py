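"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random

import pytest

from scsbeam import Alphabet, Instance, default_alphabet


def embeds_recursive(t: str, s: str) -> bool:
    """Literal recursive definition of the supersequence relation.

    Independent of the greedy-scan implementation: t embeds s iff s is
    empty, or t is nonempty and either (heads match and the tails embed)
    or (t's tail embeds all of s).
    """
    if not s:
        return True
    if not t:
        return False
    if t[0] == s[0]:
        return embeds_recursive(t[1:], s[1:])
    return embeds_recursive(t[1:], s)


def random_toy_instance(rng: random.Random, label: str | None = None) -> Instance:
    """A small random instance: 2-4 strings of length <= 8 over q in {2,3,4}."""
    q = rng.choice((2, 3, 4))
    m = rng.choice((2, 3, 4))
    alphabet = default_alphabet(q)
    strings = tuple(
        "".join(rng.choice(alphabet.symbols)
                for _ in range(rng.randint(1, 8)))
        for _ in range(m)
    )
    return Instance(alphabet, strings, id=label)


@pytest.fixture
def ab_ba() -> Instance:
    """The classic two-string instance with optimum length 3."""
    return Instance(Alphabet.from_string("ab"), ("ab", "ba"))
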