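"""Probabilistic Beam Search (PBS) for the shortest common supersequence.

Level-synchronous construction: the beam holds up to ``kw`` partial
solutions of equal length.  Each level extends every member with every
symbol that contributes (embeds a new symbol of at least one string),
ranks the children by the probabilistic heuristic, seeds the next beam
with the top ``kb`` children (the *dominators*), then fills the remaining
slots one draw at a time: with probability ``mu`` the next member is
sampled by Baker's linear ranking over the remaining pool, otherwise the
pool's best is taken.  Either way the pick is discarded instead of added
if a dominator dominates it (dominance pruning).  ``mu = 0`` with
``kb = kw`` is plain deterministic beam search.

The first complete child found is returned immediately — it sits at the
lowest reachable level of the current run, and since every retained child
embeds at least one new symbol per level, termination is guaranteed within
the total input length.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np

from .core import CandidateSolution, Instance
from .scoring import ProbabilityTable, build_probability_table

__all__ = [
    "PBSConfig",
    "Beam",
    "contributes",
    "extend",
    "linear_rank_sample",
    "select_beam",
    "pbs_solve",
]


@dataclass(frozen=True)
class PBSConfig:
    """Knobs of one PBS run.

    beam_width (kw): partial solutions kept per level.
    dominators (kb): top-ranked children that enter the beam unconditionally
        and serve as references for dominance pruning; clipped to kw.
    mu: probability of the linear-ranking branch per fill draw (0 = greedy).
    seed: drives all randomness when no generator is passed explicitly.
    length_mode / fixed_length: reference random-string length for the
        heuristic (see scoring module).
    max_levels: safety cap on levels; defaults to the total input length,
        which no run can exceed.
    """

    beam_width: int = 100
    dominators: int = 11
    mu: float = 0.1
    seed: int = 0
    length_mode: str = "max_remaining"
    fixed_length: int | None = None
    max_levels: int | None = None

    def __post_init__(self) -> None:
        if self.beam_width < 1:
            raise ValueError("beam_width must be >= 1")
        if self.dominators < 0:
            raise ValueError("dominators must be >= 0")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")


@dataclass
class Beam:
    level: int
    members: list[CandidateSolution] = field(default_factory=list)


def contributes(c: CandidateSolution, a: str, inst: Instance) -> bool:
    """True iff appending ``a`` embeds a new symbol of at least one string."""
    return any(
        l < len(s) and s[l] == a for l, s in zip(c.lambdas, inst.strings)
    )


def extend(beam: Beam, inst: Instance) -> list[CandidateSolution]:
    """All contributing one-symbol extensions of the beam's members.

    No deduplication here: children from different parents may share a
    lambda vector; selection-time dominance pruning removes redundancy.
    """
    strings = inst.strings
    symbols = inst.alphabet.symbols
    children: list[CandidateSolution] = []
    for c in beam.members:
        lam = c.lambdas
        by_sym: dict[str, list[int]] = {}
        for i, (l, s) in enumerate(zip(lam, strings)):
            if l < len(s):
                by_sym.setdefault(s[l], []).append(i)
        for a in symbols:
            idxs = by_sym.get(a)
            if idxs:
                new = list(lam)
                for i in idxs:
                    new[i] += 1
                children.append(CandidateSolution(c.seq + a, tuple(new)))
    return children


def _linear_rank_index(n: int, rng: random.Random) -> int:
    """0-based index under Baker's linear ranking: weight of rank r is n - r + 1."""
    total = n * (n + 1) // 2
    u = rng.random() * total
    # smallest r (1-based) with S(r) = r*n - r*(r-1)/2 > u; start from the
    # real root of the quadratic and fix up.
    disc = (2 * n + 1) ** 2 - 8 * u
    r = max(1, int(((2 * n + 1) - math.sqrt(disc)) / 2))
    while r * n - r * (r - 1) // 2 <= u and r < n:
        r += 1
    while r > 1 and (r - 1) * n - (r - 1) * (r - 2) // 2 > u:
        r -= 1
    return r - 1


def linear_rank_sample(ranked: list[CandidateSolution],
                       rng: random.Random) -> CandidateSolution:
    """Draw one element from a best-first list with rank-linear probabilities.

    The element at rank r (1 = best) is chosen with probability
    proportional to ``N - r + 1``; with N = 2 the best wins 2/3 of draws.
    The caller removes the chosen element from its pool.
    """
    if not ranked:
        raise ValueError("cannot sample from an empty pool")
    return ranked[_linear_rank_index(len(ranked), rng)]


def _rank(children: list[CandidateSolution], inst: Instance,
          tab: ProbabilityTable, cfg: PBSConfig
          ) -> tuple[list[CandidateSolution], np.ndarray]:
    """Best-first order by log heuristic; ties by more total progress, then arrival.

    Returns the reordered children together with their lambda matrix (rows
    in ranked order), which select_beam reuses for dominance pruning.
    """
    lam = np.array([c.lambdas for c in children], dtype=np.int64)
    r = np.asarray(inst.lengths, dtype=np.int64)[None, :] - lam
    if cfg.length_mode == "fixed":
        if cfg.fixed_length is None:
            raise ValueError("length_mode='fixed' requires fixed_length")
        j = np.full(len(children), cfg.fixed_length)
    else:
        j = r.max(axis=1)
    logh = tab.logP_np[r, j[:, None]].sum(axis=1)
    # np.lexsort: last key is primary; arange makes ties stable by arrival
    order = np.lexsort((np.arange(len(children)), -lam.sum(axis=1), -logh))
    ranked = []
    for idx in order:
        c = children[idx]
        c.logh = float(logh[idx])
        ranked.append(c)
    return ranked, lam[order]


def select_beam(bprime: list[CandidateSolution], cfg: PBSConfig,
                inst: Instance, tab: ProbabilityTable,
                rng: random.Random) -> Beam:
    """Build the next beam from the children pool.

    The best ``min(kb, |pool|)`` children become dominators and enter the
    beam; the rest of the beam is filled draw by draw (greedy or linear
    ranking, governed by ``mu``), discarding draws dominated by any
    dominator.  A dominated draw consumes the draw but not a beam slot.
    If everything outside an empty dominator set gets pruned away, the
    overall best child is retained so the search can continue.
    """
    if not bprime:
        raise ValueError("cannot select from an empty candidate pool")
    level = len(bprime[0].seq)
    ranked, lam = _rank(bprime, inst, tab, cfg)
    best_overall = ranked[0]
    kb = min(cfg.dominators, len(ranked))
    members = ranked[:kb]
    pool = ranked[kb:]
    if kb and pool:
        # dominator set is fixed for the whole fill, so pruning flags can be
        # precomputed for the entire pool in one vector comparison
        dominated = (lam[None, :kb, :] >= lam[kb:, None, :]).all(2).any(1)
        dominated = dominated.tolist()
    else:
        dominated = [False] * len(pool)
    mu = cfg.mu
    members = list(members)
    while len(members) < cfg.beam_width and pool:
        if mu > 0.0 and rng.random() < mu:
            idx = _linear_rank_index(len(pool), rng)
        else:
            idx = 0
        c = pool.pop(idx)
        if dominated.pop(idx):
            continue
        members.append(c)
    if not members:
        members = [best_overall]
    return Beam(level=level, members=members)


def pbs_solve(inst: Instance, cfg: PBSConfig,
              rng: random.Random | None = None,
              tab: ProbabilityTable | None = None) -> str:
    """Run one PBS construction; returns a valid common supersequence.

    The result length is at least the longest input string and at most the
    total input length.  Identical (instance, config, seed) gives an
    identical result; with ``mu = 0`` and ``kb = kw`` the run is fully
    deterministic regardless of seed.
    """
    if rng is None:
        rng = random.Random(cfg.seed)
    if inst.m == 0:
        return ""
    if tab is None:
        n = max(inst.lengths)
        jmax = max(n, cfg.fixed_length or 0)
        tab = build_probability_table(inst.alphabet.size, n, jmax)
    empty = CandidateSolution.empty(inst)
    if empty.is_complete(inst):
        return ""
    beam = Beam(level=0, members=[empty])
    lengths = inst.lengths
    max_levels = cfg.max_levels if cfg.max_levels is not None else sum(lengths)
    for _ in range(max_levels):
        children = extend(beam, inst)
        for c in children:
            if c.lambdas == lengths:
                return c.seq
        beam = select_beam(children, cfg, inst, tab, rng)
    raise RuntimeError("beam search exceeded max_levels without completing")
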