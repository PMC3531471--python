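"""PBS as a local searcher: reduction and perturbation of a known solution.

Reduction: split the incumbent ``z`` into a prefix ``z[:p]`` and suffix
``y = z[p:]``.  The suffix already embeds, for each input string, some
longest suffix of that string; PBS then solves the sub-instance made of
the leftover (non-embedded) prefixes.  If the sub-solution ``w`` is
shorter than ``p``, the prefix is replaced (``z <- w + y``) and the scan
restarts.  Compositionality makes the replacement safe: ``w`` embeds what
the old prefix had to embed, ``y`` embeds the rest.

Perturbation: overwrite one position of ``z`` with a different symbol,
keep the mutated prefix up to and including that position, and repair by
solving the sub-instance of the parts of each string the prefix does not
embed.  The repair PBS's randomness ``mu`` rises linearly over the
iterations (0 -> 0.65 by default), so early rounds search near the
incumbent and later rounds drift to dissimilar solutions.  Only strictly
shorter candidates replace the incumbent, so both procedures are
non-worsening and validity-preserving by construction.
"""

from __future__ import annotations

import logging
import random
import time
from dataclasses import dataclass, replace

from .core import (
    Instance,
    is_supersequence_of_all,
    longest_embedded_suffix_split,
    remaining,
)
from .pbs import PBSConfig, pbs_solve
from .scoring import ProbabilityTable, build_probability_table

logger = logging.getLogger(__name__)

__all__ = ["PerturbationSchedule", "pbs_reduction", "pbs_perturbation"]


@dataclass(frozen=True)
class PerturbationSchedule:
    """Linear ramp of the repair PBS's randomness across iterations."""

    iterations: int = 100
    mu_start: float = 0.0
    mu_end: float = 0.65

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 <= self.mu_start <= self.mu_end <= 1.0:
            raise ValueError("need 0 <= mu_start <= mu_end <= 1")

    def mu_at(self, k: int) -> float:
        """Randomness for 1-based iteration ``k``."""
        if not 1 <= k <= self.iterations:
            raise ValueError("iteration index out of range")
        span = max(1, self.iterations - 1)
        return self.mu_start + (k - 1) * (self.mu_end - self.mu_start) / span


def _shared_table(inst: Instance, cfg: PBSConfig) -> ProbabilityTable:
    n = max(inst.lengths) if inst.m else 0
    jmax = max(n, cfg.fixed_length or 0)
    return build_probability_table(inst.alphabet.size, n, jmax)


def pbs_reduction(inst: Instance, z: str, cfg: PBSConfig,
                  rng: random.Random | None = None,
                  deadline: float | None = None) -> str:
    """Shorten a supersequence by re-solving prefixes against every split point.

    Split points scan ``p = 1 .. |z|`` ascending and restart from 1 after
    any improvement (``p = |z|`` keeps an empty suffix, i.e. re-solves the
    whole instance — without it, solutions one symbol off the optimum can
    be local optima of the scan).  The scan stops early at ``deadline``
    (monotonic-clock seconds), returning the incumbent.  Output is always
    a valid common supersequence no longer than the input.
    """
    if not is_supersequence_of_all(z, inst):
        raise ValueError("z is not a common supersequence of the instance")
    if rng is None:
        rng = random.Random(cfg.seed)
    tab = _shared_table(inst, cfg)
    improved = True
    while improved:
        improved = False
        for p in range(1, len(z) + 1):
            if deadline is not None and time.monotonic() >= deadline:
                return z
            y = z[p:]
            prefixes = tuple(
                longest_embedded_suffix_split(s, y) for s in inst.strings
            )
            nonempty = tuple(x for x in prefixes if x)
            if nonempty:
                sub = Instance(inst.alphabet, nonempty)
                w = pbs_solve(sub, cfg, rng, tab)
            else:
                w = ""
            if len(w) < p:
                z = w + y
                improved = True
                break
    return z


def pbs_perturbation(inst: Instance, z: str, sched: PerturbationSchedule,
                     cfg: PBSConfig, rng: random.Random | None = None,
                     deadline: float | None = None) -> str:
    """Mutate-and-repair local search around a supersequence.

    Each iteration mutates one uniformly chosen position of the *current*
    incumbent to a different uniformly chosen symbol, repairs with PBS at
    the schedule's randomness, and accepts only strict improvements.  A
    size-1 alphabet admits no mutation: the input is returned unchanged
    with a logged warning.
    """
    if not is_supersequence_of_all(z, inst):
        raise ValueError("z is not a common supersequence of the instance")
    if inst.alphabet.size < 2:
        logger.warning("alphabet of size 1: perturbation has no legal move")
        return z
    if rng is None:
        rng = random.Random(cfg.seed)
    tab = _shared_table(inst, cfg)
    symbols = inst.alphabet.symbols
    for k in range(1, sched.iterations + 1):
        if deadline is not None and time.monotonic() >= deadline:
            return z
        if not z:
            return z
        p = rng.randrange(len(z))
        a = rng.choice([b for b in symbols if b != z[p]])
        w = z[:p] + a
        suffixes = tuple(remaining(w, s) for s in inst.strings)
        nonempty = tuple(x for x in suffixes if x)
        if nonempty:
            sub = Instance(inst.alphabet, nonempty)
            repair = pbs_solve(sub, replace(cfg, mu=sched.mu_at(k)), rng, tab)
        else:
            repair = ""
        cand = w + repair
        if len(cand) < len(z):
            z = cand
    return z
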