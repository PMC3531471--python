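"""Multilevel PBS (MPBS): the anytime driver over construction + local search.

The driver first runs several independent seeded PBS constructions and
keeps the shortest result, then alternates the reduction and perturbation
local searches on the incumbent until the wall-clock budget runs out,
recording every improvement with its elapsed time.  It can be stopped at
any time and always holds a valid supersequence whose recorded length
never increases — the anytime contract.

Stopping: the time budget is always honoured (checked between
sub-instance solves, so a phase overshoots by at most one solve).  Two
optional extra stops exist: ``target_length`` (quit as soon as the
incumbent reaches a known-good length, e.g. a proven lower bound) and
``max_rounds`` (a fixed number of reduction+perturbation rounds, which
makes runs reproducible independently of machine speed).
"""

from __future__ import annotations

import csv
import random
import time
from dataclasses import dataclass, field, replace

from .core import Instance
from .local_search import PerturbationSchedule, pbs_perturbation, pbs_reduction
from .pbs import PBSConfig, pbs_solve
from .scoring import build_probability_table

__all__ = ["MPBSConfig", "TraceEvent", "RunTrace", "mpbs_solve", "rpd",
           "write_trace_csv"]

_SEED_SPACE = 2**31


def _default_construction() -> PBSConfig:
    return PBSConfig()


def _default_reduction() -> PBSConfig:
    # deterministic greedy repair keeps the many reduction sub-solves cheap
    return PBSConfig(mu=0.0)


def _default_perturbation() -> PBSConfig:
    return PBSConfig()


@dataclass(frozen=True)
class MPBSConfig:
    """Budget and per-phase settings of one MPBS run.

    All randomness flows from ``seed``: each construction run and each
    local-search phase gets its own derived sub-seed, so the whole run is
    reproducible (use ``max_rounds`` or ``target_length`` to decouple the
    stopping point from machine speed).
    """

    time_budget: float = 30.0
    initial_runs: int = 5
    construction_cfg: PBSConfig = field(default_factory=_default_construction)
    reduction_cfg: PBSConfig = field(default_factory=_default_reduction)
    perturbation_cfg: PBSConfig = field(default_factory=_default_perturbation)
    perturbation_schedule: PerturbationSchedule = field(
        default_factory=PerturbationSchedule)
    seed: int = 0
    target_length: int | None = None
    max_rounds: int | None = None

    def __post_init__(self) -> None:
        if self.time_budget <= 0:
            raise ValueError("time_budget must be positive")
        if self.initial_runs < 1:
            raise ValueError("initial_runs must be >= 1")


@dataclass(frozen=True)
class TraceEvent:
    elapsed_sec: float
    best_length: int
    phase: str  # construction | reduction | perturbation


@dataclass
class RunTrace:
    """Anytime log: every improvement of the incumbent, plus the final solution."""

    events: list[TraceEvent] = field(default_factory=list)
    final: str = ""


def rpd(length: int, best_known: int) -> float:
    """Relative percentage difference from a best-known length.

    ``100 * (length - best_known) / best_known``; negative when the
    solution improves on the reference.
    """
    if best_known < 1:
        raise ValueError("best_known must be a positive length")
    return 100.0 * (length - best_known) / best_known


def mpbs_solve(inst: Instance, cfg: MPBSConfig) -> tuple[str, RunTrace]:
    """Run MPBS on an instance; returns (best supersequence, anytime trace)."""
    t0 = time.monotonic()
    deadline = t0 + cfg.time_budget
    master = random.Random(cfg.seed)
    trace = RunTrace()

    def record(length: int, phase: str) -> None:
        trace.events.append(TraceEvent(time.monotonic() - t0, length, phase))

    def done(length: int) -> bool:
        return cfg.target_length is not None and length <= cfg.target_length

    if inst.m == 0:
        trace.final = ""
        record(0, "construction")
        return "", trace

    n = max(inst.lengths)
    tab = build_probability_table(inst.alphabet.size, n, n)

    best: str | None = None
    for _ in range(cfg.initial_runs):
        sub_rng = random.Random(master.randrange(_SEED_SPACE))
        z = pbs_solve(inst, cfg.construction_cfg, sub_rng, tab)
        if best is None or len(z) < len(best):
            best = z
            record(len(best), "construction")
        if done(len(best)) or time.monotonic() >= deadline:
            break
    assert best is not None

    rounds = 0
    while (time.monotonic() < deadline and not done(len(best))
           and (cfg.max_rounds is None or rounds < cfg.max_rounds)):
        rounds += 1
        red_rng = random.Random(master.randrange(_SEED_SPACE))
        z = pbs_reduction(inst, best, cfg.reduction_cfg, red_rng, deadline)
        if len(z) < len(best):
            best = z
            record(len(best), "reduction")
        if time.monotonic() >= deadline or done(len(best)):
            break
        per_rng = random.Random(master.randrange(_SEED_SPACE))
        z = pbs_perturbation(inst, best, cfg.perturbation_schedule,
                             cfg.perturbation_cfg, per_rng, deadline)
        if len(z) < len(best):
            best = z
            record(len(best), "perturbation")

    trace.final = best
    return best, trace


def write_trace_csv(trace: RunTrace, path) -> None:
    """Export an anytime trace as CSV: elapsed_sec,best_length,phase."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["elapsed_sec", "best_length", "phase"])
        for ev in trace.events:
            w.writerow([f"{ev.elapsed_sec:.6f}", ev.best_length, ev.phase])
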