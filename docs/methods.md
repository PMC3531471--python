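# Methods

## Model and notation

An SCSP instance is an alphabet Σ of size q and strings s₁,…,s_m over Σ.
For a partial solution y, the progress function λᵢ(y) is the length of the
longest prefix of sᵢ that is a subsequence of y (greedy left-to-right
matching attains it: skipping an available match can never help, which the
test suite verifies against the literal recursive definition of the
embedding relation).  The remaining part of sᵢ has length rᵢ = |sᵢ| − λᵢ.
A candidate is complete when all rᵢ = 0.  Everything is case-sensitive and
strand-agnostic: a supersequence of a DNA set says nothing about reverse
complements, and none are taken.

Empty input strings are dropped at instance construction (logged): they are
embedded by anything.  Duplicates are kept — they genuinely shift Majority
Merge counts and the heuristic product.

## The probabilistic heuristic

`build_probability_table(q, imax, jmax)` fills P[i][j], the probability that
a fixed string of length i is a subsequence of a uniform random string of
length j, via the recurrence obtained by conditioning on the random
string's first symbol: P[i][j] = (1/q)P[i−1][j−1] + (1−1/q)P[i][j−1], with
P[0][·] = 1 and P[i][j] = 0 for i > j.  The i = 1 row has the closed form
1 − (1−1/q)^j and the diagonal is q^{−i}; both are asserted exactly, and
every entry with i ≤ 6, j ≤ 10 is checked against Monte-Carlo embedding
frequencies (20 000 trials, 4-standard-error band) for q ∈ {2, 4}.

A candidate scores ∏ᵢ P[rᵢ][j], treating the strings as independent.  Two
numerical choices:

* **Reference length j.**  The heuristic needs the length j of the
  hypothetical random string.  Default `max_remaining`: j = maxᵢ rᵢ of the
  candidate under evaluation, which needs no global horizon estimate and
  keeps the score well-defined for every candidate; a `fixed(L)` mode is
  available.  With per-candidate j the ranking is not perfectly consistent
  with componentwise progress (shrinking the largest rᵢ also shrinks j);
  the monotonicity that beam selection relies on — fewer remaining symbols
  at a common j never scores worse — holds and is tested.
* **Log space.**  Products over many strings underflow doubles, so ranking
  uses Σᵢ log P[rᵢ][j] (−∞ entries are safe: with j = maxᵢ rᵢ every factor
  is ≥ q^{−rᵢ} > 0).  The table is O(imax·jmax) floats — negligible at the
  string lengths this package targets.

## Probabilistic Beam Search

Per level, every beam member is extended with every contributing symbol;
children are ranked by log-heuristic, ties broken by larger total progress
Σλ, then arrival order (deterministic under a fixed seed).  The best
k_b children are *dominators*: they enter the next beam unconditionally and
define the pruning references.  Remaining slots are filled one draw at a
time from the ranked pool: with probability μ by Baker's linear ranking
(rank r drawn proportional to N − r + 1; the simplest parameter-free form),
otherwise the pool's best.  A draw dominated componentwise (non-strict, so
exact duplicates of a dominator are included) by any dominator is discarded
— it consumes the draw, not a slot.  μ is the probability of the *random*
branch: the perturbation schedule "ramps randomness up", so larger μ must
mean more sampling, and μ = 0 is purely greedy.  If pruning with k_b = 0
empties the selection, the single best child is kept as a liveness guard.
The first complete child encountered ends the run; since every retained
child embeds ≥ 1 new symbol, a run needs at most Σ|sᵢ| levels.

Defaults k_w = 100, k_b = 11, μ = 0.1 follow the sensitivity pattern that
beam-search quality improves with width up to ~100 and that a small nonzero
dominator count beats none; μ is deliberately configurable, as solution
quality is flat over a wide μ range at these settings.

Ranking and dominance flags are computed with vectorised numpy over the
whole child pool (the dominator set is fixed during the fill, so pruning
flags are one 3-D comparison); the fill loop itself stays scalar because it
must consume the random stream draw by draw.

## Local search

**Reduction** scans split points p = 1…|z| ascending.  For each p the
suffix y = z[p:] is kept; for every string the longest suffix embeddable in
y is removed (right-to-left greedy scan) and PBS solves the sub-instance of
the leftover prefixes with μ = 0 (greedy repair keeps the many sub-solves
cheap; k_w = 100, k_b = 11 as in construction).  A strictly shorter
replacement restarts the scan from p = 1.  The scan includes p = |z|
(empty suffix — a fresh solve of the whole instance): without it,
solutions exactly one symbol above the optimum can be fixed points of the
scan (no proper split improves), and the padded-solution recovery test
demonstrably stalls there.  Ascending order with restart-from-1 is the
deterministic, cheap choice; the restart point after an improvement is not
critical because the scan is repeated to a fixed point.

**Perturbation** runs a fixed number of iterations (default 100).  Each
iteration picks a position p and a different symbol a uniformly from the
*current* incumbent ("arbitrary" mutation read as uniform, the
minimal-assumption choice), keeps w = z[:p] + a, and repairs the
non-embedded suffixes with PBS at randomness μ_k = 0 + (k−1)·0.65/(n−1).
Only strictly shorter candidates are accepted, so both searches are
non-worsening and always return valid supersequences (replacement
correctness is compositional: w embeds a prefix of every string, the repair
embeds the rest).  A size-1 alphabet admits no mutation; the input is
returned with a warning.

## The multilevel driver

MPBS runs `initial_runs` = 5 seeded PBS constructions (one shared
configuration; distinct sub-seeds drawn from the master seed), keeps the
shortest, then alternates reduction and perturbation until the wall-clock
budget expires, recording every improvement as (elapsed s, length, phase).
The deadline is checked between sub-instance solves — a phase finishes its
current sub-solve, so overshoot is bounded by one solve.  Two optional
stops: `target_length` (quit when a known-good length, e.g. a proven lower
bound or oracle optimum, is reached) and `max_rounds` (fixed number of
local-search rounds, which makes a run bit-reproducible independent of
machine speed; with wall-clock stopping alone, reproducibility holds only
per machine).  Timing uses the monotonic clock.

Quality is reported as RPD = 100·(length − best_known)/best_known; when no
external best-known table exists, the best length observed in the compared
set serves as reference.

## Synthetic instances

`generate_random_instance` draws i.i.d. uniform symbols — the RandomSet
recipe: 8 strings, four of length 40 and four of 80, alphabet sizes
{2, 4, 8, 16, 24}, five instances per size in the canonical benchmark.
Uniform strings are the hardest natural case for the probabilistic
heuristic's independence assumption to exploit, but they lack the repeat
structure and compositional bias of genomic sequence; passing tests on them
shows the machinery ranks, prunes and reduces correctly, not that measured
RPDs transfer to real probe sets.  Real inputs come in via FASTA (DNA or
protein) or the plain-text format.  Synthetic alphabets use the first q of
lowercase + uppercase + digits (q ≤ 62); DNA is ACGT; protein the 20
standard letters.

## Test and benchmark scales

The exact oracle (BFS over the product state space, alphabet-order
tie-break, default cap 2·10⁶ states) certifies optimality on tiny
instances: 2–4 strings of length ≤ 8 over q ≤ 4, cross-checked against the
two-string identity |SCS| = |x| + |y| − |LCS| and, where total length ≤ 10,
against exhaustive enumeration (only length opt−1 needs scanning:
supersequence-ness is monotone under extension).  The benchmark suite runs
MPBS at a 30 s budget on 20 RandomSet-style q = 8 instances and at 2 s on
200 tiny instances — sizes chosen so the full suite runs on one desktop
core in minutes while still separating the algorithms cleanly (MPBS ≈
best-of-constructions + local search vs. single deterministic beam search
vs. greedy merges).

## Known limitations

* Reduction's full split scan is O(|z|) PBS solves; on long incumbents one
  pass can consume a small time budget, leaving perturbation little room —
  the alternation shines at larger budgets.
* The heuristic's independence assumption ignores correlations between
  strings (shared motifs); on highly similar inputs WMM-style weighting can
  be comparatively stronger.
* No lower-bound pruning is performed anywhere (a deliberate trait of this
  algorithm family); optimality statements come only from the exact oracle.
* `fixed(L)` reference lengths can legitimately produce −∞ log-scores when
  some rᵢ > L; ranking handles it, but `max_remaining` is the sane default.
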