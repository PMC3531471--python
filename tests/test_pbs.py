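"""Probabilistic beam search: extension, selection, sampling, full runs."""

import random
from collections import Counter

import pytest

from scsbeam import (
    Alphabet,
    Beam,
    CandidateSolution,
    Instance,
    PBSConfig,
    build_probability_table,
    contributes,
    exact_scs,
    extend,
    generate_random_instance,
    GeneratorSpec,
    is_supersequence_of_all,
    linear_rank_sample,
    pbs_solve,
    select_beam,
)
from conftest import random_toy_instance


@pytest.fixture
def abc_inst():
    return Instance(Alphabet.from_string("abc"), ("ab", "ba"))


def test_contributes(abc_inst, ab_ba):
    empty = CandidateSolution.empty(abc_inst)
    assert contributes(empty, "a", abc_inst)
    assert contributes(empty, "b", abc_inst)
    assert not contributes(empty, "c", abc_inst)
    only_b = Instance(Alphabet.from_string("ab"), ("bb",))
    assert not contributes(CandidateSolution.empty(only_b), "a", only_b)
    complete = CandidateSolution("aba", (2, 2))
    assert not contributes(complete, "a", ab_ba)


def test_extend_only_contributing_symbols(abc_inst):
    beam = Beam(0, [CandidateSolution.empty(abc_inst)])
    children = extend(beam, abc_inst)
    assert sorted(c.seq for c in children) == ["a", "b"]
    assert {c.seq: c.lambdas for c in children} == {
        "a": (1, 0), "b": (0, 1)}


def test_extend_complete_member_has_no_children(ab_ba):
    beam = Beam(3, [CandidateSolution("aba", (2, 2))])
    assert extend(beam, ab_ba) == []


def test_extend_counting_bound():
    rng = random.Random(5)
    for _ in range(10):
        inst = random_toy_instance(rng)
        beam = Beam(0, [CandidateSolution.empty(inst)])
        for _ in range(3):
            children = extend(beam, inst)
            if not children:
                break
            assert len(children) <= len(beam.members) * inst.alphabet.size
            beam = Beam(beam.level + 1, children[: 4])


@pytest.mark.parametrize(
    "n, expected",
    [(2, [2 / 3, 1 / 3]), (3, [3 / 6, 2 / 6, 1 / 6])],
)
def test_linear_rank_sampling_frequencies(n, expected):
    """Baker's linear ranking: rank r drawn with probability (N-r+1)/T."""
    pool = [CandidateSolution(str(i), (0,)) for i in range(n)]
    rng = random.Random(42)
    draws = 20_000
    counts = Counter(linear_rank_sample(pool, rng).seq for _ in range(draws))
    for i, p in enumerate(expected):
        freq = counts[str(i)] / draws
        # 4 standard errors of a binomial proportion
        assert abs(freq - p) <= 4 * (p * (1 - p) / draws) ** 0.5


def test_linear_rank_single_element_and_empty():
    pool = [CandidateSolution("x", (0,))]
    assert linear_rank_sample(pool, random.Random(0)) is pool[0]
    with pytest.raises(ValueError):
        linear_rank_sample([], random.Random(0))


def _children_pool(inst, k=3):
    beam = Beam(0, [CandidateSolution.empty(inst)])
    children = extend(beam, inst)
    for _ in range(k - 1):
        children = extend(Beam(0, children), inst)
    return children


def test_select_beam_greedy_mode_is_top_kw():
    inst = Instance(Alphabet.from_string("abc"), ("abca", "bacb", "cab"))
    tab = build_probability_table(3, 4, 4)
    pool = _children_pool(inst, 3)
    cfg = PBSConfig(beam_width=4, dominators=0, mu=0.0)
    beam = select_beam(list(pool), cfg, inst, tab, random.Random(0))
    assert len(beam.members) <= 4
    ranked_scores = sorted((c.logh for c in pool), reverse=True)
    got = [c.logh for c in beam.members]
    assert got == ranked_scores[: len(got)]


def test_select_beam_kb_equals_kw_is_plain_beam_search():
    inst = Instance(Alphabet.from_string("abc"), ("abca", "bacb", "cab"))
    tab = build_probability_table(3, 4, 4)
    pool = _children_pool(inst, 3)
    cfg = PBSConfig(beam_width=5, dominators=5, mu=0.9)
    b1 = select_beam(list(pool), cfg, inst, tab, random.Random(1))
    b2 = select_beam(list(pool), cfg, inst, tab, random.Random(99))
    assert [c.seq for c in b1.members] == [c.seq for c in b2.members]
    assert len(b1.members) == 5


def test_select_beam_prunes_dominated_members():
    inst = Instance(Alphabet.from_string("ab"), ("aaaa", "bbbb"))
    tab = build_probability_table(2, 4, 4)
    # two level-1 children: 'a' -> (1,0), 'b' -> (0,1); neither dominates
    pool = _children_pool(inst, 1)
    cfg = PBSConfig(beam_width=2, dominators=1, mu=0.0)
    beam = select_beam(list(pool), cfg, inst, tab, random.Random(0))
    assert len(beam.members) == 2
    # duplicate of the dominator must be pruned
    dup = [pool[0], CandidateSolution(pool[0].seq, pool[0].lambdas), pool[1]]
    beam = select_beam(dup, cfg, inst, tab, random.Random(0))
    lam_counts = Counter(c.lambdas for c in beam.members)
    assert max(lam_counts.values()) == 1


def test_pbs_single_string_returns_it():
    inst = Instance(Alphabet.from_string("ab"), ("ab",))
    for mu in (0.0, 0.5):
        assert pbs_solve(inst, PBSConfig(beam_width=3, mu=mu)) == "ab"


def test_pbs_attains_optimum_on_two_string_instance(ab_ba):
    sol = pbs_solve(ab_ba, PBSConfig(beam_width=2, dominators=2, mu=0.0))
    assert len(sol) == len(exact_scs(ab_ba)) == 3
    assert is_supersequence_of_all(sol, ab_ba)


def test_pbs_output_always_valid_and_bounded():
    rng = random.Random(202)
    for k in range(15):
        inst = random_toy_instance(rng)
        cfg = PBSConfig(beam_width=5, dominators=2, mu=0.3, seed=k)
        sol = pbs_solve(inst, cfg)
        assert is_supersequence_of_all(sol, inst)
        assert max(inst.lengths) <= len(sol) <= sum(inst.lengths)


def test_pbs_seeded_reproducibility():
    inst = generate_random_instance(GeneratorSpec(4, (20, 20, 30), 7))
    cfg = PBSConfig(beam_width=10, dominators=3, mu=0.4, seed=123)
    assert pbs_solve(inst, cfg) == pbs_solve(inst, cfg)


def test_pbs_deterministic_mode_is_seed_independent():
    inst = generate_random_instance(GeneratorSpec(4, (20, 20, 30), 7))
    a = pbs_solve(inst, PBSConfig(beam_width=8, dominators=8, mu=0.0, seed=1))
    b = pbs_solve(inst, PBSConfig(beam_width=8, dominators=8, mu=0.0, seed=2))
    assert a == b


def test_pbs_level_synchronicity_via_select():
    """Every selected beam holds members of equal constructed length."""
    inst = Instance(Alphabet.from_string("abc"), ("abca", "bacb", "cab"))
    tab = build_probability_table(3, 4, 4)
    beam = Beam(0, [CandidateSolution.empty(inst)])
    rng = random.Random(3)
    cfg = PBSConfig(beam_width=3, dominators=1, mu=0.5)
    for _ in range(4):
        children = extend(beam, inst)
        if not children:
            break
        beam = select_beam(children, cfg, inst, tab, rng)
        assert len({len(c.seq) for c in beam.members}) == 1
        assert beam.level == len(beam.members[0].seq)


def test_wider_beam_not_worse_on_random_instances():
    """Scaled-down beam-width trend: kw=20 never loses to kw=1 on average."""
    lens = (15, 15, 25, 25)
    narrow, wide = [], []
    for k in range(8):
        inst = generate_random_instance(GeneratorSpec(8, lens, 300 + k))
        narrow.append(len(pbs_solve(
            inst, PBSConfig(beam_width=1, dominators=1, mu=0.0))))
        wide.append(len(pbs_solve(
            inst, PBSConfig(beam_width=20, dominators=5, mu=0.0))))
    assert sum(wide) <= sum(narrow)
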