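"""Certify heuristic quality on a tiny instance with the exact oracle.

For small instances the optimum is computable by breadth-first search over
the product state space (one embedded-prefix counter per string).  The
classical identity |SCS(x,y)| = |x| + |y| - |LCS(x,y)| provides an
independent check on two-string instances.
"""

from scsbeam import (
    Alphabet,
    Instance,
    MPBSConfig,
    exact_scs,
    lcs_length,
    majority_merge,
    mpbs_solve,
)

inst = Instance(Alphabet.from_string("acgt"), ("gattaca", "catgac", "ttgca"))
opt = exact_scs(inst)
mm = majority_merge(inst)
sol, _ = mpbs_solve(inst, MPBSConfig(time_budget=2.0, seed=0,
                                     target_length=len(opt)))

print(f"strings:           {inst.strings}")
print(f"exact optimum:     {opt!r}  (length {len(opt)})")
print(f"majority merge:    length {len(mm)}")
print(f"MPBS (2 s budget): length {len(sol)}")

x, y = "gattaca", "catgac"
pair = Instance(Alphabet.from_string("acgt"), (x, y))
assert len(exact_scs(pair)) == len(x) + len(y) - lcs_length(x, y)
print(f"\ntwo-string identity holds: |SCS| = {len(x)} + {len(y)} - "
      f"{lcs_length(x, y)} = {len(exact_scs(pair))}")
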