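"""Watch the multilevel driver improve a solution over its time budget.

MPBS first runs several seeded PBS constructions, keeps the shortest, then
alternates reduction and perturbation local search until the wall-clock
budget expires.  The trace lists every improvement: elapsed seconds, the
new best length, and which phase found it.
"""

from scsbeam import GeneratorSpec, MPBSConfig, generate_random_instance, mpbs_solve

inst = generate_random_instance(
    GeneratorSpec(alphabet_size=16, lengths=(40,) * 4 + (80,) * 4, seed=7))
sol, trace = mpbs_solve(inst, MPBSConfig(time_budget=20.0, seed=3))

print(f"final supersequence length: {len(sol)}")
print("elapsed_sec  best_length  phase")
for ev in trace.events:
    print(f"{ev.elapsed_sec:10.2f}  {ev.best_length:11d}  {ev.phase}")
print("\nBest length never increases: the driver can be stopped at any "
      "time and returns the best solution found so far.")
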