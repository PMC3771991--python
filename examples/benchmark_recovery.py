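"""Modular AR benchmark: which estimator recovers the planted link?

Generates the 6-module validation system (one true module-level link,
Module 1 -> Module 2), runs the repeated-simulation Wilcoxon decision
protocol for pairwise GC and both partially conditioned variants, and
prints the module-level decisions.  Scaled down (k = 10,
10 repetitions) to run in about a minute.
"""

from pcgc import BenchmarkSpec, ground_truth, run_all_protocols, score_decisions

spec = BenchmarkSpec(k=10, t_points=5000, reps=10, seed=0)
decisions = run_all_protocols(spec)
truth = ground_truth()

print("module-level decisions (rows drive columns), truth = Module 1 -> Module 2")
for method, dec in decisions.items():
    tp, fp, fn = score_decisions(dec, truth)
    links = ", ".join(f"M{a + 1}->M{b + 1}" for a, b in dec.links()) or "none"
    print(f"  {method:9s} links: {links:30s} TP={tp} FP={fp} FN={fn}")
print()
print("Pairwise analysis adds the spurious reverse link M2->M1")
print("(Module 2's variables carry delayed copies of Module 1's latent);")
print("the conditioned estimators return exactly the planted truth.")
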