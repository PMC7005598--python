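"""Designing a spacing pattern by simulated annealing.

The fitness of a pattern is the F-score of the index it induces on a fixed
simulated benchmark.  A short annealing run on a tiny benchmark shows the
mechanics; real designs use more Rmaps and thousands of iterations.
"""

from omcorrect import IndexParams, anneal, fitness, make_benchmark

benchmark = make_benchmark(seed=1, n_rmaps=80, genome_len=400_000)
params = IndexParams(l_bp=40_000, k=3, bin_bp=1000, pattern_bits="1" * 40)

print("benchmark:", len(benchmark[0]), "Rmaps,", len(benchmark[1]), "related pairs")
print("all-ones pattern F-score:", round(fitness("1" * 40, benchmark, params), 4))

result = anneal(
    lambda bits: fitness(bits, benchmark, params),
    n_bits=40, iters=15, t0=0.05, alpha=0.995, seed=2,
)
print("best pattern:", result.best_pattern)
print("best F-score:", round(result.best_fitness, 4))
print("accepted moves:", sum(1 for t in result.trace if t["accepted"]), "/ 15")

# Each round flips one random bit; better patterns are always kept and worse
# ones survive with probability exp(dF / T) under geometric cooling, so the
# search can escape local optima early and settles as T -> 0.
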