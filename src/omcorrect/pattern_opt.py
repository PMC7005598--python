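"""Simulated-annealing optimization of the spacing pattern.

The fitness of a spacing pattern is the F-score (harmonic mean of precision
and recall) of the spaced (l,k)-mer index it induces on a fixed simulated
benchmark, where two Rmaps are predicted related when they share at least two
seeds.  Exhaustive search over 80-bit patterns is infeasible, so a random
pattern (each bit 1 with probability 0.5) is refined by single-bit flips with
Metropolis acceptance of worsening moves under a geometrically cooling
temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Optional

from .evaluation import predict_related_pairs, score_retrieval, true_related
from .seed_index import IndexParams, build_index, rmap_seeds
from .rmap_core import RmapSet
from .simulator import SimParams, simulate_dataset, substream

__all__ = ["fitness", "make_benchmark", "anneal", "AnnealResult"]


def make_benchmark(
    seed: int,
    n_rmaps: int = 2000,
    genome_len: int = 4_600_000,
    add_rate: float = 1.0,
    p_digest: float = 0.85,
    sizing_sigma: float = 0.05,
) -> tuple[RmapSet, set[frozenset]]:
    """A fixed benchmark: simulated Rmaps plus their true related pairs.

    Defaults mirror the pattern-design setting: 2000 Rmaps from a 4.6-Mbp
    bacterial-scale genome with one added cut per 100 kbp and 15% missing
    cut sites.  Simulation is truncated to the first ``n_rmaps`` Rmaps.
    """
    params = SimParams(
        genome_len=genome_len,
        coverage=n_rmaps * 250_000 * 1.05 / genome_len,
        add_rate=add_rate,
        p_digest=p_digest,
        sizing_sigma=sizing_sigma,
        seed=seed,
    )
    rmaps, truth, _ = simulate_dataset(params)
    subset = RmapSet(rmaps.rmaps[:n_rmaps])
    truth["rmaps"] = {rid: truth["rmaps"][rid] for rid in subset.ids()}
    return subset, true_related(truth)


def fitness(
    pattern_bits: str,
    benchmark: tuple[RmapSet, set[frozenset]],
    params: Optional[IndexParams] = None,
    min_shared: int = 2,
) -> float:
    """F-score of the merged spaced (l,k)-mer index under ``pattern_bits``.

    Deterministic given the benchmark and pattern.  An all-zeros pattern
    yields no seeds, predicts nothing, and scores 0.
    """
    rmaps, truth_pairs = benchmark
    params = replace(params or IndexParams(), pattern_bits=pattern_bits)
    index = build_index(rmaps, params).merge_similar()
    seed_sets = {r.id: rmap_seeds(r, params) for r in rmaps}
    predicted = predict_related_pairs(seed_sets, index.entries, min_shared)
    return score_retrieval(predicted, truth_pairs).f_score


@dataclass
class AnnealResult:
    best_pattern: str
    best_fitness: float
    trace: list[dict]  # per-iteration: fitness, best, temperature, accepted


def anneal(
    fitness_fn: Callable[[str], float],
    n_bits: int = 80,
    init: Optional[str] = None,
    iters: int = 2000,
    t0: float = 0.05,
    alpha: float = 0.995,
    seed: int = 0,
) -> AnnealResult:
    """Optimize a spacing pattern by simulated annealing.

    Each round flips one random bit; an improving (or equal) pattern is always
    accepted, a worsening one with probability exp((f_new - f_old) / T), and
    the temperature cools geometrically (T <- alpha * T).  The best pattern
    ever seen is returned; fitness evaluations are cached per pattern.
    """
    if iters < 1:
        raise ValueError("iters must be >= 1")
    rng = substream(seed, "anneal")
    if init is None:
        init = "".join("1" if rng.random() < 0.5 else "0" for _ in range(n_bits))
    cache: dict[str, float] = {}

    def f(bits: str) -> float:
        if bits not in cache:
            cache[bits] = fitness_fn(bits)
        return cache[bits]

    current = init
    f_cur = f(current)
    best, f_best = current, f_cur
    temp = t0
    trace = []
    for it in range(iters):
        pos = int(rng.integers(0, len(current)))
        flipped = current[:pos] + ("0" if current[pos] == "1" else "1") + current[pos + 1 :]
        f_new = f(flipped)
        if f_new >= f_cur:
            accepted = True
        else:
            p = math.exp((f_new - f_cur) / temp) if temp > 0 else 0.0
            accepted = rng.random() < p
        if accepted:
            current, f_cur = flipped, f_new
            if f_cur > f_best:
                best, f_best = current, f_cur
        trace.append(
            {
                "iteration": it,
                "fitness": f_cur,
                "best_fitness": f_best,
                "temperature": temp,
                "accepted": accepted,
            }
        )
        temp *= alpha
    return AnnealResult(best, f_best, trace)
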