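"""Quantized spaced (l,k)-mer index over an Rmap set.

Fragment lengths are quantized to bins of width ``bin_bp`` (floor division) to
absorb sizing error, then spaced (l,k)-mers are extracted in bin units and
hashed to the set of Rmap ids containing them.  Entries of seeds at L1
distance 1 are merged (bounded by a similarity budget ``t_sim``) to bridge
quantization-bin boundaries, and related Rmaps for a query are the top-N by
number of distinct shared seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .rmap_core import Rmap, RmapSet
from .seeds import DEFAULT_PATTERN_BITS, SpacingPattern, extract_spaced

__all__ = ["IndexParams", "SeedIndex", "quantize", "seed_dist", "build_index"]

INCOMPARABLE = None  # sentinel distance for seeds of different length


def quantize(x: int, b: int) -> int:
    """Quantized fragment length: floor(x / b)."""
    if x < 0 or b < 1:
        raise ValueError("require x >= 0 and b >= 1")
    return x // b


def seed_dist(m1: Sequence[int], m2: Sequence[int]) -> Optional[int]:
    """L1 distance between equal-length seeds; None if incomparable."""
    if len(m1) != len(m2):
        return INCOMPARABLE
    return sum(abs(a - b) for a, b in zip(m1, m2))


@dataclass(frozen=True)
class IndexParams:
    """Spaced (l,k)-mer index parameters.

    l_bp and the pattern are given in bp; extraction happens in bin units, so
    l_bp must be divisible by bin_bp and the pattern bit count must divide
    l_bp/bin_bp.  Defaults follow the published operating point for a
    bacterial-scale run: l = 80 kbp, k = 5, 1-kbp bins, an 80-bit pattern
    (1 kbp per bit) and the top N = 64 candidates; for large genomes k = 6 and
    N = 32 are recommended.
    """

    l_bp: int = 80_000
    k: int = 5
    bin_bp: int = 1000
    t_sim: int = 2
    N: int = 64
    pattern_bits: str = DEFAULT_PATTERN_BITS

    def __post_init__(self):
        if self.l_bp % self.bin_bp != 0:
            raise ValueError("l_bp must be divisible by bin_bp")
        l_bins = self.l_bp // self.bin_bp
        if l_bins % len(self.pattern_bits) != 0:
            raise ValueError("pattern length must divide l_bp/bin_bp")

    @property
    def l_bins(self) -> int:
        return self.l_bp // self.bin_bp

    def pattern(self) -> SpacingPattern:
        return SpacingPattern.for_window(self.pattern_bits, self.l_bins)


def _quantized(rmap: Rmap, b: int) -> list[int]:
    return [quantize(r, b) for r in rmap.fragments]


def rmap_seeds(rmap: Rmap, params: IndexParams) -> set[tuple[int, ...]]:
    """Distinct quantized spaced (l,k)-mers of one Rmap."""
    q = _quantized(rmap, params.bin_bp)
    return set(extract_spaced(q, params.l_bins, params.k, params.pattern()))


class SeedIndex:
    """Hash index from quantized spaced (l,k)-mer to a set of Rmap ids.

    ``counters[M]`` tracks how many seeds have been merged into M's entry
    (the merge budget), starting at 1.
    """

    def __init__(self, params: IndexParams):
        self.params = params
        self.entries: dict[tuple[int, ...], set[str]] = {}
        self.counters: dict[tuple[int, ...], int] = {}
        self.merged = False

    def add_rmap(self, rmap: Rmap) -> None:
        for seed in rmap_seeds(rmap, self.params):
            if seed not in self.entries:
                self.entries[seed] = set()
                self.counters[seed] = 1
            self.entries[seed].add(rmap.id)

    def merge_similar(self, t_sim: Optional[int] = None) -> "SeedIndex":
        """Merge entries of seeds at L1 distance 1, bounded by ``t_sim``.

        Two passes over all seeds in lexicographic order; for each seed M and
        each indexed neighbour M' at distance 1, if the accumulated budget
        i_M + i_M' - 1 <= t_sim the two entries are both set to their union
        and both counters to i_M + i_M'.  This guarantees that entries of two
        seeds farther apart than t_sim (along any merge chain) never share a
        merge, while entries of some close seeds may stay unmerged if their
        budgets were already spent.
        """
        t = self.params.t_sim if t_sim is None else t_sim
        order = sorted(self.entries)
        for _ in range(2):
            for m in order:
                for m2 in self._neighbours(m):
                    if self.counters[m] + self.counters[m2] - 1 <= t:
                        union = self.entries[m] | self.entries[m2]
                        self.entries[m] = set(union)
                        self.entries[m2] = set(union)
                        total = self.counters[m] + self.counters[m2]
                        self.counters[m] = total
                        self.counters[m2] = total
        self.merged = True
        return self

    def _neighbours(self, m: tuple[int, ...]) -> Iterable[tuple[int, ...]]:
        """Indexed seeds at L1 distance exactly 1 from m, in sorted order."""
        out = []
        for i in range(len(m)):
            for delta in (-1, 1):
                v = m[i] + delta
                if v < 0:
                    continue
                cand = m[:i] + (v,) + m[i + 1 :]
                if cand in self.entries:
                    out.append(cand)
        return sorted(out)

    def query_related(self, rmap: Rmap, n: Optional[int] = None) -> list[tuple[str, int]]:
        """Top-N Rmaps sharing the most distinct seeds with ``rmap``.

        The query Rmap itself (by id) is excluded.  Ties are broken by
        ascending id for determinism.
        """
        n = self.params.N if n is None else n
        counts: dict[str, int] = {}
        for seed in rmap_seeds(rmap, self.params):
            for rid in self.entries.get(seed, ()):
                if rid != rmap.id:
                    counts[rid] = counts.get(rid, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return ranked[:n]

    # -- persistence --------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "params": {
                "l_bp": self.params.l_bp,
                "k": self.params.k,
                "bin_bp": self.params.bin_bp,
                "t_sim": self.params.t_sim,
                "N": self.params.N,
                "pattern_bits": self.params.pattern_bits,
            },
            "merged": self.merged,
            "entries": [
                [list(seed), sorted(ids), self.counters[seed]]
                for seed, ids in sorted(self.entries.items())
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SeedIndex":
        with open(path) as fh:
            payload = json.load(fh)
        idx = cls(IndexParams(**payload["params"]))
        idx.merged = payload["merged"]
        for seed, ids, counter in payload["entries"]:
            key = tuple(seed)
            idx.entries[key] = set(ids)
            idx.counters[key] = counter
        return idx


def build_index(rmaps: RmapSet, params: IndexParams = IndexParams()) -> SeedIndex:
    """Index every Rmap's distinct quantized spaced (l,k)-mers."""
    idx = SeedIndex(params)
    for rmap in rmaps:
        idx.add_rmap(rmap)
    return idx
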