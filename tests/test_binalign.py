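"""Binary encoding and cut-site-weighted overlap alignment.

The DP is checked against `brute_force_best_score`, an independent oracle
that enumerates every monotone alignment path and scores it with free
leading/trailing gap runs.
"""

from functools import lru_cache

import pytest

from omcorrect import Rmap, align, filter_candidates, to_binary
from omcorrect.binalign import corpus_counts


def brute_force_best_score(a: str, b: str, w: float) -> float:
    """Max over all alignments of (matches - edit costs), end-gap runs free."""

    def gap_cost(ch):
        return w if ch == "1" else 1.0

    @lru_cache(maxsize=None)
    def paths(i, j):
        # all op sequences aligning a[i:] with b[j:], as tuples of ops
        # ops: ('D', i, j) diagonal, ('U', i) gap in b, ('L', j) gap in a
        if i == len(a) and j == len(b):
            return [()]
        out = []
        if i < len(a) and j < len(b):
            out += [(("D", i, j),) + p for p in paths(i + 1, j + 1)]
        if i < len(a):
            out += [(("U", i),) + p for p in paths(i + 1, j)]
        if j < len(b):
            out += [(("L", j),) + p for p in paths(i, j + 1)]
        return out

    best = 0.0  # the all-end-gap alignment always scores 0
    for path in paths(0, 0):
        # free leading/trailing runs of one gap type
        start = 0
        while start < len(path) and path[start][0] == path[0][0] != "D":
            start += 1
        end = len(path)
        while end > start and path[end - 1][0] == path[-1][0] != "D":
            end -= 1
        score = 0.0
        for op in path[start:end]:
            if op[0] == "D":
                score += 1.0 if a[op[1]] == b[op[2]] else -w
            elif op[0] == "U":
                score -= gap_cost(a[op[1]])
            else:
                score -= gap_cost(b[op[1]])
        best = max(best, score)
    return best


class TestToBinary:
    def test_fig_example(self):
        b = to_binary(Rmap("r", [4, 28, 10, 6, 9, 3]), 5)
        assert b.chars == "11000001011011"
        assert b.cutmap == [0, 1, 2, 3, 4, 5, 6]

    def test_single_fragment(self):
        assert to_binary(Rmap("r", [3]), 5).chars == "11"

    def test_ones_count(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 30))
            frags = [int(x) for x in rng.integers(1, 9000, size=n)]
            b = to_binary(Rmap("r", frags), 2000)
            assert b.chars.count("1") == n + 1


class TestAlign:
    def test_identical_strings(self):
        s = "1010011"
        c0, c1 = corpus_counts(s, s)
        aln = align(s, s, c0, c1)
        assert aln.cost == 0 and aln.cutsite_edits == 0
        assert aln.score == pytest.approx(len(s))

    def test_end_gapped_cut_sites_are_free(self):
        aln = align("11", "1", 0, 3)
        assert aln.cost == 0 and aln.cutsite_edits == 0

    def test_empty_string(self):
        aln = align("", "101", 1, 2)
        assert aln.cost == 0 and aln.gapped_a == "---" and aln.gapped_b == "101"

    def test_gap_removal_recovers_inputs(self, rng):
        for _ in range(50):
            a = "".join(rng.choice(["0", "1"], size=int(rng.integers(1, 30))))
            b = "".join(rng.choice(["0", "1"], size=int(rng.integers(1, 30))))
            c0, c1 = corpus_counts(a, b)
            aln = align(a, b, c0, c1)
            assert aln.gapped_a.replace("-", "") == a
            assert aln.gapped_b.replace("-", "") == b
            assert len(aln.gapped_a) == len(aln.gapped_b)

    def test_matches_exhaustive_enumeration(self, rng):
        cases = [("1", "1"), ("101", "111"), ("11", "1"), ("0110", "1001")]
        for _ in range(40):
            la, lb = rng.integers(1, 7, size=2)
            cases.append((
                "".join(rng.choice(["0", "1"], size=la)),
                "".join(rng.choice(["0", "1"], size=lb)),
            ))
        for a, b in cases:
            c0, c1 = corpus_counts(a, b)
            w = (c0 + c1) / c1 if c1 else 1.0
            got = align(a, b, c0, c1)
            assert got.score == pytest.approx(brute_force_best_score(a, b, w))

    def test_score_symmetry(self, rng):
        for _ in range(40):
            a = "".join(rng.choice(["0", "1"], size=int(rng.integers(1, 20))))
            b = "".join(rng.choice(["0", "1"], size=int(rng.integers(1, 20))))
            c0, c1 = corpus_counts(a, b)
            assert align(a, b, c0, c1).score == pytest.approx(
                align(b, a, c0, c1).score
            )

    def test_prepended_zeros_are_free(self, rng):
        # an unaligned prefix on one side rides in the free leading gap run;
        # (with the cost model held fixed, so w is unchanged by the padding)
        for _ in range(20):
            a = "1" + "".join(rng.choice(["0", "1"], size=12))
            c0, c1 = corpus_counts(a, a)
            base = align(a, a, c0, c1).score
            padded = align("000" + a, a, c0, c1)
            assert padded.score == pytest.approx(base)
            # and at worst each prepended '0' costs one plain edit in general
            b = "1" + "".join(rng.choice(["0", "1"], size=12))
            c0, c1 = corpus_counts(a, b)
            base = align(a, b, c0, c1).score
            assert align("000" + a, b, c0, c1).score >= base - 3 - 1e-9


class TestFilter:
    def test_identical_candidate_kept(self):
        t = Rmap("t", [10_000] * 12)
        kept = filter_candidates(t, [Rmap("c", [10_000] * 12)])
        assert [c.id for c in kept] == ["c"]

    def test_threshold_is_strict_exceed(self):
        # craft a pair with a known cut-edit count e; the candidate is kept
        # exactly when e <= frac * min_cuts, i.e. "exceeds" is strict
        t = Rmap("t", [10_000] * 9)  # 10 cuts
        c = Rmap("c", [10_000] * 4 + [5_000, 5_000] + [10_000] * 4)  # one added cut
        from omcorrect.binalign import align_rmaps, to_binary

        aln = align_rmaps(to_binary(t), to_binary(c))
        e = aln.cutsite_edits
        assert e > 0
        n_min = min(to_binary(t).n_cuts, to_binary(c).n_cuts)
        assert filter_candidates(t, [c], max_edit_frac=e / n_min) == [c]
        assert filter_candidates(t, [c], max_edit_frac=(e - 0.5) / n_min) == []

    def test_ranking_preserved(self, rng):
        t = Rmap("t", [10_000] * 12)
        cands = [Rmap(f"c{i}", [10_000] * 12) for i in range(5)]
        assert [c.id for c in filter_candidates(t, cands)] == [c.id for c in cands]
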