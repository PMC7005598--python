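"""Relatedness ground truth, retrieval scores and correction metrics."""

import itertools

import numpy as np
import pytest

from omcorrect import (
    Rmap,
    RmapSet,
    score_correction,
    score_retrieval,
    true_related,
)
from omcorrect.evaluation import RetrievalScore, match_cuts
from omcorrect.rmap_core import cuts_to_frags
from omcorrect.simulator import SimParams, simulate_dataset


def brute_force_related(truth, min_bp=100_000, min_frags=7):
    sites = sorted(truth["site_positions"])
    pairs = set()
    items = list(truth["rmaps"].items())
    for (ida, a), (idb, b) in itertools.combinations(items, 2):
        lo = max(a["start"], b["start"])
        hi = min(a["end"], b["end"])
        if hi - lo < min_bp:
            continue
        inside = [s for s in sites if lo <= s <= hi]
        if len(inside) - 1 >= min_frags:
            pairs.add(frozenset((ida, idb)))
    return pairs


def brute_force_max_matching(obs, true_cuts, tol, rel_tol=0.15):
    """Exhaustive search over monotone chain-consistent matchings."""
    best = 0
    n, m = len(obs), len(true_cuts)

    def extend(chain, i0, j0):
        nonlocal best
        best = max(best, len(chain))
        for i in range(i0, n):
            for j in range(j0, m):
                if chain:
                    pi, pj = chain[-1]
                    dt = true_cuts[j] - true_cuts[pj]
                    do = obs[i] - obs[pi]
                    if abs(do - dt) > max(tol, rel_tol * dt):
                        continue
                extend(chain + [(i, j)], i + 1, j + 1)

    extend([], 0, 0)
    return best


class TestScores:
    def test_formula_example(self):
        s = RetrievalScore(tp=2, fp=1, fn=2)
        assert s.precision == pytest.approx(2 / 3)
        assert s.recall == pytest.approx(1 / 2)
        assert s.f_score == pytest.approx(4 / 7)

    def test_perfect_prediction(self):
        pairs = {frozenset(("a", "b")), frozenset(("b", "c"))}
        s = score_retrieval(pairs, pairs)
        assert s.precision == s.recall == s.f_score == 1.0

    def test_swapping_swaps_fp_fn(self):
        pred = {frozenset(("a", "b"))}
        truth = {frozenset(("a", "b")), frozenset(("a", "c"))}
        s1 = score_retrieval(pred, truth)
        s2 = score_retrieval(truth, pred)
        assert (s1.fp, s1.fn) == (s2.fn, s2.fp)

    def test_bounds_and_zero(self, rng):
        for _ in range(100):
            tp, fp, fn = (int(x) for x in rng.integers(0, 6, size=3))
            s = RetrievalScore(tp, fp, fn)
            assert 0.0 <= s.f_score <= 1.0
            assert (s.f_score == 0.0) == (s.precision * s.recall == 0.0)


class TestTrueRelated:
    def test_identical_and_disjoint(self):
        truth = {
            "site_positions": list(range(5_000, 400_000, 10_000)),
            "rmaps": {
                "a": {"start": 0, "end": 200_000},
                "b": {"start": 0, "end": 200_000},
                "c": {"start": 200_000, "end": 400_000},
            },
        }
        pairs = true_related(truth)
        assert frozenset(("a", "b")) in pairs
        assert frozenset(("a", "c")) not in pairs

    def test_matches_brute_force(self):
        p = SimParams(genome_len=1_000_000, coverage=10, seed=13)
        _, truth, _ = simulate_dataset(p)
        assert true_related(truth) == brute_force_related(truth)


class TestMatchCuts:
    def test_identity(self):
        cuts = [10_000, 20_000, 31_000, 45_000]
        added, deleted, matched = match_cuts(cuts, cuts, 1500)
        assert (added, deleted) == (0, 0) and len(matched) == 4

    def test_added_and_deleted(self):
        true_cuts = [10_000, 20_000, 30_000, 40_000]
        obs = [10_000, 15_000, 20_000, 40_000]  # one add, one miss
        added, deleted, _ = match_cuts(obs, true_cuts, 1000)
        assert (added, deleted) == (1, 1)

    def test_drift_is_not_an_error(self):
        # a 4% stretch accumulates to 8 kbp at the end of the molecule; the
        # structure-based matching still pairs every cut
        true_cuts = list(range(10_000, 210_000, 10_000))
        obs = [round(c * 1.04) for c in true_cuts]
        added, deleted, _ = match_cuts(obs, true_cuts, 1500)
        assert (added, deleted) == (0, 0)

    def test_matches_exhaustive_search(self, rng):
        for _ in range(30):
            n, m = rng.integers(1, 7, size=2)
            obs = sorted(int(x) for x in rng.integers(0, 60_000, size=n))
            true_cuts = sorted(int(x) for x in rng.integers(0, 60_000, size=m))
            _, _, matched = match_cuts(obs, true_cuts, 1500)
            assert len(matched) == brute_force_max_matching(obs, true_cuts, 1500)


class TestScoreCorrection:
    def _dataset(self):
        p = SimParams(genome_len=400_000, coverage=6, seed=17)
        return simulate_dataset(p)[:2]

    def test_truth_digest_scores_zero(self):
        rmaps, truth = self._dataset()
        perfect = RmapSet()
        for r in rmaps:
            info = truth["rmaps"][r.id]
            cuts = [0] + info["true_cuts"] + [info["end"] - info["start"]]
            perfect.add(Rmap(r.id, cuts_to_frags(sorted(set(cuts)))))
        report = score_correction(rmaps, perfect, truth)
        assert report["total_errors_after"] == 0
        assert report["error_reduction"] == 1.0

    def test_identity_correction_changes_nothing(self):
        rmaps, truth = self._dataset()
        clone = RmapSet(Rmap(r.id, list(r.fragments)) for r in rmaps)
        report = score_correction(rmaps, clone, truth)
        assert report["total_errors_after"] == report["total_errors_before"]
        assert report["improved"] == 0

    def test_id_mismatch_raises(self):
        rmaps, truth = self._dataset()
        other = RmapSet([Rmap("nope", [10_000] * 10)])
        with pytest.raises(ValueError):
            score_correction(rmaps, other, truth)
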