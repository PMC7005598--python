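"""Ground-truth relatedness labels and retrieval / correction metrics.

Two simulated Rmaps are *related* when their genomic intervals overlap by at
least 100 kbp and the intersection fully contains at least 7 true fragments.
Retrieval schemes are scored as precision/recall/F over predicted vs true
related pairs.  Correction quality is scored against the simulator's ground
truth by matching observed cut sites to true cut sites (monotone greedy
matching within a tolerance, under the candidate shift that minimises the
error count) and counting added and deleted cut sites before and after
correction.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .rmap_core import RmapSet, frag_to_cuts

__all__ = [
    "RetrievalScore",
    "true_related",
    "score_retrieval",
    "predict_related_pairs",
    "match_cuts",
    "score_correction",
]


@dataclass
class RetrievalScore:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f_score(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def true_related(
    truth: dict, min_overlap_bp: int = 100_000, min_overlap_frags: int = 7
) -> set[frozenset]:
    """All unordered pairs of Rmaps whose intervals overlap enough.

    The fragment condition counts true fragments (between consecutive genome
    site positions) lying fully inside the intersection of the two intervals.
    """
    sites = sorted(truth["site_positions"])
    items = sorted(
        ((v["start"], v["end"], rid) for rid, v in truth["rmaps"].items())
    )
    pairs: set[frozenset] = set()
    for idx, (s1, e1, id1) in enumerate(items):
        for s2, e2, id2 in items[idx + 1 :]:
            if s2 >= e1 - min_overlap_bp:
                break
            lo, hi = max(s1, s2), min(e1, e2)
            if hi - lo < min_overlap_bp:
                continue
            n_cuts = bisect_right(sites, hi) - bisect_left(sites, lo)
            if n_cuts - 1 >= min_overlap_frags:
                pairs.add(frozenset((id1, id2)))
    return pairs


def score_retrieval(
    predicted: Iterable[frozenset], truth_pairs: Iterable[frozenset]
) -> RetrievalScore:
    pred, true = set(predicted), set(truth_pairs)
    tp = len(pred & true)
    return RetrievalScore(tp=tp, fp=len(pred) - tp, fn=len(true) - tp)


def predict_related_pairs(
    seed_sets: dict[str, set],
    entries: Optional[dict] = None,
    min_shared: int = 2,
) -> set[frozenset]:
    """Pairs of Rmaps sharing at least ``min_shared`` distinct seeds.

    ``seed_sets`` maps each Rmap id to its distinct seeds; ``entries`` maps
    each seed to the ids containing it (pass a merged index's entries to
    score a merging scheme; by default it is built from ``seed_sets``).
    """
    if entries is None:
        entries = {}
        for rid, seeds in seed_sets.items():
            for s in seeds:
                entries.setdefault(s, set()).add(rid)
    pairs: set[frozenset] = set()
    for rid, seeds in seed_sets.items():
        counts: dict[str, int] = {}
        for s in seeds:
            for other in entries.get(s, ()):
                if other != rid:
                    counts[other] = counts.get(other, 0) + 1
        for other, c in counts.items():
            if c >= min_shared:
                pairs.add(frozenset((rid, other)))
    return pairs


def match_cuts(
    observed: Sequence[int],
    true_cuts: Sequence[int],
    tol: int = 1500,
    rel_tol: float = 0.15,
    max_skip: int = 6,
) -> tuple[int, int, list[tuple[int, int]]]:
    """Optimal monotone matching of observed to true cut sites.

    Cut sites are matched by local structure rather than absolute position:
    two consecutive matched pairs must imply agreeing inter-cut distances,
    ``|(obs[i'] - obs[i]) - (true[j'] - true[j])| <= max(tol, rel_tol * true
    distance)``.  Absolute coordinates never enter, so the multiplicative
    sizing drift that accumulates along a molecule (and any global offset of
    a corrected Rmap against its source molecule) is not mis-counted as
    added/deleted cuts; it is reported separately as sizing error.  The first
    matched pair anchors the chain and is unconstrained.

    Consecutive matches may skip at most ``max_skip`` cuts on either side
    (runs of adjacent added/deleted cuts longer than that break the chain).
    Returns (added, deleted, matched index pairs): unmatched observed cuts
    are *added*; unmatched true cuts *between* the first and last matched
    true cut are *deleted* (flanks the chain never reached are not charged).
    Both inputs must be sorted.
    """
    n, m = len(observed), len(true_cuts)
    if n == 0 or m == 0:
        return n, 0, []
    dp = [[1] * m for _ in range(n)]
    # equal-cardinality chains are disambiguated by total link slack, so a
    # chain of genuine correspondences beats one of tolerance coincidences
    slack = [[0.0] * m for _ in range(n)]
    back: list[list[Optional[tuple[int, int]]]] = [[None] * m for _ in range(n)]
    for i in range(n):
        for j in range(m):
            for i2 in range(max(0, i - max_skip), i):
                for j2 in range(max(0, j - max_skip), j):
                    dt = true_cuts[j] - true_cuts[j2]
                    do = observed[i] - observed[i2]
                    s = abs(do - dt)
                    if s > max(tol, rel_tol * dt):
                        continue
                    cand = (dp[i2][j2] + 1, -(slack[i2][j2] + s))
                    if cand > (dp[i][j], -slack[i][j]):
                        dp[i][j] = dp[i2][j2] + 1
                        slack[i][j] = slack[i2][j2] + s
                        back[i][j] = (i2, j2)
    # best chain; ties prefer the smallest slack, then the earliest end
    bi, bj = max(
        ((i, j) for i in range(n) for j in range(m)),
        key=lambda t: (dp[t[0]][t[1]], -slack[t[0]][t[1]], -t[0], -t[1]),
    )
    matched = []
    at: Optional[tuple[int, int]] = (bi, bj)
    while at is not None:
        matched.append(at)
        at = back[at[0]][at[1]]
    matched.reverse()
    added = n - len(matched)
    interior = matched[-1][1] - matched[0][1] + 1
    deleted = interior - len(matched)
    return added, deleted, matched


def _score_one(
    observed: list[int], true_cuts: list[int], tol: int
) -> dict:
    """Cut-site error counts and sizing error for one Rmap against truth."""
    if not observed or not true_cuts:
        return {"added": len(observed), "deleted": 0, "sizing_rel_err": None}
    added, deleted, matched = match_cuts(observed, true_cuts, tol)
    errs = []
    for (i1, j1), (i2, j2) in zip(matched, matched[1:]):
        if i2 == i1 + 1 and j2 == j1 + 1:
            tf = true_cuts[j2] - true_cuts[j1]
            of = observed[i2] - observed[i1]
            if tf > 0:
                errs.append(abs(of - tf) / tf)
    return {
        "added": added,
        "deleted": deleted,
        "sizing_rel_err": sum(errs) / len(errs) if errs else None,
    }


def _internal_cuts(fragments: Sequence[int]) -> list[int]:
    return frag_to_cuts(fragments)[1:-1]


def score_correction(
    before: RmapSet, after: RmapSet, truth: dict, tol: int = 1500
) -> dict:
    """Truth-based cut-site error counts before vs after correction.

    Only internal cut sites are scored (molecule endpoints are breaks, not
    cuts).  An Rmap is *improved* when its added+deleted count strictly
    decreased.  Raises if the two sets are not id-matched.
    """
    if set(before.ids()) != set(after.ids()):
        raise ValueError("before/after Rmap sets are not id-matched")
    per_rmap = {}
    totals = {"before": {"added": 0, "deleted": 0}, "after": {"added": 0, "deleted": 0}}
    improved = 0
    sizing = {"before": [], "after": []}
    for rmap in before:
        true_cuts = sorted(truth["rmaps"][rmap.id]["true_cuts"])
        b = _score_one(_internal_cuts(rmap.fragments), true_cuts, tol)
        a = _score_one(_internal_cuts(after[rmap.id].fragments), true_cuts, tol)
        per_rmap[rmap.id] = {"before": b, "after": a}
        for key, r in (("before", b), ("after", a)):
            totals[key]["added"] += r["added"]
            totals[key]["deleted"] += r["deleted"]
            if r["sizing_rel_err"] is not None:
                sizing[key].append(r["sizing_rel_err"])
        if a["added"] + a["deleted"] < b["added"] + b["deleted"]:
            improved += 1
    tot_b = totals["before"]["added"] + totals["before"]["deleted"]
    tot_a = totals["after"]["added"] + totals["after"]["deleted"]
    return {
        "totals": totals,
        "total_errors_before": tot_b,
        "total_errors_after": tot_a,
        "error_reduction": 1.0 - tot_a / tot_b if tot_b else 0.0,
        "improved": improved,
        "n_rmaps": len(before),
        "mean_sizing_rel_err_before": (
            sum(sizing["before"]) / len(sizing["before"]) if sizing["before"] else None
        ),
        "mean_sizing_rel_err_after": (
            sum(sizing["after"]) / len(sizing["after"]) if sizing["after"] else None
        ),
        "per_rmap": per_rmap,
    }
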