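"""Binary-string encoding of Rmaps and cut-site-weighted overlap alignment.

An Rmap's line segment is divided into blocks of ``block_bp`` bp; a block
containing c cut sites contributes c '1' characters, an empty block one '0'.
Pairs of encoded Rmaps are aligned with a Needleman-Wunsch variant allowing
free gaps at both ends, so prefix-suffix overlaps between molecules from
overlapping genomic intervals can be found.

Because the strings are sparse in '1's, uniform edit costs would happily
misalign the cut sites: the abundant '0's pair up and the '1's get pushed
into gaps.  Any edit involving a cut site (a 0<->1 substitution or a gapped
'1') therefore costs ``(c0 + c1) / c1`` -- c0 and c1 counting the 0s and 1s
over all strings participating in the alignment -- while every other edit
costs 1.  The alignment is chosen to maximise (matches - edit costs): with
free end gaps a pure cost minimisation is degenerate (a one-column overlap
of two '1's always costs zero), whereas rewarding matched columns makes the
optimum the genuine overlap for related Rmaps -- and for unrelated ones an
alignment needing so many interior edits that the candidate filter rejects
it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .rmap_core import Rmap, frag_to_cuts

__all__ = [
    "BinaryRmap",
    "PairAlignment",
    "to_binary",
    "align",
    "align_rmaps",
    "filter_candidates",
]

_TOL = 1e-9
MATCH_REWARD = 1.0


@dataclass
class BinaryRmap:
    """{0,1}-string encoding of an Rmap by fixed-size blocks.

    Both molecule endpoints (coordinates 0 and |R|) count as cut sites, so the
    string holds n+1 '1's for an n-fragment Rmap.  ``cutmap[j]`` is the index
    (into the cut-site representation) of the cut behind the j-th '1'.
    """

    chars: str
    block_bp: int
    cutmap: list[int]

    def __len__(self) -> int:
        return len(self.chars)

    @property
    def n_cuts(self) -> int:
        return len(self.cutmap)


def to_binary(rmap: Rmap, block_bp: int = 2000) -> BinaryRmap:
    """Encode an Rmap as a binary string over blocks [iB, (i+1)B).

    The trailing block exists iff a cut (always the endpoint |R|) falls in it.
    """
    if block_bp < 1:
        raise ValueError("block_bp must be >= 1")
    cuts = frag_to_cuts(rmap.fragments)
    n_blocks = cuts[-1] // block_bp + 1
    chars = []
    cutmap = []
    ci = 0
    for i in range(n_blocks):
        hi = (i + 1) * block_bp
        count = 0
        while ci < len(cuts) and cuts[ci] < hi:
            cutmap.append(ci)
            ci += 1
            count += 1
        chars.append("1" * count if count else "0")
    return BinaryRmap("".join(chars), block_bp, cutmap)


@dataclass
class PairAlignment:
    """A gapped pairwise alignment of two binary strings.

    ``score`` is the optimised objective (matched columns minus edit costs,
    end gaps free); ``cost`` is the edit cost the chosen alignment incurs
    under the cut-site-weighted model; ``cutsite_edits`` counts the interior
    edit operations involving a '1' and ``interior_edits`` every interior
    edit operation (substitutions and gaps, end-gap runs excluded).
    """

    gapped_a: str
    gapped_b: str
    score: float
    cost: float
    cutsite_edits: int
    interior_edits: int


def corpus_counts(*strings: str) -> tuple[int, int]:
    """Totals of '0' and '1' characters over the given strings."""
    c0 = sum(s.count("0") for s in strings)
    c1 = sum(s.count("1") for s in strings)
    return c0, c1


def _cutsite_cost(c0: int, c1: int) -> float:
    # a corpus without any '1' cannot occur for real Rmaps (n+1 >= 2 endpoint
    # cuts); fall back to the plain-edit cost there
    return (c0 + c1) / c1 if c1 > 0 else 1.0


def align(a: str, b: str, corpus_c0: int, corpus_c1: int) -> PairAlignment:
    """Best overlap alignment of two {0,1} strings.

    Dynamic programme over match reward +1, 0<->1 substitution or interior
    gap on '1' at -(c0+c1)/c1, interior gap on '0' at -1, with free leading
    and trailing gap runs in either string.  Traceback ties prefer match over
    substitution over a gap in ``b`` over a gap in ``a``.
    """
    w = _cutsite_cost(corpus_c0, corpus_c1)
    m, n = len(a), len(b)
    if m == 0 or n == 0:
        return PairAlignment("-" * n + a, b + "-" * m, 0.0, 0.0, 0, 0)

    av = np.frombuffer(a.encode(), dtype=np.uint8) == ord("1")
    bv = np.frombuffer(b.encode(), dtype=np.uint8) == ord("1")
    gap_a = np.where(av, w, 1.0)  # penalty for gapping a character of a
    gap_b = np.where(bv, w, 1.0)

    S = np.zeros((m + 1, n + 1))
    # free leading gaps: first row and column stay 0
    G = np.concatenate(([0.0], np.cumsum(gap_b)))
    for i in range(1, m + 1):
        diag = np.where(av[i - 1] != bv, -w, MATCH_REWARD)
        t = np.maximum(S[i - 1, :-1] + diag, S[i - 1, 1:] - gap_a[i - 1])
        # chain of left moves: S[i,j] = max_{k<=j} (T[k] - (G[j] - G[k]))
        e = np.maximum.accumulate(np.concatenate(([S[i, 0]], t)) + G)
        S[i] = e - G

    # free trailing gaps: best cell on the last row or column
    end_i, end_j = m, n
    best = S[m, n]
    for j in range(n - 1, -1, -1):
        if S[m, j] > best + _TOL:
            best, end_i, end_j = S[m, j], m, j
    for i in range(m - 1, -1, -1):
        if S[i, n] > best + _TOL:
            best, end_i, end_j = S[i, n], i, n

    ga: list[str] = []
    gb: list[str] = []
    # trailing free gaps (at most one of the two runs is non-empty)
    ga.extend(a[end_i:][::-1])
    gb.extend("-" * (m - end_i))
    ga.extend("-" * (n - end_j))
    gb.extend(b[end_j:][::-1])

    i, j = end_i, end_j
    cut_edits = 0
    edits = 0
    cost = 0.0
    while i > 0 and j > 0:
        here = S[i, j]
        ca, cb = a[i - 1], b[j - 1]
        if ca == cb and abs(S[i - 1, j - 1] + MATCH_REWARD - here) <= _TOL:
            i, j = i - 1, j - 1
        elif ca != cb and abs(S[i - 1, j - 1] - w - here) <= _TOL:
            cut_edits += 1
            edits += 1
            cost += w
            i, j = i - 1, j - 1
        elif abs(S[i - 1, j] - gap_a[i - 1] - here) <= _TOL:
            cut_edits += ca == "1"
            edits += 1
            cost += gap_a[i - 1]
            ca, cb = ca, "-"
            i -= 1
        else:
            cut_edits += cb == "1"
            edits += 1
            cost += gap_b[j - 1]
            ca, cb = "-", cb
            j -= 1
        ga.append(ca)
        gb.append(cb)
    # leading free gaps (at most one of i, j is positive)
    ga.extend(a[:i][::-1])
    gb.extend("-" * i)
    ga.extend("-" * j)
    gb.extend(b[:j][::-1])

    return PairAlignment(
        "".join(ga[::-1]), "".join(gb[::-1]), float(best), cost, cut_edits, edits
    )


def align_rmaps(a: BinaryRmap, b: BinaryRmap) -> PairAlignment:
    """Align two encoded Rmaps, with corpus counts taken over the pair."""
    c0, c1 = corpus_counts(a.chars, b.chars)
    return align(a.chars, b.chars, c0, c1)


def filter_candidates(
    target: Rmap,
    candidates: Sequence[Rmap],
    block_bp: int = 2000,
    max_edit_frac: float = 0.8,
) -> list[Rmap]:
    """Keep candidates whose pairwise alignment to the target is clean enough.

    A candidate is removed when the number of cut-site-involving edits of its
    alignment to the target strictly exceeds ``max_edit_frac`` times the cut
    count of the Rmap with fewer cut sites: Rmaps are assumed to carry at
    most 40% added-plus-missing cut sites each, so a related pair should not
    exceed 80%.  This is a permissive pre-filter -- the consensus stage
    applies its own, sharper agreement test per member -- so its job is only
    to discard candidates whose cut structure is grossly incompatible.
    Input ranking is preserved.
    """
    tb = to_binary(target, block_bp)
    kept = []
    for cand in candidates:
        cb = to_binary(cand, block_bp)
        aln = align_rmaps(tb, cb)
        if aln.cutsite_edits <= max_edit_frac * min(tb.n_cuts, cb.n_cuts):
            kept.append(cand)
    return kept
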