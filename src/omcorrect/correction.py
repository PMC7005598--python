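"""Consensus-based error correction of Rmaps.

For each target Rmap, the related Rmaps retrieved from the spaced (l,k)-mer
index (and surviving the pairwise-alignment filter) are stacked into a
heuristic multiple alignment of their binary encodings: the target is the
initial consensus, each related Rmap is aligned against the current consensus
in retrieval-rank order, insertions open new columns, and the per-column
majority symbol becomes the new consensus.  Rows disagreeing too much with
the consensus (> 3 extra cut sites, or > 40% of the consensus cuts in their
span deleted) are dropped and the alignment rebuilt.  If at least five Rmaps
remain, consensus cut columns define a consensus Rmap whose fragment lengths
are averaged from the original (unquantized) supporting Rmaps, and every
member is replaced by the consensus stretch it aligns to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .binalign import BinaryRmap, align, corpus_counts, filter_candidates, to_binary
from .evaluation import match_cuts
from .rmap_core import Rmap, RmapSet, frag_to_cuts
from .seed_index import IndexParams, SeedIndex, build_index

__all__ = [
    "CorrectionParams",
    "Consensus",
    "MsaRow",
    "MultipleAlignment",
    "build_msa",
    "filter_msa",
    "consensus_fragments",
    "correct_rmap",
    "correct_all",
]


@dataclass
class CorrectionParams:
    index: IndexParams = field(default_factory=IndexParams)
    block_bp: int = 2000
    max_edit_frac: float = 0.8
    max_extra_cuts: int = 3
    max_deleted_frac: float = 0.4
    min_msa: int = 5
    max_corrections: int = 5


@dataclass
class MsaRow:
    rmap: Rmap
    binary: BinaryRmap
    gapped: str

    def cut_columns(self) -> dict[int, int]:
        """Map from alignment column to the original cut coordinate (bp)."""
        cuts = [0]
        for r in self.rmap.fragments:
            cuts.append(cuts[-1] + r)
        out = {}
        k = 0
        for j, ch in enumerate(self.gapped):
            if ch == "1":
                out[j] = cuts[self.binary.cutmap[k]]
                k += 1
        return out


@dataclass
class MultipleAlignment:
    rows: list[MsaRow]  # rows[0] is the target
    consensus: str
    block_bp: int

    @property
    def members(self) -> list[str]:
        return [row.rmap.id for row in self.rows]


def _span(gapped: str) -> tuple[int, int]:
    """First and last non-gap column of a row (end-gap runs lie outside)."""
    lo = 0
    while lo < len(gapped) and gapped[lo] == "-":
        lo += 1
    hi = len(gapped) - 1
    while hi >= 0 and gapped[hi] == "-":
        hi -= 1
    return lo, hi


def _column_consensus(rows: Sequence[str], prev: Sequence[Optional[str]]) -> str:
    """Most prevalent symbol per column over the rows covering that column.

    Two departures from a literal per-column vote, both forced by the data:

    * A row votes only within its aligned span.  Leading and trailing gap
      runs are free end gaps -- absence of data, not an observed deletion --
      and at moderate coverage they would drown out the covering rows
      wherever members overlap the target region only partially.
    * Cut columns are decided on votes pooled over a one-column window with
      non-maximum suppression.  The binary encoding is ambiguous at block
      boundaries, so the supporters of one true cut land on 2-3 adjacent
      columns; requiring an exact-column majority would silently delete such
      cuts from the consensus.  A column becomes a consensus cut when its
      pooled '1' votes beat both the competing 0/'-' votes at that column and
      every overlapping candidate.

    Non-cut columns take the majority of their remaining votes, ties
    favouring the previous consensus symbol, then '0' over '-'.
    """
    n_cols = len(rows[0])
    spans = [_span(r) for r in rows]
    ones = [0] * n_cols
    zeros = [0] * n_cols
    gaps = [0] * n_cols
    for row, (lo, hi) in zip(rows, spans):
        for j in range(lo, hi + 1):
            ch = row[j]
            if ch == "1":
                ones[j] += 1
            elif ch == "0":
                zeros[j] += 1
            else:
                gaps[j] += 1
    pooled = [
        ones[j]
        + (ones[j - 1] if j > 0 else 0)
        + (ones[j + 1] if j + 1 < n_cols else 0)
        for j in range(n_cols)
    ]
    # candidate cut columns by descending pooled support, then position;
    # a chosen cut suppresses its direct neighbours
    order = sorted(
        (j for j in range(n_cols) if ones[j]),
        key=lambda j: (-pooled[j], -ones[j], j),
    )
    # rows supporting both of two adjacent columns mark two distinct cuts
    # (one molecule cannot place a single cut in two columns)
    both_next = [0] * n_cols
    for row in rows:
        for j in range(n_cols - 1):
            if row[j] == "1" and row[j + 1] == "1":
                both_next[j] += 1
    is_cut = [False] * n_cols
    blocked = [False] * n_cols
    for j in order:
        if blocked[j]:
            continue
        others = zeros[j] + gaps[j] - (ones[j - 1] if j > 0 else 0) - (
            ones[j + 1] if j + 1 < n_cols else 0
        )
        # pooled cut votes must be the most prevalent interpretation
        if pooled[j] > max(others, 0):
            is_cut[j] = True
            for k in (j - 1, j + 1):
                if 0 <= k < n_cols:
                    pair = both_next[min(j, k)]
                    if 2 * pair < ones[k]:
                        blocked[k] = True
        blocked[j] = True
    out = []
    for j in range(n_cols):
        if is_cut[j]:
            out.append("1")
            continue
        counts = {"0": zeros[j], "-": gaps[j]}
        best = max(counts.values())
        winners = {s for s, c in counts.items() if c == best}
        if prev[j] in winners:
            out.append(prev[j])
        else:
            out.append("0" if "0" in winners else "-")
    return "".join(out)


def build_msa(
    target: Rmap, related: Sequence[Rmap], block_bp: int = 2000
) -> MultipleAlignment:
    """Stack the target and its related Rmaps into a gapped binary alignment.

    Rmaps are aligned consecutively (in the given order) against the running
    consensus; corpus counts for the cut-site edit cost are taken over the
    consensus plus the incoming string.  Incoming strings are aligned against
    the consensus with its gap-majority columns removed: a '-' consensus
    column records an insertion most members do not share, and letting it
    consume alignment width would stretch the consensus geometry by one block
    per insertion, systematically shifting every later member.
    """
    tb = to_binary(target, block_bp)
    rows = [MsaRow(target, tb, tb.chars)]
    consensus = tb.chars
    for rm in related:
        rb = to_binary(rm, block_bp)
        keep = [j for j, ch in enumerate(consensus) if ch != "-"]
        compact = "".join(consensus[j] for j in keep)
        c0, c1 = corpus_counts(compact, rb.chars)
        aln = align(compact, rb.chars, c0, c1)

        length = len(consensus)
        new_chars: dict[int, str] = {}  # full column -> incoming symbol
        inserts: dict[int, list[str]] = {}  # before-column -> inserted symbols
        ci = 0
        for ca, cb in zip(aln.gapped_a, aln.gapped_b):
            if ca != "-":
                if cb != "-":
                    new_chars[keep[ci]] = cb
                ci += 1
            else:
                at = keep[ci] if ci < len(keep) else length
                inserts.setdefault(at, []).append(cb)

        prev: list[Optional[str]]
        if inserts:
            def splice(chars: Sequence, filler) -> list:
                out: list = []
                for col in range(length):
                    out.extend([filler] * len(inserts.get(col, ())))
                    out.append(chars[col])
                out.extend([filler] * len(inserts.get(length, ())))
                return out

            for row in rows:
                row.gapped = "".join(splice(row.gapped, "-"))
            prev = splice(list(consensus), None)
            incoming = []
            for col in range(length):
                incoming.extend(inserts.get(col, ()))
                incoming.append(new_chars.get(col, "-"))
            incoming.extend(inserts.get(length, ()))
            gapped_b = "".join(incoming)
        else:
            prev = list(consensus)
            gapped_b = "".join(new_chars.get(col, "-") for col in range(length))
        rows.append(MsaRow(rm, rb, gapped_b))
        consensus = _column_consensus([r.gapped for r in rows], prev)
    return MultipleAlignment(rows, consensus, block_bp)


def filter_msa(
    msa: MultipleAlignment,
    max_extra_cuts: int = 3,
    max_deleted_frac: float = 0.4,
) -> MultipleAlignment:
    """Drop rows disagreeing heavily with the consensus, then realign.

    A row is removed when it shows more than ``max_extra_cuts`` cut sites
    absent from the consensus, or when more than ``max_deleted_frac`` of the
    consensus cut sites within its aligned span are missing from it -- as
    judged by the cut-coordinate chain matching of
    :func:`consensus_fragments`, which is where those quantities are
    unambiguous.  The target row anchors the region and is never removed.
    If anything was removed the multiple alignment is rebuilt from the
    survivors in order.
    """
    cons = consensus_fragments(msa, max_extra_cuts, max_deleted_frac)
    survivors = [
        row.rmap
        for i, row in enumerate(msa.rows)
        if i == 0 or row.rmap.id in cons.spans
    ]
    if len(survivors) == len(msa.rows):
        return msa
    return build_msa(survivors[0], survivors[1:], msa.block_bp)


def consensus_fragments(
    msa: MultipleAlignment,
    max_extra_cuts: int = 3,
    max_deleted_frac: float = 0.4,
) -> "Consensus":
    """Consensus cut sites and averaged fragment lengths for an alignment.

    The gapped columns give only block-resolution correspondence, and at a
    realistic cut density neighbouring cut sites often lie within the
    alignment's snapping radius of each other, so the consensus is built on
    the members' original (unquantized) cut coordinates instead.  The target
    is the backbone; each member's cuts are put in correspondence with the
    consensus cut list by an optimal monotone matching on inter-cut distances
    (multiplicative sizing error accumulates along a molecule, so no global
    offset aligns two 250-kbp molecules end to end, and a greedy walk lets an
    added cut capture its true neighbour's supporters).  A backbone cut is
    kept when the members covering it support it by majority; member cuts
    matching no consensus cut are pooled in the target frame, and a cluster
    supported by at least two members and a majority of the covering members
    becomes a new consensus cut -- a deleted cut of the target, restored.
    Molecule endpoints are breaks, not cut sites, and never vote.

    Site calling runs twice: members are first pooled without any agreement
    filter, and only then are rows with more than ``max_extra_cuts`` cuts
    absent from the called consensus, or more than ``max_deleted_frac`` of
    the consensus cuts in their span missing, removed and the sites re-called
    from the survivors.  Filtering against the consensus rather than the raw
    target matters: a member carrying a cut the target lost is exactly what
    restoration needs, not evidence of disagreement.

    Each pair of adjacent consensus cut sites defines one fragment whose
    length is the mean, over the member Rmaps carrying a cut at both sites,
    of the original distance between those cuts, rounded to the nearest bp;
    a fragment nobody supports falls back to the distance between the
    consensus positions.
    """
    target = msa.rows[0]
    tol = 3 * msa.block_bp // 5

    backbone = [float(c) for c in frag_to_cuts(target.rmap.fragments)[1:-1]]
    member_cuts: dict[int, list[int]] = {}
    for ridx, row in enumerate(msa.rows):
        cuts = frag_to_cuts(row.rmap.fragments)[1:-1]  # endpoints are breaks
        if cuts:
            member_cuts[ridx] = cuts

    def call_sites(reference: list[float], members: dict[int, list[int]]):
        """Match members to reference cuts, then majority-call cut sites."""
        site_events: list[dict[int, int]] = [dict() for _ in reference]
        leftovers: list[tuple[float, int, int]] = []
        spans: dict[int, tuple[float, float]] = {}
        for ridx, cuts in members.items():
            if ridx == 0 and reference is backbone:
                for j, c in enumerate(backbone):
                    site_events[j][0] = int(c)
                spans[0] = (0.0, float(target.rmap.length))
                continue
            _, _, matched = match_cuts(cuts, reference, tol, rel_tol=0.2)
            if len(matched) < min(3, len(reference)):
                continue  # too weak an anchor to trust
            pairs = {i: j for i, j in matched}
            anchor_i = sorted(pairs)
            for i, j in matched:
                site_events[j][ridx] = cuts[i]
            # place unmatched cuts in the target frame via the nearest anchor
            for i, c in enumerate(cuts):
                if i in pairs:
                    continue
                near = min(anchor_i, key=lambda ai: abs(ai - i))
                leftovers.append((reference[pairs[near]] + (c - cuts[near]), ridx, c))
            i0, iN = anchor_i[0], anchor_i[-1]
            lo = reference[pairs[i0]] - cuts[i0]
            hi = reference[pairs[iN]] + (msa.rows[ridx].rmap.length - cuts[iN])
            spans[ridx] = (lo, hi)

        def covering(x: float) -> int:
            return sum(1 for lo, hi in spans.values() if lo + tol <= x <= hi - tol)

        sites: list[tuple[float, dict[int, int]]] = []
        for j, pos in enumerate(reference):
            support = len(site_events[j])
            cov = covering(pos)
            # where only the target itself covers (flanks), its own cut stands
            if support >= min(2, max(cov, 1)) and 2 * support > cov:
                sites.append((pos, dict(site_events[j])))

        # cluster leftover member cuts: majority-backed restored cut sites
        leftovers.sort()
        chunks: list[list[tuple[float, int, int]]] = []
        for ev in leftovers:
            if chunks and ev[0] - chunks[-1][-1][0] <= tol:
                chunks[-1].append(ev)
            else:
                chunks.append([ev])

        def split_chunk(chunk):
            # a chunk holds two distinct cut sites only if rows see both:
            # a majority of the covering rows contributing >= 2 events is
            # two-cut evidence, and the chunk splits at its largest gap
            if len(chunk) < 2:
                return [chunk]
            per_row: dict[int, int] = {}
            for _, ridx, _ in chunk:
                per_row[ridx] = per_row.get(ridx, 0) + 1
            multi = sum(1 for c in per_row.values() if c >= 2)
            centre = _median([x for x, _, _ in chunk])
            if 2 * multi <= covering(centre):
                return [chunk]
            gaps = [chunk[i + 1][0] - chunk[i][0] for i in range(len(chunk) - 1)]
            gi = max(range(len(gaps)), key=lambda i: gaps[i])
            if gaps[gi] <= 0:
                return [chunk]
            return split_chunk(chunk[: gi + 1]) + split_chunk(chunk[gi + 1 :])

        chunks = [c for chunk in chunks for c in split_chunk(chunk)]
        kept_positions = [p for p, _ in sites]
        for chunk in chunks:
            centre = _median([x for x, _, _ in chunk])
            supporters: dict[int, tuple[float, int]] = {}
            for x, ridx, coord in chunk:
                if ridx not in supporters or abs(x - centre) < abs(
                    supporters[ridx][0] - centre
                ):
                    supporters[ridx] = (x, coord)
            cov = covering(centre)
            # restoring a cut the target lacks takes real evidence: at least
            # two supporters, a majority, and at least three covering members
            # (where almost nobody covers, two stray events are not evidence)
            if len(supporters) < 2 or 2 * len(supporters) <= cov or cov < 3:
                continue
            if any(abs(centre - p) <= tol for p in kept_positions):
                continue  # straggler of an existing site
            mean_pos = sum(x for x, _ in supporters.values()) / len(supporters)
            sites.append((mean_pos, {r: c for r, (_, c) in supporters.items()}))
        sites.sort(key=lambda s: s[0])
        return sites, spans

    sites, spans = call_sites(backbone, member_cuts)
    positions = [p for p, _ in sites]
    if positions:
        survivors: dict[int, list[int]] = {}
        for ridx, cuts in member_cuts.items():
            if ridx == 0:
                survivors[0] = cuts  # the target anchors the region
                continue
            if ridx not in spans:
                continue
            # agreement is judged leniently (twice the calling tolerance):
            # a borderline-placed true cut is not evidence of disagreement
            _, _, matched = match_cuts(cuts, positions, 2 * tol, rel_tol=0.3)
            lo, hi = spans[ridx]
            in_span = sum(1 for p in positions if lo <= p <= hi)
            extra = len(cuts) - len(matched)
            deleted = in_span - len(matched)
            if extra > max_extra_cuts or deleted > max_deleted_frac * max(in_span, 1):
                continue
            survivors[ridx] = cuts
        # final pass: re-anchor every survivor against the full called
        # consensus rather than the bare target backbone -- a member that
        # overlaps the target only weakly has a short true chain against the
        # backbone, which a spurious chain of tolerance coincidences can
        # beat, silently mis-placing its span; against the full consensus
        # the true chain covers the member's whole span and wins outright
        sites, spans = call_sites(positions, survivors)

    positions = [p for p, _ in sites]
    row_coord = [s[1] for s in sites]
    out_spans = {
        msa.rows[ridx].rmap.id: span for ridx, span in spans.items()
    }

    fragments = []
    for i in range(len(positions) - 1):
        expected = positions[i + 1] - positions[i]
        dists = [
            row_coord[i + 1][r] - row_coord[i][r]
            for r in row_coord[i]
            if r in row_coord[i + 1] and row_coord[i + 1][r] > row_coord[i][r]
            # supporters must corroborate the consensus geometry; a distance
            # bridging the wrong cut pair would otherwise poison the average
            and abs((row_coord[i + 1][r] - row_coord[i][r]) - expected)
            <= max(tol, 0.25 * expected)
        ]
        if dists:
            fragments.append(max(1, round(_median(dists))))
        else:
            fragments.append(max(1, round(expected)))
    return Consensus(positions, fragments, out_spans)


def _median(xs: list) -> float:
    s = sorted(xs)
    n = len(s)
    return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2


@dataclass
class Consensus:
    """Consensus cut positions (target-frame bp), fragments and member spans."""

    positions: list[float]
    fragments: list[int]
    spans: dict[str, tuple[float, float]]


def correct_rmap(row: MsaRow, consensus: "Consensus") -> Optional[Rmap]:
    """The consensus stretch a member covers, or None if it spans < 2 cuts.

    The member's molecule ends are breaks, not cut sites, so the corrected
    Rmap keeps its own flank fragments (span edge to the first/last consensus
    cut inside the span) around the consensus stretch.
    """
    span = consensus.spans.get(row.rmap.id)
    if span is None:
        return None
    lo, hi = span
    idx = [i for i, p in enumerate(consensus.positions) if lo <= p <= hi]
    if len(idx) < 2:
        return None
    frags = list(consensus.fragments[idx[0] : idx[-1]])
    left = round(consensus.positions[idx[0]] - lo)
    right = round(hi - consensus.positions[idx[-1]])
    if left >= 1:
        frags = [left] + frags
    if right >= 1:
        frags = frags + [right]
    return Rmap(row.rmap.id, frags, meta={**row.rmap.meta, "corrected": True})


def correct_all(
    rmaps: RmapSet,
    index: Optional[SeedIndex] = None,
    params: Optional[CorrectionParams] = None,
) -> tuple[RmapSet, dict]:
    """Correct every Rmap in the set towards local consensus Rmaps.

    Iterates the Rmaps in input order; a target already corrected
    ``max_corrections`` times is skipped.  For a processed target the related
    Rmaps are retrieved, filtered pairwise, stacked into a multiple alignment
    and filtered again; if at least ``min_msa`` Rmaps remain, every member of
    the alignment is replaced by its consensus stretch (its correction
    counter incremented).  Each Rmap's output is its last correction;
    untouched Rmaps pass through unchanged.  Deterministic given input order.
    """
    params = params or CorrectionParams()
    if index is None:
        index = build_index(rmaps, params.index)
        index.merge_similar()
    counters: dict[str, int] = {r.id: 0 for r in rmaps}
    corrected: dict[str, Rmap] = {}
    log = []
    for target in rmaps:
        entry = {"id": target.id}
        if counters[target.id] >= params.max_corrections:
            entry["status"] = "skipped: correction cap reached"
            log.append(entry)
            continue
        hits = index.query_related(target)
        candidates = [rmaps[rid] for rid, _ in hits]
        entry["n_candidates"] = len(candidates)
        filtered = filter_candidates(
            target, candidates, params.block_bp, params.max_edit_frac
        )
        entry["n_filtered"] = len(filtered)
        msa = build_msa(target, filtered, params.block_bp)
        msa = filter_msa(msa, params.max_extra_cuts, params.max_deleted_frac)
        entry["n_msa"] = len(msa.rows)
        if len(msa.rows) < params.min_msa:
            entry["status"] = "skipped: fewer than five Rmaps in the alignment"
            log.append(entry)
            continue
        consensus = consensus_fragments(
            msa, params.max_extra_cuts, params.max_deleted_frac
        )
        n_corr = 0
        for row in msa.rows:
            corr = correct_rmap(row, consensus)
            if corr is not None:
                corrected[row.rmap.id] = corr
                counters[row.rmap.id] += 1
                n_corr += 1
        entry["status"] = f"corrected {n_corr} members"
        log.append(entry)
    out = RmapSet()
    for rmap in rmaps:
        if rmap.id in corrected:
            out.add(corrected[rmap.id])
        else:
            out.add(Rmap(rmap.id, list(rmap.fragments), dict(rmap.meta)))
    report = {
        "n_rmaps": len(rmaps),
        "n_corrected": len(corrected),
        "targets": log,
    }
    return out, report
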