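"""Extraction of k-mers, l-mers, (l,k)-mers and spaced (l,k)-mers from Rmaps.

Viewing an Rmap as a line segment with cut sites as points, an *l-mer* is the
set of cut sites falling inside an l-bp window, expressed as fragment sizes.
An *(l,k)-mer* extends the window rightward fragment-by-fragment until it
holds at least k fragments.  A *spaced (l,k)-mer* first removes every cut
site lying under a gap (0) bit of a spacing pattern aligned to the window,
then takes the (l,k)-mer of the modified Rmap; added/deleted cut sites under
gap bits thus stop distinguishing otherwise identical seeds.

All functions accept a plain sequence of fragment lengths (bp, or quantized
bin counts -- zero-length fragments from quantization are legal) and return
seeds as tuples of fragment lengths in sweep order.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = [
    "SpacingPattern",
    "DEFAULT_PATTERN_BITS",
    "extract_kmers",
    "extract_lmers",
    "extract_lk_mers",
    "extract_spaced",
]

# 80-bit default spacing pattern; at l = 80 kbp each bit spans 1 kbp.
DEFAULT_PATTERN_BITS = (
    "11111111110001110110010010011101001110001010010100001010011000010111100000001100"
)


@dataclass(frozen=True)
class SpacingPattern:
    """A {0,1} pattern over an l-bp window; each bit spans ``span_bp`` bp.

    1-bits are solid (cut sites kept), 0-bits are gaps (cut sites removed).
    """

    bits: str
    span_bp: int

    def __post_init__(self):
        if not self.bits or set(self.bits) - {"0", "1"}:
            raise ValueError("pattern must be a non-empty string over {0,1}")
        if self.span_bp < 1:
            raise ValueError("span_bp must be >= 1")

    @property
    def length_bp(self) -> int:
        return len(self.bits) * self.span_bp

    @classmethod
    def for_window(cls, bits: str, l: int) -> "SpacingPattern":
        """Pattern spanning an l-bp window: each bit covers l/|bits| bp."""
        if l % len(bits) != 0:
            raise ValueError(f"window length {l} not divisible by |S|={len(bits)}")
        return cls(bits, l // len(bits))

    def is_solid(self, offset: int) -> bool:
        """Whether a cut at ``offset`` bp from the window start is kept."""
        return self.bits[offset // self.span_bp] == "1"


def _cuts(fragments: Sequence[int]) -> list[int]:
    cuts = [0]
    for r in fragments:
        cuts.append(cuts[-1] + r)
    return cuts


def extract_kmers(fragments: Sequence[int], k: int) -> list[tuple[int, ...]]:
    """All k-length windows of consecutive fragment sizes, in order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    frags = tuple(fragments)
    return [frags[i : i + k] for i in range(len(frags) - k + 1)]


def _seed_at(
    cuts: list[int], p: int, l: int, k: int, pattern: Optional[SpacingPattern]
) -> Optional[tuple[int, ...]]:
    """The (spaced) (l,k)-mer anchored at window position p, or None.

    Cut sites under gap bits are dropped; cuts beyond the window (offset >= l)
    lie outside the pattern and are always kept.  The window's kept cuts are
    extended rightward through kept cuts until at least k fragments are
    present (truncated at the Rmap end).  Windows with no kept cut, or seeds
    with fewer than one fragment, yield None.
    """
    i = bisect_left(cuts, p)
    sel: list[int] = []
    j = i
    n = len(cuts)
    while j < n and cuts[j] - p < l:
        if pattern is None or pattern.is_solid(cuts[j] - p):
            sel.append(cuts[j])
        j += 1
    if not sel:
        return None
    while len(sel) - 1 < k and j < n:
        sel.append(cuts[j])
        j += 1
    if len(sel) < 2:
        return None
    return tuple(b - a for a, b in zip(sel, sel[1:]))


def _event_positions(
    cuts: list[int], l: int, pattern: Optional[SpacingPattern]
) -> list[int]:
    """Window positions p where the swept seed can change.

    The seed at p is a function of each cut's offset d = c - p; it can only
    change where some d crosses the window boundary (entry at d = l-1, exit
    at d = -1) or a solid/gap transition of the pattern.  Evaluating at every
    such p (plus p = 0) therefore reproduces the full integer-p sweep.
    """
    total = cuts[-1]
    p_max = max(0, total - l + 1)
    offsets = {0, l}  # exit handled separately; l = window-entry boundary
    if pattern is not None:
        s = pattern.span_bp
        bits = pattern.bits
        for idx in range(1, len(bits)):
            if bits[idx] != bits[idx - 1]:
                offsets.add(idx * s)
    positions = {0}
    for c in cuts:
        for off in offsets:
            p = c - off + 1
            if 0 < p <= p_max:
                positions.add(p)
        if 0 < c + 1 <= p_max:
            positions.add(c + 1)
    return sorted(positions)


def _sweep(
    fragments: Sequence[int], l: int, k: int, pattern: Optional[SpacingPattern]
) -> list[tuple[int, ...]]:
    """Event sweep over window positions; consecutive duplicates collapsed."""
    cuts = _cuts(fragments)
    out: list[tuple[int, ...]] = []
    for p in _event_positions(cuts, l, pattern):
        seed = _seed_at(cuts, p, l, k, pattern)
        if seed is not None and (not out or out[-1] != seed):
            out.append(seed)
    return out


def _dedupe(seeds: list[tuple[int, ...]]) -> list[tuple[int, ...]]:
    seen = set()
    out = []
    for s in seeds:
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def extract_lmers(fragments: Sequence[int], l: int) -> list[tuple[int, ...]]:
    """All distinct maximal cut-site sets within an l-bp window, as fragments.

    Window sets with fewer than two cut sites (no complete fragment) are
    dropped.  If l exceeds the Rmap length the single all-cuts seed results.
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    return _dedupe(_sweep(fragments, l, 0, None))


def extract_lk_mers(fragments: Sequence[int], l: int, k: int) -> list[tuple[int, ...]]:
    """(l,k)-mers: l-mers extended rightward until >= k fragments.

    (0,k)-mers reduce to k-mers and (l,0)-mers to l-mers.  Duplicate seeds
    arising from the extension are collapsed in first-occurrence order.
    """
    if l < 0 or k < 0:
        raise ValueError("l and k must be non-negative")
    if l == 0:
        return extract_kmers(fragments, k)
    if k == 0:
        return extract_lmers(fragments, l)
    return _dedupe(_sweep(fragments, l, k, None))


def extract_spaced(
    fragments: Sequence[int], l: int, k: int, pattern: SpacingPattern
) -> list[tuple[int, ...]]:
    """Spaced (l,k)-mers under ``pattern``, deduplicated in sweep order.

    With an all-ones pattern this equals :func:`extract_lk_mers`; an all-zeros
    pattern keeps no cut in any window and yields an empty list.
    """
    if pattern.length_bp != l:
        raise ValueError(
            f"pattern spans {pattern.length_bp} bp but window length is {l}"
        )
    return _dedupe(_sweep(fragments, l, k, pattern))
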