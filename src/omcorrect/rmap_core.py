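"""Rmap data model, representation conversions, in-silico digestion and file I/O.

An Rmap is the raw output of optical mapping for one DNA molecule: an ordered
list of fragment lengths (bp) between restriction cut sites.  Two equivalent
encodings are used throughout:

* fragment-size representation ``[r_1, ..., r_n]`` and
* cut-site representation ``[c_1, ..., c_{n+1}]`` with ``c_1 = 0`` and
  ``r_i = c_{i+1} - c_i``.

All internal units are integer base pairs; kilobase decimals appear only at
I/O boundaries (the Valouev-style text dialect).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Rmap",
    "RmapSet",
    "InvalidRmapError",
    "frag_to_cuts",
    "cuts_to_frags",
    "digest",
    "delete_cut",
    "split_fragment",
    "read_rmaps",
    "write_rmaps",
    "read_fasta",
]


class InvalidRmapError(ValueError):
    """Raised for malformed Rmaps, cut lists or input records."""


@dataclass
class Rmap:
    """One optical-mapping read: an identifier plus ordered fragment sizes (bp).

    An Rmap with an empty fragment list is only produced by :func:`digest`
    when the input sequence contains fewer than two restriction-site
    occurrences; it carries ``meta["undigestible"] = True``.
    """

    id: str
    fragments: list[int]
    meta: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        """Number of fragments n."""
        return len(self.fragments)

    @property
    def length(self) -> int:
        """Total molecule length |R| = sum of fragments (bp)."""
        return sum(self.fragments)

    @property
    def undigestible(self) -> bool:
        return bool(self.meta.get("undigestible", False))

    def validate(self) -> None:
        if not self.fragments:
            raise InvalidRmapError(f"Rmap {self.id!r} has no fragments")
        for r in self.fragments:
            if r < 1:
                raise InvalidRmapError(
                    f"Rmap {self.id!r} has non-positive fragment {r}"
                )


class RmapSet:
    """Ordered multiset of Rmaps with id lookup.

    Duplicate ids are suffixed deterministically (``id.2``, ``id.3``, ...) so
    that ids are unique after construction.
    """

    def __init__(self, rmaps: Iterable[Rmap] = ()):
        self.rmaps: list[Rmap] = []
        self._by_id: dict[str, Rmap] = {}
        for r in rmaps:
            self.add(r)

    def add(self, rmap: Rmap) -> None:
        rid = rmap.id
        if rid in self._by_id:
            n = 2
            while f"{rid}.{n}" in self._by_id:
                n += 1
            rmap.id = f"{rid}.{n}"
        self.rmaps.append(rmap)
        self._by_id[rmap.id] = rmap

    def __len__(self) -> int:
        return len(self.rmaps)

    def __iter__(self) -> Iterator[Rmap]:
        return iter(self.rmaps)

    def __getitem__(self, rid: str) -> Rmap:
        return self._by_id[rid]

    def __contains__(self, rid: str) -> bool:
        return rid in self._by_id

    def ids(self) -> list[str]:
        return [r.id for r in self.rmaps]


def frag_to_cuts(fragments: Sequence[int]) -> list[int]:
    """Convert fragment sizes to the cut-site representation.

    ``cuts[i]`` is the cumulative sum of the first ``i`` fragments, so
    ``cuts[0] == 0`` and ``cuts[n] == |R|``.
    """
    if not fragments:
        raise InvalidRmapError("cannot convert an empty fragment list")
    cuts = [0]
    for r in fragments:
        if r < 1:
            raise InvalidRmapError(f"non-positive fragment {r}")
        cuts.append(cuts[-1] + r)
    return cuts


def cuts_to_frags(cuts: Sequence[int]) -> list[int]:
    """Convert a cut-site representation back to fragment sizes."""
    if len(cuts) < 2:
        raise InvalidRmapError("cut-site representation needs >= 2 coordinates")
    if cuts[0] != 0:
        raise InvalidRmapError("cut-site representation must start at 0")
    frags = []
    for a, b in zip(cuts, cuts[1:]):
        if b <= a:
            raise InvalidRmapError("cut coordinates must be strictly increasing")
        frags.append(b - a)
    return frags


def _occurrences(sequence: str, site: str) -> list[int]:
    """0-based start positions of every (possibly overlapping) occurrence."""
    out = []
    start = sequence.find(site)
    while start != -1:
        out.append(start)
        start = sequence.find(site, start + 1)
    return out


def digest(sequence: str, site: str, rid: str = "digest") -> Rmap:
    """In-silico digestion of a nucleotide sequence at every site occurrence.

    The cut coordinate of the i-th occurrence is its 0-based start position;
    the sequence before the first cut and after the last cut is discarded, so
    the returned fragments are the gaps between consecutive occurrence starts.
    Overlapping occurrences all count.  With fewer than two occurrences the
    sequence is undigestible and an empty, flagged Rmap is returned.
    """
    if not site:
        raise InvalidRmapError("restriction site must be non-empty")
    seq = sequence.upper()
    occ = _occurrences(seq, site.upper())
    if len(occ) < 2:
        return Rmap(rid, [], meta={"undigestible": True, "site": site})
    cuts = [p - occ[0] for p in occ]
    return Rmap(rid, cuts_to_frags(cuts), meta={"site": site})


def delete_cut(fragments: Sequence[int], cut_index: int) -> list[int]:
    """Simulate a deleted cut site: merge the two fragments flanking one cut.

    ``cut_index`` is the 1-based index into the cut-site representation
    ``C = [c_1, ..., c_{n+1}]``; only internal cuts (2 <= cut_index <= n) can
    be deleted.  Deleting ``c_i`` merges fragments ``i-1`` and ``i``: an
    enzyme missing the second cut site of ``[5,9,14,5]`` yields ``[14,14,5]``.
    """
    frags = list(fragments)
    if not 2 <= cut_index <= len(frags):
        raise InvalidRmapError(f"no internal cut with index {cut_index}")
    i = cut_index - 1  # fragment to the right of the deleted cut, 0-based
    merged = frags[i - 1] + frags[i]
    return frags[: i - 1] + [merged] + frags[i + 1 :]


def split_fragment(
    fragments: Sequence[int], frag_index: int, left_size: int
) -> list[int]:
    """Simulate an added cut site: split one fragment into two.

    ``frag_index`` is 1-based; the new cut falls ``left_size`` bp into the
    fragment: splitting the third fragment of ``[5,9,14,5]`` at 6 bp yields
    ``[5,9,6,8,5]``.
    """
    frags = list(fragments)
    if not 1 <= frag_index <= len(frags):
        raise InvalidRmapError(f"no fragment with index {frag_index}")
    r = frags[frag_index - 1]
    if not 1 <= left_size <= r - 1:
        raise InvalidRmapError(f"cannot split a {r}-bp fragment at {left_size}")
    return (
        frags[: frag_index - 1]
        + [left_size, r - left_size]
        + frags[frag_index:]
    )


# ---------------------------------------------------------------------------
# File I/O


def read_fasta(path) -> str:
    """Read the first record of a FASTA file as an upper-case string."""
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return str(rec.seq).upper()


def read_rmaps(path, dialect: str = "tsv") -> RmapSet:
    """Read an RmapSet from ``path``.

    dialect ``tsv``: one Rmap per line, ``id<TAB>comma-separated bp sizes``.
    dialect ``valouev``: 3-line records -- id line; enzyme name followed by
    whitespace-separated fragment sizes in kbp decimals; blank separator line.
    kbp decimals are converted to integer bp by rounding to nearest.
    """
    if dialect not in ("tsv", "valouev"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rmaps = RmapSet()
    with open(path) as fh:
        lines = fh.read().splitlines()
    if dialect == "tsv":
        for lineno, line in enumerate(lines, 1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InvalidRmapError(f"{path}:{lineno}: expected 'id<TAB>sizes'")
            rid, sizes = parts
            try:
                frags = [int(s) for s in sizes.split(",")]
            except ValueError as e:
                raise InvalidRmapError(f"{path}:{lineno}: bad fragment list") from e
            _check_frags(frags, path, lineno)
            rmaps.add(Rmap(rid, frags))
        return rmaps
    # valouev dialect
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        rid = lines[i].strip()
        if i + 1 >= len(lines):
            raise InvalidRmapError(f"{path}:{i + 1}: truncated record")
        tokens = lines[i + 1].split()
        if not tokens:
            raise InvalidRmapError(f"{path}:{i + 2}: empty fragment line")
        enzyme = tokens[0]
        try:
            frags = [int(round(float(t) * 1000)) for t in tokens[1:]]
        except ValueError as e:
            raise InvalidRmapError(f"{path}:{i + 2}: bad fragment size") from e
        _check_frags(frags, path, i + 2)
        rmaps.add(Rmap(rid, frags, meta={"enzyme": enzyme}))
        i += 2
        if i < len(lines) and lines[i].strip():
            raise InvalidRmapError(f"{path}:{i + 1}: expected blank separator line")
        i += 1
    return rmaps


def _check_frags(frags: list[int], path, lineno: int) -> None:
    if not frags:
        raise InvalidRmapError(f"{path}:{lineno}: record has no fragments")
    for r in frags:
        if r < 1:
            raise InvalidRmapError(f"{path}:{lineno}: non-positive fragment {r}")


def write_rmaps(rmaps: RmapSet, path, dialect: str = "tsv") -> None:
    """Write an RmapSet; inverse of :func:`read_rmaps` (fragments to 1 bp)."""
    if dialect not in ("tsv", "valouev"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for rmap in rmaps:
            if dialect == "tsv":
                fh.write(f"{rmap.id}\t{','.join(str(r) for r in rmap.fragments)}\n")
            else:
                enzyme = rmap.meta.get("enzyme", "enzyme")
                sizes = " ".join(f"{r / 1000:.3f}" for r in rmap.fragments)
                fh.write(f"{rmap.id}\n{enzyme} {sizes}\n\n")
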