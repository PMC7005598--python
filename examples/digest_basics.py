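"""In-silico digestion and the two Rmap representations.

Digest a short sequence at every occurrence of a restriction site, convert
between the fragment-size and cut-site representations, and apply the two
cut-site error channels.
"""

from omcorrect import cuts_to_frags, delete_cut, digest, frag_to_cuts, split_fragment

sequence = "CGCGTCGCGAATATCGCGTTAATAATAACGCGACGCG"
rmap = digest(sequence, "CGCG")

print(f"sequence ({len(sequence)} bp) digested at CGCG")
print("fragments:", rmap.fragments)          # [5, 9, 14, 5]
print("cut sites:", frag_to_cuts(rmap.fragments))  # [0, 5, 14, 28, 33]
print("round trip:", cuts_to_frags(frag_to_cuts(rmap.fragments)))

# a deleted cut site merges its two flanking fragments
print("enzyme misses cut 2:", delete_cut(rmap.fragments, 2))   # [14, 14, 5]
# a spurious break splits one fragment into two
print("fragment 3 breaks at 6 bp:", split_fragment(rmap.fragments, 3, 6))

# The fragment list is what optical mapping reports for a molecule; the cut
# list is the same molecule viewed as points on a line segment.  All of the
# seeding and alignment machinery moves between the two.
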