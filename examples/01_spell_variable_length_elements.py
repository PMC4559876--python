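"""Spell variable-length regulatory elements from overlapping hexamers.

Two 6-mers that overlap in five nucleotides are adjacent in the de Bruijn
graph, and walking that edge spells a single 7-mer candidate element; a
chain of m hexamers spells an (m+5)-mer.
"""

from sremine import MCS, spell_mcs

pair = MCS(
    id=1,
    element_type="enhancer",
    vertex_set=frozenset({"GTCATC", "TCATCC"}),
    exon_set=frozenset({"exon_a"}),
)
(spelled,) = spell_mcs(pair)
print(f"vertices GTCATC, TCATCC spell: {spelled.sequence} ({len(spelled.sequence)} nt)")

chain = MCS(
    id=2,
    element_type="enhancer",
    vertex_set=frozenset({"CCCGGA", "CCGGAG", "CGGAGC", "GGAGCC"}),
    exon_set=frozenset({"exon_a"}),
)
(spelled,) = spell_mcs(chain)
print(f"a chain of 4 hexamers spells:  {spelled.sequence} ({len(spelled.sequence)} nt)")
print("each extra overlapping hexamer extends the candidate element by one nucleotide")
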