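"""Mine maximal alpha-cohesive subgraphs from a tiny hand-built instance.

An SRE graph over six 3-mers and a small occurrence profile: the miner
grows connected subgraphs while their vertices still co-occur in at least
alpha exons, and reports each maximal one with its shared exon set.
"""

from sremine import ProfileMatrix, SREGraph, mine_mcs

# AAC -> ACG -> CGT -> GTA is a de Bruijn chain; TTT is isolated from it
graph = SREGraph(
    element_type="enhancer",
    k=3,
    vertex_set=frozenset({"AAC", "ACG", "CGT", "GTA", "TTT"}),
)
exons = [f"x{i}" for i in range(1, 6)]
matrix = ProfileMatrix(
    {
        "AAC": {"x1", "x2", "x3"},
        "ACG": {"x1", "x2", "x3", "x4"},
        "CGT": {"x1", "x2", "x4"},
        "GTA": {"x4", "x5"},
        "TTT": {"x3", "x4", "x5"},
    },
    exons,
)

for alpha in (2, 3):
    print(f"alpha = {alpha}:")
    for m in mine_mcs(graph, matrix, alpha=alpha):
        vertices = ",".join(m.sorted_vertices())
        print(
            f"  MCS {m.id}: {{{vertices}}} shared by {len(m.exon_set)} exons "
            f"({','.join(sorted(m.exon_set))})"
        )
print("higher alpha demands broader co-occurrence, so subgraphs shrink or vanish")
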