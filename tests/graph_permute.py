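"""Test helper: relabel the nodes of a molecular graph by a permutation."""

from molssl.chem_io import MolecularGraph


def permute_graph(g: MolecularGraph, perm: list[int]) -> MolecularGraph:
    inv = {old: new for new, old in enumerate(perm)}
    nodes = [g.nodes[old] for old in perm]
    edges = []
    for u, v, f in g.edges:
        a, b = inv[u], inv[v]
        if a > b:
            a, b = b, a
        edges.append((a, b, f))
    edges.sort(key=lambda e: (e[0], e[1]))
    return MolecularGraph(nodes, edges)
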