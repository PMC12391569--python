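"""Independent test oracles, kept free of the implementation under test."""

import itertools

import networkx as nx
import numpy as np


def max_constant_weight_code(n_bits: int, w_on: int, min_hd: int) -> int:
    """Exhaustive optimum code size via exact maximum clique.

    Vertices are all weight-w words; edges join words whose on-bit overlap
    is at most w_on - min_hd/2 (equivalently Hamming distance >= min_hd).
    """
    words = [frozenset(c) for c in itertools.combinations(range(n_bits), w_on)]
    max_overlap = w_on - min_hd // 2
    g = nx.Graph()
    g.add_nodes_from(range(len(words)))
    g.add_edges_from(
        (i, j) for i, j in itertools.combinations(range(len(words)), 2)
        if len(words[i] & words[j]) <= max_overlap
    )
    _, size = nx.max_weight_clique(g, weight=None)
    return size


def brute_force_near_neighbor(table, reference_gene, radius_um, genes):
    """O(n*m) proximity probabilities by direct distance enumeration."""
    refs = table[table["gene"] == reference_gene]
    out = {}
    for g in genes:
        pts = table[table["gene"] == g]
        hits = 0
        for _, r in refs.iterrows():
            best = np.inf
            for idx, p in pts.iterrows():
                if g == reference_gene and idx == r.name:
                    continue
                d = np.hypot(p["x_um"] - r["x_um"], p["y_um"] - r["y_um"])
                best = min(best, d)
            if best <= radius_um:
                hits += 1
        out[g] = hits / len(refs)
    return out
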