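"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (quadratic scans, plain DP) and
shares no code with the package paths it checks.
"""

from __future__ import annotations

import numpy as np


def gotoh_local_score(a: str, b: str, match=1, mismatch=-2, gap_open=-4,
                      gap_extend=-1) -> float:
    """Affine-gap Smith-Waterman best local score by plain Gotoh DP.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.
    """
    n, m = len(a), len(b)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consuming b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consuming a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def brute_mean_difference(cells: np.ndarray) -> np.ndarray:
    """Pairwise mean character difference by explicit loops (-1 = missing)."""
    n_loci, n_acc = cells.shape
    d = np.zeros((n_acc, n_acc))
    for i in range(n_acc):
        for j in range(n_acc):
            shared = diff = 0
            for l in range(n_loci):
                x, y = cells[l, i], cells[l, j]
                if x < 0 or y < 0:
                    continue
                shared += 1
                diff += x != y
            d[i, j] = diff / shared if shared else np.nan
    return d


def brute_annotate(pos: int, chrom: str, genes, window: int = 500):
    """Gene-proximity category by scanning every gene feature directly."""
    hits = {"CDS": [], "intron": [], "upstream": [], "downstream": []}
    for g in genes:
        if g.chrom != chrom:
            continue
        for s, e in g.cds_intervals:
            if s <= pos < e:
                hits["CDS"].append(g)
        for s, e in g.intron_intervals:
            if s <= pos < e:
                hits["intron"].append(g)
        gs, ge = g.span
        if g.strand == "+":
            up = (gs - window, gs)
            down = (ge, ge + window)
        else:
            up = (ge, ge + window)
            down = (gs - window, gs)
        if up[0] <= pos < up[1]:
            hits["upstream"].append(g)
        if down[0] <= pos < down[1]:
            hits["downstream"].append(g)
    for cat in ("CDS", "intron", "upstream", "downstream"):
        if hits[cat]:
            def dist(g):
                s, e = g.span
                return (0 if s <= pos < e else (s - pos if pos < s else pos - e + 1),
                        g.gene_id)
            return cat, min(hits[cat], key=dist).gene_id
    return "intergenic", None


def random_tree_distances(rng: np.random.Generator, n: int):
    """Random binary tree over n labelled leaves and its additive distances.

    Returns (labels, D, edges) where D are exact leaf-to-leaf path lengths.
    """
    labels = [f"t{i}" for i in range(n)]
    nodes = list(range(n))
    parent = {}
    lengths = {}
    nxt = n
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        for child in (a, b):
            parent[child] = nxt
            lengths[child] = float(rng.integers(1, 20)) / 2.0
        nodes = [x for x in nodes if x not in (a, b)] + [nxt]
        nxt += 1
    root = nodes[0]

    def path_to_root(x):
        out = []
        while x != root:
            out.append(x)
            x = parent[x]
        return out

    D = np.zeros((n, n))
    for i in range(n):
        pi = path_to_root(i)
        anc_i = {x: k for k, x in enumerate(pi + [root])}
        for j in range(i + 1, n):
            d = 0.0
            x = j
            while x not in anc_i:
                d += lengths[x]
                x = parent[x]
            for y in pi:
                if y == x:
                    break
                d += lengths[y]
            D[i, j] = D[j, i] = d
    return labels, D


def wc84_example():
    """Hand-computed W&C84 variance components for one small locus.

    Group 1 diploid dosages (2,2,1,0): n1=4, p1=0.625, h1=0.25;
    group 2 (0,0,1,1): n2=4, p2=0.25, h2=0.5.
    nbar=4, nc=4, pbar=0.4375, s2=0.0703125, hbar=0.375 give
    a=0.03125, b=0.0625, c=0.1875 and FST = a/(a+b+c) = 1/9.
    """
    return {
        "group1": [2, 2, 1, 0],
        "group2": [0, 0, 1, 1],
        "a": 0.03125,
        "b": 0.0625,
        "c": 0.1875,
        "fst": 1.0 / 9.0,
    }
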