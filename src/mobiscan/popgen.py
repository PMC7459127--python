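"""Binary-marker population genetics on the mobilome profile.

The genotype matrix is recoded as binary markers ("1" presence, "0"
absence, "?" missing; heterozygotes count as carriers) and restricted to
loci with intermediate population frequency (0.2 <= freq <= 0.8 by
default), which carry the phylogenetic signal.  On this matrix the module
offers the mean pairwise character difference distance, Saitou-Nei
neighbor joining, PCA on the SNP-style normalized genotype covariance, and
Weir & Cockerham's (1984) variance-component FST, with each mostly
homozygous accession treated as a diploid genotype (P -> 2 presence
alleles, H -> 1, A -> 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .types import FrequencyRecord, MobilomeProfile


@dataclass
class BinaryMatrix:
    """Loci x accessions binary marker matrix.

    ``cells``: 1 presence, 0 absence, -1 missing ("?"); H is encoded as 1.
    ``dosage`` retains the diploid allele count (P=2, H=1, A=0, -1 missing)
    for the FST estimator, which needs observed heterozygosity.
    """

    locus_ids: list[str]
    accessions: list[str]
    cells: np.ndarray
    dosage: np.ndarray


_CELL_CODE = {"P": 1, "H": 1, "A": 0, "M": -1}
_DOSAGE_CODE = {"P": 2, "H": 1, "A": 0, "M": -1}


def select_informative(
    freqs: list[FrequencyRecord],
    profile: MobilomeProfile,
    lo: float = 0.2,
    hi: float = 0.8,
) -> BinaryMatrix:
    """Encode loci with lo <= carrier frequency <= hi as binary markers."""
    by_id = {f.locus_id: f for f in freqs}
    keep = [
        i for i, loc in enumerate(profile.loci)
        if loc.locus_id in by_id and lo <= by_id[loc.locus_id].freq <= hi
    ]
    if not keep:
        raise ValueError("no locus passed the informative-frequency window")
    states = profile.states[keep]
    cells = np.vectorize(_CELL_CODE.get, otypes=[np.int8])(states)
    dosage = np.vectorize(_DOSAGE_CODE.get, otypes=[np.int8])(states)
    bm = BinaryMatrix(
        [profile.loci[i].locus_id for i in keep], list(profile.accessions),
        cells, dosage,
    )
    if (bm.cells == -1).all(axis=1).any() or (bm.cells == -1).all(axis=0).any():
        raise ValueError("all-missing row or column after selection")
    return bm


def mean_difference_distance(matrix: BinaryMatrix) -> DistanceMatrix:
    """Mean pairwise character difference over mutually called loci."""
    cells = matrix.cells
    n = len(matrix.accessions)
    d = np.zeros((n, n))
    called = cells != -1
    for i in range(n):
        for j in range(i + 1, n):
            both = called[:, i] & called[:, j]
            shared = int(both.sum())
            if shared == 0:
                raise ValueError(
                    f"accessions {matrix.accessions[i]!r} and "
                    f"{matrix.accessions[j]!r} share no called locus"
                )
            diff = int((cells[both, i] != cells[both, j]).sum())
            d[i, j] = d[j, i] = diff / shared
    return DistanceMatrix(d, matrix.accessions)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dist: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie handling.

    Ties in the Q criterion are broken by the lexicographically smallest
    label pair (each cluster is labelled by its smallest leaf).  Negative
    branch lengths are clamped to zero with the deficit moved to the
    sister branch, preserving the pair's summed length.
    """
    labels = list(dist.ids)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = np.asarray(dist.data, dtype=float)
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix is not symmetric")
    nodes = {i: TreeNode(name=labels[i]) for i in range(n)}
    tags = {i: labels[i] for i in range(n)}  # smallest leaf label per cluster
    active = list(range(n))
    Dw = {i: {j: D[i, j] for j in active if j != i} for i in active}
    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(Dw[i][j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * Dw[i][j] - r[i] - r[j]
                pair_tag = tuple(sorted((tags[i], tags[j])))
                key = (q, pair_tag)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = Dw[i][j]
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        nodes[i].length, nodes[j].length = li, lj
        new = TreeNode(children=[nodes[i], nodes[j]])
        u = next_id
        next_id += 1
        nodes[u] = new
        tags[u] = min(tags[i], tags[j])
        Dw[u] = {}
        for k in active:
            if k in (i, j):
                continue
            duk = (Dw[i][k] + Dw[j][k] - dij) / 2
            Dw[u][k] = duk
            Dw[k][u] = duk
        active = [k for k in active if k not in (i, j)] + [u]
    i, j, k = active
    # three-point closed form for the last join
    li = (Dw[i][j] + Dw[i][k] - Dw[j][k]) / 2
    lj = (Dw[i][j] + Dw[j][k] - Dw[i][k]) / 2
    lk = (Dw[i][k] + Dw[j][k] - Dw[i][j]) / 2
    for node, ln in ((i, li), (j, lj), (k, lk)):
        nodes[node].length = max(ln, 0.0)
    children = sorted((i, j, k), key=lambda x: tags[x])
    return TreeNode(children=[nodes[c] for c in children])


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    coordinates: np.ndarray  # accessions x components
    percent_variance: np.ndarray
    accessions: list[str]


def pca(matrix: BinaryMatrix, scale: bool = True) -> PCAResult:
    """Eigen-decomposition of the accession genotype covariance matrix.

    Missing cells are imputed with the locus mean; loci are centered and,
    with ``scale=True``, divided by sqrt(p(1-p)) with p the locus mean, the
    normalization conventional for SNP dosage data.  Component signs are
    fixed by making each component's largest-magnitude coordinate positive.
    """
    X = matrix.cells.astype(float).T.copy()  # accessions x loci
    X[X < 0] = np.nan
    locus_mean = np.nanmean(X, axis=0)
    nan_idx = np.where(np.isnan(X))
    X[nan_idx] = locus_mean[nan_idx[1]]
    keep = ~np.isnan(locus_mean)
    if scale:
        keep &= (locus_mean > 0) & (locus_mean < 1)
    X = X[:, keep]
    p = locus_mean[keep]
    X = X - p
    if scale:
        X = X / np.sqrt(p * (1 - p))
    if X.shape[1] == 0 or not np.any(X != 0):
        raise ValueError("zero-variance matrix")
    cov = X @ X.T / X.shape[1]
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    for c in range(eigvec.shape[1]):
        idx = np.argmax(np.abs(eigvec[:, c]))
        if eigvec[idx, c] < 0:
            eigvec[:, c] = -eigvec[:, c]
    coords = eigvec * np.sqrt(np.clip(eigval, 0, None))
    positive = eigval[eigval > 0].sum()
    percent = np.where(eigval > 0, eigval / positive * 100, 0.0)
    return PCAResult(eigval, coords, percent, list(matrix.accessions))


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) FST


@dataclass
class FstResult:
    fst: float
    a: np.ndarray  # among-population variance component per locus
    b: np.ndarray  # among individuals within populations
    c: np.ndarray  # within individuals
    locus_ids: list[str]


def fst_wc84(
    matrix: BinaryMatrix, group_a: list[str], group_b: list[str]
) -> FstResult:
    """Weir & Cockerham variance-component FST between two accession groups.

    Each accession is a diploid genotype at a biallelic locus; loci with
    fewer than two called accessions in either group are skipped.  The
    reported FST is the ratio of sums sum(a) / sum(a+b+c).
    """
    acc_idx = {a: i for i, a in enumerate(matrix.accessions)}
    ia = [acc_idx[a] for a in group_a]
    ib = [acc_idx[a] for a in group_b]
    dosage = matrix.dosage
    a_list, b_list, c_list, ids = [], [], [], []
    for row, locus_id in zip(dosage, matrix.locus_ids):
        ga = row[ia]
        gb = row[ib]
        ga = ga[ga >= 0]
        gb = gb[gb >= 0]
        n1, n2 = len(ga), len(gb)
        if n1 < 2 or n2 < 2:
            continue
        p1, p2 = ga.mean() / 2, gb.mean() / 2
        h1, h2 = (ga == 1).mean(), (gb == 1).mean()
        r = 2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_list.append(a)
        b_list.append(b)
        c_list.append(c)
        ids.append(locus_id)
    a_arr = np.array(a_list)
    b_arr = np.array(b_list)
    c_arr = np.array(c_list)
    denom = (a_arr + b_arr + c_arr).sum()
    if not ids or denom == 0:
        raise ValueError("FST undefined: no polymorphic locus with enough calls")
    return FstResult(float(a_arr.sum() / denom), a_arr, b_arr, c_arr, ids)


def pairwise_fst(matrix: BinaryMatrix, groups: dict[str, str]):
    """FST for every unordered pair of groups, as a tidy DataFrame."""
    import pandas as pd

    labels = sorted(set(groups.values()))
    members = {
        g: [a for a in matrix.accessions if groups.get(a) == g] for g in labels
    }
    rows = []
    for i, g1 in enumerate(labels):
        for g2 in labels[i + 1 :]:
            fst = fst_wc84(matrix, members[g1], members[g2]).fst
            rows.append((g1, g2, fst))
    return pd.DataFrame(rows, columns=["group1", "group2", "fst"])
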