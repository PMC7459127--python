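"""Population-frequency analytics, differential fixation, and locus annotation.

Carrier frequency at a locus is (#P + #H) / (#P + #A + #H): a heterozygote
carries the insertion.  Frequency classes follow the integer-percent bins
low (0-30%], median (30-70%], high (70-<100%) and fixed (exactly 100%).
Gene-proximity annotation assigns each breakpoint a single category with
precedence CDS > intron > upstream > downstream > intergenic, where
up/downstream are the strand-aware 500-bp windows adjacent to a gene.
"""

from __future__ import annotations

import warnings
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .types import (
    AnnotationRecord,
    FrequencyRecord,
    GeneModel,
    GroupFrequency,
    MobilomeProfile,
    SubgenomeBlock,
    TELocus,
)

FREQ_CLASSES = ("low", "median", "high", "fixed")
GENE_CATEGORIES = ("CDS", "intron", "upstream", "downstream", "intergenic")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up, as used in the printed report tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def classify_frequency(freq: float) -> str:
    if freq == 1:
        return "fixed"
    if freq > 0.70:
        return "high"
    if freq > 0.30:
        return "median"
    return "low"


def locus_frequencies(profile: MobilomeProfile) -> list[FrequencyRecord]:
    """Carrier frequency and frequency class for every locus."""
    carrier = ((profile.states == "P") | (profile.states == "H")).sum(axis=1)
    called = (profile.states != "M").sum(axis=1)
    out = []
    for loc, nc, na in zip(profile.loci, carrier, called):
        if na == 0:
            raise ValueError(f"locus {loc.locus_id}: no called accessions")
        freq = nc / na
        out.append(FrequencyRecord(loc.locus_id, int(nc), int(na), freq,
                                   classify_frequency(freq)))
    return out


def group_frequencies(
    profile: MobilomeProfile,
    groups: dict[str, str],
    min_called: int = 1,
) -> list[GroupFrequency]:
    """Per-group carrier frequencies.

    ``groups`` maps every accession to exactly one group.  A locus/group
    with fewer than ``min_called`` called accessions gets ``freq=None``.
    """
    labels = sorted(set(groups.values()))
    cols: dict[str, list[int]] = {g: [] for g in labels}
    for j, acc in enumerate(profile.accessions):
        if acc not in groups:
            raise ValueError(f"accession {acc!r} not assigned to a group")
        cols[groups[acc]].append(j)
    for g, js in cols.items():
        if not js:
            raise ValueError(f"group {g!r} has no accessions")
    out = []
    for i, loc in enumerate(profile.loci):
        row = profile.states[i]
        for g in labels:
            js = cols[g]
            sub = row[js]
            called = int((sub != "M").sum())
            if called < max(min_called, 1):
                out.append(GroupFrequency(loc.locus_id, g, None, called))
                continue
            carrier = int(((sub == "P") | (sub == "H")).sum())
            out.append(GroupFrequency(loc.locus_id, g, carrier / called, called))
    return out


def _freq_table(groupfreqs: list[GroupFrequency]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(g.locus_id, g.group, g.freq) for g in groupfreqs],
        columns=["locus_id", "group", "freq"],
    )
    return df.pivot(index="locus_id", columns="group", values="freq")


def differential_fixed(
    groupfreqs: list[GroupFrequency], hi: float = 0.90, lo: float = 0.10
) -> dict[tuple[str, str], list[str]]:
    """Loci nearly fixed in one group and nearly absent from another.

    Returns, per ordered group pair ``(g1, g2)``, the loci with carrier
    frequency >= ``hi`` in g1 and <= ``lo`` in g2.
    """
    table = _freq_table(groupfreqs)
    out: dict[tuple[str, str], list[str]] = {}
    labels = list(table.columns)
    for g1 in labels:
        for g2 in labels:
            if g1 == g2:
                continue
            mask = (table[g1] >= hi) & (table[g2] <= lo)
            out[(g1, g2)] = sorted(table.index[mask.fillna(False)])
    return out


def heterogeneous_loci(
    groupfreqs: list[GroupFrequency], delta: float = 0.5
) -> list[str]:
    """Loci whose carrier frequency differs by more than ``delta`` between groups."""
    table = _freq_table(groupfreqs)
    spread = table.max(axis=1, skipna=True) - table.min(axis=1, skipna=True)
    return sorted(table.index[spread > delta])


def venn_and_singletons(
    profile: MobilomeProfile, groups: dict[str, str]
) -> dict:
    """Shared/group-specific locus counts and the per-group singleton table.

    A locus is present in a group when it has at least one carrier there;
    a singleton is carried by exactly one accession overall.  The singleton
    average per accession is reported rounded half-up to one decimal.
    """
    labels = sorted(set(groups.values()))
    col_groups = np.array([groups[a] for a in profile.accessions])
    carrier = (profile.states == "P") | (profile.states == "H")
    present = {g: carrier[:, col_groups == g].any(axis=1) for g in labels}
    present_mat = np.column_stack([present[g] for g in labels])
    n_groups_present = present_mat.sum(axis=1)
    shared_by_all = int((n_groups_present == len(labels)).sum())
    group_specific = {
        g: int((present[g] & (n_groups_present == 1)).sum()) for g in labels
    }
    singleton_mask = carrier.sum(axis=1) == 1
    singleton_rows = []
    total_acc = 0
    total_sing = 0
    for g in labels:
        js = col_groups == g
        n_acc = int(js.sum())
        n_sing = int((singleton_mask & carrier[:, js].any(axis=1)).sum())
        singleton_rows.append(
            (g, n_acc, n_sing, round_half_up(n_sing / n_acc, 1))
        )
        total_acc += n_acc
        total_sing += n_sing
    singleton_rows.append(
        ("Total", total_acc, total_sing, round_half_up(total_sing / total_acc, 1))
    )
    singles = pd.DataFrame(
        singleton_rows, columns=["group", "n_accessions", "n_singletons", "average"]
    )
    return {
        "shared_by_all": shared_by_all,
        "group_specific": group_specific,
        "singletons": singles,
    }


# ---------------------------------------------------------------------------
# Gene-proximity annotation


def _gene_feature_trees(gene_models: list[GeneModel], window: int):
    trees: dict[str, dict[str, IntervalTree]] = {}
    for g in gene_models:
        per = trees.setdefault(g.chrom, {c: IntervalTree() for c in GENE_CATEGORIES[:4]})
        for s, e in g.cds_intervals:
            if e > s:
                per["CDS"].addi(s, e, g)
        for s, e in g.intron_intervals:
            if e > s:
                per["intron"].addi(s, e, g)
        gs, ge = g.span
        if g.strand == "+":
            up = (max(0, gs - window), gs)
            down = (ge, ge + window)
        else:
            up = (ge, ge + window)
            down = (max(0, gs - window), gs)
        if up[1] > up[0]:
            per["upstream"].addi(up[0], up[1], g)
        if down[1] > down[0]:
            per["downstream"].addi(down[0], down[1], g)
    return trees


def _gene_distance(pos: int, g: GeneModel) -> int:
    s, e = g.span
    if s <= pos < e:
        return 0
    return s - pos if pos < s else pos - e + 1


def annotate_loci(
    loci: list[TELocus],
    gene_models: list[GeneModel],
    window: int = 500,
    blocks: list[SubgenomeBlock] | None = None,
) -> list[AnnotationRecord]:
    """Assign each breakpoint one gene-proximity category (and subgenome).

    Precedence CDS > intron > upstream > downstream > intergenic; within a
    category, overlapping genes are resolved by distance to the gene span,
    then gene id.
    """
    trees = _gene_feature_trees(gene_models, window)
    block_lookup = _block_trees(blocks) if blocks else {}
    out = []
    for loc in loci:
        per = trees.get(loc.chrom)
        category, gene_id = "intergenic", None
        if per is not None:
            for cat in GENE_CATEGORIES[:4]:
                hits = per[cat][loc.pos]
                if hits:
                    genes = sorted(
                        (h.data for h in hits),
                        key=lambda g: (_gene_distance(loc.pos, g), g.gene_id),
                    )
                    category, gene_id = cat, genes[0].gene_id
                    break
        subgenome = "unassigned"
        tree = block_lookup.get(loc.chrom)
        if tree is not None:
            hits = tree[loc.pos]
            if hits:
                subgenome = next(iter(hits)).data
        out.append(AnnotationRecord(loc.locus_id, category, gene_id, subgenome))
    return out


# ---------------------------------------------------------------------------
# Subgenome statistics


def _block_trees(blocks: list[SubgenomeBlock]) -> dict[str, IntervalTree]:
    per: dict[str, IntervalTree] = {}
    for b in blocks:
        tree = per.setdefault(b.chrom, IntervalTree())
        if tree.overlap(b.start, b.end):
            raise ValueError(
                f"overlapping subgenome blocks on {b.chrom} at [{b.start},{b.end})"
            )
        tree.addi(b.start, b.end, b.label)
    return per


def te_density(count: int, size_mb: float) -> int:
    """Loci per Mb, rounded half-up to an integer for reporting."""
    return int(round_half_up(count / size_mb, 0))


def subgenome_stats(
    loci: list[TELocus], blocks: list[SubgenomeBlock]
) -> pd.DataFrame:
    """Locus count, size and density per subgenome partition.

    Raises on overlapping blocks.  Loci outside every block are reported
    under "unassigned" with no size or density.
    """
    trees = _block_trees(blocks)
    labels = sorted({b.label for b in blocks})
    counts = {g: 0 for g in labels}
    counts["unassigned"] = 0
    for loc in loci:
        tree = trees.get(loc.chrom)
        hits = tree[loc.pos] if tree is not None else ()
        if hits:
            counts[next(iter(hits)).data] += 1
        else:
            counts["unassigned"] += 1
    sizes = {g: 0 for g in labels}
    for b in blocks:
        sizes[b.label] += b.end - b.start
    rows = []
    for g in labels:
        size_mb = sizes[g] / 1e6
        rows.append(
            (g, counts[g], size_mb, te_density(counts[g], size_mb) if size_mb else 0)
        )
    rows.append(("unassigned", counts["unassigned"], float("nan"), 0))
    return pd.DataFrame(rows, columns=["subgenome", "n_loci", "size_mb", "density"])


# ---------------------------------------------------------------------------
# Frequency class x gene category / superfamily tables


def class_by_category_table(
    freqs: list[FrequencyRecord], annotations: list[AnnotationRecord]
) -> dict[str, pd.DataFrame]:
    """Cross-tab of frequency class by gene-proximity category.

    Returns count and row-percentage tables; the "Total" column sums the
    four gene-associated categories, and percentages are relative to all
    loci of the class (intergenic included), rounded half-up to 1 decimal.
    """
    cls = {f.locus_id: f.class_ for f in freqs}
    rows = [(cls[a.locus_id], a.category) for a in annotations if a.locus_id in cls]
    df = pd.DataFrame(rows, columns=["class_", "category"])
    counts = pd.crosstab(df["class_"], df["category"]).reindex(
        index=list(FREQ_CLASSES), columns=list(GENE_CATEGORIES), fill_value=0
    )
    counts.loc["Total"] = counts.sum()
    gene_cols = list(GENE_CATEGORIES[:4])
    counts["Total"] = counts[gene_cols].sum(axis=1)
    counts["class_total"] = counts[gene_cols + ["intergenic"]].sum(axis=1)
    pct = counts[gene_cols + ["Total"]].div(counts["class_total"], axis=0) * 100
    pct = pct.map(lambda v: round_half_up(v, 1) if np.isfinite(v) else v)
    return {"counts": counts, "percent": pct}


def class_by_superfamily_chisq(
    freqs: list[FrequencyRecord], loci: list[TELocus]
) -> tuple[float, int, float]:
    """Pearson chi-square of frequency class composition across superfamilies."""
    sf = {loc.locus_id: loc.superfamily for loc in loci}
    rows = [(sf[f.locus_id], f.class_) for f in freqs if f.locus_id in sf]
    table = pd.crosstab(
        pd.Series([r[0] for r in rows], name="superfamily"),
        pd.Series([r[1] for r in rows], name="class_"),
    ).reindex(columns=list(FREQ_CLASSES), fill_value=0)
    empty_cols = table.columns[table.sum(axis=0) == 0]
    empty_rows = table.index[table.sum(axis=1) == 0]
    if len(empty_cols) or len(empty_rows):
        warnings.warn(
            f"dropping empty rows {list(empty_rows)} / columns {list(empty_cols)}"
        )
        table = table.drop(index=empty_rows, columns=empty_cols)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table needs >=2 superfamilies and >=2 classes")
    chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(chi2), int(dof), float(p)
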