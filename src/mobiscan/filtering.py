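"""Four-rule locus filter cascade and profile quality summaries.

Rules, applied in order with exact accounting:

1. drop loci missing in more than half of the accessions;
2. drop loci with excessive heterozygosity (> 0.41 of non-missing calls);
3. drop loci carried by a single accession whose carrier has fewer than 3
   presence-supporting reads;
4. merge locus pairs predicted independently from the two ends of the same
   insertion.

All thresholds are strict inequalities exactly as stated.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import FilterReport, MobilomeProfile, TELocus


def filter_missing(
    profile: MobilomeProfile, max_missing: float = 0.5
) -> MobilomeProfile:
    """Drop loci with missing calls in more than ``max_missing`` of accessions."""
    m_frac = (profile.states == "M").mean(axis=1)
    return profile.subset_loci(~(m_frac > max_missing))


def filter_heterozygosity(
    profile: MobilomeProfile, max_het: float = 0.41
) -> MobilomeProfile:
    """Drop loci whose heterozygote fraction among non-missing calls exceeds ``max_het``."""
    called = (profile.states != "M").sum(axis=1)
    het = (profile.states == "H").sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(called > 0, het / np.maximum(called, 1), 0.0)
    return profile.subset_loci(~(frac > max_het))


def filter_singleton_support(
    profile: MobilomeProfile, min_reads: int = 3
) -> MobilomeProfile:
    """Drop single-carrier loci whose one carrier has < ``min_reads`` presence reads.

    The rule targets singletons only; loci with two or more carriers are
    never touched regardless of read support.
    """
    carrier = (profile.states == "P") | (profile.states == "H")
    n_carriers = carrier.sum(axis=1)
    drop = np.zeros(profile.n_loci, dtype=bool)
    for i in np.flatnonzero(n_carriers == 1):
        j = int(np.flatnonzero(carrier[i])[0])
        if profile.presence_reads[i, j] < min_reads:
            drop[i] = True
    return profile.subset_loci(~drop)


_JOIN = {
    ("P", "P"): "P", ("A", "A"): "A",
    ("P", "A"): "M", ("A", "P"): "M",
}


def _join_states(a: str, b: str) -> str:
    if a == "H" or b == "H":
        return "H"
    if a == "M":
        return b
    if b == "M":
        return a
    return _JOIN[(a, b)]


def _mergeable(a: TELocus, b: TELocus, pair_window: int) -> bool:
    if a.te_id != b.te_id or a.chrom != b.chrom:
        return False
    if {a.side, b.side} != {"left", "right"}:
        return False
    left, right = (a, b) if a.side == "left" else (b, a)
    if a.ref_status == "Ref" or b.ref_status == "Ref":
        span = left.ref_span or right.ref_span
        if span is None:
            return False
        s, e = span
        # the two junctions flank the reference TE span
        return abs(left.pos - (s - 1)) <= pair_window and abs(
            right.pos - (e - 1)
        ) <= pair_window
    return abs(a.pos - b.pos) <= pair_window


def merge_end_pairs(
    profile: MobilomeProfile, pair_window: int = 25
) -> tuple[MobilomeProfile, int]:
    """Merge loci predicted independently from both ends of one insertion.

    Two loci merge when they share te_id, lie on opposite junction sides
    and — for non-reference insertions — sit within ``pair_window`` bp
    (target-site duplication plus jitter), or — for reference insertions —
    flank one reference TE span.  The merged locus keeps the leftmost
    position, per-accession genotypes are joined ((P,A) conflicts become
    missing), and read counts are summed.  Returns the merged profile and
    the number of pairs merged.
    """
    n = profile.n_loci
    loci = profile.loci
    # candidate pairs within each (chrom, te_id) group
    groups: dict[tuple, list[int]] = {}
    for i, loc in enumerate(loci):
        groups.setdefault((loc.chrom, loc.te_id), []).append(i)
    pairs = []
    for members in groups.values():
        cand = [
            (abs(loci[i].pos - loci[j].pos), i, j)
            for ki, i in enumerate(members)
            for j in members[ki + 1 :]
            if _mergeable(loci[i], loci[j], pair_window)
        ]
        cand.sort()
        used: set[int] = set()
        overflow = False
        for _, i, j in cand:
            if i in used or j in used:
                overflow = True
                continue
            used.update((i, j))
            pairs.append((i, j))
        if overflow:
            warnings.warn(
                "more than two mergeable loci in one group; merged the "
                "closest pair and left the rest"
            )
    merged_away = set()
    for i, j in pairs:
        left, right = (i, j) if loci[i].pos <= loci[j].pos else (j, i)
        keep, drop = left, right
        loc = loci[keep]
        loc.side_support = "pair"
        loc.side = "pair"
        if loc.ref_span is None:
            loc.ref_span = loci[drop].ref_span
        loc.support += loci[drop].support
        for col in range(profile.n_accessions):
            profile.states[keep, col] = _join_states(
                profile.states[keep, col], profile.states[drop, col]
            )
        profile.presence_reads[keep] += profile.presence_reads[drop]
        profile.absence_reads[keep] += profile.absence_reads[drop]
        merged_away.add(drop)
    keep_mask = np.array([i not in merged_away for i in range(n)])
    return profile.subset_loci(keep_mask), len(pairs)


def apply_filters(
    profile: MobilomeProfile,
    max_missing: float = 0.5,
    max_het: float = 0.41,
    min_singleton_reads: int = 3,
    pair_window: int = 25,
) -> tuple[MobilomeProfile, FilterReport]:
    """Run the full cascade in order and return the exact accounting."""
    report = FilterReport(initial_loci=profile.n_loci)
    step = filter_missing(profile, max_missing)
    report.removed_missing = profile.n_loci - step.n_loci
    prev = step
    step = filter_heterozygosity(step, max_het)
    report.removed_het = prev.n_loci - step.n_loci
    prev = step
    step = filter_singleton_support(step, min_singleton_reads)
    report.removed_low_support_singleton = prev.n_loci - step.n_loci
    step, n_merged = merge_end_pairs(step.copy(), pair_window)
    report.merged_pairs = n_merged
    report.final_loci = step.n_loci
    report.check()
    return step, report


def pair_concordance(
    profile: MobilomeProfile, pair_window: int = 25
) -> tuple[float, int]:
    """Genotype concordance of pre-merge locus pairs from the two TE ends.

    Returns (concordant fraction over non-missing call pairs, number of
    pairs considered); the fraction is NaN when no comparable calls exist.
    """
    loci = profile.loci
    groups: dict[tuple, list[int]] = {}
    for i, loc in enumerate(loci):
        groups.setdefault((loc.chrom, loc.te_id), []).append(i)
    agree = total = 0
    n_pairs = 0
    for members in groups.values():
        for ki, i in enumerate(members):
            for j in members[ki + 1 :]:
                if not _mergeable(loci[i], loci[j], pair_window):
                    continue
                n_pairs += 1
                a, b = profile.states[i], profile.states[j]
                mask = (a != "M") & (b != "M")
                total += int(mask.sum())
                agree += int((a[mask] == b[mask]).sum())
    return (agree / total if total else float("nan")), n_pairs


def qc_summaries(profile: MobilomeProfile) -> dict:
    """Detection rate, supporting-read distribution and pair concordance."""
    states = profile.states
    called = states != "M"
    detection_rate = float(called.mean()) if states.size else float("nan")
    support = (profile.presence_reads + profile.absence_reads)[called]
    concordance, n_pairs = pair_concordance(profile)
    return {
        "detection_rate": detection_rate,
        "mean_supporting_reads": float(support.mean()) if support.size else float("nan"),
        "frac_calls_ge3_reads": float((support >= 3).mean()) if support.size else float("nan"),
        "support_histogram": np.bincount(support, minlength=1).tolist() if support.size else [],
        "pair_concordance": concordance,
        "n_end_pairs": n_pairs,
    }
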