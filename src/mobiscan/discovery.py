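"""Stage 1: population-wide discovery of TE insertion loci.

Reads from every accession are screened against the TE end-sequence
library.  A read is a junction read when a sufficiently long, high-identity
match to an end sequence reaches the terminal base of the element and
leaves a single contiguous genomic flank on exactly one side.  Flanks are
placed on the reference by a seed-and-extend search that demands a unique
best location; the resulting per-accession breakpoints are pooled and
clustered into the non-redundant population locus set, and each locus is
classified as present in (Ref) or absent from (nonRef) the reference.

Breakpoint convention: ``pos`` is the 0-based reference base immediately
left of the insertion point.  For a non-reference insertion with a
target-site duplication of t bp, the left-side and right-side junctions of
the same event therefore cluster t bp apart; they are reconciled by the
pair-merging filter.
"""

from __future__ import annotations

from ._seq import KmerIndex, n_matches, revcomp, ungapped_overlap
from .endlib import EndLibrary, local_align
from .types import (
    CandidateBreakpoint,
    JunctionRead,
    TEElement,
    TELocus,
)

#: Terminus of the parent element that can form a junction, per end side.
_END_TERMINI = {"L": ("start",), "R": ("end",), "whole": ("start", "end")}


def as_genome(records) -> dict[str, str]:
    """Chromosome name -> sequence mapping from a list of sequence records."""
    return {r.id: r.sequence for r in records}


# ---------------------------------------------------------------------------
# Junction-read detection


class EndLibraryIndex:
    """Seed index over the representative end sequences."""

    def __init__(self, library: EndLibrary, k: int = 15):
        self.k = k
        self.index = KmerIndex(k)
        self.seqs: dict[str, str] = {}
        self.sides: dict[str, str] = {}
        self.te_ids: dict[str, str] = {}
        self.order: dict[str, int] = {}
        for i, end in enumerate(library):
            eid = end.end_id
            self.index.add(eid, end.sequence)
            self.seqs[eid] = end.sequence
            self.sides[eid] = end.side
            self.te_ids[eid] = end.te_id
            self.order[eid] = i


def _classify_junction(
    oriented: str,
    end_seq: str,
    side: str,
    diag: int,
    min_te_match: int,
    min_flank: int,
    min_ident: float,
):
    """Check the junction pattern of one read-vs-end diagonal.

    Returns ``(matches, te_span, flank_seq, flank_side, terminus)`` or None.
    """
    qs, qe = ungapped_overlap(oriented, end_seq, diag)
    span = qe - qs
    if span < min_te_match:
        return None
    matches = n_matches(oriented[qs:qe], end_seq[qs + diag : qe + diag])
    if matches < min_ident * span:
        return None
    left_un = qs
    right_un = len(oriented) - qe
    for terminus in _END_TERMINI[side]:
        if terminus == "start":
            # flank | TE-start junction: match must include the first base of
            # the end sequence; the flank is the left unaligned part.
            if qs + diag != 0:
                continue
            if left_un >= min_flank and right_un < min_flank:
                return matches, (qs, qe), oriented[:qs], "left", "start"
        else:
            # TE-end | flank junction: match must include the last base.
            if qe + diag != len(end_seq):
                continue
            if right_un >= min_flank and left_un < min_flank:
                return matches, (qs, qe), oriented[qe:], "right", "end"
    return None


def find_junction_reads(
    reads,
    library: EndLibrary | EndLibraryIndex,
    accession: str = "",
    min_te_match: int = 20,
    min_flank: int = 30,
    min_ident: float = 0.95,
) -> list[JunctionRead]:
    """Scan a read stream for TE-junction reads.

    Both read orientations are searched against the forward end library;
    the best-scoring qualifying end wins, with ties broken by library
    order then by forward orientation.
    """
    if isinstance(library, EndLibrary):
        library = EndLibraryIndex(library)
    idx = library
    k = idx.k
    # stride such that any error-free segment of min_te_match bases
    # contains at least one sampled k-mer
    stride = max(1, min_te_match - k + 1)
    out = []
    for read in reads:
        best = None  # (-matches, order, orientation_rank, payload)
        for orientation, oriented in (("+", read.sequence), ("-", revcomp(read.sequence))):
            votes = idx.index.seed_diagonals(oriented, stride)
            for (eid, diag), _ in votes.items():
                res = _classify_junction(
                    oriented, idx.seqs[eid], idx.sides[eid], diag,
                    min_te_match, min_flank, min_ident,
                )
                if res is None:
                    continue
                matches, te_span, flank, flank_side, terminus = res
                key = (-matches, idx.order[eid], 0 if orientation == "+" else 1)
                if best is None or key < best[0]:
                    best = (
                        key,
                        JunctionRead(
                            read.id, accession, eid, te_span, flank,
                            flank_side, terminus, orientation, matches,
                        ),
                    )
        if best is not None:
            out.append(best[1])
    return out


# ---------------------------------------------------------------------------
# Flank placement


class ReferenceIndex:
    """Exact 15-mer index of the reference genome for flank placement."""

    def __init__(self, genome: dict[str, str], k: int = 15):
        self.genome = dict(genome)
        self.k = k
        self.index = KmerIndex(k)
        for chrom, seq in self.genome.items():
            self.index.add(chrom, seq)


def map_flank(
    flank: str,
    reference: ReferenceIndex | dict,
    min_ident: float = 0.95,
    second_best_ratio: float = 0.95,
):
    """Place a flank on the reference, demanding a unique best location.

    Searches both strands with exact k-mer seeding and ungapped extension.
    Returns ``(chrom, start, end, strand)`` when exactly one location
    attains the best score and no other location scores within
    ``second_best_ratio`` of it; otherwise None.
    """
    if isinstance(reference, dict):
        reference = ReferenceIndex(reference)
    idx = reference
    k = idx.k
    if len(flank) < k:
        return None
    hits: dict[tuple[str, int, str], int] = {}
    for strand, query in (("+", flank), ("-", revcomp(flank))):
        votes = idx.index.seed_diagonals(query, stride=max(1, (len(query) - k) // 4 + 1))
        for (chrom, diag), _ in votes.items():
            key = (chrom, diag, strand)
            if key in hits:
                continue
            seq = idx.genome[chrom]
            q = query if strand == "+" else query  # already oriented
            qs, qe = ungapped_overlap(q, seq, diag)
            if qe - qs <= 0:
                continue
            hits[key] = n_matches(q[qs:qe], seq[qs + diag : qe + diag])
    if not hits:
        return None
    ranked = sorted(hits.items(), key=lambda kv: -kv[1])
    (chrom, diag, strand), best_score = ranked[0]
    if best_score < min_ident * len(flank):
        return None
    if len(ranked) > 1 and ranked[1][1] >= second_best_ratio * best_score:
        return None
    query = flank if strand == "+" else revcomp(flank)
    qs, qe = ungapped_overlap(query, idx.genome[chrom], diag)
    return chrom, qs + diag, qe + diag, strand


def breakpoint_from_junction(
    jread: JunctionRead, reference: ReferenceIndex, min_ident: float = 0.95
) -> CandidateBreakpoint | None:
    """Convert a junction read into a reference breakpoint candidate.

    The flank's mapped location and strand, combined with which element
    terminus formed the junction, determine the side of the insertion the
    flank lies on and the orientation of the inserted element.
    """
    loc = map_flank(jread.flank_seq, reference, min_ident)
    if loc is None:
        return None
    chrom, m_start, m_end, strand = loc
    te_id = jread.end_id.rpartition("|")[0]
    if jread.flank_side == "left":  # flank | TE-start on the oriented read
        if strand == "+":
            side, pos, te_strand = "left", m_end - 1, "+"
        else:
            side, pos, te_strand = "right", m_start - 1, "-"
    else:  # TE-end | flank
        if strand == "+":
            side, pos, te_strand = "right", m_start - 1, "+"
        else:
            side, pos, te_strand = "left", m_end - 1, "-"
    return CandidateBreakpoint(
        jread.accession, chrom, pos, te_id, side, te_strand, jread.end_id
    )


# ---------------------------------------------------------------------------
# Clustering and reference-status classification


def cluster_breakpoints(
    candidates: list[CandidateBreakpoint], window: int = 15
) -> list[TELocus]:
    """Single-linkage clustering of pooled breakpoints into population loci.

    Candidates sharing (chrom, te_id, side) are chained while consecutive
    positions differ by at most ``window`` bp; the locus position is the
    median member position (lower of the two middles on even counts).
    """
    groups: dict[tuple, list[CandidateBreakpoint]] = {}
    for c in candidates:
        groups.setdefault((c.chrom, c.te_id, c.side), []).append(c)
    loci = []
    for (chrom, te_id, side), members in sorted(groups.items()):
        members.sort(key=lambda c: c.pos)
        cluster: list[CandidateBreakpoint] = []
        for c in members + [None]:
            if cluster and (c is None or c.pos - cluster[-1].pos > window):
                positions = [m.pos for m in cluster]
                pos = positions[(len(positions) - 1) // 2]
                plus = sum(1 for m in cluster if m.te_strand == "+")
                strand = "+" if plus * 2 >= len(cluster) else "-"
                loci.append(
                    TELocus(
                        locus_id="",
                        chrom=chrom,
                        pos=pos,
                        te_id=te_id,
                        side=side,
                        te_strand=strand,
                        side_support="single",
                        support=len(cluster),
                    )
                )
                cluster = []
            if c is not None:
                cluster.append(c)
    loci.sort(key=lambda l: (l.chrom, l.pos, l.te_id, l.side))
    for i, loc in enumerate(loci, 1):
        loc.locus_id = f"L{i:06d}"
    return loci


def classify_ref_status(
    locus: TELocus,
    reference: dict[str, str],
    te: TEElement,
    min_len: int = 50,
    min_ident: float = 0.90,
    end_len: int = 150,
) -> tuple[str, tuple[int, int] | None]:
    """Decide whether the element is present in the reference at this locus.

    The reference sequence adjacent to the breakpoint (on the side opposite
    the mapped flank) is compared with the correspondingly oriented element
    terminus; a match at >= ``min_ident`` over >= ``min_len`` bases means
    Ref.  For Ref loci the full element alignment delimits the reference TE
    span (bounded by twice the element length); an exact occurrence is
    tried first since it is by far the common case.
    """
    seq = reference[locus.chrom]
    te_seq = te.sequence if locus.te_strand == "+" else revcomp(te.sequence)
    L = len(te_seq)
    window = 2 * L + 20
    p = locus.pos
    if locus.side == "left":
        w = seq[p + 1 : p + 1 + window]
        if w.startswith(te_seq):
            return "Ref", (p + 1, p + 1 + L)
        terminus = te_seq[:end_len]
        probe = w[: end_len + 50]
        if not probe:
            return "nonRef", None
        aln = local_align(terminus, probe)
        if aln.aligned_len >= min_len and aln.identity >= min_ident and aln.b_span[0] <= 5:
            full = local_align(te_seq, w)
            if full.aligned_len >= min_ident * L:
                return "Ref", (p + 1 + full.b_span[0], p + 1 + full.b_span[1])
            return "Ref", None
        return "nonRef", None
    else:
        start = max(0, p + 1 - window)
        w = seq[start : p + 1]
        if w.endswith(te_seq):
            return "Ref", (p + 1 - L, p + 1)
        terminus = te_seq[-end_len:]
        probe = w[-(end_len + 50):]
        if not probe:
            return "nonRef", None
        aln = local_align(terminus, probe)
        if (
            aln.aligned_len >= min_len
            and aln.identity >= min_ident
            and len(probe) - aln.b_span[1] <= 5
        ):
            full = local_align(te_seq, w)
            if full.aligned_len >= min_ident * L:
                return "Ref", (start + full.b_span[0], start + full.b_span[1])
            return "Ref", None
        return "nonRef", None


# ---------------------------------------------------------------------------
# Stage-1 driver


def discover_loci(
    read_sets: dict[str, list],
    library: EndLibrary,
    reference: dict[str, str],
    elements: list[TEElement],
    min_te_match: int = 20,
    min_flank: int = 30,
    min_ident: float = 0.95,
    window: int = 15,
    ref_min_len: int = 50,
    ref_min_ident: float = 0.90,
) -> list[TELocus]:
    """Full discovery stage: junction reads -> breakpoints -> loci.

    ``read_sets`` maps accession name to its reads.  The returned loci are
    annotated with family/superfamily from the element set and classified
    Ref/nonRef.
    """
    lib_index = EndLibraryIndex(library)
    ref_index = ReferenceIndex(reference)
    candidates = []
    for accession in sorted(read_sets):
        jreads = find_junction_reads(
            read_sets[accession], lib_index, accession,
            min_te_match, min_flank, min_ident,
        )
        for jr in jreads:
            cand = breakpoint_from_junction(jr, ref_index, min_ident)
            if cand is not None:
                candidates.append(cand)
    loci = cluster_breakpoints(candidates, window)
    by_id = {e.te_id: e for e in elements}
    for loc in loci:
        el = by_id.get(loc.te_id)
        if el is not None:
            loc.family = el.family
            loc.superfamily = el.superfamily
            status, span = classify_ref_status(
                loc, reference, el, ref_min_len, ref_min_ident
            )
            loc.ref_status = status
            loc.ref_span = span
    return loci
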