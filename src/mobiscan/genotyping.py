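"""Stage 2: per-accession presence/absence calling at discovered loci.

For every locus a pair of allele templates is built: the *presence*
template reproduces the junction sequence (genomic flank joined to the
element terminus), the *absence* template the contiguous sequence across
the empty site.  For non-reference loci the reference itself provides the
absence allele; for reference loci the absence template is the excision
joint, with the duplicated target site removed once so it matches a true
pre-insertion haplotype.  A read supports an allele when it aligns to that
allele's template across the junction point with at least ``min_overlap``
matched bases on both sides; calling is purely count based:
(0,0) -> M, (p,0) -> P, (0,a) -> A, (p,a) -> H.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import KmerIndex, n_matches, revcomp, ungapped_overlap
from .types import MobilomeProfile, TEElement, TELocus


@dataclass
class AlleleTemplates:
    """Junction templates for the two alleles of one locus.

    Each entry is ``(sequence, junction_offset)`` where the junction lies
    between template positions ``offset - 1`` and ``offset``.
    """

    locus_id: str
    presence: list[tuple[str, int]] = field(default_factory=list)
    absence: tuple[str, int] | None = None


def _oriented_te(te: TEElement, strand: str) -> str:
    return te.sequence if strand == "+" else revcomp(te.sequence)


def _tsd_length(ref: str, s: int, e: int, max_tsd: int = 12) -> int:
    """Length of the duplicated target site flanking a reference TE span."""
    for t in range(min(max_tsd, s, len(ref) - e), 0, -1):
        if ref[s - t : s] == ref[e : e + t]:
            return t
    return 0


def build_templates(
    loci: list[TELocus],
    reference: dict[str, str],
    te_elements: list[TEElement],
    flank_len: int = 150,
    min_overlap: int = 20,
) -> list[AlleleTemplates]:
    """Build presence/absence templates for every locus.

    Raises ``ValueError`` when a locus sits so close to a contig edge that
    a truncated template cannot span the junction by ``min_overlap`` on
    both sides.
    """
    by_id = {e.te_id: e for e in te_elements}
    out = []
    for loc in loci:
        ref = reference[loc.chrom]
        te = by_id[loc.te_id]
        oriented = _oriented_te(te, loc.te_strand)
        p = loc.pos
        tmpl = AlleleTemplates(loc.locus_id)
        insertion_point = p + 1  # junction position in reference coordinates

        def ref_window(center: int) -> tuple[str, int]:
            start = max(0, center - flank_len)
            end = min(len(ref), center + flank_len)
            return ref[start:end], center - start

        if loc.ref_status == "Ref":
            # the reference carries the element: the junction window read
            # straight off the reference is the presence template
            tmpl.presence.append(ref_window(insertion_point))
            if loc.ref_span is not None:
                s, e = loc.ref_span
                t = _tsd_length(ref, s, e)
                left = ref[max(0, s - flank_len) : s]
                right = ref[e + t : e + t + flank_len]
                tmpl.absence = (left + right, len(left))
        else:
            if loc.side == "left":
                flank = ref[max(0, insertion_point - flank_len) : insertion_point]
                tmpl.presence.append(
                    (flank + oriented[:flank_len], len(flank))
                )
            else:
                flank = ref[insertion_point : insertion_point + flank_len]
                seg = oriented[-flank_len:]
                tmpl.presence.append((seg + flank, len(seg)))
            tmpl.absence = ref_window(insertion_point)

        for seq, off in tmpl.presence + ([tmpl.absence] if tmpl.absence else []):
            if off < min_overlap or len(seq) - off < min_overlap:
                raise ValueError(
                    f"locus {loc.locus_id}: template truncated at a contig "
                    f"edge below 2 x min_overlap"
                )
        out.append(tmpl)
    return out


class TemplateIndex:
    """Seed index over all allele templates of a locus set."""

    def __init__(self, templates: list[AlleleTemplates], k: int = 15):
        self.k = k
        self.index = KmerIndex(k)
        self.seqs: dict[str, str] = {}
        self.offsets: dict[str, int] = {}
        self.alleles: dict[str, tuple[str, str]] = {}  # name -> (locus_id, allele)
        for t in templates:
            for i, (seq, off) in enumerate(t.presence):
                self._add(f"{t.locus_id}::P{i}", seq, off, (t.locus_id, "P"))
            if t.absence is not None:
                self._add(f"{t.locus_id}::A", t.absence[0], t.absence[1],
                          (t.locus_id, "A"))

    def _add(self, name, seq, off, allele):
        self.index.add(name, seq)
        self.seqs[name] = seq
        self.offsets[name] = off
        self.alleles[name] = allele


def _supported_alleles(
    seq: str,
    index: TemplateIndex,
    min_overlap: int,
    min_ident: float,
    stride: int,
) -> set[tuple[str, str]]:
    """All (locus_id, allele) pairs a read supports, both orientations."""
    supported: set[tuple[str, str]] = set()
    for oriented in (seq, revcomp(seq)):
        votes = index.index.seed_diagonals(oriented, stride)
        for (name, diag), _ in votes.items():
            if index.alleles[name] in supported:
                continue
            tmpl = index.seqs[name]
            j = index.offsets[name]
            qs, qe = ungapped_overlap(oriented, tmpl, diag)
            rj = j - diag  # junction position in read coordinates
            if qs + min_overlap > rj or rj + min_overlap > qe:
                continue
            span = qe - qs
            left = n_matches(oriented[qs:rj], tmpl[qs + diag : j])
            right = n_matches(oriented[rj:qe], tmpl[j : qe + diag])
            if left < min_overlap or right < min_overlap:
                continue
            if left + right < min_ident * span:
                continue
            supported.add(index.alleles[name])
    return supported


def collect_evidence(
    reads,
    templates: AlleleTemplates,
    min_overlap: int = 20,
    min_ident: float = 0.95,
) -> tuple[int, int]:
    """Count junction-crossing reads supporting each allele of one locus.

    Reads supporting both alleles are discarded as uninformative.
    """
    index = TemplateIndex([templates])
    stride = max(1, 2 * min_overlap - index.k + 1)
    presence = absence = 0
    for read in reads:
        sup = _supported_alleles(read.sequence, index, min_overlap, min_ident, stride)
        has_p = (templates.locus_id, "P") in sup
        has_a = (templates.locus_id, "A") in sup
        if has_p and has_a:
            continue
        presence += has_p
        absence += has_a
    return presence, absence


def call_genotype(presence_reads: int, absence_reads: int) -> str:
    """Count-based call: M no evidence, P/A one allele, H both alleles."""
    if presence_reads < 0 or absence_reads < 0:
        raise ValueError("negative read counts")
    if presence_reads and absence_reads:
        return "H"
    if presence_reads:
        return "P"
    if absence_reads:
        return "A"
    return "M"


def genotype_population(
    loci: list[TELocus],
    read_sets: dict[str, list],
    reference: dict[str, str],
    te_elements: list[TEElement],
    morphotypes: dict[str, str] | None = None,
    flank_len: int = 150,
    min_overlap: int = 20,
    min_ident: float = 0.95,
) -> MobilomeProfile:
    """Genotype every accession at every locus.

    Accessions listed without reads receive an all-M column (a warning is
    emitted).  Supporting-read counts are retained per call.
    """
    import warnings

    templates = build_templates(loci, reference, te_elements, flank_len, min_overlap)
    index = TemplateIndex(templates)
    stride = max(1, 2 * min_overlap - index.k + 1)
    accessions = list(read_sets)
    morphotypes = morphotypes or {a: "unknown" for a in accessions}
    locus_pos = {loc.locus_id: i for i, loc in enumerate(loci)}
    shape = (len(loci), len(accessions))
    presence = np.zeros(shape, dtype=np.int64)
    absence = np.zeros(shape, dtype=np.int64)
    for j, acc in enumerate(accessions):
        reads = read_sets[acc]
        if not reads:
            warnings.warn(f"accession {acc!r} has no reads; calling all-missing")
            continue
        for read in reads:
            sup = _supported_alleles(
                read.sequence, index, min_overlap, min_ident, stride
            )
            by_locus: dict[str, set[str]] = {}
            for locus_id, allele in sup:
                by_locus.setdefault(locus_id, set()).add(allele)
            for locus_id, alleles in by_locus.items():
                if len(alleles) == 2:
                    continue  # ambiguous read
                i = locus_pos[locus_id]
                if "P" in alleles:
                    presence[i, j] += 1
                else:
                    absence[i, j] += 1
    states = np.empty(shape, dtype="<U1")
    for i in range(shape[0]):
        for j in range(shape[1]):
            states[i, j] = call_genotype(presence[i, j], absence[i, j])
    return MobilomeProfile(loci, accessions, morphotypes, states, presence, absence)
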