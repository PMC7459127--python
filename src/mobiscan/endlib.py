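"""TE end-sequence library construction.

Junction-read search only ever sees the terminal segments of TE elements,
so the library holds the first and last ``end_len`` bases of every element
(or the whole element when it is shorter).  Near-identical ends — abundant
within TE families — are collapsed: a candidate end is redundant when it
aligns to an already-kept representative at >= 90% identity over >= 75
aligned bases, the criterion applied on exact local alignments rather than
through a BLAST e-value heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align

from ._seq import revcomp
from .types import LocalAlignment, SequenceRecord, TEEnd, TEElement
from . import io as mio

#: BLASTN-like local alignment scoring used throughout the package.
DEFAULT_SCORING = {"match": 1, "mismatch": -2, "gap_open": -4, "gap_extend": -1}


def extract_ends(elements: list[TEElement], end_len: int = 150) -> list[TEEnd]:
    """Extract terminal segments from each element.

    Elements longer than ``end_len`` yield an L (prefix) and an R (suffix)
    end, which overlap when the element is shorter than ``2 * end_len``;
    shorter elements (e.g. MITEs) yield a single ``side="whole"`` end.
    """
    if not elements:
        raise ValueError("no TE elements supplied")
    ends = []
    for el in elements:
        if len(el.sequence) <= end_len:
            ends.append(TEEnd(el.te_id, "whole", el.sequence))
        else:
            ends.append(TEEnd(el.te_id, "L", el.sequence[:end_len]))
            ends.append(TEEnd(el.te_id, "R", el.sequence[-end_len:]))
    return ends


def _aligner(scoring: dict) -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="local",
        match_score=scoring["match"],
        mismatch_score=scoring["mismatch"],
        open_gap_score=scoring["gap_open"],
        extend_gap_score=scoring["gap_extend"],
    )


def local_align(a: str, b: str, scoring: dict | None = None) -> LocalAlignment:
    """Optimal Smith-Waterman local alignment of two sequences.

    A gap of length L scores ``gap_open + (L - 1) * gap_extend``.  Identity
    is matches over aligned columns (gap columns included).  When no
    positive-scoring alignment exists the empty alignment is returned.
    """
    if not a or not b:
        raise ValueError("local_align requires non-empty sequences")
    scoring = scoring or DEFAULT_SCORING
    result = _aligner(scoring).align(a, b)
    if len(result) == 0 or result.score <= 0:
        return LocalAlignment(0.0, 0, 0.0, (0, 0), (0, 0))
    aln = result[0]  # deterministic first alignment as the tie-break
    counts = aln.counts()
    ncols = aln.length
    blocks_a, blocks_b = aln.aligned
    a_span = (int(blocks_a[0][0]), int(blocks_a[-1][1]))
    b_span = (int(blocks_b[0][0]), int(blocks_b[-1][1]))
    identity = counts.identities / ncols if ncols else 0.0
    return LocalAlignment(float(aln.score), int(ncols), identity, a_span, b_span)


def is_redundant(
    a: str,
    b: str,
    min_len: int = 75,
    min_ident: float = 0.90,
    both_strands: bool = True,
    scoring: dict | None = None,
) -> bool:
    """Whether two sequences align at >= min_ident over >= min_len columns."""
    for query in (a, revcomp(a)) if both_strands else (a,):
        aln = local_align(query, b, scoring)
        if aln.aligned_len >= min_len and aln.identity >= min_ident:
            return True
    return False


def collapse_redundancy(
    ends: list[TEEnd],
    min_len: int = 75,
    min_ident: float = 0.90,
    both_strands: bool = True,
    scoring: dict | None = None,
) -> list[TEEnd]:
    """Greedy redundancy collapse of an end library.

    Candidates are visited sorted by (length desc, te_id asc, side asc) and
    kept unless they are redundant with an already-kept representative.
    Dropped ends are annotated in place with their representative's id, so
    the result is independent of the input order.
    """
    order = sorted(ends, key=lambda e: (-len(e.sequence), e.te_id, e.side))
    reps: list[TEEnd] = []
    for cand in order:
        rep_hit = None
        for rep in reps:
            if is_redundant(
                cand.sequence, rep.sequence, min_len, min_ident, both_strands, scoring
            ):
                rep_hit = rep
                break
        if rep_hit is None:
            cand.representative = True
            cand.representative_id = None
            reps.append(cand)
        else:
            cand.representative = False
            cand.representative_id = rep_hit.end_id
    return reps


def write_end_library(ends: list[TEEnd], fasta_path, mapping_path=None) -> None:
    """Write representative ends as FASTA plus a dropped->representative TSV."""
    reps = [e for e in ends if e.representative]
    mio.write_fasta(
        [SequenceRecord(e.end_id, e.sequence) for e in reps], fasta_path
    )
    if mapping_path is not None:
        dropped = [
            (e.end_id, e.representative_id) for e in ends if not e.representative
        ]
        pd.DataFrame(dropped, columns=["dropped", "representative"]).to_csv(
            mapping_path, sep="\t", index=False
        )


@dataclass
class EndLibrary:
    """Representative end sequences plus the te_id/side they came from."""

    ends: list[TEEnd]

    @classmethod
    def from_fasta(cls, path) -> "EndLibrary":
        ends = []
        for rec in mio.read_sequences(path, "fasta"):
            te_id, _, side = rec.id.rpartition("|")
            if side not in ("L", "R", "whole") or not te_id:
                raise ValueError(f"malformed end id {rec.id!r}")
            ends.append(TEEnd(te_id, side, rec.sequence))
        return cls(ends)

    def __iter__(self):
        return iter(self.ends)

    def __len__(self):
        return len(self.ends)
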