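"""Core domain types of the mobilome pipeline.

Coordinate convention: every position stored on these objects is 0-based,
half-open.  Conversion to the 1-based inclusive convention used by GFF3 and
the emitted tables happens exactly once, at I/O (see :mod:`mobiscan.io`).

Breakpoint positions (`TELocus.pos`, `CandidateBreakpoint.pos`) denote the
reference base immediately to the *left* of the insertion point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Genotype symbols: present, absent, heterozygous, missing.
GENOTYPE_SYMBOLS = ("P", "A", "H", "M")

TE_CLASSES = ("DNA", "Retro")
TE_ORDERS = ("TIR", "Helitron", "LTR", "SINE", "LINE")

#: Valid (class, order) combinations of the TE taxonomy.
CLASS_ORDERS = {
    "DNA": ("TIR", "Helitron"),
    "Retro": ("LTR", "SINE", "LINE"),
}


@dataclass
class SequenceRecord:
    id: str
    sequence: str


@dataclass
class ReadRecord:
    id: str
    sequence: str
    qualities: str
    mate: str = "unpaired"  # {"1", "2", "unpaired"}

    def __post_init__(self):
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qualities)} != "
                f"sequence length {len(self.sequence)}"
            )


@dataclass
class GeneModel:
    """A gene with exon/CDS structure; introns are the gaps between exons."""

    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    exon_intervals: list[tuple[int, int]] = field(default_factory=list)
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)
    intron_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id!r}: unknown strand {self.strand!r}")


@dataclass
class SubgenomeBlock:
    chrom: str
    start: int
    end: int
    label: str  # LF / MF1 / MF2


@dataclass
class TEElement:
    te_id: str
    class_: str
    order: str
    superfamily: str
    family: str
    sequence: str

    def __post_init__(self):
        if self.class_ not in CLASS_ORDERS:
            raise ValueError(f"{self.te_id}: unknown TE class {self.class_!r}")
        if self.order not in CLASS_ORDERS[self.class_]:
            raise ValueError(
                f"{self.te_id}: order {self.order!r} invalid for class {self.class_!r}"
            )
        if len(self.sequence) < 50:
            raise ValueError(f"{self.te_id}: element shorter than 50 bp")


@dataclass
class TEEnd:
    """A terminal segment of a TE element used for junction-read search."""

    te_id: str
    side: str  # "L", "R", or "whole" for short elements
    sequence: str
    representative: bool = True
    representative_id: str | None = None

    @property
    def end_id(self) -> str:
        return f"{self.te_id}|{self.side}"


@dataclass
class LocalAlignment:
    score: float
    aligned_len: int
    identity: float
    a_span: tuple[int, int]
    b_span: tuple[int, int]
    strand: str = "+"


@dataclass
class JunctionRead:
    """A read spanning a TE terminus / genomic flank boundary.

    Coordinates refer to the *oriented* read (reverse-complemented when
    ``orientation`` is "-") so that the TE segment matches the library end
    sequence in forward orientation.
    """

    read_id: str
    accession: str
    end_id: str
    te_span: tuple[int, int]
    flank_seq: str
    flank_side: str  # "left" or "right" of the TE segment on the oriented read
    te_terminus: str  # "start" or "end" of the parent element at the junction
    orientation: str  # "+" read used as-is, "-" reverse-complemented
    matches: int = 0


@dataclass
class CandidateBreakpoint:
    accession: str
    chrom: str
    pos: int
    te_id: str
    side: str  # "left"/"right": which side of the insertion the flank maps to
    te_strand: str
    end_id: str


@dataclass
class TELocus:
    locus_id: str
    chrom: str
    pos: int
    te_id: str
    family: str = ""
    superfamily: str = ""
    side: str = "left"  # "left", "right", or "pair" after end merging
    te_strand: str = "+"
    side_support: str = "single"  # "single" or "pair"
    ref_status: str = "unknown"  # "Ref", "nonRef", "unknown"
    ref_span: tuple[int, int] | None = None
    support: int = 1


@dataclass
class GenotypeCall:
    locus_id: str
    accession: str
    state: str
    presence_reads: int = 0
    absence_reads: int = 0


class MobilomeProfile:
    """Loci x accessions genotype matrix with per-call supporting-read counts.

    ``states`` holds one of {P, A, H, M} per cell; ``presence_reads`` and
    ``absence_reads`` the number of breakpoint-spanning reads supporting each
    allele of the call.
    """

    def __init__(
        self,
        loci: list[TELocus],
        accessions: list[str],
        morphotypes: dict[str, str],
        states: np.ndarray | None = None,
        presence_reads: np.ndarray | None = None,
        absence_reads: np.ndarray | None = None,
    ):
        self.loci = list(loci)
        self.accessions = list(accessions)
        self.morphotypes = dict(morphotypes)
        shape = (len(self.loci), len(self.accessions))
        self.states = (
            np.full(shape, "M", dtype="<U1") if states is None else np.asarray(states)
        )
        self.presence_reads = (
            np.zeros(shape, dtype=np.int64)
            if presence_reads is None
            else np.asarray(presence_reads)
        )
        self.absence_reads = (
            np.zeros(shape, dtype=np.int64)
            if absence_reads is None
            else np.asarray(absence_reads)
        )
        for arr in (self.states, self.presence_reads, self.absence_reads):
            if arr.shape != shape:
                raise ValueError(
                    f"matrix shape {arr.shape} inconsistent with "
                    f"{len(self.loci)} loci x {len(self.accessions)} accessions"
                )
        bad = set(np.unique(self.states)) - set(GENOTYPE_SYMBOLS)
        if bad:
            raise ValueError(f"unknown genotype symbols {sorted(bad)!r}")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def locus_index(self) -> dict[str, int]:
        return {loc.locus_id: i for i, loc in enumerate(self.loci)}

    def subset_loci(self, keep: np.ndarray) -> "MobilomeProfile":
        """New profile restricted to loci where ``keep`` is True (or indexed)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return MobilomeProfile(
            [self.loci[i] for i in idx],
            self.accessions,
            self.morphotypes,
            self.states[idx],
            self.presence_reads[idx],
            self.absence_reads[idx],
        )

    def copy(self) -> "MobilomeProfile":
        import copy as _copy

        return MobilomeProfile(
            [_copy.copy(l) for l in self.loci],
            self.accessions,
            self.morphotypes,
            self.states.copy(),
            self.presence_reads.copy(),
            self.absence_reads.copy(),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, MobilomeProfile):
            return NotImplemented
        return (
            self.accessions == other.accessions
            and self.morphotypes == other.morphotypes
            and [l.__dict__ for l in self.loci] == [l.__dict__ for l in other.loci]
            and np.array_equal(self.states, other.states)
            and np.array_equal(self.presence_reads, other.presence_reads)
            and np.array_equal(self.absence_reads, other.absence_reads)
        )


@dataclass
class FilterReport:
    """Exact accounting of the four-rule locus filter cascade."""

    initial_loci: int
    removed_missing: int = 0
    removed_het: int = 0
    removed_low_support_singleton: int = 0
    merged_pairs: int = 0
    final_loci: int = 0

    def check(self) -> None:
        expected = (
            self.initial_loci
            - self.removed_missing
            - self.removed_het
            - self.removed_low_support_singleton
            - self.merged_pairs
        )
        if expected != self.final_loci:
            raise ValueError(
                f"filter accounting violated: {self.initial_loci} - "
                f"{self.removed_missing} - {self.removed_het} - "
                f"{self.removed_low_support_singleton} - {self.merged_pairs} "
                f"= {expected} != {self.final_loci}"
            )

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class FrequencyRecord:
    locus_id: str
    n_carrier: int
    n_called: int
    freq: float
    class_: str  # low / median / high / fixed


@dataclass
class GroupFrequency:
    locus_id: str
    group: str
    freq: float | None  # None when no accession of the group was called
    n_called: int


@dataclass
class AnnotationRecord:
    locus_id: str
    category: str  # CDS / intron / upstream / downstream / intergenic
    gene_id: str | None = None
    subgenome: str = "unassigned"
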