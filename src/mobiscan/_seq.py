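"""Low-level DNA string utilities shared across the pipeline.

Sequences are plain uppercase Python strings over {A, C, G, T, N}.  N is a
valid character but never counts as a match in any comparison, so reads or
flanks falling in N-rich sequence simply fail identity thresholds.
"""

from __future__ import annotations

import numpy as np

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, *, context: str = "sequence") -> str:
    """Uppercase ``seq`` and reject characters outside {A,C,G,T,N}."""
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{context}: empty sequence")
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"{context}: invalid characters {sorted(bad)!r}")
    return seq


def n_matches(a: str, b: str) -> int:
    """Number of identical positions between two equal-length strings.

    N never matches anything, including another N.  The all-equal fast path
    matters: on error-free data most compared slices are byte-identical and
    the C-level string comparison avoids the per-character loop.
    """
    if len(a) != len(b):
        raise ValueError("n_matches requires equal-length strings")
    if a == b:
        return len(a) - a.count("N")
    return sum(x == y for x, y in zip(a, b) if x != "N")


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform i.i.d. ACGT string of the given length."""
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


class KmerIndex:
    """Exact k-mer lookup table over a set of named sequences.

    Maps every k-mer to the list of ``(name, offset)`` positions at which it
    occurs.  K-mers containing N are not indexed.
    """

    def __init__(self, k: int = 15):
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = {}
        self.lengths: dict[str, int] = {}

    def add(self, name: str, seq: str) -> None:
        k = self.k
        if name in self.lengths:
            raise ValueError(f"duplicate sequence name {name!r}")
        self.lengths[name] = len(seq)
        idx = self._index
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            idx.setdefault(kmer, []).append((name, i))

    def get(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, ())

    def __contains__(self, kmer: str) -> bool:
        return kmer in self._index

    def seed_diagonals(self, query: str, stride: int = 1) -> dict[tuple[str, int], int]:
        """Vote for (target, diagonal) pairs using sampled query k-mers.

        The diagonal is ``target_offset - query_offset``; co-diagonal seed
        hits indicate a candidate ungapped alignment.  Returns a vote count
        per (target name, diagonal).
        """
        k = self.k
        votes: dict[tuple[str, int], int] = {}
        n = len(query) - k + 1
        if n <= 0:
            return votes
        positions = range(0, n, stride)
        for qpos in positions:
            for name, tpos in self.get(query[qpos : qpos + k]):
                key = (name, tpos - qpos)
                votes[key] = votes.get(key, 0) + 1
        return votes


def ungapped_overlap(query: str, target: str, diag: int) -> tuple[int, int]:
    """Query-coordinate interval [qs, qe) where query overlaps target on a diagonal.

    ``diag`` is the target offset minus the query offset.
    """
    qs = max(0, -diag)
    qe = min(len(query), len(target) - diag)
    return qs, qe
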