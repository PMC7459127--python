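"""Synthetic mobilome cohorts with full ground truth.

The generator emulates the structure of a resequenced crop population:
a random backbone genome; a curated TE library spanning DNA and
retrotransposon superfamilies; insertions flanked by target-site
duplications, present in or absent from the emitted reference; a
morphotype-structured population whose per-group carrier frequencies span
the low/median/high/fixed spectrum plus planted differential-fixed loci;
and uniform-coverage single-end reads with a configurable substitution
error rate.  Everything is deterministic under the master seed, with one
RNG stream per stage.

Carrier counts are realized exactly (``round(freq * n_group)`` carriers
drawn without replacement) rather than by Bernoulli sampling, so planted
frequency classes and differential-fixed contrasts survive small group
sizes; heterozygous carriers are then drawn at ``het_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import random_dna, revcomp
from .types import ReadRecord, SequenceRecord, TEElement
from . import io as mio


@dataclass
class TEFamilySpec:
    class_: str
    order: str
    superfamily: str
    family: str
    length: int
    n_elements: int = 1
    tsd_len: int = 5
    #: substitution fraction of each copy relative to the family consensus
    #: (pairwise divergence between copies is about twice this); deep enough
    #: by default that ends of different copies never collapse as redundant
    divergence: float = 0.15


@dataclass
class LocusSpec:
    """A batch of loci sharing target frequencies and reference status.

    ``freqs`` is either one carrier frequency for all groups or a mapping
    group -> frequency.
    """

    n_loci: int
    freqs: float | dict[str, float]
    ref_status: str = "nonRef"


def _default_families() -> list[TEFamilySpec]:
    return [
        TEFamilySpec("DNA", "TIR", "Pong", "Pong-1", 400, 2, 3),
        TEFamilySpec("DNA", "TIR", "CACTA", "CACTA-1", 600, 2, 3),
        TEFamilySpec("DNA", "TIR", "Tc1/Mariner", "Stowaway-1", 120, 1, 2),
        TEFamilySpec("DNA", "Helitron", "Helitron", "Helitron-1", 500, 2, 0),
        TEFamilySpec("Retro", "LTR", "Copia", "Copia-1", 900, 2, 5),
        TEFamilySpec("Retro", "LTR", "Gypsy", "Gypsy-1", 800, 1, 5),
        TEFamilySpec("Retro", "SINE", "tRNA", "SINE-1", 200, 1, 8),
        TEFamilySpec("Retro", "LINE", "L1", "L1-1", 700, 1, 8),
    ]


def _default_locus_spec() -> list[LocusSpec]:
    # frequency spectrum spanning the four classes, plus differential-fixed
    # contrasts between the four large morphotypes
    mid = {"cabbage": 0.5, "kohlrabi": 0.5, "cauliflower": 0.5, "broccoli": 0.5}
    diff = []
    for g1, g2 in (
        ("cabbage", "broccoli"),
        ("cabbage", "cauliflower"),
        ("broccoli", "kohlrabi"),
        ("cauliflower", "kohlrabi"),
    ):
        f = dict(mid)
        f[g1], f[g2] = 0.95, 0.05
        diff.append(LocusSpec(3, f, "nonRef"))
    return [
        LocusSpec(6, 1.0, "Ref"),
        LocusSpec(4, 1.0, "nonRef"),
        LocusSpec(4, 0.85, "Ref"),
        LocusSpec(6, 0.85, "nonRef"),
        LocusSpec(12, 0.5, "nonRef"),
        LocusSpec(16, 0.2, "nonRef"),
        *diff,
    ]


@dataclass
class SimConfig:
    seed: int = 0
    genome_length: int = 100_000
    n_chromosomes: int = 2
    te_families: list[TEFamilySpec] = field(default_factory=_default_families)
    accessions_per_morphotype: dict[str, int] = field(
        default_factory=lambda: {
            "cabbage": 6, "kohlrabi": 5, "cauliflower": 5, "broccoli": 4,
        }
    )
    locus_spec: list[LocusSpec] = field(default_factory=_default_locus_spec)
    coverage: float = 10.0
    read_length: int = 100
    error_rate: float = 0.01
    het_rate: float = 0.05
    dropout: float = 0.0  # per accession x locus junction-coverage dropout
    duplicate_segment: bool = False  # plant a duplicated region ("hard mode")
    flank_k: int = 15

    def validate(self) -> None:
        if not self.te_families:
            raise ValueError("te_families must not be empty")
        if self.genome_length <= 0 or self.n_chromosomes <= 0:
            raise ValueError("genome dimensions must be positive")
        if not (0 <= self.error_rate < 1 and 0 <= self.het_rate <= 1
                and 0 <= self.dropout <= 1):
            raise ValueError("rates must lie in [0, 1]")
        for spec in self.locus_spec:
            freqs = (
                spec.freqs.values() if isinstance(spec.freqs, dict) else [spec.freqs]
            )
            if spec.n_loci < 0 or any(not 0 <= f <= 1 for f in freqs):
                raise ValueError("locus_spec frequencies must lie in [0, 1]")
            if spec.ref_status not in ("Ref", "nonRef"):
                raise ValueError(f"bad ref_status {spec.ref_status!r}")

    @property
    def n_loci(self) -> int:
        return sum(s.n_loci for s in self.locus_spec)

    @property
    def accessions(self) -> list[str]:
        return [
            f"{g}_{i + 1:02d}"
            for g in self.accessions_per_morphotype
            for i in range(self.accessions_per_morphotype[g])
        ]

    @property
    def morphotypes(self) -> dict[str, str]:
        return {
            a: a.rsplit("_", 1)[0] for a in self.accessions
        }


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("genome", "library", "population", "reads")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class TruthLocus:
    locus_key: str
    chrom: str
    site: int  # insertion point in backbone coordinates
    pos_left: int  # left-junction breakpoint, emitted-reference coordinates
    pos_right: int  # right-junction breakpoint
    te_id: str
    te_strand: str
    tsd_len: int
    ref_status: str
    ref_span: tuple[int, int] | None = None


@dataclass
class SimTruth:
    loci: list[TruthLocus]
    genotypes: pd.DataFrame  # loci x accessions, cells in {P, A, H}
    group_freqs: pd.DataFrame  # loci x groups, realized carrier frequencies


# ---------------------------------------------------------------------------
# Backbone and TE library


def build_genome(config: SimConfig, rng=None):
    """Random backbone plus insertion sites with unique flank k-mers.

    Returns ``(backbone, sites)`` where sites are (chrom, position) pairs
    whose surrounding windows contain no k-mer repeated anywhere in the
    backbone, guaranteeing unique flank mapping.
    """
    config.validate()
    rng = rng or _streams(config.seed)["genome"]
    per = config.genome_length // config.n_chromosomes
    backbone = {
        f"chr{i + 1}": random_dna(rng, per) for i in range(config.n_chromosomes)
    }
    if config.duplicate_segment and config.n_chromosomes >= 2 and per > 3000:
        seg = backbone["chr1"][1000:2000]
        s2 = backbone["chr2"]
        backbone["chr2"] = s2[:per - 1000] + seg[: 1000]
    k = config.flank_k
    counts: dict[str, int] = {}
    for seq in backbone.values():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            counts[kmer] = counts.get(kmer, 0) + 1

    read_len = config.read_length
    margin = read_len + 300
    spacing = 2 * read_len + 250
    window = read_len + 50
    chroms = sorted(backbone)
    sites: list[tuple[str, int]] = []
    occupied: dict[str, list[int]] = {c: [] for c in chroms}

    def window_unique(chrom: str, pos: int) -> bool:
        seq = backbone[chrom]
        lo, hi = max(0, pos - window), min(len(seq) - k + 1, pos + window)
        return all(counts[seq[i : i + k]] == 1 for i in range(lo, hi))

    for _ in range(config.n_loci):
        for _attempt in range(2000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(margin, len(backbone[chrom]) - margin))
            if any(abs(pos - q) < spacing for q in occupied[chrom]):
                continue
            if not window_unique(chrom, pos):
                continue
            occupied[chrom].append(pos)
            sites.append((chrom, pos))
            break
        else:
            raise RuntimeError(
                "could not place all insertion sites with unique flanks; "
                "increase genome_length or reduce n_loci"
            )
    return backbone, sites


def _mutate(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


def build_te_library(config: SimConfig, rng=None) -> list[TEElement]:
    """Per-family consensus sequences with diverged within-family copies."""
    config.validate()
    rng = rng or _streams(config.seed)["library"]
    elements = []
    for spec in config.te_families:
        consensus = random_dna(rng, spec.length)
        for i in range(spec.n_elements):
            seq = _mutate(rng, consensus, spec.divergence)
            elements.append(
                TEElement(
                    f"{spec.family}#{i + 1}", spec.class_, spec.order,
                    spec.superfamily, spec.family, seq,
                )
            )
    return elements


# ---------------------------------------------------------------------------
# Population planting


def _tsd_by_te(config: SimConfig) -> dict[str, int]:
    out = {}
    for spec in config.te_families:
        for i in range(spec.n_elements):
            out[f"{spec.family}#{i + 1}"] = spec.tsd_len
    return out


def plant_population(config: SimConfig, backbone, sites, telib, rng=None):
    """Plant insertions; build reference, accession haplotypes and truth.

    Returns ``(reference, haplotypes, truth)`` where ``reference`` is the
    emitted assembly (backbone plus Ref-status insertions), ``haplotypes``
    maps accession -> (hap1, hap2) genome dicts, and ``truth`` records
    planted loci, true genotypes and realized group frequencies.
    """
    config.validate()
    rng = rng or _streams(config.seed)["population"]
    accessions = config.accessions
    groups = config.morphotypes
    group_members = {
        g: [a for a in accessions if groups[a] == g]
        for g in config.accessions_per_morphotype
    }
    tsd_of = _tsd_by_te(config)

    # per-locus plan: element, strand, frequencies, ref status
    plans = []
    i_site = 0
    for spec in config.locus_spec:
        for _ in range(spec.n_loci):
            chrom, site = sites[i_site]
            i_site += 1
            el = telib[int(rng.integers(len(telib)))]
            strand = "+" if rng.random() < 0.5 else "-"
            freqs = (
                dict(spec.freqs)
                if isinstance(spec.freqs, dict)
                else {g: spec.freqs for g in group_members}
            )
            plans.append((chrom, site, el, strand, freqs, spec.ref_status))

    # genotypes: exact carrier counts per group, then heterozygote draws
    geno = {}
    for idx, (chrom, site, el, strand, freqs, status) in enumerate(plans):
        key = f"T{idx + 1:04d}"
        row = {}
        for g, members in group_members.items():
            f = freqs.get(g, 0.0)
            n_carriers = int(round(f * len(members)))
            carriers = set(
                rng.choice(members, size=n_carriers, replace=False).tolist()
            )
            for a in members:
                if a in carriers:
                    row[a] = "H" if rng.random() < config.het_rate else "P"
                else:
                    row[a] = "A"
        geno[key] = row

    # emitted reference: backbone plus Ref insertions, with coordinate shifts
    by_chrom: dict[str, list[int]] = {}
    for idx, (chrom, site, el, strand, freqs, status) in enumerate(plans):
        by_chrom.setdefault(chrom, []).append(idx)
    reference = {}
    shifts: dict[int, int] = {}  # plan index -> reference-coordinate site
    for chrom, seq in backbone.items():
        idxs = sorted(by_chrom.get(chrom, []), key=lambda i: plans[i][1])
        out = []
        prev = 0
        offset = 0
        for i in idxs:
            _, site, el, strand, _, status = plans[i]
            shifts[i] = site + offset
            if status == "Ref":
                t = tsd_of[el.te_id]
                te_seq = el.sequence if strand == "+" else revcomp(el.sequence)
                out.append(seq[prev : site + t])
                out.append(te_seq)
                prev = site
                offset += len(te_seq) + t
        out.append(seq[prev:])
        reference[chrom] = "".join(out)

    truth_loci = []
    for idx, (chrom, site, el, strand, freqs, status) in enumerate(plans):
        t = tsd_of[el.te_id]
        x = shifts[idx]
        key = f"T{idx + 1:04d}"
        if status == "Ref":
            span = (x + t, x + t + len(el.sequence))
            # the duplicated target site belongs to the flanks, so the right
            # junction sits at the span end itself
            pos_left, pos_right = span[0] - 1, span[1] - 1
        else:
            span = None
            pos_left, pos_right = x + t - 1, x - 1
        truth_loci.append(
            TruthLocus(key, chrom, site, pos_left, pos_right, el.te_id,
                       strand, t, status, span)
        )

    # accession haplotypes from the backbone
    haplotypes = {}
    for acc in accessions:
        hap_carries = ([], [])
        for idx, (chrom, site, el, strand, freqs, status) in enumerate(plans):
            state = geno[f"T{idx + 1:04d}"][acc]
            if state == "P":
                hap_carries[0].append(idx)
                hap_carries[1].append(idx)
            elif state == "H":
                hap_carries[int(rng.integers(2))].append(idx)
        haps = []
        for carried in hap_carries:
            genome = {}
            for chrom, seq in backbone.items():
                idxs = sorted(
                    (i for i in carried if plans[i][0] == chrom),
                    key=lambda i: plans[i][1],
                )
                out = []
                prev = 0
                for i in idxs:
                    _, site, el, strand, _, _ = plans[i]
                    t = tsd_of[el.te_id]
                    te_seq = el.sequence if strand == "+" else revcomp(el.sequence)
                    out.append(seq[prev : site + t])
                    out.append(te_seq)
                    prev = site
                out.append(seq[prev:])
                genome[chrom] = "".join(out)
            haps.append(genome)
        haplotypes[acc] = tuple(haps)

    geno_df = pd.DataFrame(geno).T.reindex(columns=accessions)
    geno_df.index.name = "locus_key"
    gf = {}
    for key, row in geno_df.iterrows():
        gf[key] = {
            g: np.mean([row[a] in "PH" for a in members])
            for g, members in group_members.items()
        }
    group_df = pd.DataFrame(gf).T.reindex(index=geno_df.index)
    group_df.index.name = "locus_key"
    truth = SimTruth(truth_loci, geno_df, group_df)
    return reference, haplotypes, truth


# ---------------------------------------------------------------------------
# Reads


def simulate_reads(config: SimConfig, haplotypes, rng=None, truth=None,
                   backbone=None):
    """Uniform single-end reads from every accession haplotype.

    Expected depth equals ``coverage`` (half per haplotype); substitution
    errors at ``error_rate``; strands random.  With ``dropout`` > 0 (needs
    ``truth`` and ``backbone``), junction-covering reads of randomly chosen
    accession x locus pairs are suppressed, emulating locus-level missing
    calls.
    """
    config.validate()
    rng = rng or _streams(config.seed)["reads"]
    read_len = config.read_length
    reads = {}
    for acc in sorted(haplotypes):
        acc_reads = []
        dropped_sites = set()
        if config.dropout > 0 and truth is not None and backbone is not None:
            for tl in truth.loci:
                if rng.random() < config.dropout:
                    dropped_sites.add((tl.chrom, tl.site))
        for h, genome in enumerate(haplotypes[acc]):
            for chrom in sorted(genome):
                seq = genome[chrom]
                if read_len > len(seq):
                    raise ValueError("read_length exceeds genome length")
                n_reads = int(round(config.coverage / 2 * len(seq) / read_len))
                starts = rng.integers(0, len(seq) - read_len + 1, size=n_reads)
                strands = rng.random(n_reads) < 0.5
                if config.error_rate > 0:
                    n_err = rng.binomial(read_len, config.error_rate, size=n_reads)
                else:
                    n_err = np.zeros(n_reads, dtype=int)
                for i, (start, minus) in enumerate(zip(starts, strands)):
                    frag = seq[start : start + read_len]
                    if n_err[i]:
                        frag = _mutate_exact(rng, frag, int(n_err[i]))
                    if minus:
                        frag = revcomp(frag)
                    acc_reads.append(
                        ReadRecord(
                            f"{acc}:{h}:{chrom}:{i}", frag, "I" * read_len
                        )
                    )
        if dropped_sites:
            acc_reads = _apply_dropout(acc_reads, backbone, dropped_sites)
        reads[acc] = acc_reads
    return reads


def _mutate_exact(rng, seq: str, n_err: int) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in rng.choice(len(arr), size=min(n_err, len(arr)), replace=False):
        choices = bases[bases != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


def _apply_dropout(acc_reads, backbone, dropped_sites, halfwidth=40):
    # every junction-supporting read (presence or absence allele) carries
    # >= 20 bp of the flank adjacent to the site, whose 15-mers are unique
    # by construction; dropping reads containing any 15-mer from the window
    # around the backbone site removes all evidence for the locus
    k = 15
    probes = set()
    for chrom, site in dropped_sites:
        seq = backbone[chrom]
        lo, hi = max(0, site - halfwidth), min(len(seq) - k + 1, site + halfwidth)
        for i in range(lo, hi):
            probes.add(seq[i : i + k])
            probes.add(revcomp(seq[i : i + k]))
    if not probes:
        return acc_reads
    out = []
    for r in acc_reads:
        seq = r.sequence
        if any(seq[i : i + k] in probes for i in range(0, len(seq) - k + 1, 5)):
            continue
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# Companion annotation tracks


def random_gene_models(reference: dict[str, str], n_genes: int, rng=None,
                       seed: int = 0):
    """Random non-overlapping two-exon gene models over a genome.

    Genes are 1-3 kb with two exons (CDS covering the exons) separated by
    an intron, alternating strands; used to exercise gene-proximity
    annotation against a genome of any provenance.
    """
    from .types import GeneModel

    rng = rng or np.random.default_rng(seed)
    models = []
    i = 0
    chroms = sorted(reference)
    attempts = 0
    occupied = {c: [] for c in chroms}
    while len(models) < n_genes and attempts < 50 * n_genes:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        size = int(rng.integers(1000, 3000))
        limit = len(reference[chrom]) - size - 1
        if limit <= 0:
            continue
        s = int(rng.integers(0, limit))
        e = s + size
        if any(not (e + 1000 <= os or s >= oe + 1000) for os, oe in occupied[chrom]):
            continue
        occupied[chrom].append((s, e))
        exon1 = (s, s + size // 3)
        exon2 = (e - size // 3, e)
        i += 1
        models.append(
            GeneModel(f"gene{i:04d}", chrom, "+" if i % 2 else "-", (s, e),
                      [exon1, exon2], [exon1, exon2],
                      [(exon1[1], exon2[0])])
        )
    models.sort(key=lambda m: (m.chrom, m.span))
    return models


def subgenome_partition(reference: dict[str, str]):
    """Split every chromosome into three equal LF/MF1/MF2 blocks."""
    from .types import SubgenomeBlock

    blocks = []
    for chrom in sorted(reference):
        n = len(reference[chrom])
        third = n // 3
        blocks.append(SubgenomeBlock(chrom, 0, third, "LF"))
        blocks.append(SubgenomeBlock(chrom, third, 2 * third, "MF1"))
        blocks.append(SubgenomeBlock(chrom, 2 * third, n, "MF2"))
    return blocks


# ---------------------------------------------------------------------------
# Truth I/O and the one-call driver


def write_truth(truth: SimTruth, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for tl in truth.loci:
        s = "" if tl.ref_span is None else tl.ref_span[0] + 1
        e = "" if tl.ref_span is None else tl.ref_span[1]
        rows.append(
            (tl.locus_key, tl.chrom, tl.site + 1, tl.pos_left + 1,
             tl.pos_right + 1, tl.te_id, tl.te_strand, tl.tsd_len,
             tl.ref_status, s, e)
        )
    pd.DataFrame(
        rows,
        columns=["locus_key", "chrom", "site", "pos_left", "pos_right",
                 "te_id", "te_strand", "tsd_len", "ref_status",
                 "ref_start", "ref_end"],
    ).to_csv(outdir / "truth_loci.tsv", sep="\t", index=False)
    truth.genotypes.to_csv(outdir / "truth_genotypes.tsv", sep="\t")
    truth.group_freqs.to_csv(outdir / "truth_group_freqs.tsv", sep="\t")


def read_truth(indir) -> SimTruth:
    indir = Path(indir)
    df = pd.read_csv(
        indir / "truth_loci.tsv", sep="\t", dtype={"chrom": str},
        keep_default_na=False,
    )
    loci = []
    for r in df.itertuples():
        span = None
        if str(r.ref_start) != "":
            span = (int(r.ref_start) - 1, int(r.ref_end))
        loci.append(
            TruthLocus(r.locus_key, r.chrom, int(r.site) - 1,
                       int(r.pos_left) - 1, int(r.pos_right) - 1, r.te_id,
                       r.te_strand, int(r.tsd_len), r.ref_status, span)
        )
    geno = pd.read_csv(indir / "truth_genotypes.tsv", sep="\t", index_col=0)
    gf = pd.read_csv(indir / "truth_group_freqs.tsv", sep="\t", index_col=0)
    return SimTruth(loci, geno, gf)


@dataclass
class SimResult:
    config: SimConfig
    backbone: dict[str, str]
    reference: dict[str, str]
    telib: list[TEElement]
    haplotypes: dict[str, tuple]
    reads: dict[str, list[ReadRecord]]
    truth: SimTruth


def simulate_cohort(config: SimConfig) -> SimResult:
    """Run all generator stages under per-stage RNG streams."""
    streams = _streams(config.seed)
    backbone, sites = build_genome(config, streams["genome"])
    telib = build_te_library(config, streams["library"])
    reference, haplotypes, truth = plant_population(
        config, backbone, sites, telib, streams["population"]
    )
    reads = simulate_reads(config, haplotypes, streams["reads"], truth, backbone)
    return SimResult(config, backbone, reference, telib, haplotypes, reads, truth)


def write_simulation(result: SimResult, outdir) -> None:
    """Emit reference, TE set, per-accession FASTQ, manifest and truth."""
    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    mio.write_fasta(
        [SequenceRecord(c, s) for c, s in sorted(result.reference.items())],
        outdir / "reference.fasta",
    )
    mio.write_te_elements(result.telib, outdir / "te.fasta", outdir / "te.tsv")
    manifest = []
    morphotypes = result.config.morphotypes
    for acc, reads in result.reads.items():
        path = outdir / "reads" / f"{acc}.fastq"
        mio.write_fastq(reads, path)
        manifest.append((acc, morphotypes[acc], [f"reads/{acc}.fastq"]))
    mio.write_manifest(manifest, outdir / "manifest.tsv")
    mio.write_morphotypes(morphotypes, outdir / "morphotypes.tsv")
    write_truth(result.truth, outdir / "truth")
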