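"""Readers and writers for every format the pipeline touches.

All positions are converted between the internal 0-based half-open
convention and the 1-based inclusive convention of GFF3 and the emitted
tables here, and only here.  FASTQ qualities are carried through unchanged
but play no role in calling, which is purely read-count based.
"""

from __future__ import annotations

import io as _stdio
import os
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from skbio import TreeNode

from ._seq import validate_dna
from .types import (
    GENOTYPE_SYMBOLS,
    GeneModel,
    MobilomeProfile,
    ReadRecord,
    SequenceRecord,
    SubgenomeBlock,
    TEElement,
    TELocus,
)

# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_sequences(path, format: str = "fasta"):
    """Read a FASTA or FASTQ file.

    Returns ``SequenceRecord`` objects for FASTA and ``ReadRecord`` objects
    (with qualities and mate flag parsed from ``/1``-``/2`` id suffixes) for
    FASTQ.  Order is preserved; wrapped FASTA lines are concatenated;
    lowercase is uppercased.  Malformed records raise a ``ValueError``
    naming the record index.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown sequence format {format!r}")
    out = []
    seen = set()
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), format)):
            if not rec.id:
                raise ValueError(f"record {i}: empty identifier")
            if rec.id in seen:
                raise ValueError(f"record {i}: duplicate identifier {rec.id!r}")
            seen.add(rec.id)
            seq = validate_dna(str(rec.seq), context=f"record {i} ({rec.id})")
            if format == "fasta":
                out.append(SequenceRecord(rec.id, seq))
            else:
                quals = rec.letter_annotations.get("phred_quality")
                if quals is None or len(quals) != len(seq):
                    raise ValueError(f"record {i}: sequence/quality length mismatch")
                qual_str = "".join(chr(q + 33) for q in quals)
                mate = "unpaired"
                rid = rec.id
                if rid.endswith("/1"):
                    mate, rid = "1", rid[:-2]
                elif rid.endswith("/2"):
                    mate, rid = "2", rid[:-2]
                out.append(ReadRecord(rec.id, seq, qual_str, mate))
    except ValueError:
        raise
    except Exception as exc:  # Biopython parse failures
        raise ValueError(f"malformed {format} record {len(out)}: {exc}") from exc
    return out


def write_fasta(records, path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.qualities}\n")


# ---------------------------------------------------------------------------
# Gene models (GFF3)


def read_gene_models(path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features from a GFF3 file into gene models.

    Exons from all transcripts of a gene are merged; introns are the gaps
    between merged exons inside the gene span.  Coordinates are converted to
    0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene", order_by="start"):
        if gene.strand not in "+-":
            raise ValueError(f"gene {gene.id!r}: unknown strand {gene.strand!r}")
        span = (gene.start - 1, gene.end)
        exons = _merged_child_intervals(db, gene, "exon")
        cds = _merged_child_intervals(db, gene, "CDS")
        for kind, ivs in (("exon", exons), ("CDS", cds)):
            for s, e in ivs:
                if s < span[0] or e > span[1]:
                    raise ValueError(
                        f"gene {gene.id!r}: {kind} [{s},{e}) outside gene span {span}"
                    )
        introns = _gaps(exons)
        models.append(
            GeneModel(gene.id, gene.seqid, gene.strand, span, exons, cds, introns)
        )
    return models


def _merged_child_intervals(db, gene, featuretype) -> list[tuple[int, int]]:
    ivs = sorted(
        (f.start - 1, f.end) for f in db.children(gene, featuretype=featuretype)
    )
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _gaps(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    return [
        (intervals[i][1], intervals[i + 1][0])
        for i in range(len(intervals) - 1)
        if intervals[i + 1][0] > intervals[i][1]
    ]


def write_gene_models(models: list[GeneModel], path) -> None:
    """Emit gene models as GFF3 (gene/mRNA/exon/CDS, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            s, e = m.span
            fh.write(
                f"{m.chrom}\tmobiscan\tgene\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            mrna = f"{m.gene_id}.1"
            fh.write(
                f"{m.chrom}\tmobiscan\tmRNA\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={mrna};Parent={m.gene_id}\n"
            )
            for i, (xs, xe) in enumerate(m.exon_intervals, 1):
                fh.write(
                    f"{m.chrom}\tmobiscan\texon\t{xs + 1}\t{xe}\t.\t{m.strand}\t.\t"
                    f"ID={mrna}.exon{i};Parent={mrna}\n"
                )
            for i, (cs, ce) in enumerate(m.cds_intervals, 1):
                fh.write(
                    f"{m.chrom}\tmobiscan\tCDS\t{cs + 1}\t{ce}\t.\t{m.strand}\t0\t"
                    f"ID={mrna}.cds{i};Parent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# Subgenome blocks, morphotypes, TE annotation, read manifests


def read_subgenome_blocks(path) -> list[SubgenomeBlock]:
    """BED-like 4-column TSV: chrom, start (1-based), end (inclusive), label."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    required = ["chrom", "start", "end", "label"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"subgenome table must have columns {required}")
    return [
        SubgenomeBlock(str(r.chrom), int(r.start) - 1, int(r.end), str(r.label))
        for r in df.itertuples()
    ]


def write_subgenome_blocks(blocks: list[SubgenomeBlock], path) -> None:
    pd.DataFrame(
        [(b.chrom, b.start + 1, b.end, b.label) for b in blocks],
        columns=["chrom", "start", "end", "label"],
    ).to_csv(path, sep="\t", index=False)


def read_morphotypes(path) -> dict[str, str]:
    """Accession -> morphotype mapping from a 2-column TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_morphotypes(morphotypes: dict[str, str], path) -> None:
    pd.DataFrame(
        sorted(morphotypes.items()), columns=["accession", "morphotype"]
    ).to_csv(path, sep="\t", index=False)


def read_te_elements(fasta_path, annotation_path) -> list[TEElement]:
    """Curated TE set: FASTA plus a taxonomy TSV keyed by te_id."""
    seqs = {r.id: r.sequence for r in read_sequences(fasta_path, "fasta")}
    df = pd.read_csv(annotation_path, sep="\t", dtype=str)
    elements = []
    for r in df.itertuples():
        if r.te_id not in seqs:
            raise ValueError(f"TE {r.te_id!r} missing from FASTA")
        elements.append(
            TEElement(r.te_id, getattr(r, "class_", None) or getattr(r, "class"),
                      r.order, r.superfamily, r.family, seqs[r.te_id])
        )
    return elements


def write_te_elements(elements: list[TEElement], fasta_path, annotation_path) -> None:
    write_fasta(
        [SequenceRecord(e.te_id, e.sequence) for e in elements], fasta_path
    )
    pd.DataFrame(
        [(e.te_id, e.class_, e.order, e.superfamily, e.family) for e in elements],
        columns=["te_id", "class_", "order", "superfamily", "family"],
    ).to_csv(annotation_path, sep="\t", index=False)


def read_manifest(path) -> list[tuple[str, str, list[str]]]:
    """Read manifest TSV: accession, morphotype, comma-separated FASTQ paths."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    base = Path(path).parent
    out = []
    for r in df.itertuples():
        paths = [
            p if os.path.isabs(p) else str(base / p)
            for p in str(r.fastq).split(",")
        ]
        out.append((str(r.accession), str(r.morphotype), paths))
    return out


def write_manifest(rows: list[tuple[str, str, list[str]]], path) -> None:
    pd.DataFrame(
        [(a, m, ",".join(p)) for a, m, p in rows],
        columns=["accession", "morphotype", "fastq"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Mobilome profile tables

_LOCUS_COLUMNS = [
    "locus_id", "chrom", "pos", "te_id", "family", "superfamily", "side",
    "te_strand", "side_support", "ref_status", "ref_start", "ref_end", "support",
]


def write_profile(profile: MobilomeProfile, outdir) -> None:
    """Write a profile as a directory of TSV tables.

    ``loci.tsv`` (1-based positions), ``accessions.tsv``, ``genotypes.tsv``
    with cells in {P,A,H,M}, and parallel ``presence_reads.tsv`` /
    ``absence_reads.tsv`` supporting-read-count matrices.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for loc in profile.loci:
        ref_start = "" if loc.ref_span is None else loc.ref_span[0] + 1
        ref_end = "" if loc.ref_span is None else loc.ref_span[1]
        rows.append(
            (loc.locus_id, loc.chrom, loc.pos + 1, loc.te_id, loc.family,
             loc.superfamily, loc.side, loc.te_strand, loc.side_support,
             loc.ref_status, ref_start, ref_end, loc.support)
        )
    pd.DataFrame(rows, columns=_LOCUS_COLUMNS).to_csv(
        outdir / "loci.tsv", sep="\t", index=False
    )
    write_morphotypes(
        {a: profile.morphotypes.get(a, "unknown") for a in profile.accessions},
        outdir / "accessions.tsv",
    )
    ids = [loc.locus_id for loc in profile.loci]
    for name, mat in (
        ("genotypes", profile.states),
        ("presence_reads", profile.presence_reads),
        ("absence_reads", profile.absence_reads),
    ):
        df = pd.DataFrame(mat, columns=profile.accessions)
        df.insert(0, "locus_id", ids)
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)


def read_profile(indir) -> MobilomeProfile:
    indir = Path(indir)
    loci_df = pd.read_csv(
        indir / "loci.tsv", sep="\t", dtype={"chrom": str}, keep_default_na=False
    )
    loci = []
    for r in loci_df.itertuples():
        ref_span = None
        if str(r.ref_start) != "":
            ref_span = (int(r.ref_start) - 1, int(r.ref_end))
        loci.append(
            TELocus(str(r.locus_id), str(r.chrom), int(r.pos) - 1, str(r.te_id),
                    str(r.family), str(r.superfamily), str(r.side),
                    str(r.te_strand), str(r.side_support), str(r.ref_status),
                    ref_span, int(r.support))
        )
    acc_df = pd.read_csv(indir / "accessions.tsv", sep="\t", dtype=str)
    accessions = list(acc_df["accession"])
    morphotypes = dict(zip(acc_df["accession"], acc_df["morphotype"]))

    def load_matrix(name, dtype):
        df = pd.read_csv(indir / f"{name}.tsv", sep="\t", dtype=str)
        if list(df["locus_id"]) != [l.locus_id for l in loci]:
            raise ValueError(f"{name}.tsv locus order differs from loci.tsv")
        return df[accessions].to_numpy(dtype=dtype)

    states = load_matrix("genotypes", "<U1")
    bad = set(np.unique(states)) - set(GENOTYPE_SYMBOLS) if states.size else set()
    if bad:
        raise ValueError(f"unknown genotype symbols {sorted(bad)!r} in genotypes.tsv")
    presence = load_matrix("presence_reads", np.int64)
    absence = load_matrix("absence_reads", np.int64)
    return MobilomeProfile(loci, accessions, morphotypes, states, presence, absence)


# ---------------------------------------------------------------------------
# Trees


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to a newick string (branch lengths at full precision)."""
    labels = [t.name for t in tree.tips()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate leaf labels {sorted(dupes)!r}")
    buf = _stdio.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def write_newick_file(tree: TreeNode, path) -> None:
    Path(path).write_text(write_newick(tree) + "\n")


def read_newick(source) -> TreeNode:
    if isinstance(source, (str, Path)) and os.path.exists(str(source)):
        return TreeNode.read(str(source), format="newick")
    return TreeNode.read(_stdio.StringIO(str(source)), format="newick")
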