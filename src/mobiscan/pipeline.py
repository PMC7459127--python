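"""End-to-end orchestration of all pipeline stages under one config.

The run is fully determined by the configuration (including the seed):
the simulator derives one RNG stream per stage from the master seed, and
all floating-point table output is rounded to six significant digits at
I/O, so identical configs produce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import yaml

from . import discovery, endlib, filtering, genotyping, popfreq, popgen
from . import io as mio
from . import simulate
from .popgen import mean_difference_distance, nj_tree, pairwise_fst, pca, select_informative

log = logging.getLogger("mobiscan")

_FLOAT_FMT = "%.6g"

_STAGE_DEFAULTS = {
    "endlib": {"end_len": 150, "min_len": 75, "min_ident": 0.90,
               "both_strands": True},
    "discovery": {"min_te_match": 20, "min_flank": 30, "min_ident": 0.95,
                  "window": 15, "ref_min_len": 50, "ref_min_ident": 0.90},
    "genotyping": {"flank_len": 150, "min_overlap": 20, "min_ident": 0.95},
    "filter": {"max_missing": 0.5, "max_het": 0.41, "min_singleton_reads": 3,
               "pair_window": 25},
    "popfreq": {"hi": 0.90, "lo": 0.10, "delta": 0.5, "gene_window": 500},
    "popgen": {"lo": 0.2, "hi": 0.8, "scale": True},
}

_TOP_KEYS = {"seed", "log_level", "simulate", "inputs"} | set(_STAGE_DEFAULTS)


class RunConfig:
    """Validated stage-by-stage configuration.

    Unknown keys anywhere are rejected so silent typos cannot change a run.
    """

    def __init__(self, data: dict | None = None):
        data = dict(data or {})
        unknown = set(data) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        self.seed = int(data.get("seed", 0))
        self.log_level = data.get("log_level", "INFO")
        self.simulate = data.get("simulate")  # dict of SimConfig overrides or None
        self.inputs = data.get("inputs", {})
        if self.simulate is not None:
            sim_fields = {f.name for f in dataclasses.fields(simulate.SimConfig)}
            unknown = set(self.simulate) - sim_fields
            if unknown:
                raise ValueError(f"unknown simulate keys {sorted(unknown)}")
        known_inputs = {"reference", "te_fasta", "te_annotation", "manifest",
                        "gff", "subgenomes"}
        unknown = set(self.inputs) - known_inputs
        if unknown:
            raise ValueError(f"unknown input keys {sorted(unknown)}")
        self.stages = {}
        for stage, defaults in _STAGE_DEFAULTS.items():
            params = dict(defaults)
            overrides = data.get(stage, {})
            unknown = set(overrides) - set(defaults)
            if unknown:
                raise ValueError(f"unknown {stage} keys {sorted(unknown)}")
            params.update(overrides)
            self.stages[stage] = params

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})


def _sim_config(seed: int, overrides: dict) -> "simulate.SimConfig":
    """Build a SimConfig from plain-dict overrides (e.g. parsed YAML)."""
    overrides = dict(overrides)
    if "locus_spec" in overrides:
        overrides["locus_spec"] = [
            simulate.LocusSpec(**d) if isinstance(d, dict) else d
            for d in overrides["locus_spec"]
        ]
    if "te_families" in overrides:
        overrides["te_families"] = [
            simulate.TEFamilySpec(**d) if isinstance(d, dict) else d
            for d in overrides["te_families"]
        ]
    return simulate.SimConfig(**{"seed": seed, **overrides})


def _check_inputs(config: RunConfig) -> None:
    if config.simulate is not None:
        return
    for key in ("reference", "te_fasta", "te_annotation", "manifest"):
        path = config.inputs.get(key)
        if path is None:
            raise FileNotFoundError(f"required input {key!r} not configured")
        if not Path(path).exists():
            raise FileNotFoundError(f"input {key}: no such file {path!r}")


def run_all(config: RunConfig, outdir) -> dict:
    """Execute every stage in order, writing all artifacts under ``outdir``.

    Returns a summary dict (also written as ``summary.json``) with the
    filter accounting, QC measures and stage timings.
    """
    logging.basicConfig(level=getattr(logging, str(config.log_level).upper(), 20))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _check_inputs(config)
    timings = {}

    def stage(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                log.info("stage %s started", name)
                return self_

            def __exit__(self_, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_.t0, 3)
                if exc is not None:
                    log.error("stage %s failed: %s", name, exc)
                else:
                    log.info("stage %s done in %.2fs", name, timings[name])
        return _T()

    # --- inputs (simulated or loaded) ---
    if config.simulate is not None:
        with stage("simulate"):
            sim_cfg = _sim_config(config.seed, config.simulate)
            sim = simulate.simulate_cohort(sim_cfg)
            simulate.write_simulation(sim, outdir / "sim")
        reference = sim.reference
        elements = sim.telib
        read_sets = sim.reads
        morphotypes = sim.config.morphotypes
    else:
        reference = discovery.as_genome(
            mio.read_sequences(config.inputs["reference"], "fasta")
        )
        elements = mio.read_te_elements(
            config.inputs["te_fasta"], config.inputs["te_annotation"]
        )
        manifest = mio.read_manifest(config.inputs["manifest"])
        morphotypes = {acc: morph for acc, morph, _ in manifest}
        read_sets = {
            acc: [r for p in paths for r in mio.read_sequences(p, "fastq")]
            for acc, _, paths in manifest
        }

    # --- end library ---
    with stage("endlib"):
        p = config.stages["endlib"]
        ends = endlib.extract_ends(elements, p["end_len"])
        endlib.collapse_redundancy(
            ends, p["min_len"], p["min_ident"], p["both_strands"]
        )
        endlib.write_end_library(
            ends, outdir / "endlib.fasta", outdir / "endlib_map.tsv"
        )
        library = endlib.EndLibrary([e for e in ends if e.representative])

    # --- discovery ---
    with stage("discover"):
        p = config.stages["discovery"]
        loci = discovery.discover_loci(
            read_sets, library, reference, elements,
            p["min_te_match"], p["min_flank"], p["min_ident"], p["window"],
            p["ref_min_len"], p["ref_min_ident"],
        )
        log.info("discovered %d loci", len(loci))

    # --- genotyping ---
    with stage("genotype"):
        p = config.stages["genotyping"]
        profile = genotyping.genotype_population(
            loci, read_sets, reference, elements, morphotypes,
            p["flank_len"], p["min_overlap"], p["min_ident"],
        )
        mio.write_profile(profile, outdir / "profile_raw")

    # --- filtering ---
    with stage("filter"):
        p = config.stages["filter"]
        qc = filtering.qc_summaries(profile)
        filtered, report = filtering.apply_filters(
            profile, p["max_missing"], p["max_het"],
            p["min_singleton_reads"], p["pair_window"],
        )
        mio.write_profile(filtered, outdir / "profile")
        (outdir / "filter_report.json").write_text(
            json.dumps(report.to_dict(), indent=2) + "\n"
        )

    # --- population frequency analytics ---
    with stage("popfreq"):
        p = config.stages["popfreq"]
        tables = outdir / "tables"
        tables.mkdir(exist_ok=True)
        freqs = popfreq.locus_frequencies(filtered)
        _write_df(
            tables / "frequencies.tsv",
            [(f.locus_id, f.n_carrier, f.n_called, f.freq, f.class_) for f in freqs],
            ["locus_id", "n_carrier", "n_called", "freq", "class"],
        )
        gfreqs = popfreq.group_frequencies(filtered, morphotypes)
        _write_df(
            tables / "group_freqs.tsv",
            [(g.locus_id, g.group, g.freq, g.n_called) for g in gfreqs],
            ["locus_id", "group", "freq", "n_called"],
        )
        diff = popfreq.differential_fixed(gfreqs, p["hi"], p["lo"])
        _write_df(
            tables / "differential_fixed.tsv",
            [(g1, g2, len(ids), ",".join(ids)) for (g1, g2), ids in sorted(diff.items())],
            ["group_high", "group_low", "n_loci", "loci"],
        )
        venn = popfreq.venn_and_singletons(filtered, morphotypes)
        venn["singletons"].to_csv(tables / "singletons.tsv", sep="\t", index=False)
        gff = config.inputs.get("gff")
        blocks_path = config.inputs.get("subgenomes")
        blocks = mio.read_subgenome_blocks(blocks_path) if blocks_path else None
        if gff:
            genes = mio.read_gene_models(gff)
            annotations = popfreq.annotate_loci(
                filtered.loci, genes, p["gene_window"], blocks
            )
            _write_df(
                tables / "annotations.tsv",
                [(a.locus_id, a.category, a.gene_id or "", a.subgenome)
                 for a in annotations],
                ["locus_id", "category", "gene_id", "subgenome"],
            )
            cross = popfreq.class_by_category_table(freqs, annotations)
            cross["counts"].to_csv(tables / "class_by_category_counts.tsv", sep="\t")
            cross["percent"].to_csv(
                tables / "class_by_category_percent.tsv", sep="\t",
                float_format=_FLOAT_FMT,
            )
        if blocks:
            popfreq.subgenome_stats(filtered.loci, blocks).to_csv(
                tables / "subgenome.tsv", sep="\t", index=False,
                float_format=_FLOAT_FMT,
            )

    # --- population genetics ---
    popgen_summary = {}
    with stage("popgen"):
        p = config.stages["popgen"]
        pg = outdir / "popgen"
        pg.mkdir(exist_ok=True)
        try:
            bm = select_informative(freqs, filtered, p["lo"], p["hi"])
        except ValueError as exc:
            log.warning("popgen skipped: %s", exc)
            bm = None
        if bm is not None:
            dm = mean_difference_distance(bm)
            tree = nj_tree(dm)
            mio.write_newick_file(tree, pg / "tree.nwk")
            res = pca(bm, p["scale"])
            _write_df(
                pg / "pca_coords.tsv",
                [(a, *map(float, res.coordinates[i, :10]))
                 for i, a in enumerate(res.accessions)],
                ["accession"] + [f"PC{c + 1}" for c in range(min(10, res.coordinates.shape[1]))],
            )
            _write_df(
                pg / "eigenvalues.tsv",
                list(zip(range(1, len(res.eigenvalues) + 1),
                         map(float, res.eigenvalues),
                         map(float, res.percent_variance))),
                ["component", "eigenvalue", "percent_variance"],
            )
            fst = pairwise_fst(bm, morphotypes)
            fst.to_csv(pg / "fst.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
            popgen_summary = {
                "n_informative_loci": len(bm.locus_ids),
                "pc1_percent_variance": float(res.percent_variance[0]),
                "pc2_percent_variance": float(res.percent_variance[1]),
            }

    summary = {
        "filter_report": report.to_dict(),
        "qc": {k: v for k, v in qc.items() if k != "support_histogram"},
        "popgen": popgen_summary,
        "timings": timings,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary


def _write_df(path, rows, columns) -> None:
    import pandas as pd

    pd.DataFrame(rows, columns=columns).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )
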