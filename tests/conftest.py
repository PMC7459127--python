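"""Shared fixtures: simulated cohorts and a cached end-to-end pipeline run."""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pytest

from mobiscan import discovery, endlib, filtering, genotyping, simulate
from mobiscan.types import MobilomeProfile, TELocus


def small_config(seed: int = 1, **overrides) -> simulate.SimConfig:
    """A quick 30 kb / 6-accession cohort for unit-level checks."""
    defaults = dict(
        seed=seed,
        genome_length=30_000,
        coverage=10,
        error_rate=0.0,
        accessions_per_morphotype={"cabbage": 3, "broccoli": 3},
        locus_spec=[
            simulate.LocusSpec(4, 1.0, "Ref"),
            simulate.LocusSpec(6, 0.5, "nonRef"),
        ],
    )
    defaults.update(overrides)
    return simulate.SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    return simulate.simulate_cohort(small_config())


@dataclass
class PipelineRun:
    sim: simulate.SimResult
    raw: MobilomeProfile
    filtered: MobilomeProfile
    report: object
    locus_truth: dict[str, str]  # filtered locus_id -> truth locus_key


def _match_truth(profile: MobilomeProfile, truth, window: int = 15):
    """Map called loci to planted loci by breakpoint proximity."""
    lookup = {}
    for t in truth.loci:
        lookup.setdefault(t.chrom, []).append(t)
    mapping = {}
    for loc in profile.loci:
        near = [
            t for t in lookup.get(loc.chrom, ())
            if min(abs(t.pos_left - loc.pos), abs(t.pos_right - loc.pos)) <= window
        ]
        # prefer the planted element itself; junction reads with short TE
        # overlap can tie between homologous family copies and produce a
        # position-duplicate locus keyed to the sister element
        cands = [t for t in near if t.te_id == loc.te_id] or near
        if cands:
            best = min(
                cands,
                key=lambda t: min(abs(t.pos_left - loc.pos), abs(t.pos_right - loc.pos)),
            )
            mapping[loc.locus_id] = best.locus_key
    return mapping


@lru_cache(maxsize=8)
def run_e2e(seed: int, error_rate: float = 0.0, dropout: float = 0.0) -> PipelineRun:
    """Full discover -> genotype -> filter pipeline at the default cohort scale."""
    cfg = simulate.SimConfig(seed=seed, error_rate=error_rate, dropout=dropout)
    sim = simulate.simulate_cohort(cfg)
    ends = endlib.extract_ends(sim.telib)
    reps = endlib.collapse_redundancy(ends)
    loci = discovery.discover_loci(
        sim.reads, endlib.EndLibrary(reps), sim.reference, sim.telib
    )
    raw = genotyping.genotype_population(
        loci, sim.reads, sim.reference, sim.telib, cfg.morphotypes
    )
    filtered, report = filtering.apply_filters(raw.copy())
    return PipelineRun(sim, raw, filtered, report, _match_truth(filtered, sim.truth))


@pytest.fixture(scope="session")
def e2e_seed1() -> PipelineRun:
    return run_e2e(1)


def random_profile(
    rng: np.random.Generator,
    n_loci: int,
    accessions: list[str],
    morphotypes: dict[str, str] | None = None,
    p_states=(0.55, 0.3, 0.05, 0.1),
) -> MobilomeProfile:
    """A synthetic genotype matrix with consistent supporting-read counts."""
    loci = [
        TELocus(f"L{i:05d}", "chr1", 500 + 400 * i, f"te{i % 7}",
                family=f"fam{i % 7}", superfamily=f"SF{i % 3}")
        for i in range(n_loci)
    ]
    states = rng.choice(list("PAHM"), size=(n_loci, len(accessions)), p=p_states)
    presence = np.zeros_like(states, dtype=np.int64)
    absence = np.zeros_like(states, dtype=np.int64)
    presence[np.isin(states, ["P", "H"])] = rng.integers(
        1, 12, size=int(np.isin(states, ["P", "H"]).sum())
    )
    absence[np.isin(states, ["A", "H"])] = rng.integers(
        1, 12, size=int(np.isin(states, ["A", "H"]).sum())
    )
    morphotypes = morphotypes or {a: "unknown" for a in accessions}
    return MobilomeProfile(loci, accessions, morphotypes, states, presence, absence)
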