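"""Frequency classes, group analytics, annotation and report tables."""

import numpy as np
import pytest
from scipy import stats

from mobiscan.popfreq import (
    annotate_loci,
    class_by_category_table,
    class_by_superfamily_chisq,
    classify_frequency,
    differential_fixed,
    group_frequencies,
    heterogeneous_loci,
    locus_frequencies,
    round_half_up,
    subgenome_stats,
    te_density,
    venn_and_singletons,
)
from mobiscan.types import GeneModel, SubgenomeBlock, TELocus

from tests._oracles import brute_annotate
from tests.conftest import random_profile
from tests.test_filtering import _profile


class TestFrequencyClasses:
    @pytest.mark.parametrize(
        "freq,cls",
        [(1.0, "fixed"), (0.99, "high"), (0.71, "high"), (0.70, "median"),
         (0.31, "median"), (0.30, "low"), (0.0, "low")],
    )
    def test_boundaries(self, freq, cls):
        assert classify_frequency(freq) == cls

    def test_all_carriers_is_fixed(self):
        p = _profile(["PPPPH"])
        (f,) = locus_frequencies(p)
        assert f.freq == 1.0 and f.class_ == "fixed"

    def test_three_of_ten_is_low(self):
        p = _profile(["PPPAAAAAAA"])
        (f,) = locus_frequencies(p)
        assert f.freq == 0.3 and f.class_ == "low"

    def test_missing_excluded_from_denominator(self):
        p = _profile(["PPMMA"])
        (f,) = locus_frequencies(p)
        assert f.n_called == 3 and f.freq == pytest.approx(2 / 3)

    def test_simulated_spectrum_matches_truth_classes(self, e2e_seed1):
        run = e2e_seed1
        freqs = {f.locus_id: f for f in locus_frequencies(run.filtered)}
        agree = total = 0
        for locus_id, key in run.locus_truth.items():
            truth_freq = np.mean(
                [s in "PH" for s in run.sim.truth.genotypes.loc[key]]
            )
            total += 1
            agree += freqs[locus_id].class_ == classify_frequency(truth_freq)
        assert total >= 0.95 * len(run.sim.truth.loci)
        assert agree / total >= 0.95


class TestGroupFrequencies:
    def _groups(self, profile):
        return {a: ("cabbage" if i < 2 else "broccoli")
                for i, a in enumerate(profile.accessions)}

    def test_full_contrast(self):
        p = _profile(["PPAA"])
        out = group_frequencies(p, self._groups(p))
        by = {g.group: g.freq for g in out}
        assert by == {"cabbage": 1.0, "broccoli": 0.0}

    def test_uncalled_group_flagged_none(self):
        p = _profile(["PPMM"])
        out = group_frequencies(p, self._groups(p))
        by = {g.group: g.freq for g in out}
        assert by["cabbage"] == 1.0 and by["broccoli"] is None

    def test_empty_group_rejected(self):
        p = _profile(["PPAA"])
        groups = {a: "cabbage" for a in p.accessions}
        groups["missing_acc"] = "broccoli"
        with pytest.raises(ValueError):
            group_frequencies(p, {p.accessions[0]: "cabbage"})

    def test_estimates_match_truth_exactly_at_full_calls(self, e2e_seed1):
        run = e2e_seed1
        gfreqs = group_frequencies(run.filtered, run.sim.config.morphotypes)
        table = {(g.locus_id, g.group): g for g in gfreqs}
        checked = 0
        for locus_id, key in run.locus_truth.items():
            for grp, truth_f in run.sim.truth.group_freqs.loc[key].items():
                g = table[(locus_id, grp)]
                if g.n_called == run.sim.config.accessions_per_morphotype[grp]:
                    assert abs(g.freq - truth_f) <= 0.25  # het miscalls only
                    checked += 1
        assert checked > 100


class TestDifferentialFixed:
    def _gf(self, rows):
        from mobiscan.types import GroupFrequency

        return [GroupFrequency(lid, grp, f, 10) for lid, grp, f in rows]

    def test_qualifying_pair(self):
        gf = self._gf([("L1", "g1", 0.92), ("L1", "g2", 0.05)])
        assert differential_fixed(gf)[("g1", "g2")] == ["L1"]

    def test_strict_lower_bound(self):
        gf = self._gf([("L1", "g1", 0.89), ("L1", "g2", 0.05)])
        assert differential_fixed(gf)[("g1", "g2")] == []

    def test_heterogeneity_delta(self):
        gf = self._gf([("L1", "g1", 0.9), ("L1", "g2", 0.3),
                       ("L2", "g1", 0.6), ("L2", "g2", 0.4)])
        assert heterogeneous_loci(gf) == ["L1"]

    def test_differential_implies_heterogeneous(self):
        rng = np.random.default_rng(0)
        from mobiscan.types import GroupFrequency

        gf = []
        for i in range(200):
            for grp in ("g1", "g2", "g3"):
                gf.append(GroupFrequency(f"L{i}", grp, rng.random(), 10))
        het = set(heterogeneous_loci(gf))
        for pair_loci in differential_fixed(gf).values():
            assert set(pair_loci) <= het

    def test_planted_loci_recovered_exactly(self, e2e_seed1):
        run = e2e_seed1
        gfreqs = group_frequencies(run.filtered, run.sim.config.morphotypes)
        found = differential_fixed(gfreqs)
        truth_f = run.sim.truth.group_freqs
        key_of = run.locus_truth
        groups = list(truth_f.columns)
        for g1 in groups:
            for g2 in groups:
                if g1 == g2:
                    continue
                planted = set(
                    truth_f.index[(truth_f[g1] >= 0.9) & (truth_f[g2] <= 0.1)]
                )
                recovered = {key_of[lid] for lid in found[(g1, g2)] if lid in key_of}
                assert recovered == planted, (g1, g2)


class TestVennSingletons:
    def test_counts_on_constructed_matrix(self):
        p = _profile([
            "PPPP",  # shared by both groups
            "PPAA",  # cabbage-specific (2 carriers)
            "PAAA",  # cabbage singleton
            "AAPA",  # broccoli singleton
            "APPA",  # carried in both groups, 2 carriers
        ])
        groups = {"a0": "cabbage", "a1": "cabbage",
                  "a2": "broccoli", "a3": "broccoli"}
        out = venn_and_singletons(p, groups)
        assert out["shared_by_all"] == 2  # rows 0 and 4
        assert out["group_specific"] == {"cabbage": 2, "broccoli": 1}
        singles = out["singletons"].set_index("group")
        assert singles.loc["cabbage", "n_singletons"] == 1
        assert singles.loc["broccoli", "n_singletons"] == 1
        assert singles.loc["Total", "n_singletons"] == 2
        assert singles.loc["Total", "average"] == 0.5

    def test_published_singleton_averages(self):
        # per-accession singleton averages as printed: 704/46 and 2501/121
        assert round_half_up(704 / 46, 1) == 15.3
        assert round_half_up(411 / 19, 1) == 21.6
        assert round_half_up(367 / 20, 1) == 18.4
        assert round_half_up(87 / 23, 1) == 3.8
        assert round_half_up(2501 / 121, 1) == 20.7


def _gene(gene_id, chrom, strand, s, e, exons=None, cds=None):
    exons = exons or [(s, e)]
    cds = cds if cds is not None else exons
    introns = [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]
    return GeneModel(gene_id, chrom, strand, (s, e), exons, cds, introns)


class TestAnnotation:
    def test_cds_precedence_over_neighbor_upstream(self):
        g1 = _gene("g1", "chr1", "+", 1000, 2000)
        g2 = _gene("g2", "chr1", "+", 2200, 3000)  # locus is <500 bp upstream
        locus = TELocus("L1", "chr1", 1900, "te1")
        (rec,) = annotate_loci([locus], [g1, g2])
        assert rec.category == "CDS" and rec.gene_id == "g1"

    def test_upstream_boundary_inclusive_at_window(self):
        g = _gene("g1", "chr1", "+", 10_000, 12_000)
        (rec,) = annotate_loci([TELocus("L1", "chr1", 9_500, "te1")], [g])
        assert rec.category == "upstream"
        (rec,) = annotate_loci([TELocus("L1", "chr1", 9_499, "te1")], [g])
        assert rec.category == "intergenic"

    def test_strand_awareness(self):
        g = _gene("g1", "chr1", "-", 10_000, 12_000)
        (rec,) = annotate_loci([TELocus("L1", "chr1", 12_100, "te1")], [g])
        assert rec.category == "upstream"
        (rec,) = annotate_loci([TELocus("L1", "chr1", 9_900, "te1")], [g])
        assert rec.category == "downstream"

    def test_intron_detected(self):
        g = _gene("g1", "chr1", "+", 1000, 3000,
                  exons=[(1000, 1500), (2500, 3000)])
        (rec,) = annotate_loci([TELocus("L1", "chr1", 2000, "te1")], [g])
        assert rec.category == "intron"

    def test_random_loci_match_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        genes = []
        for i in range(40):
            s = int(rng.integers(0, 95_000))
            e = s + int(rng.integers(500, 4000))
            exons = sorted(
                {(s, s + int(rng.integers(100, 300))),
                 (e - int(rng.integers(100, 300)), e)}
            )
            genes.append(
                _gene(f"g{i:02d}", "chr1", "+" if i % 2 else "-", s, e,
                      exons=exons)
            )
        loci = [
            TELocus(f"L{i}", "chr1", int(rng.integers(0, 100_000)), "te1")
            for i in range(300)
        ]
        recs = annotate_loci(loci, genes)
        for loc, rec in zip(loci, recs):
            cat, gid = brute_annotate(loc.pos, "chr1", genes)
            assert (rec.category, rec.gene_id) == (cat, gid), loc.pos


class TestSubgenomes:
    def test_published_densities(self):
        assert te_density(17_402, 178) == 98
        assert te_density(12_634, 129) == 98
        assert te_density(9_890, 98) == 101

    def test_counts_and_empty_subgenome(self):
        blocks = [SubgenomeBlock("chr1", 0, 1_000_000, "LF"),
                  SubgenomeBlock("chr1", 1_000_000, 2_000_000, "MF1"),
                  SubgenomeBlock("chr2", 0, 500_000, "MF2")]
        loci = [TELocus(f"L{i}", "chr1", 100 + i, "te1") for i in range(5)]
        loci.append(TELocus("Lx", "chr3", 50, "te1"))
        df = subgenome_stats(loci, blocks).set_index("subgenome")
        assert df.loc["LF", "n_loci"] == 5
        assert df.loc["MF2", "n_loci"] == 0 and df.loc["MF2", "density"] == 0
        assert df.loc["unassigned", "n_loci"] == 1

    def test_overlapping_blocks_rejected(self):
        blocks = [SubgenomeBlock("chr1", 0, 100, "LF"),
                  SubgenomeBlock("chr1", 50, 150, "MF1")]
        with pytest.raises(ValueError, match="overlap"):
            subgenome_stats([], blocks)


class TestTables:
    def test_published_low_frequency_row_arithmetic(self):
        # CDS + intron + upstream + downstream of the low class, and the
        # corresponding row percentage over all 18,575 low-frequency loci
        assert 422 + 1247 + 2306 + 1766 == 5741
        assert round_half_up(5741 / 18_575 * 100, 1) == 30.9

    def test_cross_tab_row_sums_and_percentages(self, e2e_seed1):
        from mobiscan.simulate import random_gene_models

        run = e2e_seed1
        genes = random_gene_models(run.sim.reference, 25, seed=5)
        freqs = locus_frequencies(run.filtered)
        annotations = annotate_loci(run.filtered.loci, genes)
        out = class_by_category_table(freqs, annotations)
        counts = out["counts"]
        gene_cols = ["CDS", "intron", "upstream", "downstream"]
        assert (counts["Total"] == counts[gene_cols].sum(axis=1)).all()
        assert counts.loc["Total", "class_total"] == run.filtered.n_loci
        pct = out["percent"]
        row = counts.loc["low"]
        if row["class_total"]:
            expected = round_half_up(row["Total"] / row["class_total"] * 100, 1)
            assert pct.loc["low", "Total"] == expected

    def test_chisq_homogeneous_table_is_zero(self):
        from mobiscan.types import FrequencyRecord

        freqs, loci = [], []
        i = 0
        for sf in ("SF1", "SF2"):
            for cls, freq in (("low", 0.1), ("fixed", 1.0)) * 5:
                i += 1
                loci.append(TELocus(f"L{i}", "chr1", i, "te1", superfamily=sf))
                freqs.append(FrequencyRecord(f"L{i}", 1, 10, freq, cls))
        chi2, dof, p = class_by_superfamily_chisq(freqs, loci)
        assert chi2 == 0.0 and dof == 1 and p == 1.0

    def test_chisq_matches_hand_computed_pearson(self):
        from mobiscan.types import FrequencyRecord

        freqs, loci = [], []
        i = 0
        for sf, cls in (("SF1", "low"), ("SF2", "fixed")):
            for _ in range(20):
                i += 1
                loci.append(TELocus(f"L{i}", "chr1", i, "te1", superfamily=sf))
                freqs.append(
                    FrequencyRecord(f"L{i}", 1, 10,
                                    1.0 if cls == "fixed" else 0.1, cls)
                )
        chi2, dof, _ = class_by_superfamily_chisq(freqs, loci)
        assert chi2 == pytest.approx(40.0) and dof == 1

    def test_chisq_p_uniform_under_homogeneity(self):
        """Across replicates of homogeneous superfamilies the p-values are
        uniform (Kolmogorov-Smirnov check)."""
        from mobiscan.types import FrequencyRecord

        rng = np.random.default_rng(2)
        pvals = []
        class_p = np.array([0.4, 0.25, 0.1, 0.25])
        classes = np.array(["low", "median", "high", "fixed"])
        for _ in range(200):
            freqs, loci = [], []
            i = 0
            for sf in ("SF1", "SF2", "SF3"):
                draws = rng.multinomial(400, class_p)
                for cls, n in zip(classes, draws):
                    for _ in range(int(n)):
                        i += 1
                        loci.append(
                            TELocus(f"L{i}", "chr1", i, "te1", superfamily=sf)
                        )
                        freqs.append(FrequencyRecord(f"L{i}", 1, 10, 0.5, cls))
            pvals.append(class_by_superfamily_chisq(freqs, loci)[2])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_class_partition_of_locus_set(e2e_seed1):
    freqs = locus_frequencies(e2e_seed1.filtered)
    assert len(freqs) == e2e_seed1.filtered.n_loci
    assert sum(f.class_ in ("low", "median", "high", "fixed") for f in freqs) == len(freqs)
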