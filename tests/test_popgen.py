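"""Diversity statistics: site filters, pi against a pairwise-Hamming
oracle, Tajima's D against an independent constants oracle, region
extraction and bias-class contrasts."""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from lampyrid import popgen, simulate
from lampyrid.popgen import GenotypeMatrix


def _matrix(gt, positions=None, contig="c", length=10_000, qual=60.0, alt="T",
            ref="A"):
    gt = np.asarray(gt, dtype=np.int8)
    n_sites = gt.shape[0]
    positions = positions if positions is not None else list(range(1, n_sites + 1))
    sites = pd.DataFrame(
        {
            "contig": [contig] * n_sites,
            "pos": positions,
            "ref": [ref] * n_sites,
            "alt": [alt] * n_sites,
            "qual": [qual] * n_sites,
        }
    )
    samples = [f"s{i}" for i in range(gt.shape[1] // 2)]
    return GenotypeMatrix(sites, gt, samples, {contig: length})


class TestFilterSites:
    def _toy(self):
        sites = pd.DataFrame(
            {
                "contig": ["c"] * 5,
                "pos": [10, 20, 30, 40, 50],
                "ref": ["A", "A", "A", "AT", "A"],
                "alt": ["T", "T,G", "T", "T", "C"],
                "qual": [60.0, 60.0, 10.0, 60.0, 60.0],
            }
        )
        gt = np.zeros((5, 4), dtype=np.int8)
        gt[:, 0] = 1
        return GenotypeMatrix(sites, gt, ["s1", "s2"], {"c": 100})

    def test_removal_ledger(self):
        g = self._toy()
        filtered, ledger = popgen.filter_sites(g)
        assert len(filtered.sites) == 2
        assert ledger["indel"] == 1
        assert ledger["multiallelic"] == 1
        assert ledger["qual"] == 1
        assert filtered.sites["pos"].to_list() == [10, 50]

    def test_zero_missingness_tolerance(self):
        gt = np.array([[1, 0, 0, 0], [1, -1, 0, 0]], dtype=np.int8)
        g = _matrix(gt)
        filtered, ledger = popgen.filter_sites(g, max_missing=0.0)
        assert len(filtered.sites) == 1
        assert ledger["missing"] == 1

    def test_repeat_boundary_is_half_open(self):
        # repeat interval [10, 20): positions 10..19 removed, 20 retained
        gt = np.tile(np.array([[1, 0, 0, 0]], dtype=np.int8), (3, 1))
        g = _matrix(gt, positions=[9, 15, 20])
        repeats = pd.DataFrame({"contig": ["c"], "start": [10], "end": [20]})
        filtered, ledger = popgen.filter_sites(g, repeats=repeats)
        assert filtered.sites["pos"].to_list() == [9, 20]
        assert ledger["repeat"] == 1

    def test_monomorphic_records_exempt_from_snp_and_qual_rules(self):
        sites = pd.DataFrame(
            {
                "contig": ["c", "c"],
                "pos": [5, 6],
                "ref": ["A", "A"],
                "alt": [None, "T"],
                "qual": [0.0, 60.0],
            }
        )
        gt = np.array([[0, 0, 0, 0], [1, 0, 0, 0]], dtype=np.int8)
        g = GenotypeMatrix(sites, gt, ["s1", "s2"], {"c": 100})
        filtered, _ = popgen.filter_sites(g)
        assert len(filtered.sites) == 2

    def test_idempotence(self):
        g = self._toy()
        once, _ = popgen.filter_sites(g)
        twice, ledger = popgen.filter_sites(once)
        pd.testing.assert_frame_equal(once.sites, twice.sites)
        assert all(v == 0 for v in ledger.values())


def _pairwise_hamming_pi(gt, length):
    """Oracle: mean pairwise difference over all haplotype pairs / length."""
    n = gt.shape[1]
    total = Fraction(0)
    for site in gt:
        for i, j in combinations(range(n), 2):
            if site[i] >= 0 and site[j] >= 0 and site[i] != site[j]:
                total += Fraction(1, math.comb(n, 2))
    return float(total) / length


class TestPi:
    def test_single_site_derived_two_of_four(self):
        g = _matrix([[1, 1, 0, 0]])
        assert popgen.pi_region(g, "c") == pytest.approx((4 / 6) / 10_000)

    def test_no_segregating_sites(self):
        g = _matrix(np.zeros((3, 6), dtype=np.int8))
        assert popgen.pi_region(g, "c") == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_hamming_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_sites, n_hap = rng.integers(5, 50), 2 * rng.integers(2, 6)
        gt = rng.integers(0, 2, size=(n_sites, n_hap)).astype(np.int8)
        # sprinkle missing calls; the oracle reduces pair counts the same way
        gt[rng.random(gt.shape) < 0.1] = -1
        # oracle normalizes by full pairs; implementation by called pairs --
        # restrict to complete sites for the strict 1e-12 comparison
        complete = (gt >= 0).all(axis=1)
        gt = gt[complete]
        if gt.shape[0] == 0:
            pytest.skip("no complete sites drawn")
        g = _matrix(gt, positions=list(range(1, gt.shape[0] + 1)))
        assert popgen.pi_region(g, "c") == pytest.approx(
            _pairwise_hamming_pi(gt, 10_000), abs=1e-12
        )

    def test_missing_genotypes_reduce_n_sitewise(self):
        # j=1 among n=3 called: pi = 2*1*2/(3*2) = 2/3
        g = _matrix([[1, 0, 0, -1]])
        assert popgen.pi_region(g, "c") == pytest.approx((2 / 3) / 10_000)

    def test_doubling_length_halves_per_bp_pi(self):
        gt = np.array([[1, 1, 0, 0], [1, 0, 0, 0]], dtype=np.int8)
        pi1 = popgen.pi_region(_matrix(gt, length=5_000), "c")
        pi2 = popgen.pi_region(_matrix(gt, length=10_000), "c")
        assert pi1 == pytest.approx(2 * pi2)

    def test_zero_length_region_rejected(self):
        g = _matrix([[1, 0, 0, 0]])
        with pytest.raises(ValueError):
            popgen.pi_region(g, "c", 5, 5)


def _tajima_d_oracle(pi_total, S, n):
    """Independent evaluation of the published constants via Fractions."""
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = float(e1 * S + e2 * S * (S - 1))
    return (pi_total - S / float(a1)) / math.sqrt(var)


class TestTajimasD:
    def test_zero_when_pi_equals_watterson(self):
        n, S = 10, 5
        a1 = sum(1.0 / i for i in range(1, n))
        assert popgen.tajimas_d(S / a1, S, n) == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_constants_oracle(self):
        assert popgen.tajimas_d(2.0, 5, 10) == pytest.approx(
            _tajima_d_oracle(2.0, 5, 10), abs=1e-10
        )

    def test_undefined_when_no_segregating_sites(self):
        assert popgen.tajimas_d(0.0, 0, 10) is None

    def test_singleton_excess_drives_d_negative(self):
        n, S = 10, 8
        gt = np.zeros((S, n), dtype=np.int8)
        for k in range(S):
            gt[k, k % n] = 1  # every site a singleton
        g = _matrix(gt)
        w = popgen.region_stats(g, "c", 0, 10_000)
        assert w.tajimas_d < 0

    def test_intermediate_frequencies_drive_d_positive(self):
        n, S = 10, 8
        gt = np.zeros((S, n), dtype=np.int8)
        gt[:, : n // 2] = 1  # every site at frequency 1/2
        g = _matrix(gt)
        w = popgen.region_stats(g, "c", 0, 10_000)
        assert w.tajimas_d > 0

    def test_neutral_simulation_centers_on_zero(self):
        cfg = simulate.PopGenSimConfig(
            n_haplotypes=20, region_length=20_000,
            theta={"g": 0.001}, n_regions_per_group=300, seed=6,
        )
        g, _ = simulate.simulate_genotypes(cfg)
        ds = [
            popgen.region_stats(g, c, 0, 20_000).tajimas_d
            for c in g.contig_lengths
        ]
        ds = [d for d in ds if d is not None]
        assert abs(np.mean(ds)) < 0.15


GFF = """##gff-version 3
##sequence-region c1 1 100000
c1\tsrc\tgene\t101\t400\t.\t+\t.\tID=gplus
c1\tsrc\texon\t101\t200\t.\t+\t.\tID=gplus.e1;Parent=gplus
c1\tsrc\texon\t301\t400\t.\t+\t.\tID=gplus.e2;Parent=gplus
c1\tsrc\tgene\t9001\t9500\t.\t-\t.\tID=gminus
c1\tsrc\texon\t9001\t9500\t.\t-\t.\tID=gminus.e1;Parent=gminus
"""


class TestBuildRegions:
    @pytest.fixture()
    def regions(self, tmp_path):
        gff = tmp_path / "ann.gff3"
        gff.write_text(GFF)
        return popgen.build_regions(gff, contig_lengths={"c1": 100_000})

    def test_intron_between_exons(self, regions):
        introns = regions[(regions["gene_id"] == "gplus")
                          & (regions["region_type"] == "intron")]
        assert introns[["start", "end"]].to_numpy().tolist() == [[200, 300]]

    def test_single_exon_gene_has_no_intron(self, regions):
        assert regions[(regions["gene_id"] == "gminus")
                       & (regions["region_type"] == "intron")].empty

    def test_plus_strand_promoter_upstream_of_tss(self, regions):
        prom = regions[(regions["gene_id"] == "gplus")
                       & (regions["region_type"] == "promoter")]
        # gene starts at 0-based 100; promoter clipped at contig start
        assert prom[["start", "end"]].to_numpy().tolist() == [[0, 100]]

    def test_minus_strand_promoter_downstream_in_coordinates(self, regions):
        prom = regions[(regions["gene_id"] == "gminus")
                       & (regions["region_type"] == "promoter")]
        # minus-strand gene ends at 0-based 9500: promoter [9500, 11500)
        assert prom[["start", "end"]].to_numpy().tolist() == [[9500, 11500]]

    def test_exon_outside_gene_span_rejected(self, tmp_path):
        bad = GFF + "c1\tsrc\texon\t8000\t9600\t.\t-\t.\tID=bad;Parent=gminus\n"
        gff = tmp_path / "bad.gff3"
        gff.write_text(bad)
        with pytest.raises(ValueError, match="outside gene span"):
            popgen.build_regions(gff)


class TestCompareBiasClasses:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(-7, 0.3, 60)
        tab = pd.DataFrame(
            {
                "status": ["unbiased"] * 30 + ["female-biased"] * 30,
                "region_type": "intron",
                "pi": np.concatenate([vals[:30], vals[:30]]),
            }
        )
        res = popgen.compare_bias_classes(tab)
        assert res.loc[res["comparison"] == "female-biased", "label"].iloc[0] == "ns"
        assert (
            res.loc[res["comparison"] == "male-biased", "label"].iloc[0]
            == "ns (empty)"
        )

    def test_minimal_groups_give_p_one(self):
        tab = pd.DataFrame(
            {
                "status": ["unbiased", "male-biased"],
                "region_type": "exon",
                "pi": [1e-3, 2e-3],
            }
        )
        res = popgen.compare_bias_classes(tab)
        row = res[res["comparison"] == "male-biased"]
        assert row["pvalue"].iloc[0] == 1.0

    def test_empty_group_labeled(self):
        tab = pd.DataFrame(
            {"status": ["unbiased"] * 3, "region_type": "exon",
             "pi": [1e-3, 2e-3, 3e-3]}
        )
        res = popgen.compare_bias_classes(tab)
        assert (res["label"] == "ns (empty)").all()

    def test_planted_diversity_difference_detected(self):
        # theta 2x higher in the biased group, 200 regions per group
        detected = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = simulate.PopGenSimConfig(
                n_haplotypes=20, region_length=10_000,
                theta={"unbiased": 0.001, "female-biased": 0.002},
                n_regions_per_group=200, seed=900 + seed,
            )
            g, truth = simulate.simulate_genotypes(cfg)
            rows = []
            for contig, group, length in truth.regions.itertuples(index=False):
                rows.append(
                    (group, "intron", popgen.pi_region(g, contig, 0, length))
                )
            tab = pd.DataFrame(rows, columns=["status", "region_type", "pi"])
            res = popgen.compare_bias_classes(tab)
            p = res.loc[res["comparison"] == "female-biased", "pvalue"].iloc[0]
            detected += p < 0.01
        assert detected >= 0.9 * n_seeds
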