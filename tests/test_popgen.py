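import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mitoarch.popgen import (
    EmptyCoverageError,
    StrainMeta,
    VariantMatrix,
    call_heteroplasmy,
    call_snps,
    consensus_haplotypes,
    haploid_r2,
    haversine_km,
    ibs_matrix,
    ibs_vs_geography,
    ld_r2_decay,
    nucleotide_diversity,
)
from mitoarch.simulate import simulate_population


def _vm_from_depths(depth_rows, strains=None, ref=None):
    """depth_rows: list per strain of list per site of (A,C,G,T)."""
    n, s = len(depth_rows), len(depth_rows[0])
    return VariantMatrix(
        strains=strains or [f"s{i}" for i in range(n)],
        sites=np.arange(s),
        ref=np.array(ref or ["A"] * s),
        depths=np.array(depth_rows),
    )


def _consensus_df(rows, strains=None):
    return pd.DataFrame(
        [list(r) for r in rows],
        index=strains or [f"s{i}" for i in range(len(rows))],
        columns=range(len(rows[0])),
    )


class TestConsensus:
    def test_unanimous_depth_gives_base(self):
        vm = _vm_from_depths([[(10, 0, 0, 0)]])
        assert consensus_haplotypes(vm).iloc[0, 0] == "A"

    def test_tie_resolves_to_reference(self):
        vm = _vm_from_depths([[(5, 5, 0, 0)]], ref=["A"])
        assert consensus_haplotypes(vm).iloc[0, 0] == "A"
        vm2 = _vm_from_depths([[(5, 5, 0, 0)]], ref=["G"])
        assert consensus_haplotypes(vm2).iloc[0, 0] == "A"  # alphabetical

    def test_low_depth_masked(self):
        vm = _vm_from_depths([[(3, 0, 0, 0), (30, 0, 0, 0)]])
        cons = consensus_haplotypes(vm, min_depth=20)
        assert cons.iloc[0, 0] == "N"
        assert cons.iloc[0, 1] == "A"

    def test_zero_coverage_strain_raises(self):
        vm = _vm_from_depths([[(0, 0, 0, 0)]])
        with pytest.raises(EmptyCoverageError):
            consensus_haplotypes(vm)

    def test_simulated_truth_recovered_at_depth(self, rng):
        vm, meta, truth = simulate_population(
            ref_length=400, n_strains=4, theta_per_site=0.02,
            depth=50, error_rate=0.01, rng=rng,
        )
        cons = consensus_haplotypes(vm, min_depth=20)
        for i, hap in enumerate(truth.params["haplotypes"]):
            row = cons.iloc[i]
            covered = row != "N"
            assert (row[covered] == np.array(list(hap))[covered.to_numpy()]).all()


class TestSnps:
    def test_polymorphic_site_detected(self):
        cons = _consensus_df(["A", "A", "T"])
        out = call_snps(cons)
        assert out["count"] == 1

    def test_monomorphic_not_called(self):
        cons = _consensus_df(["AA", "AA", "AA"])
        assert call_snps(cons)["count"] == 0

    def test_density_uses_covered_sites(self):
        cons = _consensus_df(["AT", "GN"])
        out = call_snps(cons)
        assert out["covered_sites"] == 1
        assert out["count"] == 1
        assert out["density_per_kb"] == pytest.approx(1000.0)

    def test_simulated_density_within_binomial_envelope(self, rng):
        theta, L, n = 0.005, 5000, 10
        vm, _, _ = simulate_population(
            ref_length=L, n_strains=n, theta_per_site=theta,
            depth=60, error_rate=0.0, rng=rng,
        )
        out = call_snps(consensus_haplotypes(vm, min_depth=10))
        p_site = 1 - ((1 - theta) ** n + n * theta * (1 - theta) ** (n - 1) * 0)
        # a site is polymorphic unless 0 or all strains mutated to one base;
        # dominant term: P(>=1 mutation) = 1-(1-theta)^n
        expect = L * (1 - (1 - theta) ** n)
        sd = math.sqrt(L * (1 - (1 - theta) ** n) * (1 - theta) ** n)
        assert abs(out["count"] - expect) < 4 * sd


class TestHeteroplasmy:
    def test_threshold_boundary_called(self):
        vm = _vm_from_depths([[(95, 5, 0, 0)]])
        calls = call_heteroplasmy(vm, maf_min=0.05, depth_min=50)
        assert len(calls) == 1
        assert calls[0].minor_fraction == pytest.approx(0.05)
        assert (calls[0].major, calls[0].minor) == ("A", "C")

    def test_below_threshold_not_called(self):
        vm = _vm_from_depths([[(98, 2, 0, 0)]])
        assert call_heteroplasmy(vm) == []

    def test_low_depth_not_called(self):
        vm = _vm_from_depths([[(40, 9, 0, 0)]])
        assert call_heteroplasmy(vm, depth_min=50) == []

    def test_operating_characteristics_at_depth_200(self, rng):
        # planted MAF 0.10 at depth 200 with 0.5% error:
        # sensitivity >= 0.99, FPR <= 0.01
        n_sites, depth, maf, err = 2000, 200, 0.10, 0.005
        het_sites = list(range(0, n_sites, 10))
        vm, _, _ = simulate_population(
            ref_length=n_sites, n_strains=1, theta_per_site=0.0,
            het_spec=[(0, s, maf) for s in het_sites],
            depth=depth, error_rate=err, rng=rng,
        )
        calls = {c.site for c in call_heteroplasmy(vm, maf_min=0.05, depth_min=50)}
        planted = set(het_sites)
        sens = len(calls & planted) / len(planted)
        fpr = len(calls - planted) / (n_sites - len(planted))
        assert sens >= 0.99
        assert fpr <= 0.01


class TestPi:
    def test_two_strains_one_difference(self):
        cons = _consensus_df(["AAAAAAAAAA", "AAAAAAAAAT"])
        assert nucleotide_diversity(cons)["pi"] == pytest.approx(0.1)

    def test_three_strain_hand_computation(self):
        s = "AAAAAAAAAA"
        cons = _consensus_df([s, s, "TTAAAAAAAA"])
        assert nucleotide_diversity(cons)["pi"] == pytest.approx((0 + 2 + 2) / 3 / 10)

    def test_identical_strains_zero(self):
        cons = _consensus_df(["ACGT", "ACGT"])
        assert nucleotide_diversity(cons)["pi"] == 0.0

    def test_permutation_invariance_and_bounds(self, rng):
        vm, _, _ = simulate_population(
            ref_length=300, n_strains=5, theta_per_site=0.05,
            depth=40, error_rate=0.0, rng=rng,
        )
        cons = consensus_haplotypes(vm)
        pi = nucleotide_diversity(cons)["pi"]
        shuffled = cons.sample(frac=1, random_state=1)
        assert nucleotide_diversity(shuffled)["pi"] == pytest.approx(pi)
        assert 0 <= pi <= 1

    def test_per_gene_restriction(self):
        cons = _consensus_df(["AAAATTTT", "AAAAAAAA"])
        out = nucleotide_diversity(cons, gene_intervals={"g1": (0, 4), "g2": (4, 8)})
        assert out["per_gene"]["g1"] == 0.0
        assert out["per_gene"]["g2"] == 1.0


class TestLd:
    def test_perfect_coupling(self):
        x = np.array([0, 0, 1, 1.0])
        y = np.array([0, 0, 1, 1.0])
        assert haploid_r2(x, y) == pytest.approx(1.0)

    def test_independent_arrangement(self):
        x = np.array([0, 0, 1, 1.0])
        y = np.array([0, 1, 0, 1.0])
        assert haploid_r2(x, y) == pytest.approx(0.0)

    def test_site_with_itself(self):
        x = np.array([0, 1, 0, 1.0])
        assert haploid_r2(x, x) == pytest.approx(1.0)

    def test_decay_table_from_consensus(self):
        cons = _consensus_df(["AACC", "AACC", "TTGG", "TTGG"])
        out = ld_r2_decay(cons)
        assert (out["pairs"]["r2"] == 1.0).all()

    def test_no_recombination_gives_null_distance_correlation(self, rng):
        ps = []
        for _ in range(40):
            vm, _, _ = simulate_population(
                ref_length=300, n_strains=8, theta_per_site=0.03,
                depth=50, error_rate=0.0, genealogy="chain", rng=rng,
            )
            cons = consensus_haplotypes(vm)
            out = ld_r2_decay(cons, max_pairs=300, seed=0)
            if out["pearson_p"] == out["pearson_p"]:
                ps.append(out["pearson_p"])
        assert len(ps) >= 30
        assert float(np.mean(np.array(ps) < 0.05)) < 0.2
        assert 0.2 < float(np.mean(ps)) < 0.8


class TestGeography:
    def test_quarter_meridian_closed_form(self):
        assert haversine_km(0, 0, 0, 90) == pytest.approx(
            math.pi / 2 * 6371.0, abs=0.01
        )
        assert haversine_km(0, 0, 0, 90) == pytest.approx(10007.54, abs=0.01)

    def test_ibs_matrix_diagonal_and_range(self, rng):
        vm, _, _ = simulate_population(
            ref_length=200, n_strains=4, theta_per_site=0.02,
            depth=40, error_rate=0.0, rng=rng,
        )
        ibs = ibs_matrix(consensus_haplotypes(vm))
        assert (np.diag(ibs.to_numpy()) == 1.0).all()
        assert ((ibs.to_numpy() >= 0) & (ibs.to_numpy() <= 1)).all()

    def test_identical_coordinates_flagged_degenerate(self, rng):
        vm, _, _ = simulate_population(
            ref_length=200, n_strains=4, theta_per_site=0.02,
            depth=40, error_rate=0.0, rng=rng,
        )
        meta = [
            StrainMeta(s, "sp", 30.0, 100.0) for s in vm.strains
        ]
        out = ibs_vs_geography(consensus_haplotypes(vm), meta, permutations=99, seed=1)
        assert out["degenerate"]

    def test_same_seed_same_mantel_p(self, rng):
        vm, meta, _ = simulate_population(
            ref_length=300, n_strains=6, theta_per_site=0.02,
            depth=40, error_rate=0.0, rng=rng,
        )
        cons = consensus_haplotypes(vm)
        o1 = ibs_vs_geography(cons, meta, permutations=199, seed=7)
        o2 = ibs_vs_geography(cons, meta, permutations=199, seed=7)
        assert o1["p"] == o2["p"]

    def test_mantel_agrees_with_skbio_statistic(self, rng):
        from skbio.stats.distance import mantel as skbio_mantel
        from skbio import DistanceMatrix

        vm, meta, _ = simulate_population(
            ref_length=300, n_strains=6, theta_per_site=0.03,
            depth=40, error_rate=0.0, rng=rng,
        )
        cons = consensus_haplotypes(vm)
        out = ibs_vs_geography(cons, meta, permutations=0, seed=1)
        # same statistic on pre-transformed distance-like matrices
        x = np.log(out["km"] + 1.0)
        y = np.log(out["ibs"])
        np.fill_diagonal(x, 0)
        np.fill_diagonal(y, 0)
        r, _, _ = skbio_mantel(
            DistanceMatrix((x + x.T) / 2), DistanceMatrix(-(y + y.T) / 2),
            permutations=0,
        )
        assert out["mantel_r"] == pytest.approx(-r)

    def test_geography_tracking_genetics_detected(self, rng):
        # power check: genetic identity constructed to decay with distance
        hits = 0
        reps = 20
        for _ in range(reps):
            n = 8
            lats = rng.uniform(0, 60, size=n)
            meta = [StrainMeta(f"s{i}", "sp", lats[i], 0.0) for i in range(n)]
            # haplotypes: number of mutations proportional to latitude
            L = 400
            rows = []
            base = rng.choice(list("ACGT"), size=L)
            for i in range(n):
                hap = base.copy()
                k = int(lats[i] / 60 * 80)
                hap[:k] = "T"
                rows.append("".join(hap))
            cons = _consensus_df(rows, strains=[m.strain for m in meta])
            out = ibs_vs_geography(cons, meta, permutations=199, seed=int(rng.integers(2**31)))
            if out["p"] <= 0.05:
                hits += 1
        assert hits >= int(0.9 * reps)


def test_vcf_export_is_readable_and_consistent(tmp_path):
    from mitoarch.popgen import write_snps_vcf

    cons = _consensus_df(["ACGA", "ACGT", "TCNA"])
    write_snps_vcf(cons, tmp_path / "s.vcf", ref=np.array(list("ACGA")))
    import pysam

    vcf = pysam.VariantFile(str(tmp_path / "s.vcf"))
    recs = list(vcf)
    assert [r.pos for r in recs] == [1, 4]  # sites 0 and 3 are polymorphic
    assert recs[0].ref == "A" and recs[0].alts == ("T",)
    gts = [r.samples[s]["GT"] for r in recs for s in ("s0", "s1", "s2")]
    assert gts[:3] == [(0,), (0,), (1,)]


def test_variant_matrix_tsv_round_trip(tmp_path, rng):
    vm, _, _ = simulate_population(
        ref_length=50, n_strains=3, theta_per_site=0.02, depth=30, rng=rng
    )
    vm.to_tsv(tmp_path / "d.tsv")
    back = VariantMatrix.from_tsv(tmp_path / "d.tsv")
    assert back.strains == vm.strains
    assert (back.depths == vm.depths).all()
    assert (back.ref == vm.ref).all()
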