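from itertools import combinations

import numpy as np
import pytest

from regmk.diversity import (
    RegionClass,
    SiteGenotypes,
    chromosome_pi,
    diversity_ratio,
    filter_genotypes,
    per_site_pi,
    read_vcf_sites,
    windowed_pi,
)


def site(
    pos=0,
    chrom="chrY",
    genotypes=((0,),) * 6 + ((1,),) * 6,
    depths=(7,) * 12,
    alts=("G",),
    region=RegionClass.Y_NONCROSSOVER,
):
    return SiteGenotypes(chrom, pos, "A", alts, tuple(genotypes), tuple(depths), region)


class TestPerSitePi:
    @pytest.mark.parametrize(
        "c_ref, c_alt, expect",
        [(12, 0, 0.0), (2, 2, 4 / 6), (11, 1, 11 / 66)],
    )
    def test_worked_examples(self, c_ref, c_alt, expect):
        assert per_site_pi(c_ref, c_alt) == pytest.approx(expect)

    def test_matches_exhaustive_pair_enumeration_up_to_n24(self):
        # brute-force mean pairwise difference over all C(n,2) haplotype pairs
        for n in range(2, 25):
            for c_alt in range(n + 1):
                haplotypes = [0] * (n - c_alt) + [1] * c_alt
                diffs = [a != b for a, b in combinations(haplotypes, 2)]
                assert per_site_pi(n - c_alt, c_alt) == pytest.approx(np.mean(diffs))

    def test_fewer_than_two_alleles_rejected(self):
        with pytest.raises(ValueError):
            per_site_pi(1, 0)


class TestFilters:
    def test_heterozygous_call_in_hemizygous_region_dropped(self):
        het = site(genotypes=((0, 1),) + ((0,),) * 11)
        kept, tallies = filter_genotypes([het])
        assert kept == []
        assert tallies["heterozygous_hemizygous"] == 1

    def test_heterozygous_autosome_site_kept(self):
        auto = site(
            chrom="chrA",
            region=RegionClass.AUTOSOME,
            genotypes=((0, 1),) * 12,
            depths=(13,) * 12,
        )
        kept, _ = filter_genotypes([auto])
        assert len(kept) == 1

    def test_depth_outside_bounds_dropped(self):
        deep = site(depths=(15,) * 12)
        kept, tallies = filter_genotypes([deep])
        assert kept == []
        assert tallies["depth"] == 1
        shallow = site(depths=(2,) * 12)
        assert filter_genotypes([shallow])[0] == []

    def test_triallelic_site_dropped(self):
        tri = site(alts=("G", "T"))
        kept, tallies = filter_genotypes([tri])
        assert kept == []
        assert tallies["not_biallelic"] == 1

    def test_mixed_ploidy_rejected(self):
        mixed = site(genotypes=((0,),) * 6 + ((0, 1),) * 6, region=RegionClass.PAR)
        kept, tallies = filter_genotypes([mixed])
        assert kept == []
        assert tallies["mixed_ploidy"] == 1

    def test_filtering_is_order_independent(self, rng):
        sites = []
        for i in range(100):
            depths = tuple(int(d) for d in rng.poisson(7, 12))
            n_alt = int(rng.integers(0, 13))
            genotypes = tuple((1,) if j < n_alt else (0,) for j in range(12))
            alts = ("G",) if rng.random() < 0.9 else ("G", "T")
            sites.append(site(pos=i, genotypes=genotypes, depths=depths, alts=alts))
        kept_fwd, tallies_fwd = filter_genotypes(sites)
        perm = [sites[i] for i in rng.permutation(len(sites))]
        kept_rev, tallies_rev = filter_genotypes(perm)
        assert {s.pos for s in kept_fwd} == {s.pos for s in kept_rev}
        assert tallies_fwd == tallies_rev


class TestWindows:
    def test_window_mean_of_site_pi(self):
        sites = [
            site(pos=100, genotypes=((0,),) * 8 + ((1,),) * 4),   # pi = 32/66
            site(pos=9_000, genotypes=((0,),) * 6 + ((1,),) * 6),  # pi = 36/66
        ]
        table = windowed_pi(sites, chrom_length=20_000, window=10_000)
        assert table.loc[0, "pi"] == pytest.approx((32 / 66 + 36 / 66) / 2)
        assert bool(table.loc[1, "empty"])

    def test_empty_windows_excluded_from_chromosome_mean(self):
        sites = [site(pos=100)]
        table = windowed_pi(sites, chrom_length=50_000, window=10_000)
        assert chromosome_pi(table) == pytest.approx(per_site_pi(6, 6))
        assert chromosome_pi(table, include_empty=True) == pytest.approx(per_site_pi(6, 6) / 5)

    def test_single_window_equals_global_mean(self, rng):
        sites = []
        for i in range(40):
            n_alt = int(rng.integers(1, 12))
            genotypes = tuple((1,) if j < n_alt else (0,) for j in range(12))
            sites.append(site(pos=int(rng.integers(0, 9_000)), genotypes=genotypes))
        table = windowed_pi(sites, chrom_length=9_000, window=9_000)
        expect = np.mean([per_site_pi(*s.allele_counts()) for s in sites])
        assert table.loc[0, "pi"] == pytest.approx(expect)


class TestDiversityRatio:
    def test_x_below_expectation(self):
        ratio, deviation = diversity_ratio(0.0019, 0.0043, "X")
        assert ratio == pytest.approx(0.44, abs=0.005)
        assert deviation < 0  # below the 75% neutral expectation

    def test_y_expectation_identity(self):
        ratio, deviation = diversity_ratio(0.001075, 0.0043, "Y")
        assert ratio == pytest.approx(0.25)
        assert deviation == pytest.approx(0.0)

    def test_zero_region_pi(self):
        assert diversity_ratio(0.0, 0.004, "Y")[0] == 0.0

    def test_zero_autosome_undefined(self):
        with pytest.raises(ValueError):
            diversity_ratio(0.001, 0.0, "Y")


def test_windowed_ratio_recovers_theta_ratio(small_bundle):
    # theta_Y = theta_auto / 10 in a fresh cohort: the windowed pi ratio
    # should recover 0.1 within Monte-Carlo error of the site counts
    from conftest import flat_params
    from regmk.synthetic_data import simulate_polymorphism, simulate_sequences

    params = flat_params(
        seed=31, n_acrs=2, chrom_length=400_000, auto_length=400_000,
        theta_y=0.0004, theta_auto=0.004, depth_outlier_frac=0.0,
    )
    bundle = simulate_sequences(params)
    sites = simulate_polymorphism(bundle)
    kept, _ = filter_genotypes(sites)
    y_sites = [s for s in kept if s.chrom == "chrY"]
    a_sites = [s for s in kept if s.chrom == "chrA"]
    pi_y = chromosome_pi(
        windowed_pi(y_sites, 400_000, 10_000, denominator="length"), include_empty=True
    )
    pi_a = chromosome_pi(
        windowed_pi(a_sites, 400_000, 10_000, denominator="length"), include_empty=True
    )
    ratio, _ = diversity_ratio(pi_y, pi_a, 0.1)
    se = ratio * np.sqrt(1 / max(len(y_sites), 1) + 1 / max(len(a_sites), 1))
    assert abs(ratio - 0.1) < 3 * se + 0.01


def test_vcf_round_trip(tmp_path, small_bundle):
    from regmk.synthetic_data import simulate_polymorphism, write_vcf

    sites = simulate_polymorphism(small_bundle)[:200]
    path = tmp_path / "sites.vcf"
    write_vcf(sites, path, n_samples=12)
    back = read_vcf_sites(
        path,
        {
            "chrX": RegionClass.X_NONCROSSOVER,
            "chrY": RegionClass.Y_NONCROSSOVER,
            "chrA": RegionClass.AUTOSOME,
        },
    )
    assert len(back) == len(sites)
    orig = {(s.chrom, s.pos): s for s in sites}
    for got in back:
        want = orig[(got.chrom, got.pos)]
        assert got.ref == want.ref and got.alts == want.alts
        assert got.allele_counts() == want.allele_counts()
        assert got.depths == want.depths
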