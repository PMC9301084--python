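"""Simulator: meiosis model, pooling, read sampling, phenotyping records."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bsakit as bk
from bsakit.phenotype import FluorescenceTrace, PigmentContents
from bsakit.simulate import (
    _simulate_gametes,
    simulate_absorbance_readings,
    simulate_fluorescence_traces,
    simulate_marker_genotypes,
)

from conftest import single_chromosome_setup

HALDANE_10CM = (1 - np.exp(-0.2)) / 2  # 0.090634...


def test_f2_pale_fraction_is_one_quarter():
    """A recessive locus segregates 3:1 in a large F2."""
    gmap, variants, causal = single_chromosome_setup([50.0], 50.0)
    pop = bk.simulate_f2_population(gmap, variants, causal, 10_000, seed=11)
    frac = pop.phenotype_counts["pale-green"] / len(pop)
    se = np.sqrt(0.25 * 0.75 / 10_000)
    assert abs(frac - 0.25) < 3 * se


def test_single_site_genotypes_segregate_1_2_1():
    """Genotype classes at any site converge to 1:2:1 (chi-square, 20 seeds)."""
    gmap, variants, causal = single_chromosome_setup([20.0, 80.0], 20.0)
    rejections = 0
    for seed in range(20):
        pop = bk.simulate_f2_population(gmap, variants, causal, 10_000,
                                        seed=seed)
        site = variants.site_index("chrA", int(variants.sites["pos"].iloc[-1]))
        counts = np.bincount(pop.genotypes[:, site], minlength=3)
        chi2 = stats.chisquare(counts, f_exp=[2500, 5000, 2500])
        rejections += chi2.pvalue < 0.01
    # at alpha=0.01 per seed, >2 rejections out of 20 is a ~1e-3 event
    assert rejections <= 2


def test_zero_cm_chromosome_is_fully_coinherited():
    """With no genetic length there are no crossovers: one origin per gamete."""
    gmap = bk.GeneticMap(
        [bk.Chromosome("frozen", 10_000_000, 0.0),
         bk.Chromosome("other", 10_000_000, 50.0)]
    )
    sites = pd.DataFrame(
        [("frozen", p, "G", "A", "mutant-line")
         for p in (10, 1_000_000, 5_000_000, 9_999_999)]
        + [("other", 500, "C", "T", "mutant-line")],
        columns=["chrom", "pos", "ref", "alt", "origin"],
    )
    variants = bk.EMSVariantSet(sites, ems_bias=0.0)
    origin = _simulate_gametes(gmap, variants, 500, np.random.default_rng(2))
    frozen_cols = np.flatnonzero(
        variants.sites["chrom"].to_numpy() == "frozen"
    )
    assert (np.ptp(origin[:, frozen_cols], axis=1) == 0).all()


def test_haldane_recombination_fraction_at_10_cm():
    """Gametic recombination at 10 cM matches (1-e^-0.2)/2 ~ 0.0906."""
    gmap, variants, _ = single_chromosome_setup([45.0, 55.0], 45.0)
    origin = _simulate_gametes(
        gmap, variants, 50_000, np.random.default_rng(3)
    )
    r_hat = (origin[:, 0] != origin[:, 1]).mean()
    se = np.sqrt(HALDANE_10CM * (1 - HALDANE_10CM) / 50_000)
    assert abs(r_hat - HALDANE_10CM) < 3 * se


def test_causal_site_missing_raises():
    gmap, variants, _ = single_chromosome_setup([50.0], 50.0)
    absent = bk.CausalLocusSpec("chrA", 123)
    with pytest.raises(ValueError, match="chrA:123"):
        bk.simulate_f2_population(gmap, variants, absent, 10, seed=0)


def test_lethal_homozygotes_are_removed():
    gmap, variants, _ = single_chromosome_setup([50.0], 50.0)
    causal = bk.CausalLocusSpec("chrA", variants.sites["pos"].iloc[0],
                                lethal_when_homozygous=True)
    pop = bk.simulate_f2_population(gmap, variants, causal, 4000, seed=5)
    assert pop.phenotype_counts["pale-green"] == 0
    assert (pop.genotypes[:, pop.causal_index] < 2).all()
    assert len(pop) < 4000


class TestBuildPools:
    def test_pools_are_phenotypically_pure(self, demo_experiment):
        wp, mp = demo_experiment["wp"], demo_experiment["mp"]
        assert (wp.members.phenotypes == "green").all()
        assert (mp.members.phenotypes == "pale-green").all()
        assert len(wp.members) == len(mp.members) == 200

    def test_shortfall_raises_with_count(self):
        gmap, variants, causal = single_chromosome_setup([50.0], 50.0)
        pop = bk.simulate_f2_population(gmap, variants, causal, 300, seed=1)
        n_pale = pop.phenotype_counts["pale-green"]
        with pytest.raises(ValueError, match="shortfall"):
            bk.build_pools(
                pop, bk.PoolSpec("WP", 10), bk.PoolSpec("MP", n_pale + 50), 0
            )

    def test_causal_allele_frequencies(self):
        """MP is fixed for the mutant allele; WP expects frequency 1/3."""
        gmap, variants, causal = single_chromosome_setup([50.0], 50.0)
        pop = bk.simulate_f2_population(gmap, variants, causal, 6000, seed=9)
        wp, mp = bk.build_pools(
            pop, bk.PoolSpec("WP", 1500), bk.PoolSpec("MP", 1000), seed=9
        )
        ci = pop.causal_index
        assert mp.allele_frequencies[ci] == 1.0
        # green genotypes are 0 (1/3) or 1 (2/3): dosage variance 2/9
        se = np.sqrt((2 / 9) / (4 * 1500))
        assert abs(wp.allele_frequencies[ci] - 1 / 3) < 3 * se


class TestReadCounts:
    def _pool(self, dosages, spec, n_sites):
        sites = pd.DataFrame(
            [("chrA", i + 1, "G", "A", "mutant-line") for i in range(n_sites)],
            columns=["chrom", "pos", "ref", "alt", "origin"],
        )
        variants = bk.EMSVariantSet(sites, ems_bias=0.0)
        n_ind = len(dosages)
        geno = np.tile(np.array(dosages, dtype=np.uint8)[:, None],
                       (1, n_sites))
        pheno = np.array(
            ["pale-green" if d == 2 else "green" for d in dosages]
        )
        pop = bk.F2Population(
            geno, pheno, variants, bk.CausalLocusSpec("chrA", 1)
        )
        return bk.simulate.Pool(spec, pop)

    def test_fixed_pool_without_error_gives_alt_equal_total(self):
        mp = self._pool([2] * 20, bk.PoolSpec("MP", 20, 50, 0.0), 200)
        wp = self._pool([0] * 20, bk.PoolSpec("WP", 20, 50, 0.0), 200)
        counts = bk.simulate_pool_read_counts(wp, mp, seed=0)
        assert (counts["mp_alt"] == counts["mp_dp"]).all()
        assert (counts["wp_alt"] == 0).all()

    def test_half_frequency_mean_index(self):
        """f=0.5 at depth 100 over 10,000 sites: mean index within 3 SE."""
        pool = self._pool([1] * 50, bk.PoolSpec("MP", 50, 100, 0.0), 10_000)
        wp = self._pool([1] * 50, bk.PoolSpec("WP", 50, 100, 0.0), 10_000)
        counts = bk.simulate_pool_read_counts(wp, pool, seed=4)
        idx = counts["mp_alt"] / counts["mp_dp"]
        se = np.sqrt(0.25 / 100 / 10_000)
        assert abs(idx.mean() - 0.5) < 3 * se


class TestMarkerGenotypes:
    def test_causal_marker_all_hommut_in_mutant_class(self, demo_experiment):
        pop, causal = demo_experiment["pop"], demo_experiment["causal"]
        mutants = pop.subset(np.flatnonzero(pop.phenotypes == "pale-green"))
        markers = pd.DataFrame(
            {"id": ["causal"], "chrom": [causal.chromosome],
             "pos": [causal.position]}
        )
        geno = simulate_marker_genotypes(mutants, markers)
        assert (geno["causal"] == 2).all()

    def test_unlinked_marker_segregates_1_2_1_in_mutant_class(self):
        gmap, variants, causal = single_chromosome_setup([10.0], 10.0)
        far = pd.concat(
            [variants.sites,
             pd.DataFrame([("chrB", 100, "G", "A", "mutant-line")],
                          columns=variants.sites.columns)]
        )
        gmap = bk.GeneticMap(
            gmap.chromosomes + [bk.Chromosome("chrB", 1_000_000, 50.0)]
        )
        variants = bk.EMSVariantSet(far, ems_bias=0.0)
        pop = bk.simulate_f2_population(gmap, variants, causal, 8000, seed=21)
        mutants = pop.subset(np.flatnonzero(pop.phenotypes == "pale-green"))
        markers = pd.DataFrame(
            {"id": ["far"], "chrom": ["chrB"], "pos": [100]}
        )
        geno = simulate_marker_genotypes(mutants, markers)
        counts = geno["far"].value_counts().reindex([0, 1, 2]).fillna(0)
        n = counts.sum()
        chi2 = stats.chisquare(counts, f_exp=[n / 4, n / 2, n / 4])
        assert chi2.pvalue > 1e-4

    def test_expected_recombinants_at_1_cm(self):
        """885 mutant-class plants at a 1 cM marker: ~17.5 recombinants."""
        gmap, variants, causal = single_chromosome_setup([50.0, 51.0], 50.0)
        markers = pd.DataFrame(
            {"id": ["near"], "chrom": ["chrA"],
             "pos": [int(variants.sites["pos"].iloc[-1])]}
        )
        r = (1 - np.exp(-0.02)) / 2
        expected = 2 * 885 * r  # ~17.52
        totals = []
        rng = np.random.default_rng(31)
        for _ in range(10):
            pop = bk.simulate_f2_population(gmap, variants, causal, 3800, rng)
            mutants = pop.subset(
                np.flatnonzero(pop.phenotypes == "pale-green")[:885]
            )
            assert len(mutants) == 885
            geno = simulate_marker_genotypes(mutants, markers)
            totals.append(int((geno["near"] != 2).sum()))
        sd_single = np.sqrt(2 * 885 * r * (1 - r))
        assert abs(np.mean(totals) - expected) < 3 * sd_single / np.sqrt(10)

    def test_unknown_marker_raises(self, demo_experiment):
        pop = demo_experiment["pop"]
        markers = pd.DataFrame(
            {"id": ["nope"], "chrom": ["chr1"], "pos": [42]}
        )
        with pytest.raises(KeyError, match="chr1:42"):
            simulate_marker_genotypes(pop, markers)


def test_simulation_is_deterministic_under_seed(demo_map):
    outs = []
    for _ in range(2):
        rng = np.random.default_rng(77)
        variants = bk.EMSVariantSet.random(demo_map, 100, rng=rng)
        row = variants.sites.iloc[50]
        causal = bk.CausalLocusSpec(str(row["chrom"]), int(row["pos"]))
        pop = bk.simulate_f2_population(demo_map, variants, causal, 500, rng)
        wp, mp = bk.build_pools(
            pop, bk.PoolSpec("WP", 80), bk.PoolSpec("MP", 80), rng
        )
        counts = bk.simulate_pool_read_counts(wp, mp, rng)
        outs.append(counts.to_csv())
    assert outs[0] == outs[1]


class TestPhenotypingRecords:
    def test_pigment_round_trip_exact_at_zero_noise(self):
        truth = PigmentContents(chl_a=2.0, chl_b=1.0, car=0.4)
        (r,) = simulate_absorbance_readings(
            truth, volume_ml=30.0, dilution=1.0, weight_g=1.0, noise_sd=0.0
        )
        out = bk.pigments_from_absorbance(r)
        assert out.chl_a == pytest.approx(2.0, rel=1e-9)
        assert out.chl_b == pytest.approx(1.0, rel=1e-9)
        assert out.car == pytest.approx(0.4, rel=1e-9)
        assert out.chls == out.chl_a + out.chl_b

    def test_zero_pigments_give_zero_absorbances(self):
        truth = PigmentContents(chl_a=0.0, chl_b=0.0, car=0.0)
        (r,) = simulate_absorbance_readings(truth, volume_ml=30.0)
        assert r.od663 == r.od645 == r.od470 == 0.0

    def test_impossible_pigments_raise(self):
        with pytest.raises(ValueError, match="non-negative absorbance"):
            simulate_absorbance_readings(
                PigmentContents(chl_a=-1.0, chl_b=1.0, car=0.1),
                volume_ml=30.0,
            )

    def test_noisy_recovery_is_unbiased(self):
        # truth chosen so the implied ODs sit near 0.5, keeping additive
        # noise clear of the non-negativity bound
        truth = PigmentContents(chl_a=174.66, chl_b=67.08, car=40.0)
        readings = simulate_absorbance_readings(
            truth, volume_ml=30.0, noise_sd=0.01, n=1000, seed=8
        )
        rec = [bk.pigments_from_absorbance(r) for r in readings]
        # chl_a noise sd ~ |(12.72, -2.69)| * 0.01 * 30 ~ 3.9 per replicate
        assert np.mean([p.chl_a for p in rec]) == pytest.approx(174.66, abs=0.5)
        assert np.mean([p.chl_b for p in rec]) == pytest.approx(67.08, abs=1.0)

    def test_fluorescence_round_trip_at_zero_noise(self):
        truth = FluorescenceTrace(
            fo=400, fm=2000, fs=600, fm_prime=1500, fo_prime=380,
            tau=0.08, p_m=1.1, p_0=1.2, abs940=0.8, abs650=0.5,
            ref_abs940=0.7, ref_abs650=0.6, k=1.0,
        )
        (copy,) = simulate_fluorescence_traces(truth, noise_sd=0.0)
        assert bk.fluorescence_params(copy) == bk.fluorescence_params(truth)


def test_ems_variant_set_rejects_low_transition_fraction():
    sites = pd.DataFrame(
        [("chr1", i + 1, "A", "C", "mutant-line") for i in range(10)],
        columns=["chrom", "pos", "ref", "alt", "origin"],
    )
    with pytest.raises(ValueError, match="EMS bias"):
        bk.EMSVariantSet(sites, ems_bias=0.7)


def test_random_variant_set_is_ems_biased(demo_map):
    variants = bk.EMSVariantSet.random(demo_map, 400, seed=6)
    is_ts = [
        (r, a) in bk.simulate.EMS_TRANSITIONS
        for r, a in zip(variants.sites["ref"], variants.sites["alt"])
    ]
    assert np.mean(is_ts) > 0.6
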