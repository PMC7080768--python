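"""Synthetic-cohort generator: determinism, SFS shape, drift ordering,
planted signals, annotation distributions, posterior noise model."""

import numpy as np
import pytest
from scipy.stats import binom, spearmanr

from isopop import (
    AnnotationSpec,
    PosteriorNoise,
    SimConfig,
    SweepSpec,
    annotate_sites,
    corrupt_to_posteriors,
    derive_isolate,
    generate_cohort_set,
    plant_sweep,
    simulate_founders,
)
from isopop.core import folded_sfs
from isopop.imputation import concordance_r2_by_maf
from isopop.structure import fst_weir_cockerham


class TestSimulateFounders:
    def test_same_seed_bit_identical(self, small_config):
        a = simulate_founders(small_config)
        b = simulate_founders(small_config)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.positions, b.positions)
        assert a.ref_alleles == b.ref_alleles

    def test_single_founder_no_mutation_all_identical(self):
        cfg = SimConfig(seed=2, n_founders=1, mutation_rate_per_copy=0.0,
                        n_sites=100, n_haplotypes_base=20, chrom_length_bp=100_000)
        panel = simulate_founders(cfg)
        assert (panel.haplotypes == panel.haplotypes[0]).all()

    def test_folded_sfs_rare_heavy(self):
        """Neutral-style spectrum: bin counts fall with minor-allele count
        (negative rank correlation over 10 seeds)."""
        rhos = []
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_haplotypes_base=200, n_sites=5000,
                            chrom_length_bp=5_000_000)
            sfs = folded_sfs(simulate_founders(cfg).haplotypes)
            rho, _ = spearmanr(np.arange(1, sfs.size + 1), sfs)
            rhos.append(rho)
        assert all(r < 0 for r in rhos)

    def test_sites_polymorphic(self, small_base):
        ac = small_base.haplotypes.sum(axis=0)
        assert (ac > 0).all() and (ac < small_base.n_haplotypes).all()

    @pytest.mark.parametrize("field", ["n_founders", "n_sites", "n_haplotypes_base"])
    def test_nonpositive_sizes_rejected(self, field):
        cfg = SimConfig(**{field: 0})
        with pytest.raises(ValueError):
            simulate_founders(cfg)


class TestDeriveIsolate:
    def test_no_bottleneck_no_drift_is_permutation(self, small_base):
        out = derive_isolate(small_base, small_base.n_haplotypes, 0,
                             small_base.n_haplotypes, seed=3)
        a = np.asarray(sorted(map(tuple, small_base.haplotypes.tolist())))
        b = np.asarray(sorted(map(tuple, out.haplotypes.tolist())))
        assert np.array_equal(a, b)

    def test_determinism(self, small_base):
        a = derive_isolate(small_base, 30, 2, 50, seed=9)
        b = derive_isolate(small_base, 30, 2, 50, seed=9)
        assert np.array_equal(a.haplotypes, b.haplotypes)

    def test_bottleneck_larger_than_base_rejected(self, small_base):
        with pytest.raises(ValueError):
            derive_isolate(small_base, small_base.n_haplotypes + 1, 2, 50, seed=0)

    def test_drift_fst_monotone_in_bottleneck(self):
        """Fewer founders => larger Fst vs base, over 20 seeded replicates."""
        wins = 0
        for seed in range(20):
            cfg = SimConfig(seed=1000 + seed, n_sites=2000, chrom_length_bp=2_000_000)
            base = simulate_founders(cfg)
            g0 = base.genotypes()
            iso10 = derive_isolate(base, 10, 2, 100, seed=2000 + seed)
            iso100 = derive_isolate(base, 100, 2, 100, seed=3000 + seed)
            f10, _ = fst_weir_cockerham(g0, iso10.genotypes())
            f100, _ = fst_weir_cockerham(g0, iso100.genotypes())
            wins += f10 > f100
        assert wins >= 15, f"Fst ordering held in only {wins}/20 replicates"


class TestPlantSweep:
    def test_zero_flank_changes_only_focal_column(self, small_base):
        focal = int(small_base.positions[small_base.n_sites // 2])
        swept = plant_sweep(small_base, focal, 0.5, 0, seed=4)
        j = int(np.searchsorted(swept.positions, focal))
        mask = np.ones(small_base.n_sites, dtype=bool)
        mask[j] = False
        assert np.array_equal(swept.haplotypes[:, mask], small_base.haplotypes[:, mask])
        assert swept.haplotypes[:, j].sum() == int(np.ceil(0.5 * small_base.n_haplotypes))

    def test_carriers_share_flank_haplotype(self, small_base):
        focal = int(small_base.positions[small_base.n_sites // 2])
        swept = plant_sweep(small_base, focal, 0.4, 200_000, seed=5,
                            private_mutation_rate=0.0)
        j = int(np.searchsorted(swept.positions, focal))
        flank = np.abs(swept.positions - focal) <= 200_000
        flank[j] = False
        carriers = swept.haplotypes[:, j] == 1
        block = swept.haplotypes[np.ix_(carriers, flank)]
        assert (block == block[0]).all()

    def test_focal_outside_range_rejected(self, small_base):
        with pytest.raises(ValueError):
            plant_sweep(small_base, int(small_base.positions[-1]) + 10, 0.5, 1000, seed=0)


class TestAnnotateSites:
    def test_no_high_impact_when_probability_zero(self, toy_panel):
        from isopop.hko import classify_lof

        spec = AnnotationSpec(p_high_impact=0.0)
        recs = annotate_sites(toy_panel, spec, seed=1)
        assert not any(classify_lof(r) for r in recs)

    def test_high_impact_count_binomial(self, small_base):
        """P(high impact) = 0.01 over ~10^4 sites: count inside the central
        99% binomial interval."""
        spec = AnnotationSpec(p_high_impact=0.01)
        recs = annotate_sites(small_base, spec, seed=2)
        from isopop.simulate import HIGH_IMPACT_TERMS

        n = len(recs)
        count = sum(r.consequence in HIGH_IMPACT_TERMS for r in recs)
        lo, hi = binom.ppf([0.005, 0.995], n, 0.01)
        assert lo <= count <= hi

    def test_affected_transcripts_subset_of_gene(self, small_base):
        recs = annotate_sites(small_base, AnnotationSpec(), seed=3)
        for r in recs[:500]:
            assert 1 <= len(r.affected_transcripts) <= r.n_transcripts
            assert all(t.startswith(r.gene) for t in r.affected_transcripts)

    def test_deterministic(self, toy_panel):
        a = annotate_sites(toy_panel, AnnotationSpec(), seed=7)
        b = annotate_sites(toy_panel, AnnotationSpec(), seed=7)
        assert a == b


class TestCorruptToPosteriors:
    def test_zero_noise_degenerate_and_perfect_r2(self, small_base):
        g = small_base.genotypes()[:, :500]
        post = corrupt_to_posteriors(g, PosteriorNoise(rate=0.0), seed=1)
        assert np.allclose(post.expected_dosage(), g)
        report = concordance_r2_by_maf(g, post)
        populated = report[report.n_sites > 0]
        assert np.allclose(populated.mean_r2, 1.0)

    def test_probabilities_normalized(self, small_base):
        g = small_base.genotypes()[:, :300]
        post = corrupt_to_posteriors(g, PosteriorNoise(rate=0.3), seed=2)
        assert np.allclose(post.probs.sum(axis=2), 1.0, atol=1e-9)

    def test_mean_r2_monotone_in_noise(self, small_base):
        """More noise, lower concordance (over 10 seeds)."""
        g = small_base.genotypes()[:, :1000]
        wins = 0
        for seed in range(10):
            lo = corrupt_to_posteriors(g, PosteriorNoise(rate=0.05), seed=seed)
            hi = corrupt_to_posteriors(g, PosteriorNoise(rate=0.4), seed=seed)
            r_lo = concordance_r2_by_maf(g, lo).mean_r2.mean()
            r_hi = concordance_r2_by_maf(g, hi).mean_r2.mean()
            wins += r_hi <= r_lo
        assert wins >= 9

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            corrupt_to_posteriors(np.zeros((2, 2), dtype=int),
                                  PosteriorNoise(rate=-0.1), seed=0)


@pytest.fixture(scope="module")
def bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    cfg = SimConfig(seed=42, n_sites=400, chrom_length_bp=400_000,
                    n_haplotypes_base=60, bottleneck_founders=(10, 20, 30),
                    n_out_haplotypes=20)
    manifest = generate_cohort_set(cfg, out)
    return cfg, out, manifest


class TestGenerateCohortSet:
    def test_expected_file_set(self, bundle):
        _cfg, out, manifest = bundle
        assert len(manifest["populations"]) == 3
        for entry in manifest["populations"].values():
            assert (out / entry["vcf"]).exists()
            assert (out / entry["annotations"]).exists()
            assert (out / entry["posteriors"]).exists()
        assert (out / manifest["external_sites"]).exists()
        assert (out / manifest["rvis"]).exists()

    def test_rerun_byte_identical(self, bundle, tmp_path):
        cfg, out, manifest = bundle
        generate_cohort_set(cfg, tmp_path)
        for entry in manifest["populations"].values():
            assert (out / entry["vcf"]).read_bytes() == (tmp_path / entry["vcf"]).read_bytes()

    def test_external_list_subset_of_union(self, bundle):
        from isopop.io import read_site_list, read_vcf

        _cfg, out, manifest = bundle
        union = set()
        for pop, entry in manifest["populations"].items():
            union |= set(read_vcf(out / entry["vcf"], population_id=pop).keys)
        external = read_site_list(out / manifest["external_sites"])
        assert external <= union and external
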