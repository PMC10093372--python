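"""Synthetic herd generator: pedigree topology, Mendelian inheritance,
LD structure and heritability calibration."""

import numpy as np
import pandas as pd
import pytest

import gsel
from gsel.kinship import UNKNOWN
from gsel.simdata import SimConfig, drop_genotypes, simulate_pedigree, simulate_phenotypes


def _cfg(**kw):
    base = dict(
        n_founders=10,
        n_generations=2,
        matings_per_generation=4,
        offspring_per_mating=2,
        n_chromosomes=2,
        chrom_length_mb=10.0,
        n_snps=40,
        n_qtl=10,
        founder_mode="independent",
        seed=1,
    )
    base.update(kw)
    return SimConfig(**base)


class TestPedigree:
    def test_minimal_mating_structure(self):
        # 2 founders, one generation of 3 offspring -> 5 animals, 3 full sibs
        ped = simulate_pedigree(
            _cfg(n_founders=2, n_generations=1, matings_per_generation=None,
                 offspring_per_mating=3)
        )
        assert ped.n == 5
        assert ped.is_founder.sum() == 2
        sibs = np.flatnonzero(~ped.is_founder)
        assert len(sibs) == 3
        assert len({(ped.sire[i], ped.dam[i]) for i in sibs}) == 1

    def test_parents_precede_offspring(self):
        ped = simulate_pedigree(_cfg(n_generations=3))
        pos = np.empty(ped.n, dtype=int)
        pos[ped.topological_order()] = np.arange(ped.n)
        for j in range(ped.n):
            for par in (ped.sire[j], ped.dam[j]):
                if par != UNKNOWN:
                    assert pos[par] < pos[j]
                    assert ped.generation[par] < ped.generation[j]

    def test_seed_determinism(self):
        a = simulate_pedigree(_cfg(seed=7))
        b = simulate_pedigree(_cfg(seed=7))
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())
        c = simulate_pedigree(_cfg(seed=8))
        assert not a.to_frame().equals(c.to_frame())

    def test_single_sex_founders_rejected(self):
        # one founder can never supply both a sire and a dam
        with pytest.raises(ValueError, match="at least 2 founders"):
            _cfg(n_founders=1)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            _cfg(n_generations=0)
        with pytest.raises(ValueError):
            _cfg(n_qtl=1000)  # exceeds n_snps
        with pytest.raises(ValueError):
            _cfg(target_h2=0.0)
        with pytest.raises(ValueError):
            _cfg(target_h2=1.0)


class TestGeneDropping:
    def test_zero_length_chromosome_no_recombination(self):
        cfg = _cfg(n_chromosomes=1, chrom_length_mb=0.0, n_snps=1, n_qtl=1)
        ped = simulate_pedigree(cfg)
        _, H = drop_genotypes(ped, cfg, return_haplotypes=True)
        for j in range(ped.n):
            s, d = ped.sire[j], ped.dam[j]
            if s == UNKNOWN:
                continue
            assert H[j, 0, 0] in H[s, 0, :]
            assert H[j, 0, 1] in H[d, 0, :]

    def test_mendelian_consistency(self, tiny_herd):
        ped, H = tiny_herd.pedigree, tiny_herd.haplotypes
        for j in range(ped.n):
            s, d = ped.sire[j], ped.dam[j]
            if s == UNKNOWN:
                continue
            from_sire = (H[j, :, 0] == H[s, :, 0]) | (H[j, :, 0] == H[s, :, 1])
            from_dam = (H[j, :, 1] == H[d, :, 0]) | (H[j, :, 1] == H[d, :, 1])
            assert from_sire.all() and from_dam.all()

    def test_dosage_is_haplotype_sum(self, tiny_herd):
        dos = tiny_herd.haplotypes.sum(axis=2).astype(float)
        obs = tiny_herd.genotypes.dosage
        mask = ~np.isnan(obs)
        assert np.array_equal(obs[mask], dos[mask])

    def test_close_pairs_in_higher_ld_than_far_pairs(self):
        # coalescent founders + gene dropping must yield distance-decaying r2
        for seed in (1, 2, 3):
            cfg = gsel.default_config(
                seed=seed, n_snps=300, n_chromosomes=2, chrom_length_mb=30.0,
                matings_per_generation=15,
            )
            herd = gsel.simulate_herd(cfg)
            pairs = gsel.pairwise_r2(herd.genotypes, max_distance_mb=None)
            d = pairs["distance_mb"]
            close = pairs.loc[d < 0.1, "r2"].mean()
            far = pairs.loc[d > 20.0, "r2"].mean()
            assert close > far

    def test_full_sib_genomic_relationship_near_half(self):
        # 100 unrelated founder pairs, 2 offspring each -> 100 full-sib pairs
        cfg = SimConfig(
            n_founders=200,
            n_generations=1,
            matings_per_generation=100,
            mating="monogamous",
            offspring_per_mating=2,
            n_chromosomes=5,
            chrom_length_mb=20.0,
            n_snps=500,
            n_qtl=50,
            founder_mode="independent",
            seed=9,
        )
        ped = simulate_pedigree(cfg)
        geno = drop_genotypes(ped, cfg)
        G = gsel.build_G(geno).values
        sib_vals = []
        by_parents = {}
        for j in np.flatnonzero(~ped.is_founder):
            by_parents.setdefault((ped.sire[j], ped.dam[j]), []).append(j)
        for sibs in by_parents.values():
            assert len(sibs) == 2
            sib_vals.append(G[sibs[0], sibs[1]])
        assert abs(np.mean(sib_vals) - 0.5) < 0.05

    def test_founder_G_diagonal_near_one_under_hwe(self):
        cfg = _cfg(n_founders=120, n_generations=1, n_snps=400, n_qtl=10,
                   matings_per_generation=1)
        ped = simulate_pedigree(cfg)
        geno = drop_genotypes(ped, cfg)
        founders = np.flatnonzero(ped.is_founder)
        G = gsel.build_G(geno.dosage[founders]).values
        assert abs(np.diag(G).mean() - 1.0) < 0.05
        off = G[~np.eye(len(G), dtype=bool)]
        assert abs(off.mean()) < 0.05

    def test_herd_seed_determinism(self):
        cfg = _cfg(seed=13)
        h1 = gsel.simulate_herd(cfg)
        h2 = gsel.simulate_herd(cfg)
        assert np.array_equal(h1.haplotypes, h2.haplotypes)
        pd.testing.assert_frame_equal(h1.phenotypes, h2.phenotypes)
        assert np.array_equal(h1.qtl_indices, h2.qtl_indices)


class TestPhenotypes:
    def test_true_bv_is_centered_dosage_times_effects(self, tiny_herd):
        dos = np.nan_to_num(tiny_herd.genotypes.dosage, nan=0.0)
        centered = dos[:, tiny_herd.qtl_indices]
        centered = centered - centered.mean(axis=0)
        expected = centered @ tiny_herd.qtl_effects
        assert np.allclose(expected, tiny_herd.true_breeding_values)

    def test_realized_h2_near_target(self, herd400):
        assert abs(herd400.realized_h2[0] - 0.30) < 0.05

    def test_high_h2_limit(self):
        cfg = _cfg(target_h2=0.999, n_founders=30, matings_per_generation=20,
                   offspring_per_mating=4, n_generations=2)
        herd = gsel.simulate_herd(cfg)
        # phenotype ~ mu + fixed + BV: residual variance negligible
        assert herd.sigma_e2[0] < 2e-3
        assert herd.realized_h2[0] > 0.99

    def test_null_genetics_variance_decomposition(self):
        cfg = _cfg(residual_sd=1.0, fixed_effect_sd=0.5, n_founders=60,
                   matings_per_generation=60, offspring_per_mating=4,
                   n_generations=2)
        ped = simulate_pedigree(cfg)
        bv = np.zeros((ped.n, 1))
        pheno, info = simulate_phenotypes(ped, bv, cfg)
        # var(y) ~ fixed-effect variance (two factors) + residual variance
        expected = 2 * cfg.fixed_effect_sd**2 + 1.0
        assert abs(pheno["trait1"].var() - expected) / expected < 0.30
        assert info["realized_h2"][0] == 0.0

    def test_zero_bv_requires_explicit_residual(self):
        cfg = _cfg()
        ped = simulate_pedigree(cfg)
        with pytest.raises(ValueError, match="residual_sd"):
            simulate_phenotypes(ped, np.zeros((ped.n, 1)), cfg)

    def test_ld_decay_monotone_in_bins(self, herd400):
        pairs = gsel.pairwise_r2(herd400.genotypes, max_distance_mb=5.0)
        prof = gsel.ld_decay_profile(
            pairs, bin_edges_mb=(0.0, 0.1, 0.5, 2.0, 5.0)
        ).profile
        means = prof["mean_r2"].to_numpy()
        assert np.all(np.diff(means) <= 0)
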