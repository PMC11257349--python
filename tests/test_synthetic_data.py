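import numpy as np
import pytest

from neowscan.io_formats import HET, HOM_ALT, HOM_REF, MISSING
from neowscan.site_filter import candidate_fusion_sites
from neowscan.synthetic_data import (
    FusionEvent,
    SimConfig,
    simulate_background_panel,
    simulate_dataset,
    simulate_fused_lineage,
    simulate_hic,
    simulate_hic_male,
)

from oracles import hudson_fst_over_sites


def _small_cfg(**kw):
    base = dict(
        n_chromosomes=2,
        chrom_length_bp=300_000,
        n_background_sites_per_chrom=3_000,
        samples_per_species_per_sex=4,
        fusion_events=(FusionEvent("chr1", 40_000_000.0),),
        speciation_age_generations=10_000_000.0,
        p_degenerate=0.0,
        seed=1,
    )
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(balding_nichols_theta=0.0),
            dict(balding_nichols_theta=1.0),
            dict(p_degenerate=1.5),
            dict(mu=-1.0),
            dict(n_background_sites_per_chrom=0),
            dict(speciation_age_generations=5e7),  # postdates the fusion
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            _small_cfg(**kw)

    def test_fusion_on_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            _small_cfg(fusion_events=(FusionEvent("chr9", 4e7),))


class TestDeterminism:
    def test_same_seed_gives_byte_identical_dataset(self):
        d1 = simulate_dataset(_small_cfg(seed=9, p_degenerate=0.3, phase_switch_rate=0.01))
        d2 = simulate_dataset(_small_cfg(seed=9, p_degenerate=0.3, phase_switch_rate=0.01))
        assert d1.table.gt.tobytes() == d2.table.gt.tobytes()
        assert d1.table.depth.tobytes() == d2.table.depth.tobytes()
        assert d1.table.haplotypes.tobytes() == d2.table.haplotypes.tobytes()
        assert np.array_equal(d1.table.pos, d2.table.pos)
        assert d1.truth.degenerate_segments == d2.truth.degenerate_segments

    def test_panel_reproducible_from_seed(self):
        cfg = _small_cfg(seed=4)
        p1 = simulate_background_panel(cfg, "chr1", rng=np.random.default_rng(4))
        p2 = simulate_background_panel(cfg, "chr1", rng=np.random.default_rng(4))
        assert np.array_equal(p1.positions, p2.positions)
        assert all(np.array_equal(p1.haplotypes[s], p2.haplotypes[s]) for s in p1.haplotypes)


class TestBackgroundPanel:
    def test_theta_near_zero_gives_near_zero_fst(self):
        cfg = _small_cfg(balding_nichols_theta=1e-6, n_background_sites_per_chrom=20_000)
        panel = simulate_background_panel(cfg, "chr1", rng=np.random.default_rng(0), pool_size=20)
        fst = hudson_fst_over_sites(panel.haplotypes["sp1"].T, panel.haplotypes["sp2"].T)
        assert abs(fst) < 0.01

    def test_fst_within_replicate_oracle_band(self):
        # theta = 0.3, 20 + 20 haplotypes: compare the panel's genome-wide
        # Hudson FST with brute-force replicate simulations of the same model
        theta, n_sites, n_haps = 0.3, 10_000, 20
        rng = np.random.default_rng(123)
        reps = []
        for _ in range(300):
            p0 = np.clip(rng.beta(0.5, 0.5, n_sites), 1e-3, 1 - 1e-3)
            scale = (1 - theta) / theta
            pa = rng.beta(p0 * scale, (1 - p0) * scale)
            pb = rng.beta(p0 * scale, (1 - p0) * scale)
            ha = (rng.random((n_sites, n_haps)) < pa[:, None]).astype(int)
            hb = (rng.random((n_sites, n_haps)) < pb[:, None]).astype(int)
            reps.append(hudson_fst_over_sites(ha, hb))
        cfg = _small_cfg(balding_nichols_theta=0.3, n_background_sites_per_chrom=n_sites)
        panel = simulate_background_panel(cfg, "chr1", rng=np.random.default_rng(7), pool_size=n_haps)
        got = hudson_fst_over_sites(panel.haplotypes["sp1"].T, panel.haplotypes["sp2"].T)
        assert abs(got - np.mean(reps)) < 4 * np.std(reps)

    def test_zero_sites_and_bad_theta_rejected(self):
        cfg = _small_cfg()
        with pytest.raises(ValueError):
            simulate_background_panel(cfg, "chr1", n_sites=0)


class TestFusedLineage:
    def test_zero_ages_leave_founder_unchanged(self):
        cfg = _small_cfg(fusion_events=(), speciation_age_generations=0.0)
        panel = simulate_background_panel(cfg, "chr1", rng=np.random.default_rng(1))
        lin = simulate_fused_lineage(panel, 0.0, 0.0, cfg.mu, 300_000, ["sp1", "sp2"], np.random.default_rng(2))
        assert lin.shared_pos.size == 0
        assert all(v.size == 0 for v in lin.private_pos.values())
        pool = panel.haplotypes[lin.founder_species]
        assert any(np.array_equal(h, lin.founder_alleles) for h in pool)

    def test_negative_ages_rejected(self):
        cfg = _small_cfg()
        panel = simulate_background_panel(cfg, "chr1", rng=np.random.default_rng(1))
        with pytest.raises(ValueError):
            simulate_fused_lineage(panel, -1.0, 0.0, cfg.mu, 100, ["sp1"], np.random.default_rng(0))

    def test_shared_mutation_count_matches_poisson_mean(self):
        # mu 2.9e-9, T_f 2e6, T_s 0, L 1e7: expected mu*T_f*L = 58,000
        mu, t_f, length = 2.9e-9, 2e6, int(1e7)
        cfg = _small_cfg(chrom_length_bp=length, n_background_sites_per_chrom=100)
        panel = simulate_background_panel(cfg, "chr1", rng=np.random.default_rng(5))
        rng = np.random.default_rng(6)
        counts = [
            simulate_fused_lineage(panel, t_f, 0.0, mu, length, ["sp1"], rng).shared_pos.size
            for _ in range(300)
        ]
        expect = mu * t_f * length
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expect) < 3 * se

    def test_shared_sites_het_in_both_species_private_in_one(self, tiny_sim):
        table, truth, sheet = tiny_sim.table, tiny_sim.truth, tiny_sim.sheet
        shared = truth.shared_private_pos["chr1"]
        on1 = table.chrom == "chr1"
        f1 = table.sample_indices(sheet.select(sex="female", species="sp1"))
        f2 = table.sample_indices(sheet.select(sex="female", species="sp2"))
        idx = np.flatnonzero(on1 & np.isin(table.pos, shared))
        assert idx.size > 0
        assert (table.gt[np.ix_(idx, f1)] == HET).all()
        assert (table.gt[np.ix_(idx, f2)] == HET).all()
        priv1 = truth.species_private_pos["chr1"]["sp1"]
        idx1 = np.flatnonzero(on1 & np.isin(table.pos, priv1))
        assert idx1.size > 0
        assert (table.gt[np.ix_(idx1, f1)] == HET).all()
        assert (table.gt[np.ix_(idx1, f2)] == HOM_REF).all()


class TestSimulateDataset:
    def test_row_conservation_and_biallelic_sites(self, tiny_sim):
        cfg, truth, table = tiny_sim.config, tiny_sim.truth, tiny_sim.table
        n_private = sum(v.size for v in truth.shared_private_pos.values()) + sum(
            v.size for d in truth.species_private_pos.values() for v in d.values()
        )
        assert table.n_sites == cfg.n_chromosomes * cfg.n_background_sites_per_chrom + n_private
        table.validate_sorted()

    def test_full_degeneration_silences_female_heterozygosity_and_halves_depth(self):
        ds = simulate_dataset(_small_cfg(p_degenerate=1.0, seed=3))
        on = ds.table.chrom == "chr1"
        fem = ds.table.sample_indices(ds.sheet.select(sex="female"))
        mal = ds.table.sample_indices(ds.sheet.select(sex="male"))
        # with the whole clade fused and every segment degenerated, females
        # report only the background haplotype: homozygous everywhere
        assert not (ds.table.gt[np.ix_(np.flatnonzero(on), fem)] == HET).any()
        f_depth = ds.table.depth[np.ix_(np.flatnonzero(on), fem)].mean()
        m_depth = ds.table.depth[np.ix_(np.flatnonzero(on), mal)].mean()
        assert f_depth == pytest.approx(m_depth / 2, rel=0.05)

    def test_w_scaffold_males_have_exactly_zero_depth(self):
        ds = simulate_dataset(
            _small_cfg(n_w_scaffolds=1, w_scaffold_length_bp=50_000, seed=8)
        )
        on = ds.table.chrom == "W_scaf1"
        mal = ds.table.sample_indices(ds.sheet.select(sex="male"))
        fem = ds.table.sample_indices(ds.sheet.select(sex="female"))
        assert (ds.table.depth[np.ix_(np.flatnonzero(on), mal)] == 0).all()
        assert (ds.table.gt[np.ix_(np.flatnonzero(on), mal)] == MISSING).all()
        # female dosage: mean depth within 3 SE of lambda / 2
        d = ds.table.depth[np.ix_(np.flatnonzero(on), fem)].astype(float)
        se = d.std(ddof=1) / np.sqrt(d.size)
        assert abs(d.mean() - ds.config.depth_lambda / 2) < 3 * se

    def test_female_z_emitted_homozygous_at_half_depth(self):
        ds = simulate_dataset(_small_cfg(include_z=True, z_length_bp=300_000, seed=12))
        on = np.flatnonzero(ds.table.chrom == "chrZ")
        fem = ds.table.sample_indices(ds.sheet.select(sex="female"))
        gt_f = ds.table.gt[np.ix_(on, fem)]
        assert np.isin(gt_f, [HOM_REF, HOM_ALT]).all()
        d = ds.table.depth[np.ix_(on, fem)].astype(float)
        assert d.mean() == pytest.approx(ds.config.depth_lambda / 2, rel=0.05)

    def test_private_shared_sites_outside_dropout_pass_candidate_criteria(self):
        ds = simulate_dataset(_small_cfg(p_degenerate=0.3, seed=21))
        report = candidate_fusion_sites(ds.table, ds.sheet, ds.config.fused_clade)
        passing = set(zip(ds.table.chrom[report.site_index], ds.table.pos[report.site_index]))
        shared = ds.truth.shared_private_pos["chr1"]
        deg = ds.truth.degenerate_mask("chr1", shared)
        expected = {("chr1", int(p)) for p in shared[~deg]}
        assert expected, "simulation produced no clean shared private sites"
        assert expected <= passing

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            _small_cfg(samples_per_species_per_sex=0)

    def test_genotypes_consistent_with_emitted_haplotypes_without_switch_errors(self, tiny_sim):
        t = tiny_sim.table
        called = t.gt != MISSING
        hap_sum = t.haplotypes[:, :, 0] + t.haplotypes[:, :, 1]
        assert np.array_equal(t.gt[called], hap_sum[called].astype(np.int8))


class TestSimulatedHic:
    def test_unfused_haplotype_with_zero_trans_noise_has_no_cross_contacts(self):
        cfg = _small_cfg(hic_trans_noise=0.0)
        ds = simulate_dataset(cfg)
        cm = simulate_hic(cfg, ds.truth, "unfused", np.random.default_rng(0))
        chrom = cm.bins["chrom"].to_numpy()
        cross = cm.matrix[np.ix_(chrom == "chr1", chrom == "chr2")]
        assert (cross == 0).all()

    def test_invalid_gamma_and_haplotype_rejected(self):
        ds = simulate_dataset(_small_cfg())
        bad = _small_cfg(hic_gamma=-1.0)
        with pytest.raises(ValueError):
            simulate_hic(bad, ds.truth, "unfused", np.random.default_rng(0))
        with pytest.raises(ValueError):
            simulate_hic(_small_cfg(), ds.truth, "maternal", np.random.default_rng(0))

    def test_junction_contacts_decay_with_distance_in_expectation(self):
        cfg = _small_cfg(
            fusion_events=(FusionEvent("chr1", 4e7), FusionEvent("chr2", 4e7)),
            speciation_age_generations=1e7,
            hic_bin_bp=50_000,
            hic_trans_noise=0.0,
        )
        ds = simulate_dataset(cfg)
        rng = np.random.default_rng(3)
        acc = None
        for _ in range(200):
            cm = simulate_hic(cfg, ds.truth, "fused", rng)
            chrom = cm.bins["chrom"].to_numpy()
            cross = cm.matrix[np.ix_(chrom == "chr1", chrom == "chr2")]
            acc = cross if acc is None else acc + cross
        # mean contacts between the last chr1 bin and successive chr2 bins
        # fall off monotonically with distance from the junction
        profile = acc[-1, :] / 200.0
        assert np.all(np.diff(profile) < 0)

    def test_male_matrix_shows_no_fused_pair_enrichment(self):
        from neowscan.hic import interchrom_enrichment

        cfg = _small_cfg(
            fusion_events=(FusionEvent("chr1", 4e7), FusionEvent("chr2", 4e7)),
            speciation_age_generations=1e7,
        )
        ds = simulate_dataset(cfg)
        cm = simulate_hic_male(cfg, ds.truth, np.random.default_rng(5))
        pairs = interchrom_enrichment(cm)
        assert all(not p.fused for p in pairs)
        assert all(abs(p.enrichment - 1) < 0.25 for p in pairs)
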