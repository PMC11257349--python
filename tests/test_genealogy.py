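import numpy as np
import pandas as pd
import pytest

from neowscan.genealogy import (
    FULL,
    MIXED,
    PARTIAL,
    build_local_tree,
    female_clade_verdict,
    hamming_distance_matrix,
    scan_candidate_sites,
)
from neowscan.io_formats import GenotypeTable, SampleSheet
from neowscan.site_filter import candidate_fusion_sites, subsample_every_kth

from oracles import min_evolution_topology


def _table_from_haps(haps, samples, chrom="chr1"):
    haps = np.asarray(haps, dtype=np.int8)  # (sites, samples, 2)
    gt = (haps[:, :, 0] + haps[:, :, 1]).astype(np.int8)
    n = haps.shape[0]
    return GenotypeTable(
        chrom=np.array([chrom] * n, dtype=object),
        pos=np.arange(1, n + 1) * 100,
        ref=np.full(n, "A", dtype=object),
        alt=np.full(n, "G", dtype=object),
        qual=np.full(n, 60.0),
        samples=list(samples),
        gt=gt,
        depth=np.full(gt.shape, 30, dtype=np.int32),
        haplotypes=haps,
    )


def _sheet(samples, sexes, species):
    return SampleSheet(
        pd.DataFrame({"sample": samples, "sex": sexes, "species": species, "population": species})
    )


class TestBuildLocalTree:
    def test_recovers_additive_four_leaf_topology(self):
        # sites: 12 private to {a, b} as a cherry is not needed -- make
        # {c, d} share a block of derived sites; a and b each carry a couple
        # of private ones
        n_haps = 4
        sites = []
        for _ in range(12):
            sites.append([0, 0, 1, 1])  # c,d cherry
        for _ in range(3):
            sites.append([1, 0, 0, 0])
        for _ in range(3):
            sites.append([0, 1, 0, 0])
        for _ in range(12):
            sites.append([0, 0, 0, 0])
        haps = np.array(sites, dtype=np.int8)
        labels = ["a", "b", "c", "d"]
        tree = build_local_tree(haps, labels, focal_index=10, flank_snps=15)
        assert frozenset({"c", "d"}) in tree.bipartitions() or frozenset({"a", "b"}) in tree.bipartitions()

    def test_identical_haplotypes_give_zero_length_star(self):
        haps = np.zeros((25, 5), dtype=np.int8)
        tree = build_local_tree(haps, list("abcde"), focal_index=12, flank_snps=12)
        lengths = [n.length for n in tree.tree.traverse() if n.length is not None]
        assert all(l == 0 for l in lengths)

    def test_too_few_haplotypes_or_flank_rejected(self):
        haps = np.zeros((25, 3), dtype=np.int8)
        with pytest.raises(ValueError):
            build_local_tree(haps, list("abc"), 10, flank_snps=12)
        with pytest.raises(ValueError):
            build_local_tree(np.zeros((25, 4), np.int8), list("abcd"), 10, flank_snps=5)

    def test_nj_matches_exhaustive_minimum_evolution_on_noisy_additive_data(self):
        # random 6-leaf additive trees + small noise: NJ should recover the
        # exhaustive-search minimum-evolution topology nearly always
        from neowscan.genealogy import nj_from_distances

        rng = np.random.default_rng(42)
        wins = 0
        trials = 60
        for _ in range(trials):
            # random additive tree: random topology by sequential insertion
            n = 6
            edges = {(0, 100): rng.uniform(0.2, 1), (1, 100): rng.uniform(0.2, 1), (2, 100): rng.uniform(0.2, 1)}
            next_internal = 101
            for leaf in range(3, n):
                e = list(edges)[rng.integers(len(edges))]
                w = edges.pop(e)
                u, v = e
                m = next_internal
                next_internal += 1
                s = rng.uniform(0.2, 0.8)
                edges[(u, m)] = w * s
                edges[(v, m)] = w * (1 - s)
                edges[(leaf, m)] = rng.uniform(0.2, 1)
            # path distances
            import networkx as nx

            g = nx.Graph()
            for (u, v), w in edges.items():
                g.add_edge(u, v, weight=w)
            dist = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    dist[i, j] = dist[j, i] = nx.shortest_path_length(g, i, j, weight="weight")
            dist += rng.uniform(-0.02, 0.02, size=dist.shape)
            dist = (dist + dist.T) / 2
            np.fill_diagonal(dist, 0)
            want = min_evolution_topology(dist)
            tree = nj_from_distances(dist, [str(i) for i in range(n)])
            got = set()
            for node in tree.non_tips(include_self=False):
                s = frozenset(int(t.name) for t in node.tips())
                if 2 <= len(s) <= n - 2:
                    got.add(s if 0 in s else frozenset(set(range(n)) - s))
            if frozenset(got) == want:
                wins += 1
        assert wins >= round(0.95 * trials)

    def test_hamming_distances_ignore_missing(self):
        # columns are haplotypes: h0=[0,1,0,1], h1=[1,1,0,0], h2=[-1,1,0,1]
        haps = np.array([[0, 1, -1], [1, 1, 1], [0, 0, 0], [1, 0, 1]], dtype=np.int8)
        d = hamming_distance_matrix(haps)
        # h0 vs h1: 4 co-called sites, mismatches at sites 0 and 3 -> 0.5
        assert d[0, 1] == pytest.approx(0.5)
        # h0 vs h2: site 0 missing in h2 -> 3 comparisons, 0 mismatches
        assert d[0, 2] == pytest.approx(0.0)
        # h1 vs h2: 3 comparisons (sites 1-3), mismatch at site 3 -> 1/3
        assert d[1, 2] == pytest.approx(1 / 3)


def _clade_case():
    """2 species x (2F + 1M); site 0 shared-private, site 1 spA-private,
    site 2 carried by a male, plus background sites for tree context."""
    samples = ["A_F1", "A_F2", "A_M1", "B_F1", "B_F2", "B_M1"]
    sexes = ["female", "female", "male", "female", "female", "male"]
    species = ["spA"] * 3 + ["spB"] * 3
    rng = np.random.default_rng(0)
    n_bg = 30
    haps = np.zeros((n_bg + 3, 6, 2), dtype=np.int8)
    haps[:n_bg] = (rng.random((n_bg, 6, 2)) < 0.25).astype(np.int8)
    # focal sites appended at the end; females carry the derived allele on
    # haplotype 0
    haps[n_bg, [0, 1, 3, 4], 0] = 1  # shared: all clade females
    haps[n_bg + 1, [0, 1], 0] = 1  # spA females only
    haps[n_bg + 2, [0, 1, 3, 4], 0] = 1
    haps[n_bg + 2, 2, 0] = 1  # male carries it too
    return _table_from_haps(haps, samples), _sheet(samples, sexes, species), n_bg


class TestFemaleCladeVerdict:
    def test_allele_mode_verdicts_follow_construction(self):
        table, sheet, n_bg = _clade_case()
        clade = ["spA", "spB"]
        assert female_clade_verdict(table, sheet, clade, n_bg).verdict == FULL
        v = female_clade_verdict(table, sheet, clade, n_bg + 1)
        assert v.verdict == PARTIAL and v.species_with_pattern == ("spA",)
        assert female_clade_verdict(table, sheet, clade, n_bg + 2).verdict == MIXED

    def test_verdict_invariant_to_sample_order(self):
        table, sheet, n_bg = _clade_case()
        perm = [3, 0, 5, 2, 4, 1]
        table2 = GenotypeTable(
            chrom=table.chrom,
            pos=table.pos,
            ref=table.ref,
            alt=table.alt,
            qual=table.qual,
            samples=[table.samples[i] for i in perm],
            gt=table.gt[:, perm],
            depth=table.depth[:, perm],
            haplotypes=table.haplotypes[:, perm],
        )
        sheet2 = SampleSheet(sheet.frame.iloc[perm[::-1]].reset_index(drop=True))
        for focal in (n_bg, n_bg + 1, n_bg + 2):
            assert (
                female_clade_verdict(table, sheet, ["spA", "spB"], focal).verdict
                == female_clade_verdict(table2, sheet2, ["spA", "spB"], focal).verdict
            )

    def test_tree_mode_finds_full_pattern_on_simulated_fusion(self, tiny_sim):
        table, sheet, truth = tiny_sim.table, tiny_sim.sheet, tiny_sim.truth
        shared = truth.shared_private_pos["chr1"]
        idx = int(np.flatnonzero((table.chrom == "chr1") & np.isin(table.pos, shared))[5])
        v = female_clade_verdict(table, sheet, ("sp1", "sp2"), idx, mode="tree", flank_snps=40)
        assert v.verdict == FULL

    def test_tree_mode_requires_phased_haplotypes(self):
        table, sheet, n_bg = _clade_case()
        table.haplotypes = None
        with pytest.raises(ValueError, match="allele"):
            female_clade_verdict(table, sheet, ["spA", "spB"], n_bg, mode="tree")

    def test_allele_mode_works_from_genotypes_alone(self):
        table, sheet, n_bg = _clade_case()
        table.haplotypes = None
        assert female_clade_verdict(table, sheet, ["spA", "spB"], n_bg).verdict == FULL
        v = female_clade_verdict(table, sheet, ["spA", "spB"], n_bg + 1)
        assert v.verdict == PARTIAL and v.species_with_pattern == ("spA",)


class TestScanCandidateSites:
    def test_all_full_sites_summarize_to_unit_fraction_with_dispersion(self, tiny_sim):
        table, sheet, truth = tiny_sim.table, tiny_sim.sheet, tiny_sim.truth
        report = subsample_every_kth(
            candidate_fusion_sites(table, sheet, ("sp1", "sp2")), 1
        )
        summary = scan_candidate_sites(
            table, report, sheet, ("sp1", "sp2"), chrom="chr1", chrom_length=500_000
        )
        # candidate sites include species-private ones (partial), but every
        # shared private site must be full
        shared = set(truth.shared_private_pos["chr1"].tolist())
        verd = summary.verdicts
        on_shared = verd[verd["pos"].isin(shared)]
        assert (on_shared["verdict"] == FULL).all()
        assert 0 < summary.dispersion <= 1.0

    def test_empty_subsample_yields_nan_summary(self):
        table, sheet, _ = _clade_case()
        report = candidate_fusion_sites(table, sheet, ["spA", "spB"])
        report.subsample_index = np.array([], dtype=np.int64)
        summary = scan_candidate_sites(table, report, sheet, ["spA", "spB"])
        assert np.isnan(summary.fractions[FULL])
        assert len(summary.verdicts) == 0
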