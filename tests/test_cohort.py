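"""Cohort analytics: merging, windows, correlation, saturation, profiles,
embeddings."""

import numpy as np
import pandas as pd
import pytest

import msrrbs as M
from msrrbs.calling import MethylationCallSet
from msrrbs.cohort import (downsample_saturation, element_detection_rate,
                           embed_cells, merge_callsets, metagene_profile,
                           pairwise_correlation, window_methylation)
from msrrbs.genome import ElementSet, Interval


def make_callset(sites, cell_id="c"):
    cs = MethylationCallSet(cell_id)
    for key, counts in sites.items():
        cs.cpg[key] = list(counts)
    return cs


class TestMerge:
    def test_single_input_identity(self):
        cs = make_callset({("t", 1): (3, 1)})
        assert merge_callsets([cs]).cpg == cs.cpg

    def test_disjoint_union(self):
        a = make_callset({("t", 1): (3, 1)})
        b = make_callset({("t", 9): (0, 2)})
        m = merge_callsets([a, b])
        assert m.cpg == {("t", 1): [3, 1], ("t", 9): [0, 2]}

    def test_shared_site_additive(self):
        a = make_callset({("t", 1): (3, 1)})
        b = make_callset({("t", 1): (1, 1)})
        m = merge_callsets([a, b])
        assert m.cpg[("t", 1)] == [4, 2]
        assert m.level(("t", 1)) == pytest.approx(2 / 3)

    def test_associative_and_commutative(self, rng):
        css = []
        for i in range(3):
            css.append(make_callset(
                {("t", int(rng.integers(0, 50))): (int(rng.integers(0, 5)),
                                                   int(rng.integers(1, 5)))
                 for _ in range(20)}, cell_id=f"c{i}"))
        a, b, c = css
        left = merge_callsets([merge_callsets([a, b]), c])
        right = merge_callsets([a, merge_callsets([b, c])])
        perm = merge_callsets([c, a, b])
        assert left.cpg == right.cpg == perm.cpg


class TestWindows:
    def test_single_site_level(self):
        cs = make_callset({("t", 10): (3, 1)})
        mat = window_methylation([cs], 200, {"t": 1000})
        assert mat.loc["c", "t:0-200"] == 0.75

    def test_coverage_weighted_not_site_averaged(self):
        cs = make_callset({("t", 10): (1, 0), ("t", 20): (0, 3)})
        mat = window_methylation([cs], 200, {"t": 400})
        assert mat.loc["c", "t:0-200"] == 0.25

    def test_empty_window_missing(self):
        cs = make_callset({("t", 10): (1, 1)})
        mat = window_methylation([cs], 100, {"t": 300})
        assert np.isnan(mat.loc["c", "t:100-200"])

    def test_merged_equals_count_weighted_combination(self, callsets,
                                                      small_genome):
        cells = list(callsets.values())
        merged = merge_callsets(cells)
        wm = window_methylation([merged], 200, small_genome.lengths)
        per_cell = window_methylation(cells, 200, small_genome.lengths)
        # recombine member windows by their total counts
        tot = {}
        meth = {}
        for cs in cells:
            for (chrom, pos), (m, u) in cs.cpg.items():
                w = f"{chrom}:{(pos // 200) * 200}-" \
                    f"{min((pos // 200 + 1) * 200, small_genome.lengths[chrom])}"
                meth[w] = meth.get(w, 0) + m
                tot[w] = tot.get(w, 0) + m + u
        for w, t in tot.items():
            assert wm.loc["merged", w] == pytest.approx(meth[w] / t)


class TestCorrelation:
    def test_self_correlation_unity(self):
        a = make_callset({("t", i): (i % 3, 2) for i in range(10)}, "a")
        b = make_callset({("t", i): (i % 3, 2) for i in range(10)}, "b")
        mat = pairwise_correlation([a, b])
        assert mat.loc["a", "b"] == pytest.approx(1.0)

    def test_anticorrelated_levels(self):
        a = make_callset({("t", i): ((0, 1) if i % 2 else (1, 0))
                          for i in range(4)}, "a")
        b = make_callset({("t", i): ((1, 0) if i % 2 else (0, 1))
                          for i in range(4)}, "b")
        assert pairwise_correlation([a, b]).loc["a", "b"] == pytest.approx(-1.0)

    def test_fewer_than_three_shared_sites_missing(self):
        a = make_callset({("t", 0): (1, 0), ("t", 1): (0, 1)}, "a")
        b = make_callset({("t", 0): (1, 0), ("t", 1): (1, 0)}, "b")
        assert np.isnan(pairwise_correlation([a, b]).loc["a", "b"])

    def test_min_cov_restricts_sites(self):
        a = make_callset({("t", i): (1, 0) if i < 3 else (5, 5)
                          for i in range(6)}, "a")
        b = make_callset({("t", i): (1, 0) if i < 3 else (5, 5)
                          for i in range(6)}, "b")
        assert np.isnan(pairwise_correlation([a, b], min_cov=5).loc["a", "b"]) \
            or pairwise_correlation([a, b], min_cov=5).loc["a", "b"] == 1.0

    def test_single_cells_less_correlated_than_pseudobulk_vs_truth(self, rng):
        """Sampling noise: cell-cell r < pseudobulk-truth r from one archetype."""
        probs = {("t", i * 10): float(p)
                 for i, p in enumerate(rng.beta(0.3, 0.3, size=400))}
        cells = [M.sample_callset(probs, 8, rng, cell_id=f"c{i}")
                 for i in range(8)]
        bulk = merge_callsets(cells)
        truth_cs = make_callset(
            {k: (int(round(p * 1000)), int(round((1 - p) * 1000)))
             for k, p in probs.items()}, "truth")
        r_bulk = pairwise_correlation([bulk, truth_cs]).loc["merged", "truth"]
        cc = pairwise_correlation(cells)
        vals = cc.to_numpy()[np.triu_indices(8, 1)]
        assert np.nanmean(vals) < r_bulk


class TestDetectionAndSaturation:
    def test_detection_rates(self):
        elements = ElementSet("CGI", [Interval("t", 0, 100),
                                      Interval("t", 200, 300)])
        cs = make_callset({("t", 50): (1, 0)})
        assert element_detection_rate(cs, elements) == (1, 0.5)
        cs2 = make_callset({("t", 50): (1, 0), ("t", 250): (0, 1)})
        assert element_detection_rate(cs2, elements) == (2, 1.0)
        empty = make_callset({("x", 5): (1, 0)})
        assert element_detection_rate(empty, elements) == (0, 0.0)

    def test_single_covered_cpg_counts_as_detected(self):
        elements = ElementSet("CGI", [Interval("t", 0, 100)])
        cs = make_callset({("t", 99): (0, 1)})
        assert element_detection_rate(cs, elements)[0] == 1

    def test_empty_elements_rejected(self):
        with pytest.raises(ValueError):
            element_detection_rate(make_callset({("t", 0): (1, 0)}),
                                   ElementSet("CGI", []))

    def test_saturation_full_depth_equals_exhaustive(self, aligned_pool,
                                                     catalog, cpg_index, cgis):
        aps = [ap for aps in aligned_pool.values() for ap in aps][:600]
        full_cs = M.pileup_calls(aps, catalog, cpg_index)
        curve = downsample_saturation(aps, catalog, cpg_index,
                                      depths=[0, 200, len(aps)], elements=cgis,
                                      seed=1, replicates=3)
        assert curve.iloc[0].cpg_sites == 0
        assert curve.iloc[-1].cpg_sites == full_cs.n_sites()
        assert curve.iloc[-1].elements == \
            element_detection_rate(full_cs, cgis)[0]

    def test_saturation_monotone_in_mean(self, aligned_pool, catalog,
                                         cpg_index, cgis):
        aps = [ap for aps in aligned_pool.values() for ap in aps][:600]
        curve = downsample_saturation(aps, catalog, cpg_index,
                                      depths=[50, 150, 300, 600],
                                      elements=cgis, seed=2, replicates=5)
        assert (np.diff(curve.cpg_sites) >= 0).all()
        assert (np.diff(curve.elements) >= 0).all()

    def test_excess_depth_clipped_with_warning(self, aligned_pool, catalog,
                                               cpg_index, cgis):
        aps = [ap for aps in aligned_pool.values() for ap in aps][:50]
        with pytest.warns(UserWarning):
            curve = downsample_saturation(aps, catalog, cpg_index,
                                          depths=[10 ** 6], elements=cgis,
                                          seed=3, replicates=1)
        assert curve.iloc[0].depth == 50


class TestMetagene:
    def test_uniform_methylation_flat_profile(self):
        cs = make_callset({("t", i): (1, 1) for i in range(0, 30000, 37)})
        genes = ElementSet("gene", [Interval("t", 8000, 16000, "+")])
        prof = metagene_profile(cs, genes, flank=5000, body_bins=10,
                                flank_bins=5)
        observed = prof[~np.isnan(prof)]
        assert np.allclose(observed, 0.5)

    def test_minus_strand_orientation(self):
        """Methylation only downstream of a minus-strand TSS lands in the body."""
        genes = ElementSet("gene", [Interval("t", 10000, 14000, "-")])
        # minus-strand gene: TSS at 14000, body runs 14000 -> 10000
        cs = make_callset({("t", p): (1, 0) for p in range(13000, 13900, 50)})
        prof = metagene_profile(cs, genes, flank=2000, body_bins=8,
                                flank_bins=4)
        body = prof[4:12]
        flanks = np.concatenate([prof[:4], prof[12:]])
        assert np.nansum(body) > 0
        assert np.all(np.isnan(flanks))
        # sites near the minus-strand TSS map to early body bins
        assert not np.isnan(body[0]) or not np.isnan(body[1])

    def test_single_site_single_bin(self):
        genes = ElementSet("gene", [Interval("t", 1000, 2000, "+")])
        cs = make_callset({("t", 1500): (1, 0)})
        prof = metagene_profile(cs, genes, flank=500, body_bins=4,
                                flank_bins=2)
        assert np.sum(~np.isnan(prof)) == 1

    def test_no_genes_rejected(self):
        with pytest.raises(ValueError):
            metagene_profile(make_callset({("t", 0): (1, 0)}),
                             ElementSet("gene", []))


@pytest.fixture(scope="module")
def two_archetype_matrix():
    rng = np.random.default_rng(3)
    probs_a = {("t", i * 50): float(p)
               for i, p in enumerate(rng.beta(2, 8, size=300))}
    probs_b = {k: 1 - v for k, v in probs_a.items()}
    cells = []
    for i in range(8):
        cells.append(M.sample_callset(probs_a, 10, rng, cell_id=f"a{i}"))
    for i in range(8):
        cells.append(M.sample_callset(probs_b, 10, rng, cell_id=f"b{i}"))
    return window_methylation(cells, 200, {"t": 16000})


class TestEmbedding:
    @pytest.mark.parametrize("method", ["pca", "tsne", "mds"])
    def test_separates_archetypes(self, two_archetype_matrix, method):
        from sklearn.cluster import KMeans
        from sklearn.metrics import adjusted_rand_score
        coords = embed_cells(two_archetype_matrix, method=method, seed=1)
        labels = KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(
            coords.to_numpy())
        truth = [0] * 8 + [1] * 8
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_deterministic(self, two_archetype_matrix):
        a = embed_cells(two_archetype_matrix, method="tsne", seed=5)
        b = embed_cells(two_archetype_matrix, method="tsne", seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_identical_cells_collapse(self):
        cs = make_callset({("t", i * 10): (1, 1) for i in range(100)})
        cells = [make_callset(dict(cs.cpg), f"c{i}") for i in range(5)]
        mat = window_methylation(cells, 100, {"t": 1000})
        coords = embed_cells(mat, method="pca", seed=0)
        spread = np.ptp(coords.to_numpy())
        assert spread < 1e-8

    def test_too_few_cells_rejected(self):
        mat = pd.DataFrame(np.ones((2, 4)))
        with pytest.raises(ValueError):
            embed_cells(mat, method="pca")
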