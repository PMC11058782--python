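import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gbmstate import ExpressionMatrix
from gbmstate.datatypes import EnrichmentResult
from gbmstate.signatures import (
    CALL_DOWN,
    CALL_NO_CHANGE,
    CALL_UP,
    classify_paired_enrichment,
    common_upregulated,
    derive_cluster_markers,
    enrichment_score,
    preranked_enrichment,
    preranked_enrichment_batch,
    proteomic_state_scores,
    select_top_signature,
)


def brute_force_es(stats_sorted, hit_idx, weight_exp, tie_tol=1e-9):
    """Independent running-sum enumeration over every rank position."""
    n = len(stats_sorted)
    hit = np.zeros(n, bool)
    hit[list(hit_idx)] = True
    nh = hit.sum()
    w = np.abs(stats_sorted) ** weight_exp
    wsum = w[hit].sum()
    run, lo, hi = 0.0, 0.0, 0.0
    for i in range(n):
        run += w[i] / wsum if hit[i] else -1.0 / (n - nh)
        hi, lo = max(hi, run), min(lo, run)
    return hi if hi >= -lo - tie_tol else lo


@pytest.fixture(scope="module")
def planted():
    from gbmstate import SimulationConfig, gen_state_counts
    from gbmstate.preprocess import lognormalize

    config = SimulationConfig(
        n_cells=600, n_genes=500, marker_effect=1.5, seed=31,
        state_proportions={"NPC": 0.25, "OPC": 0.25, "AC": 0.25, "MES": 0.25, "HYBRID": 0.0},
    )
    matrix, meta, catalog, truth = gen_state_counts(config)
    ln = lognormalize(matrix)
    labels = truth.cell_states
    return ln, labels, catalog


class TestClusterMarkers:
    def test_planted_markers_top_of_list(self, planted):
        ln, labels, catalog = planted
        markers = derive_cluster_markers(ln, labels, min_lfc=0.5, min_pct=0.5)
        for state in ("NPC", "MES"):
            top = set(markers[markers["cluster"] == state]["gene"].head(30))
            planted_set = set(catalog[state])
            assert len(top & planted_set) >= 25

    def test_identical_gene_excluded(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(
            rng.random((5, 20)) + 1, index=[f"g{i}" for i in range(5)],
            columns=[f"c{i}" for i in range(20)],
        )
        ln = ExpressionMatrix(values=vals, layer="lognorm")
        labels = pd.Series(["a"] * 10 + ["b"] * 10, index=vals.columns)
        out = derive_cluster_markers(ln, labels, min_lfc=0.5)
        assert out.empty  # no gene differs by >= 0.5 mean log2

    def test_min_pct_one_excludes_gene_with_zero_cell(self):
        vals = pd.DataFrame(
            {f"c{i}": [2.0 + (i < 5), 1.0] for i in range(10)},
            index=["g_hit", "g_flat"],
        )
        vals.loc["g_hit", "c0"] = 0.0  # one in-group zero
        ln = ExpressionMatrix(values=vals, layer="lognorm")
        labels = pd.Series(["in"] * 5 + ["out"] * 5, index=vals.columns)
        out = derive_cluster_markers(ln, labels, min_lfc=0.1, min_pct=1.0)
        assert "g_hit" not in set(out[out["cluster"] == "in"]["gene"])

    def test_pvalues_track_independent_ranksum_oracle(self, planted):
        scanpy = pytest.importorskip("scanpy")
        import anndata

        ln, labels, catalog = planted
        markers = derive_cluster_markers(ln, labels, min_lfc=0.5, min_pct=0.5)
        adata = anndata.AnnData(
            X=ln.values.T.to_numpy(), obs=pd.DataFrame({"state": labels.to_numpy()}, index=ln.cell_ids),
            var=pd.DataFrame(index=ln.gene_ids),
        )
        adata.obs["state"] = adata.obs["state"].astype("category")
        scanpy.tl.rank_genes_groups(adata, "state", method="wilcoxon")
        ours = markers[markers["cluster"] == "AC"].set_index("gene")
        theirs = pd.DataFrame(
            {
                "gene": adata.uns["rank_genes_groups"]["names"]["AC"],
                "p": adata.uns["rank_genes_groups"]["pvals"]["AC"],
            }
        ).set_index("gene")
        shared = ours.index.intersection(theirs.index)
        assert len(shared) >= 10
        rho = pd.Series(np.log10(ours.loc[shared, "p"] + 1e-300)).corr(
            pd.Series(np.log10(theirs.loc[shared, "p"] + 1e-300)), method="spearman"
        )
        assert rho > 0.95

    def test_degenerate_clusters_rejected(self):
        vals = pd.DataFrame(np.ones((3, 4)), index=list("abc"), columns=list("wxyz"))
        ln = ExpressionMatrix(values=vals, layer="lognorm")
        labels = pd.Series(["a", "a", "a", "b"], index=vals.columns)
        with pytest.raises(ValueError, match="fewer than 3"):
            derive_cluster_markers(ln, labels)


class TestTopSignature:
    @pytest.fixture
    def markers(self):
        return pd.DataFrame(
            {
                "cluster": "x",
                "gene": [f"g{i}" for i in range(10)],
                "lfc": np.linspace(2, 0.5, 10),
                "pct_in": 0.9,
                "pct_out": 0.1,
                "p": np.linspace(1e-8, 1e-2, 10),
                "p_adj": np.linspace(1e-7, 1e-1, 10),
            }
        )

    def test_larger_n_warns_and_returns_all(self, markers):
        with pytest.warns(UserWarning, match="only 10"):
            out = select_top_signature(markers, n=150)
        assert out == [f"g{i}" for i in range(10)]

    def test_single_most_significant(self, markers):
        assert select_top_signature(markers, n=1) == ["g0"]

    def test_deterministic(self, markers):
        assert select_top_signature(markers, n=5) == select_top_signature(markers, n=5)


class TestCommonUpregulated:
    def test_identical_sets(self):
        sets = {f"s{i}": ["a", "b", "c"] for i in range(4)}
        genes, counts = common_upregulated(sets, min_membership=3)
        assert sorted(genes) == ["a", "b", "c"]
        assert (counts == 4).all()

    def test_disjoint_sets_empty(self):
        sets = {"s1": ["a"], "s2": ["b"], "s3": ["c"], "s4": ["d"]}
        genes, _ = common_upregulated(sets, min_membership=3)
        assert genes == []

    def test_matches_bruteforce_membership(self):
        rng = np.random.default_rng(12)
        universe = [f"g{i}" for i in range(40)]
        sets = {
            f"s{i}": list(rng.choice(universe, size=15, replace=False))
            for i in range(4)
        }
        genes, counts = common_upregulated(sets, min_membership=3)
        for g in universe:
            n = sum(g in s for s in sets.values())
            assert (g in genes) == (n >= 3)
            if n:
                assert counts[g] == n

    def test_order_invariance(self):
        rng = np.random.default_rng(13)
        universe = [f"g{i}" for i in range(30)]
        sets = {f"s{i}": list(rng.choice(universe, 12, replace=False)) for i in range(4)}
        g1, _ = common_upregulated(sets, 3)
        g2, _ = common_upregulated(dict(reversed(list(sets.items()))), 3)
        assert g1 == g2


class TestEnrichmentScore:
    def test_top_gene_unweighted_es_one(self):
        stats = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        assert enrichment_score(stats, [0], weight_exp=0.0) == pytest.approx(1.0)

    def test_bottom_gene_unweighted_es_minus_one(self):
        stats = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        assert enrichment_score(stats, [4], weight_exp=0.0) == pytest.approx(-1.0)

    @pytest.mark.parametrize("weight_exp", [0.0, 1.0])
    def test_streaming_equals_bruteforce_exhaustively(self, weight_exp):
        rng = np.random.default_rng(0)
        stats = np.sort(rng.normal(size=10))[::-1]
        for r in range(1, 10):
            for sub in itertools.combinations(range(10), r):
                fast = enrichment_score(stats, np.array(sub), weight_exp)
                slow = brute_force_es(stats, sub, weight_exp)
                assert fast == pytest.approx(slow, abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**16))
    def test_antisymmetry_under_ranking_negation(self, seed):
        from hypothesis import assume

        rng = np.random.default_rng(seed)
        stats = np.sort(rng.normal(size=12))[::-1]
        hits = rng.choice(12, size=4, replace=False)
        # running-walk extremes, to exclude exact magnitude ties where the
        # positive-tie-break convention breaks antisymmetry
        hit = np.zeros(12, bool)
        hit[hits] = True
        walk = np.cumsum(np.where(hit, 1 / 4, -1 / 8))
        assume(abs(walk.max() + walk.min()) > 1e-9)
        es = enrichment_score(stats, hits, weight_exp=0.0)
        es_neg = enrichment_score(-stats[::-1], 11 - hits, weight_exp=0.0)
        assert es_neg == pytest.approx(-es, abs=1e-12)

    def test_rejects_degenerate_sets(self):
        stats = np.array([2.0, 1.0, 0.5])
        with pytest.raises(ValueError):
            enrichment_score(stats, [], 1.0)
        with pytest.raises(ValueError):
            enrichment_score(stats, [0, 1, 2], 1.0)


class TestPrerankedEnrichment:
    def test_planted_set_detected(self):
        rng = np.random.default_rng(1)
        stats = rng.normal(size=500)
        stats[:40] += 1.5
        order = rng.permutation(500)
        ranking = pd.Series(stats[order], index=[f"g{j}" for j in order])
        result = preranked_enrichment(ranking, [f"g{j}" for j in range(40)], n_perm=500, seed=2)
        assert result.es > 0 and result.nes > 0
        assert result.p < 0.05

    def test_overlap_floor(self):
        ranking = pd.Series([3.0, 2.0, 1.0, 0.5], index=list("abcd"))
        with pytest.raises(ValueError, match=">= 3"):
            preranked_enrichment(ranking, ["a", "b"])

    def test_all_zero_statistics_rejected(self):
        ranking = pd.Series(np.zeros(10), index=[f"g{i}" for i in range(10)])
        with pytest.raises(ValueError, match="all-zero"):
            preranked_enrichment(ranking, ["g0", "g1", "g2"])

    def test_batch_bh_adjusts_over_sets(self):
        from gbmstate.datatypes import GeneSetCatalog
        from scipy.stats import false_discovery_control

        rng = np.random.default_rng(3)
        ranking = pd.Series(rng.normal(size=300), index=[f"g{i}" for i in range(300)])
        catalog = GeneSetCatalog(
            {f"s{i}": list(rng.choice(ranking.index, 20, replace=False)) for i in range(5)}
        )
        results = preranked_enrichment_batch(ranking, catalog, n_perm=100, seed=4)
        qs = false_discovery_control([r.p for r in results])
        for r, q in zip(results, qs):
            assert r.q == pytest.approx(q)


class TestPairedCalls:
    @pytest.mark.parametrize(
        "nes,q,expected",
        [
            (2.0, 0.01, CALL_UP),
            (-1.8, 0.24, CALL_DOWN),
            (3.0, 0.25, CALL_NO_CHANGE),  # boundary is inclusive of no_change
            (-0.5, 0.9, CALL_NO_CHANGE),
            (1.2, 0.2499, CALL_UP),
        ],
    )
    def test_truth_table(self, nes, q, expected):
        result = EnrichmentResult(
            set_name="p1", es=np.sign(nes) * 0.5, nes=nes, p=q, q=q, n_perm=100, seed=0, n_hits=10
        )
        assert classify_paired_enrichment(result).call == expected


class TestProteomicStateScores:
    def test_all_zero_ratios_score_zero(self):
        ratios = pd.DataFrame(np.zeros((4, 3)), index=list("abcd"), columns=["t0", "t6", "t72"])
        scores, n_used = proteomic_state_scores(ratios, {"S": ["a", "b", "c"]})
        assert (scores.loc["S"] == 0).all()
        assert (n_used.loc["S"] == 3).all()

    def test_infinite_values_excluded(self):
        ratios = pd.DataFrame(
            {"t0": [np.inf, 1.0, 1.0]}, index=["a", "b", "c"]
        )
        scores, n_used = proteomic_state_scores(ratios, {"S": ["a", "b", "c"]})
        assert scores.loc["S", "t0"] == pytest.approx(1.0)
        assert n_used.loc["S", "t0"] == 2

    def test_fixture_matches_hand_means(self):
        ratios = pd.DataFrame(
            {"t0": [0.5, 1.5, -1.0, 9.9], "t6": [2.0, 0.0, 1.0, 9.9]},
            index=["a", "b", "c", "other"],
        )
        scores, _ = proteomic_state_scores(ratios, {"S": ["a", "b", "c"]})
        assert scores.loc["S", "t0"] == pytest.approx((0.5 + 1.5 - 1.0) / 3)
        assert scores.loc["S", "t6"] == pytest.approx(1.0)
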