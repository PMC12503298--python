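"""QC filtering, pseudobulk, markers, induced classification, concordance."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats as sps

from mscix import (
    CellCountMatrix,
    FormatError,
    GeneAnnotation,
    classify_induced,
    cluster_concordance,
    filter_cells,
    find_markers,
    pseudobulk,
)
from mscix.qc import PseudobulkTable


def build_matrix(counts, stages=None, clusters=None, samples=None):
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    cell_ids = [f"c{i}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {
            "sample_id": samples or ["s1"] * n_cells,
            "cluster_id": clusters or ["k0"] * n_cells,
            "stage": stages or ["meiotic"] * n_cells,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return CellCountMatrix(
        gene_ids=pd.Index([f"g{i}" for i in range(n_genes)]),
        cell_ids=pd.Index(cell_ids),
        counts=sp.csr_matrix(counts),
        cell_meta=meta,
    )


def annotation_for(matrix, mito=()):
    df = pd.DataFrame(
        {
            "chrom_class": "autosome",
            "stratum": "none",
            "gametolog_status": "none",
            "n_exons": 1,
            "is_mito": [g in mito for g in matrix.gene_ids],
        },
        index=matrix.gene_ids,
    )
    return GeneAnnotation(df)


class TestFilterCells:
    def test_boundary_cells_retained_violators_removed(self):
        """Of 10 hand-built cells, the 3 violating the bounds are removed;
        cells at exactly the bounds stay (inclusive semantics)."""
        n_genes = 3200
        cols = []
        features = [150, 200, 250, 3000, 3001, 500, 800, 0, 1200, 2999]
        for f in features:
            col = np.zeros(n_genes)
            col[:f] = 1
            cols.append(col)
        m = build_matrix(np.array(cols).T)
        kept = filter_cells(m, annotation_for(m))
        expected = [f for f in features if 200 <= f <= 3000]
        assert list((kept.counts > 0).sum(axis=0).A1) == expected
        assert kept.n_cells == 7

    def test_zero_count_cell_removed(self):
        m = build_matrix(np.array([[0, 5], [0, 5]]))
        kept = filter_cells(m, annotation_for(m), min_features=1,
                            max_features=10)
        assert list(kept.cell_ids) == ["c1"]

    def test_mito_fraction_cap(self):
        # cell0: 10% mito, cell1: 2% mito
        counts = np.array([[10, 2], [90, 98], [10, 10]])
        m = build_matrix(counts)
        ann = annotation_for(m, mito={"g0"})
        kept = filter_cells(m, ann, min_features=1, max_features=10,
                            max_mito=0.05)
        assert list(kept.cell_ids) == ["c1"]

    def test_no_mito_annotation_skips_filter(self, caplog):
        counts = np.array([[50, 2], [50, 98]])
        m = build_matrix(counts)
        kept = filter_cells(m, annotation_for(m), min_features=1,
                            max_features=10, max_mito=0.05)
        assert kept.n_cells == 2


class TestPseudobulk:
    def test_single_cluster_equals_row_sums(self):
        counts = np.array([[1, 2, 3], [0, 4, 0]])
        pb = pseudobulk(build_matrix(counts))
        assert list(pb.df["k0"]) == [6, 4]

    def test_conservation_over_clusters(self, small_sim, small_pb):
        matrix, _, _ = small_sim
        per_gene_cells = np.asarray(matrix.counts.sum(axis=1)).ravel()
        per_gene_clusters = small_pb.df.sum(axis=1).to_numpy()
        assert (per_gene_cells == per_gene_clusters).all()
        assert (small_pb.library_size == small_pb.df.sum(axis=0)).all()

    def test_matches_brute_force_accumulation(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(1.0, size=(50, 200))
        clusters = [f"k{i % 4}" for i in range(200)]
        m = build_matrix(counts, clusters=clusters)
        pb = pseudobulk(m)
        brute = {}
        for k in range(4):
            brute[f"k{k}"] = np.zeros(50, dtype=int)
        for j in range(200):
            brute[clusters[j]] += counts[:, j]
        for k, v in brute.items():
            assert (pb.df[k].to_numpy() == v).all()


class TestMarkers:
    def test_uniform_gene_is_not_a_marker(self):
        # second gene varies per cell but with the same multiset in both
        # clusters, so normalised g0 has identical group distributions
        counts = np.vstack([np.full(20, 5), np.tile(np.arange(10), 2)])
        clusters = ["a"] * 10 + ["b"] * 10
        m = build_matrix(counts, clusters=clusters)
        res = find_markers(m, min_pct=0.0, min_log2fc=0.0, alpha=0.05)
        g0 = res[res["gene_id"] == "g0"]
        assert not g0["is_marker"].any()

    def test_small_groups_use_exact_enumeration(self):
        """5 vs 6 cells: the reported p equals the full-enumeration rank-sum
        p computed independently on the normalised values."""
        from itertools import combinations

        rng = np.random.default_rng(2)
        counts = rng.poisson(3.0, size=(4, 11))
        clusters = ["a"] * 5 + ["b"] * 6
        m = build_matrix(counts, clusters=clusters)
        res = find_markers(m, min_pct=0.0, min_log2fc=0.0, alpha=0.01)
        # reproduce normalisation: counts per 1e4 per cell
        dense = counts.astype(float)
        totals = dense.sum(axis=0)
        norm = dense / totals[None, :] * 1e4
        for gi in range(4):
            row = res[(res["gene_id"] == f"g{gi}") & (res["cluster_id"] == "a")]
            pooled = norm[gi]
            ranks = sps.rankdata(pooled)
            w_obs = ranks[:5].sum()
            mu = 5 * 12 / 2.0
            d_obs = abs(w_obs - mu)
            hits = total = 0
            for idx in combinations(range(11), 5):
                total += 1
                if abs(ranks[list(idx)].sum() - mu) >= d_obs - 1e-12:
                    hits += 1
            assert row["p_raw"].iloc[0] == pytest.approx(hits / total, abs=1e-12)

    def test_fold_filter_excludes_small_effect(self):
        """A gene with strong p and pct but log2fc ~ 0.14 fails the fold gate."""
        n = 60
        clusters = ["a"] * 30 + ["b"] * 30
        g0 = np.array([11] * 30 + [10] * 30)
        g1 = 100 - g0  # keeps per-cell totals equal
        m = build_matrix(np.vstack([g0, g1]), clusters=clusters)
        res = find_markers(m, min_pct=0.25, min_log2fc=0.25, alpha=0.01)
        row = res[(res["gene_id"] == "g0") & (res["cluster_id"] == "a")].iloc[0]
        assert row["pct_in"] == 1.0
        assert row["p_adj"] < 0.01
        assert 0 < row["log2fc"] < 0.25
        assert not row["is_marker"]

    def test_filters_are_monotone(self, small_sim):
        matrix, _, _ = small_sim
        strict = find_markers(matrix, min_pct=0.25, min_log2fc=0.25, alpha=0.01)
        relaxed = find_markers(matrix, min_pct=0.10, min_log2fc=0.10, alpha=0.05)
        strict_set = set(
            map(tuple, strict.loc[strict["is_marker"],
                                  ["gene_id", "cluster_id"]].to_numpy())
        )
        relaxed_set = set(
            map(tuple, relaxed.loc[relaxed["is_marker"],
                                   ["gene_id", "cluster_id"]].to_numpy())
        )
        assert strict_set <= relaxed_set

    def test_bonferroni_never_below_raw(self, small_sim):
        matrix, _, _ = small_sim
        res = find_markers(matrix)
        assert (res["p_adj"] >= res["p_raw"] - 1e-15).all()

    def test_tiny_cluster_excluded(self):
        counts = np.ones((3, 12), dtype=int)
        clusters = ["a"] * 10 + ["b"] * 2
        m = build_matrix(counts, clusters=clusters)
        res = find_markers(m, min_pct=0.0, min_log2fc=0.0)
        assert set(res["cluster_id"]) == {"a"}


def stage_pb(values: dict[str, list[float]], genes=None) -> PseudobulkTable:
    """One cluster per stage with the given per-gene counts."""
    df = pd.DataFrame(values)
    df.index = genes or [f"g{i}" for i in range(len(df))]
    stage = pd.Series({c: c for c in df.columns})
    return PseudobulkTable(df.astype(int), stage)


class TestClassifyInduced:
    STAGES = ["pre_meiotic", "meiotic", "post_meiotic", "somatic"]

    def make(self, rows):
        """Stage pseudobulk with a filler gene equalising library sizes, so
        the stated values survive library-size normalisation unchanged."""
        values = {s: [r[i] for r in rows] for i, s in enumerate(self.STAGES)}
        totals = [sum(values[s]) for s in self.STAGES]
        top = max(totals) + 10
        for s, t in zip(self.STAGES, totals):
            values[s] = values[s] + [top - t]
        return stage_pb(values)

    def test_rule_examples(self):
        pb = self.make([
            [25, 10, 10, 10],   # induced pre_meiotic: 25 > 2*10
            [10, 10, 10, 10],   # flat -> none
            [5, 0, 0, 0],       # zero median of others -> induced
            [0, 0, 0, 0],       # all-zero -> none
        ])
        out = classify_induced(pb)
        assert out.loc["g0"] == "pre_meiotic"
        assert out.loc["g1"] == "none"
        assert out.loc["g2"] == "pre_meiotic"
        assert out.loc["g3"] == "none"

    def test_multiple_fires_resolved_by_max(self):
        # both pre_meiotic and meiotic exceed 2x their "others" medians;
        # library sizes are equal so normalisation preserves order
        pb = self.make([[50, 80, 1, 1], [30, 1, 60, 60], [20, 19, 39, 39]])
        out = classify_induced(pb)
        assert out.loc["g0"] == "meiotic"

    def test_scale_invariance(self):
        pb1 = self.make([[25, 10, 10, 10], [1, 9, 2, 2], [7, 7, 7, 2]])
        pb2 = PseudobulkTable(pb1.df * 13, pb1.stage_of_cluster)
        pd.testing.assert_series_equal(classify_induced(pb1),
                                       classify_induced(pb2))

    def test_caption_variant_differs_on_borderline_gene(self):
        # 30 > 2*median(10,10,28)=20 fails, but median(all four)=19 -> 38 > 30 fails too;
        # chosen so the two rules disagree: methods rule fires, caption rule does not
        pb = self.make([[30, 10, 10, 28]])
        assert classify_induced(pb, variant="median_others").loc["g0"] != "none"
        assert classify_induced(pb, variant="max_vs_overall").loc["g0"] == "none"


class TestConcordance:
    def test_self_correlation_is_one(self, small_sim):
        matrix, _, _ = small_sim
        pb = pseudobulk(matrix)
        mat = cluster_concordance({"s1": pb, "s2": pb}, top_n=100)
        for stage in ("pre_meiotic", "meiotic"):
            assert mat.loc[f"s1:{stage}", f"s2:{stage}"] == pytest.approx(1.0)

    def test_monotone_transform_preserves_rho(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(20.0, size=30) + 1
        pb1 = stage_pb({"meiotic": list(base)})
        pb2 = stage_pb({"meiotic": list(base**2)})  # strictly monotone
        mat = cluster_concordance({"a": pb1, "b": pb2}, top_n=30)
        assert mat.loc["a:meiotic", "b:meiotic"] == pytest.approx(1.0)

    def test_matches_hand_ranked_spearman(self):
        rng = np.random.default_rng(9)
        a = rng.poisson(30.0, size=30) + 1
        b = rng.poisson(30.0, size=30) + 1
        mat = cluster_concordance(
            {"a": stage_pb({"meiotic": list(a)}),
             "b": stage_pb({"meiotic": list(b)})},
            top_n=30,
        )
        ra, rb = sps.rankdata(a), sps.rankdata(b)
        rho = np.corrcoef(ra, rb)[0, 1]
        assert mat.loc["a:meiotic", "b:meiotic"] == pytest.approx(rho, rel=1e-9)

    def test_requires_two_samples(self, small_pb):
        with pytest.raises(ValueError):
            cluster_concordance({"only": small_pb})
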