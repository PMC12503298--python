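"""Dosage contrasts, mono-allelic enrichment, and faster-X statistics."""

import math
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mscix import (
    ConfigError,
    DnDsTable,
    GeneAnnotation,
    call_monoallelic,
    dnds_prepare,
    dosage_contrast,
    faster_x_contrast,
    hypergeom_enrichment,
    monoallelic_enrichment,
)
from mscix.qc import PseudobulkTable
from mscix.stats import rank_sum_test


# ---------------------------------------------------------------------------
# hypergeometric enrichment
# ---------------------------------------------------------------------------


def enumeration_tail(k, K, n, N, tail):
    """Oracle: exact combinatorial sum over all urn outcomes."""
    denom = comb(N, n)
    lo, hi = (k, min(K, n)) if tail == "over" else (max(0, n - (N - K)), k)
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(lo, hi + 1)) / denom


def test_closed_form_examples():
    res = hypergeom_enrichment(4, 5, 4, 10)
    assert res.tail == "over"
    assert res.p == pytest.approx(5 / 210, rel=1e-12)
    res = hypergeom_enrichment(0, 5, 4, 10)
    assert res.tail == "under"
    assert res.p == pytest.approx(5 / 210, rel=1e-12)
    assert math.isinf(res.signed_fold) and res.signed_fold < 0
    assert res.fold_str() == "-Inf"


def test_exact_expectation_reports_over_tail_fold_one():
    # k = expected = n*K/N exactly
    res = hypergeom_enrichment(2, 4, 5, 10)
    assert res.signed_fold == 1.0
    assert res.tail == "over"
    assert res.p >= 0.5


@settings(derandomize=True, max_examples=60, deadline=None)
@given(data=st.data())
def test_matches_enumeration_for_small_urns(data):
    N = data.draw(st.integers(1, 30))
    K = data.draw(st.integers(0, N))
    n = data.draw(st.integers(0, N))
    k = data.draw(st.integers(max(0, n - (N - K)), min(K, n)))
    res = hypergeom_enrichment(k, K, n, N)
    assert res.p == pytest.approx(
        enumeration_tail(k, K, n, N, res.tail), rel=1e-10, abs=1e-12
    )


def test_signed_fold_antisymmetry():
    """A count under expectation by factor f mirrors one over by factor f."""
    over = hypergeom_enrichment(8, 10, 10, 25)  # expected 4, fold 2
    under = hypergeom_enrichment(2, 10, 10, 25)  # expected 4, fold -2
    assert over.signed_fold == pytest.approx(2.0)
    assert under.signed_fold == pytest.approx(-2.0)
    assert over.signed_fold == pytest.approx(-under.signed_fold)


def test_invalid_urn_rejected():
    with pytest.raises(ConfigError):
        hypergeom_enrichment(6, 5, 6, 10)
    with pytest.raises(ConfigError):
        hypergeom_enrichment(1, 5, 11, 10)


# ---------------------------------------------------------------------------
# dosage contrast
# ---------------------------------------------------------------------------

STAGES = ("pre_meiotic", "meiotic", "post_meiotic", "somatic")


def dosage_annotation(n_per_class=40, strata=("1", "2", "3")):
    rows = []
    for stratum in strata:
        for i in range(n_per_class):
            rows.append((f"xo-{stratum}-{i}", "X", stratum, "X_only", None))
            rows.append((f"xy-{stratum}-{i}", "X", stratum, "XY_pair",
                         f"p{stratum}{i}"))
            rows.append((f"yy-{stratum}-{i}", "Y", stratum, "XY_pair",
                         f"p{stratum}{i}"))
    df = pd.DataFrame(
        {
            "chrom_class": [r[1] for r in rows],
            "stratum": [r[2] for r in rows],
            "gametolog_status": [r[3] for r in rows],
            "pair_id": [r[4] for r in rows],
            "n_exons": 1,
            "is_mito": False,
        },
        index=pd.Index([r[0] for r in rows], name="gene_id"),
    )
    return GeneAnnotation(df)


def ratio_table(ann, rng, shift_mask=None, factor=2.0):
    rows = []
    x_genes = ann.df.index[ann.df["chrom_class"] == "X"]
    for g in x_genes:
        boost = factor if (shift_mask is not None and shift_mask(g)) else 1.0
        for s in STAGES:
            rows.append({
                "gene_id": g, "chrom_class": "X",
                "stratum": ann.df.loc[g, "stratum"], "stage": s,
                "ratio": boost * float(rng.lognormal(0.0, 0.4)),
                "n_clusters_used": 2,
            })
    return pd.DataFrame(rows)


def test_null_rejection_rate_matches_alpha():
    """Same distribution in both gametolog classes: the raw Dunn within-stage
    p rejects at ~5% over 200 simulations."""
    ann = dosage_annotation(n_per_class=30, strata=("1",))
    rng = np.random.default_rng(77)
    n_tests = rejected = 0
    for _ in range(200):
        rt = ratio_table(ann, rng)
        res = dosage_contrast(rt, ann, by_stratum=False)
        n_tests += len(res)
        rejected += int((res["dunn_p_raw"] < 0.05).sum())
    rate = rejected / n_tests
    assert 0.03 < rate < 0.07


def test_identical_groups_give_p_near_one():
    ann = dosage_annotation(n_per_class=20, strata=("1",))
    rows = []
    vals = np.arange(1, 21) * 0.1
    for g in ann.df.index[ann.df["chrom_class"] == "X"]:
        i = int(g.rsplit("-", 1)[1])
        for s in STAGES:
            rows.append({"gene_id": g, "chrom_class": "X", "stratum": "1",
                         "stage": s, "ratio": vals[i], "n_clusters_used": 1})
    res = dosage_contrast(pd.DataFrame(rows), ann, by_stratum=False)
    assert (res["kw_p"] > 0.95).all()
    assert (res["dunn_p"] == 1.0).all()


def test_stratum_confined_doubling_recovered_once():
    """Doubled X-only ratios in stratum 1 only: significant there for every
    stage, not significant in strata 2-3 (single replicate)."""
    ann = dosage_annotation(n_per_class=60)
    rng = np.random.default_rng(123)
    rt = ratio_table(
        ann, rng,
        shift_mask=lambda g: g.startswith("xo-1-"), factor=2.0,
    )
    res = dosage_contrast(rt, ann, by_stratum=True)
    s1 = res[res["stratum"] == "1"]
    rest = res[res["stratum"] != "1"]
    assert len(s1) == 4 and s1["significant"].all()
    assert len(rest) == 8 and not rest["significant"].any()


def test_sparse_group_skipped(caplog):
    ann = dosage_annotation(n_per_class=5, strata=("1",))
    rng = np.random.default_rng(3)
    rt = ratio_table(ann, rng)
    rt = rt[~((rt["stage"] == "somatic")
              & rt["gene_id"].str.startswith("xo"))]
    res = dosage_contrast(rt, ann, by_stratum=False)
    assert "somatic" not in set(res["stage"])


# ---------------------------------------------------------------------------
# mono-allelic expression
# ---------------------------------------------------------------------------


def mono_fixture(x_counts, y_counts, bulk_x, bulk_y):
    """One gametolog pair; one cluster per stage."""
    ann = dosage_annotation(n_per_class=1, strata=("1",))
    genes = ["xo-1-0", "xy-1-0", "yy-1-0"]
    df = pd.DataFrame(
        {s: [1, x_counts[i], y_counts[i]] for i, s in enumerate(STAGES)},
        index=genes,
    )
    pb = PseudobulkTable(df, pd.Series({s: s for s in STAGES}))
    bulk_df = pd.DataFrame(
        {
            ("brain", 1): [0, 0, 0], ("brain", 2): [0, 0, 0],
            ("brain", 3): [0, 0, 0],
            ("liver", 1): [0, 0, 0], ("liver", 2): [0, 0, 0],
            ("liver", 3): [0, 0, 0],
            ("testis", 1): [5, bulk_x, bulk_y],
            ("testis", 2): [5, 0, 0], ("testis", 3): [5, 0, 0],
        },
        index=genes,
    )
    bulk_df.columns = pd.MultiIndex.from_tuples(bulk_df.columns,
                                                names=["organ", "replicate"])
    from mscix.io import BulkCountTable

    return ann, pb, BulkCountTable(bulk_df)


def test_x_only_called_when_bulk_concordant():
    ann, pb, bulk = mono_fixture(
        x_counts=[10, 10, 10, 10], y_counts=[0, 0, 0, 0], bulk_x=10, bulk_y=0
    )
    calls = call_monoallelic(pb, ann, bulk)
    assert calls["x_only"].all()


def test_y_copy_count_one_breaks_monoallelic():
    ann, pb, bulk = mono_fixture(
        x_counts=[10, 10, 10, 10], y_counts=[1, 0, 0, 0], bulk_x=10, bulk_y=0
    )
    calls = call_monoallelic(pb, ann, bulk)
    assert not calls.loc[calls["stage"] == "pre_meiotic", "x_only"].iloc[0]
    assert calls.loc[calls["stage"] == "meiotic", "x_only"].iloc[0]


def test_discordant_bulk_excludes_call():
    ann, pb, bulk = mono_fixture(
        x_counts=[10, 10, 10, 10], y_counts=[0, 0, 0, 0], bulk_x=10, bulk_y=5
    )
    calls = call_monoallelic(pb, ann, bulk)
    assert not calls["x_only"].any()


def test_enrichment_urn_parameters():
    ann, pb, bulk = mono_fixture(
        x_counts=[10, 0, 10, 10], y_counts=[0, 0, 0, 0], bulk_x=10, bulk_y=0
    )
    calls = call_monoallelic(pb, ann, bulk)
    res = monoallelic_enrichment(calls, "x_only")
    by_stage = {r.stage: r for r in res}
    assert by_stage["pre_meiotic"].N == 1
    assert by_stage["pre_meiotic"].K == 1
    assert by_stage["pre_meiotic"].k == 1
    assert by_stage["meiotic"].n == 0  # pair unexpressed in meiosis


# ---------------------------------------------------------------------------
# dN/dS
# ---------------------------------------------------------------------------


def dnds_table(rows):
    return DnDsTable(pd.DataFrame(
        [{"gene_id": g, "transcript_id": f"{g}.t{i}", "dn": v * 0.1,
          "ds": 0.1, "dnds": v}
         for g, vals in rows.items() for i, v in enumerate(vals)]
    ))


def test_dnds_prepare_rules():
    out = dnds_prepare(dnds_table({"a": [0.2, 0.4], "b": [0.2, 99.0],
                                   "c": [99.0]}))
    assert out.loc["a"] == pytest.approx(0.3)
    assert out.loc["b"] == pytest.approx(0.2)
    assert "c" not in out.index


def test_dnds_prepare_idempotent():
    t = dnds_table({"a": [0.2, 0.4], "b": [0.1, 99.0]})
    once = dnds_prepare(t)
    again = dnds_prepare(
        DnDsTable(pd.DataFrame({
            "gene_id": once.index, "transcript_id": once.index + ".t0",
            "dn": once.to_numpy() * 0.1, "ds": 0.1, "dnds": once.to_numpy(),
        }))
    )
    pd.testing.assert_series_equal(once, again, check_names=False)


# ---------------------------------------------------------------------------
# faster-X
# ---------------------------------------------------------------------------


def fasterx_annotation(n_auto=60, n_each=12):
    rows = []
    for i in range(n_auto):
        rows.append((f"a{i}", "autosome", "none", "none", None))
    for i in range(n_each):
        rows.append((f"xh{i}", "X", "1", "X_only", None))
        rows.append((f"xg{i}", "X", "1", "XY_pair", f"p{i}"))
        rows.append((f"yg{i}", "Y", "1", "XY_pair", f"p{i}"))
        rows.append((f"yh{i}", "Y", "1", "Y_only", None))
    df = pd.DataFrame(
        {
            "chrom_class": [r[1] for r in rows],
            "stratum": [r[2] for r in rows],
            "gametolog_status": [r[3] for r in rows],
            "pair_id": [r[4] for r in rows],
            "n_exons": 1,
            "is_mito": False,
        },
        index=pd.Index([r[0] for r in rows], name="gene_id"),
    )
    return GeneAnnotation(df)


def test_null_all_contrasts_familywise_controlled():
    """One shared dN/dS distribution: the Dunn-adjusted class contrasts are
    all non-significant in >= 90% of 100 simulations."""
    ann = fasterx_annotation()
    rng = np.random.default_rng(11)
    induced = pd.Series("meiotic", index=ann.df.index)
    clean = 0
    for _ in range(100):
        dnds = pd.Series(rng.gamma(2.0, 0.1, len(ann.df)), index=ann.df.index)
        fx = faster_x_contrast(dnds, ann, induced)
        dunn = fx.kruskal[(fx.kruskal["subset"] == "all")
                          & (fx.kruskal["comparison"] == "dunn")]
        if (dunn["p"] >= 0.05).all():
            clean += 1
    assert clean >= 90


def test_power_location_shift_detected():
    """X-hemizygous induced genes shifted by +50% of the mean, n=50 vs 2000
    autosomal: the pairwise contrast is significant in >= 95% of replicates."""
    rng = np.random.default_rng(21)
    detected = 0
    for _ in range(100):
        auto = rng.gamma(2.0, 0.1, 2000)
        xh = rng.gamma(2.0, 0.1, 50) + 0.1
        _, p = rank_sum_test(xh, auto)
        detected += int(p < 0.05)
    assert detected >= 95


def test_identical_duplicated_class_p_one():
    ann = fasterx_annotation(n_auto=20, n_each=20)
    vals = np.tile(np.arange(1, 21) * 0.02, 5)
    dnds = pd.Series(vals[: len(ann.df)], index=ann.df.index)
    # make X_hemizygous exactly duplicate the autosome values
    dnds.loc[[f"xh{i}" for i in range(20)]] = dnds.loc[
        [f"a{i}" for i in range(20)]
    ].to_numpy()
    fx = faster_x_contrast(dnds, ann, pd.Series("none", index=ann.df.index))
    row = fx.pairwise[(fx.pairwise["subset"] == "all")
                      & (fx.pairwise["gene_class"] == "X_hemizygous")].iloc[0]
    assert row["p"] > 0.99


def test_small_class_flagged_untestable():
    ann = fasterx_annotation(n_auto=30, n_each=12)
    dnds = pd.Series(0.2, index=ann.df.index)
    dnds = dnds.drop([f"yh{i}" for i in range(1, 12)])  # one Y-only gene left
    fx = faster_x_contrast(dnds, ann, pd.Series("none", index=ann.df.index))
    row = fx.pairwise[(fx.pairwise["subset"] == "all")
                      & (fx.pairwise["gene_class"] == "Y_hemizygous")].iloc[0]
    assert np.isnan(row["p"])
    assert "untestable" in row["note"]


def test_generator_dnds_recovers_class_structure(small_config):
    """Simulated dN/dS: Y-hemizygous above autosomes, gametologs below."""
    from mscix import simulate_counts, simulate_dnds
    from mscix.qc import classify_induced, pseudobulk

    m, ann, _ = simulate_counts(small_config)
    dnds = dnds_prepare(simulate_dnds(small_config))
    induced = classify_induced(pseudobulk(m))
    fx = faster_x_contrast(dnds, ann, induced)
    sub = fx.pairwise[fx.pairwise["subset"] == "all"].set_index("gene_class")
    assert sub.loc["XY_gametolog_X", "p"] < 0.05
    assert sub.loc["XY_gametolog_Y", "p"] < 0.05
    assert sub.loc["Y_hemizygous", "p"] < 0.05
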