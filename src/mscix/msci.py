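"""MSCI detection: sex-linked : autosome expression ratios across stages.

The central statistic is the per-gene X:AA (or Y:AA) ratio — a sex-linked
gene's pseudobulk count divided by the median count of expressed autosomal
genes in the same cluster — averaged over the clusters of each major stage.
Under meiotic sex chromosome inactivation the meiotic-stage ratio
distribution drops relative to pre-meiotic stages; the detector compares
stage ratio distributions with two-sided rank-sum tests, reported raw
(uncorrected) by default because each pairwise comparison is of standalone
interest; a Bonferroni flag is available.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import STAGES, GeneAnnotation
from .qc import PseudobulkTable
from .stats import dunn_posthoc, kruskal_wallis, rank_sum_test

__all__ = [
    "normalize_to_autosome_median",
    "stage_pairwise_tests",
    "per_cluster_ratio_profile",
    "filter_broadly_expressed",
    "plot_stage_ratios",
]

log = logging.getLogger(__name__)


def _cluster_ratios(
    pb: PseudobulkTable,
    ann: GeneAnnotation,
    include_zeros: bool = False,
    exclude_clusters=(),
) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Per-cluster ratios of sex-linked genes to the autosomal median.

    Returns ``(ratios, counts, used_clusters)`` where ``ratios`` and
    ``counts`` are sex-gene x cluster frames (ratio = count / median count of
    autosomal genes with count >= 1 in that cluster, or over all autosomal
    genes with ``include_zeros``). Clusters whose autosomal median is zero
    are excluded and logged.
    """
    ann_df = ann.df.loc[ann.df.index.intersection(pb.df.index)]
    auto_genes = ann_df.index[
        (ann_df["chrom_class"] == "autosome") & ~ann_df["is_mito"]
    ]
    sex_genes = ann_df.index[ann_df["chrom_class"].isin(["X", "Y"])]
    ratios = {}
    used = []
    excluded = set(exclude_clusters)
    for c in pb.df.columns:
        if c in excluded:
            continue
        auto = pb.df.loc[auto_genes, c]
        vals = auto.to_numpy(dtype=float)
        if not include_zeros:
            vals = vals[vals >= 1]
        med = float(np.median(vals)) if vals.size else 0.0
        if med == 0:
            log.info("cluster %r has zero autosomal median; excluded", c)
            continue
        ratios[c] = pb.df.loc[sex_genes, c] / med
        used.append(c)
    ratio_df = pd.DataFrame(ratios)
    count_df = pb.df.loc[sex_genes, used]
    return ratio_df, count_df, used


def normalize_to_autosome_median(
    pb: PseudobulkTable,
    ann: GeneAnnotation,
    include_zeros: bool = False,
    exclude_clusters=(),
) -> pd.DataFrame:
    """Stage-level X:AA / Y:AA ratio table.

    For each sex-linked gene and major stage: the gene is retained in a stage
    when it has a count >= 1 in at least one of the stage's clusters, and its
    stage ratio is the unweighted mean of its per-cluster ratios over the
    clusters where it is expressed (count >= 1). Columns: ``gene_id,
    chrom_class, stratum, stage, ratio, n_clusters_used``.
    """
    ratio_df, count_df, used = _cluster_ratios(
        pb, ann, include_zeros, exclude_clusters
    )
    rows = []
    for stage in STAGES:
        cols = [c for c in used if pb.stage_of_cluster[c] == stage]
        if not cols:
            continue
        counts = count_df[cols]
        expressed = counts >= 1
        any_expr = expressed.any(axis=1)
        sub_ratio = ratio_df[cols].where(expressed)
        stage_ratio = sub_ratio.mean(axis=1, skipna=True)
        n_used = expressed.sum(axis=1)
        for gene in counts.index[any_expr]:
            rows.append(
                {
                    "gene_id": gene,
                    "chrom_class": ann.df.loc[gene, "chrom_class"],
                    "stratum": ann.df.loc[gene, "stratum"],
                    "stage": stage,
                    "ratio": float(stage_ratio.loc[gene]),
                    "n_clusters_used": int(n_used.loc[gene]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chrom_class", "stratum", "stage", "ratio",
                 "n_clusters_used"],
    )


def stage_pairwise_tests(
    rt: pd.DataFrame, by_stratum: bool = False, correction: str | None = None
) -> pd.DataFrame:
    """Two-sided rank-sum tests between every pair of stages.

    Performed separately per chromosome (X, Y) and, with ``by_stratum``, per
    evolutionary stratum. No multiplicity correction by default (each
    pairwise P is reported raw); ``correction='bonferroni'`` scales by the
    number of tests performed. Empty strata or stages with < 2 genes are
    omitted with a log entry.
    """
    rows = []
    group_cols = ["chrom_class", "stratum"] if by_stratum else ["chrom_class"]
    for keys, grp in rt.groupby(group_cols, observed=True):
        if not by_stratum:
            keys = (keys if isinstance(keys, str) else keys[0], "all")
        chrom, stratum = keys[0], keys[1]
        stage_vals = {
            s: grp.loc[grp["stage"] == s, "ratio"].to_numpy() for s in STAGES
        }
        stages_ok = [s for s in STAGES if stage_vals[s].size >= 2]
        skipped = set(STAGES) - set(stages_ok)
        if skipped:
            log.info(
                "chrom %s stratum %s: stages %s have <2 genes; omitted",
                chrom, stratum, sorted(skipped),
            )
        for i, sa in enumerate(stages_ok):
            for sb in stages_ok[i + 1:]:
                stat, p = rank_sum_test(stage_vals[sa], stage_vals[sb])
                rows.append(
                    {
                        "stage_a": sa,
                        "stage_b": sb,
                        "chrom_class": chrom,
                        "stratum": stratum,
                        "statistic": stat,
                        "p": p,
                        "n_a": stage_vals[sa].size,
                        "n_b": stage_vals[sb].size,
                    }
                )
    out = pd.DataFrame(
        rows,
        columns=["stage_a", "stage_b", "chrom_class", "stratum", "statistic",
                 "p", "n_a", "n_b"],
    )
    if correction == "bonferroni" and len(out):
        out["p"] = np.minimum(1.0, out["p"] * len(out))
    elif correction not in (None, "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    return out


def per_cluster_ratio_profile(
    pb: PseudobulkTable,
    ann: GeneAnnotation,
    include_zeros: bool = False,
    exclude_clusters=(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster ratio distributions plus Kruskal-Wallis and Dunn tests.

    Returns ``(ratio_long, tests)``: the long-format per-cluster ratios of
    expressed sex-linked genes (no stage averaging), and per-chromosome
    Kruskal-Wallis across clusters with Dunn post-hoc pairs. With a single
    cluster the test is undefined and flagged with NaN statistics.
    """
    ratio_df, count_df, used = _cluster_ratios(
        pb, ann, include_zeros, exclude_clusters
    )
    long_rows = []
    for c in used:
        expressed = count_df[c] >= 1
        for gene in count_df.index[expressed]:
            long_rows.append(
                {
                    "gene_id": gene,
                    "chrom_class": ann.df.loc[gene, "chrom_class"],
                    "cluster_id": c,
                    "stage": pb.stage_of_cluster[c],
                    "ratio": float(ratio_df.loc[gene, c]),
                }
            )
    long_df = pd.DataFrame(
        long_rows, columns=["gene_id", "chrom_class", "cluster_id", "stage",
                            "ratio"]
    )
    test_rows = []
    for chrom in ("X", "Y"):
        sub = long_df[long_df["chrom_class"] == chrom]
        groups = {
            c: sub.loc[sub["cluster_id"] == c, "ratio"].to_numpy()
            for c in used
            if (sub["cluster_id"] == c).sum() >= 2
        }
        if len(groups) < 2:
            test_rows.append(
                {"chrom_class": chrom, "comparison": "kruskal_wallis",
                 "group_a": None, "group_b": None, "statistic": np.nan,
                 "p": np.nan, "note": "fewer than two testable clusters"}
            )
            continue
        h, p = kruskal_wallis(list(groups.values()))
        test_rows.append(
            {"chrom_class": chrom, "comparison": "kruskal_wallis",
             "group_a": None, "group_b": None, "statistic": h, "p": p,
             "note": ""}
        )
        for d in dunn_posthoc(groups):
            test_rows.append(
                {"chrom_class": chrom, "comparison": "dunn",
                 "group_a": d.group_a, "group_b": d.group_b,
                 "statistic": d.z, "p": d.p_adj, "note": ""}
            )
    tests = pd.DataFrame(
        test_rows, columns=["chrom_class", "comparison", "group_a", "group_b",
                            "statistic", "p", "note"]
    )
    return long_df, tests


def filter_broadly_expressed(
    rt: pd.DataFrame, testis_specific: set[str]
) -> pd.DataFrame:
    """Restrict the ratio table to broadly expressed genes.

    Removes every gene in the testis-specific set, isolating genes whose
    expression is not confined to testis (the class where meiotic silencing
    of housekeeping genes would show).
    """
    return rt[~rt["gene_id"].isin(testis_specific)].reset_index(drop=True)


def plot_stage_ratios(rt: pd.DataFrame, path) -> None:
    """Box plot of stage ratio distributions per chromosome (X left, Y right)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = [c for c in ("X", "Y") if (rt["chrom_class"] == c).any()]
    fig, axes = plt.subplots(1, max(len(chroms), 1), figsize=(5 * len(chroms), 4),
                             squeeze=False)
    for ax, chrom in zip(axes[0], chroms):
        sub = rt[rt["chrom_class"] == chrom]
        data = [sub.loc[sub["stage"] == s, "ratio"].to_numpy() for s in STAGES]
        ax.boxplot(data, tick_labels=[s.replace("_", "\n") for s in STAGES])
        ax.axhline(1.0, ls="--", lw=0.8, color="grey")
        ax.set_yscale("log")
        ax.set_title(f"{chrom}:AA ratio by stage")
        ax.set_ylabel("expression / autosomal median")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
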