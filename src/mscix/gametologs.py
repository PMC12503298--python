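"""Gametolog evolution: dosage compensation, mono-allelic expression
enrichment, and faster-X contrasts of protein-coding divergence.

Gametologs are X- and Y-linked copies descended from the same ancestral
gene. Where the Y copy has been lost (X-only, hemizygous) dosage
compensation predicts up-regulation of the surviving X copy toward the
autosomal level; the dosage contrast compares X-only against X+Y ratio
distributions per stage (Kruskal-Wallis panel + Dunn within-stage pairs).
Mono-allelic expression (transcripts from only one copy of a pair) is tested
for stage enrichment with a hypergeometric urn; under-enrichment is reported
as a negative reciprocal fold (e.g. -3.15x). Faster-X contrasts compare
per-gene dN/dS across chromosome classes, overall and restricted to
spermatogenesis-induced genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import ConfigError
from .io import STAGES, BulkCountTable, DnDsTable, GeneAnnotation
from .qc import PseudobulkTable
from .stats import dunn_posthoc, kruskal_wallis, rank_sum_test

__all__ = [
    "dosage_contrast",
    "call_monoallelic",
    "hypergeom_enrichment",
    "EnrichmentResult",
    "monoallelic_enrichment",
    "dnds_prepare",
    "faster_x_contrast",
    "FasterXResult",
    "assign_gene_classes",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# dosage compensation
# ---------------------------------------------------------------------------


def dosage_contrast(
    rt: pd.DataFrame,
    ann: GeneAnnotation,
    by_stratum: bool = False,
    alpha: float = 0.05,
    min_genes: int = 2,
) -> pd.DataFrame:
    """X-only vs X+Y ratio contrasts per stage (optionally per stratum).

    For each panel (all strata, or one stratum) the stage x gametolog-class
    ratio groups enter one Kruskal-Wallis test, and Dunn's post-hoc z-tests
    are reported for the within-stage X-only vs X+Y pairs, Bonferroni-scaled
    by the total number of reported pairs in the call. Groups with fewer
    than ``min_genes`` genes are skipped with a log entry.
    """
    x_rt = rt[rt["chrom_class"] == "X"].copy()
    status = ann.df["gametolog_status"]
    x_rt["class"] = status.reindex(x_rt["gene_id"]).to_numpy()
    x_rt = x_rt[x_rt["class"].isin(["X_only", "XY_pair"])]
    panels = sorted(set(x_rt["stratum"])) if by_stratum else ["all"]

    planned: list[tuple[str, str, dict]] = []
    for stratum in panels:
        sub = x_rt if stratum == "all" else x_rt[x_rt["stratum"] == stratum]
        groups: dict[str, np.ndarray] = {}
        for stage in STAGES:
            for cls in ("X_only", "XY_pair"):
                vals = sub.loc[
                    (sub["stage"] == stage) & (sub["class"] == cls), "ratio"
                ].to_numpy()
                groups[f"{stage}|{cls}"] = vals
        pairs = []
        for stage in STAGES:
            a, b = f"{stage}|X_only", f"{stage}|XY_pair"
            if groups[a].size >= min_genes and groups[b].size >= min_genes:
                pairs.append((a, b))
            else:
                log.info(
                    "stratum %s stage %s: a gametolog group has <%d genes; "
                    "contrast skipped", stratum, stage, min_genes,
                )
        if pairs:
            planned.append((stratum, "panel", {"groups": groups, "pairs": pairs}))

    n_pairs_total = sum(len(p[2]["pairs"]) for p in planned)
    rows = []
    for stratum, _, payload in planned:
        groups = {
            k: v for k, v in payload["groups"].items() if v.size >= min_genes
        }
        kw_p = np.nan
        if len(groups) >= 2:
            _, kw_p = kruskal_wallis(list(groups.values()))
        dunn = dunn_posthoc(
            groups, pairs=payload["pairs"], n_tests=n_pairs_total
        )
        for d in dunn:
            stage = d.group_a.split("|")[0]
            rows.append(
                {
                    "stage": stage,
                    "stratum": stratum,
                    "n_x_only": d.n_a,
                    "n_xy_pair": d.n_b,
                    "kw_p": kw_p,
                    "dunn_z": d.z,
                    "dunn_p_raw": d.p_raw,
                    "dunn_p": d.p_adj,
                    "significant": d.p_adj < alpha,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["stage", "stratum", "n_x_only", "n_xy_pair", "kw_p",
                 "dunn_z", "dunn_p_raw", "dunn_p", "significant"],
    )


# ---------------------------------------------------------------------------
# mono-allelic expression
# ---------------------------------------------------------------------------


def call_monoallelic(
    pb: PseudobulkTable, ann: GeneAnnotation, bulk: BulkCountTable
) -> pd.DataFrame:
    """Per gametolog pair and stage: expression and mono-allelic calls.

    A pair is X-only-expressed in a stage when the X copy has a summed stage
    count >= 1 and the Y copy exactly 0 (symmetrically Y-only-expressed),
    retained only when at least one testis bulk replicate shows the same
    pattern (count > 1 on the expressed copy and <= 1 on the silent copy in
    that replicate). Unpaired gametologs are excluded with a log entry.

    Returns one row per (pair, stage) with boolean columns ``expressed``,
    ``x_only``, ``y_only`` (bulk-verified) and the underlying counts.
    """
    pairs = ann.gametolog_pairs()
    n_ann_paired = int((ann.df["gametolog_status"] == "XY_pair").sum())
    if 2 * len(pairs) != n_ann_paired:
        log.info(
            "%d gametolog genes lack a complete X/Y pair; excluded",
            n_ann_paired - 2 * len(pairs),
        )
    stage_counts = pb.stage_counts()
    testis = bulk.organ("testis")
    rows = []
    for rec in pairs.itertuples():
        x_gene, y_gene = rec.x_gene, rec.y_gene
        if x_gene not in stage_counts.index or y_gene not in stage_counts.index:
            log.info("pair %r missing from the count matrix; excluded", rec.pair_id)
            continue
        x_bulk = testis.loc[x_gene] if x_gene in testis.index else pd.Series(0, index=testis.columns)
        y_bulk = testis.loc[y_gene] if y_gene in testis.index else pd.Series(0, index=testis.columns)
        x_mono_bulk = bool(((x_bulk > 1) & (y_bulk <= 1)).any())
        y_mono_bulk = bool(((y_bulk > 1) & (x_bulk <= 1)).any())
        for stage in stage_counts.columns:
            xc = int(stage_counts.loc[x_gene, stage])
            yc = int(stage_counts.loc[y_gene, stage])
            rows.append(
                {
                    "pair_id": rec.pair_id,
                    "stage": stage,
                    "x_count": xc,
                    "y_count": yc,
                    "expressed": xc >= 1 or yc >= 1,
                    "x_only": (xc >= 1 and yc == 0) and x_mono_bulk,
                    "y_only": (yc >= 1 and xc == 0) and y_mono_bulk,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["pair_id", "stage", "x_count", "y_count", "expressed",
                 "x_only", "y_only"],
    )


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of mono-allelic expression in one stage.

    ``signed_fold`` follows the signed convention: observed/expected when at
    or above expectation, minus expected/observed below it (so a two-fold
    depletion prints as -2.0; an observed count of 0 prints as -inf).
    """

    k: int
    K: int
    n: int
    N: int
    expected: float
    signed_fold: float
    p: float
    tail: str
    stage: str | None = None
    allele_class: str | None = None

    def fold_str(self) -> str:
        if math.isinf(self.signed_fold):
            return "-Inf"
        return f"{self.signed_fold:.2f}"


def hypergeom_enrichment(k: int, K: int, n: int, N: int) -> EnrichmentResult:
    """Tail probability of drawing k successes in n draws from an urn of N
    items containing K successes, with a signed observed/expected fold.

    The over tail P(X >= k) is reported when k >= expected = nK/N, otherwise
    the under tail P(X <= k).
    """
    if not (0 <= k <= min(K, n) <= N) or N <= 0 or K > N or n > N:
        raise ConfigError(
            f"invalid urn: k={k}, K={K}, n={n}, N={N} violates "
            f"0 <= k <= min(K, n) <= N"
        )
    expected = n * K / N
    if k >= expected:
        tail = "over"
        p = float(_sps.hypergeom.sf(k - 1, N, K, n))
        fold = k / expected if expected > 0 else 1.0
    else:
        tail = "under"
        p = float(_sps.hypergeom.cdf(k, N, K, n))
        fold = -math.inf if k == 0 else -expected / k
    return EnrichmentResult(
        k=k, K=K, n=n, N=N, expected=expected, signed_fold=fold, p=p, tail=tail
    )


def monoallelic_enrichment(
    calls: pd.DataFrame, allele_class: str = "x_only"
) -> list[EnrichmentResult]:
    """Stage enrichment of mono-allelic pairs among expressed pairs.

    Urn per stage: N = pairs expressed in at least one stage, K = pairs
    mono-allelic (in ``allele_class``) in at least one stage, n = pairs
    expressed in the focal stage, k = pairs mono-allelic in the focal stage.
    """
    if allele_class not in ("x_only", "y_only"):
        raise ConfigError(f"allele_class must be x_only or y_only")
    by_pair = calls.groupby("pair_id")
    ever_expressed = by_pair["expressed"].any()
    ever_mono = by_pair[allele_class].any()
    N = int(ever_expressed.sum())
    K = int((ever_mono & ever_expressed).sum())
    out = []
    for stage in STAGES:
        sub = calls[calls["stage"] == stage].set_index("pair_id")
        sub = sub.loc[sub.index.intersection(ever_expressed.index[ever_expressed])]
        n = int(sub["expressed"].sum())
        k = int((sub[allele_class] & sub["expressed"]).sum())
        res = hypergeom_enrichment(k, K, n, N)
        out.append(
            EnrichmentResult(
                **{**res.__dict__, "stage": stage, "allele_class": allele_class}
            )
        )
    return out


# ---------------------------------------------------------------------------
# dN/dS
# ---------------------------------------------------------------------------

_SENTINEL_DNDS = 99.0


def dnds_prepare(t: DnDsTable, sentinel: float = _SENTINEL_DNDS) -> pd.Series:
    """Per-gene dN/dS: drop sentinel transcripts, average the rest.

    Transcripts with dN/dS equal to the sentinel (99, produced when a gene
    has no synonymous substitutions and the ratio is unreliable) are removed
    to within 1e-9; each gene's value is the mean over its surviving
    transcripts, and genes with none are dropped. Idempotent on its output.
    """
    df = t.df
    keep = ~np.isclose(df["dnds"].to_numpy(dtype=float), sentinel, atol=1e-9)
    out = df.loc[keep].groupby("gene_id")["dnds"].mean()
    out.name = "dnds"
    return out


GENE_CLASSES = (
    "autosome",
    "X_hemizygous",
    "XY_gametolog_X",
    "XY_gametolog_Y",
    "Y_hemizygous",
)


def assign_gene_classes(ann: GeneAnnotation) -> pd.Series:
    """Map genes to faster-X contrast classes; unclassified genes get NaN."""
    df = ann.df
    cls = pd.Series(np.nan, index=df.index, dtype=object)
    cls[(df["chrom_class"] == "autosome") & ~df["is_mito"]] = "autosome"
    cls[df["gametolog_status"] == "X_only"] = "X_hemizygous"
    cls[(df["gametolog_status"] == "XY_pair") & (df["chrom_class"] == "X")] = (
        "XY_gametolog_X"
    )
    cls[(df["gametolog_status"] == "XY_pair") & (df["chrom_class"] == "Y")] = (
        "XY_gametolog_Y"
    )
    cls[df["gametolog_status"] == "Y_only"] = "Y_hemizygous"
    return cls


@dataclass
class FasterXResult:
    """Faster-X contrast tables.

    ``pairwise``: rank-sum contrasts of each sex-linked class vs autosomes,
    for all genes and for the induced subset. ``kruskal``: Kruskal-Wallis +
    Dunn across classes per subset. ``by_stage``: Kruskal-Wallis of induced
    genes' dN/dS across induced stages, per class. Classes with < 2 genes
    are flagged untestable (NaN p with a note).
    """

    pairwise: pd.DataFrame
    kruskal: pd.DataFrame
    by_stage: pd.DataFrame
    class_of_gene: pd.Series


def faster_x_contrast(
    dnds: pd.Series,
    ann: GeneAnnotation,
    induced: pd.Series,
    min_genes: int = 2,
) -> FasterXResult:
    """Compare per-gene dN/dS across chromosome classes.

    Two parallel analyses: all genes with a dN/dS estimate, and the subset
    induced in a major spermatogenesis stage. Each sex-linked class is
    contrasted against autosomes with a two-sided rank-sum test; a
    Kruskal-Wallis + Dunn panel across all classes is reported alongside.
    Induced genes are additionally compared across their induced stages
    within each class.
    """
    cls = assign_gene_classes(ann)
    shared = dnds.index.intersection(cls.index[cls.notna()])
    vals = dnds.loc[shared]
    cls = cls.loc[shared]
    induced = induced.reindex(shared).fillna("none")

    subsets = {
        "all": pd.Series(True, index=shared),
        "induced": induced != "none",
    }
    pairwise_rows = []
    kruskal_rows = []
    for subset, mask in subsets.items():
        groups = {
            c: vals[mask & (cls == c)].to_numpy() for c in GENE_CLASSES
        }
        auto = groups["autosome"]
        for c in GENE_CLASSES[1:]:
            if groups[c].size < min_genes or auto.size < min_genes:
                pairwise_rows.append(
                    {"subset": subset, "gene_class": c, "n": groups[c].size,
                     "n_autosome": auto.size, "statistic": np.nan, "p": np.nan,
                     "note": "untestable: fewer than 2 genes"}
                )
                continue
            stat, p = rank_sum_test(groups[c], auto)
            pairwise_rows.append(
                {"subset": subset, "gene_class": c, "n": groups[c].size,
                 "n_autosome": auto.size, "statistic": stat, "p": p, "note": ""}
            )
        testable = {c: g for c, g in groups.items() if g.size >= min_genes}
        if len(testable) >= 2:
            h, kw_p = kruskal_wallis(list(testable.values()))
            kruskal_rows.append(
                {"subset": subset, "comparison": "kruskal_wallis",
                 "group_a": None, "group_b": None, "statistic": h, "p": kw_p,
                 "note": ""}
            )
            auto_pairs = [
                (c, "autosome") for c in testable if c != "autosome"
            ]
            for d in dunn_posthoc(testable, pairs=auto_pairs):
                kruskal_rows.append(
                    {"subset": subset, "comparison": "dunn",
                     "group_a": d.group_a, "group_b": d.group_b,
                     "statistic": d.z, "p": d.p_adj, "note": ""}
                )

    by_stage_rows = []
    ind_mask = induced != "none"
    for c in GENE_CLASSES:
        stage_groups = {
            s: vals[ind_mask & (cls == c) & (induced == s)].to_numpy()
            for s in STAGES
        }
        testable = {s: g for s, g in stage_groups.items() if g.size >= min_genes}
        sizes = {s: int(g.size) for s, g in stage_groups.items()}
        if len(testable) < 2:
            by_stage_rows.append(
                {"gene_class": c, "statistic": np.nan, "p": np.nan,
                 "n_per_stage": sizes, "note": "untestable: fewer than 2 stages"}
            )
            continue
        h, p = kruskal_wallis(list(testable.values()))
        by_stage_rows.append(
            {"gene_class": c, "statistic": h, "p": p, "n_per_stage": sizes,
             "note": ""}
        )
    return FasterXResult(
        pairwise=pd.DataFrame(pairwise_rows),
        kruskal=pd.DataFrame(kruskal_rows),
        by_stage=pd.DataFrame(by_stage_rows),
        class_of_gene=cls,
    )
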