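"""Cell QC, per-cluster pseudobulk, marker genes, induced-gene classification,
testis-specific calling and cross-sample concordance.

QC follows common droplet practice: cells are kept when their number of
detected features lies inside an inclusive band (the defaults remove cells
with fewer than 200 or more than 3000 detected features, i.e. boundary cells
at exactly 200 or 3000 are retained) and their mitochondrial count fraction
does not exceed a cap. Marker detection is the standard one-vs-rest rank-sum
scan with Bonferroni correction over genes x clusters and percent-expressed /
fold-change filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import FormatError
from .io import STAGES, BulkCountTable, CellCountMatrix, GeneAnnotation
from .stats import mannwhitney_vectorized, rank_sum_test

__all__ = [
    "qc_flags",
    "filter_cells",
    "PseudobulkTable",
    "pseudobulk",
    "find_markers",
    "classify_induced",
    "testis_specific",
    "cluster_concordance",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def qc_flags(
    m: CellCountMatrix,
    ann: GeneAnnotation | None = None,
    min_features: int = 200,
    max_features: int = 3000,
    max_mito: float = 0.05,
) -> pd.DataFrame:
    """Per-cell QC table: detected features, mito fraction and pass flags.

    ``pass_features`` is inclusive on both bounds; ``pass_mito`` is always
    True when no mitochondrial genes are annotated (the filter is then
    skipped with a warning).
    """
    detected = np.asarray((m.counts > 0).sum(axis=0)).ravel()
    totals = np.asarray(m.counts.sum(axis=0)).ravel().astype(float)
    out = pd.DataFrame(
        {"n_features": detected, "total_counts": totals.astype(int)},
        index=m.cell_ids,
    )
    out["pass_features"] = (detected >= min_features) & (detected <= max_features)
    mito_genes = ann.mito_genes if ann is not None else pd.Index([])
    if len(mito_genes) == 0:
        log.warning("no mitochondrial genes annotated; mito filter skipped")
        out["mito_fraction"] = np.nan
        out["pass_mito"] = True
    else:
        mito_idx = m.gene_ids.get_indexer_for(
            mito_genes.intersection(m.gene_ids)
        )
        mito_counts = np.asarray(m.counts[mito_idx].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito_counts / totals, 0.0)
        out["mito_fraction"] = frac
        out["pass_mito"] = frac <= max_mito
    out["keep"] = out["pass_features"] & out["pass_mito"]
    return out


def filter_cells(
    m: CellCountMatrix,
    ann: GeneAnnotation | None = None,
    min_features: int = 200,
    max_features: int = 3000,
    max_mito: float = 0.05,
) -> CellCountMatrix:
    """Remove cells outside the inclusive feature band or above the mito cap."""
    flags = qc_flags(m, ann, min_features, max_features, max_mito)
    n_feat = int((~flags["pass_features"]).sum())
    n_mito = int((~flags["pass_mito"]).sum())
    log.info(
        "QC removed %d cells by feature bounds, %d by mito fraction (of %d)",
        n_feat, n_mito, m.n_cells,
    )
    return m.subset_cells(flags["keep"].to_numpy())


# ---------------------------------------------------------------------------
# pseudobulk
# ---------------------------------------------------------------------------


@dataclass
class PseudobulkTable:
    """Per-cluster summed counts with cluster -> stage mapping.

    ``df`` is genes x clusters (integer sums); ``stage_of_cluster`` maps each
    cluster id to its stage; ``library_size`` is the per-cluster column sum.
    """

    df: pd.DataFrame
    stage_of_cluster: pd.Series

    def __post_init__(self) -> None:
        if (self.df.to_numpy() < 0).any():
            raise FormatError("pseudobulk entries must be nonnegative")
        missing = set(self.df.columns) - set(self.stage_of_cluster.index)
        if missing:
            raise FormatError(f"clusters without a stage: {sorted(missing)}")

    @property
    def library_size(self) -> pd.Series:
        return self.df.sum(axis=0)

    def clusters_of_stage(self, stage: str) -> list:
        return [c for c in self.df.columns if self.stage_of_cluster[c] == stage]

    def stage_counts(self, stages=STAGES) -> pd.DataFrame:
        """Summed counts per major stage (over that stage's clusters)."""
        out = {}
        for s in stages:
            cols = self.clusters_of_stage(s)
            out[s] = self.df[cols].sum(axis=1) if cols else pd.Series(
                0, index=self.df.index
            )
        return pd.DataFrame(out)

    def drop_clusters(self, clusters) -> "PseudobulkTable":
        keep = [c for c in self.df.columns if c not in set(clusters)]
        return PseudobulkTable(
            self.df[keep].copy(), self.stage_of_cluster.loc[keep].copy()
        )


def pseudobulk(m: CellCountMatrix) -> PseudobulkTable:
    """Sum counts over the cells of each cluster (exact column-group sums)."""
    clusters = m.cell_meta["cluster_id"]
    uniq = list(pd.unique(clusters))
    indicator = np.zeros((m.n_cells, len(uniq)), dtype=np.int64)
    pos = {c: k for k, c in enumerate(uniq)}
    for i, c in enumerate(clusters):
        indicator[i, pos[c]] = 1
    sums = np.asarray(m.counts @ indicator)
    df = pd.DataFrame(sums, index=m.gene_ids, columns=uniq)
    stage = m.cell_meta.groupby("cluster_id", observed=True)["stage"].first()
    return PseudobulkTable(df, stage.loc[uniq])


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------


def _normalize_cells(m: CellCountMatrix, scale: float = 1e4) -> np.ndarray:
    """Library-size normalised expression per cell (counts per ``scale``)."""
    dense = np.asarray(m.counts.todense(), dtype=float)
    totals = dense.sum(axis=0)
    totals[totals == 0] = 1.0
    return dense / totals[None, :] * scale


def find_markers(
    m: CellCountMatrix,
    min_pct: float = 0.25,
    min_log2fc: float = 0.25,
    alpha: float = 0.01,
    correction: str = "bonferroni",
    min_cells: int = 3,
) -> pd.DataFrame:
    """One-vs-rest rank-sum marker scan over all clusters.

    For every gene and cluster the in-cluster cells are compared against all
    other cells on library-size-normalised expression (two-sided Mann-Whitney
    U; exact enumeration when both groups are tiny). P-values are corrected
    over genes x clusters (Bonferroni by default, ``correction='bh'`` for
    Benjamini-Hochberg). A gene is a marker of a cluster when it is detected
    in >= ``min_pct`` of in-cluster cells, has log2 fold change >
    ``min_log2fc`` (pseudocount 1 on normalised means) and adjusted p <
    ``alpha``. Clusters with fewer than ``min_cells`` cells are untestable
    and excluded with a log entry.
    """
    clusters = m.cell_meta["cluster_id"]
    norm = _normalize_cells(m)
    raw = np.asarray(m.counts.todense())
    rows = []
    testable = []
    for c in pd.unique(clusters):
        n_in = int((clusters == c).sum())
        if n_in < min_cells:
            log.info("cluster %r has %d cells; marked untestable", c, n_in)
            continue
        testable.append(c)
    for c in testable:
        in_mask = (clusters == c).to_numpy()
        n_in = int(in_mask.sum())
        n_out = m.n_cells - n_in
        pct_in = (raw[:, in_mask] > 0).mean(axis=1)
        mean_in = norm[:, in_mask].mean(axis=1)
        mean_out = norm[:, ~in_mask].mean(axis=1)
        log2fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        if n_in <= 8 and n_out <= 8:
            stat = np.empty(m.n_genes)
            pvals = np.empty(m.n_genes)
            for gi in range(m.n_genes):
                stat[gi], pvals[gi] = rank_sum_test(
                    norm[gi, in_mask], norm[gi, ~in_mask]
                )
        else:
            stat, pvals = mannwhitney_vectorized(norm, in_mask)
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": m.gene_ids,
                    "cluster_id": c,
                    "pct_in": pct_in,
                    "log2fc": log2fc,
                    "statistic": stat,
                    "p_raw": pvals,
                }
            )
        )
    if not rows:
        raise FormatError("no testable clusters (need >= 2 clusters with cells)")
    res = pd.concat(rows, ignore_index=True)
    n_tests = len(res)
    if correction == "bonferroni":
        res["p_adj"] = np.minimum(1.0, res["p_raw"] * n_tests)
    elif correction == "bh":
        res["p_adj"] = _sps.false_discovery_control(res["p_raw"], method="bh")
    else:
        raise ValueError(f"unknown correction {correction!r}")
    res["is_marker"] = (
        (res["pct_in"] >= min_pct)
        & (res["log2fc"] > min_log2fc)
        & (res["p_adj"] < alpha)
    )
    return res


# ---------------------------------------------------------------------------
# induced genes
# ---------------------------------------------------------------------------


def classify_induced(
    pb: PseudobulkTable, variant: str = "median_others", scale: float = 1e6
) -> pd.Series:
    """Assign each gene its induced stage, or 'none'.

    Stage expression is the library-size-normalised stage pseudobulk (counts
    per ``scale``). Under the default rule a gene is induced in stage s when
    its expression there strictly exceeds 2x the median over the other three
    stages; if several stages fire, the stage with maximum expression wins
    (exact tie -> 'none', logged). ``variant='max_vs_overall'`` instead calls
    the top stage induced when it exceeds 2x the median over all four stages.
    """
    counts = pb.stage_counts()
    lib = pd.Series(
        {s: pb.df[pb.clusters_of_stage(s)].to_numpy().sum() for s in counts.columns}
    )
    lib[lib == 0] = 1
    expr = counts / lib * scale
    vals = expr.to_numpy()
    stages = list(expr.columns)
    out = pd.Series("none", index=expr.index, name="induced_stage")
    n_ties = 0
    for i, gene in enumerate(expr.index):
        v = vals[i]
        if np.all(v == 0):
            continue
        if variant == "median_others":
            fired = []
            for s_idx in range(len(stages)):
                others = np.delete(v, s_idx)
                if v[s_idx] > 2.0 * np.median(others):
                    fired.append(s_idx)
            if not fired:
                continue
            best = max(fired, key=lambda k: v[k])
            ties = [k for k in fired if v[k] == v[best]]
        elif variant == "max_vs_overall":
            if v.max() <= 2.0 * np.median(v):
                continue
            ties = list(np.flatnonzero(v == v.max()))
            best = ties[0]
        else:
            raise ValueError(f"unknown induced-rule variant {variant!r}")
        if len(ties) > 1:
            n_ties += 1
            continue
        out.iloc[i] = stages[best]
    if n_ties:
        log.info("%d genes had tied induced stages; left as 'none'", n_ties)
    return out


# ---------------------------------------------------------------------------
# testis-specific genes (bulk)
# ---------------------------------------------------------------------------


def testis_specific(b: BulkCountTable) -> set[str]:
    """Genes expressed only in testis: count > 1 in at least one testis
    replicate and <= 1 in every brain and liver replicate."""
    for organ in ("brain", "liver", "testis"):
        if organ not in b.organs:
            raise FormatError(f"bulk table is missing organ {organ!r}")
    testis = b.organ("testis")
    brain = b.organ("brain")
    liver = b.organ("liver")
    expressed = (testis > 1).any(axis=1)
    silent_elsewhere = (brain <= 1).all(axis=1) & (liver <= 1).all(axis=1)
    return set(b.df.index[expressed & silent_elsewhere])


# ---------------------------------------------------------------------------
# cross-sample concordance
# ---------------------------------------------------------------------------


def cluster_concordance(
    pb_by_sample: dict[str, PseudobulkTable], top_n: int = 2000
) -> pd.DataFrame:
    """Spearman rho between stage expression profiles across samples.

    Each sample's stage profile is the library-size-normalised stage
    pseudobulk. For every pair of (sample, stage) profiles the correlation is
    computed over the union of the two profiles' ``top_n`` highest-expressed
    genes (all genes, logged, when fewer are available). Returns a symmetric
    matrix labelled ``sample:stage``.
    """
    if len(pb_by_sample) < 2:
        raise ValueError("cluster_concordance requires >= 2 samples")
    profiles: dict[str, pd.Series] = {}
    for sample, pb in pb_by_sample.items():
        counts = pb.stage_counts()
        lib = counts.sum(axis=0)
        lib[lib == 0] = 1
        norm = counts / lib * 1e6
        for stage in counts.columns:
            if counts[stage].sum() > 0:
                profiles[f"{sample}:{stage}"] = norm[stage]
    labels = list(profiles)
    mat = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b_lab = labels[j]
            pa, pbv = profiles[a], profiles[b_lab]
            shared = pa.index.intersection(pbv.index)
            if len(shared) < top_n:
                log.info(
                    "only %d shared genes for %s vs %s (top_n=%d); using all",
                    len(shared), a, b_lab, top_n,
                )
            top_a = pa.loc[shared].nlargest(min(top_n, len(shared))).index
            top_b = pbv.loc[shared].nlargest(min(top_n, len(shared))).index
            union = top_a.union(top_b)
            rho = _sps.spearmanr(pa.loc[union], pbv.loc[union]).statistic
            mat.loc[a, b_lab] = mat.loc[b_lab, a] = float(rho)
    return mat
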