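"""Y-linked duplicate (ampliconic) gene-family expression profiling.

Multi-copy Y gene families are profiled as aggregates: the counts of all
paralogs of a family are summed per cluster, normalised by the cluster
library size, and averaged over each stage's clusters. A family counts as
expressed in a stage when its summed raw count over that stage's clusters
reaches a threshold (default 1, the same retention rule applied to single
genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io import STAGES, GeneAnnotation
from .qc import PseudobulkTable

__all__ = ["FamilyExpressionTable", "family_expression", "count_expressed_families"]

log = logging.getLogger(__name__)


@dataclass
class FamilyExpressionTable:
    """Aggregate expression of duplicate gene families.

    ``per_cluster``: family x cluster normalised aggregates (summed paralog
    counts / cluster library size). ``per_stage``: family x stage, the mean
    of the normalised per-cluster values over the stage's clusters.
    ``raw_stage_counts``: family x stage summed raw counts (drives the
    expressed-in call). ``n_paralogs``: annotated members per family.
    """

    per_cluster: pd.DataFrame
    per_stage: pd.DataFrame
    raw_stage_counts: pd.DataFrame
    n_paralogs: pd.Series

    def expressed_in(self, min_count: float = 1.0) -> dict[str, set]:
        """Stages where each family's summed raw count >= ``min_count``."""
        out: dict[str, set] = {}
        for fam in self.raw_stage_counts.index:
            out[fam] = {
                s
                for s in self.raw_stage_counts.columns
                if self.raw_stage_counts.loc[fam, s] >= min_count
            }
        return out


def family_expression(
    pb: PseudobulkTable, ann: GeneAnnotation
) -> FamilyExpressionTable:
    """Aggregate paralog counts per duplicate family.

    Families need >= 2 annotated members; members missing from the count
    matrix are summed over the present ones with a warning.
    """
    fam_col = ann.df["family_id"]
    families = {
        fid: list(genes)
        for fid, genes in fam_col.dropna().groupby(fam_col).groups.items()
    }
    families = {f: g for f, g in families.items() if len(g) >= 2}
    lib = pb.library_size.astype(float)
    lib[lib == 0] = 1.0
    per_cluster = {}
    raw_stage = {}
    n_paralogs = {}
    for fid, genes in sorted(families.items()):
        present = [g for g in genes if g in pb.df.index]
        if len(present) < len(genes):
            log.warning(
                "family %s: %d of %d members missing from matrix; summing "
                "present members", fid, len(genes) - len(present), len(genes),
            )
        sums = pb.df.loc[present].sum(axis=0) if present else pd.Series(
            0, index=pb.df.columns
        )
        per_cluster[fid] = sums / lib
        raw_stage[fid] = {
            s: int(sums[pb.clusters_of_stage(s)].sum()) for s in STAGES
        }
        n_paralogs[fid] = len(genes)
    per_cluster_df = pd.DataFrame(per_cluster).T
    per_cluster_df.index.name = "family_id"
    raw_stage_df = pd.DataFrame(raw_stage).T.reindex(columns=list(STAGES))
    per_stage = pd.DataFrame(index=per_cluster_df.index, columns=list(STAGES),
                             dtype=float)
    for s in STAGES:
        cols = pb.clusters_of_stage(s)
        per_stage[s] = (
            per_cluster_df[cols].mean(axis=1) if cols else float("nan")
        )
    return FamilyExpressionTable(
        per_cluster=per_cluster_df,
        per_stage=per_stage,
        raw_stage_counts=raw_stage_df,
        n_paralogs=pd.Series(n_paralogs, name="n_paralogs"),
    )


def count_expressed_families(
    ft: FamilyExpressionTable, min_count: float = 1.0
) -> pd.Series:
    """Number of families expressed in each stage at the given raw-count
    threshold. Monotone non-increasing in ``min_count``."""
    expressed = ft.expressed_in(min_count)
    return pd.Series(
        {s: sum(s in stages for stages in expressed.values()) for s in STAGES},
        name="n_families",
    )
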