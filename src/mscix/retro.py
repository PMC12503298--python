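"""Retrocopy detection: intronless secondary copies of multi-exon genes.

A retrocopy is created when a spliced mRNA is reverse-transcribed and
reinserted, so the hallmark is a single-block (intronless) alignment of a
multi-exon parent at a second genomic location. A candidate must (1) descend
from a parent with at least one intron (>= 2 exons), (2) align as a single
block at a locus disjoint from the parent, and (3) be absent from the
orthologous locus of the outgroup genome — an outgroup hit means the
insertion predates the split and is rejected. Multiple secondary hits at the
same locus are collapsed by 50% reciprocal overlap, keeping the top score.
"""

from __future__ import annotations

import logging

import pandas as pd

from .io import AlignmentRecordSet

__all__ = ["detect_retro"]

log = logging.getLogger(__name__)


def _overlaps(chrom_a, start_a, end_a, chrom_b, start_b, end_b) -> bool:
    """>= 1 bp overlap on half-open intervals, same chromosome."""
    return chrom_a == chrom_b and start_a < end_b and start_b < end_a


def _reciprocal_overlap(a: tuple, b: tuple, frac: float = 0.5) -> bool:
    """True when the intersection covers >= frac of both intervals."""
    if a[0] != b[0]:
        return False
    inter = min(a[2], b[2]) - max(a[1], b[1])
    if inter <= 0:
        return False
    return inter >= frac * (a[2] - a[1]) and inter >= frac * (b[2] - b[1])


def detect_retro(
    ingroup: AlignmentRecordSet,
    outgroup: AlignmentRecordSet,
    parents: pd.DataFrame,
) -> pd.DataFrame:
    """Call retrocopy candidates from ingroup/outgroup alignments.

    ``parents`` maps each query gene to its designated parent locus:
    indexed by gene id with columns ``chrom, start, end, n_exons``.
    Returns one row per secondary locus considered, with ``verdict`` in
    ``{candidate, rejected_outgroup, rejected_overlap}``; single-exon
    parents are never candidates and produce no rows. Queries absent from
    the ingroup alignments are skipped with a log entry.
    """
    in_by_query = dict(tuple(ingroup.df.groupby("query_id")))
    out_by_query = dict(tuple(outgroup.df.groupby("query_id")))
    rows = []
    for gene in parents.index:
        n_exons = int(parents.loc[gene, "n_exons"])
        if n_exons < 2:
            continue
        if gene not in in_by_query:
            log.info("query %r has no ingroup alignments; skipped", gene)
            continue
        p_chrom = parents.loc[gene, "chrom"]
        p_start = int(parents.loc[gene, "start"])
        p_end = int(parents.loc[gene, "end"])
        hits = in_by_query[gene]
        single = hits[hits["n_blocks"] == 1]
        overlapping = []
        secondary = []
        for rec in single.itertuples():
            locus = (rec.target_chrom, int(rec.target_start), int(rec.target_end))
            if _overlaps(*locus, p_chrom, p_start, p_end):
                overlapping.append((locus, float(rec.score)))
            else:
                secondary.append((locus, float(rec.score)))
        for locus, score in overlapping:
            rows.append(
                _row(gene, n_exons, locus, score, outgroup_hit=False,
                     verdict="rejected_overlap")
            )
        # collapse loci: greedy by score, 50% reciprocal overlap
        secondary.sort(key=lambda t: -t[1])
        kept: list[tuple[tuple, float]] = []
        for locus, score in secondary:
            if not any(_reciprocal_overlap(locus, k[0]) for k in kept):
                kept.append((locus, score))
        out_hits = out_by_query.get(gene)
        for locus, score in kept:
            hit = False
            if out_hits is not None:
                sub = out_hits[out_hits["n_blocks"] == 1]
                for rec in sub.itertuples():
                    if _overlaps(
                        rec.target_chrom, int(rec.target_start),
                        int(rec.target_end), *locus
                    ):
                        hit = True
                        break
            verdict = "rejected_outgroup" if hit else "candidate"
            rows.append(
                _row(gene, n_exons, locus, score, outgroup_hit=hit,
                     verdict=verdict)
            )
    return pd.DataFrame(
        rows,
        columns=["parent_gene_id", "parent_n_exons", "copy_chrom",
                 "copy_start", "copy_end", "n_blocks", "score",
                 "outgroup_hit", "verdict"],
    )


def _row(gene, n_exons, locus, score, outgroup_hit, verdict) -> dict:
    return {
        "parent_gene_id": gene,
        "parent_n_exons": n_exons,
        "copy_chrom": locus[0],
        "copy_start": locus[1],
        "copy_end": locus[2],
        "n_blocks": 1,
        "score": score,
        "outgroup_hit": outgroup_hit,
        "verdict": verdict,
    }
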