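"""Domain containers and readers/writers for the standard formats.

The pipeline consumes a CellRanger-style MTX triplet (MatrixMarket counts +
features/barcodes TSVs) plus a cell-metadata TSV, a gene-annotation TSV (or
GFF3), bulk RNA-seq count TSVs, a per-transcript dN/dS TSV and spliced
alignment TSVs. All readers validate into typed containers and reject rather
than coerce invalid input; ``write`` followed by ``read`` is the identity on
valid data.

Coordinates are 0-based half-open throughout (BED convention); the GFF3
reader converts from 1-based closed at the boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError

__all__ = [
    "STAGES",
    "CHROM_CLASSES",
    "CellCountMatrix",
    "GeneAnnotation",
    "BulkCountTable",
    "DnDsTable",
    "AlignmentRecordSet",
    "read_counts",
    "write_counts",
    "read_annotation",
    "write_annotation",
    "read_annotation_gff3",
    "read_bulk",
    "write_bulk",
    "read_dnds",
    "write_dnds",
    "read_alignments",
    "write_alignments",
]

#: the four major spermatogenesis cell types, in developmental order
STAGES = ("pre_meiotic", "meiotic", "post_meiotic", "somatic")
VALID_STAGES = STAGES + ("unassigned",)
CHROM_CLASSES = ("autosome", "X", "Y", "PAR")
STRATA = ("1", "2", "3", "PAR", "none")
GAMETOLOG_STATUSES = ("X_only", "XY_pair", "Y_only", "none")
ORGANS = ("brain", "liver", "testis")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CellCountMatrix:
    """Integer gene x cell count matrix with per-cell metadata.

    ``counts`` is a sparse CSR matrix of shape (n_genes, n_cells).
    ``cell_meta`` is indexed by cell id with columns ``sample_id``,
    ``cluster_id`` and ``stage``; a cluster belongs to exactly one stage.
    """

    gene_ids: pd.Index
    cell_ids: pd.Index
    counts: sp.csr_matrix
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.gene_ids = pd.Index(self.gene_ids, name="gene_id")
        self.cell_ids = pd.Index(self.cell_ids, name="cell_id")
        if self.gene_ids.has_duplicates:
            dup = self.gene_ids[self.gene_ids.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if self.cell_ids.has_duplicates:
            dup = self.cell_ids[self.cell_ids.duplicated()][0]
            raise FormatError(f"duplicate cell id: {dup!r}")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise FormatError("counts must be nonnegative integers")
        self.counts = self.counts.astype(np.int64)
        meta = self.cell_meta
        required = {"sample_id", "cluster_id", "stage"}
        missing = required - set(meta.columns)
        if missing:
            raise FormatError(f"cell metadata missing columns: {sorted(missing)}")
        if not self.cell_ids.equals(pd.Index(meta.index)):
            extra = set(meta.index) ^ set(self.cell_ids)
            raise FormatError(
                f"cell metadata does not cover cell ids exactly once; "
                f"mismatched ids include {sorted(extra)[:3]}"
            )
        bad = set(meta["stage"]) - set(VALID_STAGES)
        if bad:
            raise FormatError(f"unknown stage value(s): {sorted(bad)}")
        per_cluster = meta.groupby("cluster_id", observed=True)["stage"].nunique()
        multi = per_cluster[per_cluster > 1]
        if len(multi):
            raise FormatError(
                f"cluster {multi.index[0]!r} is assigned to more than one stage"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset_cells(self, keep: np.ndarray) -> "CellCountMatrix":
        """Return a new matrix restricted to cells where ``keep`` is True."""
        keep = np.asarray(keep, dtype=bool)
        return CellCountMatrix(
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[keep],
            counts=self.counts[:, keep],
            cell_meta=self.cell_meta.loc[keep].copy(),
        )

    def to_anndata(self):
        """Export as an :class:`anndata.AnnData` (cells x genes)."""
        import anndata as ad

        return ad.AnnData(
            X=self.counts.T.tocsr(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=self.gene_ids),
        )


@dataclass
class GeneAnnotation:
    """Per-gene annotation: chromosome class, stratum, gametolog status,
    duplicate-family membership, exon count, locus and mitochondrial flag.

    ``df`` is indexed by gene id. ``pair_id`` links the X and Y copies of an
    ancestral gametolog pair; ``family_id`` groups Y-linked duplicate
    (ampliconic) gene families.
    """

    df: pd.DataFrame

    REQUIRED = ("chrom_class", "stratum", "gametolog_status", "n_exons", "is_mito")
    OPTIONAL = ("chrom", "start", "end", "pair_id", "family_id")

    def __post_init__(self) -> None:
        df = self.df
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate gene id in annotation: {dup!r}")
        missing = set(self.REQUIRED) - set(df.columns)
        if missing:
            raise FormatError(f"annotation missing columns: {sorted(missing)}")
        for col in ("pair_id", "family_id", "chrom"):
            if col not in df.columns:
                df[col] = None
        bad = set(df["chrom_class"]) - set(CHROM_CLASSES)
        if bad:
            raise FormatError(f"unknown chrom_class value(s): {sorted(bad)}")
        df["stratum"] = df["stratum"].astype(str)
        bad = set(df["stratum"]) - set(STRATA)
        if bad:
            raise FormatError(f"unknown stratum value(s): {sorted(bad)}")
        bad = set(df["gametolog_status"]) - set(GAMETOLOG_STATUSES)
        if bad:
            raise FormatError(f"unknown gametolog_status value(s): {sorted(bad)}")
        n_exons = df["n_exons"]
        if np.any(n_exons < 1) or np.any(n_exons != np.round(n_exons)):
            raise FormatError("n_exons must be positive integers")
        df["n_exons"] = n_exons.astype(int)
        df["is_mito"] = df["is_mito"].astype(bool)
        sexlinked = df["chrom_class"].isin(["X", "Y", "PAR"])
        bad_strat = (df["stratum"] != "none") != sexlinked
        if bad_strat.any():
            gid = df.index[bad_strat][0]
            raise FormatError(
                f"gene {gid!r}: a stratum is assigned iff the gene is sex-linked"
            )
        for status, chrom in (("X_only", "X"), ("Y_only", "Y")):
            bad_row = (df["gametolog_status"] == status) & (df["chrom_class"] != chrom)
            if bad_row.any():
                gid = df.index[bad_row][0]
                raise FormatError(
                    f"gene {gid!r}: gametolog_status {status} requires "
                    f"chrom_class {chrom}"
                )
        bad_row = (df["gametolog_status"] == "XY_pair") & ~df["chrom_class"].isin(
            ["X", "Y"]
        )
        if bad_row.any():
            gid = df.index[bad_row][0]
            raise FormatError(f"gene {gid!r}: XY_pair requires chrom_class X or Y")
        self.df = df

    @property
    def gene_ids(self) -> pd.Index:
        return self.df.index

    def genes_where(self, **conditions) -> pd.Index:
        """Gene ids matching all column == value conditions."""
        mask = pd.Series(True, index=self.df.index)
        for col, val in conditions.items():
            mask &= self.df[col] == val
        return self.df.index[mask]

    @property
    def mito_genes(self) -> pd.Index:
        return self.df.index[self.df["is_mito"]]

    def gametolog_pairs(self) -> pd.DataFrame:
        """One row per complete gametolog pair: pair_id, x_gene, y_gene.

        Pairs with a missing X or Y member are excluded (and can be reported
        by the caller).
        """
        paired = self.df[self.df["gametolog_status"] == "XY_pair"]
        rows = []
        for pid, grp in paired.groupby("pair_id"):
            x = grp.index[grp["chrom_class"] == "X"]
            y = grp.index[grp["chrom_class"] == "Y"]
            if len(x) == 1 and len(y) == 1:
                rows.append({"pair_id": pid, "x_gene": x[0], "y_gene": y[0]})
        return pd.DataFrame(rows, columns=["pair_id", "x_gene", "y_gene"])

    def parent_loci(self) -> pd.DataFrame:
        """Gene loci (chrom, start, end, n_exons) for retrocopy detection."""
        cols = ["chrom", "start", "end", "n_exons"]
        missing = [c for c in ("chrom", "start", "end") if c not in self.df.columns]
        if missing or self.df["chrom"].isna().all():
            raise FormatError("annotation carries no gene loci (chrom/start/end)")
        return self.df[cols].copy()


@dataclass
class BulkCountTable:
    """Bulk RNA-seq counts: gene x (organ, replicate).

    ``df`` is indexed by gene id with a (organ, replicate) column MultiIndex;
    organs are brain, liver and testis with three replicates each.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if not isinstance(df.columns, pd.MultiIndex):
            raise FormatError("bulk table requires (organ, replicate) columns")
        bad = set(df.columns.get_level_values(0)) - set(ORGANS)
        if bad:
            raise FormatError(f"unknown organ label(s): {sorted(bad)}")
        vals = df.to_numpy()
        if np.any(vals < 0) or np.any(vals != np.round(vals)):
            raise FormatError("bulk counts must be nonnegative integers")
        self.df = df.astype(np.int64)

    @property
    def organs(self) -> list[str]:
        return sorted(set(self.df.columns.get_level_values(0)))

    def organ(self, name: str) -> pd.DataFrame:
        if name not in self.organs:
            raise FormatError(f"organ {name!r} not present in bulk table")
        return self.df[name]


@dataclass
class DnDsTable:
    """Per-transcript dN, dS and dN/dS between ingroup and outgroup."""

    df: pd.DataFrame

    REQUIRED = ("gene_id", "transcript_id", "dn", "ds", "dnds")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.df.columns)
        if missing:
            raise FormatError(f"dN/dS table missing columns: {sorted(missing)}")
        for col in ("dn", "ds", "dnds"):
            if (self.df[col] < 0).any():
                bad = self.df.loc[self.df[col] < 0].iloc[0]
                raise FormatError(
                    f"negative {col} for transcript {bad['transcript_id']!r}"
                )


@dataclass
class AlignmentRecordSet:
    """Spliced-alignment records of query proteins/CDS against a genome.

    One row per alignment: ``query_id, target_chrom, target_start,
    target_end, n_blocks, block_spans, score``. ``block_spans`` is a list of
    0-based half-open (start, end) intervals contained in
    [target_start, target_end); ``n_blocks == len(block_spans)``.
    """

    df: pd.DataFrame

    REQUIRED = (
        "query_id",
        "target_chrom",
        "target_start",
        "target_end",
        "n_blocks",
        "block_spans",
        "score",
    )

    def __post_init__(self) -> None:
        df = self.df
        missing = set(self.REQUIRED) - set(df.columns)
        if missing:
            raise FormatError(f"alignment table missing columns: {sorted(missing)}")
        for row in df.itertuples():
            spans = row.block_spans
            if row.n_blocks < 1 or len(spans) != row.n_blocks:
                raise FormatError(
                    f"alignment for {row.query_id!r}: n_blocks must equal the "
                    f"number of block spans and be >= 1"
                )
            for s, e in spans:
                if not (row.target_start <= s < e <= row.target_end):
                    raise FormatError(
                        f"alignment for {row.query_id!r}: block [{s},{e}) outside "
                        f"[{row.target_start},{row.target_end})"
                    )

    def for_query(self, query_id: str) -> pd.DataFrame:
        return self.df[self.df["query_id"] == query_id]


# ---------------------------------------------------------------------------
# MTX triplet + metadata
# ---------------------------------------------------------------------------


def read_counts(
    mtx_path, features_path, barcodes_path, meta_path
) -> CellCountMatrix:
    """Read a MatrixMarket count triplet plus cell-metadata TSV.

    The matrix is genes x cells (CellRanger orientation). The metadata TSV
    must have columns ``cell_id, sample_id, cluster_id, stage`` and cover the
    barcodes exactly.
    """
    mat = scipy.io.mmread(str(mtx_path))
    features = pd.read_csv(features_path, sep="\t", header=None, comment="#")
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, comment="#")
    gene_ids = features.iloc[:, 0].astype(str)
    cell_ids = barcodes.iloc[:, 0].astype(str)
    if mat.shape != (len(gene_ids), len(cell_ids)):
        raise FormatError(
            f"matrix is {mat.shape} but features/barcodes give "
            f"{len(gene_ids)} x {len(cell_ids)}"
        )
    meta = pd.read_csv(meta_path, sep="\t", comment="#")
    required = {"cell_id", "sample_id", "cluster_id", "stage"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"cell metadata missing columns: {sorted(missing)}")
    meta = meta.set_index("cell_id")
    if set(meta.index) != set(cell_ids):
        raise FormatError("cell metadata ids do not match barcodes")
    meta = meta.loc[cell_ids]
    return CellCountMatrix(
        gene_ids=pd.Index(gene_ids),
        cell_ids=pd.Index(cell_ids),
        counts=sp.csr_matrix(mat),
        cell_meta=meta,
    )


def write_counts(m: CellCountMatrix, outdir) -> dict[str, Path]:
    """Write matrix.mtx + features.tsv + barcodes.tsv + cell_metadata.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": outdir / "matrix.mtx",
        "features": outdir / "features.tsv",
        "barcodes": outdir / "barcodes.tsv",
        "meta": outdir / "cell_metadata.tsv",
    }
    scipy.io.mmwrite(str(paths["mtx"]), m.counts.tocoo(), field="integer")
    pd.Series(m.gene_ids).to_csv(paths["features"], sep="\t", index=False, header=False)
    pd.Series(m.cell_ids).to_csv(paths["barcodes"], sep="\t", index=False, header=False)
    meta = m.cell_meta.copy()
    meta.index.name = "cell_id"
    meta.to_csv(paths["meta"], sep="\t")
    return paths


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_ANN_COLS = [
    "gene_id",
    "chrom_class",
    "chrom",
    "start",
    "end",
    "stratum",
    "gametolog_status",
    "pair_id",
    "family_id",
    "n_exons",
    "is_mito",
]


def read_annotation(tsv_path) -> GeneAnnotation:
    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    if "gene_id" not in df.columns:
        raise FormatError("annotation TSV must have a gene_id column")
    df = df.set_index("gene_id")
    for col in ("pair_id", "family_id"):
        if col in df.columns:
            df[col] = df[col].where(df[col].notna(), None)
    return GeneAnnotation(df)


def write_annotation(ann: GeneAnnotation, path) -> Path:
    path = Path(path)
    df = ann.df.copy()
    df.index.name = "gene_id"
    cols = [c for c in _ANN_COLS[1:] if c in df.columns]
    df[cols].to_csv(path, sep="\t")
    return path


def read_annotation_gff3(gff_path) -> GeneAnnotation:
    """Read gene annotation from GFF3 ``gene`` features.

    Recognised attribute keys: ``ID`` (gene id), ``chrom_class``, ``stratum``,
    ``gametolog`` (status), ``pair``, ``family``, ``n_exons``, ``mito``.
    GFF3 coordinates (1-based closed) are converted to 0-based half-open.
    """
    rows = []
    with open(gff_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"malformed GFF3 line: {line[:80]!r}")
            chrom, _, ftype, start, end, _, _, _, attrs = parts
            if ftype != "gene":
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if "ID" not in attr:
                raise FormatError(f"GFF3 gene without ID attribute: {line[:80]!r}")
            rows.append(
                {
                    "gene_id": attr["ID"],
                    "chrom": chrom,
                    "start": int(start) - 1,
                    "end": int(end),
                    "chrom_class": attr.get("chrom_class", "autosome"),
                    "stratum": attr.get("stratum", "none"),
                    "gametolog_status": attr.get("gametolog", "none"),
                    "pair_id": attr.get("pair"),
                    "family_id": attr.get("family"),
                    "n_exons": int(attr.get("n_exons", 1)),
                    "is_mito": attr.get("mito", "false").lower() == "true",
                }
            )
    df = pd.DataFrame(rows, columns=_ANN_COLS)
    return GeneAnnotation(df.set_index("gene_id"))


# ---------------------------------------------------------------------------
# bulk / dnds / alignments
# ---------------------------------------------------------------------------


def read_bulk(tsv_path) -> BulkCountTable:
    """Read a bulk count TSV with columns like ``brain_1 .. testis_3``."""
    df = pd.read_csv(tsv_path, sep="\t", comment="#", index_col="gene_id")
    cols = []
    for c in df.columns:
        organ, _, rep = c.rpartition("_")
        if organ not in ORGANS or not rep.isdigit():
            raise FormatError(f"bad bulk column name: {c!r}")
        cols.append((organ, int(rep)))
    df.columns = pd.MultiIndex.from_tuples(cols, names=["organ", "replicate"])
    return BulkCountTable(df)


def write_bulk(b: BulkCountTable, path) -> Path:
    path = Path(path)
    flat = b.df.copy()
    flat.columns = [f"{o}_{r}" for o, r in flat.columns]
    flat.index.name = "gene_id"
    flat.to_csv(path, sep="\t")
    return path


def read_dnds(tsv_path) -> DnDsTable:
    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    return DnDsTable(df)


def write_dnds(t: DnDsTable, path) -> Path:
    path = Path(path)
    t.df.to_csv(path, sep="\t", index=False)
    return path


def _format_spans(spans) -> str:
    return ";".join(f"{s}-{e}" for s, e in spans)


def _parse_spans(text: str) -> list[tuple[int, int]]:
    out = []
    for part in str(text).split(";"):
        s, _, e = part.partition("-")
        try:
            out.append((int(s), int(e)))
        except ValueError as err:
            raise FormatError(f"bad block span {part!r}") from err
    return out


def read_alignments(tsv_path) -> AlignmentRecordSet:
    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    if len(df):
        df["block_spans"] = df["block_spans"].map(_parse_spans)
    else:
        df["block_spans"] = pd.Series([], dtype=object)
    return AlignmentRecordSet(df)


def write_alignments(a: AlignmentRecordSet, path) -> Path:
    path = Path(path)
    df = a.df.copy()
    df["block_spans"] = df["block_spans"].map(_format_spans)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_truth_json(truth_dict: dict, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(truth_dict, fh, indent=1, default=str)
    return path
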