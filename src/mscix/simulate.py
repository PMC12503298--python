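"""Synthetic testis single-cell data with known ground truth.

The generator emulates a stage-synchronised testis 10x experiment: four major
cell types (pre-meiotic, meiotic, post-meiotic, somatic) with cluster labels
nested within stages, sex-linked genes distributed over three evolutionary
strata plus the pseudoautosomal region (PAR), X-only / X+Y / Y-only gametolog
classes, multi-copy Y-linked (ampliconic) gene families, mitochondrial genes
for QC, planted intronless retrocopies, and matched bulk brain/liver/testis
count tables with planted testis-specific genes.

Count law
---------
Counts are gamma-Poisson (negative binomial): for gene g in a cell of stage s,

    count ~ Poisson(Gamma(shape=1/phi, scale=phi * mu_gs * L_c))

with ``phi`` the quadratic overdispersion (Var = mu + phi * mu^2) and ``L_c``
a log-normal per-cell library-size factor. Per-gene stage means ``mu_gs`` are
drawn independently across stages (log-normal around ``base_mean``), modelling
the near-complete turnover of transcriptional programs between spermatogenic
stages; under the null (``msci_multiplier = 1``) the sex-linked ratio
distributions of any two stages are therefore independent and identically
distributed, which is what the stage comparison statistics assume.

Two biological dials are exposed:

* ``msci_multiplier`` in (0, 1] multiplies the meiotic-stage means of all
  non-PAR sex-linked genes (1 = no meiotic silencing, the value observed in
  the study system).
* ``dosage_factor`` in [1, 2] multiplies X-only (hemizygous) gene means in
  the strata listed in ``dosage_strata`` (2 = full dosage compensation).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigError
from .io import (
    STAGES,
    AlignmentRecordSet,
    BulkCountTable,
    CellCountMatrix,
    GeneAnnotation,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "RetroEvent",
    "simulate_counts",
    "simulate_bulk",
    "simulate_alignments",
    "simulate_dnds",
    "write_fixture",
]

_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 21) if i != 19)  # chr19 = sex pair
_CHR_X = "chrX"
_CHR_Y = "chrY"


def _default_cells() -> dict[str, int]:
    return {"pre_meiotic": 300, "meiotic": 300, "post_meiotic": 300, "somatic": 150}


def _default_strata() -> dict[str, float]:
    return {"1": 0.40, "2": 0.25, "3": 0.25, "PAR": 0.10}


@dataclass
class SimConfig:
    """Parameters of the synthetic testis experiment.

    Defaults are chosen to resemble a desk-scale stickleback-like testis
    dataset: a few thousand genes, ~1000 cells over four stages, shallow 10x
    depth (``base_mean`` expected counts per gene per cell), strong quadratic
    overdispersion and no meiotic silencing.
    """

    n_genes_autosome: int = 800
    n_genes_X_only: int = 150
    n_genes_XY_pair: int = 150  # ancestral pairs; each emits an X and a Y copy
    n_genes_Y_only: int = 60
    n_genes_PAR: int = 0  # derived from strata_assignment when 0
    n_genes_mito: int = 10
    n_families: int = 30
    copies_per_family: tuple[int, int] = (2, 10)
    n_meiotic_only_families: int = 10
    strata_assignment: dict[str, float] = field(default_factory=_default_strata)
    n_cells_per_stage: dict[str, int] = field(default_factory=_default_cells)
    n_clusters_per_stage: int = 2
    n_samples: int = 2
    base_mean: float = 0.5
    dispersion: float = 0.3  # phi in Var = mu + phi mu^2
    stage_lognorm_sigma: float = 0.3
    libsize_sigma: float = 0.3
    msci_multiplier: float = 1.0
    dosage_factor: float = 2.0
    dosage_strata: tuple[str, ...] = ("1",)
    y_mean_factor: float = 0.5
    silent_y_fraction: float = 0.15
    induced_fraction: float = 0.2
    induced_boost: float = 4.0
    mito_fraction_range: tuple[float, float] = (0.005, 0.04)
    n_testis_specific: int = 20
    bulk_mean: float = 50.0
    n_retro_events: int = 9
    n_retro_outgroup_events: int = 3
    dnds_mean: float = 0.2
    dnds_shape: float = 2.0
    y_hemi_dnds_factor: float = 1.5
    xy_gametolog_dnds_factor: float = 0.7
    fasterx_induced_shift: float = 1.5
    dnds_sentinel_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes_autosome": self.n_genes_autosome,
            "n_genes_X_only": self.n_genes_X_only,
            "n_genes_XY_pair": self.n_genes_XY_pair,
            "n_genes_Y_only": self.n_genes_Y_only,
            "n_genes_mito": self.n_genes_mito,
            "n_families": self.n_families,
            "n_samples": self.n_samples,
            "n_clusters_per_stage": self.n_clusters_per_stage,
        }
        for name, val in counts.items():
            if val < 0:
                raise ConfigError(f"{name} must be nonnegative, got {val}")
        if self.n_samples < 1 or self.n_clusters_per_stage < 1:
            raise ConfigError("n_samples and n_clusters_per_stage must be >= 1")
        total = sum(self.strata_assignment.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"strata_assignment proportions must sum to 1, got {total}"
            )
        if set(self.strata_assignment) != {"1", "2", "3", "PAR"}:
            raise ConfigError("strata_assignment keys must be {'1','2','3','PAR'}")
        lo, hi = self.copies_per_family
        if not (2 <= lo <= hi <= 30):
            raise ConfigError("copies_per_family must lie within [2, 30]")
        if set(self.n_cells_per_stage) != set(STAGES):
            raise ConfigError(f"n_cells_per_stage keys must be {set(STAGES)}")
        if any(v < 0 for v in self.n_cells_per_stage.values()):
            raise ConfigError("cell counts must be nonnegative")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        if self.base_mean <= 0:
            raise ConfigError("base_mean must be positive")
        if not (0 < self.msci_multiplier <= 1):
            raise ConfigError("msci_multiplier must be in (0, 1]")
        if not (1 <= self.dosage_factor <= 2):
            raise ConfigError("dosage_factor must be in [1, 2]")
        lo, hi = self.mito_fraction_range
        if not (0 <= lo <= hi < 1):
            raise ConfigError("mito_fraction_range must satisfy 0 <= lo <= hi < 1")
        if not (0 <= self.silent_y_fraction <= 1):
            raise ConfigError("silent_y_fraction must be in [0, 1]")
        if not (0 <= self.induced_fraction <= 1):
            raise ConfigError("induced_fraction must be in [0, 1]")


@dataclass(frozen=True)
class RetroEvent:
    """A planted retrotransposition: an intronless copy of a multi-exon parent."""

    parent_gene_id: str
    copy_chrom: str
    copy_start: int
    copy_end: int
    in_outgroup: bool


@dataclass
class SimTruth:
    """Ground truth emitted next to the simulated data.

    ``expected_means`` holds the per-gene expected count per cell for each
    stage (before library-size scaling); ``induced_stage`` the planted
    induced-stage label per gene ('none' when not planted);
    ``gametolog_status`` the per-gene class; ``testis_specific`` the genes
    planted as testis-only in the bulk tables; ``retro_events`` the planted
    retrocopies.
    """

    expected_means: pd.DataFrame
    induced_stage: pd.Series
    gametolog_status: pd.Series
    testis_specific: list[str]
    retro_events: list[RetroEvent]

    def to_dict(self) -> dict:
        return {
            "expected_means": self.expected_means.round(6).to_dict(orient="index"),
            "induced_stage": self.induced_stage.to_dict(),
            "gametolog_status": self.gametolog_status.to_dict(),
            "testis_specific": list(self.testis_specific),
            "retro_events": [dataclasses.asdict(e) for e in self.retro_events],
        }


# ---------------------------------------------------------------------------
# gene universe (shared by counts, bulk and alignments)
# ---------------------------------------------------------------------------


def _rng_children(seed: int, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(n)]


def _draw_strata(rng, n: int, props: dict[str, float], keys: tuple[str, ...]):
    p = np.array([props[k] for k in keys], dtype=float)
    p = p / p.sum()
    return rng.choice(np.array(keys, dtype=object), size=n, p=p)


def _build_genes(config: SimConfig, rng: np.random.Generator):
    """Deterministically lay out the gene universe.

    Returns ``(annotation, extras)`` where extras carries the silent-Y gene
    set, family stage restrictions, testis-specific genes and retro events.
    PAR genes are emitted as a separate recombining class (gametolog 'none');
    the non-PAR strata proportions are renormalised over {1,2,3} for the
    degenerate gametolog classes.
    """
    rows: list[dict] = []
    cursor: dict[str, int] = {}

    def place(chrom: str, n_exons: int) -> tuple[int, int]:
        start = cursor.get(chrom, 10_000)
        end = start + 1500 * n_exons
        cursor[chrom] = end + 10_000
        return start, end

    def add(gene_id, chrom_class, chrom, stratum, status, pair_id, family_id,
            n_exons, is_mito=False):
        start, end = place(chrom, n_exons)
        rows.append(
            dict(gene_id=gene_id, chrom_class=chrom_class, chrom=chrom,
                 start=start, end=end, stratum=stratum,
                 gametolog_status=status, pair_id=pair_id,
                 family_id=family_id, n_exons=n_exons, is_mito=is_mito)
        )

    nonpar = ("1", "2", "3")
    n_sex = (
        config.n_genes_X_only + 2 * config.n_genes_XY_pair + config.n_genes_Y_only
    )
    n_par = config.n_genes_PAR or int(
        round(config.strata_assignment["PAR"] * n_sex)
    )

    for i in range(config.n_genes_autosome):
        chrom = _AUTOSOMES[i % len(_AUTOSOMES)]
        add(f"auto-{i:04d}", "autosome", chrom, "none", "none", None, None,
            int(rng.integers(1, 13)))
    for i in range(config.n_genes_mito):
        add(f"mito-{i:02d}", "autosome", "chrM", "none", "none", None, None, 1,
            is_mito=True)
    x_strata = _draw_strata(rng, config.n_genes_X_only,
                            config.strata_assignment, nonpar)
    for i in range(config.n_genes_X_only):
        add(f"xonly-{i:04d}", "X", _CHR_X, x_strata[i], "X_only", None, None,
            int(rng.integers(1, 13)))
    pair_strata = _draw_strata(rng, config.n_genes_XY_pair,
                               config.strata_assignment, nonpar)
    for i in range(config.n_genes_XY_pair):
        pid = f"pair-{i:04d}"
        n_ex = int(rng.integers(1, 13))
        add(f"xy-{i:04d}-X", "X", _CHR_X, pair_strata[i], "XY_pair", pid, None, n_ex)
        add(f"xy-{i:04d}-Y", "Y", _CHR_Y, pair_strata[i], "XY_pair", pid, None, n_ex)
    y_strata = _draw_strata(rng, config.n_genes_Y_only,
                            config.strata_assignment, nonpar)
    for i in range(config.n_genes_Y_only):
        add(f"yonly-{i:04d}", "Y", _CHR_Y, y_strata[i], "Y_only", None, None,
            int(rng.integers(1, 13)))
    for i in range(n_par):
        add(f"par-{i:04d}", "PAR", _CHR_X, "PAR", "none", None, None,
            int(rng.integers(1, 13)))

    fam_sizes = rng.integers(config.copies_per_family[0],
                             config.copies_per_family[1] + 1,
                             size=config.n_families)
    fam_strata = _draw_strata(rng, config.n_families,
                              config.strata_assignment, nonpar)
    meiotic_only_families: set[str] = set()
    for i in range(config.n_families):
        fid = f"fam-{i:03d}"
        if i < min(config.n_meiotic_only_families, config.n_families):
            meiotic_only_families.add(fid)
        for j in range(fam_sizes[i]):
            add(f"{fid}-copy{j:02d}", "Y", _CHR_Y, fam_strata[i], "none",
                None, fid, int(rng.integers(1, 13)))

    df = pd.DataFrame(rows).set_index("gene_id")
    ann = GeneAnnotation(df)

    # silent Y copies of gametolog pairs (degenerated, expression lost)
    n_silent = int(round(config.silent_y_fraction * config.n_genes_XY_pair))
    silent_pairs = rng.choice(config.n_genes_XY_pair, size=n_silent, replace=False)
    silent_y = {f"xy-{i:04d}-Y" for i in silent_pairs}

    # testis-specific genes (X-linked, per the study system's observation)
    x_genes = [g for g in df.index
               if df.loc[g, "chrom_class"] == "X"]
    n_ts = min(config.n_testis_specific, len(x_genes))
    testis_specific = list(rng.choice(np.array(x_genes, dtype=object),
                                      size=n_ts, replace=False))

    # retrocopy events: multi-exon autosomal/X parents, intronless copies
    eligible = [g for g in df.index
                if df.loc[g, "n_exons"] >= 2
                and df.loc[g, "chrom_class"] in ("autosome", "X")
                and not df.loc[g, "is_mito"]]
    n_events = config.n_retro_events + config.n_retro_outgroup_events
    parents = rng.choice(np.array(eligible, dtype=object),
                         size=min(n_events, len(eligible)), replace=False)
    retro_events = []
    for k, parent in enumerate(parents):
        chrom = _AUTOSOMES[int(rng.integers(len(_AUTOSOMES)))]
        start = cursor.get(chrom, 10_000) + 50_000 * (k + 1)
        length = int(df.loc[parent, "end"] - df.loc[parent, "start"])
        retro_events.append(
            RetroEvent(parent_gene_id=str(parent), copy_chrom=chrom,
                       copy_start=start, copy_end=start + length,
                       in_outgroup=k >= config.n_retro_events)
        )

    extras = {
        "silent_y": silent_y,
        "meiotic_only_families": meiotic_only_families,
        "testis_specific": testis_specific,
        "retro_events": retro_events,
    }
    return ann, extras


def _stage_means(config: SimConfig, ann: GeneAnnotation, extras: dict,
                 rng: np.random.Generator) -> tuple[pd.DataFrame, pd.Series]:
    """Expected count per cell for each gene x stage, plus induced truth.

    Stage means are iid log-normal per (gene, stage); the MSCI multiplier,
    dosage factor, Y attenuation, silent-Y zeroing, meiotic-only family
    restriction and induced-stage boosts are applied on top, in that order of
    description. Mitochondrial gene means are handled per cell (their summed
    fraction is drawn per cell), so they carry a placeholder stage mean here.
    """
    df = ann.df
    genes = df.index
    n_g = len(genes)
    mu = config.base_mean * np.exp(
        rng.normal(0.0, config.stage_lognorm_sigma, size=(n_g, len(STAGES)))
        - 0.5 * config.stage_lognorm_sigma**2
    )
    mu = pd.DataFrame(mu, index=genes, columns=list(STAGES))

    is_y = (df["chrom_class"] == "Y").to_numpy()
    mu.loc[is_y] *= config.y_mean_factor

    dosage_mask = (
        (df["gametolog_status"] == "X_only")
        & df["stratum"].isin(config.dosage_strata)
    ).to_numpy()
    mu.loc[dosage_mask] *= config.dosage_factor

    silent = genes.isin(extras["silent_y"])
    mu.loc[silent] = 0.0

    fam_meiotic = df["family_id"].isin(extras["meiotic_only_families"]).to_numpy()
    for stage in STAGES:
        if stage != "meiotic":
            mu.loc[fam_meiotic, stage] = 0.0

    # planted induced genes: one stage boosted well past the 2x-median rule
    induced = pd.Series("none", index=genes, name="induced_stage")
    candidates = genes[~df["is_mito"] & ~silent]
    n_induced = int(round(config.induced_fraction * len(candidates)))
    if n_induced:
        chosen = rng.choice(np.array(candidates, dtype=object),
                            size=n_induced, replace=False)
        stages_arr = rng.choice(np.array(STAGES, dtype=object), size=n_induced)
        for g, s in zip(chosen, stages_arr):
            others = [t for t in STAGES if t != s]
            floor = config.induced_boost * float(np.median(mu.loc[g, others])) * 1.1
            mu.loc[g, s] = max(float(mu.loc[g, s]) * config.induced_boost, floor)
            induced.loc[g] = s

    # meiotic silencing dial: non-PAR sex-linked genes only
    sex_mask = df["chrom_class"].isin(["X", "Y"]).to_numpy()
    mu.loc[sex_mask, "meiotic"] *= config.msci_multiplier

    mu.loc[df["is_mito"].to_numpy()] = np.nan  # drawn per cell, see _sample_cells
    return mu, induced


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def simulate_counts(
    config: SimConfig,
) -> tuple[CellCountMatrix, GeneAnnotation, SimTruth]:
    """Draw a cell x gene count matrix with cluster labels nested in stages.

    Deterministic under a fixed ``config.seed``: the gene universe, cell
    layout and all count draws derive from independent child streams of the
    seed, so :func:`simulate_bulk` and :func:`simulate_alignments` see the
    identical gene universe.
    """
    config.validate()
    rng_genes, rng_cells, _, _ = _rng_children(config.seed, 4)
    ann, extras = _build_genes(config, rng_genes)
    mu, induced = _stage_means(config, ann, extras, rng_cells)

    n_cells_total = sum(config.n_cells_per_stage.values())
    if n_cells_total == 0:
        raise ConfigError("n_cells_per_stage requests zero cells in every stage")

    stage_of_cell: list[str] = []
    cluster_of_cell: list[str] = []
    sample_of_cell: list[str] = []
    cell_ids: list[str] = []
    i = 0
    for stage in STAGES:
        n = config.n_cells_per_stage[stage]
        for j in range(n):
            stage_of_cell.append(stage)
            cluster_of_cell.append(f"{stage}.{j % config.n_clusters_per_stage}")
            sample_of_cell.append(
                f"sample{(j // config.n_clusters_per_stage) % config.n_samples + 1}"
            )
            cell_ids.append(f"cell-{i:05d}")
            i += 1

    genes = ann.df.index
    stage_idx = np.array([STAGES.index(s) for s in stage_of_cell])
    mu_arr = mu.to_numpy()  # genes x stages, NaN for mito rows
    lam = mu_arr[:, stage_idx]  # genes x cells

    lib = np.exp(rng_cells.normal(0.0, config.libsize_sigma, size=n_cells_total)
                 - 0.5 * config.libsize_sigma**2)
    lam = lam * lib[None, :]

    # mitochondrial genes: per-cell summed fraction drawn from the range
    mito_mask = ann.df["is_mito"].to_numpy()
    if mito_mask.any():
        lo, hi = config.mito_fraction_range
        frac = rng_cells.uniform(lo, hi, size=n_cells_total)
        nonmito_total = np.nansum(lam[~mito_mask], axis=0)
        mito_total = nonmito_total * frac / (1.0 - frac)
        lam[mito_mask] = mito_total[None, :] / mito_mask.sum()

    phi = config.dispersion
    shape = 1.0 / phi
    with np.errstate(invalid="ignore"):
        gamma_draw = rng_cells.gamma(shape, scale=np.maximum(lam, 0.0) * phi)
    counts = rng_cells.poisson(gamma_draw).astype(np.int64)

    meta = pd.DataFrame(
        {
            "sample_id": sample_of_cell,
            "cluster_id": cluster_of_cell,
            "stage": stage_of_cell,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    matrix = CellCountMatrix(
        gene_ids=genes,
        cell_ids=pd.Index(cell_ids),
        counts=sp.csr_matrix(counts),
        cell_meta=meta,
    )
    truth = SimTruth(
        expected_means=mu,
        induced_stage=induced,
        gametolog_status=ann.df["gametolog_status"].copy(),
        testis_specific=extras["testis_specific"],
        retro_events=extras["retro_events"],
    )
    return matrix, ann, truth


def simulate_bulk(
    config: SimConfig, organs: tuple[str, ...] = ("brain", "liver", "testis")
) -> BulkCountTable:
    """Bulk RNA-seq counts (3 replicates per organ) for the same gene universe.

    Planted testis-specific genes have counts > 1 only in testis (guaranteed
    by construction: at least one testis replicate is floored at 2, brain and
    liver draws are capped at 1). All other genes are broadly expressed with
    negative-binomial counts around a gene-specific mean.
    """
    config.validate()
    unknown = set(organs) - {"brain", "liver", "testis"}
    if unknown:
        raise ConfigError(f"unknown organ label(s): {sorted(unknown)}")
    rng_genes, rng_cells, rng_bulk, _ = _rng_children(config.seed, 4)
    ann, extras = _build_genes(config, rng_genes)
    mu, _ = _stage_means(config, ann, extras, rng_cells)

    genes = ann.df.index
    rel = mu.fillna(config.base_mean).to_numpy().mean(axis=1)  # mito: baseline
    denom = rel.mean() if rel.mean() > 0 else 1.0
    bulk_mu = config.bulk_mean * rel / denom

    phi = config.dispersion
    shape = 1.0 / phi
    ts = set(extras["testis_specific"])
    ts_mask = genes.isin(ts)
    cols: dict[tuple[str, int], np.ndarray] = {}
    for organ in organs:
        for rep in (1, 2, 3):
            lam = rng_bulk.gamma(shape, scale=np.maximum(bulk_mu, 0.0) * phi)
            draw = rng_bulk.poisson(lam).astype(np.int64)
            if organ == "testis":
                if rep == 1:
                    draw[ts_mask] = np.maximum(draw[ts_mask], 2)
            else:
                draw[ts_mask] = np.minimum(draw[ts_mask], 1)
            cols[(organ, rep)] = draw
    df = pd.DataFrame(cols, index=genes)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["organ", "replicate"])
    return BulkCountTable(df)


def simulate_dnds(config: SimConfig) -> "DnDsTable":
    """Per-transcript dN/dS table mirroring the divergence structure the
    faster-X contrast looks for.

    Each gene carries 1-3 transcripts with gamma-distributed dN/dS around a
    class-specific mean: Y-hemizygous genes elevated (coding degeneration),
    X+Y gametologs reduced (slower-X purifying selection), and X-hemizygous
    genes that are induced in a spermatogenesis stage shifted upward by
    ``fasterx_induced_shift`` (the testis-restricted faster-X effect). A
    small fraction of transcripts carries the unreliable-estimate sentinel
    value 99 (no synonymous substitutions).
    """
    from .io import DnDsTable

    config.validate()
    rng_genes, rng_cells, _, rng_dnds = _rng_children(config.seed, 4)
    ann, extras = _build_genes(config, rng_genes)
    _, induced = _stage_means(config, ann, extras, rng_cells)

    from .gametologs import assign_gene_classes

    cls = assign_gene_classes(ann)
    rows = []
    for gene in ann.df.index:
        gene_cls = cls.get(gene)
        if not isinstance(gene_cls, str):
            continue
        mean = config.dnds_mean
        if gene_cls == "Y_hemizygous":
            mean *= config.y_hemi_dnds_factor
        elif gene_cls in ("XY_gametolog_X", "XY_gametolog_Y"):
            mean *= config.xy_gametolog_dnds_factor
        elif gene_cls == "X_hemizygous" and induced.get(gene, "none") != "none":
            mean *= config.fasterx_induced_shift
        n_tx = int(rng_dnds.integers(1, 4))
        for t in range(n_tx):
            if rng_dnds.random() < config.dnds_sentinel_fraction:
                dn, ds, dnds = 0.05, 0.0, 99.0
            else:
                dnds = float(
                    rng_dnds.gamma(config.dnds_shape,
                                   scale=mean / config.dnds_shape)
                )
                ds = float(rng_dnds.uniform(0.05, 0.3))
                dn = dnds * ds
            rows.append(
                {"gene_id": gene, "transcript_id": f"{gene}.t{t + 1}",
                 "dn": round(dn, 6), "ds": round(ds, 6),
                 "dnds": round(dnds, 6)}
            )
    return DnDsTable(pd.DataFrame(rows, columns=list(DnDsTable.REQUIRED)))


def simulate_alignments(
    config: SimConfig,
) -> tuple[AlignmentRecordSet, AlignmentRecordSet]:
    """Spliced-alignment fixtures for the ingroup and outgroup genomes.

    Every gene receives a parent-locus record whose block count equals its
    exon count. Planted retrocopies appear as single-block records at a
    distinct locus in the ingroup; events flagged ``in_outgroup`` also receive
    a single-block record at the orthologous locus (same chromosome name and
    span) in the outgroup. Outgroup parent loci are emitted for all genes.
    """
    config.validate()
    rng_genes, _, _, _ = _rng_children(config.seed, 4)
    ann, extras = _build_genes(config, rng_genes)

    def parent_record(row) -> dict:
        n_ex = int(row.n_exons)
        start, end = int(row.start), int(row.end)
        width = (end - start) // n_ex
        spans = []
        for k in range(n_ex):
            s = start + k * width
            e = min(s + max(width - 200, 1), end)
            spans.append((s, e))
        return dict(query_id=row.Index, target_chrom=row.chrom,
                    target_start=start, target_end=end, n_blocks=n_ex,
                    block_spans=spans, score=1000.0)

    ingroup_rows = [parent_record(r) for r in ann.df.itertuples()]
    outgroup_rows = [parent_record(r) for r in ann.df.itertuples()]
    for ev in extras["retro_events"]:
        copy = dict(query_id=ev.parent_gene_id, target_chrom=ev.copy_chrom,
                    target_start=ev.copy_start, target_end=ev.copy_end,
                    n_blocks=1,
                    block_spans=[(ev.copy_start, ev.copy_end)], score=800.0)
        ingroup_rows.append(copy)
        if ev.in_outgroup:
            outgroup_rows.append(dict(copy))
    cols = list(AlignmentRecordSet.REQUIRED)
    ingroup = AlignmentRecordSet(pd.DataFrame(ingroup_rows, columns=cols))
    outgroup = AlignmentRecordSet(pd.DataFrame(outgroup_rows, columns=cols))
    return ingroup, outgroup


def write_fixture(config: SimConfig, outdir) -> dict:
    """Simulate everything and write the on-disk fixture bundle.

    Emits the MTX triplet + cell metadata, annotation TSV, bulk TSV, dN/dS
    placeholder-free alignment TSVs and truth JSON under ``outdir``.
    """
    from pathlib import Path

    from .io import (
        write_alignments,
        write_annotation,
        write_bulk,
        write_counts,
        write_dnds,
        write_truth_json,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, ann, truth = simulate_counts(config)
    bulk = simulate_bulk(config)
    ingroup, outgroup = simulate_alignments(config)
    paths = write_counts(matrix, outdir)
    paths["annotation"] = write_annotation(ann, outdir / "annotation.tsv")
    paths["bulk"] = write_bulk(bulk, outdir / "bulk.tsv")
    paths["dnds"] = write_dnds(simulate_dnds(config), outdir / "dnds.tsv")
    paths["ingroup"] = write_alignments(ingroup, outdir / "alignments_ingroup.tsv")
    paths["outgroup"] = write_alignments(outgroup, outdir / "alignments_outgroup.tsv")
    paths["truth"] = write_truth_json(truth.to_dict(), outdir / "truth.json")
    return paths
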