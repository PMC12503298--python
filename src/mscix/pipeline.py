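"""End-to-end orchestration: QC -> pseudobulk -> markers -> MSCI ratios ->
dosage -> mono-allelic -> amplicons -> faster-X -> retrocopies.

The run is driven by a :class:`RunConfig` (loadable from YAML). Optional
inputs (bulk, dN/dS, alignments) may be omitted; the stages that need them
are then skipped with a notice. Every output TSV carries the configuration
hash in a comment header, so re-running with any altered threshold changes
every header. The pipeline itself is deterministic; randomness exists only
in the simulator.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import amplicons as _amplicons
from . import gametologs as _gam
from . import msci as _msci
from . import qc as _qc
from . import retro as _retro
from .errors import ConfigError
from .io import (
    read_alignments,
    read_annotation,
    read_bulk,
    read_counts,
    read_dnds,
)

__all__ = ["RunConfig", "RunReport", "run_all"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs, thresholds and statistical flags for a full run."""

    mtx: str
    features: str
    barcodes: str
    cell_meta: str
    annotation: str
    outdir: str
    bulk: str | None = None
    dnds: str | None = None
    ingroup_alignments: str | None = None
    outgroup_alignments: str | None = None
    min_features: int = 200
    max_features: int = 3000
    max_mito: float = 0.05
    exclude_clusters: list[str] = field(default_factory=list)
    stage_map: dict[str, str] = field(default_factory=dict)
    marker_min_pct: float = 0.25
    marker_min_log2fc: float = 0.25
    marker_alpha: float = 0.01
    marker_correction: str = "bonferroni"
    induced_variant: str = "median_others"
    by_stratum: bool = True
    include_zero_autosomes: bool = False
    concordance_top_n: int = 2000
    run_markers: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as err:
            raise ConfigError(str(err)) from err

    def validate(self) -> None:
        required = {
            "mtx": self.mtx,
            "features": self.features,
            "barcodes": self.barcodes,
            "cell_meta": self.cell_meta,
            "annotation": self.annotation,
        }
        for name, p in required.items():
            if p is None or not Path(p).exists():
                raise ConfigError(f"required input {name!r} missing: {p}")
        for name in ("bulk", "dnds", "ingroup_alignments", "outgroup_alignments"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"optional input {name!r} does not exist: {p}")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """What a run produced, skipped and excluded (with reason codes)."""

    config_hash: str
    stages_completed: list[str] = field(default_factory=list)
    stages_skipped: list[dict] = field(default_factory=list)
    exclusions: list[dict] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_all(config: RunConfig) -> RunReport:
    """Execute every stage in order; any stage failure raises a typed error."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    report = RunReport(config_hash=chash)

    def done(stage: str, name: str, df: pd.DataFrame, index: bool = False):
        path = outdir / f"{name}.tsv"
        _write_tsv(df, path, chash, index=index)
        report.outputs[name] = str(path)
        if stage not in report.stages_completed:
            report.stages_completed.append(stage)

    matrix = read_counts(config.mtx, config.features, config.barcodes,
                         config.cell_meta)
    ann = read_annotation(config.annotation)
    if config.stage_map:
        meta = matrix.cell_meta.copy()
        unknown = set(meta["cluster_id"]) - set(config.stage_map)
        if unknown:
            raise ConfigError(
                f"stage_map does not cover clusters: {sorted(unknown)}"
            )
        meta["stage"] = meta["cluster_id"].map(config.stage_map)
        matrix.cell_meta = meta

    # --- qc ---
    flags = _qc.qc_flags(matrix, ann, config.min_features, config.max_features,
                         config.max_mito)
    for reason, col in (("feature_bounds", "pass_features"),
                        ("mito_fraction", "pass_mito")):
        n_bad = int((~flags[col]).sum())
        if n_bad:
            report.exclusions.append(
                {"item": "cells", "reason": reason, "n": n_bad}
            )
    filtered = matrix.subset_cells(flags["keep"].to_numpy())
    done("qc", "qc_flags", flags, index=True)

    # --- pseudobulk ---
    pb = _qc.pseudobulk(filtered)
    if config.exclude_clusters:
        present = [c for c in config.exclude_clusters if c in pb.df.columns]
        if present:
            report.exclusions.append(
                {"item": "clusters", "reason": "not_replicated", "n": len(present)}
            )
            pb = pb.drop_clusters(present)
    done("pseudobulk", "pseudobulk", pb.df, index=True)

    # --- markers ---
    if config.run_markers:
        markers = _qc.find_markers(
            filtered,
            min_pct=config.marker_min_pct,
            min_log2fc=config.marker_min_log2fc,
            alpha=config.marker_alpha,
            correction=config.marker_correction,
        )
        done("markers", "markers", markers)
    else:
        report.stages_skipped.append(
            {"stage": "markers", "reason": "disabled in config"}
        )

    # --- concordance (needs >= 2 samples) ---
    samples = sorted(set(filtered.cell_meta["sample_id"]))
    if len(samples) >= 2:
        pb_by_sample = {
            s: _qc.pseudobulk(
                filtered.subset_cells(
                    (filtered.cell_meta["sample_id"] == s).to_numpy()
                )
            )
            for s in samples
        }
        conc = _qc.cluster_concordance(pb_by_sample, config.concordance_top_n)
        done("concordance", "concordance", conc, index=True)
    else:
        report.stages_skipped.append(
            {"stage": "concordance", "reason": "fewer than two samples"}
        )

    # --- msci ratios ---
    rt = _msci.normalize_to_autosome_median(
        pb, ann, include_zeros=config.include_zero_autosomes
    )
    done("msci", "stage_ratios", rt)
    tests = _msci.stage_pairwise_tests(rt, by_stratum=False)
    done("msci", "stage_tests", tests)
    if config.by_stratum:
        done("msci", "stage_tests_by_stratum",
             _msci.stage_pairwise_tests(rt, by_stratum=True))
    cluster_long, cluster_tests = _msci.per_cluster_ratio_profile(pb, ann)
    done("msci", "cluster_ratios", cluster_long)
    done("msci", "cluster_ratio_tests", cluster_tests)
    try:
        _msci.plot_stage_ratios(rt, outdir / "stage_ratios.png")
        report.outputs["stage_ratios_plot"] = str(outdir / "stage_ratios.png")
    except Exception as err:  # plotting must never fail the run
        log.warning("ratio plot failed: %s", err)

    # --- bulk-dependent stages ---
    bulk = None
    if config.bulk:
        bulk = read_bulk(config.bulk)
        ts = _qc.testis_specific(bulk)
        done("testis_specific", "testis_specific",
             pd.DataFrame(sorted(ts), columns=["gene_id"]))
        broad = _msci.filter_broadly_expressed(rt, ts)
        done("msci", "stage_ratios_broad", broad)
        calls = _gam.call_monoallelic(pb, ann, bulk)
        done("monoallelic", "monoallelic_calls", calls)
        enr_rows = []
        for allele_class in ("x_only", "y_only"):
            if len(calls):
                for res in _gam.monoallelic_enrichment(calls, allele_class):
                    enr_rows.append(
                        {"allele_class": allele_class, "stage": res.stage,
                         "k": res.k, "K": res.K, "n": res.n, "N": res.N,
                         "expected": res.expected,
                         "signed_fold": res.fold_str(), "p": res.p,
                         "tail": res.tail}
                    )
        done("monoallelic", "monoallelic_enrichment", pd.DataFrame(enr_rows))
    else:
        report.stages_skipped.append(
            {"stage": "testis_specific", "reason": "no bulk input"}
        )
        report.stages_skipped.append(
            {"stage": "monoallelic", "reason": "no bulk input"}
        )

    # --- dosage ---
    dosage = _gam.dosage_contrast(rt, ann, by_stratum=False)
    done("dosage", "dosage_contrast", dosage)
    if config.by_stratum:
        done("dosage", "dosage_contrast_by_stratum",
             _gam.dosage_contrast(rt, ann, by_stratum=True))

    # --- amplicons ---
    ft = _amplicons.family_expression(pb, ann)
    if len(ft.per_stage):
        done("amplicons", "family_stage_expression", ft.per_stage, index=True)
        done("amplicons", "family_cluster_expression", ft.per_cluster,
             index=True)
        done("amplicons", "families_expressed_per_stage",
             _amplicons.count_expressed_families(ft).to_frame(), index=True)
    else:
        report.stages_skipped.append(
            {"stage": "amplicons", "reason": "no duplicate families annotated"}
        )

    # --- induced + faster-X ---
    induced = _qc.classify_induced(pb, variant=config.induced_variant)
    done("induced", "induced_stage", induced.to_frame(), index=True)
    if config.dnds:
        dnds = _gam.dnds_prepare(read_dnds(config.dnds))
        fx = _gam.faster_x_contrast(dnds, ann, induced)
        done("fasterx", "fasterx_pairwise", fx.pairwise)
        done("fasterx", "fasterx_kruskal", fx.kruskal)
        done("fasterx", "fasterx_by_stage", fx.by_stage)
    else:
        report.stages_skipped.append(
            {"stage": "fasterx", "reason": "no dN/dS input"}
        )

    # --- retro ---
    if config.ingroup_alignments and config.outgroup_alignments:
        ingroup = read_alignments(config.ingroup_alignments)
        outgroup = read_alignments(config.outgroup_alignments)
        candidates = _retro.detect_retro(ingroup, outgroup, ann.parent_loci())
        done("retro", "retro_candidates", candidates)
    else:
        report.stages_skipped.append(
            {"stage": "retro", "reason": "no alignment inputs"}
        )

    report.to_json(outdir / "run_report.json")
    report.outputs["run_report"] = str(outdir / "run_report.json")
    return report
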