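"""Self-calibration of the MSCI detector on the synthetic generator.

These routines measure the operating characteristics that justify trusting
the pipeline on real data: type-I error of the meiotic vs pre-meiotic stage
test under the no-silencing null, power and effect-size recovery under
strong silencing, stratum-confined dosage-compensation recovery, and the
retrocopy detector's truth table on planted events. Each replicate draws a
fresh dataset from :mod:`mscix.simulate` and runs the ordinary analysis
path (pseudobulk -> autosome-median normalisation -> rank statistics).

Replicate scale (500 sex-linked genes, 200 cells per stage) mirrors the
per-stage gene counts a single stickleback-like testis dataset yields.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .gametologs import dosage_contrast
from .msci import normalize_to_autosome_median, stage_pairwise_tests
from .qc import pseudobulk
from .retro import detect_retro
from .simulate import (
    SimConfig,
    simulate_alignments,
    simulate_counts,
)

__all__ = [
    "stage_test_config",
    "dosage_config",
    "null_rejection_rate",
    "msci_power_and_quotient",
    "dosage_recovery_rate",
    "retro_truth_table",
]


def _rep_seeds(seed: int, n: int) -> list[int]:
    """Independent per-replicate seeds derived from one master seed."""
    states = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in states]


def stage_test_config(seed: int, msci_multiplier: float = 1.0) -> SimConfig:
    """Study conditions for the stage-test calibration: 500 X-linked genes
    against the default autosomal background, 200 cells in each of the
    pre-meiotic and meiotic stages."""
    return SimConfig(
        n_genes_X_only=500,
        n_genes_XY_pair=0,
        n_genes_Y_only=0,
        n_families=0,
        n_meiotic_only_families=0,
        msci_multiplier=msci_multiplier,
        n_cells_per_stage={
            "pre_meiotic": 200, "meiotic": 200, "post_meiotic": 0,
            "somatic": 0,
        },
        n_samples=1,
        seed=seed,
    )


def dosage_config(seed: int) -> SimConfig:
    """Study conditions for dosage recovery: defaults (150 X-only genes,
    150 X+Y pairs over three strata, doubling confined to stratum 1)."""
    return SimConfig(seed=seed)


def _meiotic_vs_premeiotic_p(config: SimConfig) -> tuple[float, float]:
    """(p, quotient) of the X-chromosome meiotic vs pre-meiotic contrast."""
    m, ann, _ = simulate_counts(config)
    rt = normalize_to_autosome_median(pseudobulk(m), ann)
    tests = stage_pairwise_tests(rt[rt["chrom_class"] == "X"])
    row = tests[
        (tests["stage_a"] == "pre_meiotic") & (tests["stage_b"] == "meiotic")
    ].iloc[0]
    x = rt[rt["chrom_class"] == "X"]
    mean_pre = x.loc[x["stage"] == "pre_meiotic", "ratio"].mean()
    mean_mei = x.loc[x["stage"] == "meiotic", "ratio"].mean()
    return float(row["p"]), float(mean_mei / mean_pre)


def null_rejection_rate(
    n_reps: int = 200, seed: int = 1, alpha: float = 0.05
) -> float:
    """Type-I error of the meiotic vs pre-meiotic test with no silencing."""
    rejections = 0
    for s in _rep_seeds(seed, n_reps):
        p, _ = _meiotic_vs_premeiotic_p(stage_test_config(s))
        rejections += int(p < alpha)
    return rejections / n_reps


def msci_power_and_quotient(
    n_reps: int = 100, seed: int = 2, msci_multiplier: float = 0.1,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Power of the same test under strong silencing, and the recovered
    meiotic / pre-meiotic mean-ratio quotient (averaged over replicates)."""
    rejections = 0
    quotients = []
    for s in _rep_seeds(seed, n_reps):
        p, q = _meiotic_vs_premeiotic_p(
            stage_test_config(s, msci_multiplier=msci_multiplier)
        )
        rejections += int(p < alpha)
        quotients.append(q)
    return rejections / n_reps, float(np.mean(quotients))


def _dosage_pattern_recovered(config: SimConfig) -> bool:
    """True when the X-only vs X+Y contrast is significant in stratum 1 for
    all four stages and non-significant in strata 2 and 3 everywhere."""
    m, ann, _ = simulate_counts(config)
    rt = normalize_to_autosome_median(pseudobulk(m), ann)
    res = dosage_contrast(rt, ann, by_stratum=True)
    s1 = res[res["stratum"] == "1"]
    rest = res[res["stratum"].isin(["2", "3"])]
    return (
        len(s1) == 4
        and bool(s1["significant"].all())
        and not bool(rest["significant"].any())
    )


def dosage_recovery_rate(n_reps: int = 50, seed: int = 3) -> float:
    """Fraction of replicates recovering the stratum-confined dosage
    pattern under the default generator (doubling in stratum 1 only)."""
    hits = 0
    for s in _rep_seeds(seed, n_reps):
        hits += int(_dosage_pattern_recovered(dosage_config(s)))
    return hits / n_reps


@dataclass(frozen=True)
class RetroTruthTable:
    precision: float
    recall: float
    n_planted: int
    n_called: int


def retro_truth_table(seed: int = 4, config: SimConfig | None = None) -> RetroTruthTable:
    """Precision/recall of the retrocopy detector on planted events."""
    config = config or dataclasses.replace(SimConfig(), seed=seed)
    ingroup, outgroup = simulate_alignments(config)
    _, ann, truth = simulate_counts(config)
    res = detect_retro(ingroup, outgroup, ann.parent_loci())
    called = set(res.loc[res["verdict"] == "candidate", "parent_gene_id"])
    planted = {e.parent_gene_id for e in truth.retro_events
               if not e.in_outgroup}
    tp = len(called & planted)
    precision = tp / len(called) if called else 1.0
    recall = tp / len(planted) if planted else 1.0
    return RetroTruthTable(
        precision=precision, recall=recall,
        n_planted=len(planted), n_called=len(called),
    )
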