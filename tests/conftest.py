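"""Shared fixtures: one small simulated dataset reused across test modules."""

import pytest

from mscix import SimConfig, pseudobulk, simulate_counts


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_genes_autosome=120,
        n_genes_X_only=40,
        n_genes_XY_pair=30,
        n_genes_Y_only=15,
        n_genes_mito=5,
        n_families=8,
        copies_per_family=(2, 5),
        n_meiotic_only_families=3,
        n_cells_per_stage={
            "pre_meiotic": 60,
            "meiotic": 60,
            "post_meiotic": 60,
            "somatic": 40,
        },
        n_clusters_per_stage=2,
        n_samples=2,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    """(matrix, annotation, truth) for the shared small configuration."""
    return simulate_counts(small_config)


@pytest.fixture(scope="session")
def small_pb(small_sim):
    matrix, _, _ = small_sim
    return pseudobulk(matrix)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_config):
    """On-disk fixture bundle written once per session."""
    from mscix import write_fixture

    outdir = tmp_path_factory.mktemp("fixture")
    paths = write_fixture(small_config, outdir)
    return outdir, paths
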