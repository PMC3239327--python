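import pytest

from tfclust import (
    ClusterConfig,
    Genome,
    SyntheticConfig,
    build_clusters,
    generate,
)


@pytest.fixture(scope="session")
def toy_genome() -> Genome:
    return Genome({"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic genome: 2 x 10 Mb, 240 genes, 500 elements."""
    return generate(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_clusters(default_dataset):
    return build_clusters(default_dataset.all_peaks, ClusterConfig(), default_dataset.genome)


@pytest.fixture(scope="session")
def data_dir(default_dataset, tmp_path_factory):
    path = tmp_path_factory.mktemp("synthetic") / "data"
    default_dataset.write(path)
    return path
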