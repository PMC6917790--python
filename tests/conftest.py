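import pytest
from hypothesis import HealthCheck, settings

from plexscreen.fixtures import demo_fixture, write_demo_fixture
from plexscreen.pipeline import RunConfig, run_pipeline
from plexscreen.search import SearchConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def demo():
    """The bundled synthetic demo assay, in memory."""
    return demo_fixture(42)


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory):
    """Demo assay written to disk as FASTA/CSV."""
    path = tmp_path_factory.mktemp("demo")
    write_demo_fixture(path, 42)
    return path


def demo_run_config(demo_dir, out_dir) -> RunConfig:
    return RunConfig(
        references=[str(demo_dir / "references.fasta")],
        primers=[str(demo_dir / "setA.fasta"), str(demo_dir / "setB.fasta")],
        probes=[str(demo_dir / "setA_probes.fasta")],
        mapping=str(demo_dir / "mapping.csv"),
        search=SearchConfig(max_mm_primer=1, max_mm_probe=1),
        max_product_size=1000,
        out_dir=str(out_dir),
    )


@pytest.fixture(scope="session")
def demo_result(demo_dir, tmp_path_factory):
    """One full pipeline run on the demo assay, shared across tests."""
    out = tmp_path_factory.mktemp("demo_out")
    config = demo_run_config(demo_dir, out)
    return run_pipeline(config), config
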