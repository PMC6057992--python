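import pytest

from lenspg.config import PipelineConfig
from lenspg.pipeline import run_pipeline
from lenspg.synth import StudySizes, synthesize_study


@pytest.fixture()
def cfg():
    return PipelineConfig()


SMALL_SIZES = StudySizes(
    n_chromosomes=2, chrom_length=150_000, n_genes=16, n_novel=8, n_semi=6,
    as_counts={"ES": 1, "A5SS": 1, "A3SS": 1, "MXE": 1, "IR": 1},
    n_planted_peptides=12, n_known_spectra=40, n_noise_spectra=10,
)


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study for unit tests."""
    return synthesize_study(PipelineConfig(), seed=11, sizes=SMALL_SIZES)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default-size study (shared, seeded)."""
    cfg = PipelineConfig()
    workdir = tmp_path_factory.mktemp("default_run")
    return run_pipeline(cfg, workdir, seed=cfg.rng_seed)
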