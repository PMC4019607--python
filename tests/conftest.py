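import pytest

from mirlink.pipeline import PipelineConfig, run_pipeline
from mirlink.synthetic_data import default_config, write_dataset


def make_pipeline_config(paths, outdir, **overrides) -> PipelineConfig:
    base = dict(
        expression=str(paths["expression"]),
        mirnas=str(paths["mirnas"]),
        utrs=str(paths["utrs"]),
        annotation=str(paths["annotation"]),
        pathways=str(paths["pathways"]),
        trajectories=str(paths["trajectories"]),
        outdir=str(outdir),
    )
    base.update(overrides)
    return PipelineConfig(**base)


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """One seeded synthetic dataset shared across the suite."""
    cfg = default_config(rng_seed=7)
    paths = write_dataset(cfg, tmp_path_factory.mktemp("data"))
    return cfg, paths


@pytest.fixture(scope="session")
def pipeline_run(dataset, tmp_path_factory):
    cfg, paths = dataset
    outdir = tmp_path_factory.mktemp("out")
    pconfig = make_pipeline_config(paths, outdir)
    manifest = run_pipeline(pconfig)
    return cfg, pconfig, manifest
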