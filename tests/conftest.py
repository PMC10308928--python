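import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20140810)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small default community bundle shared by pipeline-level tests."""
    from metaphi.simulate import SimDesign, simulate_bundle

    out = tmp_path_factory.mktemp("bundle")
    design = SimDesign(seed=7)
    simulate_bundle(design, out)
    return design, out


@pytest.fixture(scope="session")
def small_run(small_bundle, tmp_path_factory):
    """Full pipeline result on the small bundle."""
    from metaphi.pipeline import RunConfig, run_pipeline

    design, bundle = small_bundle
    out = tmp_path_factory.mktemp("run")
    config = RunConfig(
        psm_table=str(bundle / "psms.tsv"),
        bins_dir=str(bundle / "bins"),
        candidates_fasta=str(bundle / "candidates.fasta"),
        annotations=str(bundle / "annotations.tsv"),
        fg_map=str(bundle / "fg_map.tsv"),
        samples_table=str(bundle / "samples.tsv"),
        out_dir=str(out),
        ribosome_label="Ribosome",
        seed=7,
    )
    return config, run_pipeline(config)
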