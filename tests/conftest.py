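import dataclasses

import pytest

from agoclip.synthetic import SynthConfig, generate_reference, simulate_clip_tags


# small but complete study: used by tests that only need *a* valid bundle
SMALL_CONFIG = SynthConfig(
    rng_seed=7,
    n_chroms=1,
    chrom_length=200_000,
    n_genes=20,
    n_mirnas=10,
    targets_per_mirna=2,
    ko_targets=6,
)


@pytest.fixture(scope="session")
def small_reference(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("small_ref")
    return generate_reference(SMALL_CONFIG, outdir)


@pytest.fixture(scope="session")
def small_tags(small_reference, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("small_tags")
    paths, truth = simulate_clip_tags(small_reference, outdir)
    return paths, truth


@pytest.fixture(scope="session")
def default_reference(tmp_path_factory):
    """Default study conditions, seed 1."""
    outdir = tmp_path_factory.mktemp("default_ref")
    return generate_reference(dataclasses.replace(SynthConfig(), rng_seed=1), outdir)
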