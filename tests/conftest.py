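import pytest

from te_prospector.synthetic import SyntheticGenome, standard_fixture


@pytest.fixture(scope="session")
def std_genomes() -> dict[int, SyntheticGenome]:
    """The standard planted-genome condition for seeds 1..5."""
    return {seed: standard_fixture(seed) for seed in range(1, 6)}


@pytest.fixture(scope="session")
def small_pipeline_config() -> dict:
    """A compact pipeline configuration used by orchestration tests."""
    return {
        "seed": 5,
        "geneconv": {"n_permutations": 200},
        "synthetic": {
            "length": 50_000,
            "plants": [
                {
                    "element_kind": "LTR_RT",
                    "count": 4,
                    "divergence": [0.02, 0.05, 0.08, 0.04],
                    "n_families": 2,
                },
                {"element_kind": "MITE", "count": 4, "n_families": 2},
                {"element_kind": "HELITRON", "count": 2, "n_families": 1},
                {"element_kind": "LINE", "count": 2},
            ],
        },
    }


@pytest.fixture(scope="session")
def small_pipeline_run(small_pipeline_config, tmp_path_factory):
    from te_prospector.annotate import run_pipeline

    out = tmp_path_factory.mktemp("pipeline") / "run1"
    return run_pipeline(small_pipeline_config, output_dir=out)
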