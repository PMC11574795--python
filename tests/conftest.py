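import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-parameter matrix-mode cohort, 8 subjects per group."""
    from fcreconf import SyntheticConfig, generate_cohort

    config = SyntheticConfig(
        n_per_group={"ASD": 8, "TD": 8},
        subgroup_mix={
            "ASD": {"TP-ASD": 4, "LP-ASD": 4},
            "TD": {"TD-typical": 7, "TD-low": 1},
        },
        n_missing_brief=1,
        seed=7,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """Small default cohort written to disk, plus a ready run config."""
    from fcreconf import SyntheticConfig, generate_cohort
    from fcreconf.pipeline import RunConfig

    root = tmp_path_factory.mktemp("cohort")
    config = SyntheticConfig(
        n_per_group={"ASD": 8, "TD": 8},
        subgroup_mix={
            "ASD": {"TP-ASD": 4, "LP-ASD": 4},
            "TD": {"TD-typical": 7, "TD-low": 1},
        },
        n_missing_brief=1,
        seed=11,
    )
    cohort = generate_cohort(config, out_dir=root)
    run_config = RunConfig(
        manifest=str(root / "manifest.csv"),
        phenotypes=str(root / "phenotypes.csv"),
        mode="matrix",
        permutation_B=199,
        seed=5,
    )
    return cohort, run_config
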