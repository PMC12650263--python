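import pytest

from create_lab.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-participant cohort with short eye recordings (fast to build)."""
    config = CohortConfig(n_participants=12, seed=42, eye_duration_s=20.0)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def small_cohort_dir(small_cohort, tmp_path_factory):
    from create_lab.io import write_cohort

    outdir = tmp_path_factory.mktemp("cohort")
    write_cohort(small_cohort, outdir)
    return outdir
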