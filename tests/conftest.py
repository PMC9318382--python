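import pytest

from gelmark import pipeline, synthetic


@pytest.fixture(scope="session")
def small_config():
    """A reduced reference-set layout that still exercises every sharing class."""
    return synthetic.GeneratorConfig(
        seed=11,
        shared_all=12,
        shared_subsets={("donkey", "horse"): 5, ("cattle", "horse"): 2},
        specific={"donkey": 2, "horse": 1, "cattle": 1, "pig": 1},
        inconsistent={"horse": 1},
        contaminants_per_sample=5,
        noise_per_sample=20,
    )


@pytest.fixture(scope="session")
def small_run(small_config):
    """Peak lists + planted truth for the small layout."""
    return synthetic.generate_profiles(small_config)


@pytest.fixture(scope="session")
def small_profiles(small_run):
    profiles, _ = small_run
    return [pipeline.profile_sample(pl) for pl in profiles.values()]


@pytest.fixture(scope="session")
def paper_run():
    """One full-scale seeded run: profiles, truth, and screening output."""
    profiles, truth = synthetic.generate_profiles(synthetic.paper_scale_config(seed=1))
    profs = [pipeline.profile_sample(pl) for pl in profiles.values()]
    panel, classified = pipeline.discover_markers(profs)
    return profs, truth, panel, classified
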