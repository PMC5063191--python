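import pytest
from hypothesis import HealthCheck, settings as h_settings

from armnma.data import ArmRecord, NmaDataset
from armnma.datasets import load_smoking
from armnma.simulate import GeneratorSpec, TrialDesign, generate

h_settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
h_settings.load_profile("suite")


@pytest.fixture(scope="session")
def smoking_full():
    return load_smoking(reduced=False)


@pytest.fixture(scope="session")
def smoking_reduced():
    return load_smoking(reduced=True)


@pytest.fixture(scope="session")
def one_trial_dataset():
    """A single two-arm trial: the smallest valid network."""
    return NmaDataset.from_arms(
        [
            ArmRecord("t1", "A", 18, 100),
            ArmRecord("t1", "B", 30, 100),
        ],
        reference_treatment="A",
    )


@pytest.fixture(scope="session")
def small_mixed_dataset():
    """Small synthetic network with a 3-arm trial and an indirect treatment."""
    spec = GeneratorSpec(
        n_treatments=4,
        trials=(
            TrialDesign((1, 2, 3), (150, 150, 150)),
            TrialDesign((1, 2), (120, 130)),
            TrialDesign((2, 3), (140, 110)),
            TrialDesign((3, 4), (160, 150)),
            TrialDesign((2, 4), (150, 140)),
        ),
        d=(0.0, 0.3, 0.6, 0.9),
        effects="random_common",
        sigma=0.3,
        seed=1234,
    )
    data, _ = generate(spec)
    return data
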