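import numpy as np
import pytest

from idrpipe.io import ProteinRecord, ScoreTrack
from idrpipe.disorder import DisorderProfile
from idrpipe.synthetic import (
    BindingPlant,
    GeneratorConfig,
    MotifPlant,
    generate_family,
    generate_truth_tracks,
)

#: 20 standard residues, frozen order used by random-sequence helpers
AA = "ACDEFGHIKLMNPQRSTVWY"


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(AA))[rng.integers(0, 20, size=length)])


def profile_from(values, pid="p", threshold=0.5) -> DisorderProfile:
    return DisorderProfile(ScoreTrack(pid, np.asarray(values, float)), threshold)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160630)


@pytest.fixture(scope="session")
def small_family():
    """A compact synthetic family with planted motifs, binding and variants."""
    config = GeneratorConfig(
        seed=7,
        n_proteins=3,
        motif_plants=(
            MotifPlant("WIN_LIKE", "WCW[DE]W", "WCWDW", count=6),
        ),
        binding_plants=(
            BindingPlant(12, "invariant"),
            BindingPlant(12, "divergent"),
        ),
        variant_offsets=(0, 4),
    )
    proteins, truth = generate_family(config)
    return config, proteins, truth


@pytest.fixture(scope="session")
def truth_tracks(small_family):
    config, proteins, truth = small_family
    disorder = generate_truth_tracks(truth, proteins, "disorder", seed=config.seed)
    binding = generate_truth_tracks(truth, proteins, "binding", seed=config.seed)
    return disorder, binding
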