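import numpy as np
import pytest

from lysotrace.prophage_model import ProphageAnnotation
from lysotrace.synthetic_data import ProphageSimSpec, ViromeSimConfig
from lysotrace.virome_coverage import CoverageTrack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sim_prophage():
    """A P22-like prophage planted mid-replicon (38,682 bp, pac inside)."""
    return ProphageAnnotation(
        "sim_phage", "sim", 300_001, 338_682, pac_position=320_271
    )


@pytest.fixture
def sim_config(sim_prophage):
    return ViromeSimConfig(
        replicon_length=1_000_000,
        prophages=[ProphageSimSpec(annotation=sim_prophage)],
    )


@pytest.fixture
def flat_track():
    """Constant depth 7.6 over 200 kb."""
    return CoverageTrack("flat", np.full(200_000, 7.6))
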