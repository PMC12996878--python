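import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from nsburden.lexicon import default_lexicon
from nsburden.synthgen import GeneratorConfig, generate_bundle, smoke_config


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def smoke_bundle():
    """One small bundle with every eligibility-violation path exercised."""
    return generate_bundle(smoke_config(), include_notes=False)


@pytest.fixture(scope="session")
def clean_notes_bundle():
    """Decoy-free, misspelling-free note corpus with gold labels."""
    cfg = GeneratorConfig(
        n_patients=150, seed=3, ns_prevalence=0.4, decoy_rates={}, misspelling_rate=0.0
    )
    from nsburden.synthgen import generate_notes

    return generate_notes(cfg)
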