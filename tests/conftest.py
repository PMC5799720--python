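import pytest

from laylink.fixtures import demo_resources, gen_bundle


@pytest.fixture(scope="session")
def demo():
    """(lexicon, concepts, config, modifiers) with the worked examples."""
    return demo_resources()


@pytest.fixture(scope="session")
def bundle():
    return gen_bundle(seed=11)
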