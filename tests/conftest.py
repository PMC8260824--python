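import pytest

from sluptools.synthetic import cre_like_spec


@pytest.fixture(scope="session")
def cre_spec():
    """Five-site recombinase-style library spec on a generated 1050 nt template."""
    return cre_like_spec(seed=7)
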