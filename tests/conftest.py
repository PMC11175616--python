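import pytest

from cagedit.repeat_model import canonical_allele, default_htt_template


@pytest.fixture(scope="session")
def htt_template():
    return default_htt_template((16, 17))


@pytest.fixture(scope="session")
def htt51_template():
    """HEK293-51CAG-like locus: one normal canonical 17 plus an expanded 51."""
    t = default_htt_template(())
    return t.with_alleles([canonical_allele(17), canonical_allele(51)])
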