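import pytest

import poolpat as pp


@pytest.fixture(scope="session")
def bundled_panel() -> pp.Panel:
    """The worked-example dataset shipped with the package."""
    return pp.load_bundled_panel()


@pytest.fixture(scope="session")
def bundled_freqs(bundled_panel):
    """Allele frequencies of the bundled adult panel, one per locus."""
    return [
        pp.allele_frequencies(list(bundled_panel.adults), locus)
        for locus in bundled_panel.loci
    ]


def make_adults(pairs, locus_name="L01"):
    """Adults typed at a single locus from a list of allele pairs."""
    return [
        pp.AdultGenotype(adult_id=f"A{i}", calls={locus_name: pair})
        for i, pair in enumerate(pairs)
    ]


@pytest.fixture
def single_locus():
    return pp.Locus(name="L01", repeat_motif="AC")
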