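import pytest

from flaxmark import FAD3_LOCI, build_fixture_loci, validate_caps_marker


@pytest.fixture(scope="session")
def fixture_set():
    return build_fixture_loci(seed=7)


@pytest.fixture(scope="session")
def markers(fixture_set):
    """Validated CAPS markers for the three fixture loci."""
    out = {}
    for locus_id in FAD3_LOCI:
        lc = fixture_set.loci[locus_id]
        out[locus_id] = validate_caps_marker(lc.amplicon, lc.variant, lc.enzyme)
    return out
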