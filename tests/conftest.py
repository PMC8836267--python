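import pytest

import melanostab as ms


@pytest.fixture(scope="session")
def tyrp2_fixture() -> ms.Structure:
    """300-residue mini-domain realizing the seven Tyrp2 disulfide pairings."""
    return ms.make_cys_fixture(ms.default_fixture_spec())


@pytest.fixture(scope="session")
def tyrp2_bridges(tyrp2_fixture):
    return ms.detect_disulfides(tyrp2_fixture)


@pytest.fixture(scope="session")
def tyrp2_screen(tyrp2_fixture) -> ms.FoldabilityMap:
    return ms.screen_all(tyrp2_fixture)


@pytest.fixture(scope="session")
def oca8_mini() -> ms.Structure:
    """70-residue mini-domain with the C29-C40 and C41-C61 bridges and Gly59."""
    seq = ["A"] * 70
    for pos in (29, 40, 41, 61):
        seq[pos - 1] = "C"
    seq[59 - 1] = "G"
    spec = ms.FixtureSpec(n_residues=70, sequence="".join(seq),
                          disulfide_pairs=((29, 40), (41, 61)))
    return ms.make_cys_fixture(spec)


@pytest.fixture(scope="session")
def zinc_site() -> ms.Structure:
    return ms.make_zinc_site_fixture()
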