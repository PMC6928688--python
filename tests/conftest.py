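import pytest

from vscascade import fixtures


@pytest.fixture(scope="session")
def chem_library():
    """Small toy library: 10 scaffold-decorated actives, 100 diverse inactives."""
    return fixtures.gen_chem_library(10, 100, seed=11)


@pytest.fixture(scope="session")
def feature_table():
    """Planted-signal table: 3 informative of 20 columns, separation 3 SD."""
    return fixtures.gen_feature_table(100, 100, n_features=20, n_informative=3,
                                      separation=3.0, seed=11)


@pytest.fixture(scope="session")
def complex_set():
    """18 toy complexes, four planted contacts of mixed kinds."""
    planted = [
        (("A", 828, "VAL"), "hbond_donor", 17 / 18),
        (("A", 826, "GLU"), "hbond_acceptor", 0.5),
        (("A", 729, "LYS"), "ionic", 6 / 18),
        (("A", 752, "MET"), "hydrophobic", 2 / 18),
    ]
    return fixtures.gen_complex_set(18, planted, seed=11), planted
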