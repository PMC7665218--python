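import numpy as np
import pytest

from fibrilkit import synth
from fibrilkit.helix import HelicalParams


@pytest.fixture(scope="session")
def quasi21_fibril():
    """Idealized two-subunit fibril with the deposited-map screw operator."""
    return synth.build_fibril(
        synth.BuilderSpec(
            "SQYGS", HelicalParams(2.44, 178.94, "quasi-21"), n_repeats=5
        )
    )


@pytest.fixture(scope="session")
def ideal_sheet():
    """Five-strand in-register parallel sheet, residues 1-10, 4.8 A spacing.

    Mostly Ser with a Tyr at residue 5, so hydroxyl centres and a
    chi2-bearing side chain are both available.
    """
    return synth.make_ideal_sheet(5, 10, 4.8, sequence="SSSSYSSSSS")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
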