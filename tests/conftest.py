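import numpy as np
import pytest

import oligoms as om
from oligoms.library import ChargeTable


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))


@pytest.fixture(scope="session")
def alphabet():
    return om.default_alphabet()


@pytest.fixture(scope="session")
def single_charge_table():
    return ChargeTable(((1, 10_000, (1,)),))


@pytest.fixture(scope="session")
def toy_library():
    """Deterministic target-decoy library from two random 150-nt references."""
    rng = np.random.default_rng(2024)
    refs = {f"ref{i}": random_sequence(rng, 150) for i in (1, 2)}
    entries = om.build_library(
        refs, enzyme=om.builtin_enzyme("T1"), max_missed=1, seed=11
    )
    return refs, entries


@pytest.fixture(scope="session")
def searched_dataset(toy_library):
    """200 simulated spectra searched against their own library (shared by
    the recovery, FDR-calibration and determinism checks)."""
    _, entries = toy_library
    params = om.SimParams(detection_p=0.9)
    spectra, truth = om.synthesize_dataset(entries, 200, params, seed=7)
    osms = om.search(spectra, entries)
    return entries, spectra, truth, osms
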