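import warnings

import numpy as np
import pytest

import catirt as ct


@pytest.fixture(scope="session")
def narc_bank() -> ct.ItemBank:
    """The packaged 85-item narcissism bank."""
    return ct.load_narcissism_bank()


@pytest.fixture(scope="session")
def small_bank() -> ct.ItemBank:
    """A 10-item mixed dichotomous/polytomous GRM bank for simulations."""
    return ct.generate_bank(10, n_categories=[2] * 7 + [5] * 3, seed=8)


@pytest.fixture(scope="session")
def clean_sim(small_bank) -> ct.SimulatedData:
    """Defect-free synthetic data from the small bank, n = 1000."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ct.simulate_responses(
            ct.SimulationDesign(bank=small_bank, n_persons=1000, seed=1000)
        )


@pytest.fixture(scope="session")
def calibrated_small(clean_sim):
    """GRM calibration of the clean simulated data."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bank, summary = ct.fit_model(clean_sim.responses, "GRM")
    return bank, summary


def random_response_pattern(bank: ct.ItemBank, rng: np.random.Generator, max_k: int = 30):
    """A random (item_ids, responses) pattern over a bank."""
    k = int(rng.integers(1, max_k))
    idx = rng.choice(len(bank), size=min(k, len(bank)), replace=False)
    ids = [bank.item_ids[i] for i in idx]
    resp = [int(rng.integers(0, bank.get(i).n_categories)) for i in ids]
    return ids, resp
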