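import numpy as np
import pytest

import hiriefquant as hq


def random_peptides(rng, n, min_len=8, max_len=25, require_basic=True):
    """Random tryptic-like peptides from human-like residue frequencies."""
    letters = np.array(list(hq.simulate.AA_FREQUENCIES))
    probs = np.array(list(hq.simulate.AA_FREQUENCIES.values()))
    probs = probs / probs.sum()
    peps = []
    while len(peps) < n:
        length = int(rng.integers(min_len, max_len + 1))
        pep = "".join(rng.choice(letters, size=length, p=probs))
        if require_basic:
            pep = pep + ("R" if rng.random() < 0.5 else "K") + "R"
        peps.append(pep)
    return peps


@pytest.fixture(scope="session")
def noisy_sim():
    """Small synthetic experiment at the study's noise level."""
    config = hq.SimConfig(n_proteins=60, seed=11, noise_cv=0.1)
    return hq.simulate_experiment(config)


@pytest.fixture(scope="session")
def noisy_result(noisy_sim):
    return hq.run_pipeline(
        noisy_sim.psms_phospho,
        noisy_sim.psms_standard,
        protein_sequences=dict(noisy_sim.proteome),
        ground_truth=noisy_sim.ground_truth,
    )


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free experiment with no nuisance features, for exact recovery."""
    config = hq.SimConfig(
        n_proteins=40,
        seed=3,
        noise_cv=0.0,
        frac_low_localization=0.0,
        frac_zero_reporter=0.0,
    )
    return hq.simulate_experiment(config)
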