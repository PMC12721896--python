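import pytest

from midaflux.simulate import EffectModel, SimulationDesign, simulate_study


@pytest.fixture(scope="session")
def analytic_study():
    """Tiny noise-free study: envelopes are exact mixtures (ion_counts=None)."""
    design = SimulationDesign(
        n_proteins=15,
        peptides_per_protein=(2, 3),
        n_animals_per_arm=3,
        days=(0, 31),
        ion_counts=None,
        seed=101,
    )
    return simulate_study(design, EffectModel(animal_jitter_sd=0.0))


@pytest.fixture(scope="session")
def noisy_study():
    """Small study with multinomial counting noise and animal variation."""
    design = SimulationDesign(
        n_proteins=30,
        peptides_per_protein=(2, 4),
        n_animals_per_arm=4,
        days=(0, 31),
        ion_counts=10_000,
        seed=202,
    )
    return simulate_study(design)
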