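import numpy as np
import pytest

from metasort import Register, SimConfig, run_pipeline, simulate_study


@pytest.fixture(scope="session")
def toy_register() -> Register:
    """A small hand-built register of freshwater macroinvertebrates with a
    synonym, a subspecies and a non-register (foreign) species."""
    reg = Register()
    reg.add("Isopoda", "order")
    reg.add("Asellidae", "family", parent="Isopoda")
    reg.add("Asellus", "genus", parent="Asellidae")
    reg.add("Asellus aquaticus", "species", parent="Asellus")
    reg.add("Asellus meridianus", "species", parent="Asellus")
    reg.add("Proasellus", "genus", parent="Asellidae")
    reg.add("Proasellus coxalis", "species", parent="Proasellus")
    reg.add("Amphipoda", "order")
    reg.add("Gammaridae", "family", parent="Amphipoda")
    reg.add("Gammarus", "genus", parent="Gammaridae")
    reg.add("Gammarus pulex", "species", parent="Gammarus")
    reg.add("Gammarus fossarum", "species", parent="Gammarus")
    reg.add("Gammarus exoticus", "species", parent="Gammarus",
            in_register=False)
    reg.add("Haplotaxida", "order")
    reg.add("Tubificidae", "family", parent="Haplotaxida")
    reg.add("Tubifex", "genus", parent="Tubificidae")
    reg.add("Tubifex tubifex", "species", parent="Tubifex")
    reg.add("Asellus aquaticus aquaticus", "subspecies",
            parent="Asellus aquaticus")
    reg.add_synonym("Rivulogammarus pulex", "Gammarus pulex")
    return reg


@pytest.fixture(scope="session")
def big_register() -> Register:
    """A 54-species programmatic tree for LCA and redundancy oracles."""
    reg = Register()
    n = 0
    for o in range(3):
        order = f"Ordo{o}"
        reg.add(order, "order")
        for f in range(3):
            family = f"Familia{o}{f}"
            reg.add(family, "family", parent=order)
            for g in range(2):
                genus = f"Genus{o}{f}{g}"
                reg.add(genus, "genus", parent=family)
                for s in range(3):
                    n += 1
                    reg.add(f"{genus} species{s}", "species", parent=genus)
    assert n == 54
    return reg


@pytest.fixture(scope="session")
def study():
    """One default-condition synthetic study shared across tests."""
    return simulate_study(SimConfig(seed=11))


@pytest.fixture(scope="session")
def result(study):
    return run_pipeline(study.table, study.wfd_hits, study.genbank_hits,
                        study.register, study.morphology,
                        study.refdb_species)


def noise_free_config(seed: int = 0, n_locations: int = 6) -> SimConfig:
    """The lossless limit: full reference coverage, no noise of any kind,
    no dominance. The pipeline should recover every species exactly."""
    return SimConfig(
        seed=seed, n_locations=n_locations,
        ref_coverage=(1.0,) * 6,
        biomass_sigma=0.3, species_amp_sigma=0.0, group_amp_sigma=0.0,
        amplification_dropout=0.0,
        pseudogene_rate=0.0, contaminant_rate=0.0,
        aic_contamination_rate=0.0, control_foreign_rate=0.0,
        failure_probs=(0.0,) * 6, pool_failure_prob=0.0,
        cross_genus_rate=0.0, competing_direct_rate=0.0,
        foreign_direct_rate=0.0,
        misid_rate=0.0, genus_only_rate=0.0, morph_miss_rate=0.0)


@pytest.fixture(scope="session")
def noise_free_study():
    return simulate_study(noise_free_config(seed=5))


@pytest.fixture(scope="session")
def noise_free_result(noise_free_study):
    s = noise_free_study
    return run_pipeline(s.table, s.wfd_hits, s.genbank_hits, s.register,
                        s.morphology, s.refdb_species)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
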