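import pytest

from regcircuits.simulate import SimulationConfig, simulate_all


def small_config(seed: int = 1, **overrides) -> SimulationConfig:
    """A fast, fully featured simulation: ~1 s end to end."""
    base = dict(
        seed=seed,
        chrom_length=2_000_000,
        n_genes=50,
        n_enhancers=60,
        n_motifs=100,
        n_tfs=15,
        n_catalog_snps=600,
        n_background_snvs=3_000,
        n_tissues=3,
        n_samples_per_tissue=20,
        n_perturbed_edges=6,
        n_disease_genes=20,
        n_specific_genes=6,
        n_coding_variants=25,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """One shared small simulation directory with planted truth."""
    d = tmp_path_factory.mktemp("sim")
    truth = simulate_all(small_config(seed=7), d)
    return d, truth
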