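import pytest

from triadmap.synthetic import SyntheticConfig, simulate


def small_config(seed: int = 7) -> SyntheticConfig:
    """Reduced study conditions for fast unit tests: shorter chromosomes
    (targets become interchromosomal), fewer genes/contacts/peaks."""
    return SyntheticConfig(
        seed=seed,
        n_chromosomes=3,
        chromosome_length=2_000_000,
        n_genes=60,
        n_guides=3,
        targets_per_guide=10,
        n_contacts=5000,
        n_background_peaks=100,
        sites_per_guide=8,
        decoy_lnc_genes=4,
        decoy_pc_genes=2,
        iclip_noise_events_per_replicate=300,
    )


@pytest.fixture(scope="session")
def small_cfg():
    return small_config()


@pytest.fixture(scope="session")
def small_ds(small_cfg):
    return simulate(small_cfg)
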