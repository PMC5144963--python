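import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """One shared synthetic dataset: 16 taxa, 40 genes, every pathology on."""
    from buscophylo import synth

    cfg = synth.SynthConfig(
        n_taxa=16,
        n_genes=40,
        discordant_fraction=0.3,
        missing_taxon_rate=0.1,
        rogue_rate=0.2,
        rogue_branch_factor=40.0,
        codon_length_range=(60, 120),
        cug_ser_taxa=frozenset({"t001", "t002", "t003"}),
        seed=11,
    )
    return synth.generate(cfg)


@pytest.fixture(scope="session")
def clean_dataset():
    """No injected pathology: concordant, complete, rogue-free."""
    from buscophylo import synth

    cfg = synth.SynthConfig(
        n_taxa=12,
        n_genes=25,
        discordant_fraction=0.0,
        missing_taxon_rate=0.0,
        rogue_rate=0.0,
        codon_length_range=(60, 100),
        seed=5,
    )
    return synth.generate(cfg)
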