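import numpy as np
import pytest

from coralmicro.synthetic import (GroupSpec, GuildSpec, SyntheticDesign,
                                  generate_table, guild_loading_for_spearman,
                                  otu_name)


def two_host_design(seed: int = 7, n_otus: int = 120,
                    guild_size: int = 5) -> SyntheticDesign:
    """Compact two-host study with one planted guild per host plus seawater."""
    lam = guild_loading_for_spearman(0.8)
    guilds = [
        GuildSpec([otu_name(i) for i in range(guild_size)],
                  loading=lam, target_hosts=("Galaxea",)),
        GuildSpec([otu_name(i) for i in range(guild_size, 2 * guild_size)],
                  loading=lam, target_hosts=("Montipora",)),
    ]
    groups = [
        GroupSpec("Galaxea", "CB", 6), GroupSpec("Galaxea", "LHT", 6),
        GroupSpec("Montipora", "CB", 6), GroupSpec("Montipora", "LHT", 6),
        GroupSpec("Seawater", "CB", 1, n_technical=1),
        GroupSpec("Seawater", "LHT", 1, n_technical=1),
    ]
    return SyntheticDesign(n_otus=n_otus, groups=groups, guilds=guilds,
                           seed=seed)


@pytest.fixture(scope="session")
def small_study():
    """One generated two-host study shared across tests (28 samples)."""
    return generate_table(two_host_design())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
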