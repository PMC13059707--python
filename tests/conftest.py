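import numpy as np
import pandas as pd
import pytest

import guildflow as gf


@pytest.fixture(scope="session")
def default_dataset():
    """One draw of the default fermentation scenario (240 samples)."""
    cfg = gf.default_scenario(seed=11)
    counts, meta, chem, truth = gf.generate(cfg)
    return cfg, counts, meta, chem, truth


@pytest.fixture(scope="session")
def truth_guild_table(default_dataset):
    """Guild abundance table aggregated by ground-truth membership."""
    _, counts, meta, chem, truth = default_dataset
    rel = gf.to_relative(counts)
    fg = truth.feature_guild
    gt = pd.DataFrame(
        {g: rel.loc[:, fg[fg == g].index].sum(axis=1) for g in fg.unique()}
    )
    return gt, meta, chem, truth


def two_block_scenario(seed=0, w=0.9, n_per_guild=12):
    """Two independent guilds with no treatment effects: a planted partition."""
    guilds = (
        gf.GuildSpec("A", n_per_guild, 0.0, within_guild_corr=w),
        gf.GuildSpec("B", n_per_guild, 0.0, within_guild_corr=w),
    )
    return gf.ScenarioConfig(guilds=guilds, seed=seed, library_size=5_000)


def null_scenario(seed=0, n_features=100):
    """No guild factor, no effects: all features independent given donor."""
    half = n_features // 2
    guilds = (
        gf.GuildSpec("A", half, 0.0, within_guild_corr=0.0, donor_sd=0.0),
        gf.GuildSpec("B", n_features - half, 0.0, within_guild_corr=0.0, donor_sd=0.0),
    )
    return gf.ScenarioConfig(guilds=guilds, seed=seed, library_size=20_000)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
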