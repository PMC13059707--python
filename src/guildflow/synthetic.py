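"""Synthetic fermentation-study communities with planted guild structure.

The generator emulates an ex vivo batch-fermentation design: faecal
communities from a few donors, exposed to four treatments (Control, Oxygen,
Fiber, Oxygen+Fiber), sampled at several time points with replicates, and
sequenced to a fixed library size.  Features (ASVs) are organised into
guilds — groups that share a latent per-sample factor and a common
treatment response — so that guild-inference and effect-recovery code can
be tested against known ground truth.

Generative model (per sample ``s``, feature ``f`` in guild ``g``)::

    lambda_fs = baseline_g
              + effect_g(treatment_s) * ramp(time_s)
              + donor_g(donor_s)
              + w_g * Z_gs
              + eps_fs

with ``Z_gs ~ N(0,1)`` a guild-level shared factor, ``donor_g(d) ~
N(0, donor_sd^2)`` drawn once per (guild, donor), ``eps ~ N(0,
noise_sd^2)`` i.i.d. per feature, and ``ramp(t) = min(t/24, 1)`` so
treatment effects are absent in the 0 h inoculum and fully expressed from
24 h.  Counts are drawn ``multinomial(library_size, softmax(lambda))`` per
sample, which induces the compositional coupling the downstream analysis
has to live with.

Chemistry: each SCFA concentration (uM) is a per-guild yield times the
guild's realised relative abundance, summed over guilds, plus truncated
Gaussian noise; pH falls logarithmically with total SCFA.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import SCFA_COLUMNS, TREATMENTS

__all__ = ["GuildSpec", "ScenarioConfig", "GroundTruth", "generate", "default_scenario"]


@dataclass(frozen=True)
class GuildSpec:
    """Specification of one planted guild.

    Parameters
    ----------
    guild_id
        Ground-truth label.
    n_features
        Number of member ASVs (>= 1).
    baseline_log_abundance
        Intercept of the latent log-abundance.
    effect
        Treatment -> log-fold change at full ramp, relative to Control.
        Missing treatments default to 0.
    within_guild_corr
        Loading ``w`` on the guild's shared latent factor, in [0, 1].
    donor_sd
        SD of the per-(guild, donor) random intercept.
    noise_sd
        SD of per-feature i.i.d. noise (> 0).
    scfa_yield
        SCFA -> uM produced per unit guild relative abundance.
    """

    guild_id: str
    n_features: int
    baseline_log_abundance: float = 0.0
    effect: Mapping[str, float] = field(default_factory=dict)
    within_guild_corr: float = 0.85
    donor_sd: float = 0.6
    noise_sd: float = 0.6
    scfa_yield: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if not 0.0 <= self.within_guild_corr <= 1.0:
            raise ValueError("within_guild_corr must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.donor_sd < 0:
            raise ValueError("donor_sd must be >= 0")
        unknown = set(self.effect) - set(TREATMENTS)
        if unknown:
            raise ValueError(f"effect keys must be treatment levels, got {sorted(unknown)}")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full design of a synthetic fermentation study.

    Defaults encode the study layout: 4 treatments x 4 time points x
    5 replicates x 3 donors (240 samples) at a 28,000-read library size.
    """

    guilds: Sequence[GuildSpec]
    n_donors: int = 3
    treatments: Sequence[str] = TREATMENTS
    time_points_h: Sequence[float] = (0.0, 12.0, 24.0, 48.0)
    n_replicates: int = 5
    library_size: int = 28_000
    seed: int = 0
    chem_noise_sd: float = 500.0  # uM
    ph_intercept: float = 6.7
    ph_slope: float = 0.6  # pH units per log1p(total SCFA in mM)
    ph_bounds: tuple[float, float] = (3.8, 7.2)

    def __post_init__(self):
        if self.n_donors < 2:
            raise ValueError("n_donors must be >= 2")
        if len(self.guilds) < 2:
            raise ValueError("at least 2 guilds are required")
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        ids = [g.guild_id for g in self.guilds]
        if len(set(ids)) != len(ids):
            raise ValueError("guild_id values must be unique")

    @property
    def n_samples(self) -> int:
        return (
            self.n_donors
            * len(self.treatments)
            * len(self.time_points_h)
            * self.n_replicates
        )


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure accompanying a generated dataset."""

    feature_guild: pd.Series  # feature id -> guild id
    effects: pd.DataFrame  # guilds x treatments, true log-fold changes
    latent_guild_abundance: pd.DataFrame  # samples x guilds, latent relative abundance


def _ramp(t: np.ndarray) -> np.ndarray:
    return np.minimum(np.asarray(t, dtype=float) / 24.0, 1.0)


def generate(
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one dataset: (counts, metadata, chemistry, ground truth).

    The same config (including its ``seed``) always yields bit-identical
    outputs; all randomness flows from a single ``numpy`` generator.
    """
    rng = np.random.default_rng(config.seed)
    donors = [f"D{i + 1}" for i in range(config.n_donors)]

    rows = []
    for donor in donors:
        for trt in config.treatments:
            for t in config.time_points_h:
                for rep in range(1, config.n_replicates + 1):
                    rows.append((f"{donor}.{trt}.t{t:g}.r{rep}", donor, trt, float(t), rep))
    meta = pd.DataFrame(
        rows, columns=["sample_id", "donor", "treatment", "time_h", "replicate"]
    ).set_index("sample_id")

    n_samples = len(meta)
    n_features = sum(g.n_features for g in config.guilds)
    feature_ids = [f"ASV{i:04d}" for i in range(n_features)]
    ramp = _ramp(meta["time_h"].to_numpy())

    lam = np.empty((n_samples, n_features))
    guild_of = []
    col = 0
    for g in config.guilds:
        donor_fx = {d: rng.normal(0.0, g.donor_sd) for d in donors}
        z = rng.standard_normal(n_samples)
        eff = np.array([g.effect.get(t, 0.0) for t in meta["treatment"]])
        shared = (
            g.baseline_log_abundance
            + eff * ramp
            + np.array([donor_fx[d] for d in meta["donor"]])
            + g.within_guild_corr * z
        )
        eps = rng.normal(0.0, g.noise_sd, size=(n_samples, g.n_features))
        lam[:, col : col + g.n_features] = shared[:, None] + eps
        guild_of.extend([g.guild_id] * g.n_features)
        col += g.n_features

    if not np.isfinite(lam).any(axis=1).all():
        raise ValueError("degenerate latent abundances: a sample has no finite value")

    # softmax per sample, stabilised
    lam -= lam.max(axis=1, keepdims=True)
    probs = np.exp(lam)
    probs /= probs.sum(axis=1, keepdims=True)

    counts = np.vstack(
        [rng.multinomial(config.library_size, p) for p in probs]
    ).astype("int64")
    count_table = pd.DataFrame(counts, index=meta.index, columns=feature_ids)

    feature_guild = pd.Series(guild_of, index=feature_ids, name="guild")
    guild_ids = [g.guild_id for g in config.guilds]
    latent = pd.DataFrame(
        {gid: probs[:, np.asarray(feature_guild == gid)].sum(axis=1) for gid in guild_ids},
        index=meta.index,
    )

    # chemistry coupled to realised guild relative abundance
    rel = counts / counts.sum(axis=1, keepdims=True)
    guild_rel = {
        gid: rel[:, np.asarray(feature_guild == gid)].sum(axis=1) for gid in guild_ids
    }
    chem = pd.DataFrame(index=meta.index)
    for scfa in SCFA_COLUMNS:
        conc = np.zeros(n_samples)
        for g in config.guilds:
            conc += g.scfa_yield.get(scfa, 0.0) * guild_rel[g.guild_id]
        conc += rng.normal(0.0, config.chem_noise_sd, size=n_samples)
        chem[scfa] = np.maximum(conc, 0.0)
    total_mM = chem[list(SCFA_COLUMNS)].sum(axis=1) / 1000.0
    ph = config.ph_intercept - config.ph_slope * np.log1p(total_mM)
    chem.insert(0, "pH", np.clip(ph, *config.ph_bounds))

    effects = pd.DataFrame(
        [[g.effect.get(t, 0.0) for t in TREATMENTS] for g in config.guilds],
        index=guild_ids,
        columns=list(TREATMENTS),
    )
    truth = GroundTruth(feature_guild=feature_guild, effects=effects, latent_guild_abundance=latent)
    return count_table, meta, chem, truth


def default_scenario(seed: int = 0, within_guild_corr: float = 0.85) -> ScenarioConfig:
    """The default fermentation scenario with five named guild phenotypes.

    Guilds:

    * ``pathobiont`` — facultative anaerobes that bloom under oxygen and are
      suppressed whenever fiber is present (Enterobacteriaceae-like).
    * ``rescued1..3`` — obligate-anaerobe fermenters depleted by oxygen
      alone but restored (or better) when fiber accompanies oxygen; they
      carry the SCFA yields.
    * ``transitional`` — promoted only by the oxygen x fiber combination
      (aerotolerant fermenters bridging the two niches).
    * ``fiber_only`` — responds to fiber alone.
    * ``neutral1``/``neutral2`` — background guilds with no treatment
      response.

    Effect sizes are log-fold changes at full ramp; they were fixed once to
    give clearly signed, recoverable responses at the study's sample size
    while keeping compositional spillover onto null guilds small.
    """
    w = within_guild_corr
    guilds = (
        GuildSpec(
            "pathobiont", 10, 0.5,
            {"Oxygen": 1.4, "Fiber": -1.5, "OxygenFiber": -2.0},
            within_guild_corr=w,
        ),
        GuildSpec(
            "rescued1", 12, 0.5,
            {"Oxygen": -1.8, "Fiber": 0.3, "OxygenFiber": 0.6},
            within_guild_corr=w,
            scfa_yield={"acetate": 4_000.0, "butyrate": 14_000.0, "propionate": 2_000.0},
        ),
        GuildSpec(
            "rescued2", 8, 0.0,
            {"Oxygen": -1.3, "Fiber": 0.2, "OxygenFiber": 0.9},
            within_guild_corr=w,
            scfa_yield={"acetate": 16_000.0, "butyrate": 2_000.0, "propionate": 2_000.0},
        ),
        GuildSpec(
            "rescued3", 6, -0.3,
            {"Oxygen": -2.2, "Fiber": 0.2, "OxygenFiber": 0.7},
            within_guild_corr=w,
            scfa_yield={"acetate": 4_000.0, "propionate": 16_000.0},
        ),
        GuildSpec(
            "transitional", 8, -0.8,
            {"OxygenFiber": 2.2},
            within_guild_corr=w,
            scfa_yield={"acetate": 240_000.0, "propionate": 160_000.0},
        ),
        GuildSpec(
            "fiber_only", 8, -1.3,
            {"Fiber": 2.2},
            within_guild_corr=w,
            scfa_yield={"acetate": 440_000.0, "butyrate": 80_000.0, "propionate": 80_000.0},
        ),
        GuildSpec("neutral1", 10, 2.3, within_guild_corr=w),
        GuildSpec("neutral2", 8, 1.7, within_guild_corr=w),
    )
    return ScenarioConfig(guilds=guilds, seed=seed)


def scenario_from_dict(d: Mapping) -> ScenarioConfig:
    """Build a ScenarioConfig from a plain (e.g. YAML-loaded) mapping."""
    d = dict(d)
    guilds = tuple(GuildSpec(**g) for g in d.pop("guilds"))
    fields = {f.name for f in dataclasses.fields(ScenarioConfig)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown scenario option(s): {sorted(unknown)}")
    return ScenarioConfig(guilds=guilds, **d)
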