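"""End-to-end pipeline orchestration.

``run_pipeline`` executes the full analysis — simulate (or load) ->
rarefy -> prevalence filter -> repeated-measures correlation -> network +
Ward tree + PERMANOVA tree cut -> guild aggregation -> ordination +
stratified PERMANOVA -> Procrustes -> association models — writing every
intermediate artifact as TSV (plus GraphML and Newick for the network and
tree) and a JSON manifest with parameters, seeds, stage shapes and SHA-256
checksums sufficient to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import (
    association,
    data_io,
    guilds,
    ordination,
    preprocess,
    rmcorr,
    synthetic,
)

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters for one pipeline run; defaults follow the study design."""

    out_dir: str = "guildflow_out"
    # inputs: either file paths ...
    counts_path: str | None = None
    metadata_path: str | None = None
    chem_path: str | None = None
    # ... or a simulation scenario (dict for scenario_from_dict, or None -> default)
    scenario: dict | None = None
    simulate: bool = True
    # stage parameters
    depth: int = preprocess.DEFAULT_RAREFACTION_DEPTH
    min_prevalence: float = preprocess.DEFAULT_MIN_PREVALENCE
    pseudo: str | float = "half-min"
    r_threshold: float = guilds.DEFAULT_R_THRESHOLD
    p_threshold: float = guilds.DEFAULT_P_THRESHOLD
    treecut_permutations: int = guilds.DEFAULT_TREECUT_PERMUTATIONS
    treecut_alpha: float = guilds.DEFAULT_TREECUT_ALPHA
    pairwise_permutations: int = 999
    protest_permutations: int = 999
    reference: str = "Control"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown run option(s): {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ["simulate", "rarefy", "treecut", "permanova", "protest"], ss.spawn(5)
        )
    }
    manifest: dict = {
        "config": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "scenario"
        },
        "stage_seeds": seeds,
        "stages": {},
        "outputs": {},
    }

    # --- inputs -----------------------------------------------------------
    chem = None
    if config.simulate and config.counts_path is None:
        scenario = (
            synthetic.scenario_from_dict({**config.scenario, "seed": seeds["simulate"]})
            if config.scenario
            else dataclasses.replace(synthetic.default_scenario(), seed=seeds["simulate"])
        )
        counts, meta, chem, truth = synthetic.generate(scenario)
        truth.feature_guild.rename("guild").rename_axis("feature_id").reset_index().to_csv(
            out / "ground_truth_guilds.tsv", sep="\t", index=False
        )
    else:
        counts = data_io.read_count_table(config.counts_path)
        meta = data_io.read_metadata(config.metadata_path)
        if config.chem_path:
            chem = data_io.read_chem(config.chem_path)
    data_io.check_sample_join(counts, meta)
    data_io.write_count_table(counts, out / "counts.tsv")
    data_io.write_metadata(meta, out / "metadata.tsv")
    if chem is not None:
        data_io.write_chem(chem, out / "chemistry.tsv")
    manifest["stages"]["input"] = {"n_samples": int(counts.shape[0]), "n_features": int(counts.shape[1])}

    # --- preprocessing ----------------------------------------------------
    rare = preprocess.rarefy(counts, depth=config.depth, seed=seeds["rarefy"])
    filtered, coverage = preprocess.prevalence_filter(rare, config.min_prevalence)
    rel_all = preprocess.to_relative(rare)
    rel = rel_all[filtered.columns]
    logged = preprocess.log_transform(rel, pseudo=config.pseudo)
    meta = meta.loc[rare.index]
    manifest["stages"]["preprocess"] = {
        "n_samples": int(rare.shape[0]),
        "n_prevalent_features": int(filtered.shape[1]),
        "coverage": float(coverage),
    }

    # --- guild inference ---------------------------------------------------
    rm = rmcorr.rmcorr_matrix(logged, meta["donor"])
    rm.to_long().to_csv(out / "rmcorr.tsv", sep="\t", index=False)
    net = guilds.build_network(rm, rel, config.r_threshold, config.p_threshold)
    guilds.network_edge_table(net).to_csv(out / "network_edges.tsv", sep="\t", index=False)
    nx.write_graphml(net, out / "network.graphml")
    dist = guilds.correlation_distance(rm)
    z, leaf_order = guilds.ward_tree(dist)
    (out / "tree.nwk").write_text(guilds.tree_to_newick(z, leaf_order))
    ga = guilds.cut_tree_permanova(
        z,
        dist,
        leaf_order,
        n_perm=config.treecut_permutations,
        alpha=config.treecut_alpha,
        seed=seeds["treecut"],
        abund=rel,
    )
    ga.to_frame().to_csv(out / "guild_assignment.tsv", sep="\t", index=False)
    gt = guilds.aggregate_guilds(rel, ga)
    gt.rename_axis("sample_id").to_csv(out / "guild_abundance.tsv", sep="\t")
    manifest["stages"]["guilds"] = {
        "n_guilds": int(len(ga.guild_ids)),
        "n_network_edges": int(net.number_of_edges()),
    }

    # --- ordination & community tests ---------------------------------------
    d_asv = ordination.bray_curtis(rel)
    d_cag = ordination.bray_curtis(gt)
    ord_asv = ordination.apcoa(d_asv, meta, "donor")
    ord_cag = ordination.apcoa(d_cag, meta, "donor")
    ord_asv.to_frame().rename_axis("sample_id").to_csv(out / "apcoa_asv.tsv", sep="\t")
    ord_cag.to_frame().rename_axis("sample_id").to_csv(out / "apcoa_cag.tsv", sep="\t")
    pw = ordination.pairwise_permanova(
        d_cag,
        meta["treatment"],
        n_perm=config.pairwise_permutations,
        strata=meta["donor"],
        seed=seeds["permanova"],
    )
    pw.to_csv(out / "pairwise_permanova.tsv", sep="\t", index=False)
    proc = ordination.procrustes_protest(
        ord_asv, ord_cag, n_perm=config.protest_permutations, seed=seeds["protest"]
    )
    manifest["stages"]["ordination"] = {
        "procrustes_m2": proc.m2,
        "procrustes_correlation": proc.correlation,
        "protest_p": proc.p,
    }

    # --- association models ---------------------------------------------------
    assoc = association.fit_guild_treatment(
        gt, meta, reference=config.reference, pseudo=config.pseudo
    )
    assoc.to_csv(out / "guild_treatment_associations.tsv", sep="\t", index=False)
    manifest["stages"]["association"] = {
        "n_tests": int(len(assoc)),
        "n_significant_q05": int((assoc["q"] < 0.05).sum()),
    }
    if chem is not None:
        scfa_assoc = association.fit_guild_scfa(gt, chem, meta)
        scfa_assoc.to_csv(out / "guild_scfa_associations.tsv", sep="\t", index=False)
        chem_rows = []
        for response in ("pH",) + data_io.SCFA_COLUMNS:
            tab = association.fit_chem_treatment(chem, meta, response)
            tab.insert(0, "response", response)
            chem_rows.append(tab)
        pd.concat(chem_rows).to_csv(out / "chem_treatment_contrasts.tsv", sep="\t", index=False)
    else:
        logger.warning("no chemistry table: skipping SCFA association models")
        manifest["stages"]["association"]["scfa_models"] = "skipped (no chemistry table)"

    for path in sorted(out.glob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
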