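"""End-to-end analysis orchestration.

Stages: simulate (synthetic cohort) -> energy (persistence energies and
per-parcel control input) -> impact (node-removal control impact of mean
states) -> nulls (structural- and spatial-null re-analyses) -> stats (mixed
models, demographics) -> align (receptor-map permutation alignment). Each
stage reads the previous stage's TSVs from the output directory, so stages
can be re-run independently and "all" is exactly their composition. All
numeric tables are written with 12 significant digits; a run with the same
config and seed reproduces them byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (CohortConfig, energy_table, generate_cohort,
                     generate_pet_maps)
from .connectome import (load_network, normalize_dynamics, rewire_null,
                         save_network)
from .control import EnergyEngine, control_impact
from .states import (CONDITIONS, TASKS, spatial_null, states_to_table,
                     table_to_states)
from .stats import (control_input_diff, demographics_table,
                    fit_efficiency_models, fit_energy_models,
                    receptor_alignment_suite)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.12g"

STAGES = ("simulate", "energy", "impact", "nulls", "stats", "align")

_REQUIRED = ("control.T", "control.c", "cohort.seed", "stats.n_perm")

DEFAULT_CONFIG = {
    "cohort": {},              # CohortConfig overrides
    "control": {"T": 1.0, "c": 1.0, "n_steps": 1001,
                "out_of_slab_policy": "zero", "normalization_mode": "none"},
    "stats": {"n_perm": 500, "alpha": 0.05, "fdr_scope": "within_task"},
    "nulls": {"n_swaps_per_edge": 10},
    "receptors": {"k_maps": 4, "target_rho": 0.5},
    "seed": 0,
}


def load_config(path=None, seed=None) -> dict:
    """Merge a YAML config over the defaults; validate required keys."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            if isinstance(values, dict):
                cfg.setdefault(section, {}).update(values)
            else:
                cfg[section] = values
    if seed is not None:
        cfg["seed"] = int(seed)
    cfg["cohort"].setdefault("seed", cfg["seed"])
    for dotted in _REQUIRED:
        section, key = dotted.split(".")
        if cfg.get(section, {}).get(key) is None:   # absent or explicit null
            raise KeyError(f"{dotted} required")
    return cfg


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _cohort_config(cfg: dict) -> CohortConfig:
    fields = CohortConfig.__dataclass_fields__
    kw = {k: v for k, v in cfg["cohort"].items() if k in fields}
    kw.setdefault("T", cfg["control"]["T"])
    kw.setdefault("c", cfg["control"]["c"])
    return CohortConfig(**kw)


def stage_simulate(cfg: dict, outdir: Path) -> None:
    cc = _cohort_config(cfg)
    cohort = generate_cohort(cc)
    save_network(cohort.network, outdir / "network.tsv")
    _write(states_to_table(cohort.states), outdir / "states.tsv")
    _write(cohort.behavior, outdir / "behavior.tsv")
    _write(cohort.demographics, outdir / "demographics.tsv")
    slab = cohort.states[0].slab_mask
    target = np.where(slab, np.arange(cohort.network.n_nodes, dtype=float), 0.0)
    maps = generate_pet_maps(cohort.network.n_nodes,
                             cfg["receptors"]["k_maps"], target,
                             cfg["receptors"]["target_rho"],
                             seed=cc.seed + 3)
    maps.insert(0, "parcel_label", list(cohort.network.labels))
    _write(maps, outdir / "receptor_maps.tsv")
    logger.info("simulate: %d subjects, %d nodes, seed %d",
                cc.n_controls + cc.n_relatives, cc.n_nodes, cc.seed)


def _load_inputs(outdir: Path):
    net_path = outdir / "network.tsv"
    states_path = outdir / "states.tsv"
    for p in (net_path, states_path):
        if not p.exists():
            raise FileNotFoundError(f"expected stage input {p}; run 'simulate' first")
    network = load_network(net_path)
    states = table_to_states(pd.read_csv(states_path, sep="\t"),
                             labels=network.labels)
    return network, states


def stage_energy(cfg: dict, outdir: Path) -> None:
    network, states = _load_inputs(outdir)
    T, c = cfg["control"]["T"], cfg["control"]["c"]
    _write(energy_table(states, network, T, c), outdir / "energies.tsv")
    engine = EnergyEngine(normalize_dynamics(network, c), None, T)
    X = np.array([s.values for s in states])
    NI = engine.node_inputs(X, n_steps=cfg["control"]["n_steps"])
    rows = []
    for s, ni in zip(states, NI):
        for label, val in zip(s.labels, ni):
            rows.append((s.meta.subject, s.meta.group, s.meta.drug,
                         s.meta.task, s.meta.condition, label, val))
    _write(pd.DataFrame(rows, columns=["subject", "group", "drug", "task",
                                       "condition", "parcel_label", "value"]),
           outdir / "node_input.tsv")


def stage_impact(cfg: dict, outdir: Path) -> None:
    """Control impact of the group-mean state, per task x condition."""
    network, states = _load_inputs(outdir)
    T, c = cfg["control"]["T"], cfg["control"]["c"]
    rows = []
    for task in TASKS:
        for cond in CONDITIONS:
            sel = [s for s in states
                   if s.meta.task == task and s.meta.condition == cond]
            if not sel:
                continue
            mean_state = np.mean([s.values for s in sel], axis=0)
            imp = control_impact(network, mean_state, T, c)
            for label, val in zip(imp.labels, imp.impact):
                rows.append((task, cond, label, val, imp.baseline_energy,
                             imp.definition_tag))
    _write(pd.DataFrame(rows, columns=["task", "condition", "parcel_label",
                                       "impact", "baseline_energy",
                                       "definition"]),
           outdir / "impact.tsv")


def stage_nulls(cfg: dict, outdir: Path) -> None:
    network, states = _load_inputs(outdir)
    T, c = cfg["control"]["T"], cfg["control"]["c"]
    seed = int(cfg["seed"])
    null_net = rewire_null(network, cfg["nulls"]["n_swaps_per_edge"],
                           seed=seed + 10)
    struct_energies = energy_table(states, null_net, T, c)
    _write(fit_energy_models(struct_energies,
                             fdr_scope=cfg["stats"]["fdr_scope"]),
           outdir / "null_structural_models.tsv")
    null_states = [spatial_null(s, seed + 100 + i)
                   for i, s in enumerate(states)]
    spat_energies = energy_table(null_states, network, T, c)
    _write(fit_energy_models(spat_energies,
                             fdr_scope=cfg["stats"]["fdr_scope"]),
           outdir / "null_spatial_models.tsv")


def stage_stats(cfg: dict, outdir: Path) -> None:
    energies = pd.read_csv(outdir / "energies.tsv", sep="\t")
    _write(fit_energy_models(energies, fdr_scope=cfg["stats"]["fdr_scope"]),
           outdir / "energy_models.tsv")
    behavior_path = outdir / "behavior.tsv"
    demo_path = outdir / "demographics.tsv"
    if behavior_path.exists() and demo_path.exists():
        behavior = pd.read_csv(behavior_path, sep="\t")
        demo = pd.read_csv(demo_path, sep="\t")
        records = behavior.merge(
            energies, on=["subject", "group", "drug", "task", "condition"]
        ).merge(demo[["subject", "age", "sex"]], on="subject")
        _write(fit_efficiency_models(records), outdir / "efficiency_models.tsv")
        _write(demographics_table(demo, categorical=["sex"],
                                  continuous=["age"], nonnormal=("age",)),
               outdir / "demographics_stats.tsv")


def stage_align(cfg: dict, outdir: Path) -> None:
    node_input = pd.read_csv(outdir / "node_input.tsv", sep="\t")
    receptors = pd.read_csv(outdir / "receptor_maps.tsv", sep="\t")
    states_df = pd.read_csv(outdir / "states.tsv", sep="\t")
    labels = receptors["parcel_label"].astype(str).tolist()
    slab = (states_df.drop_duplicates("parcel_label")
            .set_index("parcel_label").loc[labels, "in_slab"].to_numpy(bool))
    seed = int(cfg["seed"])
    n_perm = int(cfg["stats"]["n_perm"])
    logger.info("align: %d permutations, seed %d", n_perm, seed)
    results = []
    for task in TASKS:
        sub = node_input[(node_input["task"] == task)
                         & (node_input["condition"] == "threat")]
        if sub.empty:
            continue
        wide = sub.pivot_table(index=["subject", "drug"],
                               columns="parcel_label", values="value")[labels]
        diff_maps = []
        for subject in wide.index.get_level_values("subject").unique():
            try:
                drug = wide.loc[(subject, "alprazolam")].to_numpy()
                plac = wide.loc[(subject, "placebo")].to_numpy()
            except KeyError:
                continue
            diff_maps.append(control_input_diff(drug, plac))
        suite = receptor_alignment_suite(
            np.array(diff_maps), receptors.drop(columns="parcel_label"),
            n_perm=n_perm, seed=seed + 20, slab_mask=slab)
        suite.insert(0, "task", task)
        results.append(suite)
    _write(pd.concat(results, ignore_index=True), outdir / "alignment.tsv")


_STAGE_FN = {
    "simulate": stage_simulate,
    "energy": stage_energy,
    "impact": stage_impact,
    "nulls": stage_nulls,
    "stats": stage_stats,
    "align": stage_align,
}


def run_pipeline(cfg: dict, outdir, stages=STAGES) -> Path:
    """Run the requested stages; write a manifest recording what completed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    completed = []
    manifest = {"version": __version__, "config": cfg, "stages": completed}
    try:
        for name in stages:
            if name not in _STAGE_FN:
                raise KeyError(f"unknown stage {name!r}")
            logger.info("running stage %s", name)
            _STAGE_FN[name](cfg, outdir)
            completed.append(name)
    finally:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
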