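"""Synthetic pharmaco-fMRI cohort generator.

Emulates the statistical structure the analysis assumes: a two-group
(control / first-degree relative) by two-session (placebo / alprazolam)
crossover, two tasks (emotion identification, emotion memory) by three
emotion conditions (threat, non-threat, neutral), spatially autocorrelated
parcel-level activation states with subject random effects, behavioral
efficiency linearly coupled to persistence energy, and receptor-density-like
maps with a controllable Spearman correlation to a reference map.

The key experimental knob is ``delta_interaction``: relatives' alprazolam
threat-memory states are scaled by (1 + delta), so persistence energy —
which is quadratic in state amplitude — carries a (1 + delta)^2 group x drug
interaction through the genuine control computation rather than being pasted
onto the energies directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, truncnorm

from .connectome import StructuralNetwork, normalize_dynamics
from .control import EnergyEngine
from .states import CONDITIONS, DRUGS, TASKS, StateMeta, make_state

__all__ = [
    "CohortConfig",
    "generate_connectome",
    "generate_states",
    "generate_behavior",
    "generate_pet_maps",
    "generate_demographics",
    "generate_cohort",
    "Cohort",
]


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters for the synthetic cohort.

    Amplitudes are in GLM-beta units; the condition templates have unit
    spatial standard deviation, so ``subject_sd`` and ``session_noise_sd``
    are directly interpretable as fractions of the signal scale.
    """

    n_controls: int = 20
    n_relatives: int = 20
    n_nodes: int = 233
    slab_fraction: float = 0.6
    density: float = 0.25
    delta_interaction: float = 0.009     # (1+delta) amplitude on relative/drug/memory/threat
    drug_amplitude_effect: float = 1.0   # multiplicative drug main effect on all drug states
    subject_sd: float = 0.015
    session_noise_sd: float = 0.04
    base_efficiency: float = 0.6         # accuracy / median RT, 1/s
    efficiency_slope: float = 0.05
    drug_efficiency_drop: float = 0.1
    efficiency_noise_sd: float = 0.02
    base_accuracy: float = 0.9
    T: float = 1.0
    c: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_controls < 1 or self.n_relatives < 1:
            raise ValueError("need at least one subject per group")
        if self.subject_sd < 0 or self.session_noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if 1 + self.delta_interaction <= 0:
            raise ValueError("1 + delta_interaction must be > 0")
        if not 0 < self.slab_fraction <= 1:
            raise ValueError("slab_fraction must be in (0, 1]")

    def subjects(self) -> pd.DataFrame:
        rows = [(f"C{i + 1:03d}", "control") for i in range(self.n_controls)]
        rows += [(f"R{i + 1:03d}", "relative") for i in range(self.n_relatives)]
        return pd.DataFrame(rows, columns=["subject", "group"])


def generate_connectome(n_nodes: int, density: float = 0.25,
                        model: str = "modular", seed: int = 0,
                        n_blocks: int = 4) -> StructuralNetwork:
    """Random weighted connectome stand-in with right-skewed positive weights.

    ``modular`` plants ``n_blocks`` communities with denser, stronger
    in-block connectivity; ``geometric_like`` places nodes uniformly in a
    unit cube and favors short-range connections, mimicking the distance
    dependence of white-matter connectivity.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    labels = tuple(f"parcel_{i + 1:03d}" for i in range(n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    if model == "modular":
        block = rng.integers(0, n_blocks, size=n_nodes)
        same = block[iu[0]] == block[iu[1]]
        # keep overall density while making in-block edges ~3x likelier;
        # density 1 short-circuits to complete support
        p_out = density / (same.mean() * 3 + (1 - same.mean()))
        p_edge = np.where(same, np.minimum(3 * p_out, 1.0), p_out)
        if density >= 1.0:
            p_edge = np.ones_like(p_edge)
        w_scale = np.where(same, 2.0, 1.0)
    elif model == "geometric_like":
        pos = rng.uniform(size=(n_nodes, 3))
        d = np.linalg.norm(pos[iu[0]] - pos[iu[1]], axis=1)
        decay = np.exp(-2.0 * d)
        p_edge = np.minimum(density * decay / decay.mean(), 1.0)
        w_scale = decay / decay.mean()
    else:
        raise ValueError(f"unknown connectome model {model!r}")
    present = rng.uniform(size=len(iu[0])) < p_edge
    weights = rng.lognormal(mean=0.0, sigma=0.5, size=len(iu[0])) * w_scale
    W = np.zeros((n_nodes, n_nodes))
    W[iu] = np.where(present, weights, 0.0)
    W = W + W.T
    return StructuralNetwork(labels, W)


def _smooth_template(rng, network: StructuralNetwork, n_diffuse: int = 3):
    """Spatially autocorrelated template: white noise diffused on the graph."""
    W = network.weights
    rowsum = W.sum(axis=1)
    rowsum[rowsum == 0] = 1.0
    x = rng.standard_normal(network.n_nodes)
    for _ in range(n_diffuse):
        x = 0.5 * x + 0.5 * (W @ x) / rowsum
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_states(config: CohortConfig, network: StructuralNetwork):
    """Activation states for every subject x drug x task x condition cell.

    x = m_cond * g_drug * h + a_subject + noise, with h = (1 + delta) only
    for relatives' alprazolam threat-memory states; out-of-slab parcels are
    zeroed.
    """
    rng = np.random.default_rng(config.seed)
    n = network.n_nodes
    n_in = max(2, int(round(config.slab_fraction * n)))
    slab = np.zeros(n, dtype=bool)
    slab[rng.choice(n, size=n_in, replace=False)] = True
    templates = {
        (task, cond): _smooth_template(rng, network)
        for task in TASKS for cond in CONDITIONS
    }
    subjects = config.subjects()
    offsets = rng.normal(0.0, config.subject_sd, size=len(subjects))
    states = []
    for (_, row), a_s in zip(subjects.iterrows(), offsets):
        for drug in DRUGS:
            g = config.drug_amplitude_effect if drug == "alprazolam" else 1.0
            for task in TASKS:
                for cond in CONDITIONS:
                    h = 1.0
                    if (row["group"] == "relative" and drug == "alprazolam"
                            and task == "memory" and cond == "threat"):
                        h = 1.0 + config.delta_interaction
                    eps = rng.normal(0.0, config.session_noise_sd, size=n)
                    values = templates[(task, cond)] * g * h + a_s + eps
                    meta = StateMeta(row["subject"], row["group"], drug, task, cond)
                    states.append(make_state(values, slab, network.labels, meta))
    return states


def energy_table(states, network: StructuralNetwork, T: float = 1.0,
                 c: float = 1.0) -> pd.DataFrame:
    """Persistence energy for each state (one shared Gramian factorization)."""
    engine = EnergyEngine(normalize_dynamics(network, c), None, T)
    X = np.array([s.values for s in states])
    pe = engine.energies(X)
    rows = [
        (s.meta.subject, s.meta.group, s.meta.drug, s.meta.task,
         s.meta.condition, e)
        for s, e in zip(states, pe)
    ]
    return pd.DataFrame(
        rows, columns=["subject", "group", "drug", "task", "condition", "energy"]
    )


def generate_behavior(states, config: CohortConfig,
                      pe_table: pd.DataFrame = None,
                      network: StructuralNetwork = None) -> pd.DataFrame:
    """Accuracy and median RT per record, coupled to persistence energy.

    Efficiency (accuracy / median RT) is built as base + slope * z(Pe)
    - drop * [drug] + noise, with the Pe coupling active in the threat
    identification condition. Accuracy stays near its base on a clipped
    logistic scale; RT absorbs the efficiency variation.
    """
    if pe_table is None:
        if network is None:
            raise ValueError("need either pe_table or network to compute Pe")
        pe_table = energy_table(states, network, config.T, config.c)
    rng = np.random.default_rng(config.seed + 1)
    df = pe_table.copy()
    thr_id = (df["task"] == "identification") & (df["condition"] == "threat")
    z = np.zeros(len(df))
    pe = df.loc[thr_id, "energy"].to_numpy()
    if thr_id.any() and pe.std() > 0:
        z[thr_id.to_numpy()] = (pe - pe.mean()) / pe.std()
    drug_ind = (df["drug"] == "alprazolam").astype(float).to_numpy()
    target = (config.base_efficiency + config.efficiency_slope * z
              - config.drug_efficiency_drop * drug_ind)
    n_resampled = 0
    eff = np.empty(len(df))
    for i, t in enumerate(target):
        e = t + rng.normal(0.0, config.efficiency_noise_sd)
        while e <= 0:
            n_resampled += 1
            e = t + rng.normal(0.0, config.efficiency_noise_sd)
        eff[i] = e
    if n_resampled:
        import logging
        logging.getLogger(__name__).info(
            "resampled %d non-positive efficiencies", n_resampled
        )
    # clipped-logistic accuracy near base; RT carries the efficiency signal
    logit = np.log(config.base_accuracy / (1 - config.base_accuracy))
    acc = 1.0 / (1.0 + np.exp(-(logit + rng.normal(0.0, 0.1, size=len(df)))))
    acc = np.clip(acc, 0.0, 1.0)
    out = df[["subject", "group", "drug", "task", "condition"]].copy()
    out["accuracy"] = acc
    out["median_rt"] = acc / eff
    return out


def generate_pet_maps(n_nodes: int, k_maps: int, target_map,
                      target_rho: float, seed: int = 0) -> pd.DataFrame:
    """Receptor-density-like maps rescaled to [0, 100].

    The first map is rank-blended with ``target_map`` so that its Spearman
    correlation with the target is approximately ``target_rho`` (exact at
    |rho| = 1); the remaining maps are independent. Blending weight uses the
    bivariate-normal identity rho_s = (6/pi) asin(r/2), inverted as
    r = 2 sin(pi rho_s / 6).
    """
    if not -1 <= target_rho <= 1:
        raise ValueError("target_rho must lie in [-1, 1]")
    target = np.asarray(target_map, dtype=float)
    if target.shape != (n_nodes,):
        raise ValueError(f"target_map must have shape ({n_nodes},)")
    if np.ptp(target) == 0:
        raise ValueError("constant target_map has undefined ranks")
    rng = np.random.default_rng(seed)
    # normal scores of the target ranks
    z1 = norm.ppf(rankdata(target) / (n_nodes + 1))
    r = 2 * np.sin(np.pi * target_rho / 6)
    if abs(target_rho) == 1.0:
        first = np.sign(target_rho) * z1
    else:
        first = r * z1 + np.sqrt(1 - r**2) * rng.standard_normal(n_nodes)
    maps = [first] + [rng.standard_normal(n_nodes) for _ in range(k_maps - 1)]
    out = {}
    for k, m in enumerate(maps):
        lo, hi = m.min(), m.max()
        out[f"receptor_{k + 1}"] = (m - lo) / (hi - lo) * 100.0
    return pd.DataFrame(out)


DEMOGRAPHIC_PROFILES = {
    # (age mean, age sd, truncation low, truncation high, fraction female)
    "control": (39.0, 11.4, 21.0, 57.0, 0.519),
    "relative": (42.3, 14.8, 20.0, 60.0, 0.55),
}


def generate_demographics(config: CohortConfig, seed: int = None,
                          profiles: dict = None) -> pd.DataFrame:
    """Per-subject age and sex, matched to the study's group profiles."""
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    profiles = profiles or DEMOGRAPHIC_PROFILES
    rows = []
    for _, row in config.subjects().iterrows():
        mean, sd, lo, hi, p_f = profiles[row["group"]]
        a, b = (lo - mean) / sd, (hi - mean) / sd
        age = truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)
        sex = "F" if rng.uniform() < p_f else "M"
        rows.append((row["subject"], row["group"], float(age), sex))
    return pd.DataFrame(rows, columns=["subject", "group", "age", "sex"])


@dataclass
class Cohort:
    """Everything the downstream analysis consumes, generated from one seed."""

    config: CohortConfig
    network: StructuralNetwork
    states: list = field(repr=False)
    energies: pd.DataFrame = field(repr=False)
    behavior: pd.DataFrame = field(repr=False)
    demographics: pd.DataFrame = field(repr=False)


def generate_cohort(config: CohortConfig) -> Cohort:
    """End-to-end synthetic study: connectome, states, energies, behavior."""
    network = generate_connectome(config.n_nodes, config.density,
                                  seed=config.seed)
    states = generate_states(config, network)
    energies = energy_table(states, network, config.T, config.c)
    behavior = generate_behavior(states, config, pe_table=energies)
    demographics = generate_demographics(config)
    return Cohort(config, network, states, energies, behavior, demographics)
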