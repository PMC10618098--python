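"""Parcel-level brain activation states.

A brain state is the vector of parcel-averaged GLM beta weights for one
subject x session x task x condition cell, together with a slab mask marking
which parcels the functional acquisition actually covered. Spatial null
states permute the in-slab values, destroying the spatial arrangement of
activation while preserving its distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "StateMeta",
    "BrainState",
    "make_state",
    "spatial_null",
    "normalize_state",
    "states_to_table",
    "table_to_states",
]

GROUPS = ("control", "relative")
DRUGS = ("placebo", "alprazolam")
TASKS = ("identification", "memory")
CONDITIONS = ("threat", "nonthreat", "neutral")


@dataclass(frozen=True)
class StateMeta:
    subject: str
    group: str
    drug: str
    task: str
    condition: str
    is_null: bool = False

    def __post_init__(self):
        for name, value, allowed in (
            ("group", self.group, GROUPS),
            ("drug", self.drug, DRUGS),
            ("task", self.task, TASKS),
            ("condition", self.condition, CONDITIONS),
        ):
            if value not in allowed:
                raise ValueError(f"{name}={value!r} not in {allowed}")


@dataclass(frozen=True)
class BrainState:
    """Activation vector with slab mask and identifying metadata."""

    values: np.ndarray = field(repr=False)
    slab_mask: np.ndarray = field(repr=False)
    labels: tuple
    meta: StateMeta

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        m = np.asarray(self.slab_mask, dtype=bool)
        labels = tuple(str(l) for l in self.labels)
        if v.ndim != 1:
            raise ValueError("values must be a vector")
        if not (len(v) == len(m) == len(labels)):
            raise ValueError(
                f"length mismatch: values {len(v)}, mask {len(m)}, labels {len(labels)}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite state values")
        v = v.copy()
        v.flags.writeable = False
        m = m.copy()
        m.flags.writeable = False
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "slab_mask", m)
        object.__setattr__(self, "labels", labels)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)


def make_state(values, slab_mask, labels, meta: StateMeta,
               out_of_slab_policy: str = "zero") -> BrainState:
    """Build a state, applying the out-of-slab handling policy.

    ``zero`` keeps the full parcellation and zeroes uncovered parcels (the
    full structural network, including its indirect pathways, stays in play).
    ``drop`` restricts the state to in-slab parcels; the downstream network
    must then be restricted to the same mask.
    """
    mask = np.asarray(slab_mask, dtype=bool)
    if not mask.any():
        raise ValueError("slab mask excludes every parcel")
    if out_of_slab_policy == "zero":
        v = np.where(mask, np.asarray(values, dtype=float), 0.0)
        return BrainState(v, mask, tuple(labels), meta)
    if out_of_slab_policy == "drop":
        v = np.asarray(values, dtype=float)[mask]
        kept = tuple(l for l, keep in zip(labels, mask) if keep)
        return BrainState(v, np.ones(mask.sum(), dtype=bool), kept, meta)
    raise ValueError(f"unknown out_of_slab_policy {out_of_slab_policy!r}")


def spatial_null(state: BrainState, seed: int) -> BrainState:
    """Uniformly permute in-slab values; out-of-slab entries untouched."""
    mask = state.slab_mask
    n_in = int(mask.sum())
    if n_in == 0:
        raise ValueError("slab mask excludes every parcel")
    if n_in < 2:
        raise ValueError("need at least 2 in-slab parcels to permute")
    rng = np.random.default_rng(seed)
    v = state.values.copy()
    idx = np.flatnonzero(mask)
    v[idx] = v[idx][rng.permutation(n_in)]
    return BrainState(v, mask, state.labels, replace(state.meta, is_null=True))


def normalize_state(state: BrainState, mode: str = "none") -> BrainState:
    if mode == "none":
        return state
    if mode == "unit_norm":
        nrm = float(np.linalg.norm(state.values))
        if nrm == 0.0:
            raise ValueError("cannot unit-normalize the zero state")
        return BrainState(state.values / nrm, state.slab_mask, state.labels, state.meta)
    raise ValueError(f"unknown normalization mode {mode!r}")


def states_to_table(states) -> pd.DataFrame:
    """Long-format table: one row per (record, parcel)."""
    rows = []
    for s in states:
        for label, beta, in_slab in zip(s.labels, s.values, s.slab_mask):
            rows.append(
                (s.meta.subject, s.meta.group, s.meta.drug, s.meta.task,
                 s.meta.condition, label, beta, bool(in_slab))
            )
    return pd.DataFrame(
        rows,
        columns=["subject", "group", "drug", "task", "condition",
                 "parcel_label", "beta", "in_slab"],
    )


def table_to_states(df: pd.DataFrame, labels=None) -> list:
    """Inverse of :func:`states_to_table`; parcel order follows ``labels``."""
    states = []
    keys = ["subject", "group", "drug", "task", "condition"]
    for key, grp in df.groupby(keys, sort=True):
        grp = grp.set_index("parcel_label")
        order = list(labels) if labels is not None else list(grp.index)
        grp = grp.loc[order]
        meta = StateMeta(*[str(k) for k in key])
        states.append(
            BrainState(
                grp["beta"].to_numpy(float),
                grp["in_slab"].to_numpy(bool),
                tuple(order),
                meta,
            )
        )
    return states
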