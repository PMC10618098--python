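"""Statistical inference on control-energy and behavioral measures.

Covers the study's inferential layer: linear mixed-effects models of
persistence energy (fixed effects of group, drug and their interaction;
random intercept per subject, honoring the crossover design), mixed models
of task efficiency on persistence energy with demographic covariates,
Benjamini-Hochberg FDR across conditions, spatial permutation tests of the
alignment between drug-induced control-input differences and receptor
density maps, and the demographic comparison statistics (Fisher exact odds
ratios, t / Wilcoxon tests, Cohen's d).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata

import statsmodels.formula.api as smf

from .states import CONDITIONS, TASKS

__all__ = [
    "MixedModelResult",
    "PermutationResult",
    "fit_energy_model",
    "fit_energy_models",
    "fit_efficiency_model",
    "fit_efficiency_models",
    "efficiency",
    "bh_fdr",
    "control_input_diff",
    "receptor_alignment_test",
    "receptor_alignment_suite",
    "demographics_table",
    "cohens_d",
]


@dataclass(frozen=True)
class MixedModelResult:
    """Fixed effects of one mixed model, keyed by term name.

    ``coefficients`` maps term -> dict(estimate, se, p, df). ``symbols``
    translates the conventional coefficient names of the energy model
    (gamma00 intercept, gamma01 group, beta1i drug, gamma11 group x drug)
    and the efficiency model (beta, the persistence-energy slope) to terms.
    """

    coefficients: dict
    symbols: dict
    n_obs: int
    n_subjects: int
    converged: bool
    task: str = ""
    condition: str = ""

    def coef(self, symbol: str) -> dict:
        return self.coefficients[self.symbols[symbol]]

    def __post_init__(self):
        for term, c in self.coefficients.items():
            if not (0 <= c["p"] <= 1 or np.isnan(c["p"])):
                raise ValueError(f"invalid p-value for {term}: {c['p']}")


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    null: np.ndarray = field(repr=False)
    n_perm: int = 500
    p: float = 1.0
    q: float = np.nan
    seed: int = 0

    def __post_init__(self):
        if not 1.0 / (self.n_perm + 1) <= self.p <= 1:
            raise ValueError(f"permutation p={self.p} outside valid range")


def _fit_mixedlm(formula: str, data: pd.DataFrame, symbols: dict,
                 task: str = "", condition: str = "") -> MixedModelResult:
    """REML random-intercept fit with degenerate-outcome handling."""
    outcome = formula.split("~")[0].strip()
    y = data[outcome].to_numpy(float)
    n_fixed = len(symbols)
    df_resid = len(data) - n_fixed
    if np.ptp(y) == 0:
        # constant outcome: intercept = constant, all slopes exactly 0
        coefs = {}
        for sym, term in symbols.items():
            est = float(y[0]) if term == "Intercept" else 0.0
            coefs[term] = {"estimate": est, "se": 0.0, "p": np.nan,
                           "df": df_resid}
        return MixedModelResult(coefs, symbols, len(data),
                                data["subject"].nunique(), True, task, condition)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["subject"])
        fit = model.fit(reml=True)
    coefs = {}
    for term in fit.fe_params.index:
        est = float(fit.fe_params[term])
        se = float(fit.bse_fe[term])
        # t reference on residual df rather than the asymptotic normal:
        # mildly conservative at crossover-study sample sizes
        p = float(2 * sps.t.sf(abs(est / se), df_resid)) if se > 0 else np.nan
        coefs[term] = {"estimate": est, "se": se, "p": p, "df": df_resid}
    return MixedModelResult(coefs, symbols, int(fit.nobs),
                            data["subject"].nunique(), bool(fit.converged),
                            task, condition)


_ENERGY_SYMBOLS = {
    "gamma00": "Intercept",
    "gamma01": "group_rel",
    "beta1i": "drug_alp",
    "gamma11": "group_rel:drug_alp",
}


def fit_energy_model(records: pd.DataFrame, task: str, condition: str,
                     standardize: bool = True) -> MixedModelResult:
    """Mixed model of persistence energy for one task x condition cell.

    energy ~ group + drug + group:drug with a random intercept per subject;
    group and drug are treatment-coded (control, placebo as reference).
    With ``standardize`` the outcome is z-scored within the cell so that
    coefficients are in SD units and comparable across cells.
    """
    data = records[(records["task"] == task)
                   & (records["condition"] == condition)].copy()
    if data.empty:
        raise ValueError(f"no records for task={task}, condition={condition}")
    for grp in ("control", "relative"):
        if data.loc[data["group"] == grp, "subject"].nunique() < 2:
            raise ValueError(f"need >=2 subjects in group {grp!r}")
    data["group_rel"] = (data["group"] == "relative").astype(float)
    data["drug_alp"] = (data["drug"] == "alprazolam").astype(float)
    if standardize and data["energy"].std() > 0:
        data["energy"] = ((data["energy"] - data["energy"].mean())
                          / data["energy"].std())
    return _fit_mixedlm("energy ~ group_rel * drug_alp", data,
                        _ENERGY_SYMBOLS, task, condition)


def fit_energy_models(records: pd.DataFrame, standardize: bool = True,
                      fdr_scope: str = "within_task") -> pd.DataFrame:
    """All task x condition energy models, FDR over the interaction p-values.

    FDR is applied across the emotion conditions within each task
    (``within_task``), across all six cells (``all``), or skipped (``none``).
    """
    results = []
    for task in TASKS:
        for cond in CONDITIONS:
            res = fit_energy_model(records, task, cond, standardize)
            for sym in _ENERGY_SYMBOLS:
                c = res.coef(sym)
                results.append((task, cond, sym, c["estimate"], c["se"],
                                c["p"], c["df"], res.converged))
    df = pd.DataFrame(results, columns=["task", "condition", "term",
                                        "estimate", "se", "p", "df",
                                        "converged"])
    df["q"] = np.nan
    inter = df["term"] == "gamma11"
    if fdr_scope == "within_task":
        for task in TASKS:
            m = inter & (df["task"] == task)
            df.loc[m, "q"] = bh_fdr(df.loc[m, "p"].to_numpy())
    elif fdr_scope == "all":
        df.loc[inter, "q"] = bh_fdr(df.loc[inter, "p"].to_numpy())
    elif fdr_scope != "none":
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    return df


_EFFICIENCY_SYMBOLS = {
    "intercept": "Intercept",
    "beta": "energy_z",
    "drug": "drug_alp",
    "group": "group_rel",
    "age": "age",
    "sex": "sex_m",
}


def fit_efficiency_model(records: pd.DataFrame, task: str, condition: str,
                         standardize: bool = True) -> MixedModelResult:
    """Mixed model: efficiency ~ Pe + drug + group + age + sex, per cell.

    ``records`` must carry accuracy, median_rt, energy, age and sex per row;
    efficiency is accuracy / median RT. Pe (and, with ``standardize``, the
    outcome) is z-scored so that beta is an SD-per-SD slope.
    """
    data = records[(records["task"] == task)
                   & (records["condition"] == condition)].copy()
    if data.empty:
        raise ValueError(f"no records for task={task}, condition={condition}")
    data["efficiency"] = efficiency(data["accuracy"].to_numpy(),
                                    data["median_rt"].to_numpy())
    data["group_rel"] = (data["group"] == "relative").astype(float)
    data["drug_alp"] = (data["drug"] == "alprazolam").astype(float)
    data["sex_m"] = (data["sex"] == "M").astype(float)
    e = data["energy"]
    data["energy_z"] = (e - e.mean()) / e.std() if e.std() > 0 else 0.0
    if standardize and data["efficiency"].std() > 0:
        f = data["efficiency"]
        data["efficiency"] = (f - f.mean()) / f.std()
    return _fit_mixedlm(
        "efficiency ~ energy_z + drug_alp + group_rel + age + sex_m",
        data, _EFFICIENCY_SYMBOLS, task, condition)


def fit_efficiency_models(records: pd.DataFrame,
                          standardize: bool = True) -> pd.DataFrame:
    """All six task x condition efficiency models; FDR on the Pe slope."""
    rows = []
    for task in TASKS:
        for cond in CONDITIONS:
            res = fit_efficiency_model(records, task, cond, standardize)
            c = res.coef("beta")
            rows.append((task, cond, "beta", c["estimate"], c["se"], c["p"],
                         c["df"], res.converged))
    df = pd.DataFrame(rows, columns=["task", "condition", "term", "estimate",
                                     "se", "p", "df", "converged"])
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df


def efficiency(accuracy, median_rt):
    """Task-performance efficiency: proportion correct / median RT (1/s)."""
    accuracy = np.asarray(accuracy, dtype=float)
    median_rt = np.asarray(median_rt, dtype=float)
    if np.any((accuracy < 0) | (accuracy > 1)):
        raise ValueError("accuracy must lie in [0, 1]")
    if np.any(median_rt <= 0):
        raise ValueError("median_rt must be > 0")
    out = accuracy / median_rt
    return float(out) if out.ndim == 0 else out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def control_input_diff(node_input_drug, node_input_placebo,
                       mode: str = "absolute"):
    """Per-parcel difference in integrated control input between sessions."""
    a = np.asarray(node_input_drug, dtype=float)
    b = np.asarray(node_input_placebo, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"parcel mismatch: {a.shape} vs {b.shape}")
    d = a - b
    if mode == "absolute":
        return np.abs(d)
    if mode == "signed":
        return d
    raise ValueError(f"unknown mode {mode!r}")


def _rank_standardize(X: np.ndarray) -> np.ndarray:
    """Row-wise ranks, centered and scaled: Pearson of these = Spearman."""
    R = np.apply_along_axis(rankdata, -1, X)
    R = R - R.mean(axis=-1, keepdims=True)
    nrm = np.linalg.norm(R, axis=-1, keepdims=True)
    nrm[nrm == 0] = 1.0
    return R / nrm


def receptor_alignment_test(diff_maps, receptor_map, n_perm: int = 500,
                            seed: int = 0, slab_mask=None) -> PermutationResult:
    """Spatial permutation test of diff-map / receptor-map alignment.

    Statistic: mean over subjects of the Spearman correlation between each
    subject's control-input difference map and the receptor map, on in-slab
    parcels. The null shuffles the receptor map's parcel labels within the
    mask — one shared permutation per iteration across subjects, preserving
    the between-subject correlation structure of the statistic. Two-sided
    p = (1 + #{|null| >= |observed|}) / (n_perm + 1).
    """
    D = np.atleast_2d(np.asarray(diff_maps, dtype=float))
    r = np.asarray(receptor_map, dtype=float)
    if D.shape[1] != r.shape[0]:
        raise ValueError("diff maps and receptor map have different parcels")
    if D.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if slab_mask is not None:
        mask = np.asarray(slab_mask, dtype=bool)
        D = D[:, mask]
        r = r[mask]
    if r.shape[0] < 3:
        raise ValueError("need at least 3 in-slab parcels")
    if np.ptp(r) == 0:
        raise ValueError("receptor map is constant on the mask")
    rng = np.random.default_rng(seed)
    Dr = _rank_standardize(D)                      # (n_subj, n_parcels)
    rr = _rank_standardize(r[None, :])[0]
    observed = float(np.mean(Dr @ rr))
    perms = np.array([rng.permutation(r.shape[0]) for _ in range(n_perm)])
    null = (Dr @ rr[perms].T).mean(axis=0)         # shared permutation/iter
    p = (1.0 + np.sum(np.abs(null) >= np.abs(observed))) / (n_perm + 1.0)
    return PermutationResult(observed, null, n_perm, float(p), seed=seed)


def receptor_alignment_suite(diff_maps, receptor_maps: pd.DataFrame,
                             n_perm: int = 500, seed: int = 0,
                             slab_mask=None) -> pd.DataFrame:
    """Alignment test per receptor map, FDR-corrected across maps."""
    rows = []
    for k, name in enumerate(receptor_maps.columns):
        res = receptor_alignment_test(diff_maps, receptor_maps[name].to_numpy(),
                                      n_perm, seed + k, slab_mask)
        rows.append((name, res.observed, res.p, res.n_perm, res.seed))
    df = pd.DataFrame(rows, columns=["receptor", "observed_rho", "p",
                                     "n_perm", "seed"])
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df[["receptor", "observed_rho", "p", "q", "n_perm", "seed"]]


def cohens_d(mean1: float, sd1: float, n1: int,
             mean2: float, sd2: float, n2: int) -> float:
    """Standardized mean difference (group 2 minus group 1, pooled SD)."""
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    if pooled == 0:
        if mean1 == mean2:
            return 0.0
        raise ValueError("pooled SD is 0 with unequal means")
    return (mean2 - mean1) / pooled


def demographics_table(df: pd.DataFrame, group_col: str = "group",
                       categorical=None, continuous=None,
                       nonnormal=(), events=None) -> pd.DataFrame:
    """Two-group demographic comparison table.

    Categorical variables get a Fisher exact p and the cross-product odds
    ratio (event odds in the first group over the second; the event level is
    ``events[var]`` or the lexicographically first level). Continuous
    variables get a pooled-variance two-sample t-test (df = n1 + n2 - 2), or
    a Wilcoxon rank-sum z if listed in ``nonnormal``; Cohen's d (group 2
    minus group 1) is reported for every continuous variable.
    """
    groups = sorted(df[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    g1 = df[df[group_col] == groups[0]]
    g2 = df[df[group_col] == groups[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need >=2 members per group")
    events = events or {}
    rows = []
    for var in (categorical or ()):
        levels = sorted(df[var].dropna().unique())
        event = events.get(var, levels[0])
        a = int((g1[var] == event).sum())
        b = int((g1[var] != event).sum())
        c = int((g2[var] == event).sum())
        d = int((g2[var] != event).sum())
        table = np.array([[a, b], [c, d]])
        p = float(sps.fisher_exact(table)[1])
        orat = (a * d) / (b * c) if b * c > 0 else np.nan
        rows.append((var, "fisher_exact", p, orat, np.nan, np.nan,
                     f"event={event}"))
    for var in (continuous or ()):
        x1 = g1[var].dropna().to_numpy(float)
        x2 = g2[var].dropna().to_numpy(float)
        d_eff = cohens_d(x1.mean(), x1.std(ddof=1), len(x1),
                         x2.mean(), x2.std(ddof=1), len(x2))
        if var in nonnormal:
            stat, p = sps.ranksums(x1, x2)
            rows.append((var, "wilcoxon_ranksum", float(p), np.nan,
                         float(stat), d_eff, "z statistic"))
        else:
            res = sps.ttest_ind(x1, x2, equal_var=True)
            rows.append((var, "t_test", float(res.pvalue), np.nan,
                         float(res.statistic), d_eff,
                         f"df={len(x1) + len(x2) - 2}"))
    return pd.DataFrame(rows, columns=["variable", "test", "p", "odds_ratio",
                                       "statistic", "cohens_d", "note"])
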