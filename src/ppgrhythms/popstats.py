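"""Cross-animal statistics: correlations, ANOVA, dip test, summary tables.

Mirrors the population-level analysis: Pearson correlations between
baseline rhythm frequencies, one-way ANOVA between groups (e.g. heart vs
pyloric critical temperatures), Hartigan's dip test for multimodality of
the frequency distribution, and a per-animal summary table with bout and
coherence prevalence fractions.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._dip import dip_statistic

__all__ = ["pearson", "one_way_anova", "hartigan_dip",
           "summarize_population", "PopulationSummary", "dip_statistic"]


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with two-sided p from the t transform (n-2 dof)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def one_way_anova(*groups: Sequence[float]
                  ) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA: F statistic, (between, within) dof, and p-value."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(g, float) for g in groups]
    for g in arrs:
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
    f, p = stats.f_oneway(*arrs)
    df_between = len(arrs) - 1
    df_within = sum(g.size for g in arrs) - len(arrs)
    return float(f), (df_between, df_within), float(p)


@functools.lru_cache(maxsize=32)
def _null_dip_table(n: int, n_boot: int, seed: int) -> tuple:
    """Bootstrap null dips for sample size n (uniform samples).

    The dip's null distribution depends only on n, so the table is cached
    per (n, n_boot, seed).
    """
    rng = np.random.default_rng(seed)
    return tuple(dip_statistic(rng.uniform(size=n)) for _ in range(n_boot))


def hartigan_dip(x: Sequence[float], n_boot: int = 2000,
                 seed: int = 0) -> tuple[float, float]:
    """Hartigan's dip test of unimodality.

    The p-value is the fraction of ``n_boot`` uniform samples of the same
    size whose dip meets or exceeds the observed one (add-one smoothed).
    """
    x = np.asarray(x, float)
    if x.size < 4:
        raise ValueError("need n >= 4")
    d = dip_statistic(x)
    table = np.asarray(_null_dip_table(int(x.size), int(n_boot), int(seed)))
    p = float((1 + np.sum(table >= d)) / (n_boot + 1))
    return d, p


@dataclass
class PopulationSummary:
    """Per-animal table plus group statistics and test results."""

    table: pd.DataFrame
    bout_prevalence: float
    coherent_prevalence: float
    group_stats: dict = field(default_factory=dict)
    tests: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return self.table


def summarize_population(per_animal: pd.DataFrame,
                         run_tests: bool = True,
                         dip_column: str = "heart_hz",
                         n_boot: int = 2000,
                         seed: int = 0) -> PopulationSummary:
    """Assemble the cross-animal summary.

    ``per_animal`` carries one row per animal; recognized columns (all
    optional except ``animal_id``) are ``heart_hz``, ``pyloric_hz``,
    ``q10_heart``, ``q10_pyloric``, ``t_crit_heart``, ``t_crit_pyloric``,
    ``has_bouts`` and ``is_coherent``.  Computes bout/coherence prevalence
    fractions, mean +- sd per numeric column, and (when ``run_tests``) the
    heart-pyloric frequency correlation, the heart-vs-pyloric critical
    temperature ANOVA, and the dip test on ``dip_column``.
    """
    if len(per_animal) < 1:
        raise ValueError("need at least one animal")
    df = per_animal.copy()

    def _prevalence(col: str) -> float:
        if col not in df.columns:
            return float("nan")
        v = df[col].astype(bool)
        return float(v.sum() / len(df))

    group_stats = {}
    for col in df.columns:
        if col == "animal_id" or not np.issubdtype(df[col].dtype, np.number):
            continue
        vals = df[col].dropna().to_numpy(float)
        if vals.size:
            group_stats[col] = {"n": int(vals.size),
                                "mean": float(vals.mean()),
                                "sd": float(vals.std(ddof=1))
                                if vals.size > 1 else float("nan")}

    tests = {}
    if run_tests:
        if {"heart_hz", "pyloric_hz"} <= set(df.columns):
            paired = df[["heart_hz", "pyloric_hz"]].dropna()
            if len(paired) >= 3:
                r, p = pearson(paired["heart_hz"], paired["pyloric_hz"])
                tests["freq_correlation"] = {"r": r, "p": p,
                                             "n": int(len(paired))}
        if {"t_crit_heart", "t_crit_pyloric"} <= set(df.columns):
            gh = df["t_crit_heart"].dropna().to_numpy(float)
            gp = df["t_crit_pyloric"].dropna().to_numpy(float)
            if gh.size >= 2 and gp.size >= 2:
                f, dof, p = one_way_anova(gh, gp)
                tests["t_crit_anova"] = {"F": f, "dof": dof, "p": p}
        if dip_column in df.columns:
            vals = df[dip_column].dropna().to_numpy(float)
            if vals.size >= 4 and np.ptp(vals) > 0:
                d, p = hartigan_dip(vals, n_boot=n_boot, seed=seed)
                tests["dip"] = {"dip": d, "p": p, "n": int(vals.size)}

    return PopulationSummary(
        table=df,
        bout_prevalence=_prevalence("has_bouts"),
        coherent_prevalence=_prevalence("is_coherent"),
        group_stats=group_stats,
        tests=tests)
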