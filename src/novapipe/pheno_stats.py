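"""Phenotype statistics: relative qPCR quantification (2^-ddCt), Kaplan-Meier
survival with the Mantel-Cox log-rank test and mean-lifespan change, and
heat-shock viability comparison.

Survival machinery is delegated to lifelines; this module adds the worm-assay
conventions: integer event days, censoring for rupture/bagging/walling, a
restricted-mean lifespan (truncated at the last observed event) as the
headline "mean lifespan", and percent change between groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import restricted_mean_survival_time
from scipy import stats


@dataclass(frozen=True)
class SurvivalRecord:
    """One animal's outcome: day of death or censoring (rupture, bagging or
    walling take an animal out of the risk set without counting as death)."""

    animal: str
    group: str
    day: int
    event: bool
    censor_reason: str = ""

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError("day must be >= 0")


def ddct(ct: pd.DataFrame, reference_group: str, housekeeping: str,
         target_col: str = "gene") -> pd.DataFrame:
    """Fold changes by the 2^-ddCt method.

    ``ct`` is tidy with columns sample, genotype, gene, ct. For every sample,
    dCt = Ct_target - Ct_housekeeping (same sample); ddCt subtracts the mean
    dCt of the reference group for that target; fold = 2^-ddCt. Any additive
    per-sample shift applied to target and housekeeping alike cancels.
    """
    required = {"sample", "genotype", target_col, "ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    hk = ct[ct[target_col] == housekeeping].set_index("sample")["ct"]
    targets = ct[ct[target_col] != housekeeping].copy()
    missing = sorted(set(targets["sample"]) - set(hk.index))
    if missing:
        raise ValueError(f"no housekeeping ({housekeeping!r}) Ct for sample(s): {missing}")
    targets["dct"] = targets["ct"].to_numpy() - hk.reindex(targets["sample"]).to_numpy()
    ref_mean = (targets[targets["genotype"] == reference_group]
                .groupby(target_col)["dct"].mean())
    if ref_mean.empty:
        raise ValueError(f"no samples in reference group {reference_group!r}")
    targets["ddct"] = targets["dct"] - ref_mean.reindex(targets[target_col]).to_numpy()
    targets["fold"] = 2.0 ** (-targets["ddct"])
    return targets[["sample", "genotype", target_col, "dct", "ddct", "fold"]]


@dataclass
class KmResult:
    chi2: float
    p: float
    mean_a: float              # KM-restricted mean lifespan, group a
    mean_b: float
    pct_change: float          # 100 * (mean_b - mean_a) / mean_a
    arithmetic_mean_a: float   # plain mean of uncensored death days
    arithmetic_mean_b: float
    curves: dict[str, pd.DataFrame] = field(default_factory=dict)


def km_logrank(records: pd.DataFrame, group_a: str, group_b: str) -> KmResult:
    """Kaplan-Meier curves, Mantel-Cox log-rank test and mean lifespans.

    The headline mean lifespan is the KM-restricted mean, truncated at the
    last observed event time across both groups; the arithmetic mean over
    uncensored deaths is reported alongside. Percent change is group_b
    relative to group_a.
    """
    sub = records[records["group"].isin([group_a, group_b])]
    parts = {}
    for g in (group_a, group_b):
        part = sub[sub["group"] == g]
        if part.empty or part["event"].sum() == 0:
            raise ValueError(f"group {g!r} has no deaths; log-rank is undefined")
        parts[g] = part

    res = logrank_test(parts[group_a]["day"], parts[group_b]["day"],
                       event_observed_A=parts[group_a]["event"],
                       event_observed_B=parts[group_b]["event"])

    horizon = float(sub.loc[sub["event"] == 1, "day"].max())
    means, arith, curves = {}, {}, {}
    for g, part in parts.items():
        kmf = KaplanMeierFitter()
        kmf.fit(part["day"], event_observed=part["event"], label=g)
        means[g] = float(restricted_mean_survival_time(kmf, t=horizon))
        deaths = part.loc[part["event"] == 1, "day"]
        arith[g] = float(deaths.mean())
        curves[g] = kmf.survival_function_

    mean_a, mean_b = means[group_a], means[group_b]
    return KmResult(chi2=float(res.test_statistic), p=float(res.p_value),
                    mean_a=mean_a, mean_b=mean_b,
                    pct_change=100.0 * (mean_b - mean_a) / mean_a,
                    arithmetic_mean_a=arith[group_a], arithmetic_mean_b=arith[group_b],
                    curves=curves)


@dataclass
class ViabilityResult:
    mean_pct: dict[str, float]
    t: float
    p: float
    df: float


def viability_test(table: pd.DataFrame, group_a: str | None = None,
                   group_b: str | None = None, welch: bool = False) -> ViabilityResult:
    """Replicate-level percent survival compared by an unpaired two-tailed
    t-test (equal-variance by default, Welch by flag).

    ``table`` has columns replicate, group, n_exposed, n_alive. The statistic
    is oriented group_a minus group_b.
    """
    required = {"replicate", "group", "n_exposed", "n_alive"}
    if not required <= set(table.columns):
        raise ValueError(f"viability table needs columns {sorted(required)}")
    if ((table["n_alive"] < 0) | (table["n_alive"] > table["n_exposed"])).any():
        raise ValueError("need 0 <= n_alive <= n_exposed")
    tab = table.copy()
    tab["pct"] = 100.0 * tab["n_alive"] / tab["n_exposed"]
    groups = [group_a, group_b] if group_a is not None else sorted(tab["group"].unique())[:2]
    vals = {}
    for g in groups:
        v = tab.loc[tab["group"] == g, "pct"].to_numpy()
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
        vals[g] = v
    a, b = vals[groups[0]], vals[groups[1]]
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = res.df if hasattr(res, "df") else len(a) + len(b) - 2
    return ViabilityResult(mean_pct={g: float(v.mean()) for g, v in vals.items()},
                           t=float(res.statistic), p=float(res.pvalue), df=float(df))


def fold_change_tests(folds: pd.DataFrame, group_a: str, group_b: str,
                      target_col: str = "gene", welch: bool = False) -> pd.DataFrame:
    """Per-target two-group t-tests on log2 fold changes from :func:`ddct`."""
    rows = []
    for gene, part in folds.groupby(target_col):
        a = np.log2(part.loc[part["genotype"] == group_a, "fold"])
        b = np.log2(part.loc[part["genotype"] == group_b, "fold"])
        res = stats.ttest_ind(a, b, equal_var=not welch)
        rows.append((gene, float(b.mean() - a.mean()), float(res.statistic), float(res.pvalue)))
    return pd.DataFrame(rows, columns=[target_col, "log2_fold_diff", "t", "P"])
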