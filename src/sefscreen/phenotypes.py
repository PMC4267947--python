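"""Growth and pump-rate phenotype models and their comparison statistics.

Growth rate is measured operationally as the inverse of the number of days a
small founding population needs to exhaust the food on a plate.  Because a
plate is exhausted after roughly a fixed number of worm-generations of
multiplication, the time to exhaustion scales like 1/ln(B) in the effective
brood size B, so growth rate is proportional to ln(B): a drop in effective
brood size from 300 to 7 predicts a ln(300)/ln(7) ~ 2.9-fold (i.e. roughly
threefold) drop in growth rate.

Pump-rate datasets are per-worm terminal-bulb pumps/min with genotype labels,
optionally factored as two binary mutations for a two-way factorial
(epistasis) analysis.  An "epistasis" (same-pathway) call requires both a
significant negative interaction and a double-mutant mean no higher than the
larger single-mutant mean -- the signature of two mutations whose joint
effect is no greater than either alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .mendel import GeneticsError

TWO_GROUP = "two_group"
ONE_WAY_VS_CONTROL = "one_way_vs_control"
TWO_WAY_FACTORIAL = "two_way_factorial"


@dataclass
class GrowthObservation:
    strain: str
    days_to_exhaustion: float

    def __post_init__(self) -> None:
        if self.days_to_exhaustion <= 0:
            raise GeneticsError("days_to_exhaustion must be positive")

    @property
    def growth_rate(self) -> float:
        return 1.0 / self.days_to_exhaustion


def growth_rate(days_to_exhaustion: float) -> float:
    """Growth rate as the inverse of the food-exhaustion time (per day)."""
    if days_to_exhaustion <= 0:
        raise GeneticsError("days_to_exhaustion must be positive")
    return 1.0 / days_to_exhaustion


def relative_growth_factor(brood_1: float, brood_2: float) -> float:
    """Predicted growth-rate fold change between effective brood sizes:
    ln(B1)/ln(B2).  E.g. 300 vs 7 -> ~2.9, 'a factor of three'."""
    if brood_1 <= 1 or brood_2 <= 1:
        raise GeneticsError("brood sizes must exceed 1")
    return math.log(brood_1) / math.log(brood_2)


def compare_groups(data: pd.DataFrame, design: str, value: str = "value",
                   group: str = "group", control: str | None = None,
                   factor_a: str = "factor_a", factor_b: str = "factor_b",
                   alpha: float = 0.05, adjust: str = "bonferroni") -> dict:
    """Genotype-comparison statistics for growth or pump-rate data.

    ``two_group``: Student two-sample t test between the two group labels.
    ``one_way_vs_control``: one-way ANOVA plus per-group t tests against the
    named control with familywise adjustment (``bonferroni`` or ``holm``; a
    portable stand-in for the usual Dunnett-style compare-vs-control tables).
    ``two_way_factorial``: two-way ANOVA with interaction over two binary
    factors; issues an epistasis call per the module docstring.
    """
    if design == TWO_GROUP:
        labels = list(pd.unique(data[group]))
        if len(labels) != 2:
            raise GeneticsError("two_group design needs exactly two groups")
        a = data.loc[data[group] == labels[0], value].to_numpy(float)
        b = data.loc[data[group] == labels[1], value].to_numpy(float)
        if min(len(a), len(b)) < 2:
            raise GeneticsError("need >= 2 observations per group")
        res = stats.ttest_ind(a, b)
        return {"design": design, "groups": labels, "t": float(res.statistic),
                "p": float(res.pvalue),
                "means": {labels[0]: float(a.mean()), labels[1]: float(b.mean())}}

    if design == ONE_WAY_VS_CONTROL:
        if control is None:
            raise GeneticsError("one_way_vs_control needs a control label")
        groups = {g: sub[value].to_numpy(float) for g, sub in data.groupby(group)}
        if control not in groups:
            raise GeneticsError(f"control group {control!r} absent")
        if any(len(v) < 2 for v in groups.values()):
            raise GeneticsError("need >= 2 observations per group")
        fstat, f_p = stats.f_oneway(*groups.values())
        others = [g for g in groups if g != control]
        raw = [float(stats.ttest_ind(groups[g], groups[control]).pvalue) for g in others]
        adj = multipletests(raw, alpha=alpha, method=adjust)[1] if others else []
        comparisons = {
            g: {"mean": float(groups[g].mean()), "p_raw": p, "p_adjusted": float(q),
                "significant": bool(q < alpha)}
            for g, p, q in zip(others, raw, adj)
        }
        return {"design": design, "control": control,
                "control_mean": float(groups[control].mean()),
                "anova_F": float(fstat), "anova_p": float(f_p),
                "comparisons": comparisons}

    if design == TWO_WAY_FACTORIAL:
        needed = {value, factor_a, factor_b}
        if not needed <= set(data.columns):
            raise GeneticsError(f"two_way_factorial needs columns {sorted(needed)}")
        cells = data.groupby([factor_a, factor_b])[value]
        if cells.ngroups != 4 or (cells.count() < 2).any():
            raise GeneticsError("factorial design must be fully crossed, >= 2 per cell")
        df = data.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
        model = ols("_y ~ C(_a) * C(_b)", data=df).fit()
        table = anova_lm(model, typ=2)
        inter_row = [i for i in table.index if ":" in i][0]
        inter_p = float(table.loc[inter_row, "PR(>F)"])
        y = df["_y"].to_numpy(float)
        scale = float(np.var(y)) * len(y)
        undefined = math.isnan(inter_p) or float(
            table.loc["Residual", "sum_sq"]) <= 1e-12 * max(1.0, scale)
        means = cells.mean()
        levels_a = sorted(data[factor_a].unique())
        levels_b = sorted(data[factor_b].unique())
        # convention: first level = wild type, second = mutant
        wt = float(means[(levels_a[0], levels_b[0])])
        a_only = float(means[(levels_a[1], levels_b[0])])
        b_only = float(means[(levels_a[0], levels_b[1])])
        double = float(means[(levels_a[1], levels_b[1])])
        additive = a_only + b_only - wt
        interaction_effect = double - additive
        # "no greater than either single mutant": the double mutant must not
        # *significantly* exceed the larger single-mutant group (one-sided t);
        # a strict sample-mean comparison would misfire under equal true means
        if a_only >= b_only:
            larger = data[(data[factor_a] == levels_a[1]) & (data[factor_b] == levels_b[0])][value]
        else:
            larger = data[(data[factor_a] == levels_a[0]) & (data[factor_b] == levels_b[1])][value]
        double_obs = data[(data[factor_a] == levels_a[1]) & (data[factor_b] == levels_b[1])][value]
        if undefined:
            exceeds = False
        else:
            res_gt = stats.ttest_ind(double_obs.to_numpy(float), larger.to_numpy(float),
                                     alternative="greater")
            exceeds = bool(res_gt.pvalue < alpha)
        epistasis = (
            not undefined
            and inter_p < alpha
            and interaction_effect < 0
            and not exceeds
        )
        return {"design": design, "interaction_p": inter_p,
                "interaction_undefined": undefined,
                "cell_means": {"wt": wt, "a": a_only, "b": b_only, "double": double},
                "additive_expectation": additive,
                "interaction_effect": interaction_effect,
                "epistasis_call": bool(epistasis),
                "anova": {str(i): {"F": float(table.loc[i, "F"]),
                                   "p": float(table.loc[i, "PR(>F)"])}
                          for i in table.index if i != "Residual"}}

    raise GeneticsError(f"unknown design {design!r}")
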