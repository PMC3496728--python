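"""Per-gene rhythmicity statistics and oscillation classification.

A gene is screened for daily rhythmicity with two complementary statistics:

* an additive two-way ANOVA (colony + timepoint) on the per-colony expression
  values, testing whether expression varies over the day at all, and
* the cosinor fit of the cross-colony mean profile, testing whether that
  variation follows a 24-h cosine.

A gene's oscillation is called significant under one of two rules:

``p_only``   ANOVA timepoint p <= 0.05 AND cosine p <= 0.05
``strict``   the same, plus adjusted R^2 >= 0.5 (the cosine must also explain
             most of the variance)

Genes whose per-colony fitted acrophases disagree by more than 6 h
(circularly) are flagged as inconsistent across colonies regardless of the
significance call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .cosinor import CosinorFit

__all__ = [
    "AnovaResult",
    "two_way_anova",
    "classify_oscillation",
    "summarize",
    "CLASSIFICATION_RULES",
    "PHASE_CONSISTENCY_THRESHOLD_H",
]

CLASSIFICATION_RULES = ("strict", "p_only")

#: Maximum circular disagreement (hours) between per-colony acrophases before
#: a gene is flagged as inconsistent across colonies.
PHASE_CONSISTENCY_THRESHOLD_H = 6.0


@dataclass(frozen=True)
class AnovaResult:
    f_timepoint: float
    p_timepoint: float
    f_colony: float
    p_colony: float
    df_timepoint: int
    df_colony: int
    df_resid: int


def two_way_anova(values: pd.DataFrame, value_col: str = "zscore") -> AnovaResult:
    """Additive two-way ANOVA of expression on colony and timepoint.

    ``values`` holds one row per (colony, zt) cell with columns ``colony``,
    ``zt`` and ``value_col``.  The design has no replication within cells, so
    only main effects are estimable: timepoint on (T-1) df, colony on (C-1)
    df, residual on (T-1)(C-1) df.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for col in ("colony", "zt", value_col):
        if col not in values.columns:
            raise ValueError(f"ANOVA input is missing column {col!r}")
    colonies = values["colony"].unique()
    zts = values["zt"].unique()
    if len(colonies) < 2 or len(zts) < 2:
        raise ValueError("two-way ANOVA needs >= 2 colonies and >= 2 timepoints")
    counts = values.groupby(["colony", "zt"]).size()
    if len(counts) != len(colonies) * len(zts) or (counts != 1).any():
        raise ValueError("two-way ANOVA needs exactly one value per (colony, zt) cell")

    df = values.rename(columns={value_col: "y"})[["colony", "zt", "y"]].copy()
    model = smf.ols("y ~ C(colony) + C(zt)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    ft = table.loc["C(zt)"]
    fc = table.loc["C(colony)"]
    total_ss = float(table["sum_sq"].sum())

    def _clean(row):
        # an effect with (numerically) zero sum of squares explains nothing:
        # F = 0, p = 1, even when the residual SS is also zero (0/0 in the
        # F ratio otherwise)
        if float(row["sum_sq"]) <= 1e-12 * max(total_ss, 1.0):
            return 0.0, 1.0
        f, p = float(row["F"]), float(row["PR(>F)"])
        if not np.isfinite(f):  # zero residual SS under a real effect
            return float("inf"), 0.0
        return f, p

    f_t, p_t = _clean(ft)
    f_c, p_c = _clean(fc)
    return AnovaResult(
        f_timepoint=f_t,
        p_timepoint=p_t,
        f_colony=f_c,
        p_colony=p_c,
        df_timepoint=int(ft["df"]),
        df_colony=int(fc["df"]),
        df_resid=int(table.loc["Residual", "df"]),
    )


def classify_oscillation(
    anova_p: float, cosine_p: float, r2_adj: float, rule: str = "p_only"
) -> bool:
    """Compound significance call for a daily oscillation.

    ``p_only`` requires both the ANOVA timepoint effect and the cosinor fit
    to be significant at 0.05; ``strict`` additionally requires the cosine
    model to explain most of the variance (adjusted R^2 >= 0.5).
    """
    if rule not in CLASSIFICATION_RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {CLASSIFICATION_RULES}")
    for name, v in (("anova_p", anova_p), ("cosine_p", cosine_p), ("r2_adj", r2_adj)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")
    sig = anova_p <= 0.05 and cosine_p <= 0.05
    if rule == "strict":
        sig = sig and r2_adj >= 0.5
    return bool(sig)


def _circular_spread_h(phases: list[float], period: float = 24.0) -> float:
    """Largest pairwise circular distance (hours) among acrophases."""
    finite = [p % period for p in phases if np.isfinite(p)]
    if len(finite) < 2:
        return 0.0
    d = 0.0
    for i in range(len(finite)):
        for j in range(i + 1, len(finite)):
            diff = abs(finite[i] - finite[j])
            d = max(d, min(diff, period - diff))
    return d


def summarize(
    fits: Mapping[str, CosinorFit],
    anovas: Mapping[str, AnovaResult],
    cosine_pvalues: Mapping[str, float],
    colony_fits: Mapping[str, Mapping[str, CosinorFit]] | None = None,
    rule: str = "p_only",
) -> pd.DataFrame:
    """Build the per-gene rhythm summary table.

    One row per gene with peak time, ANOVA F/p for the timepoint effect,
    peak-trough amplitude, R^2 / adjusted R^2, cosine p, the significance
    call under ``rule`` and a cross-colony phase-consistency flag (False when
    per-colony acrophases disagree by more than 6 h circularly).
    """
    genes = sorted(fits)
    if set(genes) != set(anovas) or set(genes) != set(cosine_pvalues):
        raise ValueError("fits, anovas and cosine_pvalues must cover the same genes")
    rows = []
    for gene in genes:
        fit = fits[gene]
        an = anovas[gene]
        p_cos = cosine_pvalues[gene]
        sig = classify_oscillation(an.p_timepoint, p_cos, fit.r2_adj, rule)
        consistent = True
        if colony_fits and gene in colony_fits:
            phases = [f.params.acrophase for f in colony_fits[gene].values() if f.params.amplitude > 0]
            consistent = _circular_spread_h(phases) <= PHASE_CONSISTENCY_THRESHOLD_H
        rows.append(
            {
                "gene": gene,
                "peak_zt": fit.peak_zt_grid,
                "anova_f": an.f_timepoint,
                "anova_p": an.p_timepoint,
                "amplitude_pt": fit.amplitude_pt,
                "r2": fit.r2,
                "r2_adj": fit.r2_adj,
                "cosine_p": p_cos,
                "significant": sig,
                "rule_used": rule,
                "consistent_across_colonies": consistent,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "peak_zt",
            "anova_f",
            "anova_p",
            "amplitude_pt",
            "r2",
            "r2_adj",
            "cosine_p",
            "significant",
            "rule_used",
            "consistent_across_colonies",
        ],
    )
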