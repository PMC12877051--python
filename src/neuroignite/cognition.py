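"""Cognition coupling: latency scores versus network-level ignition.

Three questions, in order: do groups differ in raw latency at all
(Kruskal-Wallis — the expected answer is no); does higher ignition predict
faster responses within each group (per-group Pearson correlation, with a
negative r expected in controls); and is the control-group slope lost in
patients (OLS with Group x Ignition interaction, treatment coding with
control as the reference level, evaluated by Type III ANOVA)?
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

COGNITION_NETWORKS = ("VIS", "DAN", "DMN")


def build_cognition_table(
    latency: dict,
    groups: dict,
    network_metrics: pd.DataFrame,
    complete: dict | None = None,
) -> pd.DataFrame:
    """Wide per-subject table joining latency, group and network ignition.

    Subjects flagged incomplete (``complete[sub] is False``) are excluded
    from every cognition analysis.
    """
    wide = network_metrics.pivot(index="subject", columns="network", values="ignition")
    rows = []
    for sub, lat in latency.items():
        if complete is not None and not complete.get(sub, True):
            continue
        row = {"subject": sub, "group": groups[sub], "rvp_mean_latency": float(lat)}
        for net in COGNITION_NETWORKS:
            row[f"ignition_{net}"] = (
                float(wide.loc[sub, net]) if sub in wide.index else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def kruskal_wallis(table: pd.DataFrame, value_col: str = "rvp_mean_latency") -> dict:
    """Rank-based H test of latency by group (tie-corrected, chi2 p)."""
    samples = [g[value_col].to_numpy(dtype=float) for _, g in table.groupby("group")]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 subjects each")
    df = len(samples) - 1
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:  # all observations equal: degenerate, H = 0
        return {"H": 0.0, "df": df, "p": 1.0}
    h, p = stats.kruskal(*samples)
    return {"H": float(h), "df": df, "p": float(p)}


def ignition_latency_correlation(
    table: pd.DataFrame, network: str, group: str
) -> tuple[float, float]:
    """Pearson (r, p) between a network's ignition and latency in a group."""
    if network not in COGNITION_NETWORKS:
        raise ValueError(f"network must be one of {COGNITION_NETWORKS}")
    sub = table[table["group"] == group].dropna(subset=[f"ignition_{network}"])
    if len(sub) < 3:
        raise ValueError(f"need >= 3 complete subjects in group {group!r}")
    x = sub[f"ignition_{network}"].to_numpy()
    y = sub["rvp_mean_latency"].to_numpy()
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in ignition or latency")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def interaction_model(
    table: pd.DataFrame, network: str, reference: str = "control"
) -> dict:
    """OLS latency ~ ignition * group, treatment-coded with control as
    baseline, plus a Type III ANOVA table (same coding).

    Interaction coefficients measure how each patient group's
    ignition-latency slope deviates from the control slope.
    """
    col = f"ignition_{network}"
    data = table.dropna(subset=[col]).rename(columns={col: "ignition"})
    counts = data.groupby("group").size()
    if reference not in counts.index:
        raise ValueError(f"reference group {reference!r} absent")
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise ValueError(f"need >= 3 subjects per group; too few in {small}")
    formula = (
        f"rvp_mean_latency ~ ignition * C(group, Treatment(reference={reference!r}))"
    )
    model = smf.ols(formula, data=data)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        # name the collinear columns via the smallest singular vectors
        _, s, vt = np.linalg.svd(model.exog)
        bad = np.abs(vt[-1]) > 1e-8
        names = [n for n, b in zip(model.exog_names, bad) if b]
        raise ValueError(f"rank-deficient design; collinear terms: {names}")
    fit = model.fit()
    anova = sm.stats.anova_lm(fit, typ=3)
    coef = pd.DataFrame(
        {"estimate": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues}
    )
    # readable term names: ignition:meningioma etc.
    rename = {}
    for name in coef.index:
        short = name
        if "C(group" in name:
            level = name.split("[T.")[-1].rstrip("]")
            short = f"ignition:{level}" if name.startswith("ignition:") else f"group:{level}"
        rename[name] = short
    coef = coef.rename(index=rename)
    return {"coefficients": coef, "anova_typ3": anova, "fit": fit, "n": len(data)}
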