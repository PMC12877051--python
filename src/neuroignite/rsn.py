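"""Resting-state-network level analysis: 7-node parcellation, Pearson
correlation structure across subjects, and thresholded correlation graphs.

Network signals are unweighted means of member-region signals per
timepoint; ignition metrics are then computed directly on the 7-node
matrix (an alternative aggregation — averaging region-level metrics by
network — is available behind a flag). Correlation graphs keep edges with
r >= 0.4 and never retain negative correlations; p-values on edges are
reported unadjusted.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import ParcellatedBold
from .ignition import IgnitionParams, compute_profile
from .preprocess import PreprocessParams, run_preprocess

logger = logging.getLogger(__name__)

NETWORK_NAMES = ("VIS", "SMN", "DAN", "VAN", "LIM", "FPN", "DMN")

R_THRESHOLD = 0.4


def parcellate_to_networks(
    bold: ParcellatedBold, assignment: np.ndarray, names: tuple = NETWORK_NAMES
) -> ParcellatedBold:
    """Collapse regions to networks by unweighted per-timepoint means."""
    assignment = np.asarray(assignment)
    if assignment.shape[0] != bold.n_regions:
        missing = bold.n_regions - assignment.shape[0]
        raise ValueError(
            f"assignment covers {assignment.shape[0]} of {bold.n_regions} "
            f"regions ({missing} uncovered)"
        )
    labels = np.unique(assignment)
    if labels.min() < 0 or labels.max() >= len(names):
        raise ValueError(
            f"assignment labels {sorted(set(assignment) - set(range(len(names))))} "
            "have no network name"
        )
    signal = np.stack([bold.signal[assignment == k].mean(axis=0) for k in labels])
    return ParcellatedBold(
        signal=signal,
        tr_ms=bold.tr_ms,
        region_ids=[names[k] for k in labels],
        subject_id=bold.subject_id,
    )


def network_metrics(
    cohort: dict,
    assignment: np.ndarray,
    preprocess_params: PreprocessParams | None = None,
    aggregate_regions: bool = False,
    region_profiles: dict | None = None,
) -> pd.DataFrame:
    """Per-subject, per-network ignition and metastability.

    Default route: run the full conditioning chain and ignition metrics on
    the 7-node parcellated series. With ``aggregate_regions`` the metrics
    are instead network means of precomputed region-level profiles
    (``region_profiles``).
    """
    rows = []
    if aggregate_regions:
        if region_profiles is None:
            raise ValueError("aggregate_regions requires region_profiles")
        for sub, prof in region_profiles.items():
            for k, name in enumerate(NETWORK_NAMES):
                members = np.flatnonzero(np.asarray(assignment) == k)
                rows.append(
                    {
                        "subject": sub,
                        "network": name,
                        "ignition": float(np.nanmean(prof.ignition[members])),
                        "metastability": float(
                            np.nanmean(prof.metastability[members])
                        ),
                    }
                )
        return pd.DataFrame(rows)
    for sub, bold in cohort.items():
        net_bold = parcellate_to_networks(bold, assignment)
        _, raster = run_preprocess(net_bold, preprocess_params)
        prof = compute_profile(raster, IgnitionParams.for_tr(bold.tr_ms))
        for k, name in enumerate(net_bold.region_ids):
            rows.append(
                {
                    "subject": sub,
                    "network": name,
                    "ignition": prof.ignition[k],
                    "metastability": prof.metastability[k],
                }
            )
    return pd.DataFrame(rows)


def _corr(a: np.ndarray, b: np.ndarray):
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def metric_correlation_graph(
    metrics: pd.DataFrame,
    mode: str,
    group_subjects: list | None = None,
    r_min: float = R_THRESHOLD,
) -> tuple[pd.DataFrame, nx.Graph]:
    """Across-subject Pearson correlation graph over network nodes.

    ``metrics`` is the long table from :func:`network_metrics`; ``mode`` is
    one of ``ign-ign``, ``meta-meta``, ``ign-meta``. In the cross-metric
    mode the undirected edge weight between distinct networks a and b is
    the mean of corr(ign_a, meta_b) and corr(ign_b, meta_a), and
    self-edges corr(ign_a, meta_a) are included ("intra-region"). Edges
    are retained iff r >= ``r_min``; negative correlations are never
    retained. Zero-variance vectors skip the pair with a warning.
    """
    if mode not in ("ign-ign", "meta-meta", "ign-meta"):
        raise ValueError(f"unknown mode {mode!r}")
    sub = metrics
    if group_subjects is not None:
        sub = metrics[metrics["subject"].isin(group_subjects)]
    wide_ign = sub.pivot(index="subject", columns="network", values="ignition")
    wide_meta = sub.pivot(index="subject", columns="network", values="metastability")
    if len(wide_ign) < 4:
        raise ValueError(f"need >= 4 subjects, got {len(wide_ign)}")
    nets = [n for n in NETWORK_NAMES if n in wide_ign.columns]
    a_tab = wide_ign if mode.startswith("ign") else wide_meta
    b_tab = wide_meta if mode.endswith("meta") else wide_ign

    def ok(v: np.ndarray, name: str) -> bool:
        if np.isnan(v).any() or v.std() == 0:
            logger.warning("skipping pair with undefined/zero-variance vector: %s", name)
            return False
        return True

    rows = []
    graph = nx.Graph()
    graph.add_nodes_from(nets)
    for i, na in enumerate(nets):
        start = i if mode == "ign-meta" else i + 1
        for nb in nets[start:]:
            va, vb = a_tab[na].to_numpy(), b_tab[nb].to_numpy()
            if not (ok(va, na) and ok(vb, nb)):
                continue
            r, p = _corr(va, vb)
            if mode == "ign-meta" and na != nb:
                r2, p2 = _corr(a_tab[nb].to_numpy(), b_tab[na].to_numpy())
                r, p = (r + r2) / 2, min(p, p2)
            retained = bool(r >= r_min)
            rows.append(
                {"node_a": na, "node_b": nb, "r": r, "p": p, "retained": retained}
            )
            if retained:
                graph.add_edge(na, nb, r=r, p=p)
    return pd.DataFrame(rows), graph


def subject_vs_region_correlation(
    metrics: pd.DataFrame, level: str = "subject", group_subjects: list | None = None
) -> tuple[float, float]:
    """Pearson r between ignition and metastability, two pooling levels.

    ``subject``: one pair per subject (means over networks);
    ``network-region``: pooled subject x network pairs.
    """
    sub = metrics
    if group_subjects is not None:
        sub = metrics[metrics["subject"].isin(group_subjects)]
    sub = sub.dropna(subset=["ignition", "metastability"])
    if level == "subject":
        per = sub.groupby("subject")[["ignition", "metastability"]].mean()
        a, b = per["ignition"].to_numpy(), per["metastability"].to_numpy()
    elif level == "network-region":
        a, b = sub["ignition"].to_numpy(), sub["metastability"].to_numpy()
    else:
        raise ValueError(f"unknown level {level!r}")
    if len(a) < 3:
        raise ValueError(f"need >= 3 paired values, got {len(a)}")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance metric vector")
    return _corr(a, b)


def affected_network_counts(overlaps: dict, assignment: np.ndarray) -> pd.DataFrame:
    """Tumor burden per network: a network is affected iff any member
    region has involvement fraction > 0. Returns one row per subject with
    per-network flags and the affected-network count."""
    assignment = np.asarray(assignment)
    rows = []
    for sub, overlap in overlaps.items():
        frac = np.asarray(overlap.fractions)
        row = {"subject": sub}
        count = 0
        for k, name in enumerate(NETWORK_NAMES):
            hit = bool((frac[assignment == k] > 0).any())
            row[name] = hit
            count += hit
        row["n_affected_networks"] = count
        rows.append(row)
    return pd.DataFrame(rows)
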