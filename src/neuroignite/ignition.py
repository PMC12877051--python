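"""Intrinsic ignition and metastability from an event raster.

For every driving event of node ``n`` at time ``t`` the instantaneous
co-activation graph ``A(tau)`` is formed at every step of the window
``t <= tau <= t + T_win`` (inclusive at both ends, ``T_win + 1`` steps):
nodes ``i`` and ``j`` are connected at ``tau`` iff both show events at
``tau``. Global integration ``Phi(tau)`` is the size of the largest
connected component (isolated nodes count as components of size 1, so an
empty graph scores 1: the igniting node itself participates). The event's
integration is the maximum ``Phi`` over the window; a node's intrinsic
ignition is the mean of those maxima over its driving events and its
metastability their sample standard deviation (divisor ``n - 1``).

Under the instantaneous co-event adjacency the largest component is a
clique of the active nodes, so ``Phi(tau) = max(1, #active nodes)``; both
the generic graph computation and this closed form are provided, and their
agreement is part of the test surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .containers import EventRaster

logger = logging.getLogger(__name__)

#: physical window duration preserved across repetition times (7 x 2400 ms
#: = 8 x 2100 ms = 16.8 s)
WINDOW_DURATION_MS = 16800.0


class ContractError(ValueError):
    """Raised when an operation is called outside its contract."""


def window_length(tr_ms: float) -> int:
    """Window length in TRs preserving a 16.8 s physical duration.

    2400 ms -> 7 TRs, 2100 ms -> 8 TRs; any other TR generalizes as
    ``round(16800 / tr_ms)`` (half-up), keeping the duration within TR/2.
    """
    if tr_ms <= 0:
        raise ContractError("tr_ms must be positive")
    return int(np.floor(WINDOW_DURATION_MS / tr_ms + 0.5))


@dataclass
class IgnitionParams:
    """Window length (TRs) and normalization choice for integration.

    ``integration_normalized`` divides component sizes by the number of
    nodes N, reporting integration as a fraction instead of a node count.
    ``truncate_overrunning`` keeps events whose window overruns the series
    end (evaluating the partial window) instead of discarding them.
    """

    window_tr: int = 7
    integration_normalized: bool = False
    truncate_overrunning: bool = False

    def __post_init__(self) -> None:
        if self.window_tr < 1:
            raise ContractError("window_tr must be >= 1")

    @classmethod
    def for_tr(cls, tr_ms: float, **kwargs) -> "IgnitionParams":
        return cls(window_tr=window_length(tr_ms), **kwargs)

    def window_duration_ms(self, tr_ms: float) -> float:
        return self.window_tr * tr_ms


@dataclass
class IgnitionProfile:
    """Per-region ignition/metastability plus subject-level summaries.

    ``ignition[i]`` is NaN for regions with zero retained events and
    ``metastability[i]`` is NaN for regions with fewer than two; both are
    excluded from the subject-level (unweighted) means.
    """

    region_ids: list
    ignition: np.ndarray
    metastability: np.ndarray
    n_events: np.ndarray
    subject_id: str = ""
    params: IgnitionParams = field(default_factory=IgnitionParams)

    @property
    def mean_ignition(self) -> float:
        vals = self.ignition[~np.isnan(self.ignition)]
        return float(vals.mean()) if vals.size else float("nan")

    @property
    def mean_metastability(self) -> float:
        vals = self.metastability[~np.isnan(self.metastability)]
        return float(vals.mean()) if vals.size else float("nan")


def coactivation_adjacency(raster: EventRaster, tau: int) -> np.ndarray:
    """Binary N x N co-event adjacency at time ``tau`` (zero diagonal)."""
    if not 0 <= tau < raster.n_timepoints:
        raise IndexError(f"tau={tau} outside [0, {raster.n_timepoints})")
    active = raster.events[:, tau].astype(bool)
    adj = np.outer(active, active).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return adj


def integration(adjacency: np.ndarray, normalized: bool = False) -> float:
    """Largest-connected-component size of a binary symmetric adjacency.

    Isolated nodes are components of size 1, so the minimum is 1.
    """
    adjacency = np.asarray(adjacency)
    n = adjacency.shape[0]
    graph = nx.from_numpy_array(adjacency)
    phi = max(len(c) for c in nx.connected_components(graph))
    return phi / n if normalized else float(phi)


def integration_closed_form(active_counts: np.ndarray, n_regions: int, normalized: bool = False) -> np.ndarray:
    """Phi per timepoint under co-event adjacency: max(1, #active nodes)."""
    phi = np.maximum(np.asarray(active_counts, dtype=float), 1.0)
    return phi / n_regions if normalized else phi


def _phi_trace(raster: EventRaster, params: IgnitionParams, method: str) -> np.ndarray:
    if method == "closed_form":
        counts = raster.events.sum(axis=0)
        return integration_closed_form(
            counts, raster.n_regions, params.integration_normalized
        )
    if method == "graph":
        return np.array(
            [
                integration(
                    coactivation_adjacency(raster, tau),
                    params.integration_normalized,
                )
                for tau in range(raster.n_timepoints)
            ]
        )
    raise ContractError(f"unknown integration method {method!r}")


def event_integration(
    raster: EventRaster,
    node: int,
    event_time: int,
    params: IgnitionParams,
    method: str = "closed_form",
) -> float:
    """Max of Phi(tau) over the event's window [t, t + T_win]."""
    if raster.events[node, event_time] != 1:
        raise ContractError(
            f"node {node} has no driving event at t={event_time}"
        )
    end = event_time + params.window_tr
    if end >= raster.n_timepoints and not params.truncate_overrunning:
        raise ContractError(
            f"window [{event_time}, {end}] overruns the series "
            f"(T={raster.n_timepoints}); event would be discarded"
        )
    phi = _phi_trace(raster, params, method)
    return float(phi[event_time : end + 1].max())


def compute_profile(
    raster: EventRaster,
    params: IgnitionParams | None = None,
    method: str = "closed_form",
) -> IgnitionProfile:
    """Per-node intrinsic ignition and metastability over retained events.

    Events whose window would overrun the series end are discarded by
    default so every retained event is scored over an identical duration
    (``params.truncate_overrunning`` evaluates the partial window instead).
    """
    if params is None:
        params = IgnitionParams.for_tr(raster.tr_ms)
    if raster.events.sum() == 0:
        logger.warning(
            "subject %s: empty raster, all metrics undefined", raster.subject_id
        )
    phi = _phi_trace(raster, params, method)
    T = raster.n_timepoints
    win = params.window_tr

    # max of phi over [t, t+win] for each complete-window start t
    if T > win:
        from numpy.lib.stride_tricks import sliding_window_view

        win_max = sliding_window_view(phi, win + 1).max(axis=1)
    else:
        win_max = np.empty(0)

    n = raster.n_regions
    ign = np.full(n, np.nan)
    meta = np.full(n, np.nan)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        times = np.flatnonzero(raster.events[i])
        complete = times[times + win < T]
        vals = win_max[complete] if complete.size else np.empty(0)
        if params.truncate_overrunning:
            partial = times[times + win >= T]
            vals = np.concatenate(
                [vals, [phi[t:].max() for t in partial]]
            ) if partial.size else vals
        counts[i] = vals.size
        if vals.size == 0:
            logger.warning(
                "subject %s: region %s has no retained events; ignition undefined",
                raster.subject_id,
                raster.region_ids[i],
            )
            continue
        ign[i] = vals.mean()
        meta[i] = vals.std(ddof=1) if vals.size >= 2 else np.nan
    return IgnitionProfile(
        region_ids=list(raster.region_ids),
        ignition=ign,
        metastability=meta,
        n_events=counts,
        subject_id=raster.subject_id,
        params=params,
    )
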