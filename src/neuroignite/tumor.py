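"""Tumor-mask overlap with the parcellation and delta-vs-control tables.

A probabilistic tumor mask is thresholded at 0.1 (inclusive) and, per atlas
region, the involvement fraction is the share of the region's voxels at or
above threshold. Fractions are binned exactly as [0.0], (0.0, 0.33),
[0.33, 0.66), [0.66, 1.0]. Region metrics are expressed relative to the
control group as delta = subject - control mean, so negative values mark a
reduction versus controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ignition import IgnitionProfile

logger = logging.getLogger(__name__)

BIN_LABELS = ("[0.0]", "(0.0,0.33)", "[0.33,0.66)", "[0.66,1.0]")

PROB_THRESHOLD = 0.1


class GridMismatchError(ValueError):
    pass


@dataclass
class TumorOverlap:
    """Per-region tumor involvement for one subject."""

    region_ids: list
    fractions: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if ((self.fractions < 0) | (self.fractions > 1)).any():
            raise ValueError("tumor fractions must lie in [0, 1]")

    @property
    def bins(self) -> list:
        return [bin_fraction(f) for f in self.fractions]

    @property
    def involved(self) -> np.ndarray:
        """Regions with at least one voxel at/above threshold (fraction > 0)."""
        return self.fractions > 0


def bin_fraction(f: float) -> str:
    """Bin label for a tumor-involvement fraction (boundaries as printed:
    0.33 falls in the third bin, 0.66 and 1.0 in the fourth)."""
    if not 0 <= f <= 1:
        raise ValueError(f"fraction {f} outside [0, 1]")
    if f == 0:
        return BIN_LABELS[0]
    if f < 0.33:
        return BIN_LABELS[1]
    if f < 0.66:
        return BIN_LABELS[2]
    return BIN_LABELS[3]


def mask_to_region_fraction(
    mask: np.ndarray,
    atlas: np.ndarray,
    prob_thresh: float = PROB_THRESHOLD,
    region_labels: list | None = None,
    subject_id: str = "",
) -> TumorOverlap:
    """Voxel-level involvement fraction per atlas region.

    ``mask`` holds tumor probabilities in [0, 1]; ``atlas`` integer region
    labels on the same grid (0 = background). The threshold comparison is
    inclusive (probability >= ``prob_thresh`` counts as tumor).
    """
    mask = np.asarray(mask, dtype=float)
    atlas = np.asarray(atlas)
    if mask.shape != atlas.shape:
        raise GridMismatchError(
            f"mask grid {mask.shape} does not match atlas grid {atlas.shape}"
        )
    if region_labels is None:
        region_labels = sorted(int(v) for v in np.unique(atlas) if v != 0)
    tumor = mask >= prob_thresh
    fractions = np.empty(len(region_labels))
    for k, label in enumerate(region_labels):
        voxels = atlas == label
        n_vox = int(voxels.sum())
        if n_vox == 0:
            raise ValueError(f"atlas region {label} has no voxels")
        fractions[k] = tumor[voxels].sum() / n_vox
    return TumorOverlap(
        region_ids=[str(lb) for lb in region_labels],
        fractions=fractions,
        subject_id=subject_id,
    )


def build_delta_table(
    profiles: dict,
    groups: dict,
    overlaps: dict,
    control_group: str = "control",
    include_controls: bool = False,
    flip_sign: bool = False,
) -> pd.DataFrame:
    """Long-format (subject, region) table of deltas versus the control mean.

    delta = subject metric - control-group regional mean, so negative values
    mark reductions versus controls (``flip_sign`` restores the opposite
    orientation). Regions with fewer than two controls holding a defined
    value are dropped with a warning. Control subjects are included (with
    tumor fraction 0) only when ``include_controls`` — they are diagnostics,
    not model input.

    Parameters
    ----------
    profiles:
        subject_id -> :class:`IgnitionProfile`.
    groups:
        subject_id -> group label.
    overlaps:
        subject_id -> :class:`TumorOverlap` (controls may be omitted).
    """
    control_ids = [s for s, g in groups.items() if g == control_group]
    if len(control_ids) < 2:
        raise ValueError("need at least 2 control subjects for regional means")
    ref = profiles[control_ids[0]]
    region_ids = list(ref.region_ids)

    ctl_ign = np.stack([profiles[s].ignition for s in control_ids])
    ctl_meta = np.stack([profiles[s].metastability for s in control_ids])
    n_def_ign = (~np.isnan(ctl_ign)).sum(axis=0)
    ok = n_def_ign >= 2
    if not ok.all():
        dropped = [region_ids[i] for i in np.flatnonzero(~ok)]
        logger.warning(
            "dropping %d region(s) with < 2 defined control values: %s",
            len(dropped),
            dropped[:10],
        )
    with np.errstate(invalid="ignore"):
        mean_ign = np.nanmean(ctl_ign, axis=0)
        mean_meta = np.nanmean(ctl_meta, axis=0)

    sign = -1.0 if flip_sign else 1.0
    rows = []
    for sub, prof in profiles.items():
        group = groups[sub]
        if group == control_group and not include_controls:
            continue
        if sub in overlaps:
            frac = np.asarray(overlaps[sub].fractions, dtype=float)
        else:
            frac = np.zeros(len(region_ids))
        d_ign = sign * (prof.ignition - mean_ign)
        d_meta = sign * (prof.metastability - mean_meta)
        for i in np.flatnonzero(ok):
            rows.append(
                {
                    "sub_id": sub,
                    "region_id": region_ids[i],
                    "group": group,
                    "delta_ignition": d_ign[i],
                    "delta_metastability": d_meta[i],
                    "tumor_fraction": frac[i],
                    "bin": bin_fraction(frac[i]),
                }
            )
    return pd.DataFrame(rows)


def bin_summary(delta_table: pd.DataFrame, group: str) -> pd.DataFrame:
    """Per-bin mean deltas, pooled region counts and group percentages."""
    sub = delta_table[delta_table["group"] == group]
    if sub.empty:
        raise ValueError(f"no rows for group {group!r}")
    total = len(sub)
    out = []
    for label in BIN_LABELS:
        rows = sub[sub["bin"] == label]
        out.append(
            {
                "bin": label,
                "n": len(rows),
                "pct": 100.0 * len(rows) / total,
                "mean_delta_ignition": rows["delta_ignition"].mean()
                if len(rows)
                else np.nan,
                "mean_delta_metastability": rows["delta_metastability"].mean()
                if len(rows)
                else np.nan,
            }
        )
    return pd.DataFrame(out)
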