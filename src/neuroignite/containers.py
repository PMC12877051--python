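"""Core in-memory containers shared across the pipeline.

A parcellated scan is a region x time real matrix plus its repetition time
(TR); an event raster is the binary region x time matrix of driving events
derived from it. Both keep region identifiers ordered so that downstream
joins (tumor overlap, network assignment) are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Raised when an input container or parameter block is malformed."""


@dataclass
class ParcellatedBold:
    """Region x time BOLD signal matrix for one subject.

    Parameters
    ----------
    signal:
        2-D array, shape ``(n_regions, n_timepoints)``.
    tr_ms:
        Repetition time in milliseconds (positive).
    region_ids:
        Ordered region labels matching the rows of ``signal``.
    subject_id:
        Free-form subject label.
    """

    signal: np.ndarray
    tr_ms: float
    region_ids: list = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValidationError("signal must be a 2-D region x time matrix")
        n_regions, n_timepoints = self.signal.shape
        if n_regions < 2:
            raise ValidationError("need at least 2 regions")
        if n_timepoints < 30:
            raise ValidationError("need at least 30 timepoints")
        if not np.isfinite(self.signal).all():
            raise ValidationError("signal contains missing or non-finite values")
        if self.tr_ms <= 0:
            raise ValidationError("tr_ms must be positive")
        if not self.region_ids:
            self.region_ids = [f"r{i:03d}" for i in range(n_regions)]
        if len(self.region_ids) != n_regions:
            raise ValidationError(
                f"region_ids has {len(self.region_ids)} entries for "
                f"{n_regions} signal rows"
            )

    @property
    def n_regions(self) -> int:
        return self.signal.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.signal.shape[1]

    def copy_with(self, signal: np.ndarray) -> "ParcellatedBold":
        return ParcellatedBold(
            signal=np.asarray(signal, dtype=float),
            tr_ms=self.tr_ms,
            region_ids=list(self.region_ids),
            subject_id=self.subject_id,
        )


@dataclass
class EventRaster:
    """Binary region x time matrix of driving events (threshold crossings)."""

    events: np.ndarray
    tr_ms: float
    region_ids: list = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events)
        if self.events.ndim != 2:
            raise ValidationError("events must be a 2-D region x time matrix")
        uniques = np.unique(self.events)
        if not np.isin(uniques, (0, 1)).all():
            raise ValidationError("event raster entries must be 0/1")
        self.events = self.events.astype(np.int8)
        if not self.region_ids:
            self.region_ids = [f"r{i:03d}" for i in range(self.events.shape[0])]
        if len(self.region_ids) != self.events.shape[0]:
            raise ValidationError("region_ids length mismatch with events")

    @property
    def n_regions(self) -> int:
        return self.events.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.events.shape[1]
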