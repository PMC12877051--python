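"""Plain-text and NIfTI input/output.

Signal tables are TSV with one row per timepoint and a header row of region
IDs (transposed to the internal region x time layout on read). Event
rasters are written the same way as 0/1 columns. NIfTI support accepts a
4-D BOLD image plus an integer-labelled atlas and extracts the mean signal
over each atlas label (standard masker semantics); probabilistic tumor
masks are float images in [0, 1].
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import EventRaster, ParcellatedBold


def write_signals_tsv(bold: ParcellatedBold, path) -> None:
    frame = pd.DataFrame(bold.signal.T, columns=bold.region_ids)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_signals_tsv(path, tr_ms: float, subject_id: str = "") -> ParcellatedBold:
    frame = pd.read_csv(path, sep="\t")
    return ParcellatedBold(
        signal=frame.to_numpy(dtype=float).T,
        tr_ms=tr_ms,
        region_ids=[str(c) for c in frame.columns],
        subject_id=subject_id or Path(path).stem,
    )


def write_raster_tsv(raster: EventRaster, path) -> None:
    frame = pd.DataFrame(raster.events.T, columns=raster.region_ids)
    frame.to_csv(path, sep="\t", index=False)


def write_phenotype_tsv(groups: dict, tr_ms: dict, latency: dict, path) -> None:
    rows = [
        {
            "subject_id": sub,
            "group": grp,
            "tr_ms": tr_ms[sub],
            "rvp_mean_latency": latency.get(sub, np.nan) if latency else np.nan,
        }
        for sub, grp in groups.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_phenotype_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- NIfTI ------------------------------------------------------------------


def save_nifti(volume: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def extract_parcel_signals(
    bold_path, atlas_path, tr_ms: float, subject_id: str = ""
) -> ParcellatedBold:
    """Mean signal over each atlas label of a 4-D image (label order
    ascending, background 0 excluded)."""
    img = np.asarray(nib.load(str(bold_path)).get_fdata())
    atlas = np.asarray(nib.load(str(atlas_path)).get_fdata()).round().astype(int)
    if img.ndim != 4:
        raise ValueError(f"expected a 4-D BOLD image, got shape {img.shape}")
    if img.shape[:3] != atlas.shape:
        raise ValueError(
            f"BOLD grid {img.shape[:3]} does not match atlas grid {atlas.shape}"
        )
    labels = sorted(v for v in np.unique(atlas) if v != 0)
    signal = np.stack([img[atlas == lb].mean(axis=0) for lb in labels])
    return ParcellatedBold(
        signal=signal,
        tr_ms=tr_ms,
        region_ids=[str(lb) for lb in labels],
        subject_id=subject_id,
    )
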