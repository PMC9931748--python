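"""ROI extraction from volumetric images and time-series conditioning.

Structural gray-matter segment images are reduced to one value per ROI per
subject (mean density, integrated volume, or mean modulated mass); 4D
resting-state images are reduced to one time series per ROI.  Time series
are then conditioned: initial volumes discarded (field saturation),
quadratic detrend, zero-phase band-pass, and z-standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import signal

from .atlas import RoiAtlas

MEASURES = ("GMM", "GMV", "GMD")


@dataclass
class StructuralMatrix:
    """Subjects x ROIs matrix of one gray-matter measure.

    ``values`` is a DataFrame indexed by subject id with ROI-name columns.
    The measure tag (GMM / GMV / GMD) is metadata: downstream estimation is
    identical for the three measures.
    """

    values: pd.DataFrame
    measure: str
    standardized: bool = False
    deconfounded: bool = False

    @property
    def subjects(self) -> list[str]:
        return list(self.values.index)


@dataclass
class TimeSeriesSet:
    """Per-subject ROI time series (each ``timepoints x n_rois``)."""

    series: dict[str, np.ndarray]
    roi_names: list[str]
    tr: float
    n_discarded: int = 0
    band: tuple[float, float] | None = None

    @property
    def subjects(self) -> list[str]:
        return sorted(self.series)

    def n_timepoints(self) -> int:
        lengths = {s.shape[0] for s in self.series.values()}
        if len(lengths) != 1:
            raise ValueError(f"subjects have unequal timepoint counts: {lengths}")
        return lengths.pop()


def _as_image(vol) -> nib.spatialimages.SpatialImage:
    if isinstance(vol, nib.spatialimages.SpatialImage):
        return vol
    return nib.load(str(vol))


def _check_grid(img, atlas: RoiAtlas, ndim: int) -> np.ndarray:
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != ndim:
        raise ValueError(f"expected a {ndim}D image, got {data.ndim}D")
    if data.shape[:3] != atlas.labels.shape:
        raise ValueError(
            f"image grid {data.shape[:3]} does not match atlas {atlas.labels.shape}"
        )
    if not np.allclose(img.affine, atlas.affine, atol=1e-6):
        raise ValueError("image affine does not match atlas affine")
    return data


def extract_structural(
    volumes: Mapping[str, str | Path | nib.Nifti1Image],
    atlas: RoiAtlas,
    measure: str,
) -> StructuralMatrix:
    """Average a gray-matter segment image over each ROI, per subject.

    measure semantics (the input image is assumed appropriate for it):

    - ``GMD``: mean voxel value (unmodulated probability segment)
    - ``GMM``: mean voxel value (modulated segment)
    - ``GMV``: sum of voxel values times voxel volume in mm^3 (modulated
      segment), i.e. the ROI's integrated gray-matter volume

    Subjects are processed in lexicographic id order.
    """
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}, got {measure!r}")
    masks = [atlas.mask(r) for r in atlas.roi_names]
    rows = {}
    for subject in sorted(volumes):
        data = _check_grid(_as_image(volumes[subject]), atlas, ndim=3)
        row = np.empty(atlas.n_rois)
        for k, mask in enumerate(masks):
            vox = data[mask]
            if np.isnan(vox).any():
                raise ValueError(
                    f"NaN voxels inside ROI {atlas.roi_names[k]!r} for {subject!r}"
                )
            if measure == "GMV":
                row[k] = vox.sum() * atlas.voxel_volume
            else:
                row[k] = vox.mean()
        rows[subject] = row
    values = pd.DataFrame.from_dict(rows, orient="index", columns=atlas.roi_names)
    return StructuralMatrix(values=values, measure=measure)


def extract_timeseries(
    series4d: str | Path | nib.Nifti1Image, atlas: RoiAtlas
) -> np.ndarray:
    """ROI-mean time series from one 4D image -> ``timepoints x n_rois``."""
    data = _check_grid(_as_image(series4d), atlas, ndim=4)
    n_t = data.shape[3]
    out = np.empty((n_t, atlas.n_rois))
    for k, roi in enumerate(atlas.roi_names):
        vox = data[atlas.mask(roi), :]  # voxels x time
        if np.isnan(vox).any():
            raise ValueError(f"NaN voxels inside ROI {roi!r}")
        out[:, k] = vox.mean(axis=0)
    return out


def extract_timeseries_set(
    volumes: Mapping[str, str | Path | nib.Nifti1Image],
    atlas: RoiAtlas,
    tr: float,
) -> TimeSeriesSet:
    """Extract ROI time series for every subject (lexicographic order)."""
    series = {s: extract_timeseries(volumes[s], atlas) for s in sorted(volumes)}
    return TimeSeriesSet(series=series, roi_names=list(atlas.roi_names), tr=tr)


def bandpass(x: np.ndarray, tr: float, band: tuple[float, float]) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along axis 0."""
    sos = signal.butter(4, band, btype="bandpass", fs=1.0 / tr, output="sos")
    return signal.sosfiltfilt(sos, x, axis=0)


def quadratic_detrend(x: np.ndarray) -> np.ndarray:
    """Remove the least-squares quadratic polynomial trend per column."""
    n_t = x.shape[0]
    t = np.arange(n_t, dtype=np.float64)
    design = np.column_stack([np.ones(n_t), t, t * t])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


def _condition_one(
    x: np.ndarray, tr: float, n_discard: int, band: tuple[float, float]
) -> np.ndarray:
    x = quadratic_detrend(x[n_discard:].astype(np.float64))
    x = bandpass(x, tr, band)
    # z-standardize over time
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=0)) / sd


def condition_timeseries(
    ts: TimeSeriesSet,
    n_discard: int = 4,
    band: tuple[float, float] = (0.01, 0.08),
) -> TimeSeriesSet:
    """Discard initial volumes, detrend, band-pass and standardize.

    Per subject and ROI column: the first ``n_discard`` timepoints are
    dropped, a quadratic polynomial trend is removed, a 4th-order
    Butterworth band-pass is applied forward-backward (zero phase), and the
    series is z-scored over time.
    """
    nyquist = 0.5 / ts.tr
    lo, hi = band
    if not (0.0 < lo < hi < nyquist):
        raise ValueError(
            f"band {band} must lie strictly inside (0, Nyquist={nyquist:.4g}) Hz"
        )
    n_min = min(s.shape[0] for s in ts.series.values())
    if n_min <= n_discard + 10:
        raise ValueError(
            f"need > n_discard + 10 = {n_discard + 10} timepoints, got {n_min}"
        )
    out = {
        subj: _condition_one(x, ts.tr, n_discard, band)
        for subj, x in ts.series.items()
    }
    return replace(ts, series=out, n_discarded=ts.n_discarded + n_discard, band=band)


def pool_timeseries(ts: TimeSeriesSet, subjects: list[str] | None = None) -> np.ndarray:
    """Concatenate subject series along time for group-level estimation."""
    subjects = sorted(ts.series) if subjects is None else subjects
    return np.concatenate([ts.series[s] for s in subjects], axis=0)
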