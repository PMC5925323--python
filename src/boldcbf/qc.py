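"""Quality-control and amplitude metrics: RSFA, DVARS, motion-RMS exclusion."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DEFAULT_BAND
from .separation import bandpass

__all__ = ["rsfa", "dvars", "motion_exclusion", "QCReport", "MaskError"]

MOTION_RMS_THRESHOLD = 1.5  # mm
ROTATION_RADIUS_MM = 50.0


class MaskError(ValueError):
    """Empty or invalid spatial mask."""


def rsfa(
    series: np.ndarray,
    dt: float,
    band: tuple[float, float] = DEFAULT_BAND,
    exclude_edges: int = 1,
) -> np.ndarray:
    """Resting-state fluctuation amplitude: per-voxel temporal SD of the
    band-passed (default 0.01-0.071 Hz) series.

    Unnormalized -- the value carries the input's signal units.  The first
    and last ``exclude_edges`` frames are excluded from the SD window
    (filter edges).
    """
    x = np.asarray(series, dtype=float)
    if x.shape[-1] < 8:
        raise ValueError("series must have at least 8 frames")
    filtered = bandpass(x, dt, band)
    sl = slice(exclude_edges, x.shape[-1] - exclude_edges) if exclude_edges else slice(None)
    return filtered[..., sl].std(axis=-1)


def dvars(series: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, float]:
    """RMS of the differentiated timeseries over a spatial mask.

    For each consecutive frame pair, the root mean square over mask voxels
    of the frame difference; returns the per-pair values and the run
    average.
    """
    x = np.asarray(series, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if x.shape[-1] < 2:
        raise ValueError("need at least 2 frames")
    if mask.shape != x.shape[:-1]:
        raise MaskError("mask shape must match the spatial grid")
    if not mask.any():
        raise MaskError("mask is empty")
    diffs = np.diff(x[mask], axis=-1)  # (n_mask_voxels, n_frames - 1)
    values = np.sqrt(np.mean(diffs**2, axis=0))
    return values, float(values.mean())


def motion_exclusion(
    realignment_params: np.ndarray,
    threshold: float = MOTION_RMS_THRESHOLD,
    rotation_radius: float = ROTATION_RADIUS_MM,
) -> tuple[float, bool]:
    """Pooled motion RMS and the exclusion decision.

    ``realignment_params`` is (n_frames, 6): three translations in mm and
    three rotations in radians.  Rotations are converted to mm of arc
    displacement on a ``rotation_radius`` (default 50 mm) sphere, then the
    RMS is taken over all six columns and all frames.  A subject is
    excluded iff the RMS strictly exceeds ``threshold`` (default 1.5 mm).
    """
    p = np.asarray(realignment_params, dtype=float)
    if p.ndim != 2 or p.shape[1] != 6:
        raise ValueError(f"expected (n_frames, 6) realignment parameters, got {p.shape}")
    scaled = p.copy()
    scaled[:, 3:] *= rotation_radius
    rms = float(np.sqrt(np.mean(scaled**2)))
    return rms, rms > threshold


@dataclass
class QCReport:
    """Per-subject quality control summary."""

    rsfa_bold: np.ndarray | None = None
    rsfa_cbf: np.ndarray | None = None
    dvars_series: np.ndarray | None = None
    dvars_mean: float | None = None
    motion_rms: float | None = None
    excluded: bool = False

    def summary(self) -> dict:
        return {
            "dvars_mean": self.dvars_mean,
            "motion_rms": self.motion_rms,
            "excluded": bool(self.excluded),
            "rsfa_bold_mean": None
            if self.rsfa_bold is None
            else float(np.mean(self.rsfa_bold)),
            "rsfa_cbf_mean": None
            if self.rsfa_cbf is None
            else float(np.mean(self.rsfa_cbf)),
        }
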