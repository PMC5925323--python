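"""Separation of BOLD and CBF fluctuation timeseries from dual-echo pCASL.

The interleaved control/label series can be viewed as the sum of a slowly
varying BOLD-weighted component and a component modulated at the
control/label alternation frequency (the Nyquist rate of the volume
sampling).  With TR = 3.5 s the two are split at 1/(4*TR) = 0.071 Hz:

* CBF series (short echo): high-pass > 1/(4*TR), demodulate by
  cos[pi*(n-1)] (n = 1-based frame number), then sum non-overlapping
  pairs of frames.  With a control-first interleave the result
  approximates control - label, i.e. it is positive for positive
  perfusion.
* BOLD series (long echo): low-pass < 1/(4*TR), then average
  non-overlapping pairs of frames.

Both outputs have half the input frame count at sampling interval 2*TR.
Filters are realized as zero-phase frequency-domain masks.  The
high/low-pass split at 1/(4*TR) uses an ideal (brick-wall) edge so the
two channels partition the spectrum exactly and in-band BOLD cannot leak
into the demodulated perfusion channel; the output band-pass uses a
one-bin raised-cosine transition.  The first and last output frames
carry filter edge effects and are flagged as non-interior rather than
dropped.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import (
    DEFAULT_BAND,
    DualEchoPCASLRun,
    InvalidBandError,
    SeparatedTimeseries,
)

__all__ = [
    "fft_filter",
    "bandpass",
    "separate_cbf",
    "separate_bold",
    "separate_run",
    "split_and_rebuild",
    "spatial_smooth",
    "nuisance_regress",
    "retroicor_regress",
    "physio_phases",
    "PhysioCoverageError",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class PhysioCoverageError(ValueError):
    """Physiological trace does not cover the acquisition."""


# ---------------------------------------------------------------------------
# temporal filtering


def _edge_weight(freqs: np.ndarray, fc: float, df: float, rising: bool) -> np.ndarray:
    """Step from 0 to 1 (rising) at fc: raised cosine across [fc - df, fc + df]
    when df > 0, else an ideal edge (weight 1/2 at a bin exactly on fc)."""
    if df > 0:
        w = 0.5 * (1.0 - np.cos(np.pi * (freqs - (fc - df)) / (2.0 * df)))
        w = np.clip(w, 0.0, 1.0)
        w[freqs <= fc - df] = 0.0
        w[freqs >= fc + df] = 1.0
    else:
        w = (freqs > fc).astype(float)
        w[np.isclose(freqs, fc, rtol=1e-9, atol=0.0)] = 0.5
    return w if rising else 1.0 - w


def fft_filter(
    series: np.ndarray,
    dt: float,
    f_lo: float | None = None,
    f_hi: float | None = None,
    axis: int = -1,
    transition_bins: float = 1.0,
) -> np.ndarray:
    """Zero-phase frequency-domain filter.

    ``f_lo`` is the high-pass cutoff, ``f_hi`` the low-pass cutoff; either
    may be None.  The edge is a raised cosine ``transition_bins`` frequency
    bins wide; ``transition_bins = 0`` gives an ideal brick-wall mask (a
    bin exactly on the cutoff gets weight 1/2, so complementary high/low
    passes at one cutoff partition the spectrum exactly).  A pure low-pass
    preserves the mean; any filter with ``f_lo`` set removes it (the DC
    bin is zeroed).
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[axis]
    nyq = 0.5 / dt
    if f_hi is not None and f_hi > nyq * (1 + 1e-9):
        raise InvalidBandError(f"upper edge {f_hi} Hz above Nyquist {nyq} Hz")
    if f_lo is not None and f_hi is not None and f_lo >= f_hi:
        raise InvalidBandError("band lower edge must be below upper edge")
    if (f_lo is not None and f_lo <= 0) or (f_hi is not None and f_hi <= 0):
        raise InvalidBandError("band edges must be positive")
    freqs = np.fft.rfftfreq(n, dt)
    df = transition_bins / (n * dt)
    weight = np.ones_like(freqs)
    if f_lo is not None:
        weight *= _edge_weight(freqs, f_lo, df, rising=True)
        weight[0] = 0.0
    if f_hi is not None:
        weight *= _edge_weight(freqs, f_hi, df, rising=False)
    spec = np.fft.rfft(x, axis=axis)
    shape = [1] * x.ndim
    shape[axis] = freqs.size
    return np.fft.irfft(spec * weight.reshape(shape), n=n, axis=axis)


def bandpass(
    series: np.ndarray,
    dt: float,
    band: tuple[float, float] = DEFAULT_BAND,
    axis: int = -1,
) -> np.ndarray:
    """Zero-mean band-pass (default 0.01-0.071 Hz) of a timeseries array."""
    return fft_filter(series, dt, f_lo=band[0], f_hi=band[1], axis=axis)


# ---------------------------------------------------------------------------
# control/label bookkeeping


def split_and_rebuild(run: DualEchoPCASLRun) -> tuple[np.ndarray, np.ndarray]:
    """Return the two echoes as interleaved series in acquisition order.

    The run container already validates strict control/label alternation;
    this is the (trivially invertible) rebuild step after any per-class
    preprocessing, kept as the pipeline seam where label and control
    subseries are re-interleaved without resampling.
    """
    return run.echo1, run.echo2


def _pairsum(x: np.ndarray) -> np.ndarray:
    if x.shape[-1] % 2:
        raise ValueError("series length must be even")
    return x[..., 0::2] + x[..., 1::2]


def separate_cbf(
    interleaved: np.ndarray,
    tr: float,
    control_first: bool = True,
) -> np.ndarray:
    """Perfusion (CBF) fluctuation series from an interleaved pCASL series.

    High-pass above 1/(4*TR), demodulate frame n by cos[pi*(n-1)]
    (1-based n), sum non-overlapping pairs.  Output approximates
    control - label at sampling interval 2*TR; for a label-first
    interleave the carrier sign is flipped so the output keeps the
    control - label sign convention.
    """
    x = np.asarray(interleaved, dtype=float)
    if x.shape[-1] % 2:
        raise ValueError("interleaved series length must be even")
    cutoff = 1.0 / (4.0 * tr)
    hp = fft_filter(x, tr, f_lo=cutoff, transition_bins=0)
    n = np.arange(x.shape[-1])
    carrier = np.cos(np.pi * n)  # +1, -1, +1, ... for 1-based cos[pi(n-1)]
    if not control_first:
        carrier = -carrier
    return _pairsum(hp * carrier)


def separate_bold(interleaved: np.ndarray, tr: float) -> np.ndarray:
    """BOLD fluctuation series: low-pass below 1/(4*TR), then pair mean.

    The pair mean (sum of every two frames divided by two) keeps BOLD in
    signal units and preserves the DC level.
    """
    x = np.asarray(interleaved, dtype=float)
    if x.shape[-1] % 2:
        raise ValueError("interleaved series length must be even")
    cutoff = 1.0 / (4.0 * tr)
    lp = fft_filter(x, tr, f_hi=cutoff, transition_bins=0)
    return 0.5 * _pairsum(lp)


def separate_run(
    run: DualEchoPCASLRun,
    band: tuple[float, float] = DEFAULT_BAND,
    fwhm: float = 0.0,
    apply_bandpass: bool = True,
) -> SeparatedTimeseries:
    """Full separation of a run: CBF from the short echo, BOLD from the
    long echo, optional spatial smoothing, then band-pass filtering of
    both series at the separated sampling interval 2*TR."""
    te1, te2 = split_and_rebuild(run)
    cbf = separate_cbf(te1, run.acq.tr, control_first=run.control_first)
    bold = separate_bold(te2, run.acq.tr)
    if fwhm > 0:
        cbf = spatial_smooth(cbf, fwhm, run.acq.voxel_size)
        bold = spatial_smooth(bold, fwhm, run.acq.voxel_size)
    dt = run.acq.pair_dt
    if apply_bandpass:
        cbf = bandpass(cbf, dt, band)
        bold = bandpass(bold, dt, band)
    return SeparatedTimeseries(bold=bold, cbf=cbf, dt=dt, band=tuple(band))


# ---------------------------------------------------------------------------
# spatial smoothing and nuisance regression


def spatial_smooth(
    series: np.ndarray,
    fwhm: float,
    voxel_size: tuple[float, float, float],
) -> np.ndarray:
    """Per-volume 3D Gaussian smoothing.

    sigma = fwhm / (2*sqrt(2*ln 2)) per axis, in voxel units; the nearest
    boundary mode preserves spatially constant volumes.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm == 0:
        return np.asarray(series, dtype=float)
    x = np.asarray(series, dtype=float)
    sigma_vox = [fwhm * FWHM_TO_SIGMA / v for v in voxel_size]
    if x.ndim == 4:
        sigma = sigma_vox + [0.0]
    elif x.ndim == 3:
        sigma = sigma_vox
    else:
        raise ValueError("expected a 3D volume or 4D series")
    return ndimage.gaussian_filter(x, sigma=sigma, mode="nearest")


def nuisance_regress(series: np.ndarray, regressors: np.ndarray | None) -> np.ndarray:
    """Least-squares removal of confound timecourses, mean preserved.

    ``regressors`` is (n_frames, n_regressors); columns are demeaned so
    the voxel mean passes through unchanged.  Rank-deficient designs are
    handled by the pseudo-inverse (the removed component is the projection
    onto the regressor column space).
    """
    x = np.asarray(series, dtype=float)
    if regressors is None or np.size(regressors) == 0:
        return x.copy()
    r = np.atleast_2d(np.asarray(regressors, dtype=float))
    if r.shape[0] != x.shape[-1]:
        if r.shape[1] == x.shape[-1]:
            r = r.T
        else:
            raise ValueError("regressor length must match the series length")
    rc = r - r.mean(axis=0)
    flat = x.reshape(-1, x.shape[-1])
    beta = np.linalg.pinv(rc) @ flat.T  # (n_reg, n_voxels)
    return (flat - (rc @ beta).T).reshape(x.shape)


# ---------------------------------------------------------------------------
# RETROICOR-style physiological noise regression


def _peak_phase(wave: np.ndarray, fs: float, times: np.ndarray) -> np.ndarray:
    """Phase in [0, 2*pi) at ``times``, linear between successive peaks.

    Peak-based phase assignment: each detected waveform peak marks phase
    2*pi*k; phase is interpolated linearly in time between peaks and
    extrapolated with the neighbouring interval's rate outside them.
    """
    from scipy.signal import find_peaks

    wave = np.asarray(wave, dtype=float)
    peaks, _ = find_peaks(wave)
    if peaks.size < 2:
        raise ValueError("could not detect at least two peaks in the trace")
    peak_t = peaks / fs
    peak_phase = 2.0 * np.pi * np.arange(peaks.size)
    phase = np.interp(times, peak_t, peak_phase)
    # linear extrapolation beyond the first/last peak
    lo = times < peak_t[0]
    hi = times > peak_t[-1]
    rate0 = 2.0 * np.pi / (peak_t[1] - peak_t[0])
    rate1 = 2.0 * np.pi / (peak_t[-1] - peak_t[-2])
    phase[lo] = peak_phase[0] + (times[lo] - peak_t[0]) * rate0
    phase[hi] = peak_phase[-1] + (times[hi] - peak_t[-1]) * rate1
    return phase


def physio_phases(physio, volume_times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cardiac and respiratory phase at each volume's acquisition time."""
    t = np.asarray(volume_times, dtype=float)
    if t.max() > physio.duration + 1e-9:
        raise PhysioCoverageError(
            f"physio trace ({physio.duration:.1f} s) shorter than run ({t.max():.1f} s)"
        )
    fs = physio.sampling_rate
    return _peak_phase(physio.cardiac, fs, t), _peak_phase(physio.respiratory, fs, t)


def retroicor_regressors(
    physio, volume_times: np.ndarray, order: int = 2
) -> np.ndarray:
    """Low-order Fourier expansion of cardiac and respiratory phase."""
    if order < 0:
        raise ValueError("order must be >= 0")
    if order == 0:
        return np.empty((len(volume_times), 0))
    phi_c, phi_r = physio_phases(physio, volume_times)
    cols = []
    for m in range(1, order + 1):
        for phi in (phi_c, phi_r):
            cols.append(np.sin(m * phi))
            cols.append(np.cos(m * phi))
    return np.column_stack(cols)


def retroicor_regress(
    series: np.ndarray,
    physio,
    volume_times: np.ndarray,
    order: int = 2,
) -> np.ndarray:
    """Remove cardiac/respiratory Fourier terms from a voxel timeseries.

    Phases are computed per volume from the raw traces (peak-based);
    order counts harmonics per physiological process (default 2).  The
    voxel mean is preserved; order 0 is the identity.  Apply separately
    to label and control subseries of an interleaved run.
    """
    reg = retroicor_regressors(physio, volume_times, order)
    return nuisance_regress(series, reg)
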