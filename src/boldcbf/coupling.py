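"""Voxelwise BOLD-CBF coupling: zero-lag and lag-optimized correlation,
Fisher-z transforms, group statistics with BH-FDR, and ROI summaries.

The lagged scan follows the standard recipe: both separated series are
sinc-upsampled to 100 ms, the Pearson correlation is evaluated for lags
tau in +-7 s (350 ms steps) over the truncated overlap of the two
series (no wrap-around), and the maximum r_max with its optimizing lag
tau* is retained.  tau* < 0 means the BOLD series is delayed with
respect to the CBF series.  Ties in the argmax are resolved toward the
smallest |tau| (then the negative one), the most conservative shift
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft, signal, stats
from statsmodels.stats.multitest import multipletests

from .core import LagGrid, SeparatedTimeseries

__all__ = [
    "pearson_r",
    "pearson_r0",
    "upsample_sinc",
    "lagged_rmax",
    "compute_coupling",
    "fisher_z",
    "CouplingMap",
    "GroupStatMap",
    "one_sample_t",
    "two_sample_t",
    "fdr_bh",
    "roi_extract",
    "rmax_minus_r0_contrast",
    "cohens_d",
    "EmptyROIError",
    "InsufficientOverlapError",
]

MIN_OVERLAP = 10


class EmptyROIError(ValueError):
    """ROI/gray-matter intersection contains no voxels."""


class InsufficientOverlapError(ValueError):
    """Too few overlapping samples at an extreme lag."""


# ---------------------------------------------------------------------------
# correlation primitives


def pearson_r(x: np.ndarray, y: np.ndarray, axis: int = -1) -> np.ndarray:
    """Vectorized Pearson correlation along ``axis``; zero-variance pairs
    yield NaN (the undefined marker)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must share shape")
    xm = x - x.mean(axis=axis, keepdims=True)
    ym = y - y.mean(axis=axis, keepdims=True)
    num = np.sum(xm * ym, axis=axis)
    den = np.sqrt(np.sum(xm**2, axis=axis) * np.sum(ym**2, axis=axis))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return np.clip(r, -1.0, 1.0)


def pearson_r0(
    bold: SeparatedTimeseries | np.ndarray,
    cbf: np.ndarray | None = None,
    exclude_edges: int = 1,
) -> np.ndarray:
    """Zero-lag voxelwise correlation between separated BOLD and CBF series
    over interior frames (filter-edge frames excluded)."""
    if isinstance(bold, SeparatedTimeseries):
        sep = bold
        b, c = sep.bold, sep.cbf
    else:
        if cbf is None:
            raise ValueError("provide a SeparatedTimeseries or two arrays")
        b, c = np.asarray(bold), np.asarray(cbf)
        if b.shape != c.shape:
            raise ValueError("bold and cbf must share shape")
    n = b.shape[-1]
    sl = slice(exclude_edges, n - exclude_edges) if exclude_edges else slice(None)
    return pearson_r(b[..., sl], c[..., sl])


def upsample_sinc(series: np.ndarray, dt_in: float, dt_out: float = 0.1) -> np.ndarray:
    """Band-limited (Fourier) upsampling along the last axis.

    ``dt_in / dt_out`` must be an integer factor so the original samples
    are preserved exactly at their time points.
    """
    if dt_out >= dt_in:
        raise ValueError(f"dt_out ({dt_out}) must be smaller than dt_in ({dt_in})")
    factor = dt_in / dt_out
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("dt_in must be an integer multiple of dt_out")
    x = np.asarray(series, dtype=float)
    return signal.resample(x, x.shape[-1] * int(round(factor)), axis=-1)


def _lag_corr(bold: np.ndarray, cbf: np.ndarray, shift: int) -> np.ndarray:
    """Correlation of bold(t) with cbf(t + shift*dt) over the truncated
    overlap (positive shift: CBF series advanced, i.e. BOLD leads)."""
    n = bold.shape[-1]
    if abs(shift) > n - MIN_OVERLAP:
        raise InsufficientOverlapError(
            f"overlap {n - abs(shift)} samples < {MIN_OVERLAP} at shift {shift}"
        )
    if shift >= 0:
        return pearson_r(bold[..., : n - shift or None], cbf[..., shift:])
    return pearson_r(bold[..., -shift:], cbf[..., : n + shift])


def _lagged_corr_all(bold: np.ndarray, cbf: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Truncated-overlap Pearson correlation at every requested shift,
    computed for all lags at once (FFT cross-correlation for the product
    sums, prefix sums for the per-overlap means and variances).  Equals
    :func:`_lag_corr` per lag to numerical precision."""
    n = bold.shape[-1]
    if np.max(np.abs(shifts)) > n - MIN_OVERLAP:
        raise InsufficientOverlapError(
            f"overlap < {MIN_OVERLAP} samples at shift {np.max(np.abs(shifts))}"
        )
    # global demean only improves conditioning; per-overlap means are exact below
    b = bold - bold.mean(axis=-1, keepdims=True)
    c = cbf - cbf.mean(axis=-1, keepdims=True)
    max_shift = int(np.max(np.abs(shifts)))
    nfft = int(fft.next_fast_len(n + max_shift + 1))
    bf = np.fft.rfft(b, nfft, axis=-1)
    cf = np.fft.rfft(c, nfft, axis=-1)
    cross = np.fft.irfft(np.conj(bf) * cf, nfft, axis=-1)  # [s] = sum_t b_t c_{t+s}
    csb = np.cumsum(b, axis=-1)
    csc = np.cumsum(c, axis=-1)
    csb2 = np.cumsum(b * b, axis=-1)
    csc2 = np.cumsum(c * c, axis=-1)
    tb, tc, tb2, tc2 = csb[..., -1], csc[..., -1], csb2[..., -1], csc2[..., -1]
    r = np.empty(bold.shape[:-1] + (len(shifts),))
    for k, s in enumerate(shifts):
        s = int(s)
        L = n - abs(s)
        if s >= 0:  # b[:n-s] vs c[s:]
            num_bc = cross[..., s]
            sb, sb2 = csb[..., L - 1], csb2[..., L - 1]
            sc = tc - (csc[..., s - 1] if s > 0 else 0.0)
            sc2 = tc2 - (csc2[..., s - 1] if s > 0 else 0.0)
        else:  # b[-s:] vs c[:n+s]
            num_bc = cross[..., nfft + s]
            sb = tb - csb[..., -s - 1]
            sb2 = tb2 - csb2[..., -s - 1]
            sc, sc2 = csc[..., L - 1], csc2[..., L - 1]
        num = num_bc - sb * sc / L
        varb = sb2 - sb**2 / L
        varc = sc2 - sc**2 / L
        den = np.sqrt(np.maximum(varb, 0.0) * np.maximum(varc, 0.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            rk = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        r[..., k] = np.clip(rk, -1.0, 1.0)
    return r


def lagged_rmax(
    bold: np.ndarray,
    cbf: np.ndarray,
    grid: LagGrid | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum lagged correlation and its lag on an upsampled series pair.

    Inputs must already be sampled at ``grid.upsample_dt``.  Returns
    (rmax, tau_star) arrays over the leading axes.  Voxels undefined at
    any lag (zero variance) return NaN in both.
    """
    grid = grid or LagGrid()
    bold = np.asarray(bold, dtype=float)
    cbf = np.asarray(cbf, dtype=float)
    if bold.shape != cbf.shape:
        raise ValueError("bold and cbf must share shape")
    r = _lagged_corr_all(bold, cbf, grid.shifts)
    return _argmax_lag(r, grid.taus)


def _argmax_lag(r: np.ndarray, taus: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # argmax with ties resolved toward smallest |tau|, then negative tau
    order = np.lexsort((taus, np.abs(taus)))
    r_ord = r[..., order]
    with np.errstate(invalid="ignore"):
        best = np.nanmax(r, axis=-1)
    idx = np.argmax(np.where(np.isnan(r_ord), -np.inf, r_ord), axis=-1)
    tau_star = taus[order][idx].astype(float)
    bad = np.isnan(r).any(axis=-1)
    best = np.where(bad, np.nan, best)
    tau_star = np.where(bad, np.nan, tau_star)
    return best, tau_star


@dataclass
class CouplingMap:
    """Per-voxel coupling result: zero-lag r0, lag-optimized rmax, the
    optimizing lag tau* (s), and Fisher-z transforms of both."""

    r0: np.ndarray
    rmax: np.ndarray
    tau_star: np.ndarray

    @property
    def z0(self) -> np.ndarray:
        return fisher_z(self.r0)

    @property
    def zmax(self) -> np.ndarray:
        return fisher_z(self.rmax)


def compute_coupling(
    sep: SeparatedTimeseries,
    grid: LagGrid | None = None,
    exclude_edges: int = 1,
) -> CouplingMap:
    """Zero-lag and lag-optimized coupling maps from separated series.

    Interior frames of both series are sinc-upsampled to the grid's
    sampling interval; r0 is the lag scan's tau = 0 entry (which makes
    rmax >= r0 hold exactly, the zero lag being a grid member) and is
    numerically indistinguishable from the direct frame-level Pearson
    correlation.
    """
    grid = grid or LagGrid()
    sl = (
        slice(exclude_edges, sep.n_frames - exclude_edges)
        if exclude_edges
        else slice(None)
    )
    bold_up = upsample_sinc(sep.bold[..., sl], sep.dt, grid.upsample_dt)
    cbf_up = upsample_sinc(sep.cbf[..., sl], sep.dt, grid.upsample_dt)
    r = _lagged_corr_all(bold_up, cbf_up, grid.shifts)
    r0 = r[..., np.argmin(np.abs(grid.taus))]
    rmax, tau_star = _argmax_lag(r, grid.taus)
    return CouplingMap(r0=r0, rmax=rmax, tau_star=tau_star)


def fisher_z(r: np.ndarray, clamp: float = 1.0 - 1e-7) -> np.ndarray:
    """Fisher z = atanh(r); |r| is clamped at 1 - 1e-7 so that perfectly
    correlated (degenerate noise-free) voxels stay finite."""
    r = np.asarray(r, dtype=float)
    return np.arctanh(np.clip(r, -clamp, clamp))


# ---------------------------------------------------------------------------
# group statistics


@dataclass
class GroupStatMap:
    """Voxelwise group test: t, dof, two-sided p, BH-FDR q, and the mask of
    tested (defined) voxels."""

    t: np.ndarray
    dof: int
    p: np.ndarray
    mask: np.ndarray
    q: np.ndarray | None = None
    reject: np.ndarray | None = None

    def threshold(self, alpha: float = 0.05) -> "GroupStatMap":
        """Apply BH-FDR within the tested mask at level alpha."""
        q = np.full(self.p.shape, np.nan)
        reject = np.zeros(self.p.shape, dtype=bool)
        if self.mask.any():
            rej, qv = fdr_bh(self.p[self.mask], alpha=alpha)
            q[self.mask] = qv
            reject[self.mask] = rej
        return GroupStatMap(t=self.t, dof=self.dof, p=self.p, mask=self.mask, q=q, reject=reject)


def _finalize_t(t_num, t_den, dof, valid):
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(t_den > 0, t_num / np.where(t_den > 0, t_den, 1.0), np.nan)
    # zero-mean, zero-variance voxels are a well-defined t = 0
    t = np.where((t_den == 0) & (t_num == 0), 0.0, t)
    mask = valid & np.isfinite(t)
    p = np.full(t.shape, np.nan)
    p[mask] = 2.0 * stats.t.sf(np.abs(t[mask]), dof)
    t = np.where(mask, t, np.nan)
    return t, p, mask


def one_sample_t(z_maps: np.ndarray) -> GroupStatMap:
    """Voxelwise one-sample t against 0 over the subject axis (first axis).

    Voxels that are NaN for any subject, or that have zero variance with a
    nonzero mean, are marked undefined and excluded from the mask.
    """
    z = np.asarray(z_maps, dtype=float)
    n = z.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    valid = np.isfinite(z).all(axis=0)
    mean = z.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    t_num = mean
    t_den = sd / np.sqrt(n)
    t, p, mask = _finalize_t(t_num, t_den, n - 1, valid)
    return GroupStatMap(t=t, dof=n - 1, p=p, mask=mask)


def two_sample_t(
    group_a: np.ndarray,
    group_b: np.ndarray,
    welch: bool = False,
) -> GroupStatMap:
    """Voxelwise unpaired two-sample t (A - B), pooled variance by default.

    ``welch=True`` switches to the unequal-variance variant with
    Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 subjects")
    valid = np.isfinite(a).all(axis=0) & np.isfinite(b).all(axis=0)
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    if welch:
        se2 = va / na + vb / nb
        with np.errstate(invalid="ignore", divide="ignore"):
            dof_arr = se2**2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        dof = float(np.nanmedian(np.where(se2 > 0, dof_arr, np.nan)))
        t_den = np.sqrt(se2)
    else:
        dof = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / dof
        t_den = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t, p, mask = _finalize_t(ma - mb, t_den, dof, valid)
    return GroupStatMap(t=t, dof=dof, p=p, mask=mask)


def fdr_bh(p: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (rejection mask, adjusted q).

    Rejects every p <= p_(k) with k = max{i : p_(i) <= i * alpha / m};
    q values are the monotone-adjusted p * m / rank.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p.ravel(), alpha=alpha, method="fdr_bh")
    return reject.reshape(p.shape), q.reshape(p.shape)


# ---------------------------------------------------------------------------
# ROI summaries


def roi_extract(
    value_map: np.ndarray,
    mask: np.ndarray,
    gm_mask: np.ndarray | None = None,
    threshold: float = 0.3,
) -> tuple[float, int]:
    """Mean of a map over mask voxels, restricted to gray matter.

    The ROI is ``mask AND (gm_mask >= threshold)`` (threshold 0.3 on a
    probabilistic gray-matter map); returns (mean, voxel count).
    """
    value_map = np.asarray(value_map, dtype=float)
    sel = np.asarray(mask, dtype=bool)
    if sel.shape != value_map.shape:
        raise ValueError("mask shape must match the map")
    if gm_mask is not None:
        gm = np.asarray(gm_mask, dtype=float)
        if gm.shape != value_map.shape:
            raise ValueError("gm_mask shape must match the map")
        sel = sel & (gm >= threshold)
    if not sel.any():
        raise EmptyROIError("ROI/gray-matter intersection is empty")
    return float(np.nanmean(value_map[sel])), int(sel.sum())


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d for two independent samples (pooled SD)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    sp = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if sp == 0:
        return 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
    return float((a.mean() - b.mean()) / sp)


@dataclass
class ContrastResult:
    mean_a: float
    mean_b: float
    t: float
    p: float
    dof: int
    d: float


def rmax_minus_r0_contrast(
    roi_values_a: np.ndarray,
    roi_values_b: np.ndarray,
) -> ContrastResult:
    """Between-group comparison of the per-subject rmax - r0 difference.

    Inputs are (n_subjects, 2) arrays of (r0, rmax) per subject; the
    statistic is the unpaired pooled-variance t on the differences, with
    Cohen's d as the effect size.
    """
    a = np.asarray(roi_values_a, dtype=float)
    b = np.asarray(roi_values_b, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or b.ndim != 2 or b.shape[1] != 2:
        raise ValueError("expected (n_subjects, 2) arrays of (r0, rmax)")
    da = a[:, 1] - a[:, 0]
    db = b[:, 1] - b[:, 0]
    res = two_sample_t(da[:, None], db[:, None])
    return ContrastResult(
        mean_a=float(da.mean()),
        mean_b=float(db.mean()),
        t=float(res.t[0]),
        p=float(res.p[0]),
        dof=int(res.dof),
        d=cohens_d(da, db),
    )
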