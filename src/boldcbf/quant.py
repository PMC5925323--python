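"""Baseline CBF quantification with the single-compartment ASL model.

    CBF = 6000 * lambda * (SI_C - SI_L) * exp(PLD / T1a)
          -------------------------------------------------
          2 * alpha * alpha_inv * T1a * M0 * (1 - exp(-tau / T1a))

in ml/100g/min, with all times in seconds (the factor 6000 converts
ml/g/s to ml/100g/min).  SI_C and SI_L are the temporal means of control
and label volumes; PLD is the slice-dependent post-label delay, rising
linearly from ``pld_first`` at the lowest slice to ``pld_last`` at the
top slice of the ascending acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BaselineASLRun, CONTROL, LABEL, QuantParams, TagError

__all__ = [
    "CBFMap",
    "temporal_means",
    "slice_pld",
    "quantify_cbf",
    "quantify_run",
    "delta_m_from_cbf",
]


@dataclass
class CBFMap:
    """Voxelwise perfusion map (ml/100g/min) with a validity mask."""

    cbf: np.ndarray
    valid_mask: np.ndarray


def temporal_means(run: BaselineASLRun) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise temporal means of control and label volumes."""
    is_c = run.tags == CONTROL
    is_l = run.tags == LABEL
    if not is_c.any() or not is_l.any():
        raise TagError("run must contain both control and label volumes")
    return run.series[..., is_c].mean(axis=-1), run.series[..., is_l].mean(axis=-1)


def slice_pld(slice_index, params: QuantParams) -> np.ndarray:
    """Slice-dependent post-label delay (s), linear in ascending slice order.

    Slice 0 gets ``pld_first``; the top slice gets ``pld_last`` (with 19
    slices and the default 1.9-2.8 s range the increment is 50 ms/slice).
    """
    idx = np.asarray(slice_index)
    if np.any(idx < 0) or np.any(idx >= params.n_slices):
        raise IndexError(
            f"slice index out of range [0, {params.n_slices})"
        )
    if params.n_slices == 1:
        return np.broadcast_to(np.asarray(params.pld_first, dtype=float), idx.shape).copy()
    step = (params.pld_last - params.pld_first) / (params.n_slices - 1)
    return params.pld_first + idx * step


def _model_factor(params: QuantParams, pld: np.ndarray) -> np.ndarray:
    """CBF per unit fractional difference (SI_C - SI_L)/M0."""
    t1a = params.t1_arterial
    return (
        6000.0
        * params.lambda_bbp
        * np.exp(np.asarray(pld, dtype=float) / t1a)
        / (
            2.0
            * params.alpha_label
            * params.alpha_inv
            * t1a
            * (1.0 - np.exp(-params.label_duration / t1a))
        )
    )


def _pld_map(shape: tuple[int, ...], params: QuantParams, pld) -> np.ndarray:
    if pld is not None:
        return np.asarray(pld, dtype=float)
    if shape[2] != params.n_slices:
        raise ValueError(
            f"image has {shape[2]} slices but params.n_slices = {params.n_slices}; "
            "use params.with_slices(...) or pass pld explicitly"
        )
    return slice_pld(np.arange(params.n_slices), params)[None, None, :]


def quantify_cbf(
    si_c: np.ndarray,
    si_l: np.ndarray,
    m0: np.ndarray,
    params: QuantParams | None = None,
    pld: np.ndarray | None = None,
) -> CBFMap:
    """Single-compartment perfusion from control/label means and M0.

    Each voxel uses its slice's post-label delay (third array axis is the
    slice axis) unless an explicit ``pld`` array/scalar is given.  Voxels
    with M0 <= 0 are masked invalid and set to zero.
    """
    params = params or QuantParams()
    si_c = np.asarray(si_c, dtype=float)
    si_l = np.asarray(si_l, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    if si_c.shape != si_l.shape or si_c.shape != m0.shape:
        raise ValueError("SI_C, SI_L and M0 must share shape")
    pld_arr = _pld_map(si_c.shape, params, pld)
    valid = m0 > 0
    denom = np.where(valid, m0, 1.0)
    cbf = _model_factor(params, pld_arr) * (si_c - si_l) / denom
    cbf = np.where(valid, cbf, 0.0)
    return CBFMap(cbf=cbf, valid_mask=valid)


def quantify_run(run: BaselineASLRun, params: QuantParams | None = None) -> CBFMap:
    """Quantify a baseline run via its temporal control/label means."""
    params = (params or QuantParams()).with_slices(run.series.shape[2])
    si_c, si_l = temporal_means(run)
    return quantify_cbf(si_c, si_l, run.m0, params)


def delta_m_from_cbf(
    cbf: np.ndarray,
    m0: np.ndarray,
    params: QuantParams,
    pld: np.ndarray | None = None,
) -> np.ndarray:
    """Exact inverse of :func:`quantify_cbf`: the label/control difference
    SI_C - SI_L implied by a perfusion map (the generator's forward model)."""
    cbf = np.asarray(cbf, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    pld_arr = _pld_map(cbf.shape, params, pld)
    return cbf * np.where(m0 > 0, m0, 0.0) / _model_factor(params, pld_arr)
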