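"""Synthetic dual-echo pCASL data with known ground truth.

Forward model (per voxel x, volume v at time t_v, per echo e):

    S_e(x, v) = M0_x * (1 + g_e * b_x(t_v)) * (1 - w_v * dM_x/M0_x * (1 + f_x(t_v)))
                + physio_gain * M0_x * (cardiac + respiratory at t_v)
                + N(0, noise_sd * M0_x)

where f is the perfusion fluctuation process, b the BOLD fluctuation
process coupled to f at a chosen correlation and lag, w_v is 1 for label
volumes and 0 for controls, and dM is the label/control difference
implied by the voxel's baseline perfusion through the single-compartment
model evaluated at the voxel's slice-dependent post-label delay.  The
echo-dependent BOLD gain g_e = TE_e / TE2 makes the short echo carry
10/28 of the long echo's fractional BOLD amplitude (linear-in-TE
approximation), so it is perfusion-dominated but not perfectly clean.

Fluctuation processes are synthesized in the frequency domain (unit
magnitude at in-band Fourier bins, random phases), which gives exact
band containment and makes Fourier-domain time shifts exact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import (
    AcquisitionParams,
    BaselineASLRun,
    DEFAULT_BAND,
    DualEchoPCASLRun,
    InvalidBandError,
    LABEL,
    QuantParams,
    alternating_tags,
)
from .quant import delta_m_from_cbf

__all__ = [
    "PhysioTrace",
    "GroundTruth",
    "uniform_truth",
    "generate_band_limited_process",
    "generate_coupled_pair",
    "sinc_shift",
    "make_physio_trace",
    "assemble_dual_echo_run",
    "assemble_baseline_run",
    "generate_cohort",
    "cohort_preset",
    "COHORT_PRESETS",
]


@dataclass
class PhysioTrace:
    """Cardiac and respiratory waveforms sampled at 100 Hz."""

    sampling_rate: float
    cardiac: np.ndarray
    respiratory: np.ndarray

    def __post_init__(self) -> None:
        self.cardiac = np.asarray(self.cardiac, dtype=float)
        self.respiratory = np.asarray(self.respiratory, dtype=float)
        if self.cardiac.shape != self.respiratory.shape:
            raise ValueError("cardiac and respiratory traces must share length")

    @property
    def duration(self) -> float:
        return self.cardiac.size / self.sampling_rate

    def value_at(self, times: np.ndarray) -> np.ndarray:
        """Summed physiological waveform sampled at arbitrary times."""
        t_axis = np.arange(self.cardiac.size) / self.sampling_rate
        return np.interp(times, t_axis, self.cardiac) + np.interp(
            times, t_axis, self.respiratory
        )


def make_physio_trace(
    duration: float,
    sampling_rate: float = 100.0,
    cardiac_freq: float = 1.0,
    respiratory_freq: float = 0.3,
) -> PhysioTrace:
    """Unit-amplitude sinusoidal cardiac (1 Hz) and respiratory (0.3 Hz)
    traces; at TR 3.5 s both alias into the low-frequency range."""
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    return PhysioTrace(
        sampling_rate=sampling_rate,
        cardiac=np.sin(2 * np.pi * cardiac_freq * t),
        respiratory=np.sin(2 * np.pi * respiratory_freq * t),
    )


@dataclass
class GroundTruth:
    """Injected voxelwise truth for a synthetic subject.

    baseline_cbf : ml/100g/min per voxel.
    coupling : target Pearson correlation between the BOLD and CBF
        fluctuation processes, in [-1, 1].
    lag : seconds per voxel; lag < 0 means BOLD is delayed with respect
        to CBF (same convention as the analysis tau*).
    cbf_fluct_amplitude : SD of the perfusion fluctuation as a fraction
        of the voxel's mean label/control difference.
    bold_fluct_amplitude : SD of the BOLD fluctuation as a fraction of M0
        at the long echo.
    noise_sd : white thermal noise SD as a fraction of M0.
    band : frequency band (Hz) of both fluctuation processes.
    m0 : equilibrium magnetization image (arbitrary units).
    mask : brain mask; voxels outside are zero.
    """

    baseline_cbf: np.ndarray
    coupling: np.ndarray
    lag: np.ndarray
    cbf_fluct_amplitude: float = 0.10
    bold_fluct_amplitude: float = 0.01
    noise_sd: float = 2e-4
    band: tuple[float, float] = DEFAULT_BAND
    m0: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.baseline_cbf = np.asarray(self.baseline_cbf, dtype=float)
        self.coupling = np.asarray(self.coupling, dtype=float)
        self.lag = np.asarray(self.lag, dtype=float)
        shape = self.baseline_cbf.shape
        if self.coupling.shape != shape or self.lag.shape != shape:
            raise ValueError("truth maps must share one spatial shape")
        if np.any(np.abs(self.coupling) > 1):
            raise ValueError("|coupling| must be <= 1 everywhere")
        if min(self.cbf_fluct_amplitude, self.bold_fluct_amplitude, self.noise_sd) < 0:
            raise ValueError("amplitudes must be >= 0")
        if not 0 < self.band[0] < self.band[1]:
            raise InvalidBandError("band must satisfy 0 < f_lo < f_hi")
        if self.m0 is None:
            self.m0 = np.full(shape, 1000.0)
        else:
            self.m0 = np.asarray(self.m0, dtype=float)
        if self.mask is None:
            self.mask = np.ones(shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.m0.shape != shape or self.mask.shape != shape:
            raise ValueError("m0/mask must match the truth map shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.baseline_cbf.shape


def uniform_truth(
    matrix: tuple[int, int, int],
    baseline_cbf: float = 60.0,
    coupling: float = 0.24,
    lag: float = -0.5,
    **kwargs,
) -> GroundTruth:
    """Spatially uniform ground truth on the given voxel grid."""
    shape = tuple(matrix)
    return GroundTruth(
        baseline_cbf=np.full(shape, float(baseline_cbf)),
        coupling=np.full(shape, float(coupling)),
        lag=np.full(shape, float(lag)),
        **kwargs,
    )


# ---------------------------------------------------------------------------
# band-limited processes


def _band_bins(n_points: int, dt: float, band: tuple[float, float]) -> np.ndarray:
    f_lo, f_hi = band
    nyq = 0.5 / dt
    if not 0 < f_lo < f_hi or f_hi > nyq * (1 + 1e-9):
        raise InvalidBandError(f"band {band} outside (0, Nyquist={nyq:.4g}]")
    freqs = np.fft.rfftfreq(n_points, dt)
    sel = (freqs >= f_lo) & (freqs <= f_hi) & (freqs > 0)
    if not sel.any():
        raise InvalidBandError(f"band {band} contains no Fourier bins at n={n_points}")
    return sel


def _band_limited_field(
    shape: tuple,
    n_points: int,
    dt: float,
    band: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-SD band-limited processes, one per leading-shape element."""
    sel = _band_bins(n_points, dt, band)
    n_rf = sel.sum()
    spec = np.zeros(tuple(shape) + (sel.size,), dtype=complex)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=tuple(shape) + (n_rf,))
    spec[..., sel] = np.exp(1j * phases)
    if n_points % 2 == 0 and sel[-1]:
        # Nyquist bin of a real signal must be real
        spec[..., -1] = np.cos(phases[..., -1])
    x = np.fft.irfft(spec, n=n_points, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_band_limited_process(
    n_points: int,
    dt: float,
    band: tuple[float, float],
    amplitude: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Zero-mean random process with all spectral power inside ``band``.

    Synthesized in the frequency domain: unit magnitude at every Fourier
    bin inside the band, uniform random phases.  The sample SD equals
    ``amplitude`` exactly; ``amplitude = 0`` returns zeros.  Deterministic
    given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0:
        _band_bins(n_points, dt, band)  # still validate the band
        return np.zeros(n_points)
    return amplitude * _band_limited_field((), n_points, dt, band, rng)


def sinc_shift(series: np.ndarray, dt: float, shift, axis: int = -1) -> np.ndarray:
    """Evaluate a (periodic, band-limited) series at t + shift.

    Implemented as a Fourier-domain phase ramp, which is an exact time
    shift for the frequency-domain-synthesized processes used here.
    ``shift`` may be a scalar or an array broadcasting against the
    leading axes.
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[axis]
    x = np.moveaxis(x, axis, -1)
    freqs = np.fft.rfftfreq(n, dt)
    shift = np.asarray(shift, dtype=float)[..., np.newaxis]
    spec = np.fft.rfft(x, axis=-1) * np.exp(2j * np.pi * freqs * shift)
    return np.moveaxis(np.fft.irfft(spec, n=n, axis=-1), -1, axis)


def _surrogate_noise(series: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD phase-randomized surrogates (exactly band/spectrum matched)."""
    x = np.asarray(series, dtype=float)
    n = x.shape[-1]
    spec = np.fft.rfft(x, axis=-1)
    mag = np.abs(spec)
    mag[..., 0] = 0.0
    phases = rng.uniform(0.0, 2.0 * np.pi, size=mag.shape)
    new = mag * np.exp(1j * phases)
    if n % 2 == 0:
        new[..., -1] = mag[..., -1] * np.cos(phases[..., -1])
    out = np.fft.irfft(new, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def generate_coupled_pair(
    cbf_series: np.ndarray,
    target_r: float,
    lag: float,
    dt: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """BOLD fluctuation series coupled to a CBF series at a known level.

    Returns r * shat(t + lag) + sqrt(1 - r^2) * ehat, scaled back to the
    input SD, where shat is the unit-SD lag-shifted input and ehat an
    independent phase-randomized (band-matched) surrogate.  The population
    correlation with the lag-aligned CBF series is ``target_r``; lag < 0
    delays BOLD with respect to CBF.
    """
    if abs(target_r) > 1:
        raise ValueError(f"|target_r| must be <= 1, got {target_r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(cbf_series, dtype=float)
    sd = x.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("cbf_series must have nonzero variance")
    shat = sinc_shift(x, dt, lag) / sd
    shat -= shat.mean(axis=-1, keepdims=True)
    ehat = _surrogate_noise(x, rng)
    bold = target_r * shat + np.sqrt(1.0 - target_r**2) * ehat
    return bold * sd


def _coupled_fields(
    truth: GroundTruth,
    n_points: int,
    dt: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-SD perfusion (f) and coupled BOLD (b) processes per masked voxel."""
    v = int(truth.mask.sum())
    f = _band_limited_field((v,), n_points, dt, truth.band, rng)
    r = truth.coupling[truth.mask][:, None]
    lag = truth.lag[truth.mask]
    shifted = sinc_shift(f, dt, lag)
    shifted -= shifted.mean(axis=-1, keepdims=True)
    sd = shifted.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    noise = _band_limited_field((v,), n_points, dt, truth.band, rng)
    b = r * shifted / sd + np.sqrt(1.0 - r**2) * noise
    return f, b


# ---------------------------------------------------------------------------
# run assembly


def _dynamic_quant_params(acq: AcquisitionParams, base: QuantParams | None = None) -> QuantParams:
    """Quantification constants matching the dynamic (unsuppressed) run."""
    base = base or QuantParams()
    return replace(
        base,
        alpha_inv=1.0,
        label_duration=acq.label_duration,
        pld_first=acq.pld_first,
        pld_last=acq.pld_first + (acq.matrix[2] - 1) * acq.pld_increment,
        n_slices=acq.matrix[2],
    )


def _slice_pld_map(shape: tuple[int, int, int], params: QuantParams) -> np.ndarray:
    from .quant import slice_pld

    plds = slice_pld(np.arange(shape[2]), params)
    return np.broadcast_to(plds[None, None, :], shape)


def assemble_dual_echo_run(
    truth: GroundTruth,
    acq: AcquisitionParams,
    physio: PhysioTrace | None = None,
    physio_gain: float = 0.0,
    seed: int | np.random.Generator = 0,
    return_fields: bool = False,
):
    """Assemble a dual-echo interleaved control/label run from ground truth.

    With ``return_fields=True`` also returns the realized unit-SD
    perfusion and BOLD fluctuation fields as 4D arrays (the per-voxel
    processes actually injected), for ground-truth recovery checks.
    """
    if truth.shape != tuple(acq.matrix):
        raise ValueError(
            f"truth maps {truth.shape} do not conform to acq.matrix {tuple(acq.matrix)}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nt = acq.n_volumes
    tags = acq.tags()
    w = (tags == LABEL).astype(float)

    f, b = _coupled_fields(truth, nt, acq.tr, rng)

    dparams = _dynamic_quant_params(acq)
    pld = _slice_pld_map(truth.shape, dparams)
    dm = delta_m_from_cbf(truth.baseline_cbf, truth.m0, dparams, pld=pld)

    mask = truth.mask
    m0_v = truth.m0[mask][:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        dm_frac = np.where(truth.m0 > 0, dm / np.where(truth.m0 > 0, truth.m0, 1.0), 0.0)
    perf = dm_frac[mask][:, None] * (1.0 + truth.cbf_fluct_amplitude * f)

    if physio is not None and physio_gain != 0.0:
        t_mid = acq.frame_times + acq.tr / 2.0  # slice-mean acquisition time
        if physio.duration + 1e-9 < t_mid.max():
            raise ValueError("physio trace shorter than the run")
        physio_term = physio_gain * physio.value_at(t_mid)[None, :]
    else:
        physio_term = 0.0

    echoes = []
    for te in (acq.te1, acq.te2):
        gain = te / acq.te2
        sig = m0_v * (1.0 + gain * truth.bold_fluct_amplitude * b) * (1.0 - w[None, :] * perf)
        sig = sig + m0_v * physio_term
        if truth.noise_sd > 0:
            sig = sig + rng.normal(0.0, truth.noise_sd, size=sig.shape) * m0_v
        vol = np.zeros(truth.shape + (nt,))
        vol[mask] = sig
        echoes.append(vol)

    run = DualEchoPCASLRun(echo1=echoes[0], echo2=echoes[1], tags=tags, acq=acq)
    if return_fields:
        fields = {}
        for name, data in (("perfusion", f), ("bold", b)):
            vol = np.zeros(truth.shape + (nt,))
            vol[mask] = data
            fields[name] = vol
        return run, fields
    return run


def assemble_baseline_run(
    truth: GroundTruth,
    params: QuantParams | None = None,
    n_volumes: int = 60,
    seed: int | np.random.Generator = 0,
    control_first: bool = True,
) -> BaselineASLRun:
    """Background-suppressed single-echo baseline run plus M0 image.

    Control volumes are M0, label volumes M0 - dM with dM the
    single-compartment difference at each voxel's slice PLD; suppression
    enters only through the alpha_inv efficiency factor.  The temporal
    control/label means fed back to ``quantify_cbf`` with the same
    parameters return the injected perfusion map exactly when noise-free.
    """
    if n_volumes % 2 or n_volumes < 2:
        raise ValueError("n_volumes must be even and >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    params = (params or QuantParams()).with_slices(truth.shape[2])
    pld = _slice_pld_map(truth.shape, params)
    dm = delta_m_from_cbf(truth.baseline_cbf, truth.m0, params, pld=pld)
    m0 = np.where(truth.mask, truth.m0, 0.0)
    dm = np.where(truth.mask, dm, 0.0)

    tags = alternating_tags(n_volumes, control_first)
    w = (tags == LABEL).astype(float)
    series = m0[..., None] - dm[..., None] * w[None, None, None, :]
    if truth.noise_sd > 0:
        noise = rng.normal(0.0, truth.noise_sd, size=series.shape) * m0[..., None]
        series = series + noise
    return BaselineASLRun(series=series, tags=tags, m0=m0)


# ---------------------------------------------------------------------------
# cohorts

COHORT_PRESETS = {
    # group-level coupling/lag distributions emulating a young-adult and a
    # healthy-elderly resting-state cohort: mean zero-lag coupling 0.24 vs
    # 0.18 (between-subject SD 0.03 / 0.04), BOLD delayed with respect to
    # CBF by 0.5 s vs 1.8 s
    "young-like": dict(coupling=0.24, lag=-0.5, coupling_sd=0.03, lag_sd=0.3),
    "elderly-like": dict(coupling=0.18, lag=-1.8, coupling_sd=0.04, lag_sd=0.3),
}


def cohort_preset(name: str) -> dict:
    try:
        return dict(COHORT_PRESETS[name])
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(COHORT_PRESETS)}")


@dataclass
class SubjectSim:
    subject_id: str
    truth: GroundTruth
    run: DualEchoPCASLRun


def draw_subject_truth(
    template: GroundTruth,
    coupling_sd: float,
    lag_sd: float,
    rng: np.random.Generator,
) -> GroundTruth:
    """Subject-level truth: coupling perturbed on the Fisher-z scale (keeps
    |r| <= 1), lag perturbed additively."""
    z = np.arctanh(np.clip(template.coupling, -1 + 1e-12, 1 - 1e-12))
    coupling = np.tanh(z + rng.normal(0.0, coupling_sd))
    lag = template.lag + rng.normal(0.0, lag_sd)
    return replace(template, coupling=coupling, lag=lag)


def generate_cohort(
    n_subjects: int,
    template: GroundTruth,
    acq: AcquisitionParams,
    seed: int | np.random.Generator = 0,
    coupling_sd: float = 0.03,
    lag_sd: float = 0.3,
    group: str = "group",
    assemble: bool = True,
    physio: PhysioTrace | None = None,
    physio_gain: float = 0.0,
) -> tuple[list[SubjectSim], pd.DataFrame]:
    """Cohort of synthetic subjects with subject-level coupling and lag drawn
    around a template; returns the runs and a truth table."""
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    subjects, rows = [], []
    for i in range(n_subjects):
        truth = draw_subject_truth(template, coupling_sd, lag_sd, rng)
        run = (
            assemble_dual_echo_run(truth, acq, physio=physio, physio_gain=physio_gain, seed=rng)
            if assemble
            else None
        )
        sid = f"{group}{i + 1:02d}"
        subjects.append(SubjectSim(subject_id=sid, truth=truth, run=run))
        m = truth.mask
        rows.append(
            {
                "subject": sid,
                "group": group,
                "coupling": float(truth.coupling[m].mean()),
                "lag": float(truth.lag[m].mean()),
                "baseline_cbf": float(truth.baseline_cbf[m].mean()),
            }
        )
    return subjects, pd.DataFrame(rows)
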