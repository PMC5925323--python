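"""Core parameter sets and in-memory containers for dual-echo pCASL analysis.

All times are in **seconds** and all frequencies in **Hz** throughout the
package; perfusion is in ml/100g/min.  Acquisition defaults reproduce a
3T dual-echo pCASL resting-state protocol (TR 3.5 s, TE1/TE2 10/28 ms,
64x64x19 matrix, 90 interleaved control/label volumes).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np

__all__ = [
    "AcquisitionParams",
    "QuantParams",
    "LagGrid",
    "DualEchoPCASLRun",
    "SeparatedTimeseries",
    "BaselineASLRun",
    "CONTROL",
    "LABEL",
    "alternating_tags",
    "TagError",
    "InvalidBandError",
]

CONTROL = "C"
LABEL = "L"

DEFAULT_BAND = (0.01, 0.071)


class TagError(ValueError):
    """Control/label tag vector violates the interleaving contract."""


class InvalidBandError(ValueError):
    """Requested frequency band is empty or exceeds the Nyquist frequency."""


def alternating_tags(n_volumes: int, control_first: bool = True) -> np.ndarray:
    """Strictly alternating control/label tag vector of length ``n_volumes``."""
    if n_volumes % 2:
        raise ValueError(f"n_volumes must be even, got {n_volumes}")
    pair = (CONTROL, LABEL) if control_first else (LABEL, CONTROL)
    return np.array(list(pair) * (n_volumes // 2))


def _check_alternating(tags: np.ndarray) -> None:
    tags = np.asarray(tags)
    if tags.size % 2:
        raise TagError("tag vector length must be even")
    if not set(np.unique(tags)) <= {CONTROL, LABEL}:
        raise TagError(f"tags must be '{CONTROL}'/'{LABEL}', got {set(np.unique(tags))}")
    if tags.size and np.any(tags[1:] == tags[:-1]):
        raise TagError("control/label tags must strictly alternate")


@dataclass(frozen=True)
class AcquisitionParams:
    """Dual-echo pCASL acquisition geometry and timing.

    Parameters
    ----------
    tr : repetition time per volume, s.
    te1, te2 : echo times, s; the short echo is perfusion-dominated, the
        long echo BOLD-dominated.
    n_volumes : total interleaved control+label volumes (must be even).
    matrix : (nx, ny, nz) voxel counts.
    voxel_size : (dx, dy, dz) in mm.
    label_duration : labeling bolus duration, s.
    pld_first : post-label delay of the first (lowest) slice, s.
    pld_increment : extra post-label delay per ascending slice, s.
    control_first : whether the interleave starts with a control volume.
    """

    tr: float = 3.5
    te1: float = 0.010
    te2: float = 0.028
    n_volumes: int = 90
    matrix: tuple[int, int, int] = (64, 64, 19)
    voxel_size: tuple[float, float, float] = (3.6, 3.6, 5.0)
    label_duration: float = 1.65
    pld_first: float = 1.0
    pld_increment: float = 0.05
    control_first: bool = True

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not (0 < self.te1 < self.te2):
            raise ValueError("echo times must satisfy 0 < te1 < te2")
        if self.n_volumes % 2 or self.n_volumes < 2:
            raise ValueError("n_volumes must be even and >= 2")
        if len(self.matrix) != 3 or min(self.matrix) < 1:
            raise ValueError("matrix must be three positive voxel counts")

    @property
    def separation_cutoff_hz(self) -> float:
        """High-/low-pass split frequency 1/(4*TR) separating the label/control
        modulation from the slow BOLD-weighted signal."""
        return 1.0 / (4.0 * self.tr)

    @property
    def n_pairs(self) -> int:
        return self.n_volumes // 2

    @property
    def pair_dt(self) -> float:
        """Sampling interval of the separated series (2*TR), s."""
        return 2.0 * self.tr

    @property
    def frame_times(self) -> np.ndarray:
        """Nominal start time of each volume, s."""
        return np.arange(self.n_volumes) * self.tr

    @property
    def duration(self) -> float:
        return self.n_volumes * self.tr

    def slice_pld(self, slice_index: int | np.ndarray) -> np.ndarray:
        """Post-label delay of a 0-based slice for the dynamic run."""
        idx = np.asarray(slice_index)
        if np.any(idx < 0) or np.any(idx >= self.matrix[2]):
            raise IndexError("slice index out of range")
        return self.pld_first + idx * self.pld_increment

    def tags(self) -> np.ndarray:
        return alternating_tags(self.n_volumes, self.control_first)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionParams":
        d = dict(d)
        for key in ("matrix", "voxel_size"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class QuantParams:
    """Single-compartment perfusion quantification constants.

    Defaults are the standard 3T values: blood-brain partition coefficient
    lambda = 0.9 ml/g, arterial blood T1 = 1.65 s, labeling efficiency
    0.85, background-suppression correction 0.83, label duration 1.75 s,
    slice-dependent post-label delay ramping 1.9 -> 2.8 s over 19 ascending
    slices.
    """

    lambda_bbp: float = 0.9
    t1_arterial: float = 1.65
    alpha_label: float = 0.85
    alpha_inv: float = 0.83
    label_duration: float = 1.75
    pld_first: float = 1.9
    pld_last: float = 2.8
    n_slices: int = 19

    def __post_init__(self) -> None:
        for name in ("lambda_bbp", "t1_arterial", "label_duration", "pld_first"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("alpha_label", "alpha_inv"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.pld_last < self.pld_first:
            raise ValueError("pld_last must be >= pld_first")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")

    def with_slices(self, n_slices: int) -> "QuantParams":
        """Same constants on a different slice count (same PLD range)."""
        return replace(self, n_slices=n_slices)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "QuantParams":
        return cls(**d)


@dataclass(frozen=True)
class LagGrid:
    """Symmetric lag grid for the lagged cross-correlation scan.

    The scan covers tau in [tau_min, tau_max] (default +-7 s) in steps of
    ``step`` (default 0.35 s) on series upsampled to ``upsample_dt``
    (default 0.1 s).  Each nominal tau is evaluated at the nearest integer
    number of upsampled samples (worst-case rounding 0.05 s).  tau < 0
    means the BOLD series lags (is delayed with respect to) the CBF series.
    """

    tau_min: float = -7.0
    tau_max: float = 7.0
    step: float = 0.35
    upsample_dt: float = 0.1

    def __post_init__(self) -> None:
        if self.tau_max <= 0 or abs(self.tau_min + self.tau_max) > 1e-12:
            raise ValueError("grid must be symmetric about 0 (tau_min = -tau_max < 0)")
        if self.step <= 0 or self.upsample_dt <= 0:
            raise ValueError("step and upsample_dt must be positive")
        if self.step < self.upsample_dt:
            raise ValueError("step must be >= upsample_dt")
        n = self.tau_max / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("tau_max must be an integer multiple of step")

    @property
    def taus(self) -> np.ndarray:
        """Nominal lags, ascending, containing 0 exactly."""
        k = round(self.tau_max / self.step)
        return np.arange(-k, k + 1) * self.step

    @property
    def shifts(self) -> np.ndarray:
        """Integer sample shifts (at upsample_dt) realizing each nominal tau."""
        return np.rint(self.taus / self.upsample_dt).astype(int)


@dataclass
class DualEchoPCASLRun:
    """A dual-echo pCASL run: two 4D (x, y, z, t) arrays sharing one
    interleaved control/label tag vector and acquisition metadata."""

    echo1: np.ndarray
    echo2: np.ndarray
    tags: np.ndarray
    acq: AcquisitionParams

    def __post_init__(self) -> None:
        self.echo1 = np.asarray(self.echo1, dtype=float)
        self.echo2 = np.asarray(self.echo2, dtype=float)
        self.tags = np.asarray(self.tags)
        if self.echo1.shape != self.echo2.shape:
            raise ValueError("echo1 and echo2 must share shape")
        if self.echo1.ndim != 4:
            raise ValueError("echo data must be 4D (x, y, z, t)")
        if self.echo1.shape[-1] != self.tags.size:
            raise ValueError("tag vector length must match the time axis")
        _check_alternating(self.tags)

    @property
    def n_volumes(self) -> int:
        return self.echo1.shape[-1]

    @property
    def control_first(self) -> bool:
        return self.tags[0] == CONTROL


@dataclass
class SeparatedTimeseries:
    """Separated BOLD and CBF fluctuation series at sampling interval 2*TR.

    The first and last frames of each series sit on the temporal-filter
    edges; ``interior`` exposes the slice used by quantitative assertions.
    """

    bold: np.ndarray
    cbf: np.ndarray
    dt: float
    band: tuple[float, float] = DEFAULT_BAND

    def __post_init__(self) -> None:
        self.bold = np.asarray(self.bold, dtype=float)
        self.cbf = np.asarray(self.cbf, dtype=float)
        if self.bold.shape != self.cbf.shape:
            raise ValueError("bold and cbf must share shape")

    @property
    def n_frames(self) -> int:
        return self.bold.shape[-1]

    @property
    def interior(self) -> slice:
        """Time slice excluding the first and last (edge-affected) frame."""
        return slice(1, self.n_frames - 1)


@dataclass
class BaselineASLRun:
    """Background-suppressed single-echo baseline ASL run plus M0 image."""

    series: np.ndarray
    tags: np.ndarray
    m0: np.ndarray

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        self.tags = np.asarray(self.tags)
        self.m0 = np.asarray(self.m0, dtype=float)
        if self.series.ndim != 4:
            raise ValueError("series must be 4D")
        if self.series.shape[-1] != self.tags.size:
            raise ValueError("tag vector length must match time axis")
        if self.m0.shape != self.series.shape[:3]:
            raise ValueError("M0 shape must match the spatial grid")
        _check_alternating(self.tags)
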