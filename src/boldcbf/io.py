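"""Standard-format I/O: 4D NIfTI with JSON sidecars, TSV tables, YAML config.

Conventions
-----------
* A dual-echo run ``<prefix>`` is stored as ``<prefix>_echo1.nii.gz``,
  ``<prefix>_echo2.nii.gz`` and ``<prefix>.json`` (acquisition parameters
  plus the control/label tag vector, volume order = acquisition order).
* Separated series store their sampling interval (2*TR) in the NIfTI time
  axis; the band is recorded in a sidecar.
* Physiological traces are 2-column TSV (cardiac, respiratory) at 100 Hz.
* Voxel indices are 0-based; world coordinates follow the image affine
  (identity scaled by the voxel size for synthetic data); no reorientation
  is performed.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import AcquisitionParams, BaselineASLRun, DualEchoPCASLRun, SeparatedTimeseries
from .synth import PhysioTrace

__all__ = [
    "FormatError",
    "write_image",
    "read_image",
    "write_run",
    "read_run",
    "write_separated",
    "read_separated",
    "write_baseline_run",
    "read_baseline_run",
    "write_physio",
    "read_physio",
    "read_table",
    "write_table",
]


class FormatError(ValueError):
    """Malformed or missing file/field, with the offender named."""


def _affine(voxel_size) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0])
    return aff


def write_image(
    data: np.ndarray,
    path: str | Path,
    voxel_size=(1.0, 1.0, 1.0),
    dt: float | None = None,
) -> Path:
    """Write a 3D/4D array as NIfTI; ``dt`` is stored in pixdim[4] (s)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(voxel_size))
    if dt is not None:
        zooms = list(img.header.get_zooms())
        zooms[3] = dt
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units(xyz="mm", t="sec")
    img.to_filename(str(path))
    return path


def read_image(path: str | Path) -> tuple[np.ndarray, nib.Nifti1Image]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"image file not found: {path}")
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img


def _sidecar_path(prefix: Path) -> Path:
    return prefix.with_suffix(".json") if prefix.suffix != ".json" else prefix


def write_run(run: DualEchoPCASLRun, prefix: str | Path) -> Path:
    """Write a dual-echo run: one NIfTI per echo plus a JSON sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    vs = run.acq.voxel_size
    write_image(run.echo1, prefix.parent / f"{prefix.name}_echo1.nii.gz", vs, dt=run.acq.tr)
    write_image(run.echo2, prefix.parent / f"{prefix.name}_echo2.nii.gz", vs, dt=run.acq.tr)
    sidecar = {
        "acquisition": run.acq.to_dict(),
        "tags": [str(t) for t in run.tags],
    }
    side = _sidecar_path(prefix)
    side.write_text(json.dumps(sidecar, indent=2))
    return prefix


def read_run(prefix: str | Path) -> DualEchoPCASLRun:
    prefix = Path(prefix)
    side = _sidecar_path(prefix)
    if not side.exists():
        raise FormatError(f"missing tag sidecar: expected {side}")
    meta = json.loads(side.read_text())
    for key in ("acquisition", "tags"):
        if key not in meta:
            raise FormatError(f"sidecar {side} missing field '{key}'")
    acq = AcquisitionParams.from_dict(meta["acquisition"])
    e1, _ = read_image(prefix.parent / f"{prefix.name}_echo1.nii.gz")
    e2, _ = read_image(prefix.parent / f"{prefix.name}_echo2.nii.gz")
    return DualEchoPCASLRun(echo1=e1, echo2=e2, tags=np.array(meta["tags"]), acq=acq)


def write_separated(sep: SeparatedTimeseries, prefix: str | Path, voxel_size=(1, 1, 1)) -> Path:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_image(sep.bold, prefix.parent / f"{prefix.name}_bold.nii.gz", voxel_size, dt=sep.dt)
    write_image(sep.cbf, prefix.parent / f"{prefix.name}_cbf.nii.gz", voxel_size, dt=sep.dt)
    _sidecar_path(prefix).write_text(json.dumps({"dt": sep.dt, "band": list(sep.band)}))
    return prefix


def read_separated(prefix: str | Path) -> SeparatedTimeseries:
    prefix = Path(prefix)
    side = _sidecar_path(prefix)
    if not side.exists():
        raise FormatError(f"missing separated-series sidecar: expected {side}")
    meta = json.loads(side.read_text())
    bold, _ = read_image(prefix.parent / f"{prefix.name}_bold.nii.gz")
    cbf, _ = read_image(prefix.parent / f"{prefix.name}_cbf.nii.gz")
    return SeparatedTimeseries(bold=bold, cbf=cbf, dt=float(meta["dt"]), band=tuple(meta["band"]))


def write_baseline_run(run: BaselineASLRun, prefix: str | Path, voxel_size=(1, 1, 1)) -> Path:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_image(run.series, prefix.parent / f"{prefix.name}_asl.nii.gz", voxel_size)
    write_image(run.m0, prefix.parent / f"{prefix.name}_m0.nii.gz", voxel_size)
    _sidecar_path(prefix).write_text(json.dumps({"tags": [str(t) for t in run.tags]}))
    return prefix


def read_baseline_run(prefix: str | Path) -> BaselineASLRun:
    prefix = Path(prefix)
    side = _sidecar_path(prefix)
    if not side.exists():
        raise FormatError(f"missing tag sidecar: expected {side}")
    meta = json.loads(side.read_text())
    series, _ = read_image(prefix.parent / f"{prefix.name}_asl.nii.gz")
    m0, _ = read_image(prefix.parent / f"{prefix.name}_m0.nii.gz")
    return BaselineASLRun(series=series, tags=np.array(meta["tags"]), m0=m0)


def write_physio(trace: PhysioTrace, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"cardiac": trace.cardiac, "respiratory": trace.respiratory}
    ).to_csv(path, sep="\t", index=False)
    return path


def read_physio(path: str | Path, sampling_rate: float = 100.0) -> PhysioTrace:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"physio file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    for col in ("cardiac", "respiratory"):
        if col not in df.columns:
            raise FormatError(f"physio file {path} missing column '{col}'")
    return PhysioTrace(
        sampling_rate=sampling_rate,
        cardiac=df["cardiac"].to_numpy(),
        respiratory=df["respiratory"].to_numpy(),
    )


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"table not found: {path}")
    return pd.read_csv(path, sep="\t")
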