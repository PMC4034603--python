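"""Shared containers: acquisition metadata, volumes, echo series, rigid transforms.

Conventions used throughout the package:

* voxel indices are 0-based; voxel-to-world transforms are 4x4 affines in mm
  with world axes right-anterior-superior (RAS);
* rotations are applied about an explicit centre point (by default the grid
  centre of the volume the transform is applied to), in the order x, then y,
  then z (extrinsic axes);
* times are milliseconds, angles are degrees at every public interface and
  converted to radians internally.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
from scipy.spatial.transform import Rotation


# --------------------------------------------------------------------------
# acquisition metadata
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MTPulse:
    """Off-resonance magnetisation-transfer pulse descriptor (metadata only).

    The saturation physics of the pulse is not modelled; its effect enters
    the signal through the per-tissue saturation fraction delta.
    """

    duration_ms: float = 4.0
    flip_deg: float = 220.0
    offset_khz: float = 2.0


@dataclass(frozen=True)
class AcquisitionParams:
    """Sequence settings of one multi-echo FLASH contrast."""

    contrast: str                       # "PDw" | "T1w" | "MTw"
    tr_ms: float
    flip_deg: float
    echo_times_ms: tuple[float, ...]
    mt_pulse: MTPulse | None = None

    def __post_init__(self):
        if self.tr_ms <= 0:
            raise ValueError(f"TR must be positive, got {self.tr_ms}")
        if not (0 < self.flip_deg < 90):
            raise ValueError(f"flip angle must be in (0, 90) deg, got {self.flip_deg}")
        tes = np.asarray(self.echo_times_ms, dtype=float)
        if tes.size == 0 or np.any(np.diff(tes) <= 0):
            raise ValueError("echo times must be non-empty and strictly increasing")
        object.__setattr__(self, "echo_times_ms", tuple(float(t) for t in tes))

    @property
    def flip_rad(self) -> float:
        return float(np.deg2rad(self.flip_deg))

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times_ms)

    def to_sidecar(self) -> dict:
        side = {
            "Contrast": self.contrast,
            "RepetitionTime_ms": self.tr_ms,
            "FlipAngle_deg": self.flip_deg,
            "EchoTimes_ms": list(self.echo_times_ms),
            "MTState": self.mt_pulse is not None,
        }
        if self.mt_pulse is not None:
            side["MTPulse"] = {
                "Duration_ms": self.mt_pulse.duration_ms,
                "FlipAngle_deg": self.mt_pulse.flip_deg,
                "OffsetFrequency_kHz": self.mt_pulse.offset_khz,
            }
        return side

    @classmethod
    def from_sidecar(cls, side: dict, source: str = "<sidecar>") -> "AcquisitionParams":
        for key in ("RepetitionTime_ms", "FlipAngle_deg", "EchoTimes_ms", "MTState"):
            if key not in side:
                raise ValueError(f"{source}: missing required sidecar key {key!r}")
        pulse = None
        if side["MTState"]:
            p = side.get("MTPulse", {})
            pulse = MTPulse(
                duration_ms=p.get("Duration_ms", 4.0),
                flip_deg=p.get("FlipAngle_deg", 220.0),
                offset_khz=p.get("OffsetFrequency_kHz", 2.0),
            )
        return cls(
            contrast=side.get("Contrast", "unknown"),
            tr_ms=float(side["RepetitionTime_ms"]),
            flip_deg=float(side["FlipAngle_deg"]),
            echo_times_ms=tuple(side["EchoTimes_ms"]),
            mt_pulse=pulse,
        )


# --------------------------------------------------------------------------
# rigid transforms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform:
    """Six-parameter rigid mapping of world (mm) coordinates.

    Translations tx/ty/tz in mm, rotations rx/ry/rz in degrees applied in
    the order x, then y, then z about ``center`` (a world point in mm).
    ``center=None`` means "the grid centre of the volume this transform is
    applied to"; it is resolved at application time.

    The matrix maps a world point p to ``R (p - c) + c + t``.
    """

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0
    center: tuple[float, float, float] | None = None

    @property
    def params(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz, self.rx, self.ry, self.rz])

    def matrix(self, center: Sequence[float] | None = None) -> np.ndarray:
        c = self.center if center is None else tuple(center)
        if c is None:
            c = (0.0, 0.0, 0.0)
        c = np.asarray(c, dtype=float)
        rot = Rotation.from_euler("xyz", [self.rx, self.ry, self.rz], degrees=True)
        r = rot.as_matrix()
        m = np.eye(4)
        m[:3, :3] = r
        m[:3, 3] = np.array([self.tx, self.ty, self.tz]) + c - r @ c
        return m

    @classmethod
    def from_matrix(
        cls, m: np.ndarray, center: Sequence[float] | None = None
    ) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        r = m[:3, :3]
        rx, ry, rz = Rotation.from_matrix(r).as_euler("xyz", degrees=True)
        c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        t = m[:3, 3] - c + r @ c
        ctr = None if center is None else tuple(float(x) for x in c)
        return cls(*(float(v) for v in t), float(rx), float(ry), float(rz), center=ctr)

    def inverse(self) -> "RigidTransform":
        c = self.center
        return RigidTransform.from_matrix(
            np.linalg.inv(self.matrix(center=c)), center=c
        )

    def then(self, other: "RigidTransform") -> "RigidTransform":
        """Composition: resampling under the result equals resampling under
        ``self`` followed by resampling under ``other`` (pull semantics)."""
        c = self.center if self.center is not None else other.center
        return RigidTransform.from_matrix(
            self.matrix(center=c) @ other.matrix(center=c), center=c
        )

    def with_center(self, center: Sequence[float]) -> "RigidTransform":
        return replace(self, center=tuple(float(x) for x in center))

    @property
    def translation_mag_mm(self) -> float:
        return float(np.hypot(np.hypot(self.tx, self.ty), self.tz))

    @property
    def rotation_mag_deg(self) -> float:
        rot = Rotation.from_euler("xyz", [self.rx, self.ry, self.rz], degrees=True)
        return float(np.rad2deg(rot.magnitude()))

    @property
    def is_identity(self) -> bool:
        return bool(np.allclose(self.params, 0.0, atol=1e-12))

    def to_dict(self) -> dict:
        return {
            "tx_mm": self.tx, "ty_mm": self.ty, "tz_mm": self.tz,
            "rx_deg": self.rx, "ry_deg": self.ry, "rz_deg": self.rz,
            "center_mm": None if self.center is None else list(self.center),
            "convention": "RAS mm; rotations about center, order x,y,z",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        ctr = d.get("center_mm")
        return cls(
            d["tx_mm"], d["ty_mm"], d["tz_mm"],
            d["rx_deg"], d["ry_deg"], d["rz_deg"],
            center=None if ctr is None else tuple(ctr),
        )


# --------------------------------------------------------------------------
# volumes
# --------------------------------------------------------------------------

def _grid_center_world(shape: Sequence[int], affine: np.ndarray) -> np.ndarray:
    c_vox = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    return (affine[:3, :3] @ c_vox) + affine[:3, 3]


@dataclass
class Volume3D:
    """A 3D scalar grid with its voxel-to-world affine and optional mask."""

    data: np.ndarray
    affine: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D expects 3D data, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def center_world(self) -> np.ndarray:
        return _grid_center_world(self.shape, self.affine)

    def with_data(self, data: np.ndarray, mask: np.ndarray | None = None) -> "Volume3D":
        return Volume3D(data, self.affine.copy(), mask)

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(np.asarray(self.data, dtype=np.float64), self.affine),
                 str(path))

    @classmethod
    def load(cls, path: str | Path) -> "Volume3D":
        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata()), np.asarray(img.affine))


@dataclass
class EchoSeries:
    """A 4D (space x echo) signal bound to its acquisition parameters."""

    data: np.ndarray                    # (nx, ny, nz, n_echoes)
    affine: np.ndarray
    acq: AcquisitionParams

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"EchoSeries expects 4D data, got shape {self.data.shape}")
        if self.data.shape[3] != self.acq.n_echoes:
            raise ValueError(
                f"echo dimension {self.data.shape[3]} does not match "
                f"{self.acq.n_echoes} echo times"
            )
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_echoes(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def center_world(self) -> np.ndarray:
        return _grid_center_world(self.shape, self.affine)

    def echo(self, i: int) -> Volume3D:
        return Volume3D(self.data[..., i], self.affine.copy())

    def select(self, indices: Sequence[int]) -> "EchoSeries":
        idx = list(indices)
        acq = replace(self.acq,
                      echo_times_ms=tuple(self.acq.echo_times_ms[i] for i in idx))
        return EchoSeries(self.data[..., idx], self.affine.copy(), acq)

    def save(self, path: str | Path, sidecar: bool = True) -> None:
        path = Path(path)
        nib.save(nib.Nifti1Image(self.data, self.affine), str(path))
        if sidecar:
            name = path.name
            for suffix in (".nii.gz", ".nii"):
                if name.endswith(suffix):
                    name = name[: -len(suffix)]
                    break
            (path.parent / f"{name}.json").write_text(
                json.dumps(self.acq.to_sidecar(), indent=2)
            )

    @classmethod
    def load(cls, path: str | Path) -> "EchoSeries":
        path = Path(path)
        img = nib.load(str(path))
        name = path.name
        for suffix in (".nii.gz", ".nii"):
            if name.endswith(suffix):
                name = name[: -len(suffix)]
                break
        sidecar_path = path.parent / f"{name}.json"
        if not sidecar_path.exists():
            raise FileNotFoundError(f"missing JSON sidecar for {path}: {sidecar_path}")
        acq = AcquisitionParams.from_sidecar(
            json.loads(sidecar_path.read_text()), source=str(sidecar_path)
        )
        data = np.asarray(img.get_fdata())
        if data.ndim == 3:
            data = data[..., None]
        return cls(data, np.asarray(img.affine), acq)


def echo_indices(subset: str | Sequence[int], n_echoes: int) -> list[int]:
    """Resolve an echo-subset name into explicit 0-based indices.

    ``odd``/``even`` refer to 1-based echo numbers, so ``odd`` is echoes
    1, 3, 5, ... (indices 0, 2, 4, ...).
    """
    if isinstance(subset, str):
        if subset == "all":
            return list(range(n_echoes))
        if subset == "odd":
            return list(range(0, n_echoes, 2))
        if subset == "even":
            return list(range(1, n_echoes, 2))
        if subset.startswith("first_"):
            k = int(subset.split("_", 1)[1])
            if not (1 <= k <= n_echoes):
                raise ValueError(f"first_{k} out of range for {n_echoes} echoes")
            return list(range(k))
        raise ValueError(f"unknown echo subset {subset!r}")
    idx = [int(i) for i in subset]
    if len(idx) == 0:
        raise ValueError("echo subset must be non-empty")
    if any(i < 0 or i >= n_echoes for i in idx):
        raise ValueError(f"echo indices {idx} out of range for {n_echoes} echoes")
    return idx


# --------------------------------------------------------------------------
# fitted maps
# --------------------------------------------------------------------------

MAP_NAMES = ("APD", "T1", "R1", "MTsat", "MTR", "R2star")
MAP_UNITS = {
    "APD": "a.u.", "T1": "ms", "R1": "s^-1",
    "MTsat": "p.u.", "MTR": "p.u.", "R2star": "s^-1",
}


@dataclass
class ParameterMaps:
    """Co-registered voxelwise quantitative maps sharing one grid.

    Invalid voxels hold NaN and are excluded by the per-map boolean masks.
    """

    apd: np.ndarray
    t1_ms: np.ndarray
    r1_s: np.ndarray
    mtsat_pu: np.ndarray
    mtr_pu: np.ndarray
    r2star_s: np.ndarray
    affine: np.ndarray
    masks: dict = field(default_factory=dict)
    echo_subset: str = "all"

    _FIELD_OF = {
        "APD": "apd", "T1": "t1_ms", "R1": "r1_s",
        "MTsat": "mtsat_pu", "MTR": "mtr_pu", "R2star": "r2star_s",
    }

    def __getitem__(self, name: str) -> np.ndarray:
        return getattr(self, self._FIELD_OF[name])

    def mask(self, name: str) -> np.ndarray:
        m = self.masks.get(name)
        if m is None:
            m = np.isfinite(self[name])
        return m

    def items(self) -> Iterable[tuple[str, np.ndarray]]:
        for name in MAP_NAMES:
            yield name, self[name]

    def save(self, out_dir: str | Path, prefix: str = "") -> dict:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = {}
        for name, arr in self.items():
            img = nib.Nifti1Image(np.asarray(arr, dtype=np.float64), self.affine)
            img.header["descrip"] = f"{name} [{MAP_UNITS[name]}]".encode()
            path = out_dir / f"{prefix}{name}.nii"
            nib.save(img, str(path))
            written[name] = str(path)
        return written
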