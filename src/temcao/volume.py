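"""Core image containers and NIfTI / sidecar I/O.

Axis convention throughout the package: arrays are indexed ``(x, y, z)``
with ``x`` running left-to-right, ``y`` posterior-to-anterior and ``z``
across slices, 0-based voxel indices.  World coordinates are in mm, the
center of voxel ``(0, 0, 0)`` sits at the world origin, and the atlas
midline is the sagittal ``x`` mid-plane.  The ipsilateral (stroked)
hemisphere is the right one, ``x`` above the midline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "QuantVolume",
    "EchoSeries",
    "DWISeries",
    "load_volume",
    "load_series",
]


@dataclass
class QuantVolume:
    """A 3-D scalar field with isotropic-or-not voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        return aff

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine())
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))


def load_volume(path: str | Path) -> QuantVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return QuantVolume(data, spacing)


def _check_4d(signal: np.ndarray, n_last: int, what: str) -> np.ndarray:
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 4:
        raise ValueError(f"{what} must be 4-D (x, y, z, acquisition)")
    if signal.shape[3] != n_last:
        raise ValueError(
            f"{what}: 4th dimension {signal.shape[3]} does not match "
            f"acquisition list length {n_last}"
        )
    return signal


@dataclass
class EchoSeries:
    """Multi-echo T2-weighted stack: 4-D signal plus echo times in ms."""

    signal: np.ndarray
    te_list_ms: tuple[float, ...]
    spacing: tuple[float, float, float] = (0.15, 0.15, 0.15)

    def __post_init__(self) -> None:
        self.te_list_ms = tuple(float(t) for t in self.te_list_ms)
        if len(self.te_list_ms) < 2:
            raise ValueError("need at least two echoes")
        if any(t <= 0 for t in self.te_list_ms):
            raise ValueError("echo times must be positive")
        if any(b >= a for b, a in zip(self.te_list_ms, self.te_list_ms[1:])):
            raise ValueError(f"echo times must be strictly ascending: {self.te_list_ms}")
        self.signal = _check_4d(self.signal, len(self.te_list_ms), "echo series")
        self.spacing = tuple(float(s) for s in self.spacing)

    def volume(self, index: int) -> QuantVolume:
        return QuantVolume(self.signal[..., index], self.spacing)

    def save(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        img = nib.Nifti1Image(self.signal.astype(np.float32), np.diag(list(self.spacing) + [1.0]))
        nib.save(img, str(path))
        if sidecar is not None:
            Path(sidecar).write_text(
                json.dumps({"EchoTime": list(self.te_list_ms), "EchoTimeUnits": "ms"}, indent=2)
            )


@dataclass
class DWISeries:
    """Diffusion-weighted stack: 4-D signal plus b-values in s/mm²."""

    signal: np.ndarray
    b_values: tuple[float, ...]
    spacing: tuple[float, float, float] = (0.15, 0.15, 0.15)

    def __post_init__(self) -> None:
        self.b_values = tuple(float(b) for b in self.b_values)
        if len(set(self.b_values)) < 2:
            raise ValueError("need at least two distinct b-values")
        if any(b < 0 for b in self.b_values):
            raise ValueError("b-values must be non-negative")
        if any(b >= a for b, a in zip(self.b_values, self.b_values[1:])):
            raise ValueError(f"b-values must be strictly ascending: {self.b_values}")
        if self.b_values[0] != 0:
            raise ValueError("a b=0 acquisition is required")
        self.signal = _check_4d(self.signal, len(self.b_values), "DWI series")
        self.spacing = tuple(float(s) for s in self.spacing)

    def volume(self, index: int) -> QuantVolume:
        return QuantVolume(self.signal[..., index], self.spacing)

    def save(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        img = nib.Nifti1Image(self.signal.astype(np.float32), np.diag(list(self.spacing) + [1.0]))
        nib.save(img, str(path))
        if sidecar is not None:
            Path(sidecar).write_text(
                json.dumps({"bval": list(self.b_values), "bvalUnits": "s/mm^2"}, indent=2)
            )


def load_series(path: str | Path, sidecar: str | Path):
    """Load a 4-D NIfTI plus its JSON sidecar into the matching series type.

    The sidecar must carry either an ``EchoTime`` list (ms) or a ``bval``
    list (s/mm²).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    meta = json.loads(Path(sidecar).read_text())
    if "EchoTime" in meta:
        return EchoSeries(data, tuple(meta["EchoTime"]), spacing)
    if "bval" in meta:
        return DWISeries(data, tuple(meta["bval"]), spacing)
    raise ValueError(f"sidecar {sidecar} has neither 'EchoTime' nor 'bval'")
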