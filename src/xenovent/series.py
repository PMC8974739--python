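"""The dual-energy image series container and its on-disk format.

A :class:`DualEnergySeries` is the pipeline's image currency: a time-indexed
set of 3-D Hounsfield-unit volumes, one per spectral channel.  The scanner
acquires two tube spectra simultaneously (``low_kv``, ``high_kv``) and blends
them into a routine-reading ``mixed`` image; any subset of the three may be
present.

On disk a series is one uncompressed 4-D NIfTI file per channel
(``series_<channel>.nii``, time on the 4th axis) plus a JSON sidecar
(``series.json``) holding frame timestamps, the channel list, and
provenance.  The round trip is lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import nibabel as nib
import numpy as np

from .errors import MissingChannelError, ShapeMismatchError, SidecarError

__all__ = ["DualEnergySeries", "write_series", "read_series", "CHANNELS"]

#: Canonical channel names in storage order.
CHANNELS = ("low_kv", "high_kv", "mixed")

SIDECAR_NAME = "series.json"


@dataclass
class DualEnergySeries:
    """Time-indexed multi-channel HU volumes on a fixed voxel grid.

    Attributes
    ----------
    frame_times
        Strictly increasing acquisition timestamps in seconds, length T.
    volumes
        Mapping channel name -> float array of shape ``(T, nx, ny, nz)``.
    voxel_mm
        Voxel edge lengths in millimetres.
    provenance
        Free-form metadata (phantom spec echo or acquisition details).
    """

    frame_times: np.ndarray
    volumes: dict[str, np.ndarray]
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    provenance: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.ndim != 1:
            raise ShapeMismatchError("frame_times must be 1-D")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ShapeMismatchError("frame_times must be strictly increasing")
        if not self.volumes:
            raise MissingChannelError("series holds no channels")
        shapes = {v.shape for v in self.volumes.values()}
        if len(shapes) != 1:
            raise ShapeMismatchError(f"channel shapes differ: {sorted(shapes)}")
        (shape,) = shapes
        if len(shape) != 4 or shape[0] != self.frame_times.size:
            raise ShapeMismatchError(
                f"volumes must be (T, nx, ny, nz) with T = {self.frame_times.size}, "
                f"got {shape}"
            )

    @property
    def n_frames(self) -> int:
        return int(self.frame_times.size)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return next(iter(self.volumes.values())).shape[1:]

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.volumes)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.volumes[name]
        except KeyError:
            raise MissingChannelError(
                f"channel {name!r} not in series (has {sorted(self.volumes)})"
            ) from None


def write_series(series: DualEnergySeries, path: str | Path) -> Path:
    """Write ``series`` under directory ``path``; returns the sidecar path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*series.voxel_mm, 1.0])
    for ch, vol in series.volumes.items():
        # NIfTI wants time last.
        img = nib.Nifti1Image(np.moveaxis(vol, 0, -1), affine)
        img.header.set_xyzt_units("mm", "sec")
        nib.save(img, path / f"series_{ch}.nii")
    sidecar = {
        "frame_times_s": series.frame_times.tolist(),
        "channels": list(series.volumes),
        "grid_shape": list(series.grid_shape),
        "voxel_mm": list(series.voxel_mm),
        "provenance": dict(series.provenance),
    }
    out = path / SIDECAR_NAME
    out.write_text(json.dumps(sidecar, indent=1))
    return out


def read_series(path: str | Path) -> DualEnergySeries:
    """Read a series directory written by :func:`write_series`.

    Raises
    ------
    SidecarError
        Missing/corrupt sidecar, missing channel file, or a 4-D extent that
        disagrees with the sidecar's frame count.
    """
    path = Path(path)
    sidecar_path = path / SIDECAR_NAME
    if not sidecar_path.exists():
        raise SidecarError(f"missing sidecar {sidecar_path}")
    try:
        meta = json.loads(sidecar_path.read_text())
        frame_times = np.asarray(meta["frame_times_s"], dtype=float)
        channels = list(meta["channels"])
    except (KeyError, ValueError, TypeError) as exc:
        raise SidecarError(f"corrupt sidecar {sidecar_path}: {exc}") from exc

    volumes: dict[str, np.ndarray] = {}
    for ch in channels:
        f = path / f"series_{ch}.nii"
        if not f.exists():
            raise SidecarError(f"sidecar lists channel {ch!r} but {f} is missing")
        data = np.asarray(nib.load(f).dataobj, dtype=np.float64)
        if data.ndim != 4 or data.shape[-1] != frame_times.size:
            raise SidecarError(
                f"{f}: 4-D time extent {data.shape} does not match sidecar "
                f"frame count {frame_times.size}"
            )
        volumes[ch] = np.moveaxis(data, -1, 0)
    return DualEnergySeries(
        frame_times=frame_times,
        volumes=volumes,
        voxel_mm=tuple(meta.get("voxel_mm", (1.0, 1.0, 1.0))),
        provenance=meta.get("provenance", {}),
    )
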