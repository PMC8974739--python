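"""Named ROI masks and time-density-curve extraction.

An ROI is a boolean voxel mask over the series grid; its time-density curve
(TDC) is the arithmetic mean HU inside the mask at every frame.  With the
published pre-surgery schedule a TDC holds 46 samples 1.5 s apart.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import EmptyMaskError, MissingLabelError, ShapeMismatchError
from .phantom import Region
from .series import DualEnergySeries

__all__ = ["RoiSet", "TimeDensityCurve", "rois_from_labels", "extract_tdc",
           "extract_all_tdcs", "tdcs_to_frame"]


@dataclass
class RoiSet:
    """Uniquely named boolean masks sharing one grid shape."""

    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ShapeMismatchError(f"ROI masks have mixed shapes: {sorted(shapes)}")
        for name, m in self.masks.items():
            if not m.any():
                raise EmptyMaskError(f"ROI {name!r} selects no voxels")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.masks)

    def write(self, path: str | Path) -> None:
        """Store as a NIfTI label volume plus a JSON name table."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        shape = next(iter(self.masks.values())).shape
        lab = np.zeros(shape, dtype=np.int16)
        table = {}
        for i, (name, mask) in enumerate(self.masks.items(), start=1):
            lab[mask] = i
            table[name] = i
        nib.save(nib.Nifti1Image(lab, np.eye(4)), path / "rois.nii")
        (path / "roi_names.json").write_text(json.dumps(table, indent=1))

    @classmethod
    def read(cls, path: str | Path) -> "RoiSet":
        path = Path(path)
        names = json.loads((path / "roi_names.json").read_text())
        lab = np.asarray(nib.load(path / "rois.nii").dataobj)
        return cls({name: lab == i for name, i in names.items()})


@dataclass
class TimeDensityCurve:
    """Mean HU of one ROI per frame."""

    roi_name: str
    times: np.ndarray
    hu: np.ndarray
    n_voxels: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.hu = np.asarray(self.hu, dtype=float)
        if self.times.shape != self.hu.shape:
            raise ValueError("times and hu must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def rois_from_labels(
    label_volume: np.ndarray,
    names: Iterable[str],
    erosion_voxels: int = 0,
    label_ids: Mapping[str, int] | None = None,
) -> RoiSet:
    """Build ROI masks as the exact support of integer labels.

    Parameters
    ----------
    names
        Region names to extract; by default resolved against the phantom's
        :class:`~xenovent.phantom.Region` vocabulary.
    erosion_voxels
        Optional binary erosion (in voxels) applied to each mask, e.g. to
        keep readings away from partial-volume edges.

    Raises
    ------
    MissingLabelError
        A requested name is absent from the volume.
    EmptyMaskError
        Erosion removed a region entirely.
    """
    if label_ids is None:
        label_ids = {r.name: int(r) for r in Region}
    masks: dict[str, np.ndarray] = {}
    for name in names:
        if name not in label_ids:
            raise MissingLabelError(f"unknown region name {name!r}")
        mask = label_volume == label_ids[name]
        if not mask.any():
            raise MissingLabelError(f"label {name!r} has no voxels in this volume")
        if erosion_voxels > 0:
            mask = ndimage.binary_erosion(mask, iterations=erosion_voxels)
            if not mask.any():
                raise EmptyMaskError(
                    f"eroding ROI {name!r} by {erosion_voxels} voxel(s) left it empty"
                )
        masks[name] = mask
    return RoiSet(masks)


def extract_tdc(
    series: DualEnergySeries,
    mask: np.ndarray,
    channel: str = "mixed",
    roi_name: str = "roi",
) -> TimeDensityCurve:
    """Mean HU over ``mask`` at every frame of ``channel``.

    Raises
    ------
    EmptyMaskError / ShapeMismatchError
        For an empty mask or a mask on the wrong grid.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.grid_shape:
        raise ShapeMismatchError(
            f"mask shape {mask.shape} does not match series grid {series.grid_shape}"
        )
    if not mask.any():
        raise EmptyMaskError(f"ROI {roi_name!r} selects no voxels")
    vol = series.channel(channel)
    hu = vol[:, mask].mean(axis=1)
    return TimeDensityCurve(roi_name, series.frame_times, hu, int(mask.sum()))


def extract_all_tdcs(
    series: DualEnergySeries,
    rois: RoiSet,
    channel: str = "mixed",
) -> dict[str, TimeDensityCurve]:
    """One TDC per ROI in ``rois``."""
    return {
        name: extract_tdc(series, mask, channel, roi_name=name)
        for name, mask in rois.masks.items()
    }


def tdcs_to_frame(curves: Mapping[str, TimeDensityCurve]) -> pd.DataFrame:
    """Tidy export: columns ``roi, time_s, hu, n_voxels``."""
    rows = [
        pd.DataFrame(
            {"roi": c.roi_name, "time_s": c.times, "hu": c.hu, "n_voxels": c.n_voxels}
        )
        for c in curves.values()
    ]
    if not rows:
        return pd.DataFrame(columns=["roi", "time_s", "hu", "n_voxels"])
    return pd.concat(rows, ignore_index=True)
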