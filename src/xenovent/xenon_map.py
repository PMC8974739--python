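"""Voxel-wise xenon enhancement maps and color overlays.

Replaces the vendor dual-energy post-processing step: converts a
:class:`~xenovent.series.DualEnergySeries` into per-frame enhancement
volumes, optionally combines the two spectral channels into a
material-specific xenon signal, and fuses a map with a grayscale frame for
display.

Two baselines are supported for enhancement:

``frame`` mode
    Subtract the per-voxel mean over a pre-xenon baseline window.  Any
    temporally stable material (tissue, bone) cancels exactly, so gas-free
    voxels sit near zero regardless of their HU.

``constant`` mode
    Subtract the room-air value of -1000 HU (enhancement = HU + 1000).
    This is the arithmetic used for gas-space readings: -750 HU (100%
    xenon) maps to 250 HU of enhancement.  Outside gas spaces it returns
    the offset tissue HU, which is why frame mode exists.
"""

from __future__ import annotations

import numpy as np
from matplotlib import colormaps

from .errors import EmptyBaselineError, MissingChannelError, ShapeMismatchError
from .protocol import Gas, Protocol, first_gas_onset
from .series import DualEnergySeries

__all__ = [
    "default_baseline_window",
    "temporal_enhancement",
    "spectral_xenon_map",
    "fuse_overlay",
]

ROOM_AIR_HU = -1000.0


def default_baseline_window(protocol: Protocol) -> tuple[float, float]:
    """``[0, first xenon onset)`` — the protocol's own room-air frames.

    For the published schedules this is [0, 10.5) s, i.e. 7 frames.
    """
    return (0.0, first_gas_onset(protocol, Gas.XENON))


def temporal_enhancement(
    series: DualEnergySeries,
    channel: str = "mixed",
    baseline_window: tuple[float, float] | None = None,
    mode: str = "frame",
) -> np.ndarray:
    """Per-frame enhancement volumes ``E(v, t)``, shape ``(T, nx, ny, nz)``.

    Parameters
    ----------
    channel
        Which spectral channel to read.
    baseline_window
        Half-open time interval whose frames define the per-voxel baseline
        (frame mode only).  Required in frame mode.
    mode
        ``"frame"`` subtracts the baseline-window mean per voxel;
        ``"constant"`` subtracts -1000 HU.

    Raises
    ------
    EmptyBaselineError
        Frame mode with a window containing no frames (or no window).
    """
    vol = series.channel(channel)
    if mode == "constant":
        return vol - ROOM_AIR_HU
    if mode != "frame":
        raise ValueError(f"mode must be 'frame' or 'constant', got {mode!r}")
    if baseline_window is None:
        raise EmptyBaselineError("frame mode requires a baseline_window")
    t0, t1 = baseline_window
    sel = (series.frame_times >= t0) & (series.frame_times < t1)
    if not np.any(sel):
        raise EmptyBaselineError(
            f"baseline window [{t0}, {t1}) s contains no frames"
        )
    baseline = vol[sel].mean(axis=0)
    return vol - baseline[None]


def spectral_xenon_map(
    series: DualEnergySeries,
    alpha: float = 1.0,
    baseline_window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Weighted spectral difference of frame-mode enhancements.

    ``X(v,t) = dE_low(v,t) - alpha * dE_high(v,t)``.  Under the phantom's
    rendering model this equals ``C * (e100_low - alpha * e100_high)`` —
    proportional to xenon concentration for any alpha except the degenerate
    ratio ``e100_low / e100_high``.  Because the inputs are temporal
    enhancements, stable materials cancel for every alpha; the spectral
    combination serves as a validation / denoising path rather than being
    required for quantification.

    Raises
    ------
    MissingChannelError
        If either spectral channel is absent.
    """
    for ch in ("low_kv", "high_kv"):
        if ch not in series.volumes:
            raise MissingChannelError(f"spectral xenon map needs channel {ch!r}")
    d_low = temporal_enhancement(series, "low_kv", baseline_window, mode="frame")
    d_high = temporal_enhancement(series, "high_kv", baseline_window, mode="frame")
    return d_low - alpha * d_high


def fuse_overlay(
    xenon_frame: np.ndarray,
    grayscale_frame: np.ndarray,
    window: tuple[float, float] = (-1000.0, 500.0),
    signal_max: float | None = None,
    cmap: str = "hot",
) -> np.ndarray:
    """Fuse a xenon-signal frame onto a windowed grayscale frame as RGB.

    The grayscale frame is windowed to [0, 1]; positive xenon signal is
    normalized by ``signal_max`` (its own maximum when None) and alpha-blends
    a monotone color ramp over the base.  Zero or negative signal leaves the
    grayscale untouched.  Purely deterministic; returns a float array in
    [0, 1] with a trailing RGB axis.

    Raises
    ------
    ShapeMismatchError
        If the two frames differ in shape.
    """
    xenon_frame = np.asarray(xenon_frame, dtype=float)
    grayscale_frame = np.asarray(grayscale_frame, dtype=float)
    if xenon_frame.shape != grayscale_frame.shape:
        raise ShapeMismatchError(
            f"xenon frame {xenon_frame.shape} vs grayscale {grayscale_frame.shape}"
        )
    lo, hi = window
    gray = np.clip((grayscale_frame - lo) / (hi - lo), 0.0, 1.0)
    rgb = np.stack([gray] * 3, axis=-1)

    pos = np.clip(xenon_frame, 0.0, None)
    if signal_max is None:
        signal_max = float(pos.max()) if pos.max() > 0 else 1.0
    w = np.clip(pos / signal_max, 0.0, 1.0)
    ramp = colormaps[cmap](w)[..., :3]
    return rgb * (1.0 - w[..., None]) + ramp * w[..., None]
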