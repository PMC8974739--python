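"""Synthetic dual-energy CT head phantom with compartmental gas exchange.

The phantom stands in for a cadaver-head ventilation experiment: a stylized
labeled head volume (two nasal cavities, paired maxillary / sphenoid /
frontal sinuses, soft tissue, a bone shell, background air), a first-order
compartment model of xenon exchange driven by the gas-delivery protocol, and
a dual-energy HU renderer in which xenon enhancement is linear in local
xenon concentration.

Compartment model
-----------------
The nasal cavities are directly ventilated and follow the supply gas with a
short time constant ``nasal_tau_s``::

    dC_nasal/dt = (G(t) - C_nasal) / nasal_tau_s

where ``G(t) = 1`` while xenon is supplied and ``0`` during room air.  Each
sinus exchanges gas with the nasal cavity through its ostium at a rate that
depends on the flow regime (laminar vs pulsating) and on the direction of
exchange (wash-in under xenon supply, wash-out under room air)::

    xenon supply:   dC_sinus/dt = k(flow, in)  * (c_eq * C_nasal(t) - C_sinus)
    room-air supply: dC_sinus/dt = -k(flow, out) * C_sinus

``c_eq`` caps the accessible equilibrium fraction of the sinus.  During
washout the ostium stream is modeled as xenon-free: the supply flushes the
nasal cavity on a time scale (``nasal_tau_s`` = 2.5 s) short against sinus
exchange, so sinus washout is a plain first-order decline — the functional
form the time-constant fits assume, and the monotone behaviour observed.
Within any phase the drivers are fixed, so the system has a
nested-exponential closed form which is evaluated analytically phase by
phase and sampled on the protocol's frame clock.

Rendering
---------
Per voxel with label L at frame time t and spectral channel ch::

    HU(v, t) = baseline_hu(L) + C_L(t) * e100_hu(ch) + Normal(0, noise_sigma_hu)

``e100_hu`` is the full-xenon enhancement of the channel; the mixed-image
default of 250 HU reproduces the -1000 HU (room air) to -750 HU (100% xenon)
span.  The xenon term applies only to gas-space labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    GridTooSmallError,
    MissingKineticsError,
    TraceFrameMismatchError,
    UnknownVariantError,
)
from .protocol import Flow, Gas, Protocol, frame_times
from .series import CHANNELS, DualEnergySeries

__all__ = [
    "Region",
    "GAS_REGIONS",
    "SINUS_REGIONS",
    "NASAL_REGIONS",
    "CompartmentKinetics",
    "PhantomSpec",
    "ConcentrationTrace",
    "default_kinetics",
    "simulate_concentrations",
    "build_label_map",
    "render_series",
    "simulate_phantom",
]


class Region(IntEnum):
    """Integer labels of the phantom's voxel partition."""

    background_air = 0
    soft_tissue = 1
    bone = 2
    nasal_left = 3
    nasal_right = 4
    maxillary_L = 5
    maxillary_R = 6
    sphenoid_L = 7
    sphenoid_R = 8
    frontal_L = 9
    frontal_R = 10


NASAL_REGIONS = (Region.nasal_left, Region.nasal_right)
SINUS_REGIONS = (
    Region.maxillary_L,
    Region.maxillary_R,
    Region.sphenoid_L,
    Region.sphenoid_R,
    Region.frontal_L,
    Region.frontal_R,
)
#: Labels whose HU responds to xenon (air-filled spaces reached by the gas).
GAS_REGIONS = NASAL_REGIONS + SINUS_REGIONS


@dataclass(frozen=True)
class CompartmentKinetics:
    """Ostium exchange rates of one sinus, per flow regime and direction.

    ``k_laminar`` / ``k_pulsating`` are the wash-in rates (xenon supply);
    the ``*_out`` fields are the wash-out rates (room-air supply) and default
    to the wash-in values.  A rate of 0 means no exchange under that regime.
    ``c_eq`` is the accessible equilibrium fraction: the sinus concentration
    relaxes toward ``c_eq * C_nasal``.
    """

    name: str
    k_laminar: float
    k_pulsating: float
    c_eq: float = 1.0
    k_laminar_out: float | None = None
    k_pulsating_out: float | None = None

    def __post_init__(self) -> None:
        for f in ("k_laminar", "k_pulsating", "k_laminar_out", "k_pulsating_out"):
            v = getattr(self, f)
            if v is not None and v < 0:
                raise ValueError(f"{f} must be >= 0, got {v}")
        if not 0.0 <= self.c_eq <= 1.0:
            raise ValueError(f"c_eq must be in [0, 1], got {self.c_eq}")

    def rate(self, flow: Flow, gas: Gas) -> float:
        """Exchange rate for the given flow regime and supply gas."""
        if gas == Gas.XENON:
            return self.k_laminar if flow == Flow.LAMINAR else self.k_pulsating
        if flow == Flow.LAMINAR:
            return self.k_laminar if self.k_laminar_out is None else self.k_laminar_out
        return self.k_pulsating if self.k_pulsating_out is None else self.k_pulsating_out


def default_kinetics(variant: str) -> dict[str, CompartmentKinetics]:
    """Preset per-sinus exchange-rate tables for the two study conditions.

    Pre-surgery: only pulsation moves gas through intact maxillary/frontal
    ostia (wash-in tau of 7 s left / 18 s right maxillary, active pulsating
    washout tau of 6 s); the left sphenoid has a wide natural ostium and fills
    already under laminar flow; frontal sinuses barely ventilate (~10% peak).
    Post-surgery: widened ostia make the sinuses part of the directly
    ventilated space, pulsation adds nothing, maxillary plateau ~90%.
    """
    if variant == "pre_fess":
        return {
            "maxillary_L": CompartmentKinetics(
                "maxillary_L", k_laminar=0.0, k_pulsating=1 / 7,
                k_laminar_out=1 / 60, k_pulsating_out=1 / 6),
            "maxillary_R": CompartmentKinetics(
                "maxillary_R", k_laminar=0.0, k_pulsating=1 / 18,
                k_laminar_out=1 / 60, k_pulsating_out=1 / 6),
            "sphenoid_L": CompartmentKinetics(
                "sphenoid_L", k_laminar=1 / 10, k_pulsating=1 / 8, c_eq=0.9,
                k_laminar_out=1 / 60, k_pulsating_out=1 / 8),
            "sphenoid_R": CompartmentKinetics(
                "sphenoid_R", k_laminar=0.0, k_pulsating=1 / 8,
                k_laminar_out=1 / 60, k_pulsating_out=1 / 8),
            "frontal_L": CompartmentKinetics(
                "frontal_L", k_laminar=0.0, k_pulsating=1 / 170,
                k_laminar_out=1 / 60, k_pulsating_out=1 / 30),
            "frontal_R": CompartmentKinetics(
                "frontal_R", k_laminar=0.0, k_pulsating=1 / 170,
                k_laminar_out=1 / 60, k_pulsating_out=1 / 30),
        }
    if variant == "post_fess":
        fast = dict(k_laminar=1 / 4, k_pulsating=1 / 4, c_eq=0.9)
        slow = dict(k_laminar=1 / 12, k_pulsating=1 / 12, c_eq=0.6)
        return {
            "maxillary_L": CompartmentKinetics("maxillary_L", **fast),
            "maxillary_R": CompartmentKinetics("maxillary_R", **fast),
            "sphenoid_L": CompartmentKinetics("sphenoid_L", **slow),
            "sphenoid_R": CompartmentKinetics("sphenoid_R", **fast),
            "frontal_L": CompartmentKinetics("frontal_L", **slow),
            "frontal_R": CompartmentKinetics("frontal_R", **slow),
        }
    raise UnknownVariantError(
        f"unknown kinetics variant {variant!r}; expected 'pre_fess' or 'post_fess'"
    )


def _default_baseline_hu() -> dict[str, float]:
    air = -1000.0
    return {
        "background_air": air,
        "soft_tissue": 40.0,
        "bone": 700.0,
        **{r.name: air for r in GAS_REGIONS},
    }


def _default_e100_hu() -> dict[str, float]:
    # Mixed-image value pinned by the -750 vs -1000 HU span; the spectral
    # split (stronger photoelectric xenon enhancement at the softer spectrum)
    # is a configurable model choice.
    return {"low_kv": 330.0, "high_kv": 175.0, "mixed": 250.0}


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic experiment."""

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    nasal_tau_s: float = 2.5
    compartments: Mapping[str, CompartmentKinetics] = field(
        default_factory=lambda: default_kinetics("pre_fess"))
    baseline_hu: Mapping[str, float] = field(default_factory=_default_baseline_hu)
    e100_hu: Mapping[str, float] = field(default_factory=_default_e100_hu)
    noise_sigma_hu: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if self.nasal_tau_s <= 0:
            raise ValueError("nasal_tau_s must be positive")
        if self.noise_sigma_hu < 0:
            raise ValueError("noise_sigma_hu must be >= 0")
        if any(v <= 0 for v in self.e100_hu.values()):
            raise ValueError("e100_hu values must be positive")

    @classmethod
    def for_variant(cls, variant: str, **overrides) -> "PhantomSpec":
        """Spec with the preset kinetics table for ``variant``."""
        return cls(compartments=default_kinetics(variant), **overrides)


@dataclass
class ConcentrationTrace:
    """Simulated fractional xenon concentration of one region over time."""

    region: str
    times: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.times.shape != self.c.shape:
            raise ValueError("times and c must have equal length")
        if self.c.size and not (self.c.min() >= 0.0 and self.c.max() <= 1.0):
            raise ValueError("concentrations must lie in [0, 1]")


def _nasal_phase(s: np.ndarray, c0: float, g: float, a: float) -> np.ndarray:
    return g + (c0 - g) * np.exp(-a * s)


def _sinus_phase(s: np.ndarray, c0: float, k: float, c_eq: float,
                 g: float, cn0: float, a: float) -> np.ndarray:
    """Closed-form sinus concentration within one phase.

    Driver is ``c_eq * C_nasal(s)`` with ``C_nasal(s) = g + (cn0-g)e^{-a s}``;
    the solution is a sum of two exponentials (one secular term when the
    sinus rate coincides with the nasal rate).
    """
    if k == 0.0:
        return np.full_like(np.asarray(s, dtype=float), c0)
    amp = c_eq * (cn0 - g)
    geq = c_eq * g
    if abs(k - a) <= 1e-12 * max(k, a):
        return geq + (c0 - geq) * np.exp(-k * s) + k * amp * s * np.exp(-k * s)
    d = k * amp / (k - a)
    return geq + d * np.exp(-a * s) + (c0 - geq - d) * np.exp(-k * s)


def simulate_concentrations(
    spec: PhantomSpec, protocol: Protocol
) -> dict[str, ConcentrationTrace]:
    """Exact piecewise closed-form concentrations sampled at frame times.

    Returns one trace per gas-space region (both nasal cavities share the
    supply dynamics).  All traces start at 0 and stay within [0, 1]; within
    any phase each trace moves monotonically toward its local target.

    Raises
    ------
    MissingKineticsError
        If a sinus label has no entry in ``spec.compartments``.
    """
    missing = [r.name for r in SINUS_REGIONS if r.name not in spec.compartments]
    if missing:
        raise MissingKineticsError(
            f"spec.compartments lacks kinetics for sinus region(s): {missing}"
        )

    times = frame_times(protocol)
    a = 1.0 / spec.nasal_tau_s
    sinus_names = [r.name for r in SINUS_REGIONS]

    nasal_vals = np.empty_like(times)
    sinus_vals = {n: np.empty_like(times) for n in sinus_names}
    cn = 0.0
    cs = {n: 0.0 for n in sinus_names}

    for phase in protocol.phases:
        g = 1.0 if phase.gas == Gas.XENON else 0.0
        in_phase = (times >= phase.start_s) & (times < phase.end_s)
        s = times[in_phase] - phase.start_s
        nasal_vals[in_phase] = _nasal_phase(s, cn, g, a)
        dur = phase.duration_s
        # During room-air supply the sinus sees a xenon-free stream: pure
        # first-order decline (driver clamped to zero, see module docstring).
        cn_drv = cn if g == 1.0 else 0.0
        g_drv = g
        for n in sinus_names:
            kin = spec.compartments[n]
            k = kin.rate(phase.flow, phase.gas)
            sinus_vals[n][in_phase] = _sinus_phase(s, cs[n], k, kin.c_eq, g_drv, cn_drv, a)
            cs[n] = float(_sinus_phase(np.array([dur]), cs[n], k, kin.c_eq, g_drv, cn_drv, a)[0])
        cn = float(_nasal_phase(np.array([dur]), cn, g, a)[0])

    traces = {
        "nasal_left": ConcentrationTrace("nasal_left", times, np.clip(nasal_vals, 0, 1)),
        "nasal_right": ConcentrationTrace("nasal_right", times, np.clip(nasal_vals.copy(), 0, 1)),
    }
    for n in sinus_names:
        traces[n] = ConcentrationTrace(n, times, np.clip(sinus_vals[n], 0, 1))
    return traces


def _ellipsoid(x, y, z, center, radii) -> np.ndarray:
    return (
        ((x - center[0]) / radii[0]) ** 2
        + ((y - center[1]) / radii[1]) ** 2
        + ((z - center[2]) / radii[2]) ** 2
    ) <= 1.0


def build_label_map(spec: PhantomSpec) -> np.ndarray:
    """Deterministic stylized head geometry as an integer label volume.

    Axes: x = left-right (patient left at high x), y = anterior-posterior
    (anterior at low y), z = inferior-superior.  The head is an ellipsoidal
    soft-tissue core in a bone shell; two nasal-cavity boxes flank a midline
    septum; the six sinuses are ellipsoids mirror-symmetric about the
    midline, so left/right differences in rendered series are purely kinetic.

    Raises
    ------
    GridTooSmallError
        If any declared region ends up with zero voxels on this grid.
    """
    nx, ny, nz = spec.grid_shape
    x, y, z = np.meshgrid(
        np.arange(nx, dtype=float),
        np.arange(ny, dtype=float),
        np.arange(nz, dtype=float),
        indexing="ij",
    )
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    c = (cx, cy, cz)

    lab = np.full(spec.grid_shape, Region.background_air, dtype=np.int16)
    outer = _ellipsoid(x, y, z, c, (0.46 * nx, 0.47 * ny, 0.46 * nz))
    inner = _ellipsoid(x, y, z, c, (0.40 * nx, 0.41 * ny, 0.40 * nz))
    lab[outer] = Region.bone
    lab[inner] = Region.soft_tissue

    # Nasal cavities: paraxial boxes one voxel off the midline septum.
    nasal_left = (
        (x > cx + 0.5) & (x <= cx + 0.5 + max(0.09 * nx, 1.5))
        & (np.abs(y - cy) <= 0.22 * ny)
        & (np.abs(z - cz) <= 0.15 * nz)
    )
    nasal_right = nasal_left[::-1, :, :]
    lab[nasal_left] = Region.nasal_left
    lab[nasal_right] = Region.nasal_right

    # Left sinus ellipsoids (fractions of grid size); right = mirror in x.
    sinus_geometry = {
        Region.maxillary_L: ((cx + 0.20 * nx, cy + 0.05 * ny, cz - 0.10 * nz),
                             (0.09 * nx, 0.12 * ny, 0.12 * nz)),
        Region.sphenoid_L: ((cx + 0.06 * nx, cy + 0.32 * ny, cz + 0.02 * nz),
                            (0.05 * nx, 0.08 * ny, 0.07 * nz)),
        Region.frontal_L: ((cx + 0.06 * nx, cy - 0.30 * ny, cz + 0.28 * nz),
                           (0.05 * nx, 0.06 * ny, 0.10 * nz)),
    }
    mirror_of = {
        Region.maxillary_L: Region.maxillary_R,
        Region.sphenoid_L: Region.sphenoid_R,
        Region.frontal_L: Region.frontal_R,
    }
    for left_label, (center, radii) in sinus_geometry.items():
        left_mask = _ellipsoid(x, y, z, center, radii)
        lab[left_mask] = left_label
        lab[left_mask[::-1, :, :]] = mirror_of[left_label]

    counts = np.bincount(lab.ravel(), minlength=len(Region))
    empty = [Region(i).name for i in range(len(Region)) if counts[i] == 0]
    if empty:
        raise GridTooSmallError(
            f"grid {spec.grid_shape} too small: region(s) {empty} have no voxels"
        )
    return lab


def render_series(
    spec: PhantomSpec,
    traces: Mapping[str, ConcentrationTrace],
    protocol: Protocol,
    channels: Sequence[str] = CHANNELS,
    labels: np.ndarray | None = None,
) -> DualEnergySeries:
    """Render HU volumes from concentration traces (see module docstring).

    ``labels`` may pass a precomputed label map to skip geometry rebuilds.
    Noise draws come from ``numpy.random.default_rng(spec.seed)``, so equal
    specs render bit-identical series.

    Raises
    ------
    TraceFrameMismatchError
        If any trace is not sampled exactly on the protocol frame clock.
    """
    times = frame_times(protocol)
    for tr in traces.values():
        if tr.times.shape != times.shape or not np.array_equal(tr.times, times):
            raise TraceFrameMismatchError(
                f"trace {tr.region!r} is not sampled on the protocol frame clock"
            )
    if labels is None:
        labels = build_label_map(spec)

    n_frames = times.size
    rng = np.random.default_rng(spec.seed)
    volumes: dict[str, np.ndarray] = {}
    for ch in channels:
        e100 = float(spec.e100_hu[ch])
        # Per-label HU time courses; voxel volumes are a label lookup.
        lut = np.empty((len(Region), n_frames), dtype=np.float64)
        for region in Region:
            base = float(spec.baseline_hu[region.name])
            if region in GAS_REGIONS and region.name in traces:
                lut[region] = base + traces[region.name].c * e100
            else:
                lut[region] = base
        vol = lut[labels, :]                     # (nx, ny, nz, T)
        vol = np.moveaxis(vol, -1, 0).copy()     # (T, nx, ny, nz)
        if spec.noise_sigma_hu > 0:
            vol += rng.normal(0.0, spec.noise_sigma_hu, size=vol.shape)
        volumes[ch] = vol

    return DualEnergySeries(
        frame_times=times,
        volumes=volumes,
        voxel_mm=spec.voxel_mm,
        provenance={
            "generator": "xenovent.phantom",
            "seed": spec.seed,
            "noise_sigma_hu": spec.noise_sigma_hu,
            "grid_shape": list(spec.grid_shape),
            "nasal_tau_s": spec.nasal_tau_s,
        },
    )


def simulate_phantom(
    spec: PhantomSpec,
    protocol: Protocol,
    channels: Sequence[str] = CHANNELS,
) -> tuple[DualEnergySeries, dict[str, ConcentrationTrace], np.ndarray]:
    """Convenience wrapper: simulate, build geometry, render.

    Returns ``(series, ground_truth_traces, label_volume)``.
    """
    traces = simulate_concentrations(spec, protocol)
    labels = build_label_map(spec)
    series = render_series(spec, traces, protocol, channels=channels, labels=labels)
    return series, traces, labels
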