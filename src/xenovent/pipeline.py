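"""End-to-end analysis chain: series -> TDCs -> concentrations -> fits.

This is the library behind the command line: given a dual-energy series and
a set of ROIs it extracts time-density curves, normalizes them by the
input-nostril E100 reference, runs the wash-in/wash-out exponential fits on
protocol-anchored windows, and assembles the per-sinus summary table and
figures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import matplotlib
import pandas as pd

from .errors import ConfigError
from .kinetics import (
    ConcentrationCurve,
    KineticFit,
    fit_washin,
    fit_washout,
    reference_enhancement,
    to_concentration,
    summarize,
)
from .protocol import Gas, Protocol
from .roi import RoiSet, TimeDensityCurve, extract_all_tdcs
from .series import DualEnergySeries
from .xenon_map import default_baseline_window

__all__ = ["FitWindow", "default_fit_windows", "analyze_series",
           "AnalysisResult", "plot_concentration_pairs"]


@dataclass(frozen=True)
class FitWindow:
    """One fit segment: frames in [start_s, end_s], transient onset t0_s."""

    start_s: float
    end_s: float
    t0_s: float


# Fit windows anchored to the published schedule events: xenon onset 10.5 s,
# pulsation onset 34.5 s, supply stop 52.5 s, washout pulsation 63 s.  t0 is
# the event that starts the transient for that region: xenon onset for
# directly ventilated spaces (nasal cavities, the wide-ostium left sphenoid
# pre-surgery, every sinus post-surgery), pulsation onset for sinuses that
# only exchange under pulsation.
_PRE_WINDOWS: dict[str, dict[str, FitWindow]] = {
    "nasal_left": {"wash_in": FitWindow(10.5, 34.5, 10.5),
                   "wash_out": FitWindow(52.5, 63.0, 52.5)},
    "nasal_right": {"wash_in": FitWindow(10.5, 34.5, 10.5),
                    "wash_out": FitWindow(52.5, 63.0, 52.5)},
    "sphenoid_L": {"wash_in": FitWindow(10.5, 52.5, 10.5),
                   "wash_out": FitWindow(63.0, 69.0, 63.0)},
    **{name: {"wash_in": FitWindow(34.5, 52.5, 34.5),
              "wash_out": FitWindow(63.0, 69.0, 63.0)}
       for name in ("maxillary_L", "maxillary_R", "sphenoid_R",
                    "frontal_L", "frontal_R")},
}

_POST_WINDOWS: dict[str, dict[str, FitWindow]] = {
    name: {"wash_in": FitWindow(10.5, 49.5, 10.5)}
    for name in ("nasal_left", "nasal_right", "maxillary_L", "maxillary_R",
                 "sphenoid_L", "sphenoid_R", "frontal_L", "frontal_R")
}


def default_fit_windows(variant: str) -> dict[str, dict[str, FitWindow]]:
    """Per-ROI fit windows for a published protocol variant."""
    if variant == "pre_fess":
        return {roi: dict(d) for roi, d in _PRE_WINDOWS.items()}
    if variant == "post_fess":
        return {roi: dict(d) for roi, d in _POST_WINDOWS.items()}
    raise ConfigError(f"no default fit windows for variant {variant!r}")


@dataclass
class AnalysisResult:
    """Everything the analyze step produces for one series."""

    e100_hu: float
    tdcs: dict[str, TimeDensityCurve]
    curves: dict[str, ConcentrationCurve]
    fits: list[KineticFit]
    summary: pd.DataFrame


def analyze_series(
    series: DualEnergySeries,
    rois: RoiSet,
    protocol: Protocol,
    variant: str | None = None,
    channel: str = "mixed",
    input_nostril: str = "nasal_left",
    e100: float | None = None,
    windows: Mapping[str, Mapping[str, FitWindow]] | None = None,
    enhancement_mode: str = "constant",
) -> AnalysisResult:
    """Run the full quantitative chain on one series.

    Parameters
    ----------
    variant
        Which default fit-window table to use when ``windows`` is None;
        inferred from the protocol (presence of a washout phase) if omitted.
    e100
        Full-xenon reference enhancement in HU; computed as the maximum
        enhancement of the ``input_nostril`` curve when None.
    enhancement_mode
        ``"constant"`` (HU + 1000, the documented default) or ``"frame"``
        (subtract the mean of the pre-xenon frames per ROI).
    """
    tdcs = extract_all_tdcs(series, rois, channel=channel)

    if enhancement_mode == "frame":
        t0, t1 = default_baseline_window(protocol)
        offset = {}
        for name, tdc in tdcs.items():
            sel = (tdc.times >= t0) & (tdc.times < t1)
            # shift so baseline frames sit at -1000 HU, then reuse the
            # constant-mode arithmetic
            offset[name] = TimeDensityCurve(
                name, tdc.times, tdc.hu - tdc.hu[sel].mean() - 1000.0, tdc.n_voxels
            )
        tdcs_for_c = offset
    elif enhancement_mode == "constant":
        tdcs_for_c = tdcs
    else:
        raise ConfigError(
            f"enhancement_mode must be 'constant' or 'frame', got {enhancement_mode!r}"
        )

    if e100 is None:
        if input_nostril not in tdcs_for_c:
            raise ConfigError(
                f"input nostril ROI {input_nostril!r} not among ROIs "
                f"{sorted(tdcs)}; cannot derive E100"
            )
        e100 = reference_enhancement(tdcs_for_c[input_nostril])

    curves = {n: to_concentration(t, e100) for n, t in tdcs_for_c.items()}

    if windows is None:
        if variant is None:
            has_washout = any(
                p.gas == Gas.AIR and p.start_s > 0 for p in protocol.phases
            )
            variant = "pre_fess" if has_washout else "post_fess"
        windows = default_fit_windows(variant)

    fits: list[KineticFit] = []
    for roi_name, per_dir in windows.items():
        if roi_name not in curves:
            continue
        curve = curves[roi_name]
        for direction, w in per_dir.items():
            if direction == "wash_in":
                fits.append(fit_washin(curve, (w.start_s, w.end_s), w.t0_s))
            elif direction == "wash_out":
                fits.append(fit_washout(curve, (w.start_s, w.end_s), w.t0_s))
            else:
                raise ConfigError(f"unknown fit direction {direction!r}")

    return AnalysisResult(
        e100_hu=float(e100),
        tdcs=tdcs,
        curves=curves,
        fits=fits,
        summary=summarize(fits, curves),
    )


#: Left/right panel pairs mirroring the per-region figure layout.
REGION_PAIRS = (
    ("nasal_left", "nasal_right"),
    ("maxillary_L", "maxillary_R"),
    ("sphenoid_L", "sphenoid_R"),
    ("frontal_L", "frontal_R"),
)


def plot_concentration_pairs(
    curves: Mapping[str, ConcentrationCurve],
    protocol: Protocol,
    out_dir: str | Path,
    pairs=REGION_PAIRS,
) -> list[Path]:
    """One PNG per left/right region pair: concentration (%) vs time with
    phase boundaries shaded.  Returns the written paths."""
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for left, right in pairs:
        present = [n for n in (left, right) if n in curves]
        if not present:
            continue
        fig, ax = plt.subplots(figsize=(6, 3.5))
        for phase in protocol.phases:
            if phase.gas == Gas.XENON:
                ax.axvspan(phase.start_s, phase.end_s, color="0.92", zorder=0)
            if phase.flow.value == "pulsating":
                ax.axvline(phase.start_s, color="0.6", ls=":", lw=0.8)
        for name, style in zip(present, ("-", "--")):
            c = curves[name]
            ax.plot(c.times, 100.0 * c.c, style, label=name)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("xenon concentration (%)")
        ax.set_ylim(bottom=-2)
        ax.legend(frameon=False, fontsize=8)
        ax.set_title(f"{left.rsplit('_', 1)[0]} (shaded: xenon supply)")
        fig.tight_layout()
        path = out_dir / f"curves_{left.rsplit('_', 1)[0]}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    return written
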