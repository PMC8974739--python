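"""Independent brute-force integrator for the phantom compartment model.

Fixed-step explicit RK4 at 1 ms on the coupled nasal+sinus system,
integrated phase by phase (phase boundaries are multiples of the step, so
no step straddles a discontinuity).  Shares no code with the closed-form
solver in ``xenovent.phantom``; used to cross-check it.

Model (same contract as the package):
  nasal:  dC/dt = (G - C) / nasal_tau,  G = 1 under xenon supply else 0
  sinus, xenon supply:    dC/dt = k_in(flow) * (c_eq * C_nasal - C)
  sinus, room-air supply: dC/dt = -k_out(flow) * C
"""

from __future__ import annotations

import numpy as np

from xenovent.phantom import SINUS_REGIONS, PhantomSpec
from xenovent.protocol import Flow, Gas, Protocol, frame_times


def _rates(spec: PhantomSpec, phase) -> np.ndarray:
    ks = []
    for r in SINUS_REGIONS:
        kin = spec.compartments[r.name]
        if phase.gas == Gas.XENON:
            k = kin.k_laminar if phase.flow == Flow.LAMINAR else kin.k_pulsating
        else:
            if phase.flow == Flow.LAMINAR:
                k = kin.k_laminar if kin.k_laminar_out is None else kin.k_laminar_out
            else:
                k = kin.k_pulsating if kin.k_pulsating_out is None else kin.k_pulsating_out
        ks.append(k)
    return np.asarray(ks, dtype=float)


def integrate_traces(
    spec: PhantomSpec, protocol: Protocol, dt: float = 1e-3
) -> dict[str, np.ndarray]:
    """Concentrations sampled at the protocol frame times, by RK4 at ``dt``."""
    times = frame_times(protocol)
    ceq = np.array([spec.compartments[r.name].c_eq for r in SINUS_REGIONS])
    a = 1.0 / spec.nasal_tau_s

    cn = 0.0
    cs = np.zeros(len(SINUS_REGIONS))
    nasal_out = np.empty(times.size)
    sinus_out = np.empty((len(SINUS_REGIONS), times.size))

    # frame index bookkeeping: frames fall on multiples of the interval
    next_frame = 0
    t_abs = 0.0
    eps = dt / 4

    def record(t):
        nonlocal next_frame
        while next_frame < times.size and times[next_frame] <= t + eps:
            nasal_out[next_frame] = cn
            sinus_out[:, next_frame] = cs
            next_frame += 1

    record(0.0)
    for phase in protocol.phases:
        g = 1.0 if phase.gas == Gas.XENON else 0.0
        ks = _rates(spec, phase)
        xenon = phase.gas == Gas.XENON
        n_steps = int(round(phase.duration_s / dt))

        def f(state):
            cn_, cs_ = state
            dcn = (g - cn_) * a
            if xenon:
                dcs = ks * (ceq * cn_ - cs_)
            else:
                dcs = -ks * cs_
            return dcn, dcs

        for _ in range(n_steps):
            k1n, k1s = f((cn, cs))
            k2n, k2s = f((cn + 0.5 * dt * k1n, cs + 0.5 * dt * k1s))
            k3n, k3s = f((cn + 0.5 * dt * k2n, cs + 0.5 * dt * k2s))
            k4n, k4s = f((cn + dt * k3n, cs + dt * k3s))
            cn = cn + dt / 6.0 * (k1n + 2 * k2n + 2 * k3n + k4n)
            cs = cs + dt / 6.0 * (k1s + 2 * k2s + 2 * k3s + k4s)
            t_abs += dt
            record(t_abs)

    out = {"nasal_left": nasal_out.copy(), "nasal_right": nasal_out.copy()}
    for i, r in enumerate(SINUS_REGIONS):
        out[r.name] = sinus_out[i]
    return out
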