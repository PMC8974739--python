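# Methods

## The measurement this package models

A head (in the motivating experiment, a cadaver specimen with the
nasopharynx sealed) is connected to a gas supply delivering 7 L/min of
either room air or 100% xenon to the input (left) nostril, optionally with
a 45 Hz / 25 mbar pressure pulsation superimposed. A dual-source CT scanner
acquires one volume every 1.5 s at two tube spectra plus a blended "mixed"
image. Because xenon's X-ray attenuation is linear in its concentration,
the fractional xenon concentration in any air space follows from its HU
enhancement over room air, normalized by the enhancement of pure xenon.

Two schedules are built in. *Pre-surgery* (intact ostia): room air to
10.5 s, laminar xenon to 34.5 s, pulsating xenon to 52.5 s, laminar air to
63 s, pulsating air to 69 s — 46 frames. *Post-surgery* (after functional
endoscopic sinus surgery, FESS, which widens the ostia): the same first two
phases, then pulsating xenon until 49.5 s — 33 frames, no washout recorded.
Phase intervals are half-open `[start, end)`; frame k is stamped at
`k·1.5 s` (the 46 × 1.5 s = 69 s arithmetic is only consistent with frames
starting at t = 0, which is adopted).

## Compartment model

State variables are fractional xenon concentrations, dimensionless in
[0, 1]. The nasal cavities are directly ventilated:

    dC_n/dt = (G(t) − C_n) / τ_n,   G = 1 under xenon supply, else 0

with `nasal_tau_s` τ_n = 2.5 s by default — fast enough to plateau by
~20 s after xenon onset, as the nasal time–density curves show. Each sinus
exchanges through its ostium:

    xenon supply:    dC_s/dt = k_in(flow) · (c_eq·C_n(t) − C_s)
    room-air supply: dC_s/dt = −k_out(flow) · C_s

`k` depends on the flow regime (laminar vs pulsating) and on the exchange
direction; `c_eq ∈ [0, 1]` caps the accessible equilibrium fraction.
Wash-out is modeled as a plain first-order decline rather than relaxation
toward the residual nasal concentration: the supply flushes the nasal
cavity within a few seconds, and coupling the sinuses to that brief
residual would make slowly-exchanging sinuses *keep absorbing* xenon for
several seconds after supply stop — a non-monotone washout that contradicts
the observed behaviour and the exponential form the τ fits assume. The
asymmetric driver keeps every washout segment monotone and exactly
exponential.

Within each phase all drivers are constant, so the system has a
closed-form solution (nasal: one exponential; sinus: a sum of two
exponentials, with a secular `t·e^(−kt)` term when k equals 1/τ_n). The
solver chains these phase solutions analytically and samples them on the
frame clock; the test suite cross-checks it against an independent
fixed-step 1 ms explicit RK4 integration of the same equations
(agreement ≤ 1e-4 on all default traces).

### Default rate tables

Rates are 1/s; τ = 1/k. Values marked ⋆ are calibrated to the observed
behaviour of the motivating experiment; unmarked values are the package's
own synthetic choices where no measurement exists.

Pre-surgery:

| sinus        | k_in laminar | k_in pulsating | k_out laminar | k_out pulsating | c_eq |
|--------------|--------------|----------------|---------------|-----------------|------|
| maxillary_L  | 0⋆           | 1/7⋆           | 1/60          | 1/6⋆            | 1    |
| maxillary_R  | 0⋆           | 1/18⋆          | 1/60          | 1/6⋆            | 1    |
| sphenoid_L   | 1/10         | 1/8            | 1/60          | 1/8             | 0.9  |
| sphenoid_R   | 0⋆           | 1/8            | 1/60          | 1/8             | 1    |
| frontal_L/R  | 0⋆           | 1/170⋆         | 1/60          | 1/30            | 1    |

Rationale: laminar xenon moves nothing through intact maxillary/frontal
ostia (k_in,lam = 0); the left sphenoid has a wide natural ostium and fills
already under laminar flow (rate chosen so uptake is visible from ~15 s;
c_eq = 0.9 keeps its peak inside the reported 50–90% band); 1/170 over the
18 s pulsation window yields the ≈10% frontal peak; the laminar washout
1/60 makes the 52.5–63 s decline visible but shallow; the frontal
pulsating washout 1/30 merely steepens that decline visibly.

Post-surgery: maxillary L/R and sphenoid_R k = 1/4 with c_eq = 0.9 (the
observed plateau is ≈90%, reached between 20 and 30 s — c_eq = 1 would
drive the fitted plateau to ~100%); sphenoid_L and frontal L/R k = 1/12
with c_eq = 0.6 ("delayed and less marked"); pulsating rates equal laminar
ones, since widened ostia make pulsation irrelevant.

## Phantom geometry and rendering

The label volume (default 64×64×48 voxels of 3 mm) is stylized, not
anatomical: an ellipsoidal soft-tissue head in a bone shell, two
nasal-cavity boxes flanking a two-voxel septum, and six sinus ellipsoids
placed mirror-symmetrically so that left/right differences in the rendered
data are purely kinetic. Every region is checked to occupy ≥1 voxel;
smaller grids that cannot host all regions are rejected.

Rendering: `HU = baseline(label) + C(t)·e100(channel) + N(0, σ)` per voxel
and frame. Baselines: air spaces −1000 HU, soft tissue 40 HU, bone 700 HU.
Full-xenon enhancements `e100`: mixed 250 HU (pinned by the −750 vs
−1000 HU span), low-kV 330 HU and high-kV 175 HU — the ≈1.9 low/high ratio
reflects the stronger photoelectric xenon enhancement at the softer
spectrum and is a configurable synthetic choice; only the mixed value is
anchored to measurement. Noise is additive Gaussian, independent per voxel
and frame, σ = 5 HU by default — the simplest model that supports
recovery tests; no spatial or spectral correlation is claimed. All draws
come from one generator seeded by `PhantomSpec.seed`.

### What the phantom does and does not emulate

It emulates the protocol timing, first-order exchange kinetics with
flow-dependent rates, linear xenon enhancement with channel-dependent
coefficients, and frame noise. It does **not** emulate beam hardening,
scatter, partial-volume edges, inter-frame motion, anatomical geometry, or
gas recirculation. Passing recovery tests therefore demonstrates that the
analysis chain is correct and numerically stable under the stated noise
model — not that it is robust to scanner physics absent from the phantom.

## Analysis chain

1. **Enhancement.** Constant mode `E = HU + 1000` (the room-air offset) is
   the default for gas-space readings; frame mode subtracts the per-voxel
   (or per-ROI) mean of the pre-xenon frames (t < 10.5 s, 7 frames) and is
   required outside gas spaces, where baselines differ from −1000 HU. The
   spectral map `ΔE_low − α·ΔE_high` (default α = 1 on temporal
   enhancements) is a validation/denoising path: under the rendering model
   it is proportional to concentration for any α except e100_low/e100_high.
2. **Normalization.** E100 is the maximum enhancement of the input-nostril
   curve; concentrations are `E/E100`, capped at 1.1 before fitting (noise
   can push ROI means slightly past 1). Non-positive E100 is rejected.
3. **Fits.** Bounded nonlinear least squares (τ ∈ [0.1, 1000] s,
   trust-region reflective, initialized by log-linear regression on the
   residual toward the plateau). t0 is pinned to the protocol event that
   starts the transient; c0/c_peak is anchored to the frame nearest t0 —
   with only 4 washout frames, freeing them is ill-conditioned. A flat
   curve or optimizer failure returns `converged = False` instead of
   raising. Reports are in percent; internal values are fractions.

Default fit windows (pre-surgery): wash-in 34.5–52.5 s (t0 = 34.5) for
sinuses that only exchange under pulsation, 10.5–52.5 s (t0 = 10.5) for
the left sphenoid, 10.5–34.5 s for the nasal cavities; wash-out 63–69 s
(t0 = 63) for sinuses, 52.5–63 s for the nasal cavities. Post-surgery:
wash-in 10.5–49.5 s (t0 = 10.5) everywhere. All windows are overridable
per ROI in the YAML config. Window selection is inclusive at both ends; a
boundary frame (e.g. 52.5 s) carries the concentration reached at that
instant, so it belongs to the transient that just ended.

## Numerical notes

- Closed-form vs brute force: the RK4 oracle uses the same phase-wise
  model but shares no code; 1 ms steps keep its error orders below the
  1e-4 comparison tolerance. Phase boundaries are multiples of the step.
- The degenerate sinus rate k = 1/τ_n switches to the secular closed form
  when |k − a| ≤ 1e-12·max(k, a).
- Noise-free inversion (render → ROI mean → normalize by the mixed-image
  e100) reproduces the simulated traces to ≤1e-9; volumes are kept in
  float64 for this reason.
- Washout fits on 4 frames recover the generator τ exactly because the
  washout segments are exactly exponential under the asymmetric-driver
  model; the wash-in fits carry a ≤0.05% bias from the residual nasal lag.
- The fitted wash-in plateau `c_ss` is an asymptote: on an 18 s window with
  τ = 7 s it extrapolates to ~100% while the observed peak is 92%. The
  summary table reports both (`level_pct`, `peak_pct`).

## Problem sizes

Defaults used throughout (tests, acceptance script): 64×64×48 grid, 46/33
frames, full-label ROIs. The noisy-recovery study uses 200 seeds at
σ = 5 HU on the mixed channel. A full simulate-plus-analyze run completes
in seconds on one CPU.

## Known limitations

- The phantom's rate tables are phenomenological: the pulsation frequency
  and amplitude are metadata only (no Helmholtz-resonance model); kinetics
  depend solely on the flow enum.
- Single-specimen anchoring: where the motivating experiment printed no
  value (sphenoid laminar uptake, laminar washout rates, spectral e100
  split) the defaults are explicit synthetic choices, flagged above.
- No registration between frames: the table/head are assumed fixed, as in
  a cadaver setup.
- DICOM ingestion is out of scope; readers are structured so a DICOM
  loader could slot in ahead of `DualEnergySeries`.
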