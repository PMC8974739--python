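"""Phantom geometry, compartment simulation, rendering, and series IO."""

import numpy as np
import pytest

import xenovent as xv
from xenovent.errors import (
    GridTooSmallError,
    MissingKineticsError,
    SidecarError,
    TraceFrameMismatchError,
    UnknownVariantError,
)
from xenovent.phantom import (
    GAS_REGIONS,
    SINUS_REGIONS,
    CompartmentKinetics,
    ConcentrationTrace,
    Region,
)
from xenovent.protocol import Flow, Gas, Phase, Protocol

from _oracles import integrate_traces


def _constant_driver_spec(k: float, duration: float = 19.5,
                          nasal_tau_s: float = 1e-6) -> tuple:
    """Protocol + spec where the nasal cavity is (near-)instantly at 1."""
    proto = Protocol((Phase(0.0, duration, Gas.XENON, Flow.PULSATING),))
    kin = {r.name: CompartmentKinetics(r.name, k_laminar=0.0, k_pulsating=k)
           for r in SINUS_REGIONS}
    spec = xv.PhantomSpec(nasal_tau_s=nasal_tau_s, compartments=kin,
                          noise_sigma_hu=0.0)
    return spec, proto


class TestSimulateConcentrations:
    def test_constant_driver_exponential(self):
        # k = 1/7 1/s driven by C_nasal = 1 for 18 s from 0 ends at
        # 1 - exp(-18/7) ~ 0.924
        spec, proto = _constant_driver_spec(1 / 7)
        tr = xv.simulate_concentrations(spec, proto)["maxillary_L"]
        i = int(np.where(tr.times == 18.0)[0][0])
        assert tr.c[i] == pytest.approx(1 - np.exp(-18 / 7), abs=1e-6)

    def test_constant_driver_matches_rk4_oracle(self):
        # nasal_tau within the explicit integrator's stability range
        spec, proto = _constant_driver_spec(1 / 7, nasal_tau_s=0.05)
        closed = xv.simulate_concentrations(spec, proto)
        brute = integrate_traces(spec, proto, dt=1e-3)
        np.testing.assert_allclose(closed["maxillary_L"].c,
                                   brute["maxillary_L"], atol=1e-4)

    def test_zero_rate_sinus_frozen_during_laminar_phase(self, clean_traces):
        # pre-surgery maxillary k_laminar = 0: flat through 0-34.5 s
        tr = clean_traces["maxillary_L"]
        assert np.all(tr.c[tr.times < 34.5] == 0.0)

    def test_nasal_follows_supply_with_short_lag(self, clean_traces):
        tr = clean_traces["nasal_left"]
        i = int(np.where(tr.times == 19.5)[0][0])
        assert tr.c[i] == pytest.approx(1 - np.exp(-9.0 / 2.5), rel=1e-9)
        # plateau (>97%) reached around 20 s and held until supply stop
        sel = (tr.times >= 21.0) & (tr.times <= 52.5)
        assert tr.c[sel].min() > 0.97

    def test_traces_start_at_zero_and_stay_in_unit_interval(self, clean_traces):
        for tr in clean_traces.values():
            assert tr.c[0] == 0.0
            assert tr.c.min() >= 0.0 and tr.c.max() <= 1.0

    @pytest.mark.parametrize("variant", ["pre_fess", "post_fess"])
    def test_monotone_within_phases(self, variant):
        spec = xv.PhantomSpec.for_variant(variant, noise_sigma_hu=0.0)
        proto = xv.build_protocol(variant)
        traces = xv.simulate_concentrations(spec, proto)
        for phase in proto.phases:
            for tr in traces.values():
                sel = (tr.times >= phase.start_s) & (tr.times < phase.end_s)
                d = np.diff(tr.c[sel])
                if phase.gas == Gas.XENON:
                    assert np.all(d >= -1e-12), (tr.region, phase)
                else:
                    assert np.all(d <= 1e-12), (tr.region, phase)

    def test_missing_sinus_kinetics_rejected(self, pre_protocol):
        kin = xv.default_kinetics("pre_fess")
        kin.pop("frontal_L")
        spec = xv.PhantomSpec(compartments=kin)
        with pytest.raises(MissingKineticsError):
            xv.simulate_concentrations(spec, pre_protocol)

    def test_unknown_kinetics_variant_rejected(self):
        with pytest.raises(UnknownVariantError):
            xv.default_kinetics("no_such_condition")


class TestLabelMap:
    def test_all_regions_present_on_default_grid(self, clean_labels):
        present = set(np.unique(clean_labels))
        assert present == {int(r) for r in Region}

    def test_left_right_mirror_symmetry(self, clean_labels):
        for left, right in [(Region.nasal_left, Region.nasal_right),
                            (Region.maxillary_L, Region.maxillary_R),
                            (Region.sphenoid_L, Region.sphenoid_R),
                            (Region.frontal_L, Region.frontal_R)]:
            lmask = clean_labels == left
            rmask = clean_labels == right
            assert lmask.sum() == rmask.sum() > 0
            np.testing.assert_array_equal(lmask[::-1, :, :], rmask)

    def test_deterministic(self, clean_spec, clean_labels):
        np.testing.assert_array_equal(xv.build_label_map(clean_spec), clean_labels)

    def test_too_small_grid_rejected(self):
        spec = xv.PhantomSpec(grid_shape=(6, 6, 6))
        with pytest.raises(GridTooSmallError):
            xv.build_label_map(spec)


class TestRenderSeries:
    def test_background_air_constant_minus_1000(self, clean_series, clean_labels):
        mask = clean_labels == Region.background_air
        vals = clean_series.channel("mixed")[:, mask]
        assert np.all(vals == -1000.0)

    def test_full_xenon_nasal_voxel_mixed_is_minus_750(self, small_spec, pre_protocol):
        # force C = 1 at every frame: -1000 + 1.0 * 250 = -750 HU
        t = xv.frame_times(pre_protocol)
        traces = {r.name: ConcentrationTrace(r.name, t, np.ones_like(t))
                  for r in GAS_REGIONS}
        series = xv.render_series(small_spec, traces, pre_protocol, channels=("mixed",))
        labels = xv.build_label_map(small_spec)
        vals = series.channel("mixed")[:, labels == Region.nasal_left]
        assert np.all(vals == -750.0)

    def test_equal_seed_bit_identical_render(self, small_spec, pre_protocol):
        spec = xv.PhantomSpec.for_variant(
            "pre_fess", grid_shape=(32, 32, 24), noise_sigma_hu=5.0, seed=42)
        traces = xv.simulate_concentrations(spec, pre_protocol)
        a = xv.render_series(spec, traces, pre_protocol, channels=("mixed",))
        b = xv.render_series(spec, traces, pre_protocol, channels=("mixed",))
        np.testing.assert_array_equal(a.channel("mixed"), b.channel("mixed"))

    def test_different_seed_differs(self, pre_protocol):
        base = dict(grid_shape=(32, 32, 24), noise_sigma_hu=5.0)
        s1 = xv.PhantomSpec.for_variant("pre_fess", seed=1, **base)
        s2 = xv.PhantomSpec.for_variant("pre_fess", seed=2, **base)
        traces = xv.simulate_concentrations(s1, pre_protocol)
        a = xv.render_series(s1, traces, pre_protocol, channels=("mixed",))
        b = xv.render_series(s2, traces, pre_protocol, channels=("mixed",))
        assert not np.array_equal(a.channel("mixed"), b.channel("mixed"))

    def test_zero_rates_leave_sinus_voxels_at_baseline(self, pre_protocol):
        kin = {r.name: CompartmentKinetics(r.name, 0.0, 0.0,
                                           k_laminar_out=0.0, k_pulsating_out=0.0)
               for r in SINUS_REGIONS}
        spec = xv.PhantomSpec(grid_shape=(32, 32, 24), compartments=kin,
                              noise_sigma_hu=0.0)
        series, _, labels = xv.simulate_phantom(spec, pre_protocol, channels=("mixed",))
        for r in SINUS_REGIONS:
            vals = series.channel("mixed")[:, labels == r]
            assert np.all(vals == -1000.0)

    def test_enhancement_linear_in_e100(self, small_spec, pre_protocol):
        traces = xv.simulate_concentrations(small_spec, pre_protocol)
        doubled = xv.PhantomSpec.for_variant(
            "pre_fess", grid_shape=(32, 32, 24), noise_sigma_hu=0.0,
            e100_hu={"low_kv": 660.0, "high_kv": 350.0, "mixed": 500.0})
        a = xv.render_series(small_spec, traces, pre_protocol, channels=("mixed",))
        b = xv.render_series(doubled, traces, pre_protocol, channels=("mixed",))
        labels = xv.build_label_map(small_spec)
        gas = np.isin(labels, [int(r) for r in GAS_REGIONS])
        np.testing.assert_allclose(
            b.channel("mixed")[:, gas] + 1000.0,
            2.0 * (a.channel("mixed")[:, gas] + 1000.0), atol=1e-9)

    def test_trace_clock_mismatch_rejected(self, small_spec, pre_protocol):
        t = xv.frame_times(pre_protocol)[:-1]
        traces = {r.name: ConcentrationTrace(r.name, t, np.zeros_like(t))
                  for r in GAS_REGIONS}
        with pytest.raises(TraceFrameMismatchError):
            xv.render_series(small_spec, traces, pre_protocol, channels=("mixed",))


class TestSeriesIO:
    @pytest.fixture()
    def small_series(self, small_spec, pre_protocol):
        series, _, _ = xv.simulate_phantom(small_spec, pre_protocol)
        return series

    def test_round_trip_lossless(self, small_series, tmp_path):
        xv.write_series(small_series, tmp_path / "s")
        back = xv.read_series(tmp_path / "s")
        np.testing.assert_array_equal(back.frame_times, small_series.frame_times)
        assert set(back.channels) == set(small_series.channels)
        for ch in small_series.channels:
            np.testing.assert_array_equal(back.channel(ch), small_series.channel(ch))

    def test_missing_sidecar_rejected(self, small_series, tmp_path):
        xv.write_series(small_series, tmp_path / "s")
        (tmp_path / "s" / "series.json").unlink()
        with pytest.raises(SidecarError):
            xv.read_series(tmp_path / "s")

    def test_sidecar_frame_count_mismatch_rejected(self, small_series, tmp_path):
        import json
        xv.write_series(small_series, tmp_path / "s")
        sidecar = tmp_path / "s" / "series.json"
        meta = json.loads(sidecar.read_text())
        meta["frame_times_s"] = meta["frame_times_s"][:-2]
        sidecar.write_text(json.dumps(meta))
        with pytest.raises(SidecarError):
            xv.read_series(tmp_path / "s")
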