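"""Synthetic trace/stack generator: presets, noise model, renderer consistency."""

import numpy as np
import pytest

from spimdiff.model import DiffusionParams, SingularTimeError, concentration, peak_time
from spimdiff.stacks import build_roi_ladder, extract_traces
from spimdiff.synth import (
    NoiseSpec,
    PressureSpec,
    StackGeometry,
    make_preset,
    render_stack,
    simulate_traces,
    write_simulation,
)


class TestPresets:
    @pytest.mark.parametrize(
        "name, D, t0",
        [
            ("agarose_1pct", 18.1, 0.0),
            ("agarose_2pct", 8.9, 0.0),
            ("agarose_5pct", 2.6, 0.0),
            ("control_embryo", 12.0, 320.0),
            ("xenograft_embryo", 1.0, 600.0),
            ("xenograft_variant_a", 1.9, 600.0),
            ("xenograft_variant_b", 0.82, 600.0),
        ],
    )
    def test_registry_encodes_study_conditions(self, name, D, t0):
        p = make_preset(name)
        assert p.D == D and p.t0 == t0
        assert p.frame_interval == 5.0 and p.n_frames == 720

    def test_roi_grids(self):
        agarose = make_preset("agarose_1pct")
        assert agarose.roi_distances[0] == 30 and agarose.roi_distances[-1] == 200
        embryo = make_preset("control_embryo")
        assert embryo.roi_distances == (10, 15, 20, 25, 30, 35, 40)

    def test_unknown_name(self):
        with pytest.raises(KeyError, match="unknown preset"):
            make_preset("agarose_50pct")

    def test_overrides(self):
        p = make_preset("control_embryo", n_frames=100)
        assert p.n_frames == 100 and p.D == 12.0


class TestSimulateTraces:
    def test_noise_free_equals_model(self, noise_free_traces):
        p = make_preset("control_embryo")
        for tr in noise_free_traces("control_embryo"):
            np.testing.assert_allclose(
                tr.values, concentration(p.params, tr.distance, tr.times), rtol=1e-14
            )

    def test_initial_intensity_decreases_with_distance(self, noise_free_traces):
        for name in ("control_embryo", "xenograft_embryo", "agarose_1pct"):
            first = [tr.values[0] for tr in noise_free_traces(name)]
            assert np.all(np.diff(first) < 0)

    def test_seeded_reproducibility(self):
        p = make_preset("control_embryo")
        a = simulate_traces(p, seed=7)
        b = simulate_traces(p, seed=7)
        c = simulate_traces(p, seed=8)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.values, y.values)
        assert not np.array_equal(a[0].values, c[0].values)

    def test_control_trace_halves_near_model_half_time(self, noise_free_traces):
        # value at 30 um falls to half its initial value at ~1.08e3 s
        tr = next(t for t in noise_free_traces("control_embryo") if t.distance == 30)
        below = np.nonzero(tr.values <= 0.5 * tr.values[0])[0]
        assert tr.times[below[0]] == pytest.approx(1.081e3, abs=5.0)

    def test_embryo_traces_decay_monotonically_where_peak_predates_observation(
        self, noise_free_traces
    ):
        for name in ("control_embryo", "xenograft_embryo"):
            p = make_preset(name)
            for tr in noise_free_traces(name):
                if peak_time(p.params, tr.distance) < p.t0:
                    assert np.all(np.diff(tr.values) < 0)

    def test_far_agarose_roi_rises_then_decays(self, noise_free_traces):
        tr = next(t for t in noise_free_traces("agarose_1pct") if t.distance == 200)
        k = int(np.argmax(tr.values))
        assert 0 < k < len(tr.values) - 1
        p = make_preset("agarose_1pct")
        assert tr.times[k] == pytest.approx(peak_time(p.params, 200.0), abs=3 * p.frame_interval)

    def test_pressure_ramp_linear_early_rise(self):
        ramp = PressureSpec(ramp_rate=50.0, ramp_duration=10.0, ramp_radius=10.0)
        p = make_preset("agarose_1pct", roi_distances=(5.0, 30.0), pressure_ramp=ramp)
        near, far = simulate_traces(p, noise_free=True)
        base = simulate_traces(
            make_preset("agarose_1pct", roi_distances=(5.0, 30.0), pressure_ramp=None),
            noise_free=True,
        )
        ramp_part = near.values - base[0].values
        # linear in time until saturation, then flat; absent beyond the radius
        np.testing.assert_allclose(ramp_part[:2], 50.0 * np.array([0.0, 5.0]))
        np.testing.assert_allclose(ramp_part[3:], 500.0)
        np.testing.assert_allclose(far.values, base[1].values)

    def test_noise_variance_structure(self):
        # empirical per-sample variance matches read_sigma^2 + shot_scale * signal
        p = make_preset("control_embryo", n_frames=60)
        clean = np.array([tr.values for tr in simulate_traces(p, noise_free=True)])
        reps = np.array(
            [[tr.values for tr in simulate_traces(p, seed=s)] for s in range(200)]
        )
        emp_var = reps.var(axis=0, ddof=1)
        pred_var = p.noise.read_sigma**2 + p.noise.shot_scale * clean
        assert np.mean(emp_var) / np.mean(pred_var) == pytest.approx(1.0, abs=0.1)


class TestRenderStack:
    def test_round_trip_matches_trace_generator(self, noise_free_traces):
        p = make_preset("control_embryo")
        geom = StackGeometry()
        dye, _ = render_stack(p, geom, noise_free=True)
        rois = build_roi_ladder(dye.shape, geom.source, dye.pixel_size, 10, 40, 5, 5)
        extracted = extract_traces(dye, rois)
        for got, want in zip(extracted, noise_free_traces("control_embryo")):
            np.testing.assert_allclose(got.values, want.values, rtol=0.02)

    def test_vessel_channel_is_static_mask(self):
        p = make_preset("control_embryo", n_frames=5)
        geom = StackGeometry(vessel_halfwidth=4.0, vessel_intensity=300.0)
        _, vessel = render_stack(p, geom, noise_free=True)
        assert vessel.n_frames == 1
        assert set(np.unique(vessel.frames)) == {0.0, 300.0}

    def test_singular_first_frame_rejected(self):
        p = make_preset("agarose_1pct", start_time=0.0, n_frames=5)
        with pytest.raises(SingularTimeError):
            render_stack(p, StackGeometry(), noise_free=True)

    def test_write_simulation_outputs(self, tmp_path):
        p = make_preset("control_embryo", n_frames=4)
        sidecar = write_simulation(tmp_path, p, noise_free=True)
        assert (tmp_path / "dye.tif").exists()
        assert (tmp_path / "vessel.tif").exists()
        assert (tmp_path / "sidecar.json").exists()
        assert sidecar["D_um2_per_s"] == 12.0 and sidecar["t0_s"] == 320.0


class TestSpecs:
    def test_noise_spec_validation(self):
        with pytest.raises(ValueError):
            NoiseSpec(read_sigma=-1)

    def test_preset_validation(self):
        with pytest.raises(ValueError):
            make_preset("control_embryo", roi_distances=(20.0, 10.0))
        with pytest.raises(ValueError):
            make_preset("control_embryo", n_frames=1)
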