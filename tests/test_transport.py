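import math

import numpy as np
import pytest

from magbead import magnetics as mag
from magbead import materials as mat
from magbead import synthetic_data as synth
from magbead import transport as trans


class TestChannelVolume:
    def test_duct_volume_before_wire(self):
        ch = trans.ChannelGeometry(wire_outer_radius=1e-9)
        assert trans.channel_volume(ch) == pytest.approx(14.4, rel=1e-6)

    def test_printed_capacity_one_sig_fig(self, channel):
        # the quoted channel capacity (15 uL) at 1-significant-figure rounding
        assert abs(trans.channel_volume(channel) - 15.0) < 1.0

    def test_wire_subtraction_term(self, channel):
        full = 14.4
        sub = full - trans.channel_volume(channel)
        expected = math.pi * (27.5e-6) ** 2 * 0.06 * 1e9
        assert sub == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(0.14, abs=0.01)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            trans.ChannelGeometry(length=0.0)


class TestDuctVelocity:
    def test_no_slip_walls(self, channel):
        flow = trans.FlowField(50.0)
        for pt in ((200.0, 0.0), (-200.0, 100.0), (0.0, 300.0), (150.0, -300.0)):
            assert abs(trans.duct_velocity(flow, channel, pt)) < 1e-9

    def test_flux_matches_rate(self, channel):
        flow = trans.FlowField(50.0)
        w, h = channel.width, channel.height
        x = np.linspace(-w / 2, w / 2, 201)
        z = np.linspace(-h / 2, h / 2, 301)
        X, Z = np.meshgrid(x, z)
        U = trans.duct_velocity(flow, channel, np.stack([X, Z], axis=-1))
        flux = np.trapezoid(np.trapezoid(U * 1e-6, x * 1e-6, axis=1), z * 1e-6)
        assert flux == pytest.approx(flow.rate_m3s, rel=1e-3)

    def test_centre_exceeds_mean(self, channel):
        flow = trans.FlowField(50.0)
        mean = flow.rate_m3s / (channel.width * channel.height * 1e-12) * 1e6
        centre = trans.duct_velocity(flow, channel, (0.0, 0.0))
        assert centre > mean > 0

    def test_outside_duct_rejected(self, channel):
        with pytest.raises(ValueError):
            trans.duct_velocity(trans.FlowField(50.0), channel, (500.0, 0.0))

    def test_plug_profile_uniform(self, channel):
        flow = trans.FlowField(50.0, profile_kind="plug")
        u1 = trans.duct_velocity(flow, channel, (0.0, 0.0))
        u2 = trans.duct_velocity(flow, channel, (150.0, 250.0))
        assert u1 == u2 > 0


class TestMagneticForce:
    def test_surface_force_13_nN(self, bead, wire):
        base = mag.wire_external_field(wire.operating_M, wire.core_radius,
                                       wire.glass_outer_radius, 0.0)
        # applicator and wire contributions are aligned at the working point
        H = base.H_magnitude + 106e3
        fs = mag.FieldSample(base.position, np.array([0.0, 0.0, H]), H,
                             base.grad_H_magnitude)
        force = trans.magnetic_force(bead, fs)
        assert np.linalg.norm(force) == pytest.approx(13e-9, rel=0.05)

    def test_zero_gradient_zero_force(self, bead):
        fs = mag.FieldSample(np.zeros(3), np.array([1e5, 0, 0]), 1e5,
                             np.zeros(3))
        assert np.linalg.norm(trans.magnetic_force(bead, fs)) == 0.0

    def test_linearity_in_moment(self, bead, wire):
        fs = mag.wire_external_field(wire.operating_M, wire.core_radius,
                                     50.0, 0.3)
        half = mat.BeadModel(diameter=bead.diameter / 2 ** (1 / 3),
                             saturation_M=bead.saturation_M, curve=bead.curve)
        f_full = np.linalg.norm(trans.magnetic_force(bead, fs))
        f_half = np.linalg.norm(trans.magnetic_force(half, fs))
        assert f_half == pytest.approx(0.5 * f_full, rel=1e-9)


def _seed_positions(channel, n, seed, axial_fraction=0.02):
    return synth.gen_bead_positions(n, channel, seed=seed,
                                    axial_fraction=axial_fraction)


class TestCapture:
    def test_no_flow_captures_everything(self, channel, bead, wire):
        pos = _seed_positions(channel, 40, seed=1)
        res = trans.simulate_capture(pos, trans.FlowField(0.0), channel, bead,
                                     wire, duration=5.0)
        assert res.capture_fraction == 1.0

    def test_monotone_in_flow_rate(self, channel, bead, wire):
        pos = _seed_positions(channel, 30, seed=2)
        fractions = []
        for q in (0.0, 25.0, 50.0, 100.0):
            res = trans.simulate_capture(pos, trans.FlowField(q), channel,
                                         bead, wire, duration=5.0)
            fractions.append(res.capture_fraction)
        assert fractions[0] == 1.0
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))

    def test_unmagnetized_wire_geometric_baseline(self, channel, bead, wire):
        dead = wire.at_field(0.0)
        pos = _seed_positions(channel, 30, seed=3)
        res = trans.simulate_capture(pos, trans.FlowField(50.0), channel, bead,
                                     dead, duration=5.0)
        # beads seeded outside the envelope never cross it without the force
        assert res.capture_fraction == 0.0
        assert np.all(res.exited | (res.times >= 5.0))

    def test_trajectories_never_cross_envelope(self, channel, bead, wire):
        pos = _seed_positions(channel, 20, seed=4)
        res = trans.simulate_capture(pos, trans.FlowField(50.0), channel, bead,
                                     wire, duration=5.0,
                                     record_trajectories=True)
        rho_cap = channel.wire_outer_radius + bead.diameter / 2
        for tr in res.trajectories:
            for (_, x, _, z) in tr:
                assert math.hypot(x, z) >= rho_cap - 1e-6

    def test_step_halving_convergence(self, channel, bead, wire):
        pos = _seed_positions(channel, 30, seed=5)
        f1 = trans.simulate_capture(pos, trans.FlowField(100.0), channel, bead,
                                    wire, duration=5.0,
                                    max_step=1e-3).capture_fraction
        f2 = trans.simulate_capture(pos, trans.FlowField(100.0), channel, bead,
                                    wire, duration=5.0,
                                    max_step=5e-4).capture_fraction
        assert abs(f1 - f2) < 0.01 + 1e-12

    def test_reproducible_bead_by_bead(self, channel, bead, wire):
        pos = _seed_positions(channel, 25, seed=6)
        r1 = trans.simulate_capture(pos, trans.FlowField(50.0), channel, bead,
                                    wire, duration=5.0)
        r2 = trans.simulate_capture(pos, trans.FlowField(50.0), channel, bead,
                                    wire, duration=5.0)
        assert np.array_equal(r1.captured, r2.captured)
        assert np.array_equal(r1.times, r2.times)

    def test_bad_step_rejected(self, channel, bead, wire):
        with pytest.raises(ValueError):
            trans.simulate_capture(np.zeros((1, 3)), trans.FlowField(0.0),
                                   channel, bead, wire, max_step=0.0)


class TestRetention:
    def test_no_flow_always_retained(self, channel, bead, wire):
        assert trans.retained_fraction(trans.FlowField(0.0), channel, bead,
                                       wire) == 1.0

    def test_fraction_non_increasing_in_rate(self, channel, bead, wire):
        fr = [trans.retained_fraction(trans.FlowField(q), channel, bead, wire)
              for q in (0.0, 50.0, 100.0, 10000.0)]
        assert all(a >= b for a, b in zip(fr, fr[1:]))

    def test_retained_at_100_uL_min(self, channel, bead, wire):
        # consistent with the published "up to 85%" working point
        assert trans.retained_fraction(trans.FlowField(100.0), channel, bead,
                                       wire) >= 0.5

    def test_friction_variant_weakens_holding(self, channel, bead, wire):
        strong = trans.retention_check(trans.FlowField(100.0), channel, bead,
                                       wire)
        weak = trans.retention_check(trans.FlowField(100.0), channel, bead,
                                     wire, friction_coefficient=1e-6)
        assert strong and not weak
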