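"""Pairwise stacking parameters: trivial placements, round trips, invariants."""

import numpy as np
import pytest

import ncpgeom as ng
from ncpgeom.frame import NCPFrame, transform_frame
from ncpgeom.geometry import random_rotation
from ncpgeom.synthetic import place_pair


def _random_frame(rng, span=100.0):
    R = random_rotation(rng)
    return NCPFrame(origin=rng.uniform(-span, span, 3),
                    u=R[:, 0], v=R[:, 1], normal=R[:, 2])


def test_pure_normal_stack(toy_frame):
    f2 = transform_frame(toy_frame, np.eye(3), 50.0 * toy_frame.normal)
    p = ng.compute_stack_params(toy_frame, f2)
    assert p.dist == pytest.approx(50.0)
    assert p.rise == pytest.approx(50.0)
    assert p.shift == pytest.approx(0.0, abs=1e-9)
    assert p.delta_deg == pytest.approx(0.0, abs=1e-9)
    assert p.tilt_deg == pytest.approx(0.0, abs=1e-7)
    assert p.orientation == "head-to-head"


def test_half_turn_about_normal_is_head_to_tail(toy_frame):
    from ncpgeom.geometry import rotation_about_axis
    R = rotation_about_axis(toy_frame.normal, 180.0)
    t = 55.0 * toy_frame.normal + (np.eye(3) - R) @ toy_frame.origin
    f2 = transform_frame(toy_frame, R, t)
    p = ng.compute_stack_params(toy_frame, f2)
    assert abs(p.delta_deg) == pytest.approx(180.0, abs=1e-9)
    assert p.orientation == "head-to-tail"
    assert p.delta_deg == 180.0          # +180 convention at the branch cut


def test_prescribed_tetranucleosome_like_stack(toy_frame):
    _, _, f2 = place_pair(toy_frame, rise_signed=55.0, shift=20.0, phi_deg=0.0,
                          delta_deg=180.0, tilt_deg=10.0, tilt_direction_deg=0.0)
    p = ng.compute_stack_params(toy_frame, f2)
    assert p.rise == pytest.approx(55.0, abs=1e-6)
    assert p.shift == pytest.approx(20.0, abs=1e-6)
    assert p.dist == pytest.approx(np.hypot(55, 20), abs=1e-6)
    assert p.delta_deg == pytest.approx(180.0, abs=1e-6)
    assert p.tilt_deg == pytest.approx(10.0, abs=1e-6)


@pytest.mark.parametrize("delta", [0.0, 90.0, -90.0, 180.0])
@pytest.mark.parametrize("tilt", [0.0, 8.0, 20.0])
def test_round_trip_over_design_grid(toy_frame, delta, tilt):
    for rise, shift in [(55.0, 20.0), (50.0, 40.0), (-60.0, 10.0)]:
        _, _, f2 = place_pair(toy_frame, rise, shift, phi_deg=30.0,
                              delta_deg=delta, tilt_deg=tilt,
                              tilt_direction_deg=0.0 if tilt == 0 else -45.0)
        p = ng.compute_stack_params(toy_frame, f2)
        assert p.rise_signed == pytest.approx(rise, abs=1e-6)
        assert p.shift == pytest.approx(shift, abs=1e-6)
        assert p.phi_deg == pytest.approx(30.0, abs=1e-6)
        assert p.delta_deg == pytest.approx(delta, abs=1e-6)
        assert p.tilt_deg == pytest.approx(tilt, abs=1e-6)
        if tilt > 0:
            assert p.tilt_direction_deg == pytest.approx(-45.0, abs=1e-6)


def test_round_trip_on_randomized_targets(rng):
    frame = _random_frame(rng)
    worst = 0.0
    for _ in range(200):
        target = dict(rise_signed=rng.uniform(-70, 70),
                      shift=rng.uniform(0.5, 45),
                      phi_deg=rng.uniform(-179, 179),
                      delta_deg=rng.uniform(-179, 179),
                      tilt_deg=rng.uniform(0.2, 30),
                      tilt_direction_deg=rng.uniform(-179, 179))
        _, _, f2 = place_pair(frame, **target)
        p = ng.compute_stack_params(frame, f2)
        worst = max(worst,
                    abs(p.rise_signed - target["rise_signed"]),
                    abs(p.shift - target["shift"]),
                    abs(p.phi_deg - target["phi_deg"]),
                    abs(p.delta_deg - target["delta_deg"]),
                    abs(p.tilt_deg - target["tilt_deg"]),
                    abs(p.tilt_direction_deg - target["tilt_direction_deg"]))
    assert worst < 1e-6


def test_pythagoras_for_random_frame_pairs(rng):
    for _ in range(10_000):
        f1 = _random_frame(rng)
        f2 = _random_frame(rng)
        p = ng.compute_stack_params(f1, f2)
        assert p.dist**2 == pytest.approx(p.rise_signed**2 + p.shift**2,
                                          rel=1e-6)


def test_parameters_invariant_under_global_rigid_motion(toy_frame, rng):
    _, _, f2 = place_pair(toy_frame, 55.0, 20.0, 10.0, 170.0, 12.0, 60.0)
    p0 = ng.compute_stack_params(toy_frame, f2)
    R = random_rotation(rng)
    t = rng.uniform(-100, 100, 3)
    g1 = transform_frame(toy_frame, R, t)
    g2 = transform_frame(f2, R, t)
    p1 = ng.compute_stack_params(g1, g2)
    assert np.allclose(p0.as_tuple(), p1.as_tuple(), atol=1e-9)


def test_reversal_symmetry(rng):
    f1, f2 = _random_frame(rng), _random_frame(rng)
    p = ng.compute_stack_params(f1, f2)
    q = ng.compute_stack_params(f2, f1)
    assert p.dist == pytest.approx(q.dist, abs=1e-9)
    assert p.tilt_deg == pytest.approx(q.tilt_deg, abs=1e-9)


def test_coincident_origins_warn_and_zero(toy_frame):
    with pytest.warns(UserWarning, match="coincident"):
        p = ng.compute_stack_params(toy_frame, toy_frame)
    assert p.dist == 0.0


def test_delta_undefined_when_axis_parallel_normal(toy_frame):
    f2 = NCPFrame(origin=toy_frame.origin + 50 * toy_frame.normal,
                  u=toy_frame.normal, v=toy_frame.v,
                  normal=np.cross(toy_frame.v, toy_frame.normal))
    with pytest.raises(ValueError, match="delta"):
        ng.compute_stack_params(toy_frame, f2)


@pytest.mark.parametrize("delta,expected", [
    (179.0, "head-to-tail"), (-25.0, "head-to-head"), (120.0, "other"),
    (-160.0, "head-to-tail"), (90.0, "perpendicular"), (-75.0, "perpendicular"),
])
def test_orientation_classes(delta, expected):
    p = ng.StackParams(60, 55, 55, 20, 0, delta, 5, 0)
    assert ng.classify_orientation(p) == expected


class TestCrystalPairs:
    def test_designed_columnar_contact_recovered(self, toy, tmp_path):
        model, _ = toy
        path = ng.make_toy_crystal(model, tmp_path / "c.pdb", spacegroup="P 1",
                                   cell=(150.0, 150.0, 60.0))
        ncp = ng.identify_components(ng.load_structure(path))[0]
        ng.assign_domains(ncp)
        ng.pair_bases(ncp)
        fr = ng.build_frame(ncp, sh=ng.fit_superhelix(ng.compute_axis(ncp)))
        pairs = ng.find_stacking_pairs(ng.expand_crystal(ncp), frames=fr)
        assert len(pairs) == 1                   # +c and -c images deduplicate
        assert pairs[0].dist == pytest.approx(60.0, abs=1e-3)
        assert pairs[0].params.tilt_deg == pytest.approx(0.0, abs=0.05)
        assert pairs[0].params.orientation == "head-to-head"

    def test_zero_cutoff_gives_no_pairs(self, toy, tmp_path):
        model, _ = toy
        path = ng.make_toy_crystal(model, tmp_path / "c.pdb", spacegroup="P 1",
                                   cell=(150.0, 150.0, 60.0))
        ncp = ng.identify_components(ng.load_structure(path))[0]
        ng.assign_domains(ncp)
        ng.pair_bases(ncp)
        fr = ng.build_frame(ncp, sh=ng.fit_superhelix(ng.compute_axis(ncp)))
        assert ng.find_stacking_pairs(ng.expand_crystal(ncp), frames=fr,
                                      dist_cutoff=0.0) == []

    def test_screw_axis_pair_is_head_to_tail(self, toy, tmp_path):
        model, _ = toy
        path = ng.make_toy_crystal(model, tmp_path / "c.pdb",
                                   spacegroup="P 21 21 21",
                                   cell=(80.0, 200.0, 90.0))
        ncp = ng.identify_components(ng.load_structure(path))[0]
        ng.assign_domains(ncp)
        ng.pair_bases(ncp)
        fr = ng.build_frame(ncp, sh=ng.fit_superhelix(ng.compute_axis(ncp)))
        pairs = ng.find_stacking_pairs(ng.expand_crystal(ncp), frames=fr)
        # the closest image comes from the two-fold screw parallel to the
        # particle normal: hand calculation gives sqrt(a^2+c^2)/2 and a
        # flipped symmetry axis
        assert pairs[0].dist == pytest.approx(np.hypot(80, 90) / 2, abs=1e-3)
        assert abs(pairs[0].params.delta_deg) == pytest.approx(180.0, abs=0.05)
        assert pairs[0].params.orientation == "head-to-tail"
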