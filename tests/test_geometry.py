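"""Backbone/frame parametrization: round trips, equivariance, rotation algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from idpensemble import geometry as G
from idpensemble import fixtures as fx


def _random_rigid(rng):
    return G.RigidTransform(G.random_rotation(rng), rng.normal(scale=5.0, size=3))


class TestFrames:
    def test_canonical_residue_gives_identity_frame(self):
        conf = fx.ideal_helix(3)
        # construct one residue in canonical pose: CA origin, C on +x, N in xy
        n = np.array([[G.LOCAL_N, G.LOCAL_N + [0, 0, 5]], [G.LOCAL_N, G.LOCAL_N]])
        conf = G.BackboneConformation(
            coords_N=np.array([G.LOCAL_N, G.LOCAL_N + 5.0]),
            coords_CA=np.array([G.LOCAL_CA, G.LOCAL_CA + 5.0]),
            coords_C=np.array([G.LOCAL_C, G.LOCAL_C + 5.0]),
            coords_O=np.zeros((2, 3)),
        )
        frames = G.frames_from_backbone(conf)
        assert np.allclose(frames.rotations[0], np.eye(3), atol=1e-12)
        assert np.allclose(frames.translations[0], 0.0)

    def test_backbone_frame_round_trip_is_exact(self, helix20):
        frames = G.frames_from_backbone(helix20)
        rebuilt = G.backbone_from_frames(frames, helix20.sequence)
        assert np.array_equal(rebuilt.coords_CA, helix20.coords_CA)
        assert np.allclose(rebuilt.coords_N, helix20.coords_N, atol=1e-9)
        assert np.allclose(rebuilt.coords_C, helix20.coords_C, atol=1e-9)

    def test_frame_round_trip_from_frames(self, rng):
        rots = G.random_rotation(rng, 8)
        frames = G.FrameSet(rots, rng.normal(size=(8, 3)) * 10)
        back = G.frames_from_backbone(G.backbone_from_frames(frames))
        assert np.allclose(back.rotations, frames.rotations, atol=1e-9)
        assert np.allclose(back.translations, frames.translations, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_frame_construction_equivariance(self, helix20, seed):
        rng = np.random.default_rng(seed)
        rho = _random_rigid(rng)
        direct = G.frames_from_backbone(G.apply(rho, helix20))
        composed = G.apply(rho, G.frames_from_backbone(helix20))
        assert np.allclose(direct.rotations, composed.rotations, atol=1e-8)
        assert np.allclose(direct.translations, composed.translations, atol=1e-8)

    def test_equivariance_many_transforms(self, helix20):
        rng = np.random.default_rng(7)
        frames = G.frames_from_backbone(helix20)
        for _ in range(1000):
            rho = _random_rigid(rng)
            d = G.frames_from_backbone(G.apply(rho, helix20))
            c = G.apply(rho, frames)
            assert np.abs(d.rotations - c.rotations).max() < 1e-8
            assert np.abs(d.translations - c.translations).max() < 1e-8

    def test_collinear_backbone_raises_with_residue_index(self):
        conf = fx.ideal_helix(4)
        bad = conf.copy()
        bad.coords_N[2] = bad.coords_CA[2] + 2.0 * (bad.coords_C[2] - bad.coords_CA[2])
        with pytest.raises(G.DegenerateGeometryError, match="2"):
            G.frames_from_backbone(bad)

    def test_rebuilt_ca_ca_distance_matches_ideal_geometry(self):
        # NeRF oracle: trans chain with standard bond lengths/angles gives ~3.80 A
        conf = fx.build_chain_from_torsions([180] * 10, [180] * 10)
        frames = G.frames_from_backbone(conf)
        rebuilt = G.backbone_from_frames(frames)
        d = np.linalg.norm(np.diff(rebuilt.coords_CA, axis=0), axis=1)
        assert np.all(np.abs(d - 3.80) < 0.05)


class TestRigidAlgebra:
    def test_compose_with_inverse_is_identity(self, rng):
        t = _random_rigid(rng)
        ident = G.compose(t, G.inverse(t))
        assert np.allclose(ident.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(ident.translation, 0.0, atol=1e-10)

    def test_apply_identity_is_noop(self, helix20):
        out = G.apply(G.RigidTransform.identity(), helix20)
        assert np.array_equal(out.coords_CA, helix20.coords_CA)
        assert np.array_equal(out.coords_O, helix20.coords_O)

    def test_apply_is_isometry(self, helix20, rng):
        t = _random_rigid(rng)
        moved = G.apply(t, helix20)
        d0 = np.linalg.norm(helix20.coords_CA[:, None] - helix20.coords_CA[None], axis=-1)
        d1 = np.linalg.norm(moved.coords_CA[:, None] - moved.coords_CA[None], axis=-1)
        assert np.allclose(d0, d1, atol=1e-8)

    def test_compose_matches_sequential_apply(self, helix20, rng):
        a, b = _random_rigid(rng), _random_rigid(rng)
        both = G.apply(G.compose(a, b), helix20)
        seq = G.apply(a, G.apply(b, helix20))
        assert np.allclose(both.coords_CA, seq.coords_CA, atol=1e-9)


class TestAxisAngle:
    def test_identity_angle_zero_with_canonical_axis(self):
        axis, ang = G.axis_angle(np.eye(3))
        assert ang == 0.0
        assert np.allclose(axis, [0, 0, 1])

    def test_quarter_turn_about_z(self):
        R = G.rotation_from_axis_angle([0, 0, 1], np.pi / 2)
        axis, ang = G.axis_angle(R)
        assert np.isclose(ang, np.pi / 2)
        assert np.allclose(axis, [0, 0, 1])

    @pytest.mark.parametrize("seed", range(10))
    def test_round_trip_random(self, seed):
        rng = np.random.default_rng(seed)
        R = G.random_rotation(rng)
        axis, ang = G.axis_angle(R)
        assert np.allclose(G.rotation_from_axis_angle(axis, ang), R, atol=1e-10)

    def test_angle_from_trace(self, rng):
        R = G.random_rotation(rng)
        _, ang = G.axis_angle(R)
        assert np.isclose(ang, np.arccos((np.trace(R) - 1) / 2), atol=1e-10)


class TestHaarRotations:
    def test_mean_trace_is_zero(self):
        # Haar integral oracle: tr R = 1 + 2 cos w and E[cos w] = -1/2 under
        # the (1 - cos w)/pi angle density, so E[tr R] = 0 (character
        # orthogonality of the standard representation).
        rng = np.random.default_rng(0)
        R = G.random_rotation(rng, 100_000)
        tr = np.trace(R, axis1=-2, axis2=-1)
        se = tr.std() / np.sqrt(len(tr))
        assert abs(tr.mean()) < 3 * se

    def test_angle_distribution_matches_haar_cdf(self):
        rng = np.random.default_rng(1)
        R = G.random_rotation(rng, 100_000)
        ang = np.linalg.norm(G.matrix_to_rotvec(R), axis=-1)
        grid = np.sort(ang)
        cdf = (grid - np.sin(grid)) / np.pi
        emp = np.arange(1, len(grid) + 1) / len(grid)
        assert np.abs(emp - cdf).max() < 0.01

    def test_determinants_are_one(self, rng):
        R = G.random_rotation(rng, 1000)
        assert np.allclose(np.linalg.det(R), 1.0, atol=1e-10)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 30))
def test_round_trip_preserves_ca_property(seed, n):
    rng = np.random.default_rng(seed)
    phi = rng.uniform(-180, 180, n)
    psi = rng.uniform(-180, 180, n)
    conf = fx.build_chain_from_torsions(phi, psi)
    frames = G.frames_from_backbone(conf)
    rebuilt = G.backbone_from_frames(frames)
    assert np.allclose(rebuilt.coords_CA, conf.coords_CA, atol=1e-12)
    assert np.abs(np.linalg.det(frames.rotations) - 1).max() < 1e-6
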