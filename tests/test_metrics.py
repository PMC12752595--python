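"""Ensemble metrics: hand-computed values and rigid-transform invariance."""

import numpy as np
import pandas as pd
import pytest

from idpensemble import fixtures as fx
from idpensemble import geometry as G
from idpensemble import metrics as mx


def _toy_conf(ca):
    """Conformation with CA at given positions; other atoms offset rigidly."""
    ca = np.asarray(ca, dtype=float)
    return G.BackboneConformation(
        ca + [1.0, 0, 0], ca, ca + [0, 1.0, 0], ca + [0, 0, 1.0])


class TestRadiusOfGyration:
    def test_coincident_atoms_give_zero(self):
        conf = G.BackboneConformation(*[np.zeros((3, 3))] * 4)
        assert mx.radius_of_gyration(conf) == 0.0

    def test_two_point_formula(self):
        # two unit-mass points 2d apart -> Rg = d
        d = 3.7
        conf = _toy_conf([[0, 0, 0], [2 * d, 0, 0]])
        assert np.isclose(mx.radius_of_gyration(conf, atoms="ca"), d)

    def test_matches_bruteforce_on_helix(self, helix20):
        xyz = helix20.atoms().reshape(-1, 3)
        brute = np.sqrt(((xyz - xyz.mean(0)) ** 2).sum(1).mean())
        assert abs(mx.radius_of_gyration(helix20) - brute) < 1e-10

    def test_helix_more_compact_than_extended(self):
        h, e = fx.ideal_helix(20), fx.extended_chain(20)
        assert mx.radius_of_gyration(h) < mx.radius_of_gyration(e)


class TestEpsilonRg:
    def test_example_values(self):
        ens_a = [_toy_conf([[0, 0, 0], [2 * 9.4, 0, 0]])]
        assert np.isclose(mx.epsilon_rg(ens_a, 10.0, atoms="ca"), -0.06)
        ens_b = [_toy_conf([[0, 0, 0], [2 * 11.0, 0, 0]])]
        assert np.isclose(mx.epsilon_rg(ens_b, 10.0, atoms="ca"), 0.10)

    def test_zero_when_equal(self):
        ens = [_toy_conf([[0, 0, 0], [10, 0, 0]])]
        rg = mx.radius_of_gyration(ens[0], atoms="ca")
        assert mx.epsilon_rg(ens, rg, atoms="ca") == 0.0

    def test_sign_matches_difference(self):
        ens = [_toy_conf([[0, 0, 0], [12, 0, 0]])]
        rg = mx.radius_of_gyration(ens[0], atoms="ca")
        assert mx.epsilon_rg(ens, rg * 2, atoms="ca") < 0
        assert mx.epsilon_rg(ens, rg / 2, atoms="ca") > 0


class TestRmsdObservable:
    def test_identical_gives_zero(self):
        v = np.array([1.0, 2.0, 3.0])
        val, n = mx.rmsd_observable(v, v)
        assert val == 0.0 and n == 3

    def test_single_residue_difference(self):
        val, _ = mx.rmsd_observable(np.array([2.0]), np.array([1.0]))
        assert val == 1.0

    def test_hand_arithmetic(self):
        val, n = mx.rmsd_observable(np.array([3.0, 4.0]), np.array([0.0, 0.0]))
        assert np.isclose(val, np.sqrt(12.5)) and n == 2

    def test_missing_values_excluded_and_counted(self):
        pred = np.array([1.0, 2.0, 3.0, 4.0])
        exp = np.array([1.0, np.nan, 3.0, 5.0])
        val, n = mx.rmsd_observable(pred, exp)
        assert n == 3
        assert np.isclose(val, np.sqrt(1.0 / 3.0))


class TestValidity:
    def test_self_calibrated_reference_gives_one(self):
        ens = [fx.ideal_helix(10) for _ in range(4)]
        spec = mx.ValiditySpec.from_reference(ens)
        assert mx.validity(ens, spec) == pytest.approx(1.0)

    def test_short_ca_distance_invalidates(self):
        good = _toy_conf([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
        bad = _toy_conf([[0, 0, 0], [2.5, 0, 0], [6.3, 0, 0]])  # 2.5 < 2*1.7-0.4
        assert not mx.conformation_valid(bad, mx.ValiditySpec())
        assert mx.conformation_valid(good, mx.ValiditySpec())

    def test_fraction_counting(self):
        good = _toy_conf([[0, 0, 0], [3.8, 0, 0]])
        bad = _toy_conf([[0, 0, 0], [2.0, 0, 0]])
        assert mx.validity([good, bad, good, bad]) == 0.5

    def test_delta_vdw_value(self):
        assert mx.DELTA_VDW == pytest.approx(2 * 1.7 - 0.4)


class TestGeometryDistributions:
    def test_ideal_helix_interior_torsions(self, helix20):
        tor = mx.backbone_torsions(helix20)
        interior = tor.iloc[2:-2]
        assert np.abs(interior.phi + 57).max() < 1.0
        assert np.abs(interior.psi + 47).max() < 1.0

    def test_omega_point_mass_at_180(self, helix20):
        tor = mx.backbone_torsions(helix20)
        om = tor.omega.dropna().abs()
        assert np.allclose(om, 180.0, atol=1e-6)

    def test_degenerate_torsion_flagged(self):
        # four collinear atoms -> undefined torsion, excluded as NaN
        ca = np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]], dtype=float)
        conf = G.BackboneConformation(
            coords_N=ca - [1.2, 0, 0], coords_CA=ca, coords_C=ca + [1.3, 0, 0],
            coords_O=ca + [0, 1.2, 0])
        tor = mx.backbone_torsions(conf)
        assert tor.phi.iloc[1:].isna().all()

    def test_bond_tables_cover_all_bonds(self, helix20):
        dists = mx.geometry_distributions([helix20])
        counts = dists["bonds"].bond.value_counts()
        assert counts["N-CA"] == 20 and counts["C-N"] == 19


class TestRamachandran:
    def test_pure_helix_is_all_alpha(self, helix20):
        occ = mx.ramachandran_occupancy([helix20])
        assert occ["alpha"] == pytest.approx(1.0)

    def test_occupancies_sum_to_one(self):
        ens = fx.two_state_ensemble(12, 0.5, 10, seed=2).conformations
        occ = mx.ramachandran_occupancy(ens)
        assert sum(occ.values()) == pytest.approx(1.0, abs=1e-9)

    def test_mixture_weights_recovered(self):
        basins = [
            fx.TorsionBasinSpec("helix", -57, -47, weight=0.7),
            fx.TorsionBasinSpec("coil", -135, 145, weight=0.3),
        ]
        ens = fx.ramachandran_mixture_ensemble(64, basins, 300, seed=3)
        occ = mx.ramachandran_occupancy(ens.conformations)
        assert abs(occ["alpha"] - 0.7) < 0.03
        assert abs(occ["beta_ppii"] - 0.3) < 0.03


class TestJCoupling:
    def test_phi_60_value(self):
        assert np.isclose(mx.j_coupling_hn_ha(60.0), 6.51 - 1.76 + 1.60)

    def test_phi_minus_60_value(self):
        assert np.isclose(mx.j_coupling_hn_ha(-60.0), 6.51 * 0.25 + 0.88 + 1.60)

    def test_maximum_location_by_grid_search(self):
        # f(u) = A u^2 + B u + C with A > 0 is maximized at an endpoint of
        # u = cos(phi-60) in [-1, 1]; f(-1) > f(+1) since B < 0, so the
        # maximum sits at phi = -120 (cos = -1), confirmed by brute force
        grid = np.arange(-180.0, 180.0, 0.1)
        vals = mx.j_coupling_hn_ha(grid)
        assert abs(grid[np.argmax(vals)] - (-120.0)) < 0.2
        assert np.isclose(vals.max(), 6.51 + 1.76 + 1.60)


class TestRgRmsdProjection:
    def test_reference_against_itself_is_zero(self, helix20):
        proj = mx.rg_rmsd_projection([helix20], helix20)
        assert proj.rmsd.iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_rigid_copy_has_zero_rmsd(self, helix20, rng):
        rho = G.RigidTransform(G.random_rotation(rng), rng.normal(size=3) * 20)
        moved = G.apply(rho, helix20)
        proj = mx.rg_rmsd_projection([moved], helix20)
        assert proj.rmsd.iloc[0] < 1e-6

    def test_three_point_toy_matches_grid_search(self):
        # two non-congruent planar triangles: for coplanar point sets the
        # optimal rotation is either in-plane or in-plane composed with a
        # flip, so a 1-D angle scan (x2 for the flip) is an exact brute force
        x = np.array([[0.0, 0, 0], [4, 0, 0], [4, 3, 0]])
        y = np.array([[0.0, 0, 0], [4.5, 0, 0], [3.5, 2.8, 0]])
        fast = mx.kabsch_rmsd(x, y)
        xc = x - x.mean(0)
        yc = y - y.mean(0)
        flip = np.diag([1.0, -1.0, -1.0])  # 180 deg about x (plane flip)
        best = np.inf
        for a in np.arange(0, 2 * np.pi, 0.0005):
            Rz = G.rotation_from_axis_angle([0, 0, 1], a)
            for R in (Rz, Rz @ flip):
                r = np.sqrt(((xc - yc @ R.T) ** 2).sum(1).mean())
                best = min(best, r)
        assert abs(fast - best) < 1e-3

    def test_free_energy_surface_shape(self, helix20):
        ens = [helix20] * 30
        proj = mx.rg_rmsd_projection(ens, helix20)
        fes, xe, ye = mx.free_energy_surface(proj, bins=5)
        assert fes.shape == (5, 5)
        assert np.nanmin(fes) == pytest.approx(0.0)


class TestClustering:
    def test_two_rigid_families(self, rng):
        h, e = fx.ideal_helix(12), fx.extended_chain(12)
        ens = []
        for i in range(6):
            rho = G.RigidTransform(G.random_rotation(rng), rng.normal(size=3))
            ens.append(G.apply(rho, h if i < 4 else e))
        out = mx.cluster_ensemble(ens, k=2, seed=0)
        assert out["populations"] == [4 / 6, 2 / 6]

    def test_identical_ensemble_single_cluster(self, helix20):
        out = mx.cluster_ensemble([helix20] * 5, k=1)
        assert out["populations"] == [1.0]

    def test_k_equals_n(self, rng):
        ens = fx.two_state_ensemble(8, 0.5, 5, seed=4).conformations
        out = mx.cluster_ensemble(ens, k=5, seed=1)
        assert sorted(out["medoid_indices"]) == list(range(5))
        assert np.allclose(out["populations"], 0.2)


class TestRigidInvariance:
    def test_all_metrics_invariant_under_global_rigid_motion(self, rng):
        ens = fx.two_state_ensemble(10, 0.5, 12, seed=9).conformations
        rho = G.RigidTransform(G.random_rotation(rng), rng.normal(size=3) * 15)
        moved = [G.apply(rho, c) for c in ens]
        assert np.isclose(mx.validity(ens), mx.validity(moved))
        for a, b in zip(ens, moved):
            assert np.isclose(mx.radius_of_gyration(a), mx.radius_of_gyration(b))
        occ_a = mx.ramachandran_occupancy(ens)
        occ_b = mx.ramachandran_occupancy(moved)
        for k in occ_a:
            assert np.isclose(occ_a[k], occ_b[k], atol=1e-9)
        pa = mx.rg_rmsd_projection(ens, ens[0])
        pb = mx.rg_rmsd_projection(moved, ens[0])
        assert np.allclose(pa.rmsd, pb.rmsd, atol=1e-6)


class TestShiftTable:
    def test_round_trip(self, tmp_path):
        df = pd.DataFrame({
            "residue_index": [0, 1, 3],
            "observable": ["ca_shift"] * 3,
            "value": [1.0, 2.0, 4.0],
        })
        path = tmp_path / "shifts.csv"
        df.to_csv(path, index=False)
        out = mx.read_shift_table(path)
        assert np.allclose(out["ca_shift"], [1.0, 2.0, np.nan, 4.0], equal_nan=True)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"a": [1]}).to_csv(path, index=False)
        with pytest.raises(ValueError):
            mx.read_shift_table(path)
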