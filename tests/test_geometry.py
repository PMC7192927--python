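"""Closed-form DIB geometry: contact angles, regression plane, pair deformation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import bisect

import droppack as dp
from droppack.errors import GeometryError, NonPhysicalAngleWarning, SingularFitError


class TestContactAngleFromPair:
    @pytest.mark.parametrize(
        "R1, R2, L, expected",
        [
            (1.0, 1.0, 2.0, 0.0),  # tangent spheres, zero bilayer
            (1.0, 1.0, math.sqrt(2.0), 45.0),  # cos 2theta = 0
            (1.0, 1.0, 1.0, 60.0),  # cos 2theta = -1/2
        ],
    )
    def test_hand_derived_angles(self, R1, R2, L, expected):
        assert dp.contact_angle_from_pair(R1, R2, L) == pytest.approx(expected, abs=1e-9)

    def test_equal_pair_reduces_to_arccos(self):
        # for R1 = R2 = R the general relation collapses to arccos(L / 2R)
        assert dp.contact_angle_from_pair(2.0, 2.0, 3.0) == pytest.approx(
            math.degrees(math.acos(3.0 / 4.0))
        )

    @given(
        theta=st.floats(min_value=0.01, max_value=89.9),
        R=st.floats(min_value=0.1, max_value=100.0),
    )
    def test_round_trip_through_centre_distance(self, theta, R):
        L = 2.0 * R * math.cos(math.radians(theta))
        assert dp.contact_angle_from_pair(R, R, L) == pytest.approx(theta, abs=1e-9)

    @pytest.mark.parametrize("args", [(1.0, 1.0, 2.5), (1.0, 1.0, 5.0)])
    def test_non_intersecting_circles_rejected(self, args):
        with pytest.raises(GeometryError):
            dp.contact_angle_from_pair(*args)

    @pytest.mark.parametrize("args", [(-1.0, 1.0, 1.0), (1.0, 0.0, 1.0), (1.0, 1.0, 0.0)])
    def test_non_positive_inputs_rejected(self, args):
        with pytest.raises(GeometryError):
            dp.contact_angle_from_pair(*args)


class TestSurfaceContactAngle:
    @pytest.mark.parametrize(
        "R_b, R_a, expected", [(0.0, 1.0, 0.0), (1.0, 1.0, 90.0), (0.5, 1.0, 30.0)]
    )
    def test_arcsin_relation(self, R_b, R_a, expected):
        assert dp.surface_contact_angle(R_b, R_a) == pytest.approx(expected)

    def test_patch_larger_than_cap_rejected(self):
        with pytest.raises(GeometryError):
            dp.surface_contact_angle(1.5, 1.0)


class TestRegressionPlane:
    TRUE = dict(intercept=-26.444, slope_phi=103.333, slope_x=40.889)

    def _noiseless_points(self):
        design = [(0.35, 0.0), (0.5, 0.0), (0.65, 0.0), (0.65, 0.5), (0.65, 1.0), (0.5, 0.2)]
        return [
            (p, x, self.TRUE["intercept"] + self.TRUE["slope_phi"] * p + self.TRUE["slope_x"] * x)
            for p, x in design
        ]

    def test_noiseless_fit_is_exact(self):
        plane = dp.fit_theta_plane(self._noiseless_points())
        assert plane.intercept == pytest.approx(self.TRUE["intercept"], abs=1e-9)
        assert plane.slope_phi == pytest.approx(self.TRUE["slope_phi"], abs=1e-9)
        assert plane.slope_x == pytest.approx(self.TRUE["slope_x"], abs=1e-9)
        assert plane.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noiseless_fit_matches_normal_equations_oracle(self):
        pts = np.asarray(self._noiseless_points())
        X = np.column_stack([np.ones(len(pts)), pts[:, 0], pts[:, 1]])
        beta = np.linalg.solve(X.T @ X, X.T @ pts[:, 2])
        plane = dp.fit_theta_plane(pts)
        assert [plane.intercept, plane.slope_phi, plane.slope_x] == pytest.approx(
            list(beta), abs=1e-9
        )

    def test_collinear_design_raises_named_error(self):
        rows = [(0.1 * i, 0.2 * i, 5.0 * i) for i in range(5)]
        with pytest.raises(SingularFitError, match="phi_SIL"):
            dp.fit_theta_plane(rows)

    def test_noisy_recovery_within_three_standard_errors(self):
        plane = dp.published_plane()
        design = [(phi, x) for phi in (0.35, 0.45, 0.55, 0.65, 0.75) for x in (0.0, 0.25, 0.5, 0.75, 1.0)]
        table = dp.gen_theta_dataset(plane, design[:30], noise_sigma=1.0, n_reps=2, seed=42)
        fitted = dp.fit_theta_plane(table)
        X = np.column_stack(
            [np.ones(len(table)), table["phi_SIL"], table["x_POPC"]]
        )
        resid = table["theta_deg"] - X @ np.array(
            [fitted.intercept, fitted.slope_phi, fitted.slope_x]
        )
        s2 = float(resid @ resid) / (len(table) - 3)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        truth = np.array([plane.intercept, plane.slope_phi, plane.slope_x])
        est = np.array([fitted.intercept, fitted.slope_phi, fitted.slope_x])
        assert np.all(np.abs(est - truth) < 3.0 * se)


class TestPredictTheta:
    def test_published_plane_hand_evaluations(self):
        # (0.930*0.65 + 0.368*1.00 - 0.238) / 0.009 and (0.930*0.35 - 0.238) / 0.009
        assert dp.predict_theta(dp.PUBLISHED_PLANE, 0.65, 1.00) == pytest.approx(
            0.7345 / 0.009, abs=1e-9
        )
        assert dp.predict_theta(dp.PUBLISHED_PLANE, 0.35, 0.00) == pytest.approx(
            0.0875 / 0.009, abs=1e-9
        )

    @given(
        phi=st.floats(min_value=0.3, max_value=0.7),
        delta=st.floats(min_value=-0.1, max_value=0.1),
    )
    def test_linearity_in_phi(self, phi, delta):
        p = dp.PUBLISHED_PLANE
        d = dp.predict_theta(p, phi + delta, 0.3) - dp.predict_theta(p, phi, 0.3)
        assert d == pytest.approx(p.slope_phi * delta, abs=1e-9)

    def test_non_physical_prediction_flagged_not_clamped(self):
        with pytest.warns(NonPhysicalAngleWarning):
            val = dp.predict_theta(dp.PUBLISHED_PLANE, 0.0, 0.0)
        assert val < 0.0  # returned as-is


class TestCriticalAngle:
    def test_tetrahedron_dihedral(self):
        assert dp.tetrahedron_dihedral_angle() == pytest.approx(
            math.degrees(math.acos(1.0 / 3.0)), abs=1e-12
        )
        assert round(dp.tetrahedron_dihedral_angle(), 1) == 70.5
        assert math.cos(math.radians(dp.tetrahedron_dihedral_angle())) == pytest.approx(1 / 3)

    def test_critical_angle_is_half_dihedral(self):
        assert dp.critical_contact_angle() == pytest.approx(
            dp.tetrahedron_dihedral_angle() / 2.0
        )
        assert dp.critical_contact_angle() == pytest.approx(35.2644, abs=5e-5)

    def test_matches_bisection_oracle_for_oil_exclusion_condition(self):
        # theta_c solves cos(2 theta) = 1/3 on (0, 90) degrees
        root = bisect(
            lambda t: math.cos(math.radians(2.0 * t)) - 1.0 / 3.0, 1.0, 89.0, xtol=1e-12
        )
        assert dp.critical_contact_angle() == pytest.approx(root, abs=1e-9)


class TestEquilibriumPairGeometry:
    def test_undeformed_limit(self):
        g = dp.equilibrium_pair_geometry(1.0, 0.0)
        assert (g.R_theta, g.L_theta, g.r_bilayer) == pytest.approx((1.0, 2.0, 0.0))

    def test_hemisphere_limit(self):
        # at theta -> 90 deg each droplet is a hemisphere: R -> 2^(1/3) R0
        g = dp.equilibrium_pair_geometry(1.0, 89.999)
        assert g.R_theta == pytest.approx(2.0 ** (1.0 / 3.0), abs=1e-3)
        assert g.L_theta < 0.01

    @pytest.mark.parametrize("theta", list(range(5, 90, 10)))
    def test_volume_conserved(self, theta):
        R0 = 1.7
        g = dp.equilibrium_pair_geometry(R0, float(theta))
        h = g.R_theta * (1.0 - math.cos(math.radians(theta)))
        vol = (4.0 / 3.0) * math.pi * g.R_theta**3 - math.pi * h * h * (
            3.0 * g.R_theta - h
        ) / 3.0
        assert vol == pytest.approx((4.0 / 3.0) * math.pi * R0**3, rel=1e-9)

    def test_centre_distance_strictly_decreasing(self):
        L = [dp.equilibrium_pair_geometry(1.0, float(t)).L_theta for t in range(5, 90, 10)]
        assert all(a > b for a, b in zip(L, L[1:]))

    def test_out_of_range_theta_rejected(self):
        with pytest.raises(GeometryError):
            dp.equilibrium_pair_geometry(1.0, 90.0)


class TestAdhesionEnergy:
    def test_limits_and_hand_value(self):
        assert dp.adhesion_energy(1.0, 0.0).delta_F == 0.0
        assert dp.adhesion_energy(1.0, 60.0).delta_F == pytest.approx(1.0)

    def test_young_balance_and_monotonicity(self):
        thetas = np.arange(0.0, 90.0, 5.0)
        vals = [dp.adhesion_energy(2.5, t) for t in thetas]
        for t, v in zip(thetas, vals):
            assert v.gamma_b == pytest.approx(2 * 2.5 * math.cos(math.radians(t)))
        dF = [v.delta_F for v in vals]
        assert all(a < b for a, b in zip(dF, dF[1:]))


class TestSphereVolume:
    @pytest.mark.parametrize(
        "d, expected", [(100.0, 523.598776), (0.0, 0.0), (200.0, 4188.790205)]
    )
    def test_picolitre_conversion(self, d, expected):
        assert dp.sphere_volume_pL(d) == pytest.approx(expected, abs=1e-4)

    def test_printed_droplet_rounds_to_524(self):
        assert round(dp.sphere_volume_pL(100.0)) == 524

    def test_negative_diameter_rejected(self):
        with pytest.raises(GeometryError):
            dp.sphere_volume_pL(-1.0)


class TestThetaTableIO:
    def test_round_trip(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {"phi_SIL": [0.5, 0.6], "x_POPC": [0.0, 0.1], "theta_deg": [26.0, 40.0]}
        )
        path = tmp_path / "table.csv"
        dp.geometry.write_theta_table(df, path)
        back = dp.geometry.read_theta_table(path)
        assert np.allclose(back.to_numpy(), df.to_numpy())

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="theta_deg"):
            dp.geometry.read_theta_table(path)
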