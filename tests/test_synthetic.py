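"""Generators: lattices, rendered membranes, defect injection, theta tables."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.spatial import Delaunay, cKDTree

import droppack as dp
from droppack.errors import CapacityError, GeometryError


def interior_triangles(pts, margin=1.5, spacing=45.0):
    """Simplices of a point set whose vertices all sit away from the hull."""
    tri = Delaunay(pts)
    lo = pts.min(axis=0) + margin * spacing
    hi = pts.max(axis=0) - margin * spacing
    inner = np.all((pts >= lo) & (pts <= hi), axis=1)
    keep = np.all(inner[tri.simplices], axis=1)
    return pts, tri.simplices[keep]


class TestGenLattice:
    def test_hexagonal_interior_triangles_equilateral(self):
        lat = dp.gen_lattice(dp.LatticeSpec(lattice_type="hexagonal", nx=10, ny=10, spacing=45.0))
        pts, simplices = interior_triangles(lat.centroids)
        assert len(simplices) > 20
        for s in simplices:
            v = pts[s]
            sides = [np.linalg.norm(v[i] - v[(i + 1) % 3]) for i in range(3)]
            assert np.ptp(sides) < 1e-6

    def test_square_interior_triangles_right_isosceles(self):
        lat = dp.gen_lattice(dp.LatticeSpec(lattice_type="square", nx=8, ny=8, spacing=45.0))
        pts, simplices = interior_triangles(lat.centroids)
        assert len(simplices) > 10
        for s in simplices:
            v = pts[s]
            sides = sorted(np.linalg.norm(v[i] - v[(i + 1) % 3]) for i in range(3))
            assert sides[0] == pytest.approx(sides[1], abs=1e-9)
            assert sides[2] == pytest.approx(sides[0] * np.sqrt(2.0), abs=1e-9)

    @pytest.mark.parametrize(
        "jitter_frac, oracle_nn",
        # frozen Monte-Carlo oracle: mean nearest-neighbour distance of a
        # triangular lattice under iid Gaussian jitter, in units of spacing
        # (20 independent replicates of a 20x20 lattice; SD < 0.01)
        [(0.1, 0.8377), (0.2, 0.6989), (0.3, 0.5995)],
    )
    def test_amorphous_mean_neighbour_distance_matches_oracle(self, jitter_frac, oracle_nn):
        s = 45.0
        spec = dp.LatticeSpec(
            lattice_type="amorphous", nx=12, ny=12, spacing=s, jitter_sigma=jitter_frac * s, seed=4
        )
        lat = dp.gen_lattice(spec)
        d, _ = cKDTree(lat.centroids).query(lat.centroids, k=2)
        assert np.mean(d[:, 1]) / s == pytest.approx(oracle_nn, rel=0.05)

    def test_sparse_spacing_prevents_contact(self):
        lat = dp.gen_lattice(dp.LatticeSpec(lattice_type="sparse", nx=5, ny=5, spacing=10.0, droplet_radius=25.0))
        d, _ = cKDTree(lat.centroids).query(lat.centroids, k=2)
        assert d[:, 1].min() >= 2.2 * 2 * 25.0 - 1e-9

    def test_mixed_lattice_labels_rim_sites(self):
        lat = dp.gen_lattice(dp.LatticeSpec(lattice_type="mixed", nx=10, ny=10, spacing=45.0, seed=2))
        assert set(lat.site_class) == {"core", "rim"}
        # core sites are exactly on the unjittered lattice
        ideal = dp.gen_lattice(dp.LatticeSpec(lattice_type="hexagonal", nx=10, ny=10, spacing=45.0))
        core = lat.site_class == "core"
        assert np.allclose(lat.centroids[core], ideal.centroids[core])

    def test_determinism(self):
        spec = dp.LatticeSpec(lattice_type="amorphous", nx=6, ny=6, spacing=40.0, jitter_sigma=5.0, seed=9)
        assert np.array_equal(dp.gen_lattice(spec).centroids, dp.gen_lattice(spec).centroids)

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            dp.LatticeSpec(nx=1, ny=5)


class TestRenderMembraneImage:
    def test_sparse_regions_are_isolated_discs(self, sparse_network):
        n_regions = len(np.unique(sparse_network.ground_truth_labels)) - 1
        assert n_regions == sparse_network.n_design
        # each region is a full disc
        areas = sparse_network.region_areas()
        assert np.allclose(areas, np.pi * 25.0**2, rtol=0.03)

    def test_unblurred_image_has_two_levels(self):
        lat = dp.gen_lattice(dp.LatticeSpec(nx=4, ny=4, spacing=45.0))
        net = dp.render_membrane_image(lat.centroids, blur_sigma=0.0, noise_sigma=0.0)
        assert set(np.unique(net.membrane_image)) == {0.0, 1.0}

    def test_every_centroid_inside_its_own_region(self, hex_network):
        labels = hex_network.ground_truth_labels
        for i, (x, y) in enumerate(hex_network.centroids, start=1):
            assert labels[int(round(y)), int(round(x))] == i

    def test_packed_interior_regions_are_voronoi_hexagons(self):
        # spacing = 2 r cos(theta_c): droplets overlap and interior regions
        # become the hexagonal Voronoi cells of the triangular lattice
        r = 25.0
        s = 2 * r * np.cos(np.radians(dp.critical_contact_angle()))
        lat = dp.gen_lattice(dp.LatticeSpec(nx=8, ny=8, spacing=s, droplet_radius=r))
        net = dp.render_membrane_image(lat.centroids, droplet_radius=r)
        areas = net.region_areas()
        clearance_ok = areas > 0
        hex_area = (np.sqrt(3.0) / 2.0) * s * s
        interior = [
            i
            for i in range(len(areas))
            if np.all(np.abs(net.centroids[i] - net.centroids.mean(axis=0)) < 2.2 * s)
        ]
        assert len(interior) > 10
        assert np.allclose(areas[interior], hex_area, rtol=0.03)
        assert clearance_ok.all()

    def test_determinism_with_noise(self):
        lat = dp.gen_lattice(dp.LatticeSpec(nx=4, ny=4, spacing=45.0))
        a = dp.render_membrane_image(lat.centroids, noise_sigma=0.1, seed=7)
        b = dp.render_membrane_image(lat.centroids, noise_sigma=0.1, seed=7)
        assert np.array_equal(a.membrane_image, b.membrane_image)


class TestInjectInclusions:
    def test_target_zero_is_identity(self, hex_network):
        out = dp.inject_inclusions(hex_network, 0.0, seed=1)
        assert np.array_equal(out.ground_truth_labels, hex_network.ground_truth_labels)
        assert out.inclusion_mask.sum() == 0

    def test_target_fraction_achieved_on_ground_truth(self):
        spec = dp.LatticeSpec(nx=12, ny=12, spacing=45.0, droplet_radius=25.0, seed=3)
        net = dp.inject_inclusions(dp.synthesize_network(spec), 0.18, seed=3)
        inc = net.inclusion_mask.sum()
        drop = (net.ground_truth_labels > 0).sum()
        assert 0.144 <= inc / (inc + drop) <= 0.216
        assert not net.best_effort

    def test_masks_mutually_exclusive(self):
        spec = dp.LatticeSpec(nx=8, ny=8, spacing=45.0, seed=5)
        net = dp.inject_inclusions(dp.synthesize_network(spec), 0.05, seed=5)
        assert not np.any(net.inclusion_mask & (net.ground_truth_labels > 0))

    def test_unreachable_target_flagged_best_effort(self):
        # a minimal lattice has almost no interior sites to vacate
        spec = dp.LatticeSpec(nx=3, ny=3, spacing=45.0, seed=1)
        net = dp.inject_inclusions(dp.synthesize_network(spec), 0.29, seed=1)
        assert net.best_effort


class TestAddExcessDroplets:
    def test_zero_extra_is_identity(self, hex_network):
        out = dp.add_excess_droplets(hex_network, 0, seed=1)
        assert np.array_equal(out.centroids, hex_network.centroids)

    def test_excess_on_72_site_design_gives_12_5_percent(self):
        spec = dp.LatticeSpec(nx=8, ny=9, spacing=45.0, droplet_radius=25.0, seed=5)
        net = dp.add_excess_droplets(dp.synthesize_network(spec), 9, seed=5)
        assert net.n_design == 72
        n_observed = len(np.unique(net.ground_truth_labels)) - 1
        assert dp.droplet_excess(n_observed, net.n_design) == pytest.approx(12.5)

    def test_determinism(self):
        spec = dp.LatticeSpec(nx=6, ny=6, spacing=45.0, seed=2)
        base = dp.synthesize_network(spec)
        a = dp.add_excess_droplets(base, 4, seed=11)
        b = dp.add_excess_droplets(base, 4, seed=11)
        assert np.array_equal(a.centroids, b.centroids)

    def test_capacity_error_when_no_vacancies(self):
        spec = dp.LatticeSpec(nx=4, ny=4, spacing=45.0, seed=2)
        with pytest.raises(CapacityError):
            dp.add_excess_droplets(dp.synthesize_network(spec), 10_000, seed=0)


class TestGenPairImage:
    def test_ground_truth_inverts_pair_relation(self):
        _, truth = dp.gen_pair_image(40.0, 40.0, 35.3)
        assert dp.contact_angle_from_pair(truth.R1, truth.R2, truth.L) == pytest.approx(35.3)

    def test_tangent_pair_centre_distance(self):
        _, truth = dp.gen_pair_image(40.0, 30.0, 0.0)
        assert truth.L == pytest.approx(70.0)

    def test_unblurred_image_two_levels(self):
        img, _ = dp.gen_pair_image(20.0, 20.0, 30.0, blur_sigma=0.0)
        assert set(np.unique(img)) == {0.0, 1.0}

    def test_determinism_byte_identical(self):
        a, _ = dp.gen_pair_image(25.0, 25.0, 20.0, noise_sigma=0.05, seed=3)
        b, _ = dp.gen_pair_image(25.0, 25.0, 20.0, noise_sigma=0.05, seed=3)
        assert a.tobytes() == b.tobytes()

    def test_unresolvable_radii_rejected(self):
        with pytest.raises(GeometryError):
            dp.gen_pair_image(5.0, 40.0, 30.0)


class TestGenThetaDataset:
    def test_noiseless_dataset_refits_exactly(self):
        plane = dp.published_plane()
        design = [(0.35, 0.0), (0.5, 0.1), (0.65, 0.3), (0.6, 1.0)]
        table = dp.gen_theta_dataset(plane, design, noise_sigma=0.0, n_reps=2, seed=0)
        fitted = dp.fit_theta_plane(table)
        assert fitted.slope_phi == pytest.approx(plane.slope_phi, abs=1e-9)
        assert fitted.slope_x == pytest.approx(plane.slope_x, abs=1e-9)
        assert fitted.intercept == pytest.approx(plane.intercept, abs=1e-9)

    def test_row_count_is_design_times_reps(self):
        table = dp.gen_theta_dataset(dp.PUBLISHED_PLANE, [(0.5, 0.0)] * 3, 1.0, n_reps=4, seed=1)
        assert len(table) == 12


class TestWriteNetwork:
    def test_files_written_and_reloadable(self, tmp_path, sparse_network):
        meta = dp.write_network(sparse_network, tmp_path)
        assert (tmp_path / "membrane.tif").exists()
        img = dp.load_image(tmp_path / "membrane.tif")
        assert img.shape == sparse_network.shape
        assert meta["n_design"] == sparse_network.n_design
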