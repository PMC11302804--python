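"""Surface dose extraction, developable unfolding and rasterisation."""

import numpy as np
import pytest
from scipy.spatial import Delaunay

from dermadose.core import DoseGrid, GeometryError
from dermadose.unfold import (
    SurfaceSample,
    extract_surface_dose,
    isometry_error,
    rasterize_to_film_grid,
    segment_lat_inf,
    unfold_surface,
)


def _uniform_dose(small_geometry, prescription=42.5, pct=80.0):
    dose = np.full(small_geometry.shape, prescription * pct / 100.0)
    return DoseGrid(dose, small_geometry.spacing, small_geometry.origin,
                    prescription)


class TestExtract:
    def test_uniform_grid_gives_uniform_samples(self, small_phantom,
                                                small_geometry):
        dg = _uniform_dose(small_geometry)
        sample = extract_surface_dose(dg, small_phantom["contact"])
        np.testing.assert_allclose(sample.all_doses(), 80.0, atol=1e-9)

    def test_linear_gradient_sampled_exactly(self, small_phantom,
                                             small_geometry):
        """Trilinear interpolation is exact on fields linear in x."""
        geo = small_geometry
        xs = geo.origin[0] + geo.spacing[0] * np.arange(geo.shape[0])
        dose = np.broadcast_to(
            (10.0 + 2.0 * xs)[:, None, None], geo.shape
        ).copy()
        dg = DoseGrid(dose, geo.spacing, geo.origin, prescription=100.0)
        sample = extract_surface_dose(dg, small_phantom["contact"])
        for pts, vals in zip(sample.points, sample.doses):
            np.testing.assert_allclose(vals, 10.0 + 2.0 * pts[:, 0],
                                       atol=1e-9)

    def test_matches_manual_trilinear_oracle(self, small_phantom,
                                             small_geometry, rng):
        geo = small_geometry
        dose = rng.uniform(20, 50, size=geo.shape)
        dg = DoseGrid(dose, geo.spacing, geo.origin, prescription=50.0)
        sample = extract_surface_dose(dg, small_phantom["contact"],
                                      smooth_window=1)
        pts = np.concatenate(sample.points)
        got = np.concatenate(sample.doses)
        # manual trilinear interpolation, voxel-centre convention
        rel = (pts - np.array(geo.origin)) / np.array(geo.spacing)
        i0 = np.clip(np.floor(rel).astype(int),
                     0, np.array(geo.shape) - 2)
        f = rel - i0
        acc = np.zeros(len(pts))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (
                        (f[:, 0] if dx else 1 - f[:, 0])
                        * (f[:, 1] if dy else 1 - f[:, 1])
                        * (f[:, 2] if dz else 1 - f[:, 2])
                    )
                    acc += w * dose[i0[:, 0] + dx, i0[:, 1] + dy,
                                    i0[:, 2] + dz]
        np.testing.assert_allclose(got, 100.0 * acc / 50.0, atol=1e-9)

    def test_point_outside_dose_grid_rejected(self, small_phantom,
                                              small_geometry):
        geo = small_geometry
        tiny = DoseGrid(np.ones((3, 3, 3)), geo.spacing, geo.origin, 42.5)
        with pytest.raises(GeometryError):
            extract_surface_dose(tiny, small_phantom["contact"])


def _plane_sample(n_slices=10, n_pts=20, h=0.1, tilt_deg=25.0):
    """Slices of a tilted plane; in-slice direction orthogonal to the
    anchor path, so the unfolded layout must be congruent to 3D."""
    t = np.deg2rad(tilt_deg)
    points, doses = [], []
    for i in range(n_slices):
        anchor = np.array([0.0, i * h * np.sin(t), i * h * np.cos(t)])
        pts = anchor + np.outer(np.arange(n_pts) * h, [1.0, 0.0, 0.0])
        points.append(pts)
        doses.append(np.full(n_pts, 80.0) + i)
    return SurfaceSample(points, doses)


def _cylinder_sample(r=3.0, n_slices=8, dz=0.25, h=0.1):
    """Half-cylinder sector sampled at uniform arc increments."""
    n_arc = int(np.round(np.pi * r / h))
    phi = np.linspace(0.0, np.pi, n_arc + 1)
    points, doses = [], []
    for i in range(n_slices):
        z = i * dz
        pts = np.column_stack([r * np.cos(phi), -r * np.sin(phi),
                               np.full_like(phi, z)])
        points.append(pts)
        doses.append(85.0 + 5.0 * np.sin(phi))
    return SurfaceSample(points, doses)


def _cradle_sample(r=4.0, tilt_deg=12.0, arc=1.7, n_slices=12, ds=0.25,
                   h=0.12):
    """Analytic contact arc of the tilted cradle surface."""
    t = np.deg2rad(tilt_deg)
    e_ax = np.array([0.0, np.sin(t), np.cos(t)])
    n_dn = np.array([0.0, -np.cos(t), np.sin(t)])
    e_x = np.array([1.0, 0.0, 0.0])
    n_arc = int(np.round(arc * r / h))
    phi = np.linspace(-arc / 2, arc / 2, n_arc + 1)
    points, doses = [], []
    for i in range(n_slices):
        s = i * ds
        pts = (s * e_ax
               + r * np.sin(phi)[:, None] * e_x
               + r * np.cos(phi)[:, None] * n_dn)
        points.append(pts)
        doses.append(np.full(len(phi), 80.0))
    return SurfaceSample(points, doses)


class TestUnfold:
    def test_plane_unfolds_congruently(self):
        sample = _plane_sample()
        unf = unfold_surface(sample)
        # all pairwise distances preserved, not just consecutive ones
        flat3d = np.concatenate(sample.points)
        idx = np.arange(len(flat3d))
        rng = np.random.default_rng(3)
        pairs = rng.choice(idx, size=(200, 2))
        d3 = np.linalg.norm(flat3d[pairs[:, 0]] - flat3d[pairs[:, 1]], axis=1)
        d2 = np.linalg.norm(unf.points2d[pairs[:, 0]]
                            - unf.points2d[pairs[:, 1]], axis=1)
        np.testing.assert_allclose(d2, d3, atol=1e-9)

    def test_cylinder_unrolls_to_pi_r_width(self):
        r, h = 3.0, 0.1
        unf = unfold_surface(_cylinder_sample(r=r, h=h))
        width = unf.points2d[:, 0].max()
        assert abs(width - np.pi * r) < h / 2

    def test_tilted_cradle_isometry(self):
        sample = _cradle_sample()
        unf = unfold_surface(sample)
        assert isometry_error(sample, unf) < 1e-9

    def test_dose_values_carried_unchanged(self):
        sample = _cylinder_sample()
        unf = unfold_surface(sample)
        np.testing.assert_array_equal(np.sort(unf.doses),
                                      np.sort(sample.all_doses()))

    def test_contour_gap_rejected(self):
        pts = np.array([[0, 0, 0], [0.1, 0, 0], [2.0, 0, 0]])
        sample = SurfaceSample([pts], [np.zeros(3)], step_tolerance=0.3)
        with pytest.raises(GeometryError):
            unfold_surface(sample)


class TestRasterize:
    def test_uniform_points_give_uniform_raster(self):
        sample = _cylinder_sample()
        for d in sample.doses:
            d[:] = 77.0
        film = rasterize_to_film_grid(unfold_surface(sample), 0.1)
        assert film.valid_mask.sum() > 100
        np.testing.assert_allclose(film.dose[film.valid_mask], 77.0,
                                   atol=1e-9)

    def test_linear_field_rasterised_exactly(self):
        sample = _plane_sample(n_slices=15, n_pts=25)
        unf = unfold_surface(sample)
        a, b, c = 50.0, 2.0, -1.5
        unf.doses = a + b * unf.points2d[:, 0] + c * unf.points2d[:, 1]
        film = rasterize_to_film_grid(unf, 0.05)
        rows, cols = np.nonzero(film.valid_mask)
        u = unf.points2d[:, 0].min() + cols * film.pixel_spacing
        v = unf.points2d[:, 1].min() + rows * film.pixel_spacing
        np.testing.assert_allclose(film.dose[rows, cols],
                                   a + b * u + c * v, atol=1e-9)

    def test_matches_barycentric_oracle(self, rng):
        sample = _cylinder_sample()
        unf = unfold_surface(sample)
        unf.doses = rng.uniform(50, 100, size=len(unf.doses))
        film = rasterize_to_film_grid(unf, 0.12)
        tri = Delaunay(unf.points2d)
        rows, cols = np.nonzero(film.valid_mask)
        u = unf.points2d[:, 0].min() + cols * film.pixel_spacing
        v = unf.points2d[:, 1].min() + rows * film.pixel_spacing
        q = np.column_stack([u, v])
        simplex = tri.find_simplex(q)
        ok = simplex >= 0
        T = tri.transform[simplex[ok]]
        bary2 = np.einsum("nij,nj->ni", T[:, :2],
                          q[ok] - T[:, 2])
        bary = np.column_stack([bary2, 1 - bary2.sum(axis=1)])
        expected = (unf.doses[tri.simplices[simplex[ok]]] * bary).sum(axis=1)
        np.testing.assert_allclose(film.dose[rows[ok], cols[ok]], expected,
                                   atol=1e-6)

    def test_degenerate_collinear_points_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 5), np.zeros(5),
                               np.zeros(5)])
        sample = SurfaceSample([pts], [np.zeros(5)])
        unf = unfold_surface(sample)
        with pytest.raises(GeometryError):
            rasterize_to_film_grid(unf, 0.05)

    def test_provenance_points_near_their_pixels(self):
        sample = _cylinder_sample()
        unf = unfold_surface(sample)
        film = rasterize_to_film_grid(unf, 0.1)
        rows, cols = np.nonzero(film.valid_mask)
        u = unf.points2d[:, 0].min() + cols * film.pixel_spacing
        v = unf.points2d[:, 1].min() + rows * film.pixel_spacing
        src = unf.points2d[film.source_index[rows, cols]]
        dist = np.hypot(src[:, 0] - u, src[:, 1] - v)
        # nearest source sample lies within one source-spacing diagonal
        assert dist.max() < np.hypot(0.1, 0.25) + 1e-9


class TestSegment:
    def _map(self, height_cm=6.0, width_cm=4.0, spacing=0.1):
        shape = (int(height_cm / spacing), int(width_cm / spacing))
        from dermadose.core import FilmDoseMap
        return FilmDoseMap(np.full(shape, 80.0), spacing)

    def test_bands_have_expected_heights(self):
        film = self._map(25.0, 5.0, 0.5)
        regions = segment_lat_inf(film, 11.0, 14.0)
        lat_rows = regions["lateral"].any(axis=1).sum()
        assert lat_rows == pytest.approx(11.0 / 0.5 + 1, abs=1)
        assert (regions["lateral"].sum() + regions["inferior"].sum()
                == film.valid_mask.sum())

    def test_zero_lateral_extent_puts_everything_inferior(self):
        film = self._map()
        regions = segment_lat_inf(film, 0.0, 6.0)
        assert regions["lateral"].sum() <= film.shape[1]  # boundary row only
        assert regions["inferior"].sum() >= film.valid_mask.sum() \
            - film.shape[1]

    def test_partition_of_valid_area(self, rng):
        film = self._map()
        film.valid_mask[rng.random(film.shape) < 0.3] = False
        regions = segment_lat_inf(film, 2.5, 3.5)
        assert not np.any(regions["lateral"] & regions["inferior"])
        np.testing.assert_array_equal(
            regions["lateral"] | regions["inferior"], regions["full"]
        )

    def test_short_map_rejected(self):
        with pytest.raises(GeometryError):
            segment_lat_inf(self._map(3.0), 11.0, 14.0)
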