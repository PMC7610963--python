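"""LGE projection, thresholding, corridors, gap counting, pre/post maps."""

import inspect

import numpy as np
import pytest

from cquant import scar
from cquant.errors import EmptyResultError, NormalisationError, TopologyError
from cquant.types import SurfaceMesh, Volume
from conftest import make_cylinder_mesh


@pytest.fixture
def cyl():
    return make_cylinder_mesh(radius=10.0, length=30.0)


@pytest.fixture
def cyl_rim(cyl):
    # the z=0 boundary circle, in parametric order
    return np.arange(48)


class TestProjectMip:
    def test_default_probe_range_is_1mm_in_3mm_out(self):
        sig = inspect.signature(scar.project_mip)
        assert sig.parameters["inward"].default == 1.0
        assert sig.parameters["outward"].default == 3.0

    def test_constant_image_gives_constant_score(self, sphere_mesh):
        vol = Volume(np.full((60, 60, 60), 42.0),
                     np.diag([1, 1, 1, 1.0]) + 0.0)
        vol.affine[:3, 3] = -30.0
        raw = scar.project_mip(sphere_mesh, vol)
        assert np.allclose(raw, 42.0)

    def test_monotone_in_image_intensity(self, sphere_mesh):
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 100, (60, 60, 60))
        aff = np.eye(4)
        aff[:3, 3] = -30.0
        base = scar.project_mip(sphere_mesh, Volume(data, aff))
        bumped_data = data.copy()
        bumped_data[30, 30, 40] += 500.0
        bumped = scar.project_mip(sphere_mesh, Volume(bumped_data, aff))
        assert (bumped >= base - 1e-9).all()


class TestNormalizeThreshold:
    def test_iir_is_ratio(self):
        out = scar.normalize_iir(np.array([100.0, 120.0, 90.0]), 100.0)
        assert np.allclose(out, [1.0, 1.2, 0.9])

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(NormalisationError):
            scar.normalize_iir(np.array([1.0]), 0.0)

    def test_score_equal_to_threshold_excluded(self, sphere_mesh):
        scores = np.full(sphere_mesh.n_triangles, 1.2)
        smap = scar.threshold_scar(sphere_mesh, scores, 1.2)
        assert not smap.label.any()
        assert smap.burden_percent == 0.0
        assert smap.scar_area_mm2 == 0.0

    def test_burden_non_increasing_in_threshold(self, sphere_mesh):
        rng = np.random.default_rng(1)
        scores = rng.uniform(0.5, 2.0, sphere_mesh.n_triangles)
        burdens = [scar.threshold_scar(sphere_mesh, scores, t).burden_percent
                   for t in np.linspace(0.5, 2.0, 20)]
        assert all(b >= a - 1e-12 for a, b in zip(burdens[1:], burdens))


class TestCorridor:
    def test_band_area_close_to_analytic(self, cyl, cyl_rim):
        corr = scar.build_corridor(cyl, cyl_rim, width=5.0)
        area = cyl.triangle_areas()[corr.triangles].sum()
        assert area == pytest.approx(2 * np.pi * 10 * 5, rel=0.10)

    def test_tiny_width_keeps_rim_incident_triangles(self, cyl, cyl_rim):
        corr = scar.build_corridor(cyl, cyl_rim, width=1e-3)
        incident = np.isin(cyl.triangles, cyl_rim).any(axis=1)
        assert set(corr.triangles) == set(np.flatnonzero(incident))

    def test_huge_width_covers_everything(self, cyl, cyl_rim):
        corr = scar.build_corridor(cyl, cyl_rim, width=1e4)
        assert len(corr.triangles) == cyl.n_triangles

    def test_open_loop_rejected(self, cyl):
        with pytest.raises(TopologyError):
            scar.build_corridor(cyl, np.array([0, 1, 90]), 5.0)


def _ring_labels(cyl, gap_arcs_deg):
    """Scar everywhere except triangles whose centroid angle falls in the
    given arcs (degrees)."""
    ang = np.degrees(np.arctan2(cyl.triangle_centroids()[:, 1],
                                cyl.triangle_centroids()[:, 0])) % 360.0
    labels = np.ones(cyl.n_triangles, bool)
    for lo, hi in gap_arcs_deg:
        labels &= ~((ang >= lo) & (ang < hi))
    return labels


class TestCountGaps:
    def test_fully_scarred_corridor(self, cyl, cyl_rim):
        corr = scar.build_corridor(cyl, cyl_rim, 5.0)
        n, frac = scar.count_gaps(corr, np.ones(cyl.n_triangles, bool))
        assert (n, frac) == (0, 0.0)

    def test_no_scar_wraps_to_single_gap(self, cyl, cyl_rim):
        corr = scar.build_corridor(cyl, cyl_rim, 5.0)
        n, frac = scar.count_gaps(corr, np.zeros(cyl.n_triangles, bool))
        assert (n, frac) == (1, 1.0)

    @pytest.mark.parametrize("arcs", [
        [(0.0, 10.0)],
        [(0.0, 10.0), (120.0, 130.0), (240.0, 250.0)],
    ])
    def test_planted_arcs_counted_exactly(self, cyl, cyl_rim, arcs):
        corr = scar.build_corridor(cyl, cyl_rim, 5.0)
        n, frac = scar.count_gaps(corr, _ring_labels(cyl, arcs))
        assert n == len(arcs)
        planted = sum(hi - lo for lo, hi in arcs) / 360.0
        # one rim-vertex column of quantisation per arc edge
        quantum = 2 * len(arcs) / 48
        assert abs(frac - planted) <= quantum

    def test_empty_labels_on_corridor_subset(self, cyl, cyl_rim):
        corr = scar.build_corridor(cyl, cyl_rim, 5.0)
        sub = np.ones(len(corr.triangles), bool)
        n, frac = scar.count_gaps(corr, sub)
        assert (n, frac) == (0, 0.0)


class TestComparePrePost:
    def _mesh(self):
        return make_cylinder_mesh(radius=5.0, length=10.0, n_theta=16, n_z=5)

    def test_identical_maps(self):
        m = self._mesh()
        lab = np.zeros(m.n_triangles, bool)
        lab[:40] = True
        out = scar.compare_pre_post(lab, lab, m)
        assert out == {"overlap_dice": 1.0, "new_scar_fraction": 0.0,
                       "regressed_fraction": 0.0}

    def test_disjoint_maps(self):
        m = self._mesh()
        a = np.zeros(m.n_triangles, bool)
        b = np.zeros(m.n_triangles, bool)
        a[:30] = True
        b[40:70] = True
        out = scar.compare_pre_post(a, b, m)
        assert out["overlap_dice"] == 0.0
        assert out["new_scar_fraction"] == 1.0
        assert out["regressed_fraction"] == 1.0

    def test_half_overlap_new_scar_fraction(self):
        """pre = half of post by area -> new_scar_fraction = 0.5."""
        m = self._mesh()
        areas = m.triangle_areas()
        post = np.zeros(m.n_triangles, bool)
        post[:60] = True
        # uniform cylinder triangles have equal area: take exactly half
        pre = np.zeros(m.n_triangles, bool)
        pre[:30] = True
        assert areas[pre].sum() == pytest.approx(areas[post].sum() / 2)
        out = scar.compare_pre_post(pre, post, m)
        assert out["new_scar_fraction"] == pytest.approx(0.5)
        assert out["regressed_fraction"] == 0.0

    def test_dice_symmetry(self):
        m = self._mesh()
        rng = np.random.default_rng(2)
        a = rng.random(m.n_triangles) > 0.6
        b = rng.random(m.n_triangles) > 0.6
        assert scar.compare_pre_post(a, b, m)["overlap_dice"] == \
            scar.compare_pre_post(b, a, m)["overlap_dice"]

    def test_empty_sets_convention(self):
        m = self._mesh()
        z = np.zeros(m.n_triangles, bool)
        out = scar.compare_pre_post(z, z, m)
        assert out == {"overlap_dice": 0.0, "new_scar_fraction": 0.0,
                       "regressed_fraction": 0.0}
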