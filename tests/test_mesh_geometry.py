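"""Chamber geometry, structured meshing, tags, and mesh I/O."""

import math

import numpy as np
import pytest

from strainavoid.geometry import (
    ChamberGeometry,
    GeometryError,
    MaterialProps,
    build_chamber_geometry,
    groove_hydrogel_section,
    membrane_cross_section,
    membrane_longitudinal_section,
    mesh_geometry,
)
from strainavoid.mesh import coords1d, read_msh, read_vtk, structured_mesh, write_msh, write_vtk

# a desk-scale chamber for meshing tests: same groove family, smaller footprint
SMALL = ChamberGeometry(
    chamber_length=2.0,
    chamber_width=2.1,
    chamber_height=1.0,
    thin_sidewall=0.2,
    thick_sidewall=0.2,
    bottom_wall=0.5,
    groove_axis="parallel_to_stretch",
)


class TestChamberGeometry:
    def test_default_bounding_box_matches_device(self):
        solid = build_chamber_geometry(ChamberGeometry())
        assert solid.bounding_box == (20.0, 10.0, 10.0)

    def test_groove_count_matches_counting_oracle(self):
        cfg = ChamberGeometry(groove_axis="parallel_to_stretch")
        # independent arithmetic: floor(available width / (width + spacing))
        available = 10.0 - 0.1 - 5.0
        pitch = (350 + 350) * 1e-3
        assert cfg.groove_count() == math.floor(available / pitch) == 7

    def test_groove_intervals_have_design_width(self):
        cfg = ChamberGeometry(groove_axis="parallel_to_stretch")
        for lo, hi in cfg.groove_intervals():
            assert hi - lo == pytest.approx(0.35)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"groove_width": 6000.0, "groove_axis": "parallel_to_stretch"},
            {"groove_depth": 2500.0},
            {"chamber_length": -1.0},
            {"groove_axis": "diagonal"},
        ],
    )
    def test_infeasible_configurations_raise(self, kwargs):
        with pytest.raises(GeometryError):
            cfg = ChamberGeometry(**kwargs)
            build_chamber_geometry(cfg)

    def test_material_presets_validated(self):
        with pytest.raises(ValueError):
            MaterialProps(young_modulus=1e3, poisson_ratio=0.5)
        with pytest.raises(ValueError):
            MaterialProps(young_modulus=-1.0, poisson_ratio=0.3)


class TestMeshing:
    def test_unit_cube_single_region_conforming(self):
        axes = tuple(coords1d([0, 1], 0.5) for _ in range(3))
        mesh = structured_mesh(axes, lambda c: np.full(len(c), "solid", dtype=object))
        mesh.check_invariants()
        assert mesh.n_elems == 8
        assert set(mesh.regions) == {"solid"}
        assert set(mesh.facet_tags) == {"free"}

    def test_region_tags_partition_elements(self):
        solid = build_chamber_geometry(SMALL, seeding="hydrogel_3d")
        mesh = mesh_geometry(solid, resolution=0.25)
        mesh.check_invariants()
        assert set(mesh.regions) <= {"pdms", "hydrogel"}
        assert (mesh.regions == "hydrogel").sum() > 0

    def test_volume_converges_to_analytic_solid_volume(self):
        solid = build_chamber_geometry(SMALL, seeding="none")
        for res in (0.5, 0.25):
            mesh = mesh_geometry(solid, resolution=res)
            vol = mesh.element_volumes().sum()
            assert vol == pytest.approx(solid.analytic_volume(), rel=0.01)

    def test_groove_refinement_caps_element_size(self):
        solid = build_chamber_geometry(SMALL, seeding="hydrogel_3d")
        mesh = mesh_geometry(solid, resolution=0.25, refine_grooves=True)
        groove = mesh.region_mask("hydrogel")
        assert mesh.max_edge_length(groove) <= 0.1 + 1e-12

    def test_refining_resolution_increases_element_count(self):
        solid = build_chamber_geometry(SMALL)
        n_coarse = mesh_geometry(solid, resolution=0.5).n_elems
        n_fine = mesh_geometry(solid, resolution=0.25).n_elems
        assert n_fine > n_coarse

    def test_mirror_symmetry_maps_tag_structure_onto_itself(self):
        # symmetric configuration: equal sidewalls, symmetric groove array
        solid = build_chamber_geometry(SMALL, seeding="hydrogel_3d")
        mesh = mesh_geometry(solid, resolution=0.25)
        cent = mesh.element_centroids()
        mirrored = cent.copy()
        mirrored[:, 1] = SMALL.chamber_width - mirrored[:, 1]
        assert np.array_equal(
            solid.region_of(cent).astype(str), solid.region_of(mirrored).astype(str)
        )
        # boundary tag counts are mirror-invariant too
        fc = mesh.facet_centroids()
        fm = fc.copy()
        fm[:, 1] = SMALL.chamber_width - fm[:, 1]
        for tag in set(mesh.facet_tags):
            sel = mesh.facet_tags == tag
            # mirrored centroids of tagged facets coincide with tagged facets
            a = {tuple(np.round(p, 9)) for p in fc[sel]}
            b = {tuple(np.round(p, 9)) for p in fm[sel]}
            assert a == b

    def test_end_faces_are_tagged(self):
        solid = build_chamber_geometry(SMALL)
        mesh = mesh_geometry(solid, resolution=0.25)
        tags = set(mesh.facet_tags)
        assert {"clamped_end", "moving_end", "free"} <= tags

    def test_bad_resolution_raises(self):
        solid = build_chamber_geometry(SMALL)
        with pytest.raises(GeometryError):
            mesh_geometry(solid, resolution=0.0)


class TestSections:
    def test_groove_section_tags(self):
        mesh = groove_hydrogel_section(ChamberGeometry())
        mesh.check_invariants()
        assert set(mesh.facet_tags) == {"groove_bottom", "groove_sidewall", "free"}
        assert set(mesh.regions) == {"hydrogel"}

    @pytest.mark.parametrize("seeding", ["hydrogel_3d", "layer_2d"])
    def test_cross_section_regions(self, seeding):
        mesh = membrane_cross_section(ChamberGeometry(), seeding=seeding)
        mesh.check_invariants()
        expected = "hydrogel" if seeding == "hydrogel_3d" else "cell_layer"
        assert {"pdms", expected} == set(mesh.regions)

    def test_longitudinal_grooved_section_profile(self):
        mesh = membrane_longitudinal_section(
            ChamberGeometry(), seeding="hydrogel_3d", grooved=True, length=4.2
        )
        mesh.check_invariants()
        # groove fill appears periodically along the length
        gel = mesh.element_centroids()[mesh.region_mask("hydrogel")]
        assert gel[:, 1].min() >= ChamberGeometry().floor_z - 1e-9


class TestCoords1d:
    def test_breakpoints_are_honoured(self):
        c = coords1d([0.0, 0.35, 1.0], 0.3)
        assert 0.35 in c
        assert np.all(np.diff(c) <= 0.3 + 1e-12)

    def test_refinement_window(self):
        c = coords1d([0.0, 1.0, 2.0], 0.5, refine=[(0.0, 1.0, 0.1)])
        left = np.diff(c[c <= 1.0 + 1e-12])
        assert np.all(left <= 0.1 + 1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            coords1d([0.0, 1.0], -1.0)
        with pytest.raises(ValueError):
            coords1d([1.0], 0.1)


class TestMeshIO:
    def test_msh_roundtrip_preserves_tags(self, tmp_path):
        mesh = groove_hydrogel_section(ChamberGeometry(), h=0.0875)
        path = tmp_path / "groove.msh"
        write_msh(mesh, path)
        back = read_msh(path)
        assert np.allclose(back.nodes, mesh.nodes)
        assert np.array_equal(back.elems, mesh.elems)
        assert list(back.regions) == list(mesh.regions)
        assert sorted(back.facet_tags) == sorted(mesh.facet_tags)

    def test_vtk_roundtrip_geometry(self, tmp_path):
        solid = build_chamber_geometry(SMALL, seeding="hydrogel_3d")
        mesh = mesh_geometry(solid, resolution=0.5)
        path = tmp_path / "chamber.vtk"
        write_vtk(mesh, path, cell_data={"vol": mesh.element_volumes()})
        back = read_vtk(path)
        assert np.allclose(back.nodes, mesh.nodes)
        assert np.array_equal(back.elems, mesh.elems)
        assert list(back.regions) == list(mesh.regions)
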