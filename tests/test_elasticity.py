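"""Verification of the linear-elasticity solver."""

import numpy as np
import pytest

from strainavoid.elasticity import (
    LoadCase,
    SolverError,
    StrainField,
    effective_axial_strain,
    probe_strain,
    solve,
)
from strainavoid.geometry import (
    HYDROGEL,
    PDMS,
    ChamberGeometry,
    groove_hydrogel_section,
    membrane_longitudinal_section,
)
from strainavoid.mesh import coords1d, structured_mesh

from conftest import make_bar_mesh_2d, make_bar_mesh_3d

MAT = {"solid": PDMS}


def stretch_load(strain, **kw):
    return LoadCase(kind="applied_stretch", applied_strain=strain, **kw)


class TestLoadCase:
    def test_exactly_one_stretch_specification(self):
        with pytest.raises(ValueError):
            LoadCase(kind="applied_stretch")
        with pytest.raises(ValueError):
            LoadCase(kind="applied_stretch", applied_strain=0.1, applied_displacement=1.0)

    def test_condensation_needs_positive_magnitude(self):
        with pytest.raises(ValueError):
            LoadCase(kind="self_condensation", contraction_magnitude=0.0)

    def test_negative_spring_rejected(self):
        with pytest.raises(ValueError):
            LoadCase(
                kind="self_condensation",
                contraction_magnitude=0.1,
                sidewall_spring_stiffness=-1.0,
            )


class TestPatchTests:
    def test_2d_bar_uniform_axial_strain_to_machine_precision(self):
        mesh = make_bar_mesh_2d()
        fld = solve(mesh, MAT, stretch_load(0.15), clamp="roller", pin_rigid_body=True)
        # plane strain, lateral faces free: uniform state with sigma_bb = 0
        lam, mu = PDMS.lame_lambda, PDMS.lame_mu
        ebb = -lam / (lam + 2 * mu) * 0.15
        for point in [(5.0, 1.0), (1.3, 0.4), (9.0, 1.7)]:
            eps = fld.strain_at(point)
            assert eps[0, 0] == pytest.approx(0.15, abs=1e-12)
            assert eps[2, 2] == pytest.approx(ebb, abs=1e-12)  # mesh b-axis = lab z
            assert abs(eps[0, 2]) < 1e-12

    def test_3d_bar_transverse_contraction_matches_minus_nu_eps(self):
        mesh = make_bar_mesh_3d()
        fld = solve(mesh, MAT, stretch_load(0.15), clamp="roller", pin_rigid_body=True)
        eps = probe_strain(fld, (2.0, 0.5, 0.5))
        assert eps[0, 0] == pytest.approx(0.15, abs=1e-10)
        assert eps[1, 1] == pytest.approx(-0.49 * 0.15, abs=1e-9)
        assert eps[2, 2] == pytest.approx(-0.49 * 0.15, abs=1e-9)

    def test_zero_load_gives_identically_zero_field(self):
        mesh = make_bar_mesh_2d()
        fld = solve(mesh, MAT, stretch_load(0.0), clamp="roller", pin_rigid_body=True)
        assert np.abs(fld.displacement).max() == 0.0

    def test_applied_displacement_equivalent_to_strain(self):
        mesh = make_bar_mesh_2d(length=10.0)
        f1 = solve(mesh, MAT, stretch_load(0.1), clamp="roller", pin_rigid_body=True)
        f2 = solve(
            mesh,
            MAT,
            LoadCase(kind="applied_stretch", applied_displacement=1.0),
            clamp="roller",
            pin_rigid_body=True,
        )
        assert np.allclose(f1.displacement, f2.displacement, atol=1e-12)


def make_free_block(dim):
    """Untagged (fully traction-free) block for free-contraction checks."""
    axes = tuple(coords1d([0.0, 1.0], 0.25) for _ in range(dim))
    return structured_mesh(axes, lambda c: np.full(len(c), "solid", dtype=object))


class TestEigenstrain:
    def test_free_block_isotropic_contraction_gives_uniform_minus_c(self):
        mesh = make_free_block(3)
        load = LoadCase(
            kind="self_condensation", contraction_magnitude=0.1, seeding_mode="hydrogel_3d"
        )
        fld = solve(mesh, {"solid": HYDROGEL}, load,
                    eigenstrain={"solid": np.array([-0.1, -0.1, -0.1])},
                    pin_rigid_body=True)
        eps = fld.strain_at((0.5, 0.5, 0.5))
        assert np.allclose(np.diag(eps), -0.1, atol=1e-12)
        assert np.allclose(eps - np.diag(np.diag(eps)), 0.0, atol=1e-12)

    def test_free_contraction_generalized_plane_strain(self):
        # 2D section with the out-of-plane strain set to the free value -c
        mesh = make_free_block(2)
        load = LoadCase(
            kind="self_condensation", contraction_magnitude=0.1, seeding_mode="hydrogel_3d"
        )
        fld = solve(
            mesh,
            {"solid": HYDROGEL},
            load,
            eigenstrain={"solid": np.array([-0.1, -0.1, -0.1])},
            out_of_plane_strain=-0.1,
            pin_rigid_body=True,
        )
        eps = fld.strain_at((0.5, 0.5))
        assert np.allclose(np.diag(eps), -0.1, atol=1e-12)


class TestStrainFieldKinematics:
    def test_element_strain_is_symmetric_gradient_of_displacement(self):
        # impose an arbitrary affine displacement: strain must equal sym(A)
        mesh = make_bar_mesh_2d(h=1.0)
        a = np.array([[0.02, 0.01], [-0.03, 0.04]])
        u = mesh.nodes @ a.T + np.array([0.5, -0.2])
        fld = StrainField(
            mesh=mesh, displacement=u, load=stretch_load(0.0), materials=MAT,
            plane_axes=("x", "z"),
        )
        sym = 0.5 * (a + a.T)
        voigt = fld.element_strains()
        assert np.allclose(voigt[:, 0], sym[0, 0], atol=1e-13)
        assert np.allclose(voigt[:, 1], sym[1, 1], atol=1e-13)
        assert np.allclose(voigt[:, 2], 2 * sym[0, 1], atol=1e-13)

    def test_probe_outside_mesh_raises(self):
        mesh = make_bar_mesh_2d()
        fld = solve(mesh, MAT, stretch_load(0.1), clamp="roller", pin_rigid_body=True)
        with pytest.raises(SolverError):
            fld.strain_at((50.0, 1.0))
        with pytest.raises(SolverError):
            fld.strain_at((1.0, 1.0, 1.0))

    def test_effective_axial_strain_in_percent(self):
        mesh = make_bar_mesh_2d()
        fld = solve(mesh, MAT, stretch_load(0.36), clamp="roller", pin_rigid_body=True)
        assert effective_axial_strain(fld, (5.0, 1.0)) == pytest.approx(36.0, rel=1e-9)


class TestRobinSprings:
    @staticmethod
    def _solve_groove(k):
        mesh = groove_hydrogel_section(ChamberGeometry())
        load = LoadCase(
            kind="self_condensation",
            contraction_magnitude=0.15,
            sidewall_spring_stiffness=k,
            seeding_mode="hydrogel_3d",
        )
        return solve(mesh, {"hydrogel": HYDROGEL}, load, plane_axes=("y", "z"))

    def test_zero_stiffness_recovers_detached_solution(self):
        f0 = self._solve_groove(0.0)
        f_tiny = self._solve_groove(1e-3)
        assert np.allclose(f0.displacement, f_tiny.displacement, atol=1e-9)

    def test_large_stiffness_recovers_bonded_solution(self):
        f_stiff = self._solve_groove(1e15)
        f_bonded = self._solve_groove(np.inf)
        num = np.linalg.norm(f_stiff.displacement - f_bonded.displacement)
        den = np.linalg.norm(f_bonded.displacement)
        assert num / den < 1e-2

    def test_transverse_contraction_is_monotone_in_stiffness(self):
        probe = (0.175, 0.175)
        vals = [abs(self._solve_groove(k).strain_at(probe)[1, 1]) for k in (0, 1e6, 1e8, 1e10)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestSymmetryAndConvergence:
    def test_mirror_symmetric_solve_gives_mirror_related_tensors(self):
        mesh = groove_hydrogel_section(ChamberGeometry())
        load = LoadCase(
            kind="self_condensation",
            contraction_magnitude=0.15,
            sidewall_spring_stiffness=1e8,
            seeding_mode="hydrogel_3d",
        )
        fld = solve(mesh, {"hydrogel": HYDROGEL}, load, plane_axes=("y", "z"))
        w = ChamberGeometry().groove_width_mm
        for a, b in [(0.10, 0.12), (0.05, 0.30)]:
            e1 = fld.strain_at((a, b))
            e2 = fld.strain_at((w - a, b))
            scale = max(np.abs(e1).max(), 1e-12)
            assert abs(e1[1, 1] - e2[1, 1]) / scale < 1e-8
            assert abs(e1[2, 2] - e2[2, 2]) / scale < 1e-8
            assert abs(e1[1, 2] + e2[1, 2]) / scale < 1e-8  # shear flips sign

    def test_energy_decreases_monotonically_under_refinement(self):
        cfg = ChamberGeometry()
        energies = []
        for h in (0.35, 0.175, 0.0875):
            mesh = membrane_longitudinal_section(
                cfg, seeding="hydrogel_3d", grooved=True, length=4.2, h=h, h_groove=h
            )
            fld = solve(mesh, {"pdms": PDMS, "hydrogel": HYDROGEL}, stretch_load(0.15))
            energies.append(fld.energy)
        assert energies[0] > energies[1] > energies[2]


class TestErrors:
    def test_missing_material_raises(self):
        mesh = make_bar_mesh_2d()
        with pytest.raises(SolverError):
            solve(mesh, {}, stretch_load(0.1))

    def test_unconstrained_system_raises(self):
        axes = (coords1d([0, 1], 0.5), coords1d([0, 1], 0.5))
        mesh = structured_mesh(axes, lambda c: np.full(len(c), "solid", dtype=object))
        with pytest.raises(SolverError):
            solve(mesh, MAT, stretch_load(0.1))
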