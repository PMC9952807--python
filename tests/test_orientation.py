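"""Properties of the directional-elongation and strain-addition model."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from strainavoid.orientation import (
    CombinationParams,
    combine_elongations,
    directional_elongation,
    elongation_profile,
    orientation_from_tensors,
)

positive_e = st.floats(min_value=0.2, max_value=5.0)
exponent = st.floats(min_value=0.5, max_value=16.0)


def sym_tensor(rng, scale=0.15):
    a = rng.normal(0.0, scale, size=(3, 3))
    return 0.5 * (a + a.T)


def unfolded_argmax(pred):
    prof = pred.profile
    return float(prof.angles[int(np.argmax(prof.e_tot))])


class TestDirectionalElongation:
    def test_zero_strain_gives_unit_elongation(self):
        assert directional_elongation(np.zeros((3, 3)), [1.0, 0.0, 0.0]) == 1.0

    def test_diagonal_quadratic_form(self):
        eps = np.diag([0.15, -0.05, -0.05])
        assert directional_elongation(eps, [1, 0, 0]) == pytest.approx(1.15)
        assert directional_elongation(eps, [0, 1, 0]) == pytest.approx(0.95)

    def test_matches_explicit_double_sum_oracle(self, rng):
        for _ in range(20):
            eps = sym_tensor(rng)
            u = rng.normal(size=3)
            u = u / np.linalg.norm(u)
            # brute-force double sum, written out independently
            expected = 1.0
            for i in range(3):
                for j in range(3):
                    expected += u[i] * eps[i, j] * u[j]
            assert directional_elongation(eps, u) == pytest.approx(expected, abs=1e-14)

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError):
            directional_elongation(np.zeros((3, 3)), [1.0, 1.0, 0.0])

    def test_linearized_vs_finite_strain_small_at_protocol_amplitude(self, rng):
        # fiber stretch sqrt(1 + 2 u^T eps u) vs the linearization 1 + u^T eps u:
        # within 1% up to 10% fiber strain, within 2% at the 15% protocol
        # amplitude (the compressive side is the worst case)
        for _ in range(50):
            eps = sym_tensor(rng, scale=0.075)
            u = rng.normal(size=3)
            u = u / np.linalg.norm(u)
            q = float(u @ eps @ u)
            if 1 + 2 * q <= 0 or abs(q) > 0.15:
                continue
            finite = np.sqrt(1.0 + 2.0 * q)
            rel = abs((1.0 + q) - finite) / finite
            assert rel < 0.02
            if abs(q) <= 0.10:
                assert rel < 0.01


class TestCombinationLaw:
    def test_symmetric_closed_form(self):
        assert combine_elongations(1.0, 1.0, 4) == pytest.approx(2 ** (-0.25))
        assert combine_elongations(1.0, 1.0, 4) == pytest.approx(0.8409, abs=5e-5)

    def test_dominant_term_limit(self):
        assert combine_elongations(0.85, 1e6, 4) == pytest.approx(0.85, rel=1e-9)

    def test_direct_high_precision_evaluation(self):
        # frozen from an independent exact-rational evaluation of the law
        assert combine_elongations(1.15, 0.85, 4) == pytest.approx(
            0.7962728074350509, abs=1e-12
        )

    def test_non_positive_elongation_rejected(self):
        with pytest.raises(ValueError):
            combine_elongations(0.0, 1.0, 4)
        with pytest.raises(ValueError):
            combine_elongations(1.0, -0.5, 4)
        with pytest.raises(ValueError):
            combine_elongations(1.0, 1.0, 0.0)

    @given(positive_e, positive_e, exponent)
    def test_symmetry(self, a, b, n):
        assert combine_elongations(a, b, n) == pytest.approx(
            combine_elongations(b, a, n), rel=1e-12
        )

    @given(positive_e, positive_e, exponent, st.floats(min_value=0.1, max_value=10.0))
    def test_homogeneity_scales_proportionally(self, a, b, n, k):
        assert combine_elongations(k * a, k * b, n) == pytest.approx(
            k * combine_elongations(a, b, n), rel=1e-10
        )

    @given(positive_e, positive_e, exponent)
    def test_bounded_by_the_minimum(self, a, b, n):
        assert combine_elongations(a, b, n) <= min(a, b) + 1e-12

    @given(
        st.floats(min_value=0.5, max_value=2.0),
        st.floats(min_value=0.5, max_value=2.0),
        exponent,
    )
    def test_strictly_increasing_in_each_argument(self, a, b, n):
        # strict within float resolution for comparable magnitudes
        base = combine_elongations(a, b, n)
        assert combine_elongations(a * 1.01, b, n) > base
        assert combine_elongations(a, b * 1.01, n) > base

    @given(positive_e, positive_e)
    def test_large_n_limit_approaches_the_minimum(self, a, b):
        # exact bound: min * 2^(-1/n) <= combine <= min, saturated at a = b
        c = combine_elongations(a, b, 64)
        lo = min(a, b) * 2 ** (-1.0 / 64.0)
        assert lo - 1e-12 <= c <= min(a, b) + 1e-12
        if abs(a - b) >= 0.05 * min(a, b):
            assert c == pytest.approx(min(a, b), rel=0.01)

    def test_compression_weighted_more_than_extension(self):
        # around e = 1 a compressive perturbation changes the sum more than
        # an extensional one of the same size
        delta = 0.1
        base = combine_elongations(1.0, 1.0, 4)
        down = combine_elongations(1.0 - delta, 1.0, 4)
        up = combine_elongations(1.0 + delta, 1.0, 4)
        assert base - down > up - base


class TestOrientationPrediction:
    def test_pure_cyclic_uniaxial_orients_perpendicular(self):
        eps = np.diag([0.15, -0.05, -0.05])
        pred = orientation_from_tensors(eps, None)
        assert pred.angle == 90.0
        # sign convention: compressive phase -> e_cyclic(0) = 0.85
        assert pred.profile.e_cyclic[0] == pytest.approx(0.85)

    def test_pure_condensation_in_parallel_grooves_orients_along_grooves(self):
        eps_self = np.diag([0.0, -0.15, -0.2])  # constrained along x, contracts in y
        pred = orientation_from_tensors(None, eps_self)
        assert pred.angle == 0.0

    def test_zero_stretch_gives_unit_cyclic_profile(self):
        pred = orientation_from_tensors(None, np.diag([0.0, -0.1, 0.0]))
        assert np.allclose(pred.profile.e_cyclic, 1.0)

    def test_agreeing_cues_keep_their_common_direction(self):
        eps_c = np.diag([0.15, -0.05, 0.0])   # cyclic: favours 90
        eps_s = np.diag([-0.15, 0.0, 0.0])    # condensation: also favours 90
        pred = orientation_from_tensors(eps_c, eps_s)
        assert pred.angle == 90.0

    def test_conflicting_cues_give_oblique_angle(self):
        eps_c = np.diag([0.15, -0.05, 0.0])
        eps_s = np.diag([0.0, -0.15, 0.0])
        pred = orientation_from_tensors(eps_c, eps_s)
        assert 30.0 < pred.angle < 70.0

    def test_isotropic_field_flagged_degenerate(self):
        pred = orientation_from_tensors(None, -0.1 * np.eye(3))
        assert pred.degenerate
        assert np.isnan(pred.angle)

    def test_symmetric_profile_folds_to_single_angle(self):
        # shear-free conflict: maxima at theta* and 180 - theta* fold together
        eps_c = np.diag([0.15, -0.05, 0.0])
        eps_s = np.diag([0.0, -0.15, 0.0])
        pred = orientation_from_tensors(eps_c, eps_s)
        prof = pred.profile
        peaks = prof.angles[prof.e_tot >= prof.e_tot.max() - 1e-12]
        assert len(peaks) == 2  # theta* and its mirror
        assert not pred.tie     # both fold to the same reported angle
        assert 0.0 <= pred.angle <= 90.0

    def test_rotation_equivariance_within_grid_step(self, rng):
        params = CombinationParams(angle_grid=0.5)
        for _ in range(10):
            eps_c = sym_tensor(rng)
            eps_s = sym_tensor(rng)
            base = orientation_from_tensors(eps_c, eps_s, params)
            if base.degenerate:
                continue
            phi = float(rng.uniform(5.0, 85.0))
            c, s = np.cos(np.deg2rad(phi)), np.sin(np.deg2rad(phi))
            r = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
            rot = orientation_from_tensors(
                r @ eps_c @ r.T, r @ eps_s @ r.T, params
            )
            d = abs(unfolded_argmax(rot) - (unfolded_argmax(base) + phi)) % 180.0
            d = min(d, 180.0 - d)
            assert d <= params.angle_grid + 1e-9

    def test_elongation_profile_bounded_by_component_profiles(self, rng):
        for _ in range(10):
            pred = orientation_from_tensors(sym_tensor(rng), sym_tensor(rng))
            prof = pred.profile
            assert np.all(prof.e_tot <= np.minimum(prof.e_cyclic, prof.e_self) + 1e-12)

    def test_angle_grid_must_divide_180(self):
        with pytest.raises(ValueError):
            CombinationParams(angle_grid=0.7)
        with pytest.raises(ValueError):
            CombinationParams(n=-1.0)

    def test_field_kind_checked(self):
        from strainavoid.elasticity import LoadCase, StrainField
        from strainavoid.orientation import cyclic_elongation_field

        from conftest import make_bar_mesh_2d
        from strainavoid.geometry import PDMS

        mesh = make_bar_mesh_2d(h=1.0)
        fld = StrainField(
            mesh=mesh,
            displacement=np.zeros_like(mesh.nodes),
            load=LoadCase(kind="self_condensation", contraction_magnitude=0.1,
                          seeding_mode="hydrogel_3d"),
            materials={"solid": PDMS},
            plane_axes=("x", "z"),
        )
        with pytest.raises(ValueError):
            cyclic_elongation_field(fld, (5.0, 1.0))
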