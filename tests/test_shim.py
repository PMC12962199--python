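import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lungshim as ls
from lungshim.errors import EmptyMaskError, RankDeficientError, ShimConfigParseError


def make_field(nu, valid=None):
    nu = np.asarray(nu, dtype=float)
    return ls.FieldMap(
        nu_hat=nu,
        phi0_hat=np.zeros_like(nu),
        residual_rms=np.zeros_like(nu),
        precision_hz=np.zeros_like(nu),
        valid_mask=np.ones(nu.shape, bool) if valid is None else valid,
    )


@pytest.fixture(scope="module")
def geometry():
    return ls.Geometry2D(matrix=(128, 128), fov_mm=(450.0, 450.0))


@pytest.fixture(scope="module")
def basis(geometry):
    return ls.build_basis(geometry, order=2)


class TestBuildBasis:
    def test_nine_columns(self, basis):
        assert basis.n_functions == 9

    def test_origin_evaluation(self, geometry):
        # evaluate at exactly (x, z) = (0, 0) on an odd grid with a centre pixel
        geom = ls.Geometry2D(matrix=(129, 129), fov_mm=(450.0, 450.0))
        b = ls.build_basis(geom)
        centre = b.functions[:, 64, 64]
        assert centre.tolist() == [1, 0, 0, 0, 0, 0, 0, 0, 0]

    def test_printed_order_at_sample_point(self):
        # direct evaluation at (x=100 mm, z=200 mm, y=0)
        geom = ls.Geometry2D(matrix=(5, 5), fov_mm=(1000.0, 500.0))  # 200/100 mm px
        b = ls.build_basis(geom)
        z, x = geom.coordinate_grids()
        idx = np.argwhere((z == 200.0) & (x == 100.0))
        assert len(idx) == 1
        r, c = idx[0]
        expected = [1, 200, 100, 0, 35000, 20000, 0, 10000, 0]
        assert b.functions[:, r, c].tolist() == expected

    def test_y_columns_identically_zero(self, basis):
        for k in (3, 6, 8):
            assert np.all(basis.functions[k] == 0)
        assert np.all(basis.functions[0] == 1)

    def test_excluded_set(self, basis):
        assert basis.excluded == frozenset({3, 6, 8})


class TestSolveShim:
    def test_constant_field(self, basis):
        field = make_field(np.full((128, 128), 100.0))
        mask = np.zeros((128, 128), bool)
        mask[30:90, 20:60] = True
        sol = ls.solve_shim(field, mask, basis)
        assert sol.coefficients[0] == pytest.approx(100.0, abs=1e-9)
        assert np.allclose(np.delete(sol.coefficients, 0), 0.0, atol=1e-9)

    def test_forward_constructed_recovery(self, basis):
        rng = np.random.default_rng(0)
        c_true = np.zeros(9)
        c_true[[0, 1, 2, 4, 5, 7]] = [50.0, 0.8, -0.5, 3e-3, -2e-3, 1.5e-3]
        field = make_field(np.tensordot(c_true, basis.functions, axes=1))
        mask = rng.random((128, 128)) < 0.2
        sol = ls.solve_shim(field, mask, basis)
        assert np.linalg.norm(sol.coefficients - c_true) <= 1e-9 * np.linalg.norm(c_true)
        residual = ls.predict_residual(field, sol, basis)
        assert np.sqrt(np.mean(residual.nu_hat[mask] ** 2)) <= 1e-9

    def test_matches_normal_equations_oracle(self, basis):
        rng = np.random.default_rng(1)
        field = make_field(rng.normal(scale=50.0, size=(128, 128)))
        flat = rng.choice(128 * 128, size=50, replace=False)
        mask = np.zeros(128 * 128, bool)
        mask[flat] = True
        mask = mask.reshape(128, 128)
        sol = ls.solve_shim(field, mask, basis)
        kept = [0, 1, 2, 4, 5, 7]
        a = np.stack([basis.functions[k][mask] for k in kept], axis=1)
        b = field.nu_hat[mask]
        c_ne = np.linalg.solve(a.T @ a, a.T @ b)
        assert np.allclose(sol.coefficients[kept], c_ne, rtol=1e-8, atol=1e-10)

    def test_excluded_coefficients_exactly_zero(self, basis):
        rng = np.random.default_rng(2)
        field = make_field(rng.normal(size=(128, 128)))
        mask = rng.random((128, 128)) < 0.3
        sol = ls.solve_shim(field, mask, basis)
        assert sol.coefficients[3] == 0.0
        assert sol.coefficients[6] == 0.0
        assert sol.coefficients[8] == 0.0

    def test_residual_ss_not_worse_than_zero_solution(self, basis):
        rng = np.random.default_rng(3)
        field = make_field(rng.normal(scale=30, size=(128, 128)) + 40)
        mask = rng.random((128, 128)) < 0.2
        sol = ls.solve_shim(field, mask, basis)
        assert sol.residual_ss <= sol.unshimmed_ss

    def test_residual_orthogonal_to_retained_columns(self, basis):
        rng = np.random.default_rng(4)
        field = make_field(rng.normal(scale=30, size=(128, 128)))
        mask = rng.random((128, 128)) < 0.2
        sol = ls.solve_shim(field, mask, basis)
        res = ls.predict_residual(field, sol, basis)
        r = res.nu_hat[mask]
        for k in (0, 1, 2, 4, 5, 7):
            col = basis.functions[k][mask]
            cosine = abs(r @ col) / (np.linalg.norm(r) * np.linalg.norm(col))
            assert cosine <= 1e-6

    def test_empty_mask_raises(self, basis):
        field = make_field(np.zeros((128, 128)))
        with pytest.raises(EmptyMaskError):
            ls.solve_shim(field, np.zeros((128, 128), bool), basis)

    def test_degenerate_mask_names_deficient_directions(self, basis):
        # mask on a single row: z is constant, so z-dependent terms collapse
        field = make_field(np.random.default_rng(5).normal(size=(128, 128)))
        mask = np.zeros((128, 128), bool)
        mask[64, 10:120] = True
        with pytest.raises(RankDeficientError) as exc:
            ls.solve_shim(field, mask, basis)
        assert exc.value.deficient_columns

    def test_y_independent_field_unchanged_by_exclusion(self, basis):
        rng = np.random.default_rng(6)
        field = make_field(rng.normal(scale=30, size=(128, 128)))
        mask = rng.random((128, 128)) < 0.2
        a = ls.solve_shim(field, mask, basis, excluded=frozenset({3, 6, 8}))
        # keeping the (identically zero) y columns must not change anything;
        # lstsq assigns them zero because they carry no signal
        b = ls.solve_shim(field, mask, basis, excluded=frozenset())
        kept = [0, 1, 2, 4, 5, 7]
        assert np.allclose(a.coefficients[kept], b.coefficients[kept], atol=1e-9)


class TestPredictResidual:
    def test_zero_solution_identity(self, basis):
        field = make_field(np.random.default_rng(0).normal(size=(128, 128)))
        sol = ls.ShimSolution(coefficients=np.zeros(9))
        res = ls.predict_residual(field, sol, basis)
        assert np.array_equal(res.nu_hat, field.nu_hat)

    def test_harmonic_field_fully_removed(self, basis):
        c = np.zeros(9)
        c[[0, 1, 4]] = [10.0, 0.3, 1e-3]
        field = make_field(np.tensordot(c, basis.functions, axes=1))
        mask = np.zeros((128, 128), bool)
        mask[40:80, 40:80] = True
        sol = ls.solve_shim(field, mask, basis)
        res = ls.predict_residual(field, sol, basis)
        assert np.abs(res.nu_hat[mask]).max() <= 1e-9

    def test_phantom_mean_abs_reduced(self, noiseless_fieldmap, default_phantom, basis):
        truth, _ = default_phantom
        sol = ls.solve_shim(noiseless_fieldmap, truth.lung_mask, basis)
        res = ls.predict_residual(noiseless_fieldmap, sol, basis)
        m = truth.lung_mask & noiseless_fieldmap.valid_mask
        assert np.mean(np.abs(res.nu_hat[m])) <= np.mean(
            np.abs(noiseless_fieldmap.nu_hat[m])
        )


class TestShimConfigFile:
    def test_round_trip_values(self, tmp_path):
        coeffs = np.zeros(9)
        coeffs[[0, 1, 2, 4, 5, 7]] = [11.0, -0.25, 0.125, 1e-3, -2e-3, 5e-4]
        sol = ls.ShimSolution(coefficients=coeffs)
        path = tmp_path / "shim.txt"
        ls.write_shim_config(path, sol, ls.Geometry2D((128, 128), (450.0, 450.0)))
        back = ls.read_shim_config(path)
        assert np.allclose(back.coefficients, coeffs, atol=0.5e-6)

    def test_round_trip_bit_stable(self, tmp_path):
        rng = np.random.default_rng(8)
        coeffs = np.zeros(9)
        coeffs[[0, 1, 2, 4, 5, 7]] = rng.normal(size=6)
        sol = ls.ShimSolution(coefficients=coeffs)
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        ls.write_shim_config(p1, sol)
        ls.write_shim_config(p2, ls.read_shim_config(p1))
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_key_named(self, tmp_path):
        path = tmp_path / "bad.txt"
        ls.write_shim_config(path, ls.ShimSolution(coefficients=np.zeros(9)))
        lines = [l for l in path.read_text().splitlines() if "f0_offset_hz" not in l]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ShimConfigParseError) as exc:
            ls.read_shim_config(path)
        assert "f0_offset_hz" in exc.value.missing_keys

    def test_malformed_line_reported(self, tmp_path):
        path = tmp_path / "bad.txt"
        ls.write_shim_config(path, ls.ShimSolution(coefficients=np.zeros(9)))
        path.write_text(path.read_text() + "c1_z_hz_per_mm = banana\n")
        with pytest.raises(ShimConfigParseError):
            ls.read_shim_config(path)

    def test_hand_written_f0(self, tmp_path):
        path = tmp_path / "hand.txt"
        path.write_text(
            "f0_offset_hz = 11.0\n"
            "c1_z_hz_per_mm = 0\n"
            "c2_x_hz_per_mm = 0\n"
            "c4_z2_hz_per_mm2 = 0\n"
            "c5_zx_hz_per_mm2 = 0\n"
            "c7_x2y2_hz_per_mm2 = 0\n"
        )
        sol = ls.read_shim_config(path)
        assert sol.coefficients[0] == 11.0

    @settings(max_examples=25, deadline=None)
    @given(vals=st.lists(
        st.floats(-1e3, 1e3).map(lambda v: round(v, 6)), min_size=6, max_size=6
    ))
    def test_round_trip_printed_precision(self, tmp_path_factory, vals):
        coeffs = np.zeros(9)
        coeffs[[0, 1, 2, 4, 5, 7]] = vals
        path = tmp_path_factory.mktemp("cfg") / "shim.txt"
        ls.write_shim_config(path, ls.ShimSolution(coefficients=coeffs))
        back = ls.read_shim_config(path)
        assert np.allclose(back.coefficients, coeffs, atol=0.5e-6)
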