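"""Tensor estimation: design matrix, least-squares fit, eigensystem,
scalar maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokedti.image_io import GradientTable, ImageGrid
from strokedti.synthetic_data import simulate_dwi
from strokedti.tensor_fit import (
    TensorVolume,
    design_matrix,
    eigensystem,
    fa_map,
    fit_volume,
    fit_voxel,
    matrices_to_tensor_elements,
    md_map,
    trace_map,
)

from conftest import random_spd_tensors, uniform_isotropic_volume


def volume_from_tensors(mats, s0=1000.0):
    """Pack (n, 3, 3) tensors into an n-voxel TensorVolume."""
    n = mats.shape[0]
    grid = ImageGrid((n, 1, 1))
    return TensorVolume(
        grid=grid,
        d=matrices_to_tensor_elements(mats).reshape(grid.shape + (6,)),
        ln_s0=np.full(grid.shape, np.log(s0)),
        residual_rms=np.zeros(grid.shape),
        mask=np.ones(grid.shape, dtype=bool),
    )


class TestDesignMatrix:
    def test_b0_row_is_intercept_only(self, table):
        x = design_matrix(table)
        np.testing.assert_array_equal(x[0], [1, 0, 0, 0, 0, 0, 0])

    def test_axis_aligned_row(self, table):
        ext = GradientTable(
            np.append(table.bvals, 1000.0), np.vstack([table.bvecs, [1.0, 0.0, 0.0]])
        )
        x = design_matrix(ext)
        np.testing.assert_allclose(x[-1], [1, -1000, 0, 0, 0, 0, 0], atol=1e-12)

    def test_default_table_has_full_rank(self, table):
        assert np.linalg.matrix_rank(design_matrix(table)) == 7

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError, match="rank-deficient"):
            design_matrix(GradientTable(np.zeros(8), np.zeros((8, 3))))
        # coplanar directions: everything in the x-y plane
        g = np.array([[np.cos(a), np.sin(a), 0.0] for a in np.linspace(0, 3, 7)])
        t = GradientTable([0] + [1000] * 7, np.vstack([[0, 0, 0], g]))
        with pytest.raises(ValueError, match="rank-deficient"):
            design_matrix(t)


class TestFit:
    def test_noiseless_recovery_many_random_tensors(self, table, rng):
        """Simulate→fit inverts the forward model to machine precision."""
        mats = random_spd_tensors(rng, 300)
        tv = volume_from_tensors(mats)
        stack = simulate_dwi(tv, table, snr=None)
        fit, report = fit_volume(stack)
        assert report.n_masked_out == 0
        scale = np.abs(tv.d).max(axis=-1)
        rel = np.abs(fit.d - tv.d).max(axis=-1) / scale
        assert rel.max() < 1e-9
        np.testing.assert_allclose(fit.ln_s0, tv.ln_s0, rtol=1e-9)
        assert fit.residual_rms.max() < 1e-10

    def test_constant_signal_gives_zero_tensor(self, table):
        x = design_matrix(table)
        d, ln_s0, _ = fit_voxel(np.full(len(table), 250.0), x)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)
        assert ln_s0 == pytest.approx(np.log(250.0))

    def test_isotropic_truth_recovers_diagonal(self, table):
        d_true = 7e-4
        s = 1000.0 * np.exp(-table.bvals * d_true)
        d, ln_s0, _ = fit_voxel(s, design_matrix(table))
        np.testing.assert_allclose(d[:3], d_true, rtol=1e-9)
        np.testing.assert_allclose(d[3:], 0.0, atol=1e-12)

    def test_nonpositive_rows_dropped_then_voxel_masked(self, table):
        x = design_matrix(table)
        s = 1000.0 * np.exp(-table.bvals * 5e-4)
        s_one_bad = s.copy()
        s_one_bad[3] = 0.0  # 12 rows remain -> fit proceeds
        d, _, _ = fit_voxel(s_one_bad, x)
        np.testing.assert_allclose((d[0] + d[1] + d[2]) / 3, 5e-4, rtol=1e-9)
        s_bad = s.copy()
        s_bad[:7] = 0.0  # 6 rows remain -> cannot fit
        assert fit_voxel(s_bad, x) is None

    def test_all_zero_voxel_masked_not_raised(self, table, rng):
        tv = uniform_isotropic_volume((4, 4, 1))
        stack = simulate_dwi(tv, table, snr=None)
        stack.signal[2, 2, 0, :] = 0.0
        fit, report = fit_volume(stack)
        assert not fit.mask[2, 2, 0]
        assert report.n_masked_out == 1
        assert fit.mask.sum() == 15

    def test_empty_mask_fits_nothing(self, table):
        tv = uniform_isotropic_volume((3, 3, 1))
        stack = simulate_dwi(tv, table, snr=None)
        fit, report = fit_volume(stack, mask=np.zeros((3, 3, 1), dtype=bool))
        assert report.n_attempted == 0 and report.n_fit == 0
        assert not fit.mask.any()

    def test_ols_and_wls_agree_in_noiseless_limit(self, table, rng):
        mats = random_spd_tensors(rng, 50)
        tv = volume_from_tensors(mats)
        stack = simulate_dwi(tv, table, snr=None)
        ols, _ = fit_volume(stack, weighting="ols")
        wls, _ = fit_volume(stack, weighting="wls")
        np.testing.assert_allclose(ols.d, wls.d, atol=1e-15 + 1e-9 * np.abs(ols.d).max())

    def test_rotation_invariance(self, table, rng):
        """Rotating gradients and tensor together leaves λ and MD fixed."""
        from scipy.spatial.transform import Rotation

        mats = random_spd_tensors(rng, 1)
        tv = volume_from_tensors(mats)
        base_fit, _ = fit_volume(simulate_dwi(tv, table, snr=None))
        base_es = eigensystem(base_fit)
        for rot in Rotation.random(25, rng=rng):
            r = rot.as_matrix()
            t_rot = GradientTable(table.bvals, table.bvecs @ r.T)
            tv_rot = volume_from_tensors(r @ mats @ r.T)
            fit, _ = fit_volume(simulate_dwi(tv_rot, t_rot, snr=None))
            es = eigensystem(fit)
            np.testing.assert_allclose(
                es.eigenvalues, base_es.eigenvalues, rtol=1e-9, atol=1e-18
            )


class TestEigenSystem:
    def test_diagonal_tensor(self):
        lam = np.array([3e-3, 2e-3, 1e-3])
        tv = volume_from_tensors(np.diag(lam)[None])
        es = eigensystem(tv)
        np.testing.assert_allclose(es.eigenvalues[0, 0, 0], lam, rtol=1e-12)
        np.testing.assert_allclose(np.abs(es.eigenvectors[0, 0, 0]), np.eye(3), atol=1e-12)

    def test_reconstruction_and_orthonormality(self, rng):
        mats = random_spd_tensors(rng, 200)
        es = eigensystem(volume_from_tensors(mats))
        v = es.eigenvectors.reshape(-1, 3, 3)
        lam = es.eigenvalues.reshape(-1, 3)
        assert np.all(np.diff(lam, axis=1) <= 1e-18)  # descending
        ident = np.einsum("nij,nik->njk", v, v)
        np.testing.assert_allclose(ident, np.broadcast_to(np.eye(3), ident.shape), atol=1e-6)
        rebuilt = np.einsum("nij,nj,nkj->nik", v, lam, v)
        np.testing.assert_allclose(rebuilt, mats, rtol=1e-9, atol=1e-15)

    def test_eigenvector_sign_is_deterministic(self, rng):
        mats = random_spd_tensors(rng, 50)
        es = eigensystem(volume_from_tensors(mats))
        v = es.eigenvectors.reshape(-1, 3, 3)
        picked = np.take_along_axis(v, np.argmax(np.abs(v), axis=1)[:, None, :], axis=1)
        assert np.all(picked >= 0)


class TestScalarMaps:
    def test_trace_and_md_from_eigenvalues(self):
        tv = volume_from_tensors(np.diag([3e-3, 2e-3, 1e-3])[None])
        es = eigensystem(tv)
        assert trace_map(es).values[0, 0, 0] == pytest.approx(6e-3, rel=1e-12)
        assert md_map(es).values[0, 0, 0] == pytest.approx(2e-3, rel=1e-12)

    def test_md_equals_mean_eigenvalue(self, rng):
        mats = random_spd_tensors(rng, 1000)
        es = eigensystem(volume_from_tensors(mats))
        md = md_map(es).values.ravel()
        np.testing.assert_allclose(md, es.eigenvalues.reshape(-1, 3).mean(axis=1), rtol=1e-12)

    @pytest.mark.parametrize(
        "lam, expected",
        [
            ((1e-3, 1e-3, 1e-3), 0.0),
            ((1e-3, 0.0, 0.0), 1.0),
            ((2e-3, 1e-3, 1e-3), np.sqrt(1.0 / 6.0)),  # hand-computed
        ],
    )
    def test_fa_reference_values(self, lam, expected):
        tv = volume_from_tensors(np.diag(lam)[None])
        fa = fa_map(eigensystem(tv)).values[0, 0, 0]
        assert fa == pytest.approx(expected, abs=1e-12)

    def test_fa_bounded_and_undefined_at_zero_md(self, rng):
        mats = random_spd_tensors(rng, 500)
        mats[0] = 0.0
        fa = fa_map(eigensystem(volume_from_tensors(mats))).values.ravel()
        assert np.isnan(fa[0])
        good = fa[1:]
        assert np.all((good >= 0) & (good <= 1))

    def test_negative_eigenvalues_preserved_but_clamped_in_maps(self):
        tv = volume_from_tensors(np.diag([2e-3, 1e-3, -1e-4])[None])
        es = eigensystem(tv)
        assert es.eigenvalues[0, 0, 0, 2] == pytest.approx(-1e-4)
        assert trace_map(es).values[0, 0, 0] == pytest.approx(3e-3, rel=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    d=st.floats(min_value=1e-5, max_value=3e-3),
    s0=st.floats(min_value=10.0, max_value=1e4),
)
def test_isotropic_closed_form_recovery_property(d, s0):
    """For S = S0·e^(−b·d), the fit returns d and S0 exactly."""
    from strokedti.image_io import default_gradient_table

    t = default_gradient_table()
    s = s0 * np.exp(-t.bvals * d)
    elems, ln_s0, rms = fit_voxel(s, design_matrix(t))
    np.testing.assert_allclose(elems[:3], d, rtol=1e-9)
    np.testing.assert_allclose(elems[3:], 0.0, atol=1e-12 * d)
    assert ln_s0 == pytest.approx(np.log(s0), rel=1e-9)
    assert rms < 1e-10


def test_noise_consistency_error_halves_with_snr(table):
    """Median |MD error| on an isotropic phantom shrinks as SNR doubles."""
    tv = uniform_isotropic_volume((40, 25, 1))
    med_abs = []
    for i, snr in enumerate((30, 60, 120)):
        stack = simulate_dwi(tv, table, s0=1000.0, snr=snr, seed=500 + i)
        fit, _ = fit_volume(stack)
        md = md_map(eigensystem(fit)).values
        med_abs.append(np.median(np.abs(md / 3e-4 - 1.0)))
    assert med_abs[0] > med_abs[1] > med_abs[2]
    # median estimate itself stays near truth even at the lowest SNR
    assert med_abs[2] < 0.03
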