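"""Voxelwise diffusion-tensor estimation and scalar-map derivation.

The signal model is the mono-exponential tensor model

    S_i = S0 * exp(-b_i g_i^T D g_i),

linearized as ln S_i = ln S0 - b_i g_i^T D g_i and solved per voxel by
least squares for the 7-vector (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz).
Ordinary least squares on log-signals is the default (the classic log-linear
estimator); weighted least squares with weights equal to the squared
predicted signal is available as an option.  The fitted tensor is
diagonalized per voxel into sorted eigenvalues and orthonormal eigenvectors,
from which Trace(D) = λ1+λ2+λ3, MD = Trace(D)/3 and the standard fractional
anisotropy are derived.

Handling of pathological voxels: measurement rows with signal <= 0 are
dropped for that voxel (the log is undefined there); a voxel is masked out
of the fit entirely if fewer than 7 usable rows remain.  Negative
eigenvalues produced by noise are preserved in the eigensystem and clamped
to zero only when scalar maps are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import DWIStack, GradientTable, ImageGrid, ScalarMap

__all__ = [
    "TensorVolume",
    "TensorEigenSystem",
    "FitReport",
    "design_matrix",
    "fit_voxel",
    "fit_volume",
    "eigensystem",
    "trace_map",
    "md_map",
    "fa_map",
]

#: storage order of the six unique tensor elements
TENSOR_ELEMENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


@dataclass
class TensorVolume:
    """Per-voxel symmetric tensor fit.

    ``d`` holds the six unique elements in :data:`TENSOR_ELEMENTS` order on
    the last axis, in mm^2/s; ``ln_s0`` the fitted log baseline intensity;
    ``residual_rms`` the RMS log-signal residual; ``mask`` marks voxels with
    a valid fit.
    """

    grid: ImageGrid
    d: np.ndarray  # (..., 6)
    ln_s0: np.ndarray
    residual_rms: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.d.shape != self.grid.shape + (6,):
            raise ValueError("tensor element array must be grid.shape + (6,)")
        for name in ("ln_s0", "residual_rms", "mask"):
            if getattr(self, name).shape != self.grid.shape:
                raise ValueError(f"{name} must match grid shape")
        if np.any(self.residual_rms[self.mask] < 0):
            raise ValueError("residual_rms must be nonnegative")

    def as_matrices(self) -> np.ndarray:
        """Expand the six unique elements into full (..., 3, 3) symmetric
        matrices."""
        return tensor_elements_to_matrices(self.d)


@dataclass
class TensorEigenSystem:
    """Per-voxel eigendecomposition: ``eigenvalues[..., k]`` sorted
    descending (λ1 >= λ2 >= λ3, mm^2/s), ``eigenvectors[..., :, k]`` the
    matching orthonormal eigenvector columns."""

    grid: ImageGrid
    eigenvalues: np.ndarray  # (..., 3) descending
    eigenvectors: np.ndarray  # (..., 3, 3), column k ↔ eigenvalue k
    mask: np.ndarray


@dataclass(frozen=True)
class FitReport:
    """Bookkeeping for a volume fit."""

    n_attempted: int
    n_fit: int
    n_masked_out: int

    def to_tsv(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(
            "voxels_attempted\tvoxels_fit\tvoxels_masked_out\n"
            f"{self.n_attempted}\t{self.n_fit}\t{self.n_masked_out}\n"
        )


def tensor_elements_to_matrices(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    out = np.zeros(d.shape[:-1] + (3, 3), dtype=float)
    xx, yy, zz, xy, xz, yz = (d[..., i] for i in range(6))
    out[..., 0, 0] = xx
    out[..., 1, 1] = yy
    out[..., 2, 2] = zz
    out[..., 0, 1] = out[..., 1, 0] = xy
    out[..., 0, 2] = out[..., 2, 0] = xz
    out[..., 1, 2] = out[..., 2, 1] = yz
    return out


def matrices_to_tensor_elements(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    return np.stack(
        [m[..., 0, 0], m[..., 1, 1], m[..., 2, 2], m[..., 0, 1], m[..., 0, 2], m[..., 1, 2]],
        axis=-1,
    )


# ---------------------------------------------------------------------------
# design matrix and per-voxel fit
# ---------------------------------------------------------------------------

def design_matrix(table: GradientTable) -> np.ndarray:
    """Measurement x 7 matrix encoding ln S_i = ln S0 - b_i g_i^T D g_i.

    Row i is ``[1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz,
    -2b gy gz]`` so the unknown vector is (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz,
    Dyz).  Raises if the table cannot determine a tensor (rank < 7).
    """
    b = table.bvals
    g = table.bvecs
    if len(table) < 7:
        raise ValueError(f"need >= 7 measurements to fit a tensor, got {len(table)}")
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    x = np.column_stack(
        [
            np.ones_like(b),
            -b * gx * gx,
            -b * gy * gy,
            -b * gz * gz,
            -2.0 * b * gx * gy,
            -2.0 * b * gx * gz,
            -2.0 * b * gy * gz,
        ]
    )
    if np.linalg.matrix_rank(x) < 7:
        raise ValueError(
            "gradient table is rank-deficient for tensor fitting "
            "(all b=0 or degenerate direction set)"
        )
    return x


def _solve(x: np.ndarray, y: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
    if w is None:
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        return beta
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(x * sw[:, None], y * sw, rcond=None)
    return beta


def fit_voxel(signals, matrix: np.ndarray, weighting: str = "ols"):
    """Fit a single voxel's signals against a prebuilt design matrix.

    Returns ``(d_elements, ln_s0, residual_rms)`` or ``None`` when the voxel
    cannot be fit (fewer than 7 positive signals).  ``weighting`` is
    ``"ols"`` (log-linear least squares) or ``"wls"`` (one reweighting pass
    with weights equal to the squared predicted signal).
    """
    if weighting not in ("ols", "wls"):
        raise ValueError(f"weighting must be 'ols' or 'wls', got {weighting!r}")
    s = np.asarray(signals, dtype=float).ravel()
    if s.size != matrix.shape[0]:
        raise ValueError(f"{s.size} signals but design matrix has {matrix.shape[0]} rows")
    keep = s > 0
    if keep.sum() < 7:
        return None
    x = matrix[keep]
    if np.linalg.matrix_rank(x) < 7:
        return None
    y = np.log(s[keep])
    beta = _solve(x, y)
    if weighting == "wls":
        w = np.exp(2.0 * (x @ beta))  # squared predicted signal
        beta = _solve(x, y, w)
    resid = y - x @ beta
    rms = float(np.sqrt(np.mean(resid**2)))
    return beta[1:7].copy(), float(beta[0]), rms


def fit_volume(
    stack: DWIStack,
    mask: np.ndarray | None = None,
    weighting: str = "ols",
) -> tuple[TensorVolume, FitReport]:
    """Fit every in-mask voxel of a DWI stack.

    The common case (all signals strictly positive) is solved for the whole
    volume in one vectorized least-squares pass; voxels with nonpositive
    signals fall back to the row-dropping per-voxel path.  Voxels that
    cannot be fit are masked out and counted in the report.
    """
    grid = stack.grid
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError(f"mask shape {mask.shape} does not match grid {grid.shape}")

    x = design_matrix(stack.table)
    n_meas = x.shape[0]
    sig = stack.signal.reshape(-1, n_meas)
    flat_mask = mask.ravel()

    d = np.zeros((grid.n_voxels, 6), dtype=float)
    ln_s0 = np.zeros(grid.n_voxels, dtype=float)
    rms = np.zeros(grid.n_voxels, dtype=float)
    ok = np.zeros(grid.n_voxels, dtype=bool)

    positive = np.all(sig > 0, axis=1)
    fast = flat_mask & positive
    if np.any(fast):
        y = np.log(sig[fast])  # (nv, n_meas)
        pinv = np.linalg.pinv(x)  # (7, n_meas)
        beta = y @ pinv.T  # (nv, 7)
        if weighting == "wls":
            w = np.exp(2.0 * (beta @ x.T))  # squared predicted signals
            xtwx = np.einsum("vm,mi,mj->vij", w, x, x)
            xtwy = np.einsum("vm,mi,vm->vi", w, x, y)
            beta = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]
        resid = y - beta @ x.T
        d[fast] = beta[:, 1:7]
        ln_s0[fast] = beta[:, 0]
        rms[fast] = np.sqrt(np.mean(resid**2, axis=1))
        ok[fast] = True

    slow_idx = np.nonzero(flat_mask & ~positive)[0]
    for i in slow_idx:
        res = fit_voxel(sig[i], x, weighting)
        if res is not None:
            d[i], ln_s0[i], rms[i] = res
            ok[i] = True

    n_attempted = int(flat_mask.sum())
    tv = TensorVolume(
        grid=grid,
        d=d.reshape(grid.shape + (6,)),
        ln_s0=ln_s0.reshape(grid.shape),
        residual_rms=rms.reshape(grid.shape),
        mask=ok.reshape(grid.shape),
    )
    report = FitReport(n_attempted, int(ok.sum()), n_attempted - int(ok.sum()))
    return tv, report


# ---------------------------------------------------------------------------
# eigensystem and scalar maps
# ---------------------------------------------------------------------------

def eigensystem(tv: TensorVolume) -> TensorEigenSystem:
    """Diagonalize every in-mask tensor.

    Eigenvalues come out sorted descending; negative values from noisy fits
    are preserved here (scalar-map derivation clamps them).  Eigenvector
    signs are fixed deterministically by making each vector's
    largest-magnitude component positive.
    """
    mats = tv.as_matrices()
    vals, vecs = np.linalg.eigh(mats)  # ascending
    vals = vals[..., ::-1]
    vecs = vecs[..., :, ::-1]
    # deterministic sign: largest-|component| of each eigenvector positive
    comp = np.argmax(np.abs(vecs), axis=-2)  # (..., 3) index per column
    picked = np.take_along_axis(vecs, comp[..., None, :], axis=-2)[..., 0, :]
    vecs = vecs * np.where(picked < 0, -1.0, 1.0)[..., None, :]
    out_mask = tv.mask.copy()
    vals = np.where(out_mask[..., None], vals, np.nan)
    return TensorEigenSystem(tv.grid, vals, vecs, out_mask)


def _clamped(es: TensorEigenSystem) -> np.ndarray:
    return np.clip(es.eigenvalues, 0.0, None)


def trace_map(es: TensorEigenSystem) -> ScalarMap:
    """Trace(D) = λ1 + λ2 + λ3, with negative eigenvalues clamped to 0."""
    tr = np.sum(_clamped(es), axis=-1)
    tr[~es.mask] = np.nan
    return ScalarMap(es.grid, tr, name="TraceD", units="mm^2/s")


def md_map(es: TensorEigenSystem) -> ScalarMap:
    """Mean diffusivity MD = Trace(D)/3."""
    md = np.sum(_clamped(es), axis=-1) / 3.0
    md[~es.mask] = np.nan
    return ScalarMap(es.grid, md, name="MD", units="mm^2/s")


def fa_map(es: TensorEigenSystem) -> ScalarMap:
    """Fractional anisotropy.

    FA = sqrt(3/2) * sqrt(Σ(λi - MD)^2) / sqrt(Σ λi^2), computed on clamped
    eigenvalues so FA ∈ [0, 1]; undefined (NaN) where MD <= 0.
    """
    lam = _clamped(es)
    md = np.mean(lam, axis=-1)
    num = np.sqrt(np.sum((lam - md[..., None]) ** 2, axis=-1))
    den = np.sqrt(np.sum(lam**2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa[~es.mask | (md <= 0)] = np.nan
    return ScalarMap(es.grid, fa, name="FA", units="dimensionless")
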