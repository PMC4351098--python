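"""Diffusion tensor fitting: ADC, FA, eigenvalue and eigenvector maps.

The tensor is fit voxel-wise by weighted linear least squares on the
log-signal (weights = squared predicted signal, two reweighting passes),
the standard fast estimator.  Fractional anisotropy uses the normalized
eigenvalue-dispersion formula

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||

with negative fitted eigenvalues clamped to zero first, so FA always lies
in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import DWIVolume, GradientScheme

__all__ = ["TensorField", "fit_dti", "fa_from_eigenvalues"]


@dataclass
class TensorField:
    """Per-voxel diffusion tensor and its derived scalar/vector maps.

    ``tensors`` holds symmetric 3x3 tensors (mm^2/s); ``evals`` are sorted
    descending; ``adc`` is the mean diffusivity (lambda1+lambda2+lambda3)/3.
    """

    tensors: np.ndarray  # (X, Y, Z, 3, 3)
    evals: np.ndarray  # (X, Y, Z, 3) descending
    evecs: np.ndarray  # (X, Y, Z, 3, 3) columns matching evals
    fa: np.ndarray  # (X, Y, Z)
    adc: np.ndarray  # (X, Y, Z)
    affine: np.ndarray
    mask: np.ndarray

    @property
    def principal_direction(self) -> np.ndarray:
        """Unit principal eigenvector per voxel, shape (X, Y, Z, 3)."""
        return self.evecs[..., :, 0]


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """FA from eigenvalues (last axis length 3); clamps negatives to zero."""
    ev = np.clip(np.asarray(evals, dtype=float), 0.0, None)
    mean = ev.mean(axis=-1, keepdims=True)
    num = ((ev - mean) ** 2).sum(axis=-1)
    den = (ev**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    return np.minimum(fa, 1.0)


def _design_matrix(scheme: GradientScheme) -> np.ndarray:
    """Rows: [1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz]."""
    g = scheme.bvecs_full
    b = scheme.b_values
    return np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )


def fit_dti(
    dwi: DWIVolume, scheme: GradientScheme | None = None, mask: np.ndarray | None = None
) -> TensorField:
    """Fit the diffusion tensor per voxel by iteratively reweighted log-linear LS.

    Nonpositive intensities are floored to the smallest positive intensity in
    that voxel's series before taking the log (Rician magnitude noise can
    only push low signals near zero, never produce usable nonpositives).

    Raises ``ValueError`` if the scheme has fewer than 6 nonzero-b directions
    or no b=0 volume.
    """
    scheme = scheme or dwi.scheme
    if len(scheme.directions) < 6:
        raise ValueError(
            f"tensor fit needs >= 6 diffusion directions, got {len(scheme.directions)}"
        )
    if scheme.n_b0 < 1:
        raise ValueError("tensor fit needs at least one b=0 volume")
    X = _design_matrix(scheme)
    shape = dwi.data.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    sig = dwi.data[mask]  # (V, N)
    # per-voxel signal floor for the log transform
    pos = np.where(sig > 0, sig, np.inf)
    floor = pos.min(axis=1)
    floor[~np.isfinite(floor)] = 1.0
    sig = np.maximum(sig, floor[:, None])
    y = np.log(sig)

    # OLS then two WLS passes with weights = predicted-signal^2
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y.T).T  # (V, 7)
    for _ in range(2):
        w = np.exp(X @ beta.T).T ** 2  # (V, N)
        Xw = np.einsum("vn,ni,nj->vij", w, X, X)
        rhs = np.einsum("vn,ni,vn->vi", w, X, y)
        beta = np.linalg.solve(Xw, rhs[..., None])[..., 0]

    D = np.empty((len(beta), 3, 3))
    D[:, 0, 0] = beta[:, 1]
    D[:, 1, 1] = beta[:, 2]
    D[:, 2, 2] = beta[:, 3]
    D[:, 0, 1] = D[:, 1, 0] = beta[:, 4]
    D[:, 0, 2] = D[:, 2, 0] = beta[:, 5]
    D[:, 1, 2] = D[:, 2, 1] = beta[:, 6]

    evals, evecs = np.linalg.eigh(D)  # ascending
    evals = evals[:, ::-1]
    evecs = evecs[:, :, ::-1]

    full = lambda last: np.zeros(shape + last)  # noqa: E731
    tensors, ev_map, evec_map = full((3, 3)), full((3,)), full((3, 3))
    fa_map, adc_map = np.zeros(shape), np.zeros(shape)
    tensors[mask] = D
    ev_map[mask] = evals
    evec_map[mask] = evecs
    fa_map[mask] = fa_from_eigenvalues(evals)
    adc_map[mask] = evals.mean(axis=1)
    return TensorField(
        tensors=tensors,
        evals=ev_map,
        evecs=evec_map,
        fa=fa_map,
        adc=adc_map,
        affine=dwi.affine.copy(),
        mask=mask,
    )
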