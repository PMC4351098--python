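"""Synthetic ground truth for optic-radiation (OR) tractography experiments.

This module builds a desk-scale white-matter phantom emulating the anatomy
that makes the OR hard to track: a fan-shaped bundle running from a thalamic
seed (LGN analogue) anteriorly into a sharp hairpin loop (Meyer's-loop
analogue) and back posteriorly to a cortical target (V1 analogue), with an
optional straight crossing bundle through the fan body.  The phantom carries
its own "atlas" surrogate -- a blurred probability map of the tract plus
seed/target masks -- and records the true anatomical landmarks (temporal
pole TP, occipital pole OP, and the loop apex, i.e. the true anterior tip of
Meyer's loop) in world millimetres.

Diffusion-weighted signals are simulated with a multi-tensor forward model
per voxel and Rician noise:

    S(g, b) = S0 * [ f_iso * exp(-b * d_iso)
                     + sum_k f_k * exp(-b * g^T D_k g) ]

where each fiber compartment k has an axially symmetric tensor D_k with
eigenvalues ``(lambda_par, lambda_perp, lambda_perp)`` aligned with the local
fiber orientation, and the isotropic compartment fills the remaining volume
fraction.  Rician noise is applied as the magnitude of the signal plus
complex Gaussian noise with sigma = S0 / SNR.

Coordinate convention: NIfTI-style RAS+ world millimetres; +y is anterior,
so "N mm posterior to the temporal pole" means world-y = TP_y - N.  Voxel
indices are 0-based and voxel (i, j, k) is centred at ``affine @ (i, j, k, 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.interpolate import make_interp_spline
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

__all__ = [
    "GradientScheme",
    "PhantomConfig",
    "Phantom",
    "DWIVolume",
    "generate_gradient_scheme",
    "electrostatic_energy",
    "greedy_subset",
    "build_or_phantom",
    "simulate_dwi",
]


# --------------------------------------------------------------------------
# gradient scheme
# --------------------------------------------------------------------------

@dataclass
class GradientScheme:
    """A diffusion acquisition: unit gradient directions plus b-values.

    ``b_values`` covers every volume (b=0 volumes first); ``directions`` has
    one row per *diffusion-weighted* volume, in the same order as the nonzero
    b-values.
    """

    directions: np.ndarray
    b_values: np.ndarray
    n_b0: int

    def __post_init__(self) -> None:
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        self.b_values = np.asarray(self.b_values, dtype=float)
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("gradient directions must be unit vectors")
        if np.any(self.b_values < 0):
            raise ValueError("b-values must be nonnegative")
        if int(np.count_nonzero(self.b_values)) != len(self.directions):
            raise ValueError("number of directions must equal number of nonzero b-values")

    @property
    def n_volumes(self) -> int:
        return len(self.b_values)

    @property
    def dwi_indices(self) -> np.ndarray:
        return np.nonzero(self.b_values)[0]

    @property
    def b0_indices(self) -> np.ndarray:
        return np.nonzero(self.b_values == 0)[0]

    @property
    def bvecs_full(self) -> np.ndarray:
        """Per-volume direction rows, zero rows for b=0 volumes (FSL dialect)."""
        full = np.zeros((self.n_volumes, 3))
        full[self.dwi_indices] = self.directions
        return full

    def subset(self, dw_indices: np.ndarray) -> "GradientScheme":
        """New scheme keeping all b=0 volumes and the given DW directions."""
        dw_indices = np.asarray(dw_indices, dtype=int)
        b_dw = self.b_values[self.dwi_indices][dw_indices]
        return GradientScheme(
            directions=self.directions[dw_indices],
            b_values=np.concatenate([np.zeros(self.n_b0), b_dw]),
            n_b0=self.n_b0,
        )


def electrostatic_energy(directions: np.ndarray) -> float:
    """Coulomb energy of a direction set with antipodal symmetry.

    Each direction counts together with its antipode, so the energy is
    ``sum_{i<j} 1/|x_i - x_j| + 1/|x_i + x_j|``.
    """
    x = np.asarray(directions, dtype=float)
    n = len(x)
    if n < 2:
        return 0.0
    diff = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
    summ = np.linalg.norm(x[:, None] + x[None, :], axis=-1)
    iu = np.triu_indices(n, 1)
    return float(np.sum(1.0 / diff[iu]) + np.sum(1.0 / summ[iu]))


def _repulsion_optimize(x: np.ndarray, n_iter: int = 2000, tol: float = 1e-12) -> np.ndarray:
    """Minimize antipodally-symmetric Coulomb energy by projected descent."""
    x = x / np.linalg.norm(x, axis=1, keepdims=True)
    step = 0.05
    energy = electrostatic_energy(x)
    for _ in range(n_iter):
        diff = x[:, None] - x[None, :]
        summ = x[:, None] + x[None, :]
        dn = np.linalg.norm(diff, axis=-1)
        sn = np.linalg.norm(summ, axis=-1)
        np.fill_diagonal(dn, np.inf)
        np.fill_diagonal(sn, np.inf)  # self-antipode force is radial; drop it
        force = (diff / dn[..., None] ** 3).sum(axis=1) + (summ / sn[..., None] ** 3).sum(axis=1)
        # tangent projection keeps the update on the sphere
        force -= (force * x).sum(axis=1, keepdims=True) * x
        fmax = np.abs(force).max()
        if fmax == 0:
            break
        cand = x + step * force / fmax
        cand /= np.linalg.norm(cand, axis=1, keepdims=True)
        cand_energy = electrostatic_energy(cand)
        if cand_energy < energy:
            if energy - cand_energy < tol * energy:
                x = cand
                break
            x, energy = cand, cand_energy
            step *= 1.1
        else:
            step *= 0.5
            if step < 1e-10:
                break
    return x


def generate_gradient_scheme(
    n_directions: int, b_value: float, n_b0: int = 1, seed: int = 0
) -> GradientScheme:
    """Generate an approximately uniform half-sphere gradient scheme.

    Directions are initialized at random (reproducibly from *seed*) and
    relaxed by electrostatic repulsion treating antipodes as identical, the
    standard construction for "non-collinear" clinical DWI schemes.
    """
    if n_directions < 1:
        raise ValueError("n_directions must be >= 1")
    if b_value <= 0:
        raise ValueError("b_value must be positive")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_directions, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    if n_directions > 1:
        x = _repulsion_optimize(x)
    # canonical hemisphere (z >= 0) for reproducible sign conventions
    flip = x[:, 2] < 0
    x[flip] *= -1
    b_values = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b_value))])
    return GradientScheme(directions=x, b_values=b_values, n_b0=n_b0)


def greedy_subset(directions: np.ndarray, k: int) -> np.ndarray:
    """Indices of an energy-minimal subset of *k* directions (greedy removal).

    Starting from the full set, repeatedly drop the direction whose removal
    lowers the antipodal Coulomb energy the most, until *k* remain.
    """
    directions = np.asarray(directions, dtype=float)
    n = len(directions)
    if not 1 <= k <= n:
        raise ValueError(f"subset size {k} outside [1, {n}]")
    keep = list(range(n))
    while len(keep) > k:
        energies = [
            electrostatic_energy(directions[[i for i in keep if i != j]]) for j in keep
        ]
        keep.pop(int(np.argmin(energies)))
    return np.array(keep, dtype=int)


# --------------------------------------------------------------------------
# phantom geometry
# --------------------------------------------------------------------------

@dataclass
class PhantomConfig:
    """Geometry and tissue parameters of the bent-fan OR phantom.

    All positions are world millimetres in RAS+ (+y anterior).  The default
    landmark layout places the loop apex 27 mm posterior to the temporal
    pole, matching the classic dissection estimate of the Meyer's-loop to
    temporal-pole distance, with a TP-OP span of about 119 mm.  The grid is
    40 x 50 x 20 voxels at 2.5 mm isotropic (a reduced field of view at the
    clinical voxel size) so complete simulations run in seconds.  The
    geometric defaults are artifact choices: no phantom of record exists for
    this tract, so the layout was designed once to exercise the sharp loop,
    the fanning body and a fiber crossing.
    """

    shape: tuple[int, int, int] = (40, 50, 20)
    voxel_size: float = 2.5
    lgn_mm: tuple[float, float, float] = (35.0, 72.5, 24.0)
    apex_mm: tuple[float, float, float] = (25.0, 94.0, 24.0)
    v1_mm: tuple[float, float, float] = (30.0, 7.5, 24.0)
    tp_mm: tuple[float, float, float] = (25.0, 121.0, 24.0)
    op_mm: tuple[float, float, float] = (30.0, 2.5, 24.0)
    tube_radius_mm: float = 3.75
    fan_spread_mm: float = 7.5
    n_fan_curves: int = 7
    crossing: bool = True
    crossing_y_mm: float = 40.0
    crossing_z_mm: float = 24.0
    crossing_radius_mm: float = 3.0
    seed_radius_mm: float = 5.0
    target_semiaxes_mm: tuple[float, float, float] = (12.0, 7.0, 14.0)
    fiber_fraction: float = 0.8
    eigenvalues: tuple[float, float] = (1.7e-3, 0.3e-3)  # (parallel, perpendicular) mm^2/s
    d_iso: float = 3.0e-3  # free-water diffusivity, mm^2/s
    prob_blur_sigma_vox: float = 1.0


@dataclass
class Phantom:
    """Ground-truth tract system on a regular grid.

    ``fiber_dirs``/``fiber_fracs`` hold up to two fiber populations per voxel
    (unit orientation and volume fraction; unused slots have zero fraction).
    ``anterior_tip_mm`` is the generator-recorded true anterior tip of the
    loop, the reference for Meyer's-loop localization error.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    fiber_dirs: np.ndarray  # (X, Y, Z, 2, 3)
    fiber_fracs: np.ndarray  # (X, Y, Z, 2)
    tract_mask: np.ndarray
    crossing_mask: np.ndarray
    seed_mask: np.ndarray
    target_mask: np.ndarray
    tract_probability_map: np.ndarray
    landmarks: dict
    anterior_tip_mm: np.ndarray
    config: PhantomConfig

    def __post_init__(self) -> None:
        fr = self.fiber_fracs
        if np.any(fr < 0) or np.any(fr.sum(axis=-1) > 1 + 1e-9):
            raise ValueError("fiber fractions must lie in [0,1] and sum to <= 1 per voxel")

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``(X, Y, Z, 3)``."""
        idx = np.stack(
            np.meshgrid(*[np.arange(s) for s in self.shape], indexing="ij"), axis=-1
        ).astype(float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, pts_mm: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        pts = np.atleast_2d(pts_mm)
        return pts @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class DWIVolume:
    """4-D diffusion-weighted image with its world affine and scheme."""

    data: np.ndarray
    affine: np.ndarray
    scheme: GradientScheme

    def __post_init__(self) -> None:
        if self.data.shape[-1] != self.scheme.n_volumes:
            raise ValueError(
                f"4th dimension ({self.data.shape[-1]}) must equal scheme volume "
                f"count ({self.scheme.n_volumes})"
            )
        if np.any(self.data < 0):
            raise ValueError("magnitude DWI data must be nonnegative")


def _fan_centerline(cfg: PhantomConfig, dz: float, dx: float) -> np.ndarray:
    """Control points of one fan curve: seed -> loop apex -> posterior target.

    *dz*, *dx* displace the posterior body/terminal points so the bundle fans
    out after the loop while staying coherent through the loop itself.
    """
    lgn = np.array(cfg.lgn_mm)
    apex = np.array(cfg.apex_mm)
    v1 = np.array(cfg.v1_mm)
    mid_y = 0.5 * (lgn[1] + apex[1])
    return np.array(
        [
            lgn,
            [0.5 * (lgn[0] + apex[0]) + 1.0, mid_y + 8.0, lgn[2]],
            apex,
            [apex[0] - 5.0, mid_y + 8.0, apex[2] + 0.2 * dz],
            [apex[0] - 3.0, 60.0, apex[2] + 0.5 * dz],
            [0.5 * (apex[0] + v1[0]) + 0.5 * dx, 35.0, v1[2] + 0.8 * dz],
            v1 + np.array([dx, 0.0, dz]),
        ]
    )


def _rasterize_tube(
    curves: list[np.ndarray],
    centers_flat: np.ndarray,
    tree: cKDTree,
    radius: float,
    n_vox: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Mark voxels within *radius* of any curve; average aligned tangents."""
    mask = np.zeros(n_vox, dtype=bool)
    tangent_sum = np.zeros((n_vox, 3))
    for pts in curves:
        seg = np.gradient(pts, axis=0)
        seg /= np.linalg.norm(seg, axis=1, keepdims=True)
        hit_lists = tree.query_ball_point(pts, r=radius)
        for t, hits in zip(seg, hit_lists):
            if not hits:
                continue
            hits = np.asarray(hits)
            mask[hits] = True
            # align sign with what is already accumulated per voxel
            acc = tangent_sum[hits]
            sgn = np.where((acc * t).sum(axis=1) < 0, -1.0, 1.0)
            tangent_sum[hits] += sgn[:, None] * t
    norms = np.linalg.norm(tangent_sum, axis=1)
    dirs = np.zeros_like(tangent_sum)
    ok = norms > 0
    dirs[ok] = tangent_sum[ok] / norms[ok, None]
    return mask, dirs


def build_or_phantom(config: PhantomConfig | None = None, seed: int = 0) -> Phantom:
    """Construct the bent-fan tract phantom with its atlas surrogate.

    The tract is a bundle of spline tubes from the LGN-analogue seed,
    hooking around the configured loop apex (total turning well above 90
    degrees) and fanning posteriorly to the V1-analogue target.  The tract
    probability map -- the stand-in for a population atlas -- is the binary
    truth blurred with a Gaussian (``prob_blur_sigma_vox``) and rescaled to
    max 1, mimicking inter-subject atlas variability.
    """
    cfg = config or PhantomConfig()
    shape = tuple(cfg.shape)
    if shape[0] < 20 or shape[1] < 20 or shape[2] < 10:
        raise ValueError("grid must be at least 20 x 20 x 10 voxels")
    affine = np.diag([cfg.voxel_size] * 3 + [1.0])
    extent = (np.array(shape) - 1) * cfg.voxel_size
    for name in ("apex_mm", "tp_mm", "op_mm", "lgn_mm", "v1_mm"):
        p = np.array(getattr(cfg, name))
        if np.any(p < 0) or np.any(p > extent):
            raise ValueError(f"{name} = {tuple(p)} lies outside the grid extent {tuple(extent)}")

    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    centers = idx.astype(float) * cfg.voxel_size
    centers_flat = centers.reshape(-1, 3)
    tree = cKDTree(centers_flat)
    n_vox = len(centers_flat)

    if cfg.n_fan_curves < 1:
        raise ValueError("n_fan_curves must be >= 1")
    if cfg.n_fan_curves == 1 or cfg.fan_spread_mm == 0:
        offsets = [(0.0, 0.0)]
    else:
        dzs = np.linspace(-cfg.fan_spread_mm, cfg.fan_spread_mm, cfg.n_fan_curves)
        dxs = np.linspace(-4.0, 4.0, cfg.n_fan_curves)
        offsets = list(zip(dzs, dxs))
    curves = []
    for dz, dx in offsets:
        ctrl = _fan_centerline(cfg, dz, dx)
        # chord-length parameterization, densely resampled at ~0.5 mm
        t = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(ctrl, axis=0), axis=1))])
        spline = make_interp_spline(t, ctrl, k=3)
        curves.append(spline(np.arange(0.0, t[-1], 0.5)))

    or_mask_flat, or_dirs_flat = _rasterize_tube(
        curves, centers_flat, tree, cfg.tube_radius_mm, n_vox
    )

    cross_mask_flat = np.zeros(n_vox, dtype=bool)
    cross_dirs_flat = np.zeros((n_vox, 3))
    if cfg.crossing:
        xs = np.arange(0.0, extent[0] + 0.25, 0.5)
        line = np.stack(
            [xs, np.full_like(xs, cfg.crossing_y_mm), np.full_like(xs, cfg.crossing_z_mm)],
            axis=1,
        )
        cross_mask_flat, cross_dirs_flat = _rasterize_tube(
            [line], centers_flat, tree, cfg.crossing_radius_mm, n_vox
        )

    fiber_dirs = np.zeros(shape + (2, 3))
    fiber_fracs = np.zeros(shape + (2,))
    or_mask = or_mask_flat.reshape(shape)
    cross_mask = cross_mask_flat.reshape(shape)
    fiber_dirs[..., 0, :] = or_dirs_flat.reshape(shape + (3,))
    fiber_dirs[..., 1, :] = cross_dirs_flat.reshape(shape + (3,))
    both = or_mask & cross_mask
    only_or = or_mask & ~cross_mask
    only_cross = cross_mask & ~or_mask
    fiber_fracs[only_or, 0] = cfg.fiber_fraction
    fiber_fracs[only_cross, 1] = cfg.fiber_fraction
    fiber_fracs[both, 0] = cfg.fiber_fraction / 2
    fiber_fracs[both, 1] = cfg.fiber_fraction / 2

    lgn = np.array(cfg.lgn_mm)
    v1 = np.array(cfg.v1_mm)
    d_seed = np.linalg.norm(centers - lgn, axis=-1)
    seed_mask = (d_seed <= cfg.seed_radius_mm) & or_mask
    rel = (centers - v1) / np.array(cfg.target_semiaxes_mm)
    target_mask = (rel**2).sum(axis=-1) <= 1.0

    prob = gaussian_filter(or_mask.astype(float), sigma=cfg.prob_blur_sigma_vox)
    prob /= prob.max()

    return Phantom(
        shape=shape,
        affine=affine,
        fiber_dirs=fiber_dirs,
        fiber_fracs=fiber_fracs,
        tract_mask=or_mask,
        crossing_mask=cross_mask,
        seed_mask=seed_mask,
        target_mask=target_mask,
        tract_probability_map=prob,
        landmarks={
            "tp": np.array(cfg.tp_mm),
            "op": np.array(cfg.op_mm),
            "apex": np.array(cfg.apex_mm),
        },
        anterior_tip_mm=np.array(cfg.apex_mm),
        config=cfg,
    )


# --------------------------------------------------------------------------
# DWI forward simulation
# --------------------------------------------------------------------------

def simulate_dwi(
    phantom: Phantom,
    scheme: GradientScheme,
    s0: float = 1000.0,
    snr: float = 30.0,
    seed: int = 0,
) -> DWIVolume:
    """Simulate magnitude DWI data from the phantom's multi-tensor field.

    Per voxel the noiseless signal is the volume-fraction-weighted sum of an
    isotropic compartment and one axially symmetric tensor per fiber
    population (see module docstring).  Rician noise with sigma = s0 / snr
    is added to the complex signal; ``snr=np.inf`` gives noiseless data.
    """
    if not (snr > 0):
        raise ValueError("snr must be positive (use np.inf for noiseless)")
    cfg = phantom.config
    lam_par, lam_perp = cfg.eigenvalues
    fracs = phantom.fiber_fracs  # (X,Y,Z,2)
    dirs = phantom.fiber_dirs  # (X,Y,Z,2,3)
    f_iso = 1.0 - fracs.sum(axis=-1)

    n_vol = scheme.n_volumes
    data = np.empty(phantom.shape + (n_vol,))
    bvecs = scheme.bvecs_full
    for v in range(n_vol):
        b = scheme.b_values[v]
        if b == 0:
            data[..., v] = s0
            continue
        g = bvecs[v]
        dot2 = np.einsum("xyzkc,c->xyzk", dirs, g) ** 2
        adc = lam_perp + (lam_par - lam_perp) * dot2
        signal = f_iso * np.exp(-b * cfg.d_iso) + np.einsum(
            "xyzk,xyzk->xyz", fracs, np.exp(-b * adc)
        )
        data[..., v] = s0 * signal

    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        sigma = s0 / snr
        real = data + rng.normal(0.0, sigma, size=data.shape)
        imag = rng.normal(0.0, sigma, size=data.shape)
        data = np.hypot(real, imag)

    return DWIVolume(data=data, affine=phantom.affine.copy(), scheme=scheme)


def phantom_sidecar(phantom: Phantom, seed: int | None = None) -> dict:
    """Plain-data description of the phantom truth for a text sidecar file."""
    return {
        "seed": seed,
        "landmarks_mm": {k: [float(x) for x in v] for k, v in phantom.landmarks.items()},
        "anterior_tip_mm": [float(x) for x in phantom.anterior_tip_mm],
        "config": asdict(phantom.config),
    }
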