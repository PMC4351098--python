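"""Probabilistic streamline tractography and streamline-density images.

Streamlines are launched from uniformly jittered positions inside each seed
voxel and grown bidirectionally with fixed-length Euler steps.  The
curvature cutoff, stated as a minimum radius of curvature R, is enforced as
a per-step cone via the arc-chord relation: with step length s, the maximum
turning angle per step is ``2 * arcsin(s / (2 R))`` (about 38.9 degrees at
the default s = 0.2 mm, R = 0.3 mm).

Direction sampling per step:

* **CSD**: the FOD (trilinearly interpolated SH coefficients) is sampled on
  a fixed dense set of unit directions restricted to the curvature cone;
  a direction is drawn with probability proportional to its (nonnegative,
  cutoff-thresholded) FOD amplitude -- the exact distribution that
  rejection sampling of the discretized FOD converges to.  No admissible
  direction (all cone amplitudes at or below the cutoff) terminates the
  streamline.

* **Ball-and-stick**: one posterior sample is drawn at the nearest voxel;
  among the sticks passing the inclusion rule (posterior mean fraction
  >= 0.05), the one closest to the incoming direction is followed, or the
  streamline terminates if even that stick falls outside the cone.

Streamlines also terminate on leaving the white-matter inclusion mask (the
FA-thresholded mask), leaving the grid, or exceeding ``max_length``.

The streamline-density image (SDI) counts, per voxel, the fraction of
retained streamlines that visit it, each streamline contributing at most 1
to a voxel regardless of re-entries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .fod import BallStickPosterior, FODField, sh_basis_matrix, sphere_grid
from .masks import BinaryMask

logger = logging.getLogger(__name__)

__all__ = [
    "TrackingParams",
    "StreamlineSet",
    "SDI",
    "max_turning_angle",
    "propagate",
    "filter_streamlines",
    "compute_sdi",
]


@dataclass
class TrackingParams:
    """Tracking parameters; defaults follow the clinical protocol.

    ``streamlines_per_seed_voxel`` defaults to the protocol's 5000; pipeline
    configurations typically scale this down for desk-scale runs.
    """

    streamlines_per_seed_voxel: int = 5000
    step_length: float = 0.2  # mm
    min_radius_of_curvature: float = 0.3  # mm
    fa_threshold: float = 0.1
    max_length: float = 200.0  # mm
    fod_amplitude_cutoff: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_length <= 0:
            raise ValueError("step_length must be positive")
        if self.min_radius_of_curvature <= 0:
            raise ValueError("min_radius_of_curvature must be positive")
        if self.streamlines_per_seed_voxel < 1:
            raise ValueError("streamlines_per_seed_voxel must be >= 1")


@dataclass
class StreamlineSet:
    """Tracked polylines in world mm with per-streamline status."""

    streamlines: list  # list of (n_i, 3) float arrays
    status: list  # "retained" | "rejected:<reason>"
    n_initiated: int

    @property
    def n_retained(self) -> int:
        return sum(1 for s in self.status if s == "retained")

    @property
    def retained(self) -> list:
        return [sl for sl, st in zip(self.streamlines, self.status) if st == "retained"]

    def rejection_tally(self) -> dict:
        tally: dict[str, int] = {}
        for st in self.status:
            tally[st] = tally.get(st, 0) + 1
        return tally


@dataclass
class SDI:
    """Streamline-density image: fraction of retained streamlines per voxel."""

    data: np.ndarray
    affine: np.ndarray
    n_retained: int


def max_turning_angle(params: TrackingParams) -> float:
    """Maximum per-step turning angle (radians) from the arc-chord relation."""
    ratio = params.step_length / (2.0 * params.min_radius_of_curvature)
    if ratio > 1:
        raise ValueError("step length exceeds the curvature-allowed chord")
    return 2.0 * np.arcsin(ratio)


def _world_to_voxel(affine_inv: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return pts @ affine_inv[:3, :3].T + affine_inv[:3, 3]


def _trilinear(field4d: np.ndarray, vc: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a (X,Y,Z,R) field at voxel coords (N,3)."""
    shape = np.array(field4d.shape[:3])
    vc = np.clip(vc, 0.0, shape - 1.000001)
    base = np.floor(vc).astype(int)
    frac = vc - base
    out = np.zeros((len(vc), field4d.shape[3]))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (frac[:, 0] if dx else 1 - frac[:, 0])
                    * (frac[:, 1] if dy else 1 - frac[:, 1])
                    * (frac[:, 2] if dz else 1 - frac[:, 2])
                )
                ix = np.minimum(base[:, 0] + dx, shape[0] - 1)
                iy = np.minimum(base[:, 1] + dy, shape[1] - 1)
                iz = np.minimum(base[:, 2] + dz, shape[2] - 1)
                out += w[:, None] * field4d[ix, iy, iz]
    return out


class _CSDSampler:
    """Discrete-cone FOD direction sampler for CSD tracking."""

    def __init__(self, fod: FODField, params: TrackingParams, n_dirs: int = 500):
        self.fod = fod
        self.cutoff = params.fod_amplitude_cutoff
        self.dirs = sphere_grid(n_dirs)
        self.basis = sh_basis_matrix(fod.lmax, self.dirs)
        cone_cos = np.cos(max_turning_angle(params))
        adj = self.dirs @ self.dirs.T > cone_cos  # signed: travel direction
        counts = adj.sum(axis=1)
        m = counts.max()
        self.nbr = np.full((n_dirs, m), -1, dtype=int)
        for i in range(n_dirs):
            idx = np.nonzero(adj[i])[0]
            self.nbr[i, : len(idx)] = idx

    def amplitudes(self, coeffs: np.ndarray, dir_rows: np.ndarray) -> np.ndarray:
        """FOD amplitudes (clipped at 0 and the cutoff) for given basis rows."""
        amps = np.einsum("nr,nmr->nm", coeffs, dir_rows)
        amps[amps < self.cutoff] = 0.0
        return amps

    def initial(self, coeffs: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Sample an initial direction index per row over the full sphere."""
        amps = coeffs @ self.basis.T
        amps[amps < self.cutoff] = 0.0
        return _categorical(amps, rng), amps.sum(axis=1) > 0

    def step(
        self, coeffs: np.ndarray, dir_idx: np.ndarray, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Sample the next direction index within the curvature cone."""
        nbrs = self.nbr[dir_idx]  # (N, M)
        valid = nbrs >= 0
        amps = self.amplitudes(coeffs, self.basis[np.maximum(nbrs, 0)])
        amps[~valid] = 0.0
        alive = amps.sum(axis=1) > 0
        j = _categorical(amps, rng)
        return nbrs[np.arange(len(nbrs)), j], alive


def _categorical(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise categorical draw proportional to nonnegative weights."""
    tot = weights.sum(axis=1, keepdims=True)
    safe = np.where(tot > 0, tot, 1.0)
    r = rng.random((len(weights), 1)) * safe
    return np.minimum((weights.cumsum(axis=1) < r).sum(axis=1), weights.shape[1] - 1)


def propagate(
    model: FODField | BallStickPosterior,
    seeds: BinaryMask,
    inclusion: BinaryMask,
    params: TrackingParams,
) -> StreamlineSet:
    """Launch bidirectional probabilistic streamlines from every seed voxel.

    Seed voxels outside the inclusion mask (i.e. below the FA threshold that
    defines it) launch nothing, with a warning.  Deterministic for a fixed
    ``params.seed``.
    """
    shape = inclusion.data.shape
    if seeds.data.shape != shape:
        raise ValueError("seed and inclusion masks must share the grid")
    seed_vox = np.argwhere(seeds.data)
    if len(seed_vox) == 0:
        raise ValueError("seed mask is empty")
    n_per = params.streamlines_per_seed_voxel
    n_initiated = len(seed_vox) * n_per  # every seed voxel counts as initiated
    usable = np.array([inclusion.data[tuple(v)] for v in seed_vox])
    if not usable.all():
        warnings.warn(
            f"{(~usable).sum()} seed voxel(s) fall below the FA threshold and launch no streamlines"
        )
    seed_vox = seed_vox[usable]
    if len(seed_vox) == 0:
        return StreamlineSet([], [], n_initiated=n_initiated)

    rng = np.random.default_rng(params.seed)
    affine = model.affine
    affine_inv = np.linalg.inv(affine)
    # jittered start positions, uniform inside each seed voxel
    vox_rep = np.repeat(seed_vox, n_per, axis=0).astype(float)
    jitter = rng.random((len(vox_rep), 3)) - 0.5
    start_vc = vox_rep + jitter
    start_mm = start_vc @ affine[:3, :3].T + affine[:3, 3]

    is_csd = isinstance(model, FODField)
    if is_csd:
        sampler = _CSDSampler(model, params)
        coeffs0 = _trilinear(model.coeffs, start_vc)
        init_idx, ok = sampler.initial(coeffs0, rng)
        init_dir = sampler.dirs[init_idx]
    else:
        sampler = None
        init_dir, ok = _bs_initial(model, start_vc, rng)
        init_idx = None

    halves = []
    for sign in (1.0, -1.0):
        if is_csd:
            # flip = antipodal index; rebuild by nearest lookup once
            d0 = sign * init_dir
            idx0 = np.argmax(sampler.dirs @ d0.T, axis=0)
            halves.append(
                _run_csd(sampler, model, start_mm, idx0, ok, inclusion, params, affine_inv, rng)
            )
        else:
            halves.append(
                _run_bs(model, start_mm, sign * init_dir, ok, inclusion, params, affine_inv, rng)
            )

    streamlines = []
    for fwd, bwd in zip(halves[0], halves[1]):
        streamlines.append(np.vstack([bwd[::-1][:-1], fwd]) if len(bwd) > 1 else fwd)
    status = ["candidate"] * len(streamlines)
    logger.info("initiated %d streamlines from %d seed voxels", n_initiated, len(seed_vox))
    return StreamlineSet(streamlines=streamlines, status=status, n_initiated=n_initiated)


def _mask_lookup(mask: np.ndarray, vc: np.ndarray) -> np.ndarray:
    """Nearest-voxel boolean lookup; False outside the grid."""
    idx = np.rint(vc).astype(int)
    inside = np.all((idx >= 0) & (idx < np.array(mask.shape)), axis=1)
    out = np.zeros(len(vc), dtype=bool)
    ii = idx[inside]
    out[inside] = mask[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out


def _collect(points_hist: list[np.ndarray], n: int) -> list:
    """Per-streamline polylines from the step history (NaN marks inactive)."""
    stack = np.stack(points_hist, axis=1)  # (N, T, 3)
    out = []
    for i in range(n):
        pts = stack[i]
        good = ~np.isnan(pts[:, 0])
        out.append(pts[good])
    return out


def _first_step(pos, direction, active, inclusion, params, affine_inv):
    """Advance every active streamline one step along its initial direction.

    The first segment of each half follows the sampled seed direction
    exactly, so the two halves of a bidirectional streamline join without a
    kink and every subsequent turn is bounded by the curvature cone.
    """
    pos_new = pos + params.step_length * direction
    vc_new = _world_to_voxel(affine_inv, pos_new)
    alive = active & _mask_lookup(inclusion.data, vc_new)
    pos[alive] = pos_new[alive]
    return alive


def _run_csd(sampler, model, start_mm, dir_idx, ok, inclusion, params, affine_inv, rng):
    n = len(start_mm)
    pos = start_mm.copy()
    dir_idx = dir_idx.copy()
    active = ok.copy()
    max_steps = int(np.ceil(params.max_length / params.step_length)) + 1
    hist = [np.where(active[:, None], pos, np.nan)]
    active = _first_step(pos, sampler.dirs[dir_idx], active, inclusion, params, affine_inv)
    hist.append(np.where(active[:, None], pos, np.nan))
    for _ in range(max_steps):
        if not active.any():
            break
        ia = np.nonzero(active)[0]
        vc = _world_to_voxel(affine_inv, pos[ia])
        coeffs = _trilinear(model.coeffs, vc)
        new_idx, alive = sampler.step(coeffs, dir_idx[ia], rng)
        pos_new = pos[ia] + params.step_length * sampler.dirs[new_idx]
        vc_new = _world_to_voxel(affine_inv, pos_new)
        alive &= _mask_lookup(inclusion.data, vc_new)
        sel = ia[alive]
        pos[sel] = pos_new[alive]
        dir_idx[sel] = new_idx[alive]
        active[ia[~alive]] = False
        step_pts = np.full((n, 3), np.nan)
        step_pts[sel] = pos_new[alive]
        hist.append(step_pts)
        if len(hist) * params.step_length > params.max_length:
            break
    return _collect(hist, n)


def _bs_initial(model: BallStickPosterior, start_vc, rng):
    """Initial direction for ball-and-stick: stick drawn with probability f_k."""
    idx = np.rint(start_vc).astype(int)
    shp = model.voxel_index.shape
    idx = np.clip(idx, 0, np.array(shp) - 1)
    vidx = model.voxel_index[idx[:, 0], idx[:, 1], idx[:, 2]]
    ok = vidx >= 0
    n = len(start_vc)
    s = rng.integers(model.n_samples, size=n)
    v_safe = np.maximum(vidx, 0)
    f = model.f_samples[v_safe, :, s]  # (N, K)
    f = f * (model.mean_f[v_safe] >= 0.05)
    k = _categorical(f, rng)
    dirs = model.dir_samples[v_safe, k, s]
    sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
    ok &= f.sum(axis=1) > 0
    return sign[:, None] * dirs, ok


def _run_bs(model: BallStickPosterior, start_mm, init_dir, ok, inclusion, params, affine_inv, rng):
    n = len(start_mm)
    pos = start_mm.copy()
    cur = init_dir.copy()
    active = ok.copy()
    cone_cos = np.cos(max_turning_angle(params))
    max_steps = int(np.ceil(params.max_length / params.step_length)) + 1
    hist = [np.where(active[:, None], pos, np.nan)]
    active = _first_step(pos, cur, active, inclusion, params, affine_inv)
    hist.append(np.where(active[:, None], pos, np.nan))
    shp = np.array(model.voxel_index.shape)
    for _ in range(max_steps):
        if not active.any():
            break
        ia = np.nonzero(active)[0]
        vc = _world_to_voxel(affine_inv, pos[ia])
        idx = np.rint(vc).astype(int)
        inside = np.all((idx >= 0) & (idx < shp), axis=1)
        idx = np.clip(idx, 0, shp - 1)
        vidx = model.voxel_index[idx[:, 0], idx[:, 1], idx[:, 2]]
        alive = inside & (vidx >= 0)
        v_safe = np.maximum(vidx, 0)
        s = rng.integers(model.n_samples, size=len(ia))
        dirs_k = model.dir_samples[v_safe, :, s]  # (N, K, 3)
        incl = model.mean_f[v_safe] >= 0.05  # (N, K)
        dots = np.einsum("nkc,nc->nk", dirs_k, cur[ia])
        score = np.where(incl, np.abs(dots), -np.inf)
        k = np.argmax(score, axis=1)
        rows = np.arange(len(ia))
        best = score[rows, k]
        alive &= np.isfinite(best) & (best >= cone_cos)
        sign = np.where(dots[rows, k] < 0, -1.0, 1.0)
        new_dir = sign[:, None] * dirs_k[rows, k]
        pos_new = pos[ia] + params.step_length * new_dir
        vc_new = _world_to_voxel(affine_inv, pos_new)
        alive &= _mask_lookup(inclusion.data, vc_new)
        sel = ia[alive]
        pos[sel] = pos_new[alive]
        cur[sel] = new_dir[alive]
        active[ia[~alive]] = False
        step_pts = np.full((n, 3), np.nan)
        step_pts[sel] = pos_new[alive]
        hist.append(step_pts)
        if len(hist) * params.step_length > params.max_length:
            break
    return _collect(hist, n)


def filter_streamlines(
    sset: StreamlineSet,
    waypoint: BinaryMask,
    target: BinaryMask,
    exclusion: BinaryMask,
    termination: BinaryMask | None = None,
) -> StreamlineSet:
    """Retain streamlines visiting the waypoint and target but never the exclusion.

    Each streamline is first truncated at its first termination-plane voxel
    (if a termination mask is given), then tested.  Rejection reasons are
    recorded per streamline.
    """
    affine_inv = np.linalg.inv(waypoint.affine)
    shape = np.array(waypoint.data.shape)
    new_lines, new_status = [], []
    for sl in sset.streamlines:
        if len(sl) == 0:
            new_lines.append(sl)
            new_status.append("rejected:empty")
            continue
        vc = _world_to_voxel(affine_inv, sl)
        idx = np.rint(vc).astype(int)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        idxc = np.clip(idx, 0, shape - 1)

        def visits(mask: BinaryMask, upto: int | None = None) -> np.ndarray:
            hit = inside & mask.data[idxc[:, 0], idxc[:, 1], idxc[:, 2]]
            return hit if upto is None else hit[:upto]

        cut = len(sl)
        if termination is not None:
            term_hits = np.nonzero(visits(termination))[0]
            if len(term_hits):
                cut = int(term_hits[0]) + 1
        sl_cut = sl[:cut]
        if visits(exclusion, cut).any():
            new_lines.append(sl_cut)
            new_status.append("rejected:exclusion")
        elif not visits(waypoint, cut).any():
            new_lines.append(sl_cut)
            new_status.append("rejected:no-waypoint")
        elif not visits(target, cut).any():
            new_lines.append(sl_cut)
            new_status.append("rejected:no-target")
        else:
            new_lines.append(sl_cut)
            new_status.append("retained")
    out = StreamlineSet(new_lines, new_status, n_initiated=sset.n_initiated)
    logger.info(
        "filtering: %d/%d retained (%s)", out.n_retained, len(new_lines), out.rejection_tally()
    )
    return out


def compute_sdi(
    sset: StreamlineSet, shape: tuple[int, int, int], affine: np.ndarray
) -> SDI:
    """Streamline-density image over the retained streamlines.

    Each retained streamline contributes at most once to every voxel it
    enters; the map is normalized by the number retained.
    """
    retained = sset.retained
    if len(retained) == 0:
        raise ValueError(
            "no retained streamlines; review seeding, masks and tracking parameters"
        )
    affine_inv = np.linalg.inv(affine)
    counts = np.zeros(shape)
    shp = np.array(shape)
    for sl in retained:
        vc = _world_to_voxel(affine_inv, sl)
        idx = np.rint(vc).astype(int)
        inside = np.all((idx >= 0) & (idx < shp), axis=1)
        idx = idx[inside]
        lin = np.unique(np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), shape))
        counts.flat[lin] += 1.0
    return SDI(data=counts / len(retained), affine=np.asarray(affine, float), n_retained=len(retained))
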