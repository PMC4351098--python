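"""ROI mask construction: seed/target/waypoint/exclusion/termination/inclusion masks.

Builds the atlas-style mask logic used to constrain OR tractography from
probability maps and anatomical landmarks: thresholded probability masks,
a coronal waypoint slice a fixed distance posterior to the temporal pole,
a coronal exclusion plane closer to the pole, a midline sagittal
termination plane, and an FA-thresholded white-matter inclusion mask.

"Posterior to the temporal pole" means smaller world-y in RAS+ coordinates.
Planes are single voxel slices nearest the requested world coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "BinaryMask",
    "resample_affine",
    "probability_to_mask",
    "make_planes",
    "make_inclusion_mask",
]


@dataclass
class BinaryMask:
    """A labelled boolean grid sharing the DWI affine."""

    data: np.ndarray
    affine: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def resample_affine(
    data: np.ndarray,
    source_affine: np.ndarray,
    target_shape: tuple[int, int, int],
    target_affine: np.ndarray,
) -> np.ndarray:
    """Resample a scalar volume onto a target grid under the given affines.

    Trilinear interpolation; points falling outside the source field of view
    get 0.  Only *resampling* under known affines is provided -- affine
    *estimation* (registration) is out of scope and must come from an
    external tool.
    """
    source_affine = np.asarray(source_affine, dtype=float)
    target_affine = np.asarray(target_affine, dtype=float)
    for name, aff in (("source", source_affine), ("target", target_affine)):
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError(f"{name} affine is singular")
    # target voxel -> world -> source voxel
    xform = np.linalg.inv(source_affine) @ target_affine
    idx = np.stack(
        np.meshgrid(*[np.arange(s) for s in target_shape], indexing="ij"), axis=0
    ).astype(float)
    src = np.einsum("ij,j...->i...", xform[:3, :3], idx) + xform[:3, 3][:, None, None, None]
    return map_coordinates(np.asarray(data, dtype=float), src, order=1, mode="constant", cval=0.0)


def probability_to_mask(
    prob_map: np.ndarray, affine: np.ndarray, threshold: float = 0.1, label: str = ""
) -> BinaryMask:
    """Binarize a probability map: retain voxels with value strictly > threshold."""
    prob_map = np.asarray(prob_map, dtype=float)
    if np.any(prob_map < 0) or np.any(prob_map > 1):
        raise ValueError("probability map values must lie in [0, 1]")
    data = prob_map > threshold
    if not data.any():
        raise ValueError(f"probability threshold {threshold} leaves an empty mask")
    return BinaryMask(data=data, affine=affine, label=label)


def _nearest_slice(affine: np.ndarray, axis: int, world_coord: float, n: int) -> int:
    """Grid index of the slice along *axis* nearest the given world coordinate."""
    inv = np.linalg.inv(affine)
    # build a world point on the axis (other coords at 0 -- valid for the
    # axis-aligned affines produced here; general obliques are not supported)
    p = np.zeros(4)
    p[axis] = world_coord
    p[3] = 1.0
    idx = int(np.rint((inv @ p)[axis]))
    if not 0 <= idx < n:
        raise ValueError(
            f"plane at world coordinate {world_coord} maps to slice {idx}, outside [0, {n})"
        )
    return idx


def make_planes(
    or_mask: BinaryMask,
    tp_mm: np.ndarray,
    waypoint_offset: float = 60.0,
    exclusion_offset: float = 20.0,
    midline_x: float | None = None,
) -> tuple[BinaryMask, BinaryMask, BinaryMask]:
    """Waypoint, exclusion and termination masks from the OR mask and the TP.

    * waypoint: OR-mask voxels on the coronal slice nearest
      ``y = TP_y - waypoint_offset`` (the OR midpoint in the classic recipe);
    * exclusion: the coronal plane nearest ``y = TP_y - exclusion_offset``,
      restricted to the hemisphere containing the OR mask so the
      contralateral side is not blocked;
    * termination: the full sagittal plane nearest *midline_x*.
    """
    data = or_mask.data
    affine = or_mask.affine
    shape = data.shape
    tp_mm = np.asarray(tp_mm, dtype=float)
    if midline_x is None:
        corners = np.array([[0, 0, 0], [s - 1 for s in shape]], dtype=float)
        world = corners @ affine[:3, :3].T + affine[:3, 3]
        midline_x = float(world[:, 0].mean())

    j_way = _nearest_slice(affine, 1, tp_mm[1] - waypoint_offset, shape[1])
    waypoint = np.zeros(shape, dtype=bool)
    waypoint[:, j_way, :] = data[:, j_way, :]
    if not waypoint.any():
        raise ValueError(
            f"waypoint slice j={j_way} contains no OR-mask voxels; check the offset"
        )

    j_excl = _nearest_slice(affine, 1, tp_mm[1] - exclusion_offset, shape[1])
    exclusion = np.zeros(shape, dtype=bool)
    exclusion[:, j_excl, :] = True
    # ipsilateral restriction: keep only the hemisphere holding the OR centroid
    centers_x = (np.arange(shape[0]) * affine[0, 0]) + affine[0, 3]
    or_cx = centers_x[np.nonzero(data.any(axis=(1, 2)))[0]].mean()
    if or_cx <= midline_x:
        exclusion[centers_x > midline_x, :, :] = False
    else:
        exclusion[centers_x < midline_x, :, :] = False

    i_term = _nearest_slice(affine, 0, midline_x, shape[0])
    termination = np.zeros(shape, dtype=bool)
    termination[i_term, :, :] = True

    return (
        BinaryMask(waypoint, affine, "waypoint"),
        BinaryMask(exclusion, affine, "exclusion"),
        BinaryMask(termination, affine, "termination"),
    )


def make_inclusion_mask(
    fa_map: np.ndarray,
    affine: np.ndarray,
    threshold: float = 0.1,
    hemisphere: str = "both",
    midline_x: float | None = None,
) -> BinaryMask:
    """White-matter inclusion mask: FA > threshold within the chosen hemisphere."""
    fa_map = np.asarray(fa_map, dtype=float)
    if np.any(fa_map < 0) or np.any(fa_map > 1):
        raise ValueError("FA values must lie in [0, 1]")
    if hemisphere not in ("left", "right", "both"):
        raise ValueError("hemisphere must be 'left', 'right' or 'both'")
    data = fa_map > threshold
    if hemisphere != "both":
        shape = fa_map.shape
        centers_x = (np.arange(shape[0]) * affine[0, 0]) + affine[0, 3]
        if midline_x is None:
            midline_x = float(centers_x.mean())
        # RAS+: larger world-x is the subject's right
        keep = centers_x < midline_x if hemisphere == "left" else centers_x > midline_x
        data = data & keep[:, None, None]
    if not data.any():
        raise ValueError(f"FA threshold {threshold} ({hemisphere}) leaves an empty mask")
    return BinaryMask(data=data, affine=affine, label="inclusion")
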