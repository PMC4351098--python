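"""File I/O: NIfTI volumes, FSL-dialect gradient tables, and MRtrix TCK streamlines.

All on-disk volumes are NIfTI-1 with a RAS+ affine.  Gradient tables use the
FSL text dialect: ``bvecs`` is 3 rows by N columns of unit direction
components, ``bvals`` a single row of N diffusion weightings in s/mm^2.
"""

from __future__ import annotations

import struct
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "load_nifti",
    "save_nifti",
    "read_bvecs_bvals",
    "write_bvecs_bvals",
    "write_tck",
    "read_tck",
]


def save_nifti(path: str | Path, data: np.ndarray, affine: np.ndarray) -> None:
    """Write *data* as a NIfTI-1 image with the given voxel-to-world affine."""
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine, dtype=float)), str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI image; returns ``(data, affine)``."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def write_bvecs_bvals(prefix: str | Path, directions: np.ndarray, b_values: np.ndarray) -> None:
    """Write ``<prefix>.bvecs`` / ``<prefix>.bvals`` in FSL text format.

    *directions* must have one row per volume (zero rows for b=0 volumes).
    """
    prefix = Path(prefix)
    directions = np.asarray(directions, dtype=float)
    b_values = np.asarray(b_values, dtype=float)
    if directions.shape[0] != b_values.shape[0]:
        raise ValueError("directions and b_values must cover the same volumes")
    np.savetxt(prefix.with_suffix(".bvecs"), directions.T, fmt="%.10f")
    np.savetxt(prefix.with_suffix(".bvals"), b_values[None, :], fmt="%.1f")


def read_bvecs_bvals(bvec_path: str | Path, bval_path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read an FSL-dialect gradient table; returns ``(directions[N,3], b_values[N])``."""
    bvecs = np.loadtxt(bvec_path)
    bvals = np.atleast_1d(np.loadtxt(bval_path)).ravel()
    if bvecs.ndim == 1:
        bvecs = bvecs[:, None]
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous 3x3; FSL convention is 3 rows = components
        bvecs = bvecs.T
    if bvecs.shape[0] != bvals.shape[0]:
        raise ValueError("bvec/bval volume counts disagree")
    return bvecs, bvals


def write_tck(path: str | Path, streamlines: list[np.ndarray]) -> None:
    """Write streamlines (world-mm polylines) in the MRtrix TCK track format."""
    path = Path(path)
    header_lines = [
        "mrtrix tracks",
        "datatype: Float32LE",
        f"count: {len(streamlines)}",
    ]
    # two-pass: the offset line changes its own length, so fix-point it
    offset = 0
    for _ in range(3):
        hdr = "\n".join(header_lines + [f"file: . {offset}", "END"]) + "\n"
        new_offset = len(hdr.encode())
        if new_offset == offset:
            break
        offset = new_offset
    with open(path, "wb") as fh:
        fh.write(hdr.encode())
        nan = struct.pack("<3f", np.nan, np.nan, np.nan)
        for sl in streamlines:
            fh.write(np.asarray(sl, dtype="<f4").tobytes())
            fh.write(nan)
        fh.write(struct.pack("<3f", np.inf, np.inf, np.inf))


def read_tck(path: str | Path) -> list[np.ndarray]:
    """Read an MRtrix TCK track file written by :func:`write_tck`."""
    raw = Path(path).read_bytes()
    end = raw.index(b"END\n")
    header = raw[:end].decode()
    offset = None
    for line in header.splitlines():
        if line.startswith("file:"):
            offset = int(line.split()[-1])
    if offset is None:
        raise ValueError("TCK header lacks a file offset")
    pts = np.frombuffer(raw[offset:], dtype="<f4").reshape(-1, 3)
    streamlines: list[np.ndarray] = []
    current: list[np.ndarray] = []
    for p in pts:
        if np.all(np.isinf(p)):
            break
        if np.any(np.isnan(p)):
            if current:
                streamlines.append(np.array(current))
            current = []
        else:
            current.append(p.astype(float))
    if current:
        streamlines.append(np.array(current))
    return streamlines
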