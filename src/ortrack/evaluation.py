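"""Evaluation of tractography against a gold-standard tract mask.

Implements the ROC-based comparison protocol for streamline-density images
(SDIs): with a gold-standard tract mask G and a search volume S (by default
the tractography inclusion mask united with G),

* TPR(t) = |{SDI > t} ∩ G| / |G|
* FPR(t) = |{SDI > t} ∩ (S \\ G)| / |S \\ G|

swept over all distinct SDI values; the TPR is interpolated onto 1000
equally spaced FPR points for the ROC curve, the AUC is the trapezoid area
on that grid, and Youden's J = max(TPR - FPR) over the swept thresholds.
Final binary tracts are produced by applying the cross-subject *median* of
the per-subject SDI intensities at a fixed FPR (2.1% by default) and scored
by volume and by anatomical landmark distances: the anterior tip of the
loop (MLA) is located automatically as the centroid of the tract voxels on
the most anterior occupied coronal slice, and MLA-TP / MLA-OP / TP-OP
distances are measured along the anterior-posterior axis.

Model comparisons use a paired Wilcoxon signed-rank test (exact null for
n <= 15, normal approximation beyond) and a paired t-test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .masks import BinaryMask
from .tracking import SDI

__all__ = [
    "ROCCurve",
    "EvaluationReport",
    "roc_analysis",
    "threshold_at_fpr",
    "finalize_tracts",
    "measure_landmarks",
    "paired_tests",
    "wilcoxon_signed_rank",
    "dice_coefficient",
    "plot_roc",
    "subsample_experiment",
]


@dataclass
class ROCCurve:
    """ROC of an SDI against a gold mask within a search volume."""

    fpr_grid: np.ndarray  # 1000 equally spaced FPRs in [0, 1]
    tpr: np.ndarray  # interpolated TPR at each grid point
    auc: float
    youden_j: float
    threshold_at_j: float
    swept_thresholds: np.ndarray
    swept_tpr: np.ndarray
    swept_fpr: np.ndarray
    n_search_voxels: int

    def __post_init__(self) -> None:
        if not (0 <= self.auc <= 1):
            raise ValueError("AUC outside [0, 1]")
        if np.any(np.diff(self.fpr_grid) <= 0):
            raise ValueError("FPR grid must be strictly increasing")


@dataclass
class EvaluationReport:
    """Per-subject, per-model metrics plus paired comparison statistics."""

    per_subject: "object"  # pandas DataFrame: one row per (subject, model)
    final_thresholds: dict  # model -> cross-subject median SDI threshold
    paired: dict = field(default_factory=dict)  # metric -> test results


def _rates(sdi_vals: np.ndarray, gold: np.ndarray, thresholds: np.ndarray):
    """TPR and FPR of {SDI > t} for every t, within the search volume."""
    n_gold = int(gold.sum())
    n_bg = int((~gold).sum())
    if n_gold == 0 or n_bg == 0:
        raise ValueError("ROC undefined: gold mask or background within search is empty")
    order = np.argsort(sdi_vals, kind="stable")
    sv, gv = sdi_vals[order], gold[order]
    # cumulative counts of voxels with value <= t, per distinct threshold
    idx = np.searchsorted(sv, thresholds, side="right")
    gold_cum = np.concatenate([[0], np.cumsum(gv)])
    tp = n_gold - gold_cum[idx]
    fp = (len(sv) - idx) - tp
    return tp / n_gold, fp / n_bg


def roc_analysis(
    sdi: SDI,
    gold: BinaryMask,
    search: BinaryMask,
    n_points: int = 1000,
) -> ROCCurve:
    """ROC analysis of an SDI within a search volume (see module docstring).

    All distinct SDI values are swept as thresholds; TPR is linearly
    interpolated onto *n_points* equally spaced FPR values, anchored at
    (0, 0) and (1, 1).
    """
    search_data = search.data
    if not search_data.any():
        raise ValueError("search volume is empty")
    gold_in = gold.data[search_data]
    vals = sdi.data[search_data]
    thresholds = np.unique(vals)
    tpr_sw, fpr_sw = _rates(vals, gold_in, thresholds)

    # sweep in increasing-FPR order (decreasing threshold), with anchors
    fpr_pts = np.concatenate([[0.0], fpr_sw[::-1], [1.0]])
    tpr_pts = np.concatenate([[0.0], tpr_sw[::-1], [1.0]])
    order = np.argsort(fpr_pts, kind="stable")
    fpr_pts, tpr_pts = fpr_pts[order], np.maximum.accumulate(tpr_pts[order])

    grid = np.linspace(0.0, 1.0, n_points)
    tpr_grid = np.interp(grid, fpr_pts, tpr_pts)
    auc = float(np.trapezoid(tpr_grid, grid))

    j_vals = tpr_sw - fpr_sw
    j_best = int(np.argmax(j_vals))
    return ROCCurve(
        fpr_grid=grid,
        tpr=tpr_grid,
        auc=auc,
        youden_j=float(j_vals[j_best]),
        threshold_at_j=float(thresholds[j_best]),
        swept_thresholds=thresholds,
        swept_tpr=tpr_sw,
        swept_fpr=fpr_sw,
        n_search_voxels=int(search_data.sum()),
    )


def threshold_at_fpr(
    sdi: SDI, gold: BinaryMask, search: BinaryMask, target_fpr: float = 0.021
) -> float:
    """Smallest distinct SDI value whose FPR is at most *target_fpr*.

    The FPR of {SDI > t} is non-increasing in t, so this is the loosest
    threshold meeting the false-positive budget.
    """
    if not 0 <= target_fpr <= 1:
        raise ValueError("target_fpr must lie in [0, 1]")
    search_data = search.data
    gold_in = gold.data[search_data]
    vals = sdi.data[search_data]
    thresholds = np.unique(vals)
    _, fpr_sw = _rates(vals, gold_in, thresholds)
    ok = fpr_sw <= target_fpr
    if not ok.any():
        raise ValueError(
            f"target FPR {target_fpr} unreachable: minimum achievable FPR is {fpr_sw.min():.4g}"
        )
    return float(thresholds[np.argmax(ok)])


def finalize_tracts(
    sdis: list[SDI], thresholds: list[float]
) -> tuple[list[BinaryMask], list[float], float]:
    """Binary tracts from the cross-subject median threshold; volumes in cm^3.

    Returns ``(masks, volumes_cm3, median_threshold)``.  An empty final
    tract triggers a warning and a volume of 0.
    """
    if len(sdis) < 1 or len(sdis) != len(thresholds):
        raise ValueError("need one threshold per SDI, at least one subject")
    med = float(np.median(thresholds))
    masks, volumes = [], []
    for i, sdi in enumerate(sdis):
        data = sdi.data > med
        if not data.any():
            warnings.warn(f"final tract for subject {i} is empty at threshold {med:.4g}")
        voxel_vol_mm3 = float(abs(np.linalg.det(sdi.affine[:3, :3])))
        masks.append(BinaryMask(data, sdi.affine, "final-tract"))
        volumes.append(data.sum() * voxel_vol_mm3 / 1000.0)
    return masks, volumes, med


def measure_landmarks(
    tract: BinaryMask, tp_mm: np.ndarray, op_mm: np.ndarray
) -> dict:
    """Landmark distances from the automated anterior-tip (MLA) rule.

    MLA is the centroid of tract voxels on the most anterior occupied
    coronal slice (an automated proxy for expert identification).  The
    MLA-TP, MLA-OP and TP-OP distances are anterior-posterior (|delta y|)
    measurements, the axis along which dissection studies report them.
    Returns the distances plus the MLA world coordinate.
    """
    if not tract.data.any():
        raise ValueError("cannot locate the anterior tip of an empty tract")
    tp_mm = np.asarray(tp_mm, dtype=float)
    op_mm = np.asarray(op_mm, dtype=float)
    occupied_j = np.nonzero(tract.data.any(axis=(0, 2)))[0]
    # +y is anterior; with a positive-diagonal affine the largest j is the most anterior
    j_ant = occupied_j[-1] if tract.affine[1, 1] > 0 else occupied_j[0]
    vox = np.argwhere(tract.data[:, j_ant, :])
    ijk = np.column_stack([vox[:, 0], np.full(len(vox), j_ant), vox[:, 1]]).astype(float)
    centroid_vox = ijk.mean(axis=0)
    mla = tract.affine[:3, :3] @ centroid_vox + tract.affine[:3, 3]
    return {
        "mla_mm": mla,
        "mla_tp": float(abs(mla[1] - tp_mm[1])),
        "mla_op": float(abs(mla[1] - op_mm[1])),
        "tp_op": float(abs(tp_mm[1] - op_mm[1])),
    }


# --------------------------------------------------------------------------
# paired statistics
# --------------------------------------------------------------------------

def wilcoxon_signed_rank(a: np.ndarray, b: np.ndarray) -> dict:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (the classic signed-rank convention); ties
    among |differences| get average ranks.  The null distribution of W+ is
    exact (full enumeration of sign assignments) for n <= 15 and a normal
    approximation with tie correction beyond.  All differences zero returns
    p = 1 with a ``degenerate`` flag.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return {"statistic": 0.0, "p_value": 1.0, "n": 0, "degenerate": True}
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 15:
        # exact: enumerate all 2^n sign assignments of the ranks
        signs = np.array(list(itertools.product([0, 1], repeat=n)))
        w_all = signs @ ranks
        w_max = ranks.sum()
        w_tail = min(w_plus, w_max - w_plus)
        p = float(np.mean(w_all <= w_tail) + np.mean(w_all >= w_max - w_tail))
        p = min(1.0, p)
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_corr = ((counts**3 - counts) / 48.0).sum()
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
        z = (w_plus - mean) / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return {"statistic": w_plus, "p_value": p, "n": n, "degenerate": False}


def paired_tests(values_a: np.ndarray, values_b: np.ndarray) -> dict:
    """Paired Wilcoxon signed-rank and paired t-test between two models.

    Returns ``{"wilcoxon": {...}, "ttest": {"statistic", "p_value"}}``; the
    t-test of identical vectors is reported as t = 0, p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) != len(b) or len(a) < 5:
        raise ValueError("paired tests need equal-length samples with n >= 5")
    wil = wilcoxon_signed_rank(a, b)
    if np.allclose(a, b):
        tt = {"statistic": 0.0, "p_value": 1.0}
    else:
        res = stats.ttest_rel(a, b)
        tt = {"statistic": float(res.statistic), "p_value": float(res.pvalue)}
    return {"wilcoxon": wil, "ttest": tt}


def plot_roc(curves: dict, path) -> None:
    """Plot one or more named ROC curves (AUC in the legend) to a PNG file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, roc in curves.items():
        ax.plot(roc.fpr_grid, roc.tpr, label=f"{name} (AUC {roc.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="chance")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / denom)


# --------------------------------------------------------------------------
# direction-subsampling experiment
# --------------------------------------------------------------------------

def subsample_experiment(
    dwi_full,
    scheme_full,
    counts: list[int],
    pipeline_config,
    seed: int = 0,
):
    """Tractography quality as the number of diffusion directions degrades.

    For each requested direction count an energy-minimal subset of the full
    scheme is selected (greedy electrostatic removal), the CSD + tracking +
    final-tract pipeline is re-run on the subsampled volumes, and the
    resulting tract is scored against the *full-data* final tract as gold
    standard: sensitivity, specificity, Dice, and the FPR at the full-data
    final threshold.  Returns a pandas DataFrame with one row per count.
    """
    import pandas as pd

    from .phantom import greedy_subset
    from .pipeline import _single_model_tract

    n_avail = len(scheme_full.directions)
    for c in counts:
        if c > n_avail:
            raise ValueError(f"requested {c} directions but only {n_avail} available")
        if c < 6:
            raise ValueError("need at least 6 directions")

    full = _single_model_tract(dwi_full, scheme_full, pipeline_config, seed)
    gold_tract = full["tract"].data
    search = full["search"].data
    bg = search & ~gold_tract

    rows = []
    for c in counts:
        if c == n_avail:
            sub_res, sub_tract = full, gold_tract
        else:
            keep = greedy_subset(scheme_full.directions, c)
            scheme_c = scheme_full.subset(keep)
            vol_idx = np.concatenate([scheme_full.b0_indices, scheme_full.dwi_indices[keep]])
            from .phantom import DWIVolume

            dwi_c = DWIVolume(
                data=dwi_full.data[..., vol_idx], affine=dwi_full.affine, scheme=scheme_c
            )
            sub_res = _single_model_tract(
                dwi_c, scheme_c, pipeline_config, seed, threshold=full["threshold"]
            )
            sub_tract = sub_res["tract"].data
        tp = (sub_tract & gold_tract).sum()
        fn = (~sub_tract & gold_tract).sum()
        fp = (sub_tract & bg).sum()
        tn = (~sub_tract & bg).sum()
        rows.append(
            {
                "n_directions": c,
                "sensitivity": tp / max(tp + fn, 1),
                "specificity": tn / max(tn + fp, 1),
                "dice": dice_coefficient(sub_tract, gold_tract),
                "fpr_at_final_threshold": fp / max(fp + tn, 1),
            }
        )
    return pd.DataFrame(rows)
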