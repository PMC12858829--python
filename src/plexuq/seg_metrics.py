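"""Consensus segmentation and accuracy metrics against ground truth.

Covers binarization of a mean probability map, majority voting across
ensemble masks, Dice overlap, (95th-percentile) Hausdorff distance in
physical mm, volume similarity and across-subject Pearson volume
correlation, plus a Dice-vs-threshold sweep.

Conventions where definitions are underdetermined (documented and pinned by
tests): a mean probability exactly at the threshold is foreground; an exact
even-split majority tie is background; Dice of two empty masks is 1.0 (with
a warning), of one empty mask 0.0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from .grids import BinaryMask, ScalarVolume, require_compatible

__all__ = [
    "EvalResult",
    "binarize",
    "majority_vote",
    "dice",
    "hausdorff",
    "volume_similarity",
    "volume_correlation",
    "threshold_sweep",
    "evaluate_subject",
]


@dataclass
class EvalResult:
    """Per-subject accuracy summary of an automated mask against ground truth."""

    subject_id: str
    dice: float
    hausdorff_mm: float
    hausdorff95_mm: float
    volume_similarity: float
    auto_volume_mm3: float
    truth_volume_mm3: float


def binarize(mean_map: ScalarVolume, threshold: float = 0.5) -> BinaryMask:
    """Threshold a mean probability map; voxel -> 1 iff p-bar >= threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return BinaryMask(grid=mean_map.grid, values=(mean_map.values >= threshold).astype(np.uint8))


def majority_vote(masks: Sequence[BinaryMask]) -> BinaryMask:
    """Consensus mask: foreground where strictly more than half the masks agree.

    For an even number of masks an exact tie maps to background
    (conservative under-segmentation).
    """
    if len(masks) == 0:
        raise ValueError("majority_vote needs at least one mask")
    grid = masks[0].grid
    require_compatible(*[m.grid for m in masks], context="majority_vote")
    votes = np.zeros(grid.shape, dtype=np.int64)
    for m in masks:
        votes += m.values
    return BinaryMask(grid=grid, values=(votes * 2 > len(masks)).astype(np.uint8))


def dice(a: BinaryMask, m: BinaryMask) -> float:
    """Dice overlap 2|A∩M| / (|A| + |M|) between two binary masks."""
    require_compatible(a.grid, m.grid, context="dice")
    na, nm = a.n_foreground, m.n_foreground
    if na == 0 and nm == 0:
        warnings.warn("Dice of two empty masks defined as 1.0", RuntimeWarning, stacklevel=2)
        return 1.0
    inter = int(np.count_nonzero(a.values & m.values))
    return 2.0 * inter / (na + nm)


def _boundary_coords_mm(mask: BinaryMask) -> np.ndarray:
    """World-coordinate centers of boundary voxels (any 6-neighbor background)."""
    fg = mask.astype_bool()
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    interior = ndimage.binary_erosion(fg, structure=structure, border_value=0)
    boundary = fg & ~interior
    idx = np.argwhere(boundary)
    return mask.grid.world_coordinates(idx)


def hausdorff(a: BinaryMask, m: BinaryMask, percentile: float = 100.0) -> float:
    """Symmetric (percentile) Hausdorff distance between mask boundaries, in mm.

    ``percentile=100`` gives the classical maximum; ``percentile=95`` gives
    HD95, the stated percentile of the pooled directed boundary-to-boundary
    distances from both directions.
    """
    require_compatible(a.grid, m.grid, context="hausdorff")
    if a.n_foreground == 0 or m.n_foreground == 0:
        raise ValueError("Hausdorff distance is undefined for an empty mask")
    pa = _boundary_coords_mm(a)
    pm = _boundary_coords_mm(m)
    d_a_to_m, _ = cKDTree(pm).query(pa)
    d_m_to_a, _ = cKDTree(pa).query(pm)
    if percentile >= 100.0:
        return float(max(d_a_to_m.max(), d_m_to_a.max()))
    pooled = np.concatenate([d_a_to_m, d_m_to_a])
    return float(np.percentile(pooled, percentile))


def volume_similarity(a: BinaryMask, m: BinaryMask) -> float:
    """VS = 1 - |V_a - V_m| / (V_a + V_m); 1 for equal volumes, 0 if one is empty."""
    require_compatible(a.grid, m.grid, context="volume_similarity")
    na, nm = a.n_foreground, m.n_foreground
    if na == 0 and nm == 0:
        raise ValueError("volume similarity is undefined when both masks are empty")
    return 1.0 - abs(na - nm) / (na + nm)


def volume_correlation(
    auto_volumes: Sequence[float], truth_volumes: Sequence[float]
) -> float:
    """Pearson correlation of automated vs reference volumes across subjects."""
    x = np.asarray(auto_volumes, dtype=float)
    y = np.asarray(truth_volumes, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length volume lists with at least 3 subjects")
    if np.var(x) == 0.0 or np.var(y) == 0.0:
        raise ValueError("volume correlation undefined for zero-variance inputs")
    return float(pearsonr(x, y).statistic)


def evaluate_subject(
    auto: BinaryMask, truth: BinaryMask, subject_id: str = ""
) -> EvalResult:
    """Dice, HD, HD95, volume similarity and physical volumes for one subject."""
    both_nonempty = auto.n_foreground > 0 and truth.n_foreground > 0
    hd = hausdorff(auto, truth, 100.0) if both_nonempty else float("nan")
    hd95 = hausdorff(auto, truth, 95.0) if both_nonempty else float("nan")
    return EvalResult(
        subject_id=subject_id,
        dice=dice(auto, truth),
        hausdorff_mm=hd,
        hausdorff95_mm=hd95,
        volume_similarity=volume_similarity(auto, truth),
        auto_volume_mm3=auto.volume_mm3,
        truth_volume_mm3=truth.volume_mm3,
    )


def threshold_sweep(
    mean_maps: Sequence[ScalarVolume],
    truths: Sequence[BinaryMask],
    thresholds: Sequence[float],
    subject_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Dice at each binarization threshold, per subject plus the cohort mean.

    Returns a tidy frame with columns ``subject_id, threshold, dice``; the
    cohort mean row uses subject_id ``"__mean__"``.
    """
    if len(mean_maps) != len(truths):
        raise ValueError("one truth mask per mean map is required")
    if subject_ids is None:
        subject_ids = [f"s{i:03d}" for i in range(len(mean_maps))]
    rows = []
    for sid, mean_map, truth in zip(subject_ids, mean_maps, truths):
        for tau in thresholds:
            rows.append(
                {"subject_id": sid, "threshold": float(tau), "dice": dice(binarize(mean_map, tau), truth)}
            )
    df = pd.DataFrame(rows)
    means = (
        df.groupby("threshold", as_index=False)["dice"].mean().assign(subject_id="__mean__")
    )
    return pd.concat([df, means], ignore_index=True)[["subject_id", "threshold", "dice"]]
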