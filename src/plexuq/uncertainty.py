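"""Voxel-wise uncertainty maps and per-subject masked aggregates.

From S stochastic probability samples p_s(v) per voxel the package computes
four maps, all in natural-log units (entropy ceiling ln 2):

* total predictive entropy   H_total(v) = H(p-bar(v))          — combined
* expected per-sample entropy E_s[H_s](v) = (1/S) sum_s H(p_s) — aleatoric proxy
* mutual information          MI(v) = H_total - E_s[H_s]       — epistemic
  (the BALD disagreement criterion)
* predictive standard deviation sigma(v), population form (divisor S)

Each map is reduced to a per-subject scalar C by averaging over a binary
aggregation mask b (by default the subject's own binarized consensus
segmentation):  C = sum_i U_i b_i / sum_i b_i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import BinaryMask, ImageGrid, ScalarVolume, require_compatible
from .sampling import PredictiveSummary, SampleStack, binary_entropy

__all__ = [
    "UncertaintyMaps",
    "SubjectUncertainty",
    "METRIC_NAMES",
    "total_entropy",
    "expected_entropy",
    "mutual_information",
    "predictive_std",
    "masked_mean",
    "compute_all",
]

LN2 = float(np.log(2.0))

#: canonical metric keys used in tables and output filenames
METRIC_NAMES = ("htotal", "ehs", "mi", "std")

#: raw MI below this triggers a diagnostic warning (inconsistent inputs)
_MI_WARN_FLOOR = -1e-9


@dataclass
class UncertaintyMaps:
    """The four uncertainty maps on a common grid (entropies in nats)."""

    grid: ImageGrid
    total_entropy: np.ndarray = field(repr=False)
    expected_entropy: np.ndarray = field(repr=False)
    mutual_information: np.ndarray = field(repr=False)
    std: np.ndarray = field(repr=False)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "htotal": self.total_entropy,
            "ehs": self.expected_entropy,
            "mi": self.mutual_information,
            "std": self.std,
        }


@dataclass
class SubjectUncertainty:
    """Mask-restricted aggregate C for each of the four metrics."""

    subject_id: str
    values: dict[str, float]
    mask_voxels: int

    def __post_init__(self) -> None:
        if self.mask_voxels < 1:
            raise ValueError("aggregation mask must contain at least one voxel")


def _summary_of(source: PredictiveSummary | SampleStack) -> PredictiveSummary:
    if isinstance(source, SampleStack):
        return source.summary()
    return source


def total_entropy(summary: PredictiveSummary | SampleStack) -> ScalarVolume:
    """Binary entropy of the predictive mean, nats; exactly 0 at p-bar in {0,1}."""
    summary = _summary_of(summary)
    return ScalarVolume(grid=summary.grid, values=binary_entropy(summary.mean))


def expected_entropy(summary: PredictiveSummary | SampleStack) -> ScalarVolume:
    """Mean of the per-sample binary entropies (aleatoric uncertainty proxy)."""
    summary = _summary_of(summary)
    return ScalarVolume(grid=summary.grid, values=summary.mean_sample_entropy.copy())


def mutual_information(
    h_total: ScalarVolume, expected_h: ScalarVolume, clamp: bool = True
) -> ScalarVolume:
    """Epistemic uncertainty MI = H_total - E_s[H_s], clamped below at 0.

    MI is analytically non-negative (Jensen); negative values can only come
    from floating-point round-off, so anything beyond round-off scale means
    the two inputs did not come from the same sample set.
    """
    require_compatible(h_total.grid, expected_h.grid, context="mutual_information")
    raw = h_total.values - expected_h.values
    worst = float(raw.min())
    if worst < _MI_WARN_FLOOR:
        warnings.warn(
            f"mutual information reached {worst:.3e} before clamping; "
            "H_total and E_s[H_s] look inconsistent",
            RuntimeWarning,
            stacklevel=2,
        )
    return ScalarVolume(grid=h_total.grid, values=np.maximum(raw, 0.0) if clamp else raw)


def predictive_std(summary: PredictiveSummary | SampleStack) -> ScalarVolume:
    """Population standard deviation of the samples, from streaming moments.

    sigma = sqrt(max(0, E[p^2] - p-bar^2)); the max(0, .) guards against
    negative round-off variance when all samples agree.
    """
    summary = _summary_of(summary)
    var = summary.second_moment - summary.mean**2
    return ScalarVolume(grid=summary.grid, values=np.sqrt(np.maximum(var, 0.0)))


def masked_mean(u: ScalarVolume, mask: BinaryMask) -> float:
    """Aggregate C = sum(U * b) / sum(b) over the aggregation mask b."""
    require_compatible(u.grid, mask.grid, context="masked_mean")
    n = mask.n_foreground
    if n == 0:
        raise ValueError("aggregation mask is empty; masked mean is undefined")
    return float(u.values[mask.astype_bool()].sum() / n)


def compute_all(
    summary: PredictiveSummary | SampleStack,
    mask: BinaryMask,
    subject_id: str = "",
) -> tuple[UncertaintyMaps, SubjectUncertainty]:
    """All four maps plus their masked aggregates in one pass."""
    summary = _summary_of(summary)
    require_compatible(summary.grid, mask.grid, context="compute_all")
    h_tot = total_entropy(summary)
    e_h = expected_entropy(summary)
    mi = mutual_information(h_tot, e_h)
    sd = predictive_std(summary)
    maps = UncertaintyMaps(
        grid=summary.grid,
        total_entropy=h_tot.values,
        expected_entropy=e_h.values,
        mutual_information=mi.values,
        std=sd.values,
    )
    aggregates = {
        "htotal": masked_mean(h_tot, mask),
        "ehs": masked_mean(e_h, mask),
        "mi": masked_mean(mi, mask),
        "std": masked_mean(sd, mask),
    }
    return maps, SubjectUncertainty(
        subject_id=subject_id, values=aggregates, mask_voxels=mask.n_foreground
    )
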