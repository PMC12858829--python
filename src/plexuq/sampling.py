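"""Orchestration of M-member x K-realization stochastic inference.

A *stochastic predictor* is any callable ``predictor(image, member, seed)``
returning a probability volume on the image grid, deterministic in its
arguments.  The orchestrator calls it once per (member m, dropout
realization k) pair with a seed derived injectively from ``(base_seed, m,
k)``, so execution order (or parallelism) can never change the result.

The full scheme used throughout is M=5 ensemble members x K=20 dropout
passes (S=100 samples per subject); a lighter M=5 x K=5 (S=25) preset named
``"abide-light"`` trades sampling resolution for throughput on large
cohorts.

Per-voxel means and the moments needed by every uncertainty map (second
moment and mean per-sample binary entropy, natural log) are accumulated in
a streaming fashion, so memory stays at three volumes regardless of S.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy.special import xlogy

from .grids import GridMismatchError, ImageGrid, ScalarVolume, require_compatible

__all__ = [
    "SamplingScheme",
    "SampleStack",
    "MomentAccumulator",
    "PredictiveSummary",
    "PredictorContractError",
    "StochasticPredictor",
    "derive_seed",
    "run_sampling",
    "stack_from_arrays",
    "load_stack",
    "SCHEME_PRESETS",
]


def binary_entropy(p: np.ndarray) -> np.ndarray:
    """Elementwise binary entropy in nats; p in {0, 1} contributes exactly 0.

    Uses ``xlogy`` so the x*ln(x) -> 0 limit is handled analytically rather
    than by epsilon-clamping, which would bias near-confident voxels.
    """
    p = np.asarray(p, dtype=float)
    return -xlogy(p, p) - xlogy(1.0 - p, 1.0 - p)


class StochasticPredictor(Protocol):
    def __call__(self, image: ScalarVolume, member: int, seed: int) -> ScalarVolume: ...


class PredictorContractError(RuntimeError):
    """A predictor returned an off-grid or out-of-range volume."""


@dataclass(frozen=True)
class SamplingScheme:
    """Ensemble size M, dropout passes per member K, dropout rate p, base seed.

    ``dropout_rate`` is carried for predictors that model dropout (the toy
    trainable predictor); purely parametric simulators ignore it.
    """

    members: int = 5
    realizations: int = 20
    dropout_rate: float = 0.1
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.members < 1 or self.realizations < 1:
            raise ValueError("members and realizations must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")

    @property
    def n_samples(self) -> int:
        return self.members * self.realizations


SCHEME_PRESETS: dict[str, SamplingScheme] = {
    # full scheme: 5 ensemble members x 20 MC-dropout passes = 100 samples
    "full": SamplingScheme(members=5, realizations=20),
    # lighter cohort-scale scheme: 5 x 5 = 25 samples
    "abide-light": SamplingScheme(members=5, realizations=5),
}


def derive_seed(base_seed: int, member: int, realization: int) -> int:
    """Deterministic per-(m, k) seed, independent of call order.

    Uses numpy's splittable ``SeedSequence`` hashing so that seeds for
    different (m, k) pairs are statistically independent and, in practice,
    distinct; sequential offsets would correlate streams across members.
    """
    if member < 1 or realization < 1:
        raise ValueError("member and realization are 1-based and must be >= 1")
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=(int(member), int(realization)))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


@dataclass
class MomentAccumulator:
    """Streaming per-voxel sums: sum p, sum p^2, sum H(p) over samples seen."""

    grid: ImageGrid
    count: int = 0
    sum_p: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    sum_p2: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    sum_h: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sum_p is None:
            self.sum_p = np.zeros(self.grid.shape, dtype=float)
            self.sum_p2 = np.zeros(self.grid.shape, dtype=float)
            self.sum_h = np.zeros(self.grid.shape, dtype=float)

    def accumulate(self, sample: ScalarVolume) -> "MomentAccumulator":
        """Fold one probability sample into the running sums (order-invariant)."""
        require_compatible(self.grid, sample.grid, context="accumulate")
        p = sample.values
        if p.min() < 0.0 or p.max() > 1.0:
            raise ValueError("sample values outside [0, 1]")
        self.sum_p += p
        self.sum_p2 += p * p
        self.sum_h += binary_entropy(p)
        self.count += 1
        return self

    def finalize(self) -> "PredictiveSummary":
        if self.count < 1:
            raise ValueError("cannot finalize an accumulator with no samples")
        s = float(self.count)
        return PredictiveSummary(
            grid=self.grid,
            n_samples=self.count,
            mean=self.sum_p / s,
            second_moment=self.sum_p2 / s,
            mean_sample_entropy=self.sum_h / s,
        )


@dataclass
class PredictiveSummary:
    """Per-voxel sufficient statistics of the predictive distribution.

    ``mean`` is the predictive mean probability p-bar(v); ``second_moment``
    is E_s[p_s^2] and ``mean_sample_entropy`` is E_s[H(p_s)] — together they
    determine all four uncertainty maps.
    """

    grid: ImageGrid
    n_samples: int
    mean: np.ndarray = field(repr=False)
    second_moment: np.ndarray = field(repr=False)
    mean_sample_entropy: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.mean.min() < -1e-12 or self.mean.max() > 1.0 + 1e-12:
            raise ValueError("predictive mean outside [0, 1]")
        np.clip(self.mean, 0.0, 1.0, out=self.mean)

    def mean_volume(self) -> ScalarVolume:
        return ScalarVolume(grid=self.grid, values=self.mean, is_probability=True)


@dataclass
class SampleStack:
    """The S = M*K retained probability samples for one subject.

    ``samples`` maps (member, realization) tags to probability arrays; tags
    cover {1..M} x {1..K} exactly once.
    """

    grid: ImageGrid
    samples: dict[tuple[int, int], np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        members = sorted({m for m, _ in self.samples})
        realizations = sorted({k for _, k in self.samples})
        expected = {(m, k) for m in members for k in realizations}
        if set(self.samples) != expected or members[0] != 1 or realizations[0] != 1:
            raise ValueError("sample tags must cover {1..M} x {1..K} exactly")
        for tag, arr in self.samples.items():
            if arr.shape != self.grid.shape:
                raise ValueError(f"sample {tag} shape {arr.shape} off grid {self.grid.shape}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_members(self) -> int:
        return max(m for m, _ in self.samples)

    @property
    def n_realizations(self) -> int:
        return max(k for _, k in self.samples)

    def as_array(self) -> np.ndarray:
        """Samples as an (S, *grid.shape) array in member-major order."""
        keys = sorted(self.samples)
        return np.stack([self.samples[k] for k in keys], axis=0)

    def to_accumulator(self) -> MomentAccumulator:
        acc = MomentAccumulator(grid=self.grid)
        for key in sorted(self.samples):
            acc.accumulate(ScalarVolume(self.grid, self.samples[key], is_probability=True))
        return acc

    def summary(self) -> PredictiveSummary:
        return self.to_accumulator().finalize()


def stack_from_arrays(grid: ImageGrid, arrays: Sequence[np.ndarray]) -> SampleStack:
    """Build a single-member stack (m=1, k=1..S) from raw probability arrays."""
    samples = {(1, k + 1): np.asarray(a, dtype=float) for k, a in enumerate(arrays)}
    return SampleStack(grid=grid, samples=samples)


def _check_sample(sample: ScalarVolume, grid: ImageGrid, m: int, k: int) -> None:
    try:
        require_compatible(grid, sample.grid, context=f"sample (m={m}, k={k})")
    except GridMismatchError as exc:
        raise PredictorContractError(str(exc)) from exc
    lo, hi = float(sample.values.min()), float(sample.values.max())
    if lo < 0.0 or hi > 1.0:
        raise PredictorContractError(
            f"predictor output for (m={m}, k={k}) outside [0, 1]: min={lo:.6g}, max={hi:.6g}"
        )


def run_sampling(
    predictor: StochasticPredictor,
    image: ScalarVolume,
    scheme: SamplingScheme,
    retain_stack: bool = True,
) -> SampleStack | MomentAccumulator:
    """Draw the full M x K sample set for one subject.

    With ``retain_stack`` the S individual probability volumes are kept
    (needed to write per-sample maps); otherwise only the streaming moment
    accumulator is returned and memory stays bounded by three volumes.
    """
    grid = image.grid
    acc = MomentAccumulator(grid=grid)
    retained: dict[tuple[int, int], np.ndarray] = {}
    for m in range(1, scheme.members + 1):
        for k in range(1, scheme.realizations + 1):
            seed = derive_seed(scheme.base_seed, m, k)
            sample = predictor(image, m, seed)
            _check_sample(sample, grid, m, k)
            acc.accumulate(sample)
            if retain_stack:
                retained[(m, k)] = np.asarray(sample.values, dtype=float)
    if retain_stack:
        return SampleStack(grid=grid, samples=retained)
    return acc


def load_stack(manifest, reader: Callable[[str], ScalarVolume] | None = None) -> SampleStack:
    """Load a subject's sample stack from a manifest DataFrame of NIfTI paths.

    The manifest must describe a single subject; use this to bypass the
    predictor when samples were produced elsewhere.
    """
    from . import volume_io

    if reader is None:
        reader = lambda p: volume_io.read_volume(p, expect_probability=True)
    subjects = manifest["subject_id"].unique()
    if len(subjects) != 1:
        raise ValueError(f"manifest must contain one subject, found {list(subjects)}")
    samples: dict[tuple[int, int], np.ndarray] = {}
    grid: ImageGrid | None = None
    for row in manifest.itertuples(index=False):
        vol = reader(row.path)
        if grid is None:
            grid = vol.grid
        else:
            require_compatible(grid, vol.grid, context=f"stack sample {row.path}")
        samples[(int(row.member), int(row.realization))] = vol.values
    assert grid is not None
    return SampleStack(grid=grid, samples=samples)
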