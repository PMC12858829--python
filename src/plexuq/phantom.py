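"""Self-contained synthetic data: phantoms, stochastic predictors, cohorts.

The phantom emulates the geometry that makes choroid-plexus segmentation
hard: a thin, bright, curvilinear structure (the "plexus", radius 1-2
voxels) threading through low-intensity ellipsoidal "ventricles" embedded
in mid-intensity background — i.e. T1-like contrast with a bright target
inside dark CSF.

The parametric stochastic predictor is the canonical test path.  It draws
voxel-wise logits

    logit p_{m,k}(v) = mu(v) + delta_m(v) + eps_{m,k}(v)

where mu(v) = +a on the true structure and -a elsewhere (linearly softened
within ``boundary_width`` voxels of the boundary, modelling partial-volume
ambiguity), delta_m is a per-member Gaussian field drawn once per ensemble
member (epistemic: constant across dropout realizations, so it shows up as
inter-model disagreement / mutual information), and eps_{m,k} is drawn
fresh per realization (aleatoric: it inflates the per-sample entropy).
Both fields can be smoothed to a correlation length ``smooth_length`` and
are rescaled after smoothing so their marginal SD stays at the requested
value.

A small trainable voxel classifier with real unit-level dropout
(:func:`toy_dropout_predictor`) exercises the dropout-rate / uncertainty
relationship; cohort builders assemble in-distribution and shifted groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .grids import BinaryMask, ImageGrid, ScalarVolume
from .sampling import StochasticPredictor

__all__ = [
    "PhantomSpec",
    "SimulatorSpec",
    "GroupSpec",
    "CohortSpec",
    "Subject",
    "generate_phantom",
    "simulate_predictor",
    "toy_dropout_predictor",
    "TrainingError",
    "make_cohort",
    "COHORT_PRESETS",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity model of one synthetic subject.

    Intensity ordering plexus > background > ventricle is enforced; sizes
    are in voxels, intensities in arbitrary units.  ``contrast_scale``
    shrinks the plexus-vs-ventricle intensity gap (1.0 = nominal), and
    ``size_scale`` shrinks ventricles and plexus radius together — the two
    knobs used by the shifted "child-like" cohort preset.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    ventricle_centers: tuple[tuple[float, float, float], ...] = (
        (15.0, 24.0, 24.0),
        (33.0, 24.0, 24.0),
    )
    ventricle_semiaxes: tuple[float, float, float] = (7.0, 10.0, 12.0)
    plexus_radius: float = 1.5
    background_mean: float = 100.0
    ventricle_mean: float = 40.0
    plexus_mean: float = 160.0
    noise_sd: float = 5.0
    contrast_scale: float = 1.0
    size_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.plexus_mean > self.background_mean > self.ventricle_mean):
            raise ValueError("intensity ordering plexus > background > ventricle required")
        if self.plexus_radius <= 0 or self.size_scale <= 0 or self.contrast_scale <= 0:
            raise ValueError("plexus_radius, size_scale and contrast_scale must be positive")


@dataclass(frozen=True)
class SimulatorSpec:
    """Knobs of the parametric stochastic predictor.

    ``confidence`` is the logit-scale signal a (> 0): the noise-free
    predictor outputs expit(+a) on the structure and expit(-a) outside.
    ``sigma_epistemic`` is the SD of the once-per-member logit offset;
    ``sigma_aleatoric`` the SD of the fresh per-realization logit noise.
    ``boundary_width`` (voxels) softens the logit ramp across the structure
    boundary; ``smooth_length`` (voxels) spatially correlates both noise
    fields.
    """

    confidence: float = 4.0
    sigma_epistemic: float = 0.5
    sigma_aleatoric: float = 0.5
    boundary_width: float = 1.0
    smooth_length: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.confidence <= 0:
            raise ValueError("confidence must be > 0")
        if self.sigma_epistemic < 0 or self.sigma_aleatoric < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.boundary_width < 0 or self.smooth_length < 0:
            raise ValueError("boundary_width and smooth_length must be >= 0")


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    center: Sequence[float],
    semiaxes: Sequence[float],
) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return r2 <= 1.0


def _plexus_curve(
    center: Sequence[float], semiaxes: Sequence[float], n_points: int = 400
) -> np.ndarray:
    """A curvilinear path safely inside an ellipsoid (at ~55% of each semiaxis).

    An elliptical arc with a sinusoidal out-of-plane wobble; containment is
    by construction since max |offset| per axis is 0.62 * semiaxis < 1.
    """
    t = np.linspace(-0.75 * np.pi, 0.75 * np.pi, n_points)
    cx, cy, cz = center
    ax, ay, az = semiaxes
    x = cx + 0.55 * ax * np.cos(t)
    y = cy + 0.55 * ay * np.sin(t)
    z = cz + 0.35 * az * np.sin(2.0 * t)
    return np.stack([x, y, z], axis=1)


def generate_phantom(spec: PhantomSpec) -> tuple[ScalarVolume, BinaryMask]:
    """Rasterize one phantom: intensity volume plus ground-truth plexus mask.

    Deterministic given ``spec.seed``.  The truth mask is the union of the
    tube voxels (within ``plexus_radius`` of the curve, physical distance in
    voxel units) across both ventricles.
    """
    grid = ImageGrid.from_spacing(spec.shape, spec.spacing)
    semiaxes = tuple(a * spec.size_scale for a in spec.ventricle_semiaxes)
    radius = spec.plexus_radius * spec.size_scale

    ventricle = np.zeros(spec.shape, dtype=bool)
    plexus = np.zeros(spec.shape, dtype=bool)
    for center in spec.ventricle_centers:
        ventricle |= _ellipsoid_mask(spec.shape, center, semiaxes)
        curve = _plexus_curve(center, semiaxes)
        # distance from every voxel to the sampled curve, via a seed image
        seed_img = np.ones(spec.shape, dtype=bool)
        on_curve = np.round(curve).astype(int)
        on_curve = np.clip(on_curve, 0, np.array(spec.shape) - 1)
        seed_img[tuple(on_curve.T)] = False
        dist = ndimage.distance_transform_edt(seed_img)
        plexus |= dist <= radius

    if not np.all(ventricle[plexus]):
        raise ValueError("plexus escapes the ventricles; adjust the phantom spec")
    if int(plexus.sum()) < 20:
        raise ValueError(f"plexus too small ({int(plexus.sum())} voxels, need >= 20)")
    if int(plexus.sum()) > 0.05 * grid.n_voxels:
        raise ValueError("plexus occupies more than 5% of the grid")

    plexus_mean = spec.ventricle_mean + spec.contrast_scale * (
        spec.plexus_mean - spec.ventricle_mean
    )
    intensity = np.full(spec.shape, spec.background_mean, dtype=float)
    intensity[ventricle] = spec.ventricle_mean
    intensity[plexus] = plexus_mean
    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xF0)))
        intensity += rng.normal(0.0, spec.noise_sd, size=spec.shape)

    return (
        ScalarVolume(grid=grid, values=intensity),
        BinaryMask(grid=grid, values=plexus.astype(np.uint8)),
    )


def _correlated_field(
    rng: np.random.Generator, shape: tuple[int, int, int], sd: float, length: float
) -> np.ndarray:
    """Gaussian field with marginal SD ``sd``, smoothed to correlation length."""
    if sd == 0.0:
        return np.zeros(shape)
    noise = rng.standard_normal(shape)
    if length > 0:
        noise = ndimage.gaussian_filter(noise, sigma=length, mode="nearest")
        s = noise.std()
        if s > 0:
            noise /= s
    return sd * noise


def simulate_predictor(truth: BinaryMask, spec: SimulatorSpec) -> StochasticPredictor:
    """Build the parametric stochastic predictor for one subject.

    The returned callable obeys the sampling contract: identical
    ``(image, member, seed)`` gives an identical volume.  The per-member
    offset delta_m depends only on ``(spec.seed, member)`` — constant across
    dropout realizations, which is exactly what makes it register as
    epistemic (inter-member) disagreement.
    """
    grid = truth.grid
    fg = truth.astype_bool()
    d_in = ndimage.distance_transform_edt(fg)
    d_out = ndimage.distance_transform_edt(~fg)
    signed = np.where(fg, d_in, -d_out)
    # boundary_width = 0 reduces to a hard +-a step (|signed| >= 1 always)
    mu = spec.confidence * np.clip(signed / (spec.boundary_width + 0.5), -1.0, 1.0)

    member_cache: dict[int, np.ndarray] = {}

    def member_offset(member: int) -> np.ndarray:
        if member not in member_cache:
            rng = np.random.default_rng(np.random.SeedSequence((spec.seed, int(member))))
            member_cache[member] = _correlated_field(
                rng, grid.shape, spec.sigma_epistemic, spec.smooth_length
            )
        return member_cache[member]

    def predictor(image: ScalarVolume, member: int, seed: int) -> ScalarVolume:
        rng = np.random.default_rng(int(seed))
        eps = _correlated_field(rng, grid.shape, spec.sigma_aleatoric, spec.smooth_length)
        logits = mu + member_offset(member) + eps
        return ScalarVolume(grid=grid, values=expit(logits), is_probability=True)

    return predictor


# ---------------------------------------------------------------------------
# toy trainable predictor with real unit-level dropout
# ---------------------------------------------------------------------------


class TrainingError(RuntimeError):
    """The toy classifier failed to fit its training phantoms."""


def _voxel_features(image: ScalarVolume) -> np.ndarray:
    """Per-voxel features: intensity, two Gaussian smooths, local SD. (n, 4)."""
    x = image.values
    sm1 = ndimage.gaussian_filter(x, sigma=1.0, mode="nearest")
    sm2 = ndimage.gaussian_filter(x, sigma=2.0, mode="nearest")
    local_var = ndimage.gaussian_filter(x * x, sigma=1.0, mode="nearest") - sm1 * sm1
    local_sd = np.sqrt(np.maximum(local_var, 0.0))
    feats = np.stack([x, sm1, sm2, local_sd], axis=-1).reshape(-1, 4)
    return feats


class _DropoutMLP:
    """One-hidden-layer tanh MLP with inverted unit dropout at inference.

    The dropout mask drops hidden *units* per forward pass (shared across
    voxels, as channel dropout in a convolutional net would be), so each
    stochastic pass perturbs the whole segmentation coherently.
    """

    def __init__(self, n_features: int, n_hidden: int, dropout_rate: float, rng: np.random.Generator):
        self.dropout_rate = float(dropout_rate)
        self.w1 = rng.normal(0.0, 1.0 / np.sqrt(n_features), size=(n_features, n_hidden))
        self.b1 = np.zeros(n_hidden)
        self.w2 = rng.normal(0.0, 1.0 / np.sqrt(n_hidden), size=n_hidden)
        self.b2 = 0.0
        self.mu = np.zeros(n_features)
        self.sd = np.ones(n_features)

    def _forward(self, feats: np.ndarray, unit_mask: np.ndarray | None) -> np.ndarray:
        z = np.tanh(feats @ self.w1 + self.b1)
        if unit_mask is not None:
            z = z * unit_mask / (1.0 - self.dropout_rate)
        return expit(z @ self.w2 + self.b2)

    def predict(self, feats: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        feats = (feats - self.mu) / self.sd
        mask = None
        if rng is not None and self.dropout_rate > 0.0:
            mask = (rng.random(self.w1.shape[1]) >= self.dropout_rate).astype(float)
        return self._forward(feats, mask)

    def fit(
        self,
        feats: np.ndarray,
        labels: np.ndarray,
        rng: np.random.Generator,
        epochs: int = 400,
        lr: float = 0.05,
        weight_decay: float = 1e-3,
    ) -> None:
        self.mu = feats.mean(axis=0)
        self.sd = feats.std(axis=0) + 1e-9
        x = (feats - self.mu) / self.sd
        y = labels.astype(float)
        n = len(y)
        m1 = [np.zeros_like(self.w1), np.zeros_like(self.b1), np.zeros_like(self.w2), 0.0]
        m2 = [np.zeros_like(self.w1), np.zeros_like(self.b1), np.zeros_like(self.w2), 0.0]
        b1c, b2c, eps = 0.9, 0.999, 1e-8
        for t in range(1, epochs + 1):
            # dropout active during training too, matching inference behaviour
            if self.dropout_rate > 0.0:
                mask = (rng.random(self.w1.shape[1]) >= self.dropout_rate).astype(float)
                scale = mask / (1.0 - self.dropout_rate)
            else:
                scale = np.ones(self.w1.shape[1])
            h = np.tanh(x @ self.w1 + self.b1)
            hz = h * scale
            p = expit(hz @ self.w2 + self.b2)
            d_logit = (p - y) / n
            g_w2 = hz.T @ d_logit + weight_decay * self.w2
            g_b2 = d_logit.sum()
            d_h = np.outer(d_logit, self.w2 * scale) * (1.0 - h * h)
            g_w1 = x.T @ d_h + weight_decay * self.w1
            g_b1 = d_h.sum(axis=0)
            grads = [g_w1, g_b1, g_w2, g_b2]
            params = [self.w1, self.b1, self.w2, self.b2]
            new_params = []
            for i, (g, prm) in enumerate(zip(grads, params)):
                m1[i] = b1c * m1[i] + (1 - b1c) * g
                m2[i] = b2c * m2[i] + (1 - b2c) * (g * g if i < 3 else g**2)
                mhat = m1[i] / (1 - b1c**t)
                vhat = m2[i] / (1 - b2c**t)
                new_params.append(prm - lr * mhat / (np.sqrt(vhat) + eps))
            self.w1, self.b1, self.w2 = new_params[0], new_params[1], new_params[2]
            self.b2 = float(new_params[3])


def toy_dropout_predictor(
    phantoms: Sequence[tuple[ScalarVolume, BinaryMask]],
    dropout_rate: float = 0.1,
    seed: int = 0,
    n_hidden: int = 4,
    epochs: int = 400,
    weight_decay: float = 0.03,
    min_train_dice: float = 0.9,
) -> StochasticPredictor:
    """Train a tiny dropout voxel classifier on phantom pairs.

    Returns a predictor satisfying the sampling contract; with
    ``dropout_rate = 0`` every inference pass is identical.  Raises
    :class:`TrainingError` if the fitted model does not reach Dice
    ``min_train_dice`` on its own training phantoms.

    The narrow hidden layer and the weight decay are deliberate: they keep
    output logits moderate instead of saturated, so unit dropout at
    inference produces dispersion on the scale of the dropout-rate
    "uncertainty floor" rather than being absorbed by the sigmoid.
    """
    if len(phantoms) < 2:
        raise ValueError("need at least 2 training phantoms")
    if not (0.0 <= dropout_rate <= 0.9):
        raise ValueError("dropout_rate must be in [0, 0.9]")

    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x7D)))
    feats_list, labels_list = [], []
    for image, truth in phantoms:
        feats = _voxel_features(image)
        labels = truth.values.reshape(-1)
        fg_idx = np.flatnonzero(labels == 1)
        bg_idx = np.flatnonzero(labels == 0)
        # balanced subsample: all foreground plus an equal number of background
        take_bg = rng.choice(bg_idx, size=min(len(bg_idx), 4 * len(fg_idx)), replace=False)
        keep = np.concatenate([fg_idx, take_bg])
        feats_list.append(feats[keep])
        labels_list.append(labels[keep])
    x = np.concatenate(feats_list)
    y = np.concatenate(labels_list)

    model = _DropoutMLP(x.shape[1], n_hidden, dropout_rate, rng)
    model.fit(x, y, rng, epochs=epochs, weight_decay=weight_decay)

    from .seg_metrics import dice as dice_fn

    for image, truth in phantoms:
        p = model.predict(_voxel_features(image), rng=None).reshape(image.grid.shape)
        pred = BinaryMask(grid=image.grid, values=(p >= 0.5).astype(np.uint8))
        d = dice_fn(pred, truth)
        if d < min_train_dice:
            raise TrainingError(
                f"toy classifier reached Dice {d:.3f} < {min_train_dice} on a training phantom"
            )

    def predictor(image: ScalarVolume, member: int, seed: int) -> ScalarVolume:
        feats = _voxel_features(image)
        pass_rng = np.random.default_rng(int(seed)) if dropout_rate > 0.0 else None
        p = model.predict(feats, rng=pass_rng).reshape(image.grid.shape)
        return ScalarVolume(grid=image.grid, values=np.clip(p, 0.0, 1.0), is_probability=True)

    return predictor


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """One cohort arm: size, labels and its phantom/simulator settings."""

    name: str
    n: int
    phantom: PhantomSpec = PhantomSpec()
    simulator: SimulatorSpec = SimulatorSpec()
    age_group: str = "adult"
    sites: tuple[str, ...] = ("site1",)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("each compared group needs n >= 2")
        if self.age_group not in ("adult", "child"):
            raise ValueError("age_group must be 'adult' or 'child'")


@dataclass(frozen=True)
class CohortSpec:
    """A full synthetic study: several groups plus a global seed."""

    groups: tuple[GroupSpec, ...]
    seed: int = 0


#: presets emulating an in-distribution cohort and two progressively shifted
#: ones; "shifted-child" additionally shrinks the structures and the contrast
#: (small ventricles -> partial-volume-dominated, harder target).
COHORT_PRESETS: dict[str, Callable[[], GroupSpec]] = {
    "local-like": lambda: GroupSpec(
        name="local-like",
        n=20,
        phantom=PhantomSpec(),
        simulator=SimulatorSpec(sigma_epistemic=0.3, sigma_aleatoric=0.4),
    ),
    "shifted-adult": lambda: GroupSpec(
        name="shifted-adult",
        n=20,
        phantom=PhantomSpec(),
        simulator=SimulatorSpec(sigma_epistemic=0.9, sigma_aleatoric=0.5),
    ),
    "shifted-child": lambda: GroupSpec(
        name="shifted-child",
        n=20,
        age_group="child",
        phantom=PhantomSpec(contrast_scale=0.6, size_scale=0.8),
        simulator=SimulatorSpec(sigma_epistemic=1.6, sigma_aleatoric=0.6),
    ),
}


@dataclass
class Subject:
    """One synthetic subject ready for sampling."""

    subject_id: str
    image: ScalarVolume
    truth: BinaryMask
    predictor: StochasticPredictor
    diagnosis: str
    cohort: str
    age_group: str
    site: str
    seed: int


def make_cohort(spec: CohortSpec) -> list[Subject]:
    """Instantiate every subject of a cohort spec, deterministically per seed.

    Per-subject seeds are derived injectively from (cohort seed, group
    index, subject index); diagnoses alternate ASD/CON within each group and
    sites cycle through the group's site list.
    """
    subjects: list[Subject] = []
    for gi, group in enumerate(spec.groups):
        for si in range(group.n):
            ss = np.random.SeedSequence((int(spec.seed), gi, si))
            subj_seed = int(ss.generate_state(1, dtype=np.uint32)[0])
            phantom_spec = replace(group.phantom, seed=subj_seed)
            image, truth = generate_phantom(phantom_spec)
            sim_spec = replace(group.simulator, seed=subj_seed)
            predictor = simulate_predictor(truth, sim_spec)
            subjects.append(
                Subject(
                    subject_id=f"{group.name}-{si:03d}",
                    image=image,
                    truth=truth,
                    predictor=predictor,
                    diagnosis="ASD" if si % 2 == 0 else "CON",
                    cohort=group.name,
                    age_group=group.age_group,
                    site=group.sites[si % len(group.sites)],
                    seed=subj_seed,
                )
            )
    return subjects
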