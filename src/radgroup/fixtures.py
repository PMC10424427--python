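"""Seeded synthetic data: block-correlated feature tables and CT phantoms.

Feature tables emulate the statistical structure of real radiomics panels —
strong within-class redundancy, milder cross-class correlation — as Gaussian
features with a compound-symmetric block covariance and labels drawn from a
logistic model whose nonzero weights lie in a single informative group.
Default dimensions mirror the registry (1 MeshVolume + 13 shape + 18
first-order + 73 texture features) at a realistic cohort size of 91 lesions.

Phantoms are voxelized ellipsoids with a nested low-enhancing compartment
and additive Gaussian noise, for exercising the imaging path end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features.extract import FeatureTable
from .features.registry import (
    FIRSTORDER_FEATURES,
    SHAPE_FEATURES,
    TEXTURE_FEATURES,
    FeatureKey,
)
from .imaging import BinaryMask, ImageVolume

__all__ = [
    "TableSpec",
    "PhantomSpec",
    "make_feature_table",
    "make_paired_rater_tables",
    "make_redundant_pair_table",
    "make_phantom",
    "population_auroc",
    "effect_for_population_auroc",
]


@dataclass
class TableSpec:
    """Specification of a synthetic block-correlated feature table."""

    n_samples: int = 91
    n_shape: int = 13  # non-volume shape features; MeshVolume is added on top
    n_firstorder: int = 18
    n_texture: int = 73
    rho_within: float = 0.5
    rho_between: float = 0.2
    informative_group: str = "shape"  # MeshVolume | shape | firstorder | texture
    n_signal: int = 3  # informative features within the group
    effect: float = 1.0  # log-odds per SD on each signal feature
    roi: str = "whole"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_shape, self.n_firstorder, self.n_texture) < 1:
            raise ValueError("per-class feature counts must be >= 1")

    # -- registry ---------------------------------------------------------
    def keys(self) -> list[FeatureKey]:
        names_shape = ("MeshVolume",) + SHAPE_FEATURES[1 : self.n_shape + 1]
        names_fo = _take(FIRSTORDER_FEATURES, self.n_firstorder, "fo")
        names_tx = _take(TEXTURE_FEATURES, self.n_texture, "tx")
        keys = [FeatureKey(self.roi, "shape", n) for n in names_shape]
        keys += [FeatureKey(self.roi, "firstorder", n) for n in names_fo]
        keys += [FeatureKey(self.roi, "texture", n) for n in names_tx]
        return keys

    def class_of_column(self) -> np.ndarray:
        return np.array([k.feature_class for k in self.keys()])

    @property
    def n_features(self) -> int:
        return 1 + self.n_shape + self.n_firstorder + self.n_texture

    def correlation(self) -> np.ndarray:
        """The block correlation matrix implied by the spec (must be PSD)."""
        classes = self.class_of_column()
        same = classes[:, None] == classes[None, :]
        corr = np.where(same, self.rho_within, self.rho_between)
        np.fill_diagonal(corr, 1.0)
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("correlation block structure is not positive semi-definite")
        return corr

    def signal_columns(self) -> np.ndarray:
        keys = self.keys()
        if self.informative_group == "MeshVolume":
            return np.array([i for i, k in enumerate(keys) if k.is_mesh_volume])
        if self.informative_group == "all":
            # one informative feature per class plus MeshVolume
            cols = [next(i for i, k in enumerate(keys) if k.is_mesh_volume)]
            for c in ("shape", "firstorder", "texture"):
                cols.append(
                    next(
                        i for i, k in enumerate(keys)
                        if k.feature_class == c and not k.is_mesh_volume
                    )
                )
            return np.array(cols)
        cols = np.array(
            [i for i, k in enumerate(keys) if k.feature_class == self.informative_group]
        )
        if cols.size == 0:
            raise ValueError(f"unknown informative group: {self.informative_group}")
        return cols[: self.n_signal]


def _take(names: tuple[str, ...], n: int, prefix: str) -> list[str]:
    out = list(names[:n])
    out += [f"{prefix}_extra{i}" for i in range(n - len(out))]
    return out


def _sample_features(spec: TableSpec, rng: np.random.Generator) -> np.ndarray:
    corr = spec.correlation()
    # eigendecomposition (cholesky can fail on the PSD boundary)
    w, v = np.linalg.eigh(corr)
    root = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
    z = rng.standard_normal((spec.n_samples, spec.n_features))
    return z @ root.T


def _linear_predictor(spec: TableSpec, x: np.ndarray) -> np.ndarray:
    eta = np.zeros(x.shape[0])
    for c in spec.signal_columns():
        eta += spec.effect * x[:, c]
    return eta


def make_feature_table(spec: TableSpec) -> tuple[FeatureTable, np.ndarray]:
    """Gaussian block-correlated features and logistic-model labels."""
    rng = np.random.default_rng(spec.seed)
    x = _sample_features(spec, rng)
    eta = _linear_predictor(spec, x)
    y = (rng.random(spec.n_samples) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    table = _to_table(spec, x)
    return table, y


def _to_table(spec: TableSpec, x: np.ndarray) -> FeatureTable:
    import pandas as pd

    keys = spec.keys()
    df = pd.DataFrame(
        x,
        index=[f"lesion{i:04d}" for i in range(spec.n_samples)],
        columns=pd.MultiIndex.from_tuples(
            [(k.roi, k.feature_class, k.feature_name) for k in keys],
            names=["roi", "feature_class", "feature_name"],
        ),
    )
    return FeatureTable(df, {"synthetic": True, "seed": spec.seed})


def make_paired_rater_tables(
    spec: TableSpec, noise_sd: float | np.ndarray = 0.0
) -> tuple[FeatureTable, FeatureTable]:
    """Two 'rater' tables: the second adds independent per-feature noise.

    ``noise_sd`` is a scalar or per-feature array; features with noise large
    relative to unit signal variance have low ICC by construction
    (ICC = 1 / (1 + sd²/2) under this additive model with a half-shared
    perturbation), so they fall to the reproducibility filter.
    """
    rng = np.random.default_rng(spec.seed)
    x = _sample_features(spec, rng)
    sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), (spec.n_features,))
    e1 = rng.standard_normal(x.shape) * sd / np.sqrt(2)
    e2 = rng.standard_normal(x.shape) * sd / np.sqrt(2)
    return _to_table(spec, x + e1), _to_table(spec, x + e2)


def make_redundant_pair_table(
    n_samples: int = 500, seed: int = 0, redundancy: float = 0.979
) -> tuple[FeatureTable, FeatureKey, FeatureKey]:
    """The redundant-pair preset: MeshVolume vs a size-zone texture feature.

    The texture feature glszm_GrayLevelNonUniformity is regenerated as
    ``redundancy·MeshVolume + noise`` so the pair is the most correlated in
    the table, while MeshVolume keeps the higher mean absolute correlation
    with everything else (its correlations with the rest of the table exceed
    the inherited ``redundancy``-scaled copies) — the configuration where
    standard CFR discards the volume feature but hierarchical CFR retains
    it.  The sample size and within-class correlation are large enough that
    this structural margin dominates sampling noise.
    """
    spec = TableSpec(n_samples=n_samples, rho_within=0.6, seed=seed, effect=0.0)
    rng = np.random.default_rng(spec.seed)
    x = _sample_features(spec, rng)
    keys = spec.keys()
    mv = next(i for i, k in enumerate(keys) if k.is_mesh_volume)
    glnu = next(
        i for i, k in enumerate(keys) if k.feature_name == "glszm_GrayLevelNonUniformity"
    )
    eps = rng.standard_normal(n_samples)
    x[:, glnu] = redundancy * x[:, mv] + np.sqrt(1 - redundancy**2) * eps
    return _to_table(spec, x), keys[mv], keys[glnu]


# ---------------------------------------------------------------------------
# Population AUROC of the logistic link


def population_auroc(spec: TableSpec) -> float:
    """Population AUROC implied by the spec's logistic label model.

    The linear predictor is Gaussian with variance w'Σw; the AUROC is
    P(η⁺ > η⁻) for η⁺ ~ σ(η)φ(η/s)/Z and η⁻ ~ (1-σ(η))φ(η/s)/(1-Z),
    evaluated by quadrature.
    """
    corr = spec.correlation()
    w = np.zeros(spec.n_features)
    w[spec.signal_columns()] = spec.effect
    s = float(np.sqrt(w @ corr @ w))
    return _auroc_of_eta_sd(s)


def _auroc_of_eta_sd(s: float) -> float:
    if s == 0:
        return 0.5
    from scipy.special import expit

    grid = np.linspace(-10 * s, 10 * s, 4001)
    phi = np.exp(-0.5 * (grid / s) ** 2)
    sig = expit(grid)
    p_pos = sig * phi
    p_neg = (1 - sig) * phi
    p_pos /= np.trapezoid(p_pos, grid)
    p_neg /= np.trapezoid(p_neg, grid)
    cdf_neg = np.concatenate(([0.0], np.cumsum((p_neg[1:] + p_neg[:-1]) / 2 * np.diff(grid))))
    cdf_neg /= cdf_neg[-1]
    return float(np.trapezoid(p_pos * cdf_neg, grid))


def effect_for_population_auroc(target_auroc: float, spec: TableSpec) -> float:
    """Solve for the per-feature effect giving the requested population AUROC."""
    if not 0.5 < target_auroc < 1.0:
        raise ValueError("target AUROC must be in (0.5, 1)")
    from scipy.optimize import brentq

    def f(effect):
        trial = TableSpec(**{**spec.__dict__, "effect": float(effect)})
        return population_auroc(trial) - target_auroc

    return float(brentq(f, 1e-4, 50.0, xtol=1e-5))


# ---------------------------------------------------------------------------
# CT phantoms


@dataclass
class PhantomSpec:
    """A voxelized two-compartment ellipsoid tumour on a CT-like grid."""

    grid_shape: tuple[int, int, int] = (48, 48, 16)
    spacing: tuple[float, float, float] = (1.0, 1.0, 5.0)
    semi_axes_mm: tuple[float, float, float] = (18.0, 15.0, 25.0)
    center_mm: tuple[float, float, float] | None = None  # grid centre if None
    hu_high: float = 140.0
    hu_low: float = 40.0
    hu_background: float = -50.0
    # low-enhancing compartment: ellipsoid scaled/offset inside the tumour
    compartment_scale: float = 0.55
    compartment_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd_hu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be > 0")
        if not 0 < self.compartment_scale < 1:
            raise ValueError("compartment_scale must be in (0, 1)")


def _ellipsoid_mask(
    shape, spacing, center_mm, semi_axes_mm
) -> np.ndarray:
    ax = [np.arange(n) * s for n, s in zip(shape, spacing)]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    q = (
        ((xx - center_mm[0]) / semi_axes_mm[0]) ** 2
        + ((yy - center_mm[1]) / semi_axes_mm[1]) ** 2
        + ((zz - center_mm[2]) / semi_axes_mm[2]) ** 2
    )
    return q <= 1.0


def make_phantom(spec: PhantomSpec) -> tuple[ImageVolume, BinaryMask]:
    """Voxelized ellipsoid tumour with a nested low-enhancing compartment."""
    shape, spacing = spec.grid_shape, spec.spacing
    center = spec.center_mm or tuple(
        (n - 1) * s / 2 for n, s in zip(shape, spacing)
    )
    tumour = _ellipsoid_mask(shape, spacing, center, spec.semi_axes_mm)
    comp_center = tuple(c + o for c, o in zip(center, spec.compartment_offset_mm))
    comp_axes = tuple(a * spec.compartment_scale for a in spec.semi_axes_mm)
    comp = _ellipsoid_mask(shape, spacing, comp_center, comp_axes)
    if (comp & ~tumour).any():
        raise ValueError("compartment extends outside the tumour ellipsoid")
    image = np.full(shape, spec.hu_background, dtype=float)
    image[tumour] = spec.hu_high
    image[comp] = spec.hu_low
    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        image += rng.normal(0.0, spec.noise_sd_hu, size=shape)
    return (
        ImageVolume(image, spacing),
        BinaryMask(tumour, spacing),
    )
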