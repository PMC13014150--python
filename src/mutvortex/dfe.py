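"""Distributions of fitness effects (DFEs) for new mutations.

Two families are used throughout the package:

* a gamma distribution of *deleterious* selection coefficients, specified
  by ``shape`` (:math:`\\alpha`) and ``scale`` (:math:`\\beta`) on the
  magnitude scale, with support :math:`s < 0` at the interface — all
  downstream code receives signed coefficients;
* an exponential distribution of *beneficial* coefficients with mean
  :math:`\\bar{s}_b > 0`.

The default deleterious parameters are the widely used human
non-synonymous estimates, published on the population-scaled
:math:`2 N_e s` axis (shape 0.169, scale 1327.4, :math:`2N_e = 23{,}646`)
and divided by :math:`2N_e` to obtain the per-copy scale
(:math:`\\beta \\approx 0.056`, mean :math:`\\bar{s}_d \\approx -0.00946`).

Coefficients with :math:`s \\le -1` ("worse than lethal") are retained:
they behave exactly like lethals downstream and truncating them would
distort the density.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import expon, gamma as _gamma

from .exceptions import InvalidParameterError

__all__ = [
    "GammaDeleteriousDFE",
    "PopulationScaledGammaDFE",
    "ExponentialBeneficialDFE",
    "rescale",
    "moments",
    "with_mean",
    "with_cv",
    "sample",
    "dfe_from_config",
    "dfe_to_config",
    "PRESETS",
]


def _require_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise InvalidParameterError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class GammaDeleteriousDFE:
    """Gamma DFE of deleterious selection coefficients, support s < 0.

    ``shape`` and ``scale`` parameterise the distribution of |s|; signed
    coefficients are produced by :meth:`sample` and accepted by
    :meth:`pdf`.  mean = -shape*scale, cv = 1/sqrt(shape).
    """

    shape: float
    scale: float

    def __post_init__(self):
        _require_positive("shape", self.shape)
        _require_positive("scale", self.scale)

    @property
    def mean(self) -> float:
        return -self.shape * self.scale

    @property
    def cv(self) -> float:
        return 1.0 / np.sqrt(self.shape)

    def pdf(self, s):
        """Density at signed s (zero for s >= 0)."""
        s = np.asarray(s, dtype=float)
        out = np.where(s < 0, _gamma.pdf(-s, a=self.shape, scale=self.scale), 0.0)
        return out if out.ndim else float(out)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n signed draws (all negative)."""
        if n < 0:
            raise InvalidParameterError(f"n must be >= 0, got {n}")
        return -rng.gamma(self.shape, self.scale, size=n)


@dataclass(frozen=True)
class PopulationScaledGammaDFE:
    """Gamma DFE published on the population-scaled 2*Ne*s axis."""

    shape: float
    scale: float
    two_ne: float

    def __post_init__(self):
        _require_positive("shape", self.shape)
        _require_positive("scale", self.scale)
        _require_positive("two_ne", self.two_ne)

    def rescale(self) -> GammaDeleteriousDFE:
        """Divide the scale by 2*Ne to obtain the per-copy DFE."""
        return GammaDeleteriousDFE(shape=self.shape, scale=self.scale / self.two_ne)


@dataclass(frozen=True)
class ExponentialBeneficialDFE:
    """Exponential DFE of beneficial selection coefficients, support s > 0."""

    mean: float

    def __post_init__(self):
        _require_positive("mean", self.mean)

    @property
    def cv(self) -> float:
        return 1.0

    def pdf(self, s):
        s = np.asarray(s, dtype=float)
        out = np.where(s > 0, expon.pdf(s, scale=self.mean), 0.0)
        return out if out.ndim else float(out)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 0:
            raise InvalidParameterError(f"n must be >= 0, got {n}")
        return rng.exponential(self.mean, size=n)


def rescale(popscaled: PopulationScaledGammaDFE) -> GammaDeleteriousDFE:
    """Convert a population-scaled gamma DFE to the per-copy s scale."""
    return popscaled.rescale()


def moments(dfe) -> tuple[float, float]:
    """(mean, coefficient of variation) of a DFE."""
    return float(dfe.mean), float(dfe.cv)


def with_mean(dfe: GammaDeleteriousDFE, new_mean: float) -> GammaDeleteriousDFE:
    """Adjust the scale so the mean becomes ``new_mean``; shape is kept.

    This is the knob used to vary mean deleterious effect size while
    preserving the distribution's coefficient of variation.
    """
    if not np.isfinite(new_mean) or new_mean >= 0:
        raise InvalidParameterError(f"new_mean must be negative, got {new_mean!r}")
    return replace(dfe, scale=abs(new_mean) / dfe.shape)


def with_cv(dfe: GammaDeleteriousDFE, new_cv: float) -> GammaDeleteriousDFE:
    """Adjust shape and scale together to reach ``new_cv`` at fixed mean.

    The mean is preserved exactly: the scale is chosen so that
    shape * scale reproduces the old |mean| bit-for-bit (nudging by one
    ulp when the rounded quotient misses).
    """
    if not np.isfinite(new_cv) or new_cv <= 0:
        raise InvalidParameterError(f"new_cv must be positive, got {new_cv!r}")
    target = abs(dfe.mean)
    shape = 1.0 / new_cv**2
    # With shape pinned by the cv, shape * round(target/shape) can miss the
    # target by an ulp, and for shape > 1 no representable scale may hit it
    # at all.  Walking shape over a few hundred ulps (a relative change
    # ~1e-13, far inside the cv tolerance) always yields an exact pair.
    lo_s, hi_s = float(np.nextafter(shape, 0.0)), float(np.nextafter(shape, np.inf))
    candidates = [shape]
    for _ in range(500):
        candidates.extend((hi_s, lo_s))
        lo_s = float(np.nextafter(lo_s, 0.0))
        hi_s = float(np.nextafter(hi_s, np.inf))
    for sh in candidates:
        sc = target / sh
        for sc2 in (sc, float(np.nextafter(sc, 0.0)), float(np.nextafter(sc, np.inf))):
            if sh * sc2 == target:
                return GammaDeleteriousDFE(shape=sh, scale=sc2)
    return GammaDeleteriousDFE(shape=shape, scale=target / shape)


def sample(dfe, n: int, rng: np.random.Generator) -> np.ndarray:
    """n signed selection-coefficient draws from any DFE."""
    return dfe.sample(n, rng)


#: Human non-synonymous gamma DFE on the population-scaled axis.
PRESETS: dict[str, PopulationScaledGammaDFE] = {
    "human_nonsynonymous": PopulationScaledGammaDFE(shape=0.169, scale=1327.4, two_ne=23646.0),
}


def dfe_from_config(cfg: dict):
    """Build a DFE from a key-value mapping.

    Recognised families: ``gamma_deleterious`` (keys shape, scale or mean),
    ``population_scaled_gamma`` (shape, scale, two_ne), ``exponential_beneficial``
    (mean), and ``preset`` (name, returns the rescaled per-copy DFE).
    """
    family = cfg.get("family")
    if family == "preset":
        name = cfg["name"]
        if name not in PRESETS:
            raise InvalidParameterError(f"unknown DFE preset {name!r}")
        return PRESETS[name].rescale()
    if family == "gamma_deleterious":
        if "scale" in cfg:
            return GammaDeleteriousDFE(shape=float(cfg["shape"]), scale=float(cfg["scale"]))
        return with_mean(
            GammaDeleteriousDFE(shape=float(cfg["shape"]), scale=1.0), float(cfg["mean"])
        )
    if family == "population_scaled_gamma":
        return PopulationScaledGammaDFE(
            shape=float(cfg["shape"]), scale=float(cfg["scale"]), two_ne=float(cfg["two_ne"])
        )
    if family == "exponential_beneficial":
        return ExponentialBeneficialDFE(mean=float(cfg["mean"]))
    raise InvalidParameterError(f"unknown DFE family {family!r}")


def dfe_to_config(dfe) -> dict:
    """Inverse of :func:`dfe_from_config` (always explicit, never a preset)."""
    if isinstance(dfe, GammaDeleteriousDFE):
        return {"family": "gamma_deleterious", "shape": dfe.shape, "scale": dfe.scale}
    if isinstance(dfe, PopulationScaledGammaDFE):
        return {
            "family": "population_scaled_gamma",
            "shape": dfe.shape,
            "scale": dfe.scale,
            "two_ne": dfe.two_ne,
        }
    if isinstance(dfe, ExponentialBeneficialDFE):
        return {"family": "exponential_beneficial", "mean": dfe.mean}
    raise InvalidParameterError(f"not a DFE: {dfe!r}")
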