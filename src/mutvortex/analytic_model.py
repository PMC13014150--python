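"""Linkage-equilibrium fitness-flux model of the genetic extinction vortex.

The model tracks the expected per-generation change in log mean fitness
("fitness flux") caused by fixations of new mutations in a diploid Moran
population of size N.  Deleterious mutations arise at genome-wide rate Ud
per diploid per generation with gamma-distributed effects, beneficial
mutations at rate Ub with exponential effects.  A mutation of co-dominant
effect s fixes with the exact Moran birth-death probability

    pfix(s) = (1 - e^{-s}) / (1 - e^{-2 N s})

and, once fixed, changes log mean fitness by 2s.  The fluxes are

    vd = Ud * N * int_{-inf}^{0} p_d(s) 2s pfix(s) ds      (<= 0)
    vb = Ub * N * int_{0}^{+inf} p_b(s) 2s pfix(s) ds      (>= 0)

and a constant environmental deterioration delta_env <= 0 may be added:
vnet = vd + vb + delta_env.  The critical population size Ncrit is the N
at which vnet = 0 — an unstable equilibrium: below it, net fitness loss
shrinks the population further (the extinction vortex).  The relative
importance of the two vortex mechanisms near the tipping point is the
"drought : meltdown ratio" (dvb/dN) / (dvd/dN) evaluated at Ncrit; both
derivatives are positive there, and a ratio above 1 means the shortage of
beneficial mutations (mutational drought) dominates the fixation of
deleterious ones (mutational meltdown).

The main surface is :class:`VortexModel` / :class:`VortexResults`;
module-level functions expose each step individually.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import integrate, optimize
from scipy.stats import gamma as _gamma

from .dfe import (
    ExponentialBeneficialDFE,
    GammaDeleteriousDFE,
    PRESETS,
    with_cv,
    with_mean,
)
from .exceptions import InvalidParameterError, NoRootError, NumericalError

__all__ = [
    "ModelParams",
    "FluxResult",
    "RatioResult",
    "EnvThresholdResult",
    "pfix",
    "deleterious_flux",
    "beneficial_flux",
    "net_flux",
    "find_ncrit",
    "flux_derivative",
    "drought_meltdown_ratio",
    "whitlock_ncrit",
    "env_rate",
    "env_threshold_analysis",
    "sweep",
    "VortexModel",
    "VortexResults",
]

# Integration breakpoints on the |s| half-line.  The gamma density has an
# integrable singularity at 0 for shape < 1; a single adaptive call over
# (0, inf) is unreliable there, so the integral is split.
_BREAKPOINTS = (0.0, 1e-6, 1e-4, 1e-2, 1.0, np.inf)
_QUAD_EPSREL = 1e-10


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class ModelParams:
    """Complete input of the linkage-equilibrium model.

    ud, ub: deleterious/beneficial mutation rates per diploid genome per
    generation; delta_env: constant environmental fitness change per
    generation (<= 0, 0 for a static environment).
    """

    ud: float
    ub: float
    deleterious_dfe: GammaDeleteriousDFE
    beneficial_dfe: ExponentialBeneficialDFE
    delta_env: float = 0.0

    def __post_init__(self):
        if self.ud < 0 or self.ub < 0:
            raise InvalidParameterError("mutation rates must be non-negative")
        if self.delta_env > 0:
            raise InvalidParameterError("delta_env must be <= 0 (environmental deterioration)")

    @classmethod
    def default(
        cls,
        ud: float = 2.0,
        ud_over_ub: float = 1000.0,
        sb_mean: float = 0.001,
        delta_env: float = 0.0,
        deleterious_dfe: GammaDeleteriousDFE | None = None,
    ) -> "ModelParams":
        """The package's reference parameterisation.

        Ud = 2 (a conservative human-like genome-wide deleterious rate),
        Ud/Ub = 1000, exponential beneficial effects with mean 0.001, and
        the human non-synonymous gamma DFE rescaled to the per-copy axis.
        """
        if deleterious_dfe is None:
            deleterious_dfe = PRESETS["human_nonsynonymous"].rescale()
        return cls(
            ud=ud,
            ub=ud / ud_over_ub,
            deleterious_dfe=deleterious_dfe,
            beneficial_dfe=ExponentialBeneficialDFE(mean=sb_mean),
            delta_env=delta_env,
        )


@dataclass(frozen=True)
class FluxResult:
    """Fitness fluxes evaluated at one population size."""

    N: float
    vd: float
    vb: float
    delta_env: float

    @property
    def vnet(self) -> float:
        return self.vd + self.vb + self.delta_env


@dataclass(frozen=True)
class RatioResult:
    """Flux derivatives and their ratio at the critical population size."""

    ncrit: float
    dvb_dN: float
    dvd_dN: float

    @property
    def ratio(self) -> float:
        return self.dvb_dN / self.dvd_dN


@dataclass(frozen=True)
class EnvThresholdResult:
    """Environmental rate at which drought and meltdown balance.

    ``delta_env_exact`` is the root of ratio(delta_env) = 1;
    ``delta_env_grid`` is the threshold resolved on a log-spaced grid of
    environmental rates (the coarser reading used for reporting: the first
    grid point at which the ratio exceeds 1).  ``flux_ratio_*`` are
    |delta_env| / |vd(Ncrit(delta_env))| at the respective thresholds: the
    speed of environmental decline relative to mutational degradation.
    """

    delta_env_exact: float
    flux_ratio_exact: float
    ncrit_exact: float
    delta_env_grid: float
    flux_ratio_grid: float
    ncrit_grid: float

    @property
    def generations_per_10pct_exact(self) -> float:
        return -0.1 / self.delta_env_exact

    @property
    def generations_per_10pct_grid(self) -> float:
        return -0.1 / self.delta_env_grid


# ---------------------------------------------------------------------------
# fixation probability


def _pfix_scalar(s: float, N: float) -> float:
    # exact Moran birth-death fixation probability, overflow-safe
    if s == 0.0 or abs(s) < 1e-14:
        return 1.0 / (2.0 * N)
    if s < -36.0:  # both expm1 terms overflow; use the exponent difference
        return math.exp((2.0 * N - 1.0) * s)
    num = -math.expm1(-s)
    arg = -2.0 * N * s
    if arg > 700.0:
        return num * math.exp(-arg)
    return num / (-math.expm1(arg))


def pfix(s, N: float):
    """Exact fixation probability of a new co-dominant mutation, Moran model.

    (1 - e^{-s}) / (1 - e^{-2Ns}); the s -> 0 limit 1/(2N) is taken
    explicitly and asymptotic branches avoid overflow for large |s| or N.
    Accepts scalars or arrays of s.
    """
    if N < 1:
        raise InvalidParameterError(f"N must be >= 1, got {N}")
    if np.ndim(s) == 0:
        return _pfix_scalar(float(s), float(N))
    arr = np.asarray(s, dtype=float)
    out = np.empty_like(arr)
    tiny = np.abs(arr) < 1e-14
    very_neg = arr < -36.0
    big_arg = (~very_neg) & (-2.0 * N * arr > 700.0)
    rest = ~(tiny | very_neg | big_arg)
    out[tiny] = 1.0 / (2.0 * N)
    out[very_neg] = np.exp((2.0 * N - 1.0) * arr[very_neg])
    sb = arr[big_arg]
    out[big_arg] = -np.expm1(-sb) * np.exp(2.0 * N * sb)
    sr = arr[rest]
    out[rest] = np.expm1(-sr) / np.expm1(-2.0 * N * sr)
    return out


def _d_npfix_dN_scalar(s: float, N: float) -> float:
    # d/dN [ N * pfix(s, N) ] = pfix * (1 - 2Ns / (e^{2Ns} - 1))
    if s == 0.0 or abs(s) < 1e-14:
        return 0.0
    y = 2.0 * N * s
    if y > 700.0:
        g = 1.0
    elif y < -700.0:
        g = 1.0 + y
    else:
        g = 1.0 - y / math.expm1(y)
    return _pfix_scalar(s, N) * g


# ---------------------------------------------------------------------------
# flux integrals


def _integrate_pieces(f, breakpoints=_BREAKPOINTS) -> float:
    total = 0.0
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        out = integrate.quad(f, a, b, epsabs=0.0, epsrel=_QUAD_EPSREL, limit=200, full_output=1)
        if len(out) > 3:  # quad appends an explanation on trouble
            raise NumericalError(f"quadrature failed on ({a}, {b}): {out[3]}")
        total += out[0]
    return total


def deleterious_flux(params: ModelParams, N: float) -> float:
    """vd(N) = Ud * N * int p_d(s) 2s pfix(s, N) ds over s < 0 (<= 0)."""
    if N < 1:
        raise InvalidParameterError(f"N must be >= 1, got {N}")
    if params.ud == 0:
        return 0.0
    a, scale = params.deleterious_dfe.shape, params.deleterious_dfe.scale

    def integrand(x):  # x = |s|
        return _gamma.pdf(x, a=a, scale=scale) * (-2.0 * x) * _pfix_scalar(-x, N)

    return params.ud * N * _integrate_pieces(integrand)


def beneficial_flux(params: ModelParams, N: float) -> float:
    """vb(N) = Ub * N * int p_b(s) 2s pfix(s, N) ds over s > 0 (>= 0)."""
    if N < 1:
        raise InvalidParameterError(f"N must be >= 1, got {N}")
    if params.ub == 0:
        return 0.0
    sb = params.beneficial_dfe.mean

    def integrand(x):
        return math.exp(-x / sb) / sb * 2.0 * x * _pfix_scalar(x, N)

    return params.ub * N * _integrate_pieces(integrand)


def net_flux(params: ModelParams, N: float) -> FluxResult:
    """Both fluxes plus the environmental term at one population size."""
    return FluxResult(
        N=float(N),
        vd=deleterious_flux(params, N),
        vb=beneficial_flux(params, N),
        delta_env=params.delta_env,
    )


# ---------------------------------------------------------------------------
# critical population size


def find_ncrit(
    params: ModelParams,
    bracket: tuple[float, float] = (500.0, 1e5),
    expand_limits: tuple[float, float] = (10.0, 1e8),
) -> float:
    """Root of vnet(N) = 0, treating N as a continuous positive real.

    The initial bracket is expanded outward by factors of two until the
    endpoint fluxes change sign; if no sign change exists within
    ``expand_limits`` a :class:`NoRootError` is raised carrying the
    endpoint values (as happens when Ub = 0 and vnet < 0 everywhere).
    """

    def f(N):
        return deleterious_flux(params, N) + beneficial_flux(params, N) + params.delta_env

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    while flo * fhi > 0:
        grew = False
        if lo > expand_limits[0]:
            lo = max(lo / 2.0, expand_limits[0])
            flo = f(lo)
            grew = True
        if flo * fhi > 0 and hi < expand_limits[1]:
            hi = min(hi * 2.0, expand_limits[1])
            fhi = f(hi)
            grew = True
        if not grew:
            raise NoRootError(
                "vnet does not change sign on "
                f"[{expand_limits[0]:g}, {expand_limits[1]:g}]",
                endpoints=((lo, flo), (hi, fhi)),
            )
    root = optimize.brentq(f, lo, hi, xtol=1e-7, rtol=4 * np.finfo(float).eps)
    return float(root)


def flux_derivative(
    params: ModelParams, N: float, which: Literal["deleterious", "beneficial"]
) -> float:
    """dv/dN by differentiation under the integral sign.

    d/dN [N pfix(s,N)] = pfix * (1 - 2Ns/(e^{2Ns}-1)), so the derivative
    is the same DFE integral with this kernel.  delta_env is constant in N
    and contributes nothing.
    """
    if N < 2:
        raise InvalidParameterError(f"N must be >= 2, got {N}")
    if which == "deleterious":
        if params.ud == 0:
            return 0.0
        a, scale = params.deleterious_dfe.shape, params.deleterious_dfe.scale

        def integrand(x):
            return _gamma.pdf(x, a=a, scale=scale) * (-2.0 * x) * _d_npfix_dN_scalar(-x, N)

        return params.ud * _integrate_pieces(integrand)
    if which == "beneficial":
        if params.ub == 0:
            return 0.0
        sb = params.beneficial_dfe.mean

        def integrand(x):
            return math.exp(-x / sb) / sb * 2.0 * x * _d_npfix_dN_scalar(x, N)

        return params.ub * _integrate_pieces(integrand)
    raise InvalidParameterError(f"which must be 'deleterious' or 'beneficial', got {which!r}")


def drought_meltdown_ratio(params: ModelParams) -> RatioResult:
    """Flux derivatives at Ncrit and their ratio (dvb/dN) / (dvd/dN).

    Both derivatives are positive near the tipping point: raising N speeds
    adaptation (vb grows) and slows deleterious fixation (vd rises toward
    zero).  A ratio below 1 means mutational meltdown reacts more strongly
    to population-size change than mutational drought does.
    """
    ncrit = find_ncrit(params)
    return RatioResult(
        ncrit=ncrit,
        dvb_dN=flux_derivative(params, ncrit, "beneficial"),
        dvd_dN=flux_derivative(params, ncrit, "deleterious"),
    )


def whitlock_ncrit(params: ModelParams) -> float:
    """Closed-form Ncrit approximation (exponential-DFE theory, Moran-scaled).

    2 * (Ud / (64 * sb_mean^2 * |sd_mean| * Ub))^(1/3).  Underestimates the
    quadrature Ncrit when the deleterious DFE is overdispersed relative to
    an exponential.
    """
    sd = abs(params.deleterious_dfe.mean)
    sb = params.beneficial_dfe.mean
    denom = 64.0 * sb**2 * sd * params.ub
    if denom <= 0 or params.ud <= 0:
        raise InvalidParameterError("whitlock_ncrit requires positive rates and mean effects")
    return 2.0 * (params.ud / denom) ** (1.0 / 3.0)


def env_rate(generations_per_10pct_decline: float) -> float:
    """delta_env for a 10% fitness decline over the given number of generations."""
    if not generations_per_10pct_decline > 0:
        raise InvalidParameterError("generations_per_10pct_decline must be positive")
    return -0.1 / generations_per_10pct_decline


def env_threshold_analysis(
    params: ModelParams,
    grid_log10: tuple[float, float, float] = (-6.0, -3.5, 0.1),
) -> EnvThresholdResult:
    """Find the environmental rate at which drought and meltdown balance.

    Scans delta_env = -10^k over the log grid ``grid_log10`` (start, stop,
    step in decades) for the first point where the drought:meltdown ratio
    reaches 1, then refines the exact crossing by root finding between the
    bracketing grid points.  Reports, at both the grid threshold and the
    exact root, the ratio |delta_env| / |vd(Ncrit)| — how fast the
    environment degrades fitness relative to deleterious fixations.  Both
    reported flux ratios are below 1 for the default parameters: the
    threshold environmental change is "slow".
    """
    base = replace(params, delta_env=0.0)

    def ratio_at(delta: float) -> tuple[float, float]:
        p = replace(base, delta_env=delta)
        r = drought_meltdown_ratio(p)
        return r.ratio, r.ncrit

    lo, hi, step = grid_log10
    ks = np.arange(lo, hi + 0.5 * step, step)
    # scan from the slowest environmental change (delta closest to 0) outward
    deltas = np.sort(-np.power(10.0, ks))[::-1]

    prev_delta = None
    prev_ratio = None
    grid_delta = None
    grid_ncrit = None
    for d in deltas:
        ratio, ncrit = ratio_at(float(d))
        if ratio >= 1.0:
            grid_delta, grid_ncrit = float(d), ncrit
            break
        prev_delta, prev_ratio = float(d), ratio
    if grid_delta is None:
        raise NoRootError(
            "drought:meltdown ratio stays below 1 over the delta_env grid "
            f"(last ratio {prev_ratio:.4f} at delta_env={prev_delta:g})"
        )
    if prev_delta is None:
        raise NoRootError(
            "drought:meltdown ratio is already above 1 at the slowest grid rate "
            f"delta_env={grid_delta:g}"
        )

    exact = optimize.brentq(
        lambda d: ratio_at(d)[0] - 1.0, grid_delta, prev_delta, xtol=1e-12
    )
    _, ncrit_exact = ratio_at(exact)

    def flux_ratio(delta, ncrit):
        vd = deleterious_flux(base, ncrit)
        return abs(delta) / abs(vd)

    return EnvThresholdResult(
        delta_env_exact=float(exact),
        flux_ratio_exact=flux_ratio(exact, ncrit_exact),
        ncrit_exact=float(ncrit_exact),
        delta_env_grid=grid_delta,
        flux_ratio_grid=flux_ratio(grid_delta, grid_ncrit),
        ncrit_grid=float(grid_ncrit),
    )


# ---------------------------------------------------------------------------
# parameter sweeps


def sweep(
    ud: Iterable[float] = (2.0,),
    ud_over_ub: Iterable[float] = (1000.0,),
    sb_mean: Iterable[float] = (0.001,),
    sd_mean: Iterable[float | None] = (None,),
    cv: Iterable[float | None] = (None,),
    delta_env: Iterable[float] = (0.0,),
) -> pd.DataFrame:
    """Cartesian sweep of Ncrit and the drought:meltdown ratio.

    ``sd_mean``/``cv`` of None keep the preset deleterious DFE; otherwise
    the gamma scale (and, for cv, shape) is adjusted.  Rows where no root
    exists are kept with ``status='no_root'`` and NaN results rather than
    dropped.
    """
    base_dfe = PRESETS["human_nonsynonymous"].rescale()
    rows = []
    for u in ud:
        for ratio_ub in ud_over_ub:
            for sb in sb_mean:
                for sd in sd_mean:
                    for c in cv:
                        for denv in delta_env:
                            dfe = base_dfe
                            if sd is not None:
                                dfe = with_mean(dfe, sd)
                            if c is not None:
                                dfe = with_cv(dfe, c)
                            params = ModelParams(
                                ud=u,
                                ub=u / ratio_ub,
                                deleterious_dfe=dfe,
                                beneficial_dfe=ExponentialBeneficialDFE(mean=sb),
                                delta_env=denv,
                            )
                            row = {
                                "ud": u,
                                "ub": u / ratio_ub,
                                "sb_mean": sb,
                                "sd_mean": dfe.mean,
                                "cv": dfe.cv,
                                "delta_env": denv,
                            }
                            try:
                                res = drought_meltdown_ratio(params)
                                fx = net_flux(params, res.ncrit)
                                row.update(
                                    ncrit=res.ncrit,
                                    ratio=res.ratio,
                                    dvb_dN=res.dvb_dN,
                                    dvd_dN=res.dvd_dN,
                                    vd=fx.vd,
                                    vb=fx.vb,
                                    status="ok",
                                )
                            except NoRootError as exc:
                                row.update(
                                    ncrit=np.nan,
                                    ratio=np.nan,
                                    dvb_dN=np.nan,
                                    dvd_dN=np.nan,
                                    vd=np.nan,
                                    vb=np.nan,
                                    status=f"no_root: {exc}",
                                )
                            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model-object surface


class VortexModel:
    """Extinction-vortex tipping-point model for one parameter set.

    Statsmodels-style: construct from :class:`ModelParams` (or the
    ``from_preset`` defaults), then :meth:`fit` solves for the critical
    population size and the flux derivatives and returns a
    :class:`VortexResults`.
    """

    def __init__(self, params: ModelParams):
        self.params = params

    @classmethod
    def from_preset(cls, **kwargs) -> "VortexModel":
        """Model with the reference parameterisation (see ModelParams.default)."""
        return cls(ModelParams.default(**kwargs))

    def flux(self, N: float) -> FluxResult:
        return net_flux(self.params, N)

    def fit(self) -> "VortexResults":
        ratio = drought_meltdown_ratio(self.params)
        fluxes = net_flux(self.params, ratio.ncrit)
        try:
            closed_form = whitlock_ncrit(self.params)
        except InvalidParameterError:
            closed_form = np.nan
        return VortexResults(model=self, ratio_result=ratio, flux_at_ncrit=fluxes,
                             whitlock_ncrit=closed_form)


@dataclass(frozen=True)
class VortexResults:
    """Solved tipping point: Ncrit, fluxes, derivatives, and the ratio."""

    model: VortexModel
    ratio_result: RatioResult
    flux_at_ncrit: FluxResult
    whitlock_ncrit: float

    @property
    def ncrit(self) -> float:
        return self.ratio_result.ncrit

    @property
    def ratio(self) -> float:
        return self.ratio_result.ratio

    def summary(self) -> str:
        p = self.model.params
        r = self.ratio_result
        f = self.flux_at_ncrit
        lines = [
            "Extinction-vortex tipping point (linkage equilibrium)",
            "=" * 56,
            f"Ud                    {p.ud:.6g}",
            f"Ub                    {p.ub:.6g}",
            f"deleterious DFE       gamma(shape={p.deleterious_dfe.shape:g}, "
            f"scale={p.deleterious_dfe.scale:g}), mean {p.deleterious_dfe.mean:.4g}",
            f"beneficial DFE        exponential(mean={p.beneficial_dfe.mean:g})",
            f"delta_env             {p.delta_env:.6g}",
            "-" * 56,
            f"Ncrit                 {r.ncrit:.1f}",
            f"closed-form approx.   {self.whitlock_ncrit:.1f}",
            f"vd(Ncrit)             {f.vd:.4e}",
            f"vb(Ncrit)             {f.vb:.4e}",
            f"dvd/dN at Ncrit       {r.dvd_dN:.4e}",
            f"dvb/dN at Ncrit       {r.dvb_dN:.4e}",
            f"drought:meltdown      {r.ratio:.4f}",
            "=" * 56,
        ]
        return "\n".join(lines)
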