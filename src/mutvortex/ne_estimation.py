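"""Effective population size under linkage disequilibrium.

Background selection against the many segregating deleterious mutations
reduces the effective population size of the simulated populations below
their census size N.  This module quantifies Ne three ways:

* **Coalescent**: every run can carry a parent-pointer genealogy of one
  neutral mid-genome linkage block (the "tracer").  The mean pairwise
  coalescence time T2 of the tracer copies at the end of a focal run,
  divided by T2 in a matching neutral control (Ud = Ub = 0, same N),
  estimates Ne/N directly; the ratio-to-control design cancels the Moran
  timescale constant.
* **Flux matching**: the N' at which the analytic (linkage-equilibrium)
  deleterious flux equals a simulated vd.
* **Critical-size rescaling**: Ne = N * (analytic Ncrit) / (simulated
  Ncrit), the rescaling that superimposes simulated flux curves on the
  analytic ones.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from .analytic_model import ModelParams, deleterious_flux
from .exceptions import InvalidParameterError, MutvortexError, NoSolutionError
from .genome_sim import SimConfig, SimResult, TracerAncestry, run

__all__ = [
    "NeReport",
    "pairwise_coalescence_times",
    "mean_t2",
    "coalescent_ne_ratio",
    "flux_matched_ne",
    "rescaled_ne",
]


@dataclass(frozen=True)
class NeReport:
    """Ne/N assessments for one focal configuration."""

    n: int
    ne_over_n_coalescent: Optional[float] = None
    ne_over_n_coalescent_se: Optional[float] = None
    ne_over_n_flux: Optional[float] = None
    control: str = "neutral"


def pairwise_coalescence_times(
    ancestry: TracerAncestry, n_pairs: int = 100, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Coalescence times (generations before run end) of sampled copy pairs.

    Pairs of the 2N current tracer copies are sampled without replacement
    within each pair; a pair that traces back to distinct founders (no
    common ancestor within the run) yields inf and is reported as
    censored by the caller.
    """
    if rng is None:
        rng = np.random.default_rng()
    nodes = ancestry.node.ravel()
    n_copies = len(nodes)
    out = np.empty(n_pairs)
    for i in range(n_pairs):
        a, b = rng.choice(n_copies, size=2, replace=False)
        out[i] = _coalescence_time(ancestry, int(nodes[a]), int(nodes[b]))
    return out


def _coalescence_time(anc: TracerAncestry, u: int, v: int) -> float:
    if u == v:
        return 0.0
    seen = {}
    x = u
    while x >= 0:
        seen[x] = anc.time[x]
        x = int(anc.parent[x])
    x = v
    while x >= 0:
        if x in seen:
            return anc.end_time - float(anc.time[x])
        x = int(anc.parent[x])
    return float("inf")


def mean_t2(
    result: SimResult, n_pairs: int = 100, pair_seed: int = 0
) -> tuple[float, float]:
    """(mean, censored fraction) of pairwise tracer coalescence times."""
    if result.ancestry is None:
        raise InvalidParameterError("run was not ancestry-tracked")
    times = pairwise_coalescence_times(
        result.ancestry, n_pairs=n_pairs, rng=np.random.default_rng(pair_seed)
    )
    finite = times[np.isfinite(times)]
    censored = 1.0 - len(finite) / len(times)
    if len(finite) == 0:
        raise MutvortexError("no sampled tracer pair coalesced within the run")
    return float(finite.mean()), float(censored)


def _replicate_t2s(
    config: SimConfig, replicates: int, seed: int, max_extension: int = 4
) -> np.ndarray:
    """Mean tracer T2 per replicate run, extending runs that under-coalesce.

    A run whose sampled pairs are more than 10% censored is re-run with
    double the length, up to ``max_extension`` doublings (with a warning).
    """
    child = np.random.SeedSequence(seed).generate_state(replicates) % (2**31)
    t2s = np.empty(replicates)
    for r in range(replicates):
        gens = config.total_generations
        for attempt in range(max_extension + 1):
            cfg = SimConfig(
                n=config.n,
                params=config.params,
                architecture=config.architecture,
                run_generations=gens,
                burn_in_window=config.burn_in_window,
                burn_in_slope_factor=config.burn_in_slope_factor,
                post_threshold_wait=config.post_threshold_wait,
                seed=int(child[r]) + attempt,
                focal_chromosome=config.focal_chromosome,
                focal_block=config.focal_block,
            )
            res = run(cfg, track_ancestry=True, require_burn_in=False)
            t2, censored = mean_t2(res, pair_seed=int(child[r]))
            if censored <= 0.10:
                break
            gens *= 2
            warnings.warn(
                f"{censored:.0%} of tracer pairs uncoalesced at N={config.n}; "
                f"extending run to {gens} generations"
            )
        t2s[r] = t2
    return t2s


def coalescent_ne_ratio(
    config: SimConfig,
    control_config: SimConfig,
    replicates: int = 5,
    seed: int = 0,
) -> NeReport:
    """Ne/N as the ratio of mean tracer coalescence times, focal : control.

    The control must share N and genome architecture and have no
    mutation (Ud = Ub = 0); its T2 measures the neutral Moran timescale,
    so the ratio is dimensionless and equals 1 for a neutral
    self-comparison.
    """
    if config.n != control_config.n:
        raise InvalidParameterError("focal and control must share N")
    if control_config.params.ud != 0 or control_config.params.ub != 0:
        raise InvalidParameterError("control must be neutral (Ud = Ub = 0)")
    ss = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    t2_focal = _replicate_t2s(config, replicates, int(ss[0]))
    t2_control = _replicate_t2s(control_config, replicates, int(ss[1]))
    ratio = float(t2_focal.mean() / t2_control.mean())
    # delta-method SE of a ratio of independent means
    se = ratio * math.sqrt(
        t2_focal.var(ddof=1) / (replicates * t2_focal.mean() ** 2)
        + t2_control.var(ddof=1) / (replicates * t2_control.mean() ** 2)
    )
    control_kind = "neutral" if config.params.ud == 0 else f"Ud={config.params.ud:g}"
    return NeReport(
        n=config.n,
        ne_over_n_coalescent=ratio,
        ne_over_n_coalescent_se=float(se),
        control=control_kind,
    )


def flux_matched_ne(
    simulated_vd: float, params: ModelParams, bracket: tuple[float, float] = (2.0, 1e7)
) -> float:
    """The N' at which the analytic deleterious flux equals ``simulated_vd``.

    |vd| decreases monotonically in N, so the match is a 1-D root.  A
    simulated vd outside the analytic range (including vd >= 0) has no
    solution.
    """
    if simulated_vd >= 0:
        raise NoSolutionError("analytic vd is negative for all N; cannot match vd >= 0")

    def f(n):
        return deleterious_flux(params, n) - simulated_vd

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise NoSolutionError(
            f"simulated vd={simulated_vd:g} outside the analytic range "
            f"[{deleterious_flux(params, lo):g}, {deleterious_flux(params, hi):g}]"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-6))


def rescaled_ne(analytic_ncrit: float, simulated_ncrit: float, n: float) -> float:
    """Ne = N * analytic Ncrit / simulated Ncrit (the flux-curve rescaling)."""
    if analytic_ncrit <= 0 or simulated_ncrit <= 0:
        raise InvalidParameterError("both critical sizes must be positive")
    return n * analytic_ncrit / simulated_ncrit
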