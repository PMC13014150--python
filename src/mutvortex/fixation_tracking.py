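"""Mutation-level tracking: fixations, flux decomposition, simulated ratio.

The linkage-block compression discards individual mutations, so runs that
must decompose the net flux into its deleterious and beneficial parts use
the ledger simulator in this module instead: a pure-Python Moran
simulator with the identical model (same gamete, mutation and replacement
rules as :mod:`mutvortex.genome_sim`) that additionally registers every
non-neutral mutation, maintains its carrier count among the 2N
haplotypes incrementally, and stamps the generation of fixation.  The
fluxes over the post-burn-in window of G* generations are then

    vd = sum_i 2 s_d,i / G*        vb = sum_i 2 s_b,i / G*

summed over mutations whose fixation generation lies inside the window.
These do not track mean fitness exactly — segregating polymorphism adds
fluctuations around the fixation-driven trend — but agree with it over
long windows (the conservation check in the test suite).

Simulated flux derivatives use runs at Ncrit ± eps (eps = 150 individuals
at full scale) and a central difference of the replicate-mean fluxes;
their ratio estimates the drought : meltdown ratio under linkage
disequilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .exceptions import (
    InvalidParameterError,
    MutvortexError,
    PopulationExtinctError,
)
from .genome_sim import SimConfig, detect_burn_in, estimate_vnet

__all__ = [
    "MutationRecord",
    "FixationLedger",
    "FluxDecomposition",
    "DerivativeEstimate",
    "LedgerRunResult",
    "run_with_ledger",
    "decompose",
    "simulated_ratio",
    "fixation_table",
]


@dataclass
class MutationRecord:
    """One tracked mutation: effect, origin, carrier count, fate."""

    id: int
    s: float
    kind: str  # 'deleterious' | 'beneficial'
    origin_gen: float
    count: int = 0
    fixation_gen: Optional[int] = None


@dataclass
class FixationLedger:
    """Registry of all tracked mutations.

    ``active`` holds segregating mutations keyed by id; ``fixed`` the
    fixation events in stamping order.  Mutations whose carrier count
    reaches zero at a generation boundary are pruned entirely.
    """

    active: dict[int, MutationRecord] = field(default_factory=dict)
    fixed: list[MutationRecord] = field(default_factory=list)
    n_lost: int = 0
    _next_id: int = 0

    def register(self, s: float, kind: str, origin_gen: float) -> MutationRecord:
        rec = MutationRecord(id=self._next_id, s=s, kind=kind, origin_gen=origin_gen)
        self._next_id += 1
        self.active[rec.id] = rec
        return rec

    def effect_of(self, mut_id: int) -> float:
        if mut_id in self.active:
            return self.active[mut_id].s
        for rec in self.fixed:
            if rec.id == mut_id:
                return rec.s
        raise KeyError(mut_id)


@dataclass(frozen=True)
class FluxDecomposition:
    """Fixation-based flux estimates over a post-burn-in window."""

    g_star: float
    vd: float
    vb: float
    deleterious_fixations: tuple[float, ...]
    beneficial_fixations: tuple[float, ...]


@dataclass(frozen=True)
class DerivativeEstimate:
    """Central-difference flux derivatives at Ncrit and their ratio."""

    ncrit: float
    epsilon: float
    dvd_dN: float
    dvb_dN: float
    ratio: float
    ratio_se: float
    flagged: bool
    flag_reason: str = ""


@dataclass
class LedgerRunResult:
    trajectory: pd.DataFrame
    status: str
    burn_in_end: Optional[int]
    vnet: Optional[float]
    ledger: FixationLedger
    final_loads: np.ndarray
    final_ids: list  # nested [ind][hap][chrom] -> list of id-tuples per block


def _distinct_cuts(rng, L: int, n_x: int) -> list:
    """n_x distinct sorted hotspot positions in 1..L-1."""
    cuts: list[int] = []
    while len(cuts) < n_x:
        c = int(rng.integers(1, L))
        if c not in cuts:
            cuts.append(c)
    cuts.sort()
    return cuts


def _splice(a: list, b: list, cuts, L: int) -> list:
    """Alternate segments of two per-chromosome block lists at the cut points."""
    out = []
    cur_from_a = True
    pos = 0
    for cut in list(cuts) + [L]:
        out.extend((a if cur_from_a else b)[pos:cut])
        pos = cut
        cur_from_a = not cur_from_a
    return out


def run_with_ledger(config: SimConfig, check_counts: bool = True) -> LedgerRunResult:
    """Moran run with full mutation tracking (reference Python path).

    Same model as the compiled simulator: one uniform death and one
    fitness-proportional double parentage per event, fixed crossover
    counts per chromosome, Poisson mutation numbers per offspring.
    Carrier counts are updated incrementally at every event; fixation
    (count = 2N) and loss (count = 0) are resolved at generation
    boundaries, the stamped fixation generation being the first boundary
    at which the count equals 2N.
    """
    p = config.params
    arch = config.architecture
    N, C, L = config.n, arch.n_chromosomes, arch.blocks_per_chromosome
    n_x = arch.crossovers_per_chromosome
    two_n = 2 * N
    rng = np.random.default_rng(config.seed)
    total_gens = config.total_generations

    # loads as flat python lists for cheap slicing; ids as parallel tuples
    loads = [[[[1.0] * L for _ in range(C)] for _ in range(2)] for _ in range(N)]
    ids = [[[[()] * L for _ in range(C)] for _ in range(2)] for _ in range(N)]
    fitness = np.ones(N, dtype=float)
    ledger = FixationLedger()
    means = np.empty(total_gens)
    vars_ = np.empty(total_gens)
    status = "ok"
    gen_done = 0

    for g in range(total_gens):
        for e in range(N):
            die = int(rng.integers(0, N))
            cum = np.cumsum(fitness)
            tot = float(cum[-1])
            if tot <= 0.0:
                status = "extinct"
                break
            p1 = int(np.searchsorted(cum, rng.random() * tot, side="right"))
            p2 = int(np.searchsorted(cum, rng.random() * tot, side="right"))
            p1 = min(p1, N - 1)
            p2 = min(p2, N - 1)

            child_loads = []
            child_ids = []
            for parent in (p1, p2):
                g_loads = []
                g_ids = []
                for c in range(C):
                    h = int(rng.integers(0, 2))
                    cuts = _distinct_cuts(rng, L, n_x)
                    g_loads.append(
                        _splice(loads[parent][h][c], loads[parent][1 - h][c], cuts, L)
                    )
                    g_ids.append(_splice(ids[parent][h][c], ids[parent][1 - h][c], cuts, L))
                child_loads.append(g_loads)
                child_ids.append(g_ids)

            t_now = g + e / N
            nd = int(rng.poisson(p.ud))
            nb = int(rng.poisson(p.ub))
            for m in range(nd + nb):
                if m < nd:
                    s = float(-rng.gamma(p.deleterious_dfe.shape, p.deleterious_dfe.scale))
                    kind = "deleterious"
                else:
                    s = float(rng.exponential(p.beneficial_dfe.mean))
                    kind = "beneficial"
                h = int(rng.integers(0, 2))
                c = int(rng.integers(0, C))
                j = int(rng.integers(0, L))
                rec = ledger.register(s, kind, t_now)
                fac = 1.0 + s
                child_loads[h][c][j] = 0.0 if fac <= 0.0 else child_loads[h][c][j] * fac
                child_ids[h][c][j] = child_ids[h][c][j] + (rec.id,)

            # carrier-count bookkeeping: dying copies leave, offspring enter
            for h in range(2):
                for c in range(C):
                    for tup in ids[die][h][c]:
                        for mid in tup:
                            rec = ledger.active.get(mid)
                            if rec is not None:
                                rec.count -= 1
                    for tup in child_ids[h][c]:
                        for mid in tup:
                            rec = ledger.active.get(mid)
                            if rec is not None:
                                rec.count += 1

            loads[die] = child_loads
            ids[die] = child_ids
            w = 1.0
            for h in range(2):
                for c in range(C):
                    w *= math.prod(child_loads[h][c])
            fitness[die] = w
        else:
            # generation boundary: stats, then resolve fixations and losses
            mu = float(fitness.mean())
            means[g] = mu
            vars_[g] = float(fitness.var())
            gen_done = g + 1
            for mid in list(ledger.active):
                rec = ledger.active[mid]
                if check_counts and not 0 <= rec.count <= two_n:
                    raise MutvortexError(
                        f"carrier count {rec.count} outside [0, {two_n}] for mutation {mid}"
                    )
                if rec.count == 0:
                    del ledger.active[mid]
                    ledger.n_lost += 1
                elif rec.count == two_n:
                    rec.fixation_gen = gen_done
                    ledger.fixed.append(rec)
                    del ledger.active[mid]
            continue
        break  # inner loop broke: extinction

    trajectory = pd.DataFrame(
        {
            "generation": np.arange(1, gen_done + 1),
            "mean_fitness": means[:gen_done],
            "var_fitness": vars_[:gen_done],
        }
    )
    burn_in_end = None
    vnet = None
    if status == "ok":
        try:
            burn_in_end = detect_burn_in(
                vars_[:gen_done],
                N,
                window=config.burn_in_window,
                slope_factor=config.burn_in_slope_factor,
                wait=config.post_threshold_wait,
            )
            vnet = estimate_vnet(means[:gen_done], burn_in_end)
        except MutvortexError:
            status = "burnin_failed"
    if status == "extinct":
        raise PopulationExtinctError("population fitness collapsed to zero mid-run")
    return LedgerRunResult(
        trajectory=trajectory,
        status=status,
        burn_in_end=burn_in_end,
        vnet=vnet,
        ledger=ledger,
        final_loads=np.array(loads),
        final_ids=ids,
    )


def decompose(ledger: FixationLedger, burn_in_end: float, run_end: float) -> FluxDecomposition:
    """Fixation-based vd and vb over (burn_in_end, run_end].

    Each fixation of effect s contributes 2s (the homozygous log-fitness
    effect) to the cumulative change; dividing by G* = run_end -
    burn_in_end gives per-generation fluxes.
    """
    g_star = run_end - burn_in_end
    if g_star <= 0:
        raise InvalidParameterError(f"empty decomposition window: G*={g_star}")
    dels, bens = [], []
    for rec in ledger.fixed:
        if rec.fixation_gen is None:
            continue
        if burn_in_end < rec.fixation_gen <= run_end:
            (dels if rec.kind == "deleterious" else bens).append(rec.s)
    return FluxDecomposition(
        g_star=float(g_star),
        vd=2.0 * sum(dels) / g_star,
        vb=2.0 * sum(bens) / g_star,
        deleterious_fixations=tuple(dels),
        beneficial_fixations=tuple(bens),
    )


def fixation_table(ledger: FixationLedger) -> pd.DataFrame:
    """Tidy table of fixation events (id, type, s, origin_gen, fixation_gen)."""
    return pd.DataFrame(
        {
            "id": [r.id for r in ledger.fixed],
            "type": [r.kind for r in ledger.fixed],
            "s": [r.s for r in ledger.fixed],
            "origin_gen": [r.origin_gen for r in ledger.fixed],
            "fixation_gen": [r.fixation_gen for r in ledger.fixed],
        }
    )


def simulated_ratio(
    flux_runner: Callable[[float, int], tuple[float, float]],
    ncrit: float,
    epsilon: float = 150.0,
    replicates: int = 10,
    seed: int = 0,
) -> DerivativeEstimate:
    """Drought : meltdown ratio from simulations at Ncrit ± eps.

    ``flux_runner(N, seed)`` must return one replicate's (vd, vb) — e.g. a
    ledger run followed by :func:`decompose` — or analytic fluxes when
    used as a noise-free oracle.  The derivatives are central differences
    of the replicate means; the ratio's standard error combines the four
    replicate-mean SEs by the delta method.
    """
    if epsilon < 1:
        raise InvalidParameterError("epsilon must be at least 1 individual")
    if epsilon >= ncrit:
        raise InvalidParameterError("epsilon must be smaller than ncrit")
    child = np.random.SeedSequence(seed).generate_state(2 * replicates) % (2**31)
    vd_hi = np.empty(replicates)
    vb_hi = np.empty(replicates)
    vd_lo = np.empty(replicates)
    vb_lo = np.empty(replicates)
    for r in range(replicates):
        vd_hi[r], vb_hi[r] = flux_runner(ncrit + epsilon, int(child[2 * r]))
        vd_lo[r], vb_lo[r] = flux_runner(ncrit - epsilon, int(child[2 * r + 1]))
    dvd = (vd_hi.mean() - vd_lo.mean()) / (2.0 * epsilon)
    dvb = (vb_hi.mean() - vb_lo.mean()) / (2.0 * epsilon)

    def _sem2(x):
        return x.var(ddof=1) / len(x) if len(x) > 1 else 0.0

    var_dvd = (_sem2(vd_hi) + _sem2(vd_lo)) / (2.0 * epsilon) ** 2
    var_dvb = (_sem2(vb_hi) + _sem2(vb_lo)) / (2.0 * epsilon) ** 2
    flagged = dvd <= 0
    ratio = dvb / dvd if dvd != 0 else float("nan")
    if dvd > 0:
        ratio_se = math.sqrt(var_dvb / dvd**2 + (dvb**2 / dvd**4) * var_dvd)
    else:
        ratio_se = float("nan")
    return DerivativeEstimate(
        ncrit=float(ncrit),
        epsilon=float(epsilon),
        dvd_dN=float(dvd),
        dvb_dN=float(dvb),
        ratio=float(ratio),
        ratio_se=float(ratio_se),
        flagged=bool(flagged),
        flag_reason="dvd/dN <= 0: noise-dominated" if flagged else "",
    )
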