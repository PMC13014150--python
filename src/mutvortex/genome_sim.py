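"""Forward-time diploid Moran simulator over linkage blocks.

Each of N diploid individuals carries two haplotypes of ``n_chromosomes``
chromosomes, each split into L non-recombining linkage blocks.  Mutations
within a block are not tracked individually; only the block's load
l_j = prod_i (1 + s_i) is stored, and an individual's fitness is the
product of all its 2 * n_chromosomes * L block loads.  Recombination
happens only at the L-1 hotspot boundaries between adjacent blocks, with
a fixed number of crossovers per chromosome per meiosis (default 2).

One generation = N Moran birth-death events.  Runs start clonal (all
loads 1) and a burn-in is declared over 100 generations after the OLS
slope of the fitness variance over the trailing 200 generations first
drops below 0.07/N.  The net fitness flux is estimated post burn-in as
the OLS slope of ln(mean population fitness) against time.

The heavy event loop is compiled (see ``_moran_core``); the pure-Python
operations in this module (:func:`make_gamete`, :func:`mutate_offspring`,
:func:`moran_event`) implement the identical model on the same state
layout and are the reference path used by the mutation-ledger simulator
and the unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _moran_core as core
from .analytic_model import ModelParams
from .exceptions import (
    BurnInFailureError,
    InvalidParameterError,
    MutvortexError,
    PopulationExtinctError,
)

__all__ = [
    "GenomeArchitecture",
    "SimConfig",
    "PopulationState",
    "TracerAncestry",
    "SimResult",
    "init_population",
    "make_gamete",
    "mutate_offspring",
    "moran_event",
    "detect_burn_in",
    "estimate_vnet",
    "run",
    "neutral_marker_fixation",
]

_CHUNK_GENS = 500


@dataclass(frozen=True)
class GenomeArchitecture:
    """Chromosome count, linkage blocks per chromosome, crossovers per meiosis."""

    n_chromosomes: int = 23
    blocks_per_chromosome: int = 100
    crossovers_per_chromosome: int = 2

    def __post_init__(self):
        if self.blocks_per_chromosome < 2:
            raise InvalidParameterError("need at least 2 blocks per chromosome")
        if self.n_chromosomes < 1:
            raise InvalidParameterError("need at least 1 chromosome")
        if not 0 <= self.crossovers_per_chromosome <= self.blocks_per_chromosome - 1:
            raise InvalidParameterError(
                "crossovers per chromosome must lie in [0, blocks_per_chromosome - 1]"
            )


@dataclass(frozen=True)
class SimConfig:
    """Complete simulator input: population size, mutation model, run control.

    ``run_generations`` defaults to 100 * n (long enough for many fixation
    events).  ``delta_env`` in ``params`` plays no role inside the
    simulator (the environment enters only the analytic net flux).
    The focal block used for genealogy/marker tracking sits mid-genome
    (chromosome 12, block 50, 1-based) by default.
    """

    n: int
    params: ModelParams
    architecture: GenomeArchitecture = field(default_factory=GenomeArchitecture)
    run_generations: Optional[int] = None
    burn_in_window: int = 200
    burn_in_slope_factor: float = 0.07
    post_threshold_wait: int = 100
    seed: int = 0
    focal_chromosome: Optional[int] = None  # default: chromosome 12, capped to genome
    focal_block: Optional[int] = None  # default: block 50, capped to chromosome

    def __post_init__(self):
        if self.n < 2:
            raise InvalidParameterError("population size must be at least 2")
        gens = self.total_generations
        if gens <= self.burn_in_window + self.post_threshold_wait:
            raise InvalidParameterError(
                f"run length {gens} cannot accommodate burn-in detection "
                f"({self.burn_in_window} + {self.post_threshold_wait} generations)"
            )
        arch = self.architecture
        if self.focal_chromosome is None:
            object.__setattr__(self, "focal_chromosome", min(12, arch.n_chromosomes))
        if self.focal_block is None:
            object.__setattr__(self, "focal_block", min(50, arch.blocks_per_chromosome))
        if not 1 <= self.focal_chromosome <= arch.n_chromosomes:
            raise InvalidParameterError("focal_chromosome outside the genome")
        if not 1 <= self.focal_block <= arch.blocks_per_chromosome:
            raise InvalidParameterError("focal_block outside the chromosome")

    @property
    def total_generations(self) -> int:
        return self.run_generations if self.run_generations is not None else 100 * self.n


@dataclass
class PopulationState:
    """In-memory population: block loads, fitnesses, generation counter, RNG."""

    loads: np.ndarray  # (N, 2, C, L)
    fitness: np.ndarray  # (N,)
    generation: float
    rng: np.random.Generator

    @property
    def n(self) -> int:
        return int(self.loads.shape[0])

    def recompute_fitness(self) -> np.ndarray:
        """Fitness from scratch as the product of all block loads."""
        return self.loads.reshape(self.n, -1).prod(axis=1)


@dataclass
class TracerAncestry:
    """Parent-pointer genealogy of the focal block's 2N copies.

    ``node[i, h]`` is the genealogy node currently attached to haplotype h
    of individual i; ``parent``/``time`` are append-only arrays over all
    nodes ever created (roots have parent -1, time 0).
    """

    node: np.ndarray  # (N, 2) int64
    parent: np.ndarray  # (n_nodes,) int64
    time: np.ndarray  # (n_nodes,) float64
    end_time: float


@dataclass
class SimResult:
    """Output of one simulator run."""

    config: SimConfig
    trajectory: pd.DataFrame  # generation, mean_fitness, var_fitness
    status: str  # 'ok' | 'extinct' | 'burnin_failed'
    burn_in_end: Optional[int]
    vnet: Optional[float]
    final_state: PopulationState
    ancestry: Optional[TracerAncestry] = None


# ---------------------------------------------------------------------------
# reference (pure-Python) operations


def init_population(config: SimConfig) -> PopulationState:
    """Clonal founding population: every block load 1, every fitness 1."""
    arch = config.architecture
    loads = np.ones(
        (config.n, 2, arch.n_chromosomes, arch.blocks_per_chromosome), dtype=np.float64
    )
    return PopulationState(
        loads=loads,
        fitness=np.ones(config.n, dtype=np.float64),
        generation=0.0,
        rng=np.random.default_rng(config.seed),
    )


def make_gamete(
    parent: np.ndarray, arch: GenomeArchitecture, rng: np.random.Generator
) -> np.ndarray:
    """One recombinant haploid genome (C, L) from a parent's (2, C, L) loads.

    Per chromosome: fair-coin starting haplotype, then the copy source
    switches at ``crossovers_per_chromosome`` hotspots drawn uniformly
    without replacement from the L-1 internal boundaries.
    """
    C, L = arch.n_chromosomes, arch.blocks_per_chromosome
    n_x = arch.crossovers_per_chromosome
    gam = np.empty((C, L), dtype=np.float64)
    for c in range(C):
        h = int(rng.integers(0, 2))
        cuts = np.sort(rng.choice(np.arange(1, L), size=n_x, replace=False)) if n_x else []
        cur, pos = h, 0
        for b in list(cuts) + [L]:
            gam[c, pos:b] = parent[cur, c, pos:b]
            pos = b
            cur = 1 - cur
    return gam


def mutate_offspring(
    genome: np.ndarray, params: ModelParams, arch: GenomeArchitecture, rng: np.random.Generator
) -> list[tuple[float, str, int, int, int]]:
    """Apply Poisson(Ud) deleterious + Poisson(Ub) beneficial mutations in place.

    Each mutation multiplies one uniformly chosen block copy (haplotype,
    chromosome, block) by (1 + s); loads are clamped to 0 when 1 + s <= 0
    (lethal).  Returns the list of applied mutations
    (s, kind, haplotype, chromosome, block) for ledger callers.
    """
    C, L = arch.n_chromosomes, arch.blocks_per_chromosome
    nd = rng.poisson(params.ud)
    nb = rng.poisson(params.ub)
    applied = []
    for k in range(nd + nb):
        if k < nd:
            s = float(-rng.gamma(params.deleterious_dfe.shape, params.deleterious_dfe.scale))
            kind = "deleterious"
        else:
            s = float(rng.exponential(params.beneficial_dfe.mean))
            kind = "beneficial"
        h = int(rng.integers(0, 2))
        c = int(rng.integers(0, C))
        j = int(rng.integers(0, L))
        fac = 1.0 + s
        genome[h, c, j] = 0.0 if fac <= 0.0 else genome[h, c, j] * fac
        applied.append((s, kind, h, c, j))
    return applied


def moran_event(
    state: PopulationState, params: ModelParams, arch: GenomeArchitecture
) -> dict:
    """One birth-death event on the Python path.

    A uniformly chosen individual dies and is replaced by the offspring of
    two fitness-proportionally sampled parents (with replacement; selfing
    possible).  Returns a record of the event (dead index, parents,
    applied mutations) so ledger bookkeeping can follow along.
    """
    rng = state.rng
    N = state.n
    die = int(rng.integers(0, N))
    tot = float(state.fitness.sum())
    if tot <= 0.0:
        raise PopulationExtinctError("all individuals have fitness zero")
    p = state.fitness / tot
    p1 = int(rng.choice(N, p=p))
    p2 = int(rng.choice(N, p=p))
    offspring = np.stack(
        [make_gamete(state.loads[p1], arch, rng), make_gamete(state.loads[p2], arch, rng)]
    )
    mutations = mutate_offspring(offspring, params, arch, rng)
    state.loads[die] = offspring
    state.fitness[die] = float(offspring.reshape(-1).prod())
    state.generation += 1.0 / N
    return {"dead": die, "parents": (p1, p2), "mutations": mutations}


# ---------------------------------------------------------------------------
# burn-in and flux estimation


def _rolling_ols_slopes(y: np.ndarray, window: int) -> np.ndarray:
    """OLS slope of y against index over each trailing window.

    Returns an array aligned with y; entries before the first full window
    are NaN.  Uses closed-form sums, vectorised with cumulative sums.
    """
    n = len(y)
    out = np.full(n, np.nan)
    if n < window:
        return out
    x = np.arange(window, dtype=float)
    sx = x.sum()
    sxx = (x * x).sum()
    denom = window * sxx - sx * sx
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cxy = np.concatenate([[0.0], np.cumsum(y * np.arange(n, dtype=float))])
    for g in range(window - 1, n):
        lo = g - window + 1
        sy = cy[g + 1] - cy[lo]
        # sum of x_k * y_{lo+k} = sum((t - lo) * y_t) over the window
        sxy = (cxy[g + 1] - cxy[lo]) - lo * sy
        out[g] = (window * sxy - sx * sy) / denom
    return out


def detect_burn_in(
    var_fitness: np.ndarray,
    n: int,
    window: int = 200,
    slope_factor: float = 0.07,
    wait: int = 100,
) -> int:
    """First generation whose trailing-window variance slope is < slope_factor/n,
    plus the post-threshold wait.

    ``var_fitness`` is indexed by generation (completed generations 1..G
    stored at positions 0..G-1); the returned burn-in end is a 1-based
    generation index.
    """
    if len(var_fitness) < window:
        raise BurnInFailureError(
            f"need at least {window} recorded generations, have {len(var_fitness)}"
        )
    slopes = _rolling_ols_slopes(np.asarray(var_fitness, dtype=float), window)
    threshold = slope_factor / n
    # strict inequality, with a relative guard so a series rising at
    # exactly the threshold slope never triggers through float rounding
    hits = np.nonzero(slopes < threshold * (1.0 - 1e-9))[0]
    if len(hits) == 0:
        raise BurnInFailureError(
            f"variance slope never dropped below {threshold:g} within {len(var_fitness)} generations"
        )
    return int(hits[0] + 1 + wait)  # +1: positions are 0-based, generations 1-based


def estimate_vnet(mean_fitness: np.ndarray, burn_in_end: int) -> float:
    """OLS slope of ln(mean population fitness) over post-burn-in generations."""
    y = np.asarray(mean_fitness, dtype=float)[burn_in_end:]
    if len(y) < 2:
        raise InvalidParameterError("need at least 2 post-burn-in generations")
    if np.any(y <= 0):
        raise MutvortexError("mean fitness reached zero: ln is undefined")
    t = np.arange(len(y), dtype=float)
    slope, _ = np.polyfit(t, np.log(y), 1)
    return float(slope)


# ---------------------------------------------------------------------------
# compiled-path runner


def run(
    config: SimConfig,
    track_ancestry: bool = False,
    check_every: int = 100,
    require_burn_in: bool = True,
) -> SimResult:
    """Run the full simulation on the compiled path.

    Seed-deterministic: identical config (including seed) gives identical
    output.  Every ``check_every`` generations the incrementally
    maintained fitnesses are re-derived from the block loads and must
    agree to 1e-9 relative tolerance (internal consistency trap).

    With ``require_burn_in`` the burn-in criterion must be met within the
    run, else :class:`BurnInFailureError`; pass False to get a result
    flagged ``burnin_failed`` instead (vnet is then None).
    """
    arch = config.architecture
    N = config.n
    C, L = arch.n_chromosomes, arch.blocks_per_chromosome
    total = config.total_generations
    p = config.params

    core.seed_compiled_rng(config.seed % 2**31)
    loads = np.ones((N, 2, C, L), dtype=np.float64)
    loads2 = loads.reshape(2 * N, C * L)  # contiguous view shared with loads
    fitness = np.ones(N, dtype=np.float64)

    track_mode = 1 if track_ancestry else 0
    focal_c = config.focal_chromosome - 1
    focal_b = config.focal_block - 1
    if track_ancestry:
        tracer_node = np.arange(2 * N, dtype=np.int64).reshape(N, 2)
        parents = [np.full(2 * N, -1, dtype=np.int64)]
        times = [np.zeros(2 * N, dtype=np.float64)]
        anc_n = 2 * N
    else:
        tracer_node = np.zeros((1, 2), dtype=np.int64)
        parents, times, anc_n = [], [], 0
    marker = np.zeros((1, 2), dtype=np.int64)

    means = np.empty(total, dtype=np.float64)
    vars_ = np.empty(total, dtype=np.float64)
    status = "ok"
    done = 0
    next_check = check_every
    while done < total:
        chunk = min(_CHUNK_GENS, total - done)
        if track_ancestry:
            cp = np.empty(2 * N * chunk, dtype=np.int64)
            ct = np.empty(2 * N * chunk, dtype=np.float64)
            offset = anc_n
        else:
            cp = np.empty(0, dtype=np.int64)
            ct = np.empty(0, dtype=np.float64)
        n_new, _, st, gdone = core.run_generations(
            loads2,
            fitness,
            chunk,
            C,
            L,
            arch.crossovers_per_chromosome,
            p.ud,
            p.ub,
            p.deleterious_dfe.shape,
            p.deleterious_dfe.scale,
            p.beneficial_dfe.mean,
            track_mode,
            focal_c,
            focal_b,
            tracer_node,
            cp,
            ct,
            anc_n,
            float(done),
            marker,
            0,
            means[done : done + chunk],
            vars_[done : done + chunk],
        )
        if track_ancestry:
            parents.append(cp[:n_new].copy())
            times.append(ct[:n_new].copy())
            anc_n += n_new
        done += gdone
        if st == core.STATUS_EXTINCT:
            status = "extinct"
            break
        if done >= next_check:
            exact = loads.reshape(N, -1).prod(axis=1)
            scale = np.maximum(np.abs(exact), 1e-300)
            if np.max(np.abs(exact - fitness) / scale) > 1e-9:
                raise MutvortexError("incremental fitness diverged from block loads")
            next_check = done + check_every

    trajectory = pd.DataFrame(
        {
            "generation": np.arange(1, done + 1),
            "mean_fitness": means[:done],
            "var_fitness": vars_[:done],
        }
    )

    burn_in_end = None
    vnet = None
    if status == "ok":
        try:
            burn_in_end = detect_burn_in(
                vars_[:done],
                N,
                window=config.burn_in_window,
                slope_factor=config.burn_in_slope_factor,
                wait=config.post_threshold_wait,
            )
            if done - burn_in_end < 2:
                raise BurnInFailureError(
                    f"burn-in ended at generation {burn_in_end} of a {done}-generation run"
                )
            vnet = estimate_vnet(means[:done], burn_in_end)
        except BurnInFailureError:
            if require_burn_in:
                raise
            status = "burnin_failed"
            burn_in_end = None

    ancestry = None
    if track_ancestry:
        ancestry = TracerAncestry(
            node=tracer_node,
            parent=np.concatenate(parents) if parents else np.empty(0, np.int64),
            time=np.concatenate(times) if times else np.empty(0, np.float64),
            end_time=float(done),
        )

    final = PopulationState(
        loads=loads, fitness=fitness, generation=float(done), rng=np.random.default_rng(config.seed)
    )
    return SimResult(
        config=config,
        trajectory=trajectory,
        status=status,
        burn_in_end=burn_in_end,
        vnet=vnet,
        final_state=final,
        ancestry=ancestry,
    )


def neutral_marker_fixation(
    n: int,
    n_runs: int,
    seed: int,
    arch: GenomeArchitecture | None = None,
    max_generations: int = 1_000_000,
) -> float:
    """Fixation frequency of a neutral marker injected at count 1.

    Runs the full Moran machinery (neutral: Ud = Ub = 0) with a 0/1 marker
    on the focal block of one haplotype of one individual, until loss or
    fixation.  The expected frequency is pfix(0, N) = 1/(2N).
    """
    if arch is None:
        arch = GenomeArchitecture()
    C, L = arch.n_chromosomes, arch.blocks_per_chromosome
    focal_c = min(11, C - 1)
    focal_b = min(49, L - 1)
    fixed = 0
    core.seed_compiled_rng(seed % 2**31)
    loads2 = np.ones((2 * n, C * L), dtype=np.float64)
    fitness = np.ones(n, dtype=np.float64)
    dummy_node = np.zeros((1, 2), dtype=np.int64)
    empty_i = np.empty(0, dtype=np.int64)
    empty_f = np.empty(0, dtype=np.float64)
    means = np.empty(max_generations, dtype=np.float64)
    vars_ = np.empty(max_generations, dtype=np.float64)
    for r in range(n_runs):
        marker = np.zeros((n, 2), dtype=np.int64)
        marker[0, 0] = 1
        _, count, st, _ = core.run_generations(
            loads2,
            fitness,
            max_generations,
            C,
            L,
            arch.crossovers_per_chromosome,
            0.0,
            0.0,
            1.0,
            1.0,
            1.0,
            2,
            focal_c,
            focal_b,
            dummy_node,
            empty_i,
            empty_f,
            0,
            0.0,
            marker,
            1,
            means,
            vars_,
        )
        if st == core.STATUS_MARKER_FIXED:
            fixed += 1
        elif st != core.STATUS_MARKER_LOST:
            raise MutvortexError("neutral marker run did not absorb")
    return fixed / n_runs
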