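"""Stochastic root finding for the simulated critical population size.

The net-flux estimate v̂net from a forward simulation is noisy, so Ncrit
cannot be found by deterministic root finding alone.  The procedure used
here, per replicate: (1) bracket the root starting from N = 1500 and
6000, expanding outward by factors of two until the two v̂net values
straddle zero; (2) iterate the secant method until the successive v̂net
magnitude changes by less than 15%; (3) fit a straight line to all
evaluated (N, v̂net) points with N within a factor of 3 of the final
evaluated N, and take its zero-intercept.  The replicate intercepts are
averaged over (by default) 10 independent replicates.

The evaluator is any callable N -> v̂net, so the same pipeline runs
against the full linkage-block simulator, the deterministic analytic
model (an oracle for correctness), or synthetic noisy test functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .exceptions import BracketFailureError, InsufficientPointsError, InvalidParameterError

__all__ = [
    "NcritEstimate",
    "ReplicateResult",
    "bracket",
    "secant_search",
    "fit_intercept",
    "estimate_ncrit",
]

_START_LOW = 1500.0
_START_HIGH = 6000.0
_CAP_HIGH = 1e6
_CAP_LOW = 50.0
_MAX_SECANT_ITER = 30


@dataclass
class ReplicateResult:
    """One replicate's evaluated points, fitted line, and zero-intercept."""

    points: list[tuple[float, float]]
    intercept: float
    slope: float
    offset: float
    flagged: bool = False
    flag_reason: str = ""


@dataclass
class NcritEstimate:
    """Replicate zero-intercepts and their mean."""

    replicates: list[ReplicateResult]
    failures: list[str] = field(default_factory=list)

    @property
    def intercepts(self) -> np.ndarray:
        return np.array([r.intercept for r in self.replicates])

    @property
    def ncrit(self) -> float:
        return float(self.intercepts.mean())

    @property
    def se(self) -> float:
        vals = self.intercepts
        if len(vals) < 2:
            return float("nan")
        return float(vals.std(ddof=1) / np.sqrt(len(vals)))


def bracket(
    evaluator: Callable[[float], float],
    start: tuple[float, float] = (_START_LOW, _START_HIGH),
    caps: tuple[float, float] = (_CAP_LOW, _CAP_HIGH),
) -> list[tuple[float, float]]:
    """Evaluated points ending with a sign change in v̂net.

    Starts at the two initial guesses and alternately expands the lower
    guess down and the upper guess up by factors of two (1500, 6000, 750,
    12000, 375, ...) until the extreme evaluations straddle zero.  Raises
    :class:`BracketFailureError` once either cap is crossed.
    """
    lo, hi = start
    points = [(lo, evaluator(lo)), (hi, evaluator(hi))]

    def straddles():
        vals = [v for _, v in points]
        return min(vals) < 0.0 < max(vals)

    next_lo, next_hi = lo / 2.0, hi * 2.0
    while not straddles():
        if next_lo < caps[0] and next_hi > caps[1]:
            raise BracketFailureError(
                f"no v̂net sign change between N={caps[0]:g} and N={caps[1]:g}"
            )
        if next_lo >= caps[0]:
            points.append((next_lo, evaluator(next_lo)))
            next_lo /= 2.0
            if straddles():
                break
        if next_hi <= caps[1]:
            points.append((next_hi, evaluator(next_hi)))
            next_hi *= 2.0
    return points


def secant_search(
    evaluator: Callable[[float], float],
    points: Sequence[tuple[float, float]],
    rel_change_tol: float = 0.15,
    max_iter: int = _MAX_SECANT_ITER,
    criterion: Literal["vnet", "N"] = "vnet",
    min_n: float = 4.0,
) -> tuple[list[tuple[float, float]], bool]:
    """Secant iterations appended to the bracketing evaluations.

    Terminates when the successive change drops below ``rel_change_tol``
    — by default the relative change in v̂net magnitude (the literal
    reading of the stopping rule); ``criterion='N'`` switches to relative
    change in N.  Equal successive v̂net values (zero secant denominator)
    are handled by perturbing N by 1%.  Returns (all points, flagged):
    flagged is True when the iteration cap was reached without
    termination.
    """
    pts = list(points)
    # seed the secant from the two most recent evaluations (the bracket ends)
    (n0, v0), (n1, v1) = pts[-2], pts[-1]
    for _ in range(max_iter):
        if v1 == v0:
            n2 = n1 * 1.01
        else:
            n2 = n1 - v1 * (n1 - n0) / (v1 - v0)
        if not np.isfinite(n2) or n2 < min_n:
            n2 = max(min_n, 0.5 * (n0 + n1))
        v2 = evaluator(n2)
        pts.append((n2, v2))
        if v2 == 0.0:  # landed on the root exactly (noise-free evaluators)
            return pts, False
        if v1 != 0 and abs(v2 - v1) / abs(v1) < rel_change_tol:
            return pts, False
        if criterion == "N" and n1 != 0 and abs(n2 - n1) / abs(n1) < rel_change_tol:
            return pts, False
        if abs(n2 - n1) <= 1e-9 * abs(n1):
            # N has stopped moving to machine precision: a smooth evaluator
            # has converged even though successive v values keep halving
            return pts, False
        n0, v0, n1, v1 = n1, v1, n2, v2
    warnings.warn("secant iteration cap reached without meeting the stopping rule")
    return pts, True


def fit_intercept(
    points: Sequence[tuple[float, float]], final_n: float
) -> tuple[float, float, float, bool]:
    """Zero-intercept of the line fitted to points near the final N.

    Only points with N within a factor of 3 of ``final_n`` enter the OLS
    fit v̂net = a + b N; the estimate is -a/b.  Returns
    (intercept, slope b, offset a, flagged); flagged marks a non-positive
    fitted slope (an unreliable fit, since vnet must increase through
    zero at the tipping point).
    """
    included = [(n, v) for n, v in points if final_n / 3.0 <= n <= 3.0 * final_n]
    if len(included) < 2:
        raise InsufficientPointsError(
            f"only {len(included)} points within a factor of 3 of N={final_n:g}"
        )
    ns = np.array([n for n, _ in included])
    vs = np.array([v for _, v in included])
    b, a = np.polyfit(ns, vs, 1)
    flagged = b <= 0
    if flagged:
        warnings.warn("fitted v̂net slope is non-positive; intercept unreliable")
    return float(-a / b), float(b), float(a), bool(flagged)


def estimate_ncrit(
    evaluator_factory: Callable[[int], Callable[[float], float]],
    n_replicates: int = 10,
    seed: int = 0,
    start: tuple[float, float] = (_START_LOW, _START_HIGH),
    rel_change_tol: float = 0.15,
) -> NcritEstimate:
    """Full bracket -> secant -> line-fit pipeline over independent replicates.

    ``evaluator_factory(replicate_seed)`` must return a fresh evaluator
    N -> v̂net whose stochasticity (if any) is governed by the given seed;
    replicate seeds are spawned from ``seed``.  Replicate failures are
    recorded and the mean is taken over the successful replicates (with a
    warning when fewer than requested).
    """
    if n_replicates < 1:
        raise InvalidParameterError("need at least one replicate")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    replicates: list[ReplicateResult] = []
    failures: list[str] = []
    for r in range(n_replicates):
        evaluator = evaluator_factory(int(child_seeds[r]))
        try:
            bracket_pts = bracket(evaluator, start=start)
            pts, sec_flag = secant_search(evaluator, bracket_pts, rel_change_tol=rel_change_tol)
            final_n = pts[-1][0]
            # fit over the secant-phase evaluations: the bracket seeds sit far
            # from the root, where vnet's curvature would bias the intercept;
            # fall back to all points when the secant converged in one step
            secant_pts = pts[len(bracket_pts):]
            try:
                intercept, slope, offset, fit_flag = fit_intercept(secant_pts, final_n)
            except InsufficientPointsError:
                intercept, slope, offset, fit_flag = fit_intercept(pts, final_n)
            replicates.append(
                ReplicateResult(
                    points=pts,
                    intercept=intercept,
                    slope=slope,
                    offset=offset,
                    flagged=sec_flag or fit_flag,
                    flag_reason="secant cap" if sec_flag else ("slope<=0" if fit_flag else ""),
                )
            )
        except (BracketFailureError, InsufficientPointsError) as exc:
            failures.append(f"replicate {r}: {exc}")
    if not replicates:
        raise BracketFailureError("all replicates failed: " + "; ".join(failures))
    if failures:
        warnings.warn(
            f"{len(failures)} of {n_replicates} replicates failed; "
            "mean taken over the rest"
        )
    return NcritEstimate(replicates=replicates, failures=failures)
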