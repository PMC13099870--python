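"""Potential landscapes, stable states, tipping points and theory checks.

A stability landscape assigns every system state (active-symptom count for
the Ising models, sum score for the GVAR model) the potential

    U(state) = -ln P(state),

so valleys (local minima of U) are stable states and the hill separating two
adjacent valleys is a tipping point. Barrier height — the potential at the
separating tipping point minus the potential at the minimum — is used as the
escape-difficulty measure of a stable state's resilience.

Two qualitative predictions of the symptom-network theory are checked on a
connectivity-multiplier sweep:

1. *Severity*: with increasing connectivity the high-activation ("unhealthy")
   half of the landscape deepens while the low-activation ("healthy") half
   becomes shallower.
2. *Discontinuity*: the number of stable states goes from one to two
   somewhere along the sweep (a tipping point appears).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


class AxisKind(str, enum.Enum):
    ACTIVE_COUNT = "active_count"
    SUM_SCORE = "sum_score"


@dataclass(frozen=True)
class Landscape:
    """A potential landscape over an ordered one-dimensional state grid.

    ``probability`` must sum to one (discrete axis) or integrate to one by
    the trapezoid rule (continuous axis) to within 1e-6; the constructor in
    ``to_landscape`` normalises, which leaves potential differences — and
    hence every landscape feature — unchanged.
    """

    axis_kind: AxisKind
    grid: np.ndarray
    probability: np.ndarray
    potential: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        p = np.asarray(self.probability, dtype=float)
        u = np.asarray(self.potential, dtype=float)
        if grid.ndim != 1 or grid.size != p.size or grid.size != u.size:
            raise ValueError("grid, probability and potential must be equal-length vectors")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("probabilities must be nonnegative")
        total = p.sum() if self.is_discrete else np.trapezoid(p, grid)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"probability mass {total} is not 1 within 1e-6")
        if not np.all(np.isfinite(u[p > 0])):
            raise ValueError("potential must be finite wherever probability is positive")
        object.__setattr__(self, "axis_kind", AxisKind(self.axis_kind))
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "probability", p)
        object.__setattr__(self, "potential", u)

    @property
    def is_discrete(self) -> bool:
        return AxisKind(self.axis_kind) is AxisKind.ACTIVE_COUNT

    @property
    def midpoint(self) -> float:
        """Axis midpoint splitting the healthy (low) and unhealthy (high) halves."""
        return 0.5 * (self.grid[0] + self.grid[-1])


def to_landscape(
    grid: np.ndarray,
    probability: np.ndarray,
    axis_kind: AxisKind | str = AxisKind.ACTIVE_COUNT,
    meta: dict | None = None,
) -> Landscape:
    """Build a potential landscape U = -ln P from (possibly unnormalised) mass.

    Zero-probability grid points get an infinite potential and are excluded
    from the minima search downstream.
    """
    axis_kind = AxisKind(axis_kind)
    grid = np.asarray(grid, dtype=float)
    p = np.asarray(probability, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be nonnegative")
    total = p.sum() if axis_kind is AxisKind.ACTIVE_COUNT else np.trapezoid(p, grid)
    if total <= 0:
        raise ValueError("probability mass must be positive")
    p = p / total
    with np.errstate(divide="ignore"):
        u = np.where(p > 0, -np.log(np.where(p > 0, p, 1.0)), np.inf)
    return Landscape(axis_kind=axis_kind, grid=grid, probability=p, potential=u,
                     meta=meta or {})


@dataclass(frozen=True)
class StableStateReport:
    """Stable states and tipping points of one landscape.

    ``minima`` holds (grid location, potential) pairs in axis order;
    ``tipping_points`` the separating maxima between adjacent minima;
    ``barrier_heights[i]`` is the smallest potential rise from minimum ``i``
    to an adjacent tipping point (``nan`` when there is a single minimum,
    whose barrier is undefined). ``healthy_depth``/``unhealthy_depth`` are
    -min U over the low/high half of the axis — how deep the landscape digs
    on each side regardless of whether that side hosts a local minimum.
    """

    axis_kind: AxisKind
    minima: tuple[tuple[float, float], ...]
    tipping_points: tuple[tuple[float, float], ...]
    barrier_heights: tuple[float, ...]
    deepest_state: float
    healthy_depth: float
    unhealthy_depth: float
    midpoint: float

    @property
    def n_stable(self) -> int:
        return len(self.minima)

    @property
    def healthy_minima(self) -> tuple[tuple[float, float], ...]:
        return tuple(m for m in self.minima if m[0] <= self.midpoint)

    @property
    def unhealthy_minima(self) -> tuple[tuple[float, float], ...]:
        return tuple(m for m in self.minima if m[0] > self.midpoint)

    def to_dict(self) -> dict:
        return {
            "axis_kind": AxisKind(self.axis_kind).value,
            "n_stable": self.n_stable,
            "minima": [list(m) for m in self.minima],
            "tipping_points": [list(m) for m in self.tipping_points],
            "barrier_heights": [None if np.isnan(b) else b for b in self.barrier_heights],
            "deepest_state": self.deepest_state,
            "healthy_depth": self.healthy_depth,
            "unhealthy_depth": self.unhealthy_depth,
            "midpoint": self.midpoint,
        }


def _minima_indices(u: np.ndarray) -> list[int]:
    """Plateau-aware local-minimum indices of a potential vector.

    A maximal run of equal values is a minimum iff every existing neighbour
    of the run is strictly higher (a boundary counts as "no neighbour"); the
    run is represented by its midpoint index, rounded down. A landscape that
    is entirely flat is treated as a single minimum at its midpoint.
    """
    n = u.size
    out: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and u[j + 1] == u[i]:
            j += 1
        left_higher = i == 0 or u[i - 1] > u[i]
        right_higher = j == n - 1 or u[j + 1] > u[i]
        if left_higher and right_higher and np.isfinite(u[i]):
            out.append((i + j) // 2)
        i = j + 1
    return out


def find_stable_states(landscape: Landscape) -> StableStateReport:
    """Locate minima (stable states), tipping points and barrier heights."""
    u = landscape.potential
    grid = landscape.grid
    if np.count_nonzero(np.isfinite(u)) < 3:
        raise ValueError("need at least 3 finite-potential grid points")
    mins = _minima_indices(u)
    if not mins:  # unreachable for a proper landscape; guard for safety
        raise ValueError("no stable state found")

    tips: list[int] = []
    for a, b in zip(mins[:-1], mins[1:]):
        seg = u[a + 1:b]
        tips.append(a + 1 + int(np.argmax(seg)))

    barriers: list[float] = []
    for k, m in enumerate(mins):
        adj = []
        if k > 0:
            adj.append(u[tips[k - 1]] - u[m])
        if k < len(tips):
            adj.append(u[tips[k]] - u[m])
        barriers.append(min(adj) if adj else float("nan"))

    mid = landscape.midpoint
    lo = grid <= mid
    hi = grid > mid
    finite = np.isfinite(u)
    healthy_depth = float(-np.min(u[lo & finite])) if np.any(lo & finite) else -np.inf
    unhealthy_depth = float(-np.min(u[hi & finite])) if np.any(hi & finite) else -np.inf

    return StableStateReport(
        axis_kind=landscape.axis_kind,
        minima=tuple((float(grid[m]), float(u[m])) for m in mins),
        tipping_points=tuple((float(grid[t]), float(u[t])) for t in tips),
        barrier_heights=tuple(barriers),
        deepest_state=float(grid[mins[int(np.argmin([u[m] for m in mins]))]]),
        healthy_depth=healthy_depth,
        unhealthy_depth=unhealthy_depth,
        midpoint=float(mid),
    )


class Verdict(str, enum.Enum):
    YES = "yes"
    PARTIAL = "partial"
    NO = "no"


@dataclass(frozen=True)
class SweepClassification:
    """Theory check for one condition's connectivity-multiplier sweep."""

    prediction1_severity: bool
    prediction2_discontinuity: Verdict
    n_stable_by_multiplier: dict[float, int]
    details: dict = field(default_factory=dict, compare=False)


def classify_sweep(
    reports: Mapping[float, StableStateReport],
) -> SweepClassification:
    """Classify one multiplier sweep against the network theory's predictions.

    Prediction 1 (severity) holds when, across increasing multipliers, the
    unhealthy half-depth strictly increases while the healthy half-depth
    strictly decreases — probability mass shifts monotonically toward the
    high-activation side. Prediction 2 (discontinuity) is ``yes`` when the
    stable-state count rises from 1 to 2 and stays there, ``partial`` when
    two states appear and then one vanishes again (1 -> 2 -> 1), and ``no``
    when no tipping point ever appears.
    """
    if not reports:
        raise ValueError("empty sweep")
    kinds = {AxisKind(r.axis_kind) for r in reports.values()}
    if len(kinds) > 1:
        raise ValueError("inconsistent axis kinds across the sweep")
    mults = sorted(reports)
    seq = [reports[m] for m in mults]

    unhealthy = [r.unhealthy_depth for r in seq]
    healthy = [r.healthy_depth for r in seq]
    p1 = all(b > a for a, b in zip(unhealthy[:-1], unhealthy[1:])) and \
        all(b < a for a, b in zip(healthy[:-1], healthy[1:]))

    counts = [min(r.n_stable, 2) for r in seq]
    if all(c == counts[0] for c in counts):
        p2 = Verdict.NO
    else:
        rose = any(a < b for a, b in zip(counts[:-1], counts[1:]))
        fell = any(a > b for a, b in zip(counts[:-1], counts[1:]))
        if rose and not fell:
            p2 = Verdict.YES
        elif rose and fell:
            p2 = Verdict.PARTIAL
        else:
            p2 = Verdict.NO
    return SweepClassification(
        prediction1_severity=p1,
        prediction2_discontinuity=p2,
        n_stable_by_multiplier={m: r.n_stable for m, r in zip(mults, seq)},
        details={"healthy_depth": dict(zip(mults, healthy)),
                 "unhealthy_depth": dict(zip(mults, unhealthy))})


@dataclass(frozen=True)
class TheoryClassification:
    """Model-level verdicts aggregated over theory-consistent conditions."""

    prediction1_severity: Verdict
    prediction2_discontinuity: Verdict
    per_condition: dict[str, SweepClassification] = field(default_factory=dict,
                                                          compare=False)

    def to_dict(self) -> dict:
        return {
            "prediction1_severity": self.prediction1_severity.value,
            "prediction2_discontinuity": self.prediction2_discontinuity.value,
            "per_condition": {
                c: {"prediction1": s.prediction1_severity,
                    "prediction2": s.prediction2_discontinuity.value,
                    "n_stable_by_multiplier": {str(k): v for k, v in
                                               s.n_stable_by_multiplier.items()}}
                for c, s in self.per_condition.items()},
        }


def _aggregate(verdicts: Sequence[Verdict]) -> Verdict:
    if all(v is Verdict.YES for v in verdicts):
        return Verdict.YES
    if all(v is Verdict.NO for v in verdicts):
        return Verdict.NO
    return Verdict.PARTIAL


def classify_model(
    sweeps: Mapping[str, SweepClassification],
    theory_conditions: Sequence[str] | None = None,
) -> TheoryClassification:
    """Aggregate per-condition sweep verdicts into a per-model classification.

    Only the theory-consistent conditions (negative mean thresholds for the
    Ising models; all mean conditions for the GVAR model) enter the verdict.
    All-yes maps to yes, all-no to no, a mixture to partial; prediction 1 is
    reported as a plain yes/no (partial collapses to no — the severity shift
    either holds across the theory-consistent regime or it does not).
    """
    keys = list(theory_conditions) if theory_conditions is not None else list(sweeps)
    missing = [k for k in keys if k not in sweeps]
    if missing:
        raise ValueError(f"missing sweeps for conditions: {missing}")
    sel = [sweeps[k] for k in keys]
    p1 = _aggregate([Verdict.YES if s.prediction1_severity else Verdict.NO
                     for s in sel])
    if p1 is Verdict.PARTIAL:
        p1 = Verdict.NO
    p2 = _aggregate([s.prediction2_discontinuity for s in sel])
    return TheoryClassification(prediction1_severity=p1,
                                prediction2_discontinuity=p2,
                                per_condition=dict(sweeps))


def mean_field_fixed_points(
    mean_coupling: float, mean_field: float, n: int, tol: float = 1e-10
) -> np.ndarray:
    """Roots of the mean-field self-consistency m = tanh((n-1) c m + h).

    Sign-change bracketing on [-1, 1] followed by bisection. Used only to
    calibrate the synthetic-network defaults and to sanity-check which
    parameter regimes are mono- vs. bistable; the landscapes themselves come
    from exact enumeration.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    j = (n - 1) * mean_coupling

    def g(m: float) -> float:
        return np.tanh(j * m + mean_field) - m

    xs = np.linspace(-1.0, 1.0, 4001)
    gs = np.array([g(x) for x in xs])
    roots: list[float] = []
    for a, b, ga, gb in zip(xs[:-1], xs[1:], gs[:-1], gs[1:]):
        if ga == 0.0:
            roots.append(float(a))
            continue
        if ga * gb < 0:
            lo, hi = float(a), float(b)
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                if g(lo) * g(mid) <= 0:
                    hi = mid
                else:
                    lo = mid
            roots.append(0.5 * (lo + hi))
    if gs[-1] == 0.0:
        roots.append(1.0)
    # dedupe near-identical roots from adjacent brackets
    out: list[float] = []
    for r in sorted(roots):
        if not out or abs(r - out[-1]) > 100 * tol:
            out.append(r)
    return np.array(out)
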