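"""Distribution, attraction and redistribution of relative fish biomass.

Biomass around a reef decays exponentially with distance: ``B_i =
exp(-k * D_i)`` with ``k = ln(2) / D_h``, so abundance halves every
``D_h`` metres (fidelity). When an artificial reef appears, each cell
gives up a fraction of its biomass according to a logistic habitat-choice
function of the cell's distance to the new reef: half a cell's biomass
moves at ``D_50`` metres (mobility), ~99% of the decline in attraction is
spanned by ``D_99 = 2 * D_50``, and the limiting attracted proportion at
zero distance is ``Q0 = Q / (Q + 1)`` where ``Q`` is the artificial:natural
quality (density) ratio. The attracted biomass is then laid back down
around the artificial reef with the same exponential kernel. Attraction
only redistributes biomass; the system total is conserved.

Fields are plain ``numpy`` arrays of shape ``(n_side, n_side)`` holding
dimensionless relative biomass per cell (reef cells carry 1.0 for
residents).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .grid import GridSpec, ReefLayout, distance_field

__all__ = [
    "ScenarioParams",
    "AttractionOutcome",
    "shape_param",
    "q0_from_q",
    "q_from_q0",
    "density_ratio_at_zero",
    "resident_field",
    "attraction_fraction",
    "apply_attraction",
    "redistribute",
    "deploy_for_residents",
    "deploy_for_pelagics",
    "deploy",
]

#: Logistic slope constant: ln(99^2) = 2 ln 99, chosen so the attracted
#: fraction falls from 0.99*Q0 at distance 0 to 0.01*Q0 at D_99 (= 2*D_50).
_LOG99SQ = 2.0 * math.log(99.0)

Group = Literal["resident", "pelagic"]
OverlapRule = Literal["additive", "max"]


@dataclass(frozen=True)
class ScenarioParams:
    """One point in scenario parameter space.

    Parameters
    ----------
    d_h : float
        Fidelity: distance (m) at which biomass density halves around a reef.
    q : float
        Relative quality of the artificial reef; the AR:adjacent-NR biomass
        density ratio after attraction. ``q >= 1``.
    d_50 : float
        Mobility: distance (m) at which half a cell's biomass relocates.
    d_99 : float
        Span of ~99% of the attraction decline; fixed at ``2 * d_50``.
    d_r_step : int
        Reef-separation step on the 12-level diagonal ladder.
    s_r : int
        Natural reef side length in cells (1, 2 or 3).
    p : int
        Fishing effort: number of cells fished simultaneously.
    group : {"resident", "pelagic"}
        Functional group. Residents live only around reefs; pelagics start
        uniformly distributed and undergo two rounds of attraction.
    q_nr : float
        Natural-reef quality for the pelagic first-stage attraction
        (default 1: the natural reef is no better than open water is
        attractive, it simply exists).
    overlap_rule : {"additive", "max"}
        How biomass associated with both reefs combines in a cell after
        redistribution. "additive" conserves total biomass exactly and is
        the default; "max" takes the element-wise maximum of the two reef
        fields and breaks conservation.
    """

    d_h: float = 10.0
    q: float = 1.0
    d_50: float = 300.0
    d_99: float | None = None
    d_r_step: int = 1
    s_r: int = 1
    p: int = 5
    group: Group = "resident"
    q_nr: float = 1.0
    overlap_rule: OverlapRule = "additive"
    n_side: int = 211
    cell_size: float = 10.0

    def __post_init__(self) -> None:
        if not self.d_h > 0:
            raise ValueError(f"d_h must be positive, got {self.d_h}")
        if not self.q >= 1:
            raise ValueError(f"q must be >= 1, got {self.q}")
        if not self.d_50 > 0:
            raise ValueError(f"d_50 must be positive, got {self.d_50}")
        if self.d_99 is None:
            object.__setattr__(self, "d_99", 2.0 * self.d_50)
        elif not math.isclose(self.d_99, 2.0 * self.d_50, rel_tol=1e-12):
            raise ValueError(
                f"d_99 is fixed at twice d_50; got d_99={self.d_99}, d_50={self.d_50}"
            )
        if self.s_r not in (1, 2, 3):
            raise ValueError(f"s_r must be 1, 2 or 3, got {self.s_r}")
        if not isinstance(self.p, (int, np.integer)) or self.p < 1:
            raise ValueError(f"p must be a positive integer, got {self.p!r}")
        if self.p > self.n_side * self.n_side:
            raise ValueError(f"p={self.p} exceeds the {self.n_side}x{self.n_side} cell count")
        if self.group not in ("resident", "pelagic"):
            raise ValueError(f"group must be 'resident' or 'pelagic', got {self.group!r}")
        if not self.q_nr > 0:
            raise ValueError(f"q_nr must be positive, got {self.q_nr}")
        if self.overlap_rule not in ("additive", "max"):
            raise ValueError(f"overlap_rule must be 'additive' or 'max', got {self.overlap_rule!r}")

    def with_updates(self, **changes) -> "ScenarioParams":
        """Return a copy with ``changes`` applied; updating ``d_50`` re-derives
        ``d_99 = 2 * d_50`` unless ``d_99`` is set explicitly."""
        if "d_50" in changes and "d_99" not in changes:
            changes["d_99"] = 2.0 * changes["d_50"]
        return replace(self, **changes)

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.n_side, self.cell_size)


@dataclass(frozen=True)
class AttractionOutcome:
    """Before/after biomass fields for one artificial-reef deployment.

    ``before`` is the system state prior to AR deployment (for pelagics,
    after the first-stage attraction to the natural reef), ``remaining``
    the field after attraction toward the AR but before redistribution,
    and ``after`` the final field. ``attracted_fraction`` is the share of
    total system biomass that moved to the artificial reef.
    """

    before: np.ndarray
    remaining: np.ndarray
    after: np.ndarray
    attracted_total: float
    attracted_fraction: float


def shape_param(d_h: float) -> float:
    """Exponential decay rate ``k = ln(2) / d_h`` (per metre)."""
    if not d_h > 0:
        raise ValueError(f"d_h must be positive, got {d_h}")
    return math.log(2.0) / d_h


def q0_from_q(q: float) -> float:
    """Limiting attracted proportion ``Q0 = Q / (Q + 1)``, in (0, 1)."""
    if not q > 0:
        raise ValueError(f"q must be positive, got {q}")
    return q / (q + 1.0)


def q_from_q0(q0: float) -> float:
    """Inverse map ``Q = Q0 / (1 - Q0)``."""
    if not 0 < q0 < 1:
        raise ValueError(f"q0 must be in (0, 1), got {q0}")
    return q0 / (1.0 - q0)


def density_ratio_at_zero(q: float) -> float:
    """AR:adjacent-NR biomass-density ratio in the zero-distance limit.

    At ``D_i -> 0`` a proportion ``Q0`` of a cell's biomass moves to the
    artificial reef and ``1 - Q0`` stays, so the density ratio is
    ``Q0 / (1 - Q0)``, which recovers ``Q`` exactly.
    """
    return q_from_q0(q0_from_q(q))


def resident_field(dist: np.ndarray, d_h: float) -> np.ndarray:
    """Exponential biomass surface ``exp(-k * D_i)`` around a reef.

    ``dist`` is the nearest-reef-cell distance field, so for a multi-cell
    reef this equals the element-wise maximum over per-reef-cell
    exponential surfaces (the kernel is monotone decreasing): overlapping
    biomass fields within a reef combine by the max rule, not additively.
    """
    k = shape_param(d_h)
    return np.exp(-k * np.asarray(dist, dtype=np.float64))


def attraction_fraction(
    d_i: float | np.ndarray, q0: float, d_50: float, d_99: float
) -> float | np.ndarray:
    """Proportion of a cell's biomass attracted to a reef at distance ``d_i``.

    Logistic in distance: ``q0 / (1 + exp((ln(99^2)/d_99) * (d_i - d_50)))``.
    Equals ``0.99*q0`` at zero distance, ``q0/2`` at ``d_50`` and
    ``0.01*q0`` at ``d_99``; strictly decreasing in ``d_i``.
    """
    if not 0 < q0 < 1:
        raise ValueError(f"q0 must be in (0, 1), got {q0}")
    if not d_50 > 0 or not d_99 > 0:
        raise ValueError("d_50 and d_99 must be positive")
    z = (_LOG99SQ / d_99) * (np.asarray(d_i, dtype=np.float64) - d_50)
    # exp overflows harmlessly to inf for very distant cells; fraction -> 0
    with np.errstate(over="ignore"):
        out = q0 / (1.0 + np.exp(z))
    if np.isscalar(d_i):
        return float(out)
    return out


def apply_attraction(
    field: np.ndarray, dist_to_reef: np.ndarray, q0: float, d_50: float, d_99: float
) -> tuple[np.ndarray, float]:
    """Deplete ``field`` by the logistic attracted fraction of each cell.

    Returns ``(remaining, attracted_total)`` with
    ``remaining_i = field_i * (1 - f(D_i))`` and
    ``attracted_total = sum(field - remaining)``.
    """
    field = np.asarray(field, dtype=np.float64)
    dist_to_reef = np.asarray(dist_to_reef, dtype=np.float64)
    if field.shape != dist_to_reef.shape:
        raise ValueError(
            f"field shape {field.shape} does not match distance field {dist_to_reef.shape}"
        )
    f = attraction_fraction(dist_to_reef, q0, d_50, d_99)
    remaining = field * (1.0 - f)
    attracted_total = float((field - remaining).sum())
    return remaining, attracted_total


def redistribute(
    remaining: np.ndarray,
    attracted_total: float,
    weight_field: np.ndarray,
    overlap_rule: OverlapRule = "additive",
) -> np.ndarray:
    """Lay the attracted biomass back down around the destination reef.

    ``weight_field`` is the exponential biomass surface around the
    destination reef; cell ``i`` receives ``attracted_total * w_i`` with
    ``w_i = weight_i / sum(weights)``. Under the default additive rule the
    system total is conserved exactly; under the literal "max" rule a cell
    holding biomass from both reefs keeps only the larger contribution,
    which breaks conservation.
    """
    remaining = np.asarray(remaining, dtype=np.float64)
    weight_field = np.asarray(weight_field, dtype=np.float64)
    if remaining.shape != weight_field.shape:
        raise ValueError(
            f"field shape {remaining.shape} does not match weights {weight_field.shape}"
        )
    total_w = weight_field.sum()
    if not total_w > 0:
        raise ValueError("redistribution weights sum to zero; degenerate destination field")
    incoming = attracted_total * (weight_field / total_w)
    if overlap_rule == "additive":
        return remaining + incoming
    if overlap_rule == "max":
        return np.maximum(remaining, incoming)
    raise ValueError(f"unknown overlap_rule {overlap_rule!r}")


def _deploy(
    before: np.ndarray, layout: ReefLayout, params: ScenarioParams
) -> AttractionOutcome:
    """Shared second stage: attract ``before`` toward the AR and redistribute."""
    grid = layout.grid
    dist_ar = distance_field(grid, layout.artificial_cells)
    remaining, attracted_total = apply_attraction(
        before, dist_ar, q0_from_q(params.q), params.d_50, params.d_99
    )
    ar_weights = resident_field(dist_ar, params.d_h)
    after = redistribute(remaining, attracted_total, ar_weights, params.overlap_rule)
    total_before = float(before.sum())
    attracted_fraction = attracted_total / total_before if total_before > 0 else 0.0
    return AttractionOutcome(
        before=before,
        remaining=remaining,
        after=after,
        attracted_total=attracted_total,
        attracted_fraction=attracted_fraction,
    )


def deploy_for_residents(layout: ReefLayout, params: ScenarioParams) -> AttractionOutcome:
    """Full deployment sequence for reef residents.

    Biomass starts distributed exponentially around the natural reef
    (1.0 on reef cells), is attracted toward the artificial reef, and the
    attracted total is redistributed around the artificial reef.
    """
    if params.group != "resident":
        raise ValueError(f"expected resident params, got group={params.group!r}")
    grid = layout.grid
    before = resident_field(distance_field(grid, layout.natural_cells), params.d_h)
    return _deploy(before, layout, params)


def deploy_for_pelagics(layout: ReefLayout, params: ScenarioParams) -> AttractionOutcome:
    """Two-stage deployment for reef-associated pelagics.

    Pelagic biomass starts uniform (1.0 per cell, reef or not). Stage one
    attracts it to the natural reef with quality ``q_nr`` (default 1) and
    redistributes around the NR; that state is the pre-deployment baseline.
    Stage two attracts toward the artificial reef with quality ``q`` and
    redistributes around the AR. Every cell, including natural-reef cells,
    is subject to stage-two attraction.
    """
    if params.group != "pelagic":
        raise ValueError(f"expected pelagic params, got group={params.group!r}")
    grid = layout.grid
    uniform = np.ones(grid.shape, dtype=np.float64)
    dist_nr = distance_field(grid, layout.natural_cells)
    remaining1, attracted1 = apply_attraction(
        uniform, dist_nr, q0_from_q(params.q_nr), params.d_50, params.d_99
    )
    nr_weights = resident_field(dist_nr, params.d_h)
    before = redistribute(remaining1, attracted1, nr_weights, params.overlap_rule)
    return _deploy(before, layout, params)


def deploy(layout: ReefLayout, params: ScenarioParams) -> AttractionOutcome:
    """Dispatch on functional group."""
    if params.group == "resident":
        return deploy_for_residents(layout, params)
    return deploy_for_pelagics(layout, params)
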