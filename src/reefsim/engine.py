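"""Scenario engine: single runs, factorial sweeps and named presets.

A scenario wires the spatial layout, the biomass attraction model for the
chosen functional group and the gravity-model harvest into one
deterministic evaluation. Sweeps evaluate a bivariate grid of scenarios
and return a tidy long-format table (one row per scenario); heat-map
panels are pivots of that table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .biomass import AttractionOutcome, ScenarioParams, deploy
from .grid import place_reefs
from .harvest import CatchModel, DEFAULT_THRESHOLD_LEVEL, HarvestResult, cpue_ratio

__all__ = [
    "ScenarioResult",
    "run_scenario",
    "sweep",
    "sweep_preset",
    "PRESETS",
    "SWEEPABLE",
    "TABLE1_LEVELS",
]

#: Standard simulation levels for each varied parameter.
TABLE1_LEVELS: dict[str, tuple] = {
    "d_h": (10, 15, 20, 25, 30, 35, 40),
    "q": tuple(range(1, 11)),
    "d_50": (100, 150, 200, 250, 300),
    "d_r_step": tuple(range(1, 13)),
    "s_r": (1, 2, 3),
    "p": (2, 5, 10, 20, 30, 40, 50, 70, 100),
}

#: Parameters a sweep axis may range over.
SWEEPABLE = ("d_h", "q", "d_50", "d_r_step", "s_r", "p", "q_nr")


@dataclass(frozen=True)
class ScenarioResult:
    """Outcome of one scenario: attraction outcome plus harvest metrics."""

    params: ScenarioParams
    outcome: AttractionOutcome
    harvest: HarvestResult
    realized_d_r: float

    @property
    def attracted_fraction(self) -> float:
        return self.outcome.attracted_fraction

    @property
    def ratio(self) -> float:
        return self.harvest.ratio

    def to_record(self) -> dict:
        p = self.params
        return {
            "group": p.group,
            "s_r": p.s_r,
            "d_r_step": p.d_r_step,
            "d_r_m": self.realized_d_r,
            "q": p.q,
            "q_nr": p.q_nr,
            "d_h": p.d_h,
            "d_50": p.d_50,
            "d_99": p.d_99,
            "p": p.p,
            "catch_model": self.harvest.catch_model,
            "attracted_fraction": self.attracted_fraction,
            "cpue_b": self.harvest.cpue_b,
            "cpue_a": self.harvest.cpue_a,
            "ratio": self.harvest.ratio,
        }


def run_scenario(
    params: ScenarioParams,
    catch_model: CatchModel = "linear",
    threshold_level: float = DEFAULT_THRESHOLD_LEVEL,
) -> ScenarioResult:
    """Evaluate one scenario end to end. Deterministic given ``params``."""
    layout = place_reefs(params.grid, params.s_r, params.d_r_step)
    outcome = deploy(layout, params)
    harvest = cpue_ratio(outcome, params.p, catch_model, threshold_level)
    return ScenarioResult(
        params=params, outcome=outcome, harvest=harvest, realized_d_r=layout.d_r
    )


def sweep(
    base: ScenarioParams,
    axis1: tuple[str, Sequence],
    axis2: tuple[str, Sequence] | None = None,
    catch_model: CatchModel = "linear",
    threshold_level: float = DEFAULT_THRESHOLD_LEVEL,
) -> pd.DataFrame:
    """Factorial sweep over one or two parameter axes.

    Returns one row per level combination (axis1 outer, axis2 inner), in
    long format. Results are independent of evaluation order. Sweeping
    ``d_50`` re-derives ``d_99 = 2 * d_50`` at every level.
    """
    name1, levels1 = axis1
    name2, levels2 = axis2 if axis2 is not None else (None, [None])
    for name in (name1, name2):
        if name is not None and name not in SWEEPABLE:
            raise ValueError(f"unknown sweep parameter {name!r}; valid: {SWEEPABLE}")
    if name1 == name2:
        raise ValueError("sweep axes must name distinct parameters")
    if len(levels1) == 0 or len(levels2) == 0:
        raise ValueError("sweep axes must have at least one level")

    records = []
    for v1 in levels1:
        for v2 in levels2:
            changes = {name1: v1}
            if name2 is not None:
                changes[name2] = v2
            result = run_scenario(base.with_updates(**changes), catch_model, threshold_level)
            records.append(result.to_record())
    return pd.DataFrame.from_records(records)


def _resident_base(**kw) -> dict:
    base = dict(group="resident", d_h=10, d_50=300, p=5, q=5)
    base.update(kw)
    return base


def _pelagic_base(**kw) -> dict:
    base = dict(group="pelagic", d_h=20, d_50=200, p=5, q=5, q_nr=1)
    base.update(kw)
    return base


#: Named sweep presets reproducing the standard result panels: attracted
#: fraction and CPUE ratio over (reef separation x quality) at each natural
#: reef size, and over (fidelity x effort) at a fixed mid-range separation;
#: the S-variants rerun the harvest with the threshold catch model.
PRESETS: dict[str, dict] = {}


def _register_presets() -> None:
    dr_q = (("d_r_step", TABLE1_LEVELS["d_r_step"]), ("q", TABLE1_LEVELS["q"]))
    dh_p = (("d_h", TABLE1_LEVELS["d_h"]), ("p", TABLE1_LEVELS["p"]))
    PRESETS["fig3A"] = dict(base=_resident_base(s_r=2), axes=dr_q, catch_model="linear")
    PRESETS["fig3B"] = dict(base=_pelagic_base(s_r=2), axes=dr_q, catch_model="linear")
    for panel, s_r in zip("ACE", (1, 2, 3)):
        PRESETS[f"fig4{panel}"] = dict(
            base=_resident_base(s_r=s_r), axes=dr_q, catch_model="linear"
        )
        PRESETS[f"fig5{panel}"] = dict(
            base=_pelagic_base(s_r=s_r), axes=dr_q, catch_model="linear"
        )
    for panel, s_r in zip("BDF", (1, 2, 3)):
        PRESETS[f"fig4{panel}"] = dict(
            base=_resident_base(s_r=s_r, q=7, d_r_step=3), axes=dh_p, catch_model="linear"
        )
        PRESETS[f"fig5{panel}"] = dict(
            base=_pelagic_base(s_r=s_r, q=7, d_r_step=3), axes=dh_p, catch_model="linear"
        )
    # threshold-CPUE variants of the same panels
    for name in list(PRESETS):
        if name.startswith("fig4"):
            PRESETS["figS1" + name[-1]] = {**PRESETS[name], "catch_model": "threshold"}
        elif name.startswith("fig5"):
            PRESETS["figS2" + name[-1]] = {**PRESETS[name], "catch_model": "threshold"}


_register_presets()


def sweep_preset(name: str, **overrides) -> pd.DataFrame:
    """Run a named preset sweep; ``overrides`` patch the base parameters."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    spec = PRESETS[name]
    base = ScenarioParams(**{**spec["base"], **overrides})
    return sweep(base, *spec["axes"], catch_model=spec["catch_model"])
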