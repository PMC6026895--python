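"""Operating-cost and productivity metrics for the self-cycling process.

Costs accrue per cycle from three line items: hourly operation (personnel,
maintenance, utilities), liquid-medium preparation per litre of fresh
medium, and substrate per gram dissolved in that medium.  Harvested and
discarded streams carry no credit or disposal cost.  The headline figure
for process optimization is the cost per phage particle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from .process import CycleRecord, ProcessSpec

__all__ = ["CostModel", "CycleEconomics", "cycle_cost", "economics_summary"]


@dataclass(frozen=True)
class CostModel:
    """Unit cost rates.  Defaults reflect current list prices at common
    suppliers for medium components at pilot scale.

    ``operation_rate`` in $/h, ``substrate_cost`` in $/g of substrate,
    ``medium_cost`` in $/L of prepared, sterilized liquid medium.
    """

    operation_rate: float = 40.0
    substrate_cost: float = 0.1
    medium_cost: float = 15.0

    def __post_init__(self) -> None:
        if min(self.operation_rate, self.substrate_cost, self.medium_cost) < 0:
            raise ValueError("cost rates must be non-negative")


@dataclass(frozen=True)
class CycleEconomics:
    """Per-cycle cost and productivity at steady state.

    Identities: ``cost_per_hour = cost_per_cycle / cycle_time``,
    ``phages_per_hour = phages_per_cycle / cycle_time`` and
    ``cost_per_phage = cost_per_cycle / phages_per_cycle`` (infinite when
    no phage is harvested).
    """

    cost_per_cycle: float
    cost_per_hour: float
    cost_per_phage: float
    phages_per_cycle: float
    phages_per_hour: float
    degenerate: bool = False  # True when the cycle harvested no phage


def cycle_cost(record: CycleRecord, spec: ProcessSpec, costs: CostModel) -> float:
    """Operating cost ($) of one cycle.

    ``operation_rate * cycle_time + medium_cost * fresh medium volume +
    substrate_cost * substrate mass``, where volume (L) and mass (g) cover
    the fresh-medium additions of both vessels for the cycle.
    """
    return (
        costs.operation_rate * spec.cycle_time
        + costs.medium_cost * record.fresh_medium_total
        + costs.substrate_cost * record.substrate_mass_added
    )


def economics_summary(
    records: Sequence[CycleRecord], spec: ProcessSpec, costs: CostModel
) -> CycleEconomics:
    """Steady-state economics computed from the final cycle's record.

    A cycle with zero harvest is flagged degenerate and reported with
    infinite cost per phage (with a warning) rather than raising, so that
    optimization sweeps can rank such scenarios as maximally unfavourable.
    """
    if not records:
        raise ValueError("no cycle records supplied")
    last = records[-1]
    cost = cycle_cost(last, spec, costs)
    phages = last.harvested_phages
    if phages > 0:
        cost_per_phage = cost / phages
        degenerate = False
    else:
        warnings.warn(
            "no phages harvested in the final cycle; cost per phage is undefined",
            stacklevel=2,
        )
        cost_per_phage = math.inf
        degenerate = True
    return CycleEconomics(
        cost_per_cycle=cost,
        cost_per_hour=cost / spec.cycle_time,
        cost_per_phage=cost_per_phage,
        phages_per_cycle=phages,
        phages_per_hour=phages / spec.cycle_time,
        degenerate=degenerate,
    )
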