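"""Two-stage self-cycling process: growth vessel feeding an infection vessel.

The first reactor (SCF, self-cycling fermentation) repeatedly grows an
uninfected batch culture; the second (SCI, self-cycling infection) receives
the grown broth and produces phage by lytic infection.  Liquid handling is
driven by level sensors: each vessel cycles between its low (LLS) and high
(HLS) level sensors, and the SCI additionally has a mid-level sensor (MLS)
marking how much grown broth it accepts before being topped up with fresh
medium.

Between cycling events both vessels behave as constant-volume batch
reactors (``phagecycle.kinetics``).  A cycling event is instantaneous:

1. harvest the SCI down to its LLS (the harvested stream is the product);
2. drain the SCF down to its LLS;
3. transfer the drained broth into the SCI up to at most the MLS,
   discarding any excess;
4. top the SCI up to its HLS with fresh medium;
5. refill the SCF to its HLS with fresh medium.

Streams mix ideally and instantaneously; fresh medium carries substrate
only.  Flow is strictly one-way, so phage can never contaminate the growth
vessel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .kinetics import (
    BatchState,
    BatchTrajectory,
    DiscretizedInfection,
    KineticParameters,
    simulate_batch_ode,
)

__all__ = [
    "ReactorSpec",
    "ProcessSpec",
    "ReactorState",
    "CycleRecord",
    "ProcessResult",
    "SteadyStateSummary",
    "cycling_event",
    "simulate_process",
    "steady_state_summary",
]

#: mL per L — concentrations are per mL while working volumes are in L.
ML_PER_L = 1000.0


@dataclass(frozen=True)
class ReactorSpec:
    """Level-sensor geometry and feed for one vessel.

    ``hls``/``lls`` (and ``mls`` for the infection vessel) are working
    volumes in litres; ``influent_substrate`` is the substrate
    concentration of the fresh medium supplied to this vessel (ug/mL).
    """

    hls: float
    lls: float
    influent_substrate: float
    mls: float | None = None

    def __post_init__(self) -> None:
        if self.lls <= 0 or self.hls <= 0:
            raise ValueError("sensor levels must be positive volumes")
        if self.mls is not None:
            if not (self.lls < self.mls <= self.hls):
                raise ValueError(
                    f"levels must satisfy LLS < MLS <= HLS, "
                    f"got LLS={self.lls}, MLS={self.mls}, HLS={self.hls}"
                )
        elif not self.lls < self.hls:
            raise ValueError(f"LLS must lie below HLS, got LLS={self.lls}, HLS={self.hls}")
        if self.influent_substrate < 0:
            raise ValueError("influent substrate concentration must be non-negative")


@dataclass(frozen=True)
class ProcessSpec:
    """Complete two-vessel process definition.

    ``cycle_time`` is the batch phase length between cycling events (h);
    the process runs for ``n_cycles`` cycles.  Initial conditions default
    to the standard start-up: the growth vessel full at its HLS with fresh
    medium and a small inoculum, the infection vessel at its LLS holding a
    phage solution and no bacteria.
    """

    scf: ReactorSpec
    sci: ReactorSpec
    cycle_time: float
    n_cycles: int = 45
    initial_inoculum: float = 1e6  # cells/mL in the growth vessel at start
    initial_phage: float = 1e8  # particles/mL in the infection vessel at start

    def __post_init__(self) -> None:
        if self.cycle_time <= 0:
            raise ValueError(f"cycle_time must be positive, got {self.cycle_time}")
        if self.n_cycles < 1:
            raise ValueError(f"n_cycles must be >= 1, got {self.n_cycles}")
        if self.sci.mls is None:
            raise ValueError("the infection vessel requires a mid-level sensor (mls)")


@dataclass
class ReactorState:
    """Liquid volume (L) plus the concentrations of the vessel contents."""

    volume: float
    contents: BatchState


@dataclass(frozen=True)
class CycleRecord:
    """Bookkeeping of one cycling event (volumes in L, amounts absolute)."""

    cycle: int
    harvest_volume: float
    harvest_phage_concentration: float  # particles/mL
    harvested_phages: float  # = harvest_volume * 1000 * concentration
    transfer_volume: float
    discarded_volume: float
    fresh_medium_scf: float
    fresh_medium_sci: float
    substrate_mass_added: float  # g, across both fresh-medium streams

    @property
    def fresh_medium_total(self) -> float:
        return self.fresh_medium_scf + self.fresh_medium_sci


def _mix(state: BatchState, volume: float, added: BatchState, added_volume: float) -> BatchState:
    """Ideal instantaneous mixing of two streams (volumes in L)."""
    if added_volume <= 0:
        return replace(state, XI=state.XI.copy())
    total = volume + added_volume
    w0, w1 = volume / total, added_volume / total
    return BatchState(
        S=w0 * state.S + w1 * added.S,
        XS=w0 * state.XS + w1 * added.XS,
        XI=w0 * state.XI + w1 * added.XI,
        P=w0 * state.P + w1 * added.P,
    )


def cycling_event(
    scf: ReactorState, sci: ReactorState, spec: ProcessSpec, cycle: int = 0
) -> tuple[ReactorState, ReactorState, CycleRecord]:
    """Apply one instantaneous harvest/transfer/refill sequence.

    Removal steps leave concentrations unchanged (well-mixed withdrawal);
    additions mix ideally.  If the drained growth-vessel broth does not
    reach the infection vessel's MLS, all of it is transferred and the
    fresh-medium top-up starts from the actual level, so both vessels
    always return exactly to their HLS.  Species amounts are conserved
    across the streams: remaining + harvested + discarded = before + added.
    """
    transfer_capacity = spec.scf.hls - spec.scf.lls
    if transfer_capacity <= 0:
        raise ValueError("growth vessel LLS must lie below its HLS")

    # 1. harvest the infection vessel down to its LLS
    harvest_volume = max(sci.volume - spec.sci.lls, 0.0)
    harvest_conc = sci.contents.P
    sci_vol = sci.volume - harvest_volume
    sci_contents = replace(sci.contents, XI=sci.contents.XI.copy())

    # 2. drain the growth vessel down to its LLS
    drained = max(scf.volume - spec.scf.lls, 0.0)
    scf_vol = scf.volume - drained
    broth = scf.contents

    # 3. transfer drained broth into the SCI up to at most the MLS
    assert spec.sci.mls is not None
    transfer = min(drained, spec.sci.mls - sci_vol)
    transfer = max(transfer, 0.0)
    discard = drained - transfer
    sci_contents = _mix(sci_contents, sci_vol, broth, transfer)
    sci_vol += transfer

    # 4. fresh medium into the SCI up to its HLS
    fresh_sci = spec.sci.hls - sci_vol
    medium_sci = BatchState.empty(*broth.XI.shape, S=spec.sci.influent_substrate)
    sci_contents = _mix(sci_contents, sci_vol, medium_sci, fresh_sci)
    sci_vol += fresh_sci

    # 5. fresh medium into the SCF up to its HLS
    fresh_scf = spec.scf.hls - scf_vol
    medium_scf = BatchState.empty(*broth.XI.shape, S=spec.scf.influent_substrate)
    scf_contents = _mix(scf.contents, scf_vol, medium_scf, fresh_scf)
    scf_vol += fresh_scf

    substrate_mass = (
        fresh_scf * spec.scf.influent_substrate + fresh_sci * spec.sci.influent_substrate
    ) * ML_PER_L * 1e-6  # ug -> g

    record = CycleRecord(
        cycle=cycle,
        harvest_volume=harvest_volume,
        harvest_phage_concentration=harvest_conc,
        harvested_phages=harvest_volume * ML_PER_L * harvest_conc,
        transfer_volume=transfer,
        discarded_volume=discard,
        fresh_medium_scf=fresh_scf,
        fresh_medium_sci=fresh_sci,
        substrate_mass_added=substrate_mass,
    )
    return (
        ReactorState(scf_vol, scf_contents),
        ReactorState(sci_vol, sci_contents),
        record,
    )


@dataclass
class ProcessResult:
    """Outcome of a multi-cycle process simulation."""

    records: list[CycleRecord]
    scf_final: ReactorState
    sci_final: ReactorState
    scf_trajectories: list[BatchTrajectory] = field(default_factory=list)
    sci_trajectories: list[BatchTrajectory] = field(default_factory=list)


def simulate_process(
    spec: ProcessSpec,
    params: KineticParameters,
    disc: DiscretizedInfection,
    *,
    record_trajectories: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-2,
    samples_per_cycle: int = 25,
) -> ProcessResult:
    """Run the two-stage process for ``spec.n_cycles`` cycles.

    Each cycle integrates both vessels as independent batches for
    ``cycle_time`` and then applies one :func:`cycling_event`.  The first
    event finds the infection vessel still at its LLS, so its harvest
    volume is zero; from the second event on both vessels start each event
    at their HLS.  Integration failures are re-raised with the cycle index.
    """
    M, N = disc.M, disc.N
    scf = ReactorState(
        spec.scf.hls,
        BatchState.empty(M, N, S=spec.scf.influent_substrate, XS=spec.initial_inoculum),
    )
    sci = ReactorState(spec.sci.lls, BatchState.empty(M, N, P=spec.initial_phage))

    t_eval = np.linspace(0.0, spec.cycle_time, samples_per_cycle + 1)
    records: list[CycleRecord] = []
    scf_traj: list[BatchTrajectory] = []
    sci_traj: list[BatchTrajectory] = []

    for cycle in range(1, spec.n_cycles + 1):
        try:
            tr_scf = simulate_batch_ode(
                scf.contents, params, disc, spec.cycle_time, t_eval=t_eval, rtol=rtol, atol=atol
            )
            tr_sci = simulate_batch_ode(
                sci.contents, params, disc, spec.cycle_time, t_eval=t_eval, rtol=rtol, atol=atol
            )
        except RuntimeError as exc:
            raise RuntimeError(f"integration failed during cycle {cycle}: {exc}") from exc
        scf = ReactorState(scf.volume, tr_scf.final_state())
        sci = ReactorState(sci.volume, tr_sci.final_state())
        if record_trajectories:
            scf_traj.append(tr_scf)
            sci_traj.append(tr_sci)
        scf, sci, record = cycling_event(scf, sci, spec, cycle=cycle)
        records.append(record)

    return ProcessResult(
        records=records,
        scf_final=scf,
        sci_final=sci,
        scf_trajectories=scf_traj,
        sci_trajectories=sci_traj,
    )


@dataclass(frozen=True)
class SteadyStateSummary:
    """Steady-state metrics extracted from the tail of a cycle series."""

    harvested_phages: float  # final cycle, absolute count
    harvest_phage_concentration: float  # particles/mL
    harvest_volume: float  # L
    converged: bool
    relative_change: float  # spread of harvest counts over the window


def steady_state_summary(
    records: Sequence[CycleRecord], window: int = 5, threshold: float = 1e-3
) -> SteadyStateSummary:
    """Check cycle-to-cycle convergence of the harvest and report the last cycle.

    The process is flagged converged when the relative spread
    ``(max - min) / max`` of the harvested-phage count over the final
    ``window`` cycles falls below ``threshold``.  Non-convergence is
    reported, not fatal.
    """
    if len(records) < window + 1:
        raise ValueError(f"need at least {window + 1} cycles, got {len(records)}")
    counts = np.array([r.harvested_phages for r in records[-(window + 1):]])
    peak = float(np.max(np.abs(counts)))
    rel = float((counts.max() - counts.min()) / peak) if peak > 0 else 0.0
    last = records[-1]
    return SteadyStateSummary(
        harvested_phages=last.harvested_phages,
        harvest_phage_concentration=last.harvest_phage_concentration,
        harvest_volume=last.harvest_volume,
        converged=rel < threshold,
        relative_change=rel,
    )
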