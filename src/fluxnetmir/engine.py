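"""Petri-net simulation and Flux Comparative Analysis (FCA).

The engine implements a discrete-step token-flow semantics. At every time
step the reactions are visited sequentially in pinned id order; a reaction's
speed follows the mass-action law

    S = k * prod([reactant]) * prod([enzyme]) * prod(iKd / [I]) / eKd

(absent enzymes contribute factor 1; an inhibitor with [I] = 0 contributes
factor 1; eKd defaults to 1 when absent). The reaction fires only when the
limiting (minimum-concentration) product is below the limiting reactant and
the speed is below 75 % of the limiting reactant, in which case S tokens are
added to every product and removed from every consumed reactant. Enzymes and
templates are never consumed. Updates are in-place within a step, so
reaction i sees the effects of reaction i-1 — the reason the reaction order
is pinned.

A state is steady at step t (t >= window) when every species satisfies
|C_j,t - C_j,t-window| <= tol with the default window 5 and tolerance 0.001.
The absolute value is used so that slow oscillating decline is also caught.

FCA simulates an untreated (control) and a drug-treated copy of the same
initialized model and reports, per hallmark readout, the fold change
P = readout under treatment / readout under control. P < 1 means the
treatment drains the hallmark — the signature of a responder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .model import MolecularModel, Reaction
from .drugs import DrugSpec, apply_treatment

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "FCAResult",
    "reaction_speed",
    "step",
    "simulate_to_steady",
    "run_fca",
]


@dataclass
class SimulationConfig:
    """Knobs of the discrete-step simulator.

    max_steps: hard iteration cap; non-convergence is reported, never raised.
    steady_window / steady_tol: steady when no species moved more than
        ``steady_tol`` over the last ``steady_window`` steps.
    firing_cap_fraction: a reaction may consume at most this fraction of its
        limiting reactant in one step.
    record_trajectory: keep per-step concentration snapshots and fired
        reaction speeds (memory-heavy; off by default).
    """

    max_steps: int = 10_000
    steady_window: int = 5
    steady_tol: float = 0.001
    firing_cap_fraction: float = 0.75
    record_trajectory: bool = False

    def __post_init__(self) -> None:
        if self.max_steps < 1 or self.steady_window < 1:
            raise ValueError("max_steps and steady_window must be >= 1")
        if self.steady_tol <= 0 or self.firing_cap_fraction <= 0:
            raise ValueError("steady_tol and firing_cap_fraction must be > 0")


@dataclass
class SimulationResult:
    """Outcome of one run to steady state."""

    final: dict[str, float]
    steps_taken: int
    reached_steady: bool
    total_inflow: dict[str, float]
    trajectory: list[dict[str, float]] | None = None
    fired: list[list[tuple[str, float]]] | None = None

    def readout_value(self, species_id: str) -> float:
        """Steady-state token count of a readout species."""
        return self.final[species_id]

    def readout_flux(self, species_id: str) -> float:
        """Cumulative inflow (summed incident fired speeds) into a species."""
        return self.total_inflow[species_id]


@dataclass
class FCAResult:
    """Per-readout fold change of treatment over control.

    ``P[readout]`` is treatment / control steady token count; ``None`` when
    the control readout is zero (flagged in ``warnings``).
    """

    P: dict[str, float | None]
    control: SimulationResult
    treatment: SimulationResult
    drug: str
    warnings: list[str] = field(default_factory=list)

    def responder_call(self, readout: str) -> str:
        from .scoring import classify_responder

        p = self.P[readout]
        if p is None:
            raise ValueError(f"P undefined for readout {readout!r}")
        return classify_responder(p)


def _inhibitor_factor(inh, state, treatment_context) -> float:
    if inh.ref in state:
        conc = state[inh.ref]
    elif treatment_context and inh.ref in treatment_context:
        conc = treatment_context[inh.ref]
    elif inh.conc is not None:
        conc = inh.conc
    else:
        conc = 0.0
    return inh.ikd / conc if conc > 0 else 1.0


def reaction_speed(reaction: Reaction, state, treatment_context=None) -> float:
    """Mass-action speed of a reaction in a given concentration state.

    ``state`` maps species id to concentration; ``treatment_context``
    optionally maps non-species inhibitor names (drugs) to concentrations,
    overriding the concentration stored on the inhibitor annotation.
    """
    s = reaction.k
    for ref in reaction.reactants:
        c = state[ref]
        if c < 0:
            raise RuntimeError(f"negative concentration for {ref!r}: invariant violated")
        s *= c
    for ref in reaction.enzymes:
        c = state[ref]
        if c < 0:
            raise RuntimeError(f"negative concentration for {ref!r}: invariant violated")
        s *= c
    for inh in reaction.inhibitors:
        s *= _inhibitor_factor(inh, state, treatment_context)
    if reaction.ekd is not None:
        s /= reaction.ekd
    return s


def _compile(model: MolecularModel, treatment_context=None):
    """Lower reactions onto integer-indexed tuples for the inner loop."""
    sids = list(model.species)
    idx = {sid: i for i, sid in enumerate(sids)}
    creactions = []
    for rx in sorted(model.reactions, key=lambda r: r.id):
        inhs = []
        for inh in rx.inhibitors:
            if inh.ref in idx:
                inhs.append((idx[inh.ref], inh.ikd, None))
            else:
                conc = inh.conc
                if treatment_context and inh.ref in treatment_context:
                    conc = treatment_context[inh.ref]
                inhs.append((None, inh.ikd, 0.0 if conc is None else conc))
        creactions.append(
            (
                rx.id,
                [idx[r] for r in rx.reactants],
                [idx[p] for p in rx.products],
                [idx[e] for e in rx.enzymes],
                inhs,
                rx.k,
                rx.ekd,
            )
        )
    return sids, idx, creactions


def _fire_all(creactions, state: list[float], cap: float, record=None, inflow=None):
    """One sweep over all reactions with sequential in-place updates."""
    for rid, ridx, pidx, eidx, inhs, k, ekd in creactions:
        s = k
        for i in ridx:
            s *= state[i]
        for i in eidx:
            s *= state[i]
        for i, ikd, conc in inhs:
            c = state[i] if i is not None else conc
            if c > 0:
                s *= ikd / c
        if ekd is not None:
            s /= ekd
        # guard drivers: limiting reactant, or limiting enzyme/template for
        # pure-source reactions (e.g. transcription from a gene template)
        if ridx:
            la = min(state[i] for i in ridx)
        elif eidx:
            la = min(state[i] for i in eidx)
        else:
            continue
        lp = min((state[i] for i in pidx), default=0.0)
        if lp < la and s < la * cap:
            for i in ridx:
                state[i] -= s
            for i in pidx:
                state[i] += s
                if inflow is not None:
                    inflow[i] += s
            if record is not None:
                record.append((rid, s))


def step(model: MolecularModel, state: dict[str, float], config: SimulationConfig | None = None):
    """Advance one time step; returns (next_state, fired) without mutating ``state``.

    ``fired`` lists (reaction id, speed) for every reaction that fired, in
    firing order.
    """
    config = config or SimulationConfig()
    sids, idx, creactions = _compile(model)
    vec = [state[sid] for sid in sids]
    fired: list[tuple[str, float]] = []
    _fire_all(creactions, vec, config.firing_cap_fraction, record=fired)
    return {sid: vec[i] for i, sid in enumerate(sids)}, fired


def simulate_to_steady(
    model: MolecularModel,
    config: SimulationConfig | None = None,
    treatment_context=None,
) -> SimulationResult:
    """Iterate the firing rule from the model's concentrations to steady state.

    Stops at the first step t >= steady_window at which no species changed
    by more than steady_tol relative to step t - steady_window, or at
    max_steps (``reached_steady`` is False in that case).
    """
    config = config or SimulationConfig()
    sids, idx, creactions = _compile(model, treatment_context)
    state = [model.species[sid].concentration for sid in sids]
    n = len(state)
    window = config.steady_window
    tol = config.steady_tol
    history: list[list[float]] = [state.copy()]  # history[t] = state after t steps
    inflow = [0.0] * n
    trajectory = [dict(zip(sids, state))] if config.record_trajectory else None
    fired_log: list[list[tuple[str, float]]] | None = [] if config.record_trajectory else None

    steps_taken = 0
    reached = False
    for t in range(1, config.max_steps + 1):
        record = [] if config.record_trajectory else None
        _fire_all(
            creactions, state, config.firing_cap_fraction, record=record, inflow=inflow
        )
        steps_taken = t
        if config.record_trajectory:
            trajectory.append(dict(zip(sids, state)))
            fired_log.append(record)
        history.append(state.copy())
        if len(history) > window + 1:
            history.pop(0)
        if t >= window:
            old = history[0]
            if all(abs(state[i] - old[i]) <= tol for i in range(n)):
                reached = True
                break
    else:
        logger.warning("simulation did not reach steady state in %d steps", config.max_steps)

    return SimulationResult(
        final=dict(zip(sids, state)),
        steps_taken=steps_taken,
        reached_steady=reached,
        total_inflow=dict(zip(sids, inflow)),
        trajectory=trajectory,
        fired=fired_log,
    )


def run_fca(
    model: MolecularModel,
    drug: DrugSpec,
    readouts: list[str] | None = None,
    config: SimulationConfig | None = None,
    inhibitor_conc: float = 1.0,
) -> FCAResult:
    """Flux Comparative Analysis: control vs. treatment from one initial state.

    The model must already carry an individual's expression values as
    initial concentrations. ``inhibitor_conc`` is the administered drug
    concentration in token units. Returns per-readout
    P = treatment steady value / control steady value.
    """
    config = config or SimulationConfig()
    readouts = list(readouts) if readouts is not None else list(model.readouts)
    warnings: list[str] = []

    control = simulate_to_steady(model, config)
    treated_model = apply_treatment(model, drug, inhibitor_conc)
    treatment = simulate_to_steady(treated_model, config)

    if not control.reached_steady:
        warnings.append("control state did not converge; P computed from final state")
    if not treatment.reached_steady:
        warnings.append("treatment state did not converge; P computed from final state")

    P: dict[str, float | None] = {}
    for rid in readouts:
        c = control.final[rid]
        tval = treatment.final[rid]
        if c > 0:
            P[rid] = tval / c
        else:
            P[rid] = None
            warnings.append(f"control readout {rid!r} is zero; P undefined")
    for w in warnings:
        logger.warning("%s", w)
    return FCAResult(P=P, control=control, treatment=treatment, drug=drug.name, warnings=warnings)
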