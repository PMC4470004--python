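"""Simulation engine: speed law, firing rule, steady state, FCA."""

import random

import pytest

from fluxnetmir.drugs import DrugSpec, DrugTarget
from fluxnetmir.engine import (
    SimulationConfig,
    reaction_speed,
    run_fca,
    simulate_to_steady,
    step,
)
from fluxnetmir.model import (
    Compartment,
    Inhibitor,
    MolecularModel,
    Reaction,
    ReactionType,
    Species,
    SpeciesKind,
)
from _reference import naive_trajectory, random_net


def _species(model, sid, conc=0.0, kind=SpeciesKind.PROTEIN):
    model.add_species(Species(sid, sid, kind, Compartment.CYTOPLASM, conc))


def _catalyzed_reaction(ikd=None, ekd=None, k=0.01):
    model = MolecularModel()
    _species(model, "a", 10.0)
    _species(model, "e", 2.0)
    _species(model, "p", 0.0)
    inhibitors = [] if ikd is None else [Inhibitor(ref="drug", ikd=ikd, conc=None)]
    model.add_reaction(
        Reaction(
            id="r1",
            rtype=ReactionType.PHOSPHORYLATION,
            reactants=["a"],
            products=["p"],
            enzymes=["e"],
            inhibitors=inhibitors,
            k=k,
            ekd=ekd,
        )
    )
    return model


class TestReactionSpeed:
    def test_mass_action_with_enzyme(self):
        model = _catalyzed_reaction()
        state = {"a": 10.0, "e": 2.0, "p": 0.0}
        assert reaction_speed(model.reactions[0], state) == pytest.approx(0.2)

    def test_inhibitor_at_ikd_is_neutral(self):
        model = _catalyzed_reaction(ikd=0.65)
        state = {"a": 10.0, "e": 2.0, "p": 0.0}
        s = reaction_speed(model.reactions[0], state, treatment_context={"drug": 0.65})
        assert s == reaction_speed(_catalyzed_reaction().reactions[0], state)

    def test_inhibitor_at_twice_ikd_halves_speed(self):
        model = _catalyzed_reaction(ikd=0.65)
        state = {"a": 10.0, "e": 2.0, "p": 0.0}
        s = reaction_speed(model.reactions[0], state, treatment_context={"drug": 1.3})
        assert s == 0.5 * reaction_speed(_catalyzed_reaction().reactions[0], state)

    def test_absent_inhibitor_contributes_factor_one(self):
        model = _catalyzed_reaction(ikd=0.65)  # conc resolves to 0
        state = {"a": 10.0, "e": 2.0, "p": 0.0}
        assert reaction_speed(model.reactions[0], state) == pytest.approx(0.2)

    def test_ekd_divides_speed(self):
        model = _catalyzed_reaction(ekd=4.0)
        state = {"a": 10.0, "e": 2.0, "p": 0.0}
        assert reaction_speed(model.reactions[0], state) == pytest.approx(0.05)

    def test_negative_concentration_aborts(self):
        model = _catalyzed_reaction()
        with pytest.raises(RuntimeError, match="negative"):
            reaction_speed(model.reactions[0], {"a": -1.0, "e": 2.0, "p": 0.0})


class TestStep:
    def test_hand_traced_firing(self):
        """Guard (0 < 10 and 0.2 < 7.5) passes: p += S, a -= S."""
        model = _catalyzed_reaction()
        nxt, fired = step(model, {"a": 10.0, "e": 2.0, "p": 0.0})
        assert nxt == pytest.approx({"a": 9.8, "e": 2.0, "p": 0.2})
        assert fired == [("r1", pytest.approx(0.2))]

    def test_product_guard_blocks(self):
        model = _catalyzed_reaction()
        state = {"a": 10.0, "e": 2.0, "p": 12.0}
        nxt, fired = step(model, state)
        assert nxt == state and fired == []

    def test_speed_cap_guard_blocks(self):
        model = _catalyzed_reaction(k=0.45)  # S = 9 > 7.5 = 0.75 * 10
        state = {"a": 10.0, "e": 2.0, "p": 0.0}
        nxt, fired = step(model, state)
        assert nxt == state and fired == []

    def test_sequential_updates_within_step(self):
        """Reaction r2 sees r1's effect in the same sweep."""
        model = MolecularModel()
        for sid, c in (("a", 8.0), ("b", 0.0), ("c", 0.0)):
            _species(model, sid, c)
        model.add_reaction(
            Reaction(id="r1", rtype=ReactionType.TRANSLOCATION, reactants=["a"], products=["b"], k=0.5)
        )
        model.add_reaction(
            Reaction(id="r2", rtype=ReactionType.TRANSLOCATION, reactants=["b"], products=["c"], k=0.5)
        )
        nxt, _ = step(model, {"a": 8.0, "b": 0.0, "c": 0.0})
        # r1 moves 4.0 into b; r2 then moves 2.0 of that into c
        assert nxt == {"a": 4.0, "b": 2.0, "c": 2.0}


class TestSteadyState:
    def test_no_fireable_reactions_steady_at_window(self):
        model = _catalyzed_reaction()
        model.species["a"].concentration = 10.0
        model.species["e"].concentration = 0.0  # enzyme absent: S = 0 fires as no-op
        model.species["p"].concentration = 12.0  # and product guard blocks anyway
        res = simulate_to_steady(model, SimulationConfig())
        assert res.reached_steady and res.steps_taken == 5
        assert res.final == {"a": 10.0, "e": 0.0, "p": 12.0}

    def test_two_species_transfer_matches_naive_trace_exactly(self):
        model = MolecularModel()
        _species(model, "a", 10.0)
        _species(model, "b", 0.0)
        model.add_reaction(
            Reaction(id="r1", rtype=ReactionType.TRANSLOCATION, reactants=["a"], products=["b"], k=0.01)
        )
        config = SimulationConfig(max_steps=1000, record_trajectory=True)
        res = simulate_to_steady(model, config)
        ref = naive_trajectory(model, res.steps_taken)
        for mine, theirs in zip(res.trajectory, ref):
            assert mine == theirs  # bit-identical

    def test_decaying_chain_converges_within_tolerance(self):
        model = MolecularModel()
        _species(model, "a", 20.0)
        _species(model, "b", 0.0)
        model.add_reaction(
            Reaction(id="r1", rtype=ReactionType.TRANSLOCATION, reactants=["a"], products=["b"], k=0.05)
        )
        model.add_reaction(
            Reaction(id="r2", rtype=ReactionType.DECAY, reactants=["b"], k=0.1)
        )
        config = SimulationConfig(record_trajectory=True)
        res = simulate_to_steady(model, config)
        assert res.reached_steady and res.steps_taken < 10_000
        last, lag = res.trajectory[-1], res.trajectory[-6]
        assert all(abs(last[s] - lag[s]) <= config.steady_tol for s in last)

    def test_max_steps_exhaustion_is_flagged_not_raised(self):
        model = MolecularModel()
        _species(model, "g", 10.0, kind=SpeciesKind.GENE)
        _species(model, "m", 0.0, kind=SpeciesKind.MRNA)
        model.add_reaction(
            Reaction(id="tx", rtype=ReactionType.TRANSCRIPTION, enzymes=["g"], products=["m"], k=0.01)
        )
        res = simulate_to_steady(model, SimulationConfig(max_steps=20))
        assert not res.reached_steady and res.steps_taken == 20

    @pytest.mark.parametrize("seed", range(25))
    def test_oracle_equivalence_on_random_nets(self, seed):
        """Engine trajectories are bit-identical to the naive simulator."""
        model = random_net(random.Random(seed))
        config = SimulationConfig(max_steps=300, steady_tol=1e-15, record_trajectory=True)
        res = simulate_to_steady(model, config)
        ref = naive_trajectory(model, res.steps_taken)
        assert res.trajectory == ref

    def test_mass_conservation_in_closed_transfer_net(self):
        model = MolecularModel()
        for sid, c in (("a", 7.0), ("b", 3.0), ("c", 0.0)):
            _species(model, sid, c)
        model.add_reaction(
            Reaction(id="r1", rtype=ReactionType.TRANSLOCATION, reactants=["a"], products=["b"], k=0.2)
        )
        model.add_reaction(
            Reaction(id="r2", rtype=ReactionType.TRANSLOCATION, reactants=["b"], products=["c"], k=0.1)
        )
        model.add_reaction(
            Reaction(id="r3", rtype=ReactionType.TRANSLOCATION, reactants=["c"], products=["a"], k=0.3)
        )
        res = simulate_to_steady(model, SimulationConfig(max_steps=2000, record_trajectory=True))
        for snap in res.trajectory:
            assert abs(sum(snap.values()) - 10.0) <= 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_non_negativity(self, seed):
        rng = random.Random(1000 + seed)
        model = random_net(rng)
        res = simulate_to_steady(model, SimulationConfig(max_steps=500, record_trajectory=True))
        for snap in res.trajectory:
            assert all(v >= 0.0 for v in snap.values())

    def test_determinism_bit_identical(self):
        model = random_net(random.Random(77))
        config = SimulationConfig(max_steps=400, record_trajectory=True)
        r1 = simulate_to_steady(model, config)
        r2 = simulate_to_steady(model, config)
        assert r1.trajectory == r2.trajectory and r1.final == r2.final


def _cascade_with_kinase():
    """gene-driven chain whose only hallmark feed is kinase-catalyzed."""
    model = MolecularModel(readouts=["hallmark"])
    _species(model, "g", 10.0, kind=SpeciesKind.GENE)
    _species(model, "m", 0.0, kind=SpeciesKind.MRNA)
    _species(model, "p", 0.0)
    _species(model, "pp", 0.0)
    _species(model, "kin", 0.0)
    _species(model, "gkin", 8.0, kind=SpeciesKind.GENE)
    _species(model, "mkin", 0.0, kind=SpeciesKind.MRNA)
    _species(model, "hallmark", 0.0, kind=SpeciesKind.PSEUDO_OBJECT)
    model.add_reaction(Reaction(id="tx", rtype=ReactionType.TRANSCRIPTION, enzymes=["g"], products=["m"], k=0.005))
    model.add_reaction(Reaction(id="tl", rtype=ReactionType.TRANSLATION, reactants=["m"], products=["p"], k=0.01))
    model.add_reaction(Reaction(id="txk", rtype=ReactionType.TRANSCRIPTION, enzymes=["gkin"], products=["mkin"], k=0.005))
    model.add_reaction(Reaction(id="tlk", rtype=ReactionType.TRANSLATION, reactants=["mkin"], products=["kin"], k=0.01))
    model.add_reaction(Reaction(id="dck", rtype=ReactionType.DECAY, reactants=["kin"], k=0.02))
    model.add_reaction(Reaction(id="ph", rtype=ReactionType.PHOSPHORYLATION, reactants=["p"], products=["pp"], enzymes=["kin"], k=0.002))
    model.add_reaction(Reaction(id="dcp", rtype=ReactionType.DECAY, reactants=["p"], k=0.02))
    model.add_reaction(Reaction(id="act", rtype=ReactionType.ACTIVATION, reactants=["pp"], products=["hallmark"], k=0.005))
    model.add_reaction(Reaction(id="dch", rtype=ReactionType.DECAY, reactants=["hallmark"], k=0.5))
    model.sort_reactions()
    return model


class TestFCA:
    def test_no_target_drug_gives_p_exactly_one(self):
        model = _cascade_with_kinase()
        drug = DrugSpec("nothingib", (DrugTarget("ABSENT", 1.0),))
        res = run_fca(model, drug)
        assert res.P["hallmark"] == 1.0

    def test_inhibiting_sole_feeding_kinase_reduces_p(self):
        model = _cascade_with_kinase()
        drug = DrugSpec("kinib", (DrugTarget("kin", 1.0),))
        res = run_fca(model, drug, inhibitor_conc=2.0)
        assert res.P["hallmark"] < 1.0

    def test_dose_doubling_strictly_reduces_p(self):
        model = _cascade_with_kinase()
        drug = DrugSpec("kinib", (DrugTarget("kin", 1.0),))
        p2 = run_fca(model, drug, inhibitor_conc=2.0).P["hallmark"]
        p4 = run_fca(model, drug, inhibitor_conc=4.0).P["hallmark"]
        assert p4 < p2

    def test_zero_control_readout_flagged_undefined(self):
        model = _cascade_with_kinase()
        model.species["g"].concentration = 0.0
        model.species["gkin"].concentration = 0.0
        drug = DrugSpec("kinib", (DrugTarget("kin", 1.0),))
        res = run_fca(model, drug)
        assert res.P["hallmark"] is None
        assert any("undefined" in w for w in res.warnings)
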