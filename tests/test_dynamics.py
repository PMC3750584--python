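import itertools
import math

import numpy as np
import pytest

from oracles import brute_step, count_orderings

from timkit import (
    BooleanNetwork,
    DirectionalPathway,
    PathwayStructure,
    apply_inhibition,
    boolean_sensitivity,
    count_models,
    experiment_bounds,
    generate_pathway,
    pathway_to_bn,
    structure_to_pathway,
    tim_from_bn,
)


@pytest.fixture
def converging_pair() -> DirectionalPathway:
    # two mutated upstream kinases converge (OR) on the tumor driver
    return DirectionalPathway(
        targets=("K1", "K2", "K3"),
        activations={"K3": ("K1", "K2")},
        mutated=frozenset({"K1", "K2"}),
        drivers=frozenset({"K3"}),
    )


class TestTransitionRules:
    def test_transient_activation_decays_then_reignites(self, converging_pair):
        bn = pathway_to_bn(converging_pair)
        # K3 active alone: phenotype turns on, K3 decays, mutations rise
        assert bn.decode(bn.step(bn.encode("0010"))) == "1101"
        # two steps later the mutations have re-activated K3
        s = bn.step(bn.step(bn.encode("0010")))
        assert bn.decode(s) == "1110"

    def test_no_mutations_keeps_all_zeros_fixed(self):
        pw = DirectionalPathway(
            targets=("A", "B"), activations={"B": ("A",)}, drivers=frozenset({"B"})
        )
        bn = pathway_to_bn(pw)
        zero = bn.encode("000")
        assert bn.step(zero) == zero

    def test_step_matches_per_bit_rule_oracle_on_random_pathways(self, rng):
        for _ in range(25):
            names = tuple(f"K{i}" for i in range(4))
            acts = {}
            for i in range(1, 4):  # acyclic: parents only among earlier targets
                k = int(rng.integers(0, i + 1))
                if k:
                    acts[names[i]] = tuple(
                        names[j] for j in rng.choice(i, size=k, replace=False)
                    )
            gates = {n: ("AND" if rng.random() < 0.3 else "OR") for n in names}
            pw = DirectionalPathway(
                targets=names,
                activations=acts,
                gates=gates,
                mutated=frozenset(n for n in names if rng.random() < 0.4),
                drivers=frozenset({names[-1]}),
            )
            inhibited = frozenset(n for n in names if rng.random() < 0.25)
            bn = BooleanNetwork(pw, inhibited)
            for state in range(bn.n_states):
                bits = {n: bn._target_bit(state, n) for n in names}
                bits["tumor"] = state & 1
                expected = brute_step(bits, pw, set(inhibited))
                got = bn.step(state)
                for i, n in enumerate(names):
                    assert got >> (i + 1) & 1 == expected[n]
                assert got & 1 == expected["tumor"]

    def test_cyclic_activation_rejected(self):
        with pytest.raises(ValueError, match="acyclic"):
            DirectionalPathway(
                targets=("A", "B"),
                activations={"A": ("B",), "B": ("A",)},
                drivers=frozenset({"B"}),
            )


class TestInhibition:
    def test_inhibiting_the_driver_clears_the_tumor(self, converging_pair):
        bn = apply_inhibition(pathway_to_bn(converging_pair), ["K3"])
        cycle = bn.attractor()
        assert [bn.decode(s) for s in cycle] == ["1100"]
        assert not bn.tumorous()

    def test_inhibiting_one_upstream_branch_fails(self, converging_pair):
        bn = apply_inhibition(pathway_to_bn(converging_pair), ["K2"])
        cycle = bn.attractor()
        assert [bn.decode(s) for s in cycle] == ["1011"]
        assert bn.tumorous()

    def test_empty_inhibition_is_identity(self, converging_pair):
        bn = pathway_to_bn(converging_pair)
        same = apply_inhibition(bn, [])
        assert same.transition_vector() == bn.transition_vector()

    def test_idempotent(self, converging_pair):
        bn = pathway_to_bn(converging_pair)
        once = apply_inhibition(bn, ["K1"])
        twice = apply_inhibition(once, ["K1"])
        assert once.transition_vector() == twice.transition_vector()

    def test_inhibiting_everything_clears_any_tumor(self, rng):
        for seed in range(10):
            pw = structure_to_pathway(generate_pathway(int(rng.integers(2, 7)), seed=seed))
            bn = BooleanNetwork(pw, frozenset(pw.targets))
            assert not bn.tumorous()


class TestTimFromBN:
    def test_three_target_map_matches_biology(self, converging_pair):
        tim = tim_from_bn(pathway_to_bn(converging_pair))
        value = {  # bit i inhibits target i (K1, K2, K3)
            "K3": tim.predict(0b100),
            "K1K2": tim.predict(0b011),
            "K1": tim.predict(0b001),
            "K2": tim.predict(0b010),
            "none": tim.predict(0b000),
        }
        assert value["K3"] == 1.0 and value["K1K2"] == 1.0
        assert value["K1"] == value["K2"] == value["none"] == 0.0

    def test_monotone_for_promoter_pathways(self, rng):
        for seed in range(10):
            structure = generate_pathway(int(rng.integers(2, 7)), seed=100 + seed)
            tim = tim_from_bn(pathway_to_bn(structure_to_pathway(structure)))
            n = tim.n
            for p in range(1 << n):
                for i in range(n):
                    q = p | (1 << i)
                    assert tim.predict(p) <= tim.predict(q)

    def test_matches_block_cut_semantics_for_all_combinations(self):
        # cross-module consistency: dynamics attractors vs static cuts
        for seed in range(8):
            structure = generate_pathway(5, seed=seed)
            pw = structure_to_pathway(structure)
            tim = tim_from_bn(pathway_to_bn(pw))
            active = sorted(structure.active_targets)
            for pattern in range(1 << len(active)):
                profile = np.zeros(structure.n_universe, dtype=np.uint8)
                for i, t in enumerate(active):
                    if pattern >> i & 1:
                        profile[t] = 1
                assert tim.predict(pattern) == boolean_sensitivity(profile, structure)

    def test_exhaustive_mode_guard(self):
        pw = structure_to_pathway(generate_pathway(5, seed=1))
        bn = pathway_to_bn(pw)
        with pytest.raises(ValueError, match="sample"):
            tim_from_bn(bn, max_targets=3)

    def test_upstream_state_separates_model_orientations(self):
        # same steady-state map, opposite flow: inhibiting the hub tells
        # them apart through the upstream target's steady state
        forward = DirectionalPathway(  # K1, K2 -> K3
            targets=("K1", "K2", "K3"),
            activations={"K3": ("K1", "K2")},
            mutated=frozenset({"K1", "K2"}),
            drivers=frozenset({"K3"}),
        )
        reverse = DirectionalPathway(  # K3 -> K1, K2
            targets=("K1", "K2", "K3"),
            activations={"K1": ("K3",), "K2": ("K3",)},
            mutated=frozenset({"K3"}),
            drivers=frozenset({"K3"}),
        )
        fwd = BooleanNetwork(forward, frozenset({"K3"}))
        rev = BooleanNetwork(reverse, frozenset({"K3"}))
        k1 = lambda bn: bn._target_bit(bn.attractor()[0], "K1")
        assert k1(fwd) == 1  # K1 upstream: stays mutated-active
        assert k1(rev) == 0  # K1 downstream of the silenced hub


class TestCounting:
    def test_single_target_structure_has_one_model(self):
        s = PathwayStructure(blocks=(((0,),),), n_universe=1)
        assert count_models(s) == 1

    def test_two_serial_two_target_lines(self):
        s = PathwayStructure(blocks=(((0, 1),), ((2, 3),)), n_universe=4)
        assert count_models(s) == 2 * 2 * 2  # L! * prod b!

    def test_matches_enumeration_on_small_structures(self, rng):
        for seed in range(20):
            structure = generate_pathway(int(rng.integers(1, 7)), seed=seed)
            assert count_models(structure) == count_orderings(structure.blocks)


class TestExperimentBounds:
    def test_two_blocks_expected_one_experiment(self):
        s = PathwayStructure(blocks=(((0,),), ((1,),)), n_universe=2)
        assert experiment_bounds(s).ne_expected == pytest.approx(1.0)

    def test_single_block_costs_nothing_serially(self):
        s = PathwayStructure(blocks=(((0, 1), (2,)),), n_universe=3)
        assert experiment_bounds(s).ne_expected == 0.0

    def test_formula_term_by_term(self):
        # two blocks: {lines (3,2)} and {line (2,)}
        s = PathwayStructure(blocks=(((0, 1, 2), (3, 4)), ((5, 6),)), n_universe=7)
        plan = experiment_bounds(s)
        b1 = max(3 - 2, math.ceil((5 - 2) / 1) - 1, 0)  # = 2
        b2 = max(2 - 2, 0)  # single-line block: only the line-length term
        assert plan.ne_worst_bound == pytest.approx(max(b1, b2) + 1)
        a1 = max((2 * 3 - 4) / 3, math.ceil((10 - 2) / 3) - 1, 0)
        a2 = max((2 * 2 - 4) / 3, 0)
        assert plan.ne_avg_bound == pytest.approx(max(a1, a2) + 1.0)
        assert plan.model_count == count_models(s)

    def test_nonnegative_and_worst_dominates_under_multiline_blocks(self):
        # the clamped bounds satisfy worst >= averaged whenever every
        # block has >= 2 lines averaging >= 2 targets
        rng = np.random.default_rng(0)
        for _ in range(300):
            L = int(rng.integers(1, 4))
            blocks = []
            cursor = 0
            for _ in range(L):
                a = int(rng.integers(2, 4))
                lines = []
                for _ in range(a):
                    b = int(rng.integers(2, 5))
                    lines.append(tuple(range(cursor, cursor + b)))
                    cursor += b
                blocks.append(tuple(lines))
            s = PathwayStructure(blocks=tuple(blocks), n_universe=cursor)
            plan = experiment_bounds(s)
            assert plan.ne_worst_bound >= 0 and plan.ne_avg_bound >= 0
            assert plan.ne_worst_bound >= plan.ne_avg_bound - 1e-9
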