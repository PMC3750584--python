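import itertools

import numpy as np
import pytest

from conftest import make_drugs, random_screen
from oracles import brute_bounds

from timkit import (
    TIM,
    DrugProfile,
    InconsistentDataWarning,
    TargetSet,
    build_tim,
    combine_inhibitions,
    continuous_inhibition,
    sffs_select,
    threshold_profile,
    write_tim_json,
    read_tim_json,
)


def random_tim(rng, n, n_known=None, monotone=False) -> TIM:
    n_known = n_known if n_known is not None else int(rng.integers(0, 2**n // 2 + 1))
    pats = rng.choice(2**n, size=n_known, replace=False) if n_known else []
    if monotone:
        # draw values consistent with subset ordering: value = fraction of
        # a random weight mass covered by the pattern
        w = rng.random(n) + 0.05
        known = {
            int(p): float(min(1.0, sum(w[i] for i in range(n) if p >> i & 1) / w.sum()))
            for p in pats
        }
    else:
        known = {int(p): float(np.round(rng.random(), 3)) for p in pats}
    return TIM(members=tuple(range(n)), known=known)


class TestBounds:
    def test_known_pattern_is_its_own_bracket(self):
        tim = TIM(members=(0, 1, 2), known={0b011: 0.7})
        b = tim.bounds(0b011)
        assert b.y_l == b.y_u == 0.7
        assert b.c_l == b.c_u == 0b011

    def test_empty_known_set_uses_boundary(self):
        tim = TIM(members=(0, 1, 2, 3), known={})
        b = tim.bounds(0b0101)
        assert (b.y_l, b.y_u) == (0.0, 1.0)
        assert (b.c_l, b.c_u) == (0, 0b1111)
        assert b.h == 4

    def test_matches_exhaustive_scan_on_random_tims(self, rng):
        for _ in range(60):
            tim = random_tim(rng, 5)
            for pattern in range(32):
                if pattern in tim.known:
                    continue
                b = tim.bounds(pattern)
                y_l, y_u = brute_bounds(pattern, tim.known, 5)
                assert (b.y_l, b.y_u) == (y_l, y_u)


class TestInference:
    def test_interpolation_endpoints(self):
        # d = 0 gives the lower anchor, d = h the upper
        tim = TIM(members=(0, 1, 2), known={0b001: 0.2, 0b111: 0.8})
        assert tim.predict(0b001) == pytest.approx(0.2)
        assert tim.predict(0b111) == pytest.approx(0.8)

    def test_linear_interpolation_hand_value(self):
        # y_l=0.2, y_u=0.8, h=3, d=1, n=1: 0.2 + 0.6/3 = 0.4
        tim = TIM(members=tuple(range(4)), known={0b0001: 0.2, 0b1111: 0.8})
        assert tim.predict(0b0011) == pytest.approx(0.4)

    def test_two_target_worked_example(self):
        tim = TIM(members=(0, 1), known={0b01: 0.6})
        table = tim.materialize()
        assert table == pytest.approx({0: 0.0, 0b01: 0.6, 0b10: 0.5, 0b11: 1.0})

    def test_uniform_weights_reduce_to_unweighted_form(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 7))
            tim = random_tim(rng, n, monotone=True)
            w = float(rng.uniform(0.2, 5.0))
            weighted = TIM(members=tim.members, known=tim.known, weights=(w,) * n)
            p = int(rng.integers(0, 2**n))
            assert weighted.predict(p) == pytest.approx(tim.predict(p))

    def test_monotone_in_pattern_inclusion(self, rng):
        violations = []
        for _ in range(150):
            n = int(rng.integers(2, 6))
            tim = random_tim(rng, n, monotone=True)
            for p, q in itertools.combinations(range(2**n), 2):
                if p & q == p:
                    if tim.predict(p) > tim.predict(q) + 1e-9:
                        violations.append((tim.known, p, q))
        assert not violations

    def test_lower_discount_raises_interior_predictions(self):
        base = TIM(members=tuple(range(4)), known={}, discount=1.0)
        optimistic = TIM(members=tuple(range(4)), known={}, discount=0.5)
        for p in range(1, 15):  # strictly interior patterns
            assert optimistic.predict(p) > base.predict(p)

    def test_inconsistent_data_is_clamped_with_warning(self):
        # known subset 001 (0.9) out-scores known superset 111 (0.1):
        # the in-between pattern clamps to the lower anchor
        tim = TIM(members=(0, 1, 2), known={0b001: 0.9, 0b111: 0.1})
        with pytest.warns(InconsistentDataWarning):
            y = tim.predict(0b011)
        assert y == pytest.approx(0.9)
        assert tim.known[0b111] == 0.1  # the violation stays at the data

    def test_dense_and_lazy_agree(self, rng):
        tim = random_tim(rng, 10, n_known=40, monotone=True)
        lazy = TIM(members=tim.members, known=dict(tim.known))
        dense_table = tim.materialize()
        probe = rng.choice(2**10, size=64, replace=False)
        for p in probe:
            assert lazy.predict(int(p)) == dense_table[int(p)]

    def test_dense_cap_guard(self):
        big = TIM(members=tuple(range(31)), known={})
        with pytest.raises(ValueError, match="lazy"):
            big.materialize()


class TestBuildAndPredict:
    def test_known_entries_are_bin_means(self):
        drugs = make_drugs([[1, 0], [1, 0], [0, 1]], [0.2, 0.4, 1.0])
        tim = build_tim(drugs, TargetSet(members=(0, 1), score=0.0))
        assert tim.known[0b01] == pytest.approx(0.3)
        assert tim.known[0b10] == pytest.approx(1.0)

    def test_withheld_drug_matching_a_bin_gets_its_mean(self):
        drugs = make_drugs([[1, 0], [1, 0], [0, 1]], [0.2, 0.4, 1.0])
        tim = build_tim(drugs, TargetSet(members=(0, 1), score=0.0))
        (probe,) = make_drugs([[1, 0]], [0.9], prefix="new")
        assert tim.predict_drug(probe) == pytest.approx(0.3)

    def test_drug_missing_all_selected_targets_predicts_zero(self):
        drugs = make_drugs([[1, 0, 0], [0, 1, 0]], [1.0, 0.5])
        tim = build_tim(drugs, TargetSet(members=(0, 1), score=0.0))
        (probe,) = make_drugs([[0, 0, 1]], [0.7], prefix="new")
        assert tim.predict_drug(probe) == 0.0

    def test_loo_predictions_match_straight_reimplementation(self, rng):
        # independent re-derivation: bracket + linear ratio per pattern,
        # then an explicit full-subset max for the monotone closure
        def naive(pattern, entries, n):
            if pattern in entries:
                return entries[pattern]
            y_l = max(y for p, y in entries.items() if p & pattern == p)
            y_u = min(y for p, y in entries.items() if p | pattern == p)
            c_l = max(
                (p for p, y in entries.items() if p & pattern == p and y == y_l),
                key=lambda p: (p.bit_count(), -p),
            )
            c_u = min(
                (p for p, y in entries.items() if p | pattern == p and y == y_u),
                key=lambda p: (p.bit_count(), p),
            )
            if y_l > y_u:
                y_u = y_l
            h = (c_l ^ c_u).bit_count()
            d = (c_l ^ pattern).bit_count()
            return y_l if h == 0 else y_l + (y_u - y_l) * d / h

        def oracle(pattern, entries, n):
            if pattern in entries:
                return entries[pattern]
            return max(
                naive(s, entries, n) for s in range(pattern + 1) if s & pattern == s
            )

        drugs = random_screen(rng, 12, 5, discrete=True)
        tset = sffs_select(drugs)
        nT = len(tset.members)
        for held in drugs:
            train = [d for d in drugs if d.drug_id != held.drug_id]
            tim = build_tim(train, tset)
            pattern = sum(
                int(held.dtip[j]) << i for i, j in enumerate(tset.members)
            )
            entries = {0: 0.0, 2**nT - 1: 1.0}
            from timkit import bin_partition

            for b in bin_partition(train, tset.members).bins:
                entries[sum(v << i for i, v in enumerate(b.pattern))] = b.mean
            assert tim.predict(pattern) == pytest.approx(oracle(pattern, entries, nT))

    def test_json_round_trip(self, tmp_path, rng):
        tim = random_tim(rng, 4, n_known=5, monotone=True)
        path = tmp_path / "tim.json"
        write_tim_json(tim, path)
        back = read_tim_json(path)
        assert back.known == tim.known
        assert back.members == tim.members
        write_tim_json(tim, tmp_path / "tim2.json")
        assert (tmp_path / "tim2.json").read_text() == path.read_text()


class TestContinuousInhibition:
    def test_half_inhibition_at_ec50(self):
        z = continuous_inhibition({0: 50.0, 2: 500.0}, x=50.0, n_targets=3)
        assert z[0] == pytest.approx(0.5)
        assert z[1] == 0.0
        assert z[2] == pytest.approx(50 / 550)

    def test_dose_limits(self):
        lo = continuous_inhibition({0: 50.0}, x=1e-9, n_targets=1)[0]
        hi = continuous_inhibition({0: 50.0}, x=1e9, n_targets=1)[0]
        assert lo < 1e-6 and hi > 1 - 1e-6

    def test_combination_rule_against_direct_evaluation(self, rng):
        za = rng.random(6) * 0.9
        zb = rng.random(6) * 0.9
        joint = combine_inhibitions([za, zb])
        assert joint == pytest.approx(1 - (1 - za) * (1 - zb))
        assert np.all(joint >= np.maximum(za, zb) - 1e-12)

    def test_threshold_bridge(self):
        z = np.array([0.2, 0.5, 0.9])
        assert threshold_profile(z).tolist() == [0, 1, 1]
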