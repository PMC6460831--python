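import numpy as np
import pytest

from chidt.contingency import DegenerateTableError
from chidt.features import FeatureSpec, LabeledWindow, default_feature_specs, encode_batch
from chidt.model import (
    DecisionTable,
    DonorSiteModel,
    build_decision_table,
    classify,
    classify_rule,
    entropy,
    gain_ratio,
    information_gain,
    intrinsic_value,
    introduce_features,
    PartitionCell,
)
from oracles import entropy_reference, gain_reference, iv_reference


class TestEntropyAndGain:
    def test_entropy_values(self):
        assert entropy(50, 50) == pytest.approx(1.0)
        assert entropy(100, 0) == 0.0
        assert entropy(87, 1687) == pytest.approx(entropy_reference(87, 1687))
        assert entropy(87, 1687) == pytest.approx(0.2823, abs=5e-4)

    def test_entropy_empty_set(self):
        with pytest.raises(DegenerateTableError):
            entropy(0, 0)

    def test_gain_class_independent_feature(self):
        parent = [(50.0, 50.0)]
        refined = [(25.0, 25.0), (25.0, 25.0)]
        assert information_gain(parent, refined) == pytest.approx(0.0)

    def test_gain_perfect_separator(self):
        assert information_gain([(50.0, 50.0)], [(50.0, 0.0), (0.0, 50.0)]) == pytest.approx(1.0)

    def test_gain_worked_grouping_matches_oracle(self):
        parent = [(87.0, 1687.0)]
        refined = [(38.0, 184.0), (12.0, 1026.0), (26.0, 289.0), (11.0, 188.0)]
        assert information_gain(parent, refined) == pytest.approx(
            gain_reference(parent, refined), abs=1e-12
        )

    def test_gain_bounded_by_parent_entropy_random(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            parent = [(float(rng.integers(1, 50)), float(rng.integers(1, 50)))]
            k = rng.integers(2, 5)
            pos = rng.multinomial(int(parent[0][0]), np.ones(k) / k).astype(float)
            neg = rng.multinomial(int(parent[0][1]), np.ones(k) / k).astype(float)
            refined = list(zip(pos, neg))
            g = information_gain(parent, refined)
            assert -1e-12 <= g <= entropy(*parent[0]) + 1e-12

    def test_gain_rejects_mismatched_mass(self):
        with pytest.raises(ValueError):
            information_gain([(10.0, 10.0)], [(5.0, 5.0)])

    def test_intrinsic_value_and_ratio(self):
        assert intrinsic_value([25, 25, 25, 25]) == pytest.approx(2.0)
        assert gain_ratio(1.0, [50, 50]) == pytest.approx(1.0)
        sizes = [222, 1038, 315, 200]
        assert intrinsic_value(sizes) == pytest.approx(iv_reference(sizes), abs=1e-12)
        with pytest.raises(ValueError):
            gain_ratio(0.5, [100])  # single sub-cell: IV = 0


def _specs(n, domain=(0, 1)):
    return [FeatureSpec(f"f{k}", "categorical", tuple(domain)) for k in range(n)]


class TestFeatureIntroduction:
    def test_perfect_binary_separator(self):
        X = np.array([[0], [0], [1], [1]])
        y = np.array([True, True, False, False])
        introduced, cells = introduce_features(X, y, _specs(1), alpha=0.05)
        assert introduced == ["f0"]
        assert len(cells) == 2

    def test_class_independent_features(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(200, 3))
        y = np.concatenate([np.ones(100, bool), np.zeros(100, bool)])
        introduced, cells = introduce_features(X, y, _specs(3), alpha=0.01)
        assert introduced == []
        assert len(cells) == 1

    def test_one_class_training_set(self):
        X = np.zeros((5, 2), dtype=int)
        y = np.ones(5, bool)
        introduced, cells = introduce_features(X, y, _specs(2))
        assert introduced == [] and len(cells) == 1

    def test_matches_plain_reference_on_small_instances(self):
        """Same selection rule re-implemented naively gives the same model."""

        def reference(X, y, specs, alpha):
            # plain dict/list re-implementation of the introduction loop
            from chidt.contingency import ContingencyTable, compress

            cells = [list(range(len(y)))]
            conds = [[]]
            remaining = list(range(len(specs)))
            order = []
            while remaining:
                cand = {}
                for f in remaining:
                    splits, any_split = [], False
                    for idx in cells:
                        counts = np.zeros((2, len(specs[f].domain)))
                        for i in idx:
                            counts[0 if y[i] else 1, X[i, f]] += 1
                        out, _ = compress(
                            ContingencyTable(counts, [(s,) for s in specs[f].domain],
                                             ordinal=specs[f].ordinal), alpha)
                        if out.r < 2:
                            splits.append(None)
                            continue
                        any_split = True
                        lookup = {s: g for g, grp in enumerate(out.column_groups) for s in grp}
                        buckets = [[] for _ in out.column_groups]
                        for i in idx:
                            buckets[lookup[specs[f].domain[X[i, f]]]].append(i)
                        splits.append((out.column_groups, buckets))
                    if not any_split:
                        continue
                    refined = []
                    for idx, sp in zip(cells, splits):
                        parts = [idx] if sp is None else sp[1]
                        for part in parts:
                            p = sum(1 for i in part if y[i])
                            refined.append((float(p), float(len(part) - p)))
                    parent = [
                        (float(sum(1 for i in idx if y[i])),
                         float(sum(1 for i in idx if not y[i])))
                        for idx in cells
                    ]
                    g = gain_reference(parent, refined)
                    sizes = [p + q for p, q in refined if p + q > 0]
                    if len(sizes) < 2:
                        continue
                    cand[f] = (g, g / iv_reference(sizes), splits)
                if not cand:
                    break
                mean_g = sum(v[0] for v in cand.values()) / len(cand)
                eligible = [f for f, v in cand.items() if v[0] >= mean_g - 1e-12]
                best = max(eligible, key=lambda f: (cand[f][1], -f))
                new_cells, new_conds = [], []
                for idx, cnd, sp in zip(cells, conds, cand[best][2]):
                    if sp is None:
                        new_cells.append(idx)
                        new_conds.append(cnd)
                    else:
                        for grp, part in zip(*sp):
                            new_cells.append(part)
                            new_conds.append(cnd + [(specs[best].id, tuple(grp))])
                cells, conds = new_cells, new_conds
                order.append(specs[best].id)
                remaining.remove(best)
            return order, conds

        rng = np.random.default_rng(21)
        for trial in range(8):
            n = 60
            X = rng.integers(0, 3, size=(n, 3))
            planted = (X[:, 0] == 0) | (X[:, 1] == 2)
            y = planted ^ (rng.random(n) < 0.1)
            specs = [FeatureSpec(f"f{k}", "categorical", (0, 1, 2)) for k in range(3)]
            introduced, cells = introduce_features(X, y, specs, alpha=0.05)
            ref_order, ref_conds = reference(X, y, specs, 0.05)
            assert introduced == ref_order
            assert [c.conditions for c in cells] == ref_conds


class TestDecisionTable:
    def test_theta_reweighting_display(self, worked):
        theta = worked["theta_main"]
        assert round(47512 * theta, 1) == 350.5
        cell = PartitionCell([], np.arange(0), 5.0, 47512.0)
        cell2 = PartitionCell([], np.arange(0), 11.0, 368.0)
        dt = build_decision_table([cell, cell2], balanced=True, theta_override=theta)
        assert [round(b, 1) for b in dt.neg_weighted] == [350.5, 2.7]

    def test_worked_balanced_row(self, worked):
        dt = DecisionTable([[]] * 4, worked["table14"][0], worked["table14"][1],
                           worked["theta14"])
        assert np.round(dt.neg_weighted, 1).tolist() == [9.5, 52.9, 14.9, 9.7]

    def test_balanced_mass_equality(self, small_model):
        t = small_model.table
        assert t.neg_weighted.sum() == pytest.approx(t.pos_counts.sum())

    def test_theta_one_reproduces_raw_counts(self, small_model):
        flat = small_model.reweighted(1.0)
        np.testing.assert_array_equal(flat.table.neg_weighted, flat.table.neg_raw)

    def test_balanced_requires_negatives(self):
        cell = PartitionCell([], np.arange(0), 5.0, 0.0)
        with pytest.raises(ValueError):
            build_decision_table([cell], balanced=True)


class TestClassify:
    def test_worked_example_imbalanced(self, worked):
        dt = DecisionTable([[]] * 4, worked["table14"][0], worked["table14"][1], 1.0)
        p = classify_rule(dt, 3)
        assert p.chi2_pos == pytest.approx(109.2, abs=0.05)
        assert p.chi2_neg == pytest.approx(110.1, abs=0.05)
        assert not p.label  # wrongly negative under imbalance

    def test_worked_example_balanced(self, worked):
        dt = DecisionTable([[]] * 4, worked["table14"][0], worked["table14"][1],
                           worked["theta14"])
        p = classify_rule(dt, 3)
        assert p.chi2_pos == pytest.approx(46.2, abs=0.05)
        assert p.chi2_neg == pytest.approx(45.9, abs=0.05)
        assert p.label and p.score == pytest.approx(p.chi2_pos - p.chi2_neg)

    def test_single_rule_table_ties_negative(self):
        dt = DecisionTable([[]], np.array([5.0]), np.array([9.0]), 1.0)
        p = classify_rule(dt, 0)
        assert not p.label and p.score == 0.0

    def test_classify_routes_through_matching_rule(self, small_model):
        spec_ids = [s.id for s in small_model.specs]
        window = LabeledWindow("GAGGTAAGTAG"[:11], True)
        pred = classify(
            encode_batch([window], small_model.specs)[0][0],
            small_model.table,
            small_model.specs,
        )
        batch = small_model.predict([window])[0]
        assert pred.rule_index == batch.rule_index
        assert pred.label == batch.label


class TestModelStructure:
    def test_rule_exhaustiveness_random_windows(self, small_model):
        rng = np.random.default_rng(17)
        windows = [
            LabeledWindow("".join(rng.choice(list("ACGT"), 11)), False)
            for _ in range(100_000 // 10)
        ]
        X, _ = encode_batch(windows, small_model.specs)
        X = np.tile(X, (10, 1))  # 100k encoded samples
        idx = small_model.match_batch(X)
        assert (idx >= 0).all()
        # exclusivity: per-sample rule membership counts equal exactly 1
        spec_by_id = {s.id: k for k, s in enumerate(small_model.specs)}
        matches = np.zeros(len(X), dtype=int)
        for rule in small_model.table.rules:
            mask = np.ones(len(X), bool)
            for fid, group in rule:
                col = spec_by_id[fid]
                member = np.array([s in group for s in small_model.specs[col].domain])
                mask &= member[X[:, col]]
            matches += mask
        assert (matches == 1).all()

    def test_serialization_round_trip_bit_exact(self, small_model):
        text = small_model.to_json()
        back = DonorSiteModel.from_json(text)
        assert back.to_json() == text
        np.testing.assert_array_equal(back.table.pos_counts, small_model.table.pos_counts)
        np.testing.assert_array_equal(back.table.neg_raw, small_model.table.neg_raw)
        assert back.table.theta == small_model.table.theta
        assert back.table.rules == small_model.table.rules

    def test_fit_is_deterministic(self, strong_pwm):
        from chidt.model import fit
        from chidt.simulate import SimConfig, generate_dataset
        from conftest import windows_of

        records = generate_dataset(SimConfig(80, 240, seed=5), strong_pwm)
        m1 = fit(windows_of(records))
        m2 = fit(windows_of(records))
        assert m1.to_json() == m2.to_json()

    def test_predict_consistent_with_classify_on_duplicate(self, small_model):
        w = LabeledWindow("AAGGTAAGTCA", True)
        direct = classify(
            encode_batch([w], small_model.specs)[0][0],
            small_model.table,
            small_model.specs,
        )
        assert small_model.predict([w, w])[1].label == direct.label
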