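"""Relative qPCR quantification and windowed letter display."""
import itertools

import numpy as np
import pytest

from critweight import CtRecord, TimecourseSample, relative_expression, \
    windowed_letter_groups
from critweight.exceptions import ConfigError, InvariantError
from critweight.timecourse import insert_absorb_letters


def ct(gene, group, time, rep, dct, ref=18.0):
    return CtRecord(gene=gene, group=group, time=time, replicate=rep,
                    ct_target=ref + dct, ct_reference=ref)


class TestRelativeExpression:
    def test_two_cycle_advantage_is_fourfold(self):
        recs = [ct("g", "ctrl", 0.0, 0, 7.0), ct("g", "ctrl", 0.0, 1, 7.0),
                ct("g", "mut", 8.0, 0, 5.0)]
        rel = relative_expression(recs, ("ctrl", 0.0))
        by = {(r.group, r.time): r.value for r in rel}
        assert by[("mut", 8.0)] == pytest.approx(4.0)
        assert by[("ctrl", 0.0)] == pytest.approx(1.0)

    def test_calibrator_replicate_at_mean_is_one(self):
        recs = [ct("g", "ctrl", 0.0, 0, 6.0), ct("g", "ctrl", 0.0, 1, 8.0),
                ct("g", "ctrl", 0.0, 2, 7.0)]
        rel = relative_expression(recs, ("ctrl", 0.0))
        assert rel[2].value == pytest.approx(1.0)  # dCt 7 == calibrator mean

    def test_calibrator_geometric_mean_is_exactly_one(self):
        rng = np.random.default_rng(0)
        recs = [ct("g", "ctrl", 0.0, i, 7.0 + rng.normal(0, 0.3))
                for i in range(6)]
        rel = relative_expression(recs, ("ctrl", 0.0))
        log_mean = np.mean([np.log2(r.value) for r in rel])
        assert log_mean == pytest.approx(0.0, abs=1e-12)

    def test_uniform_target_shift_halves_values(self):
        recs = [ct("g", "ctrl", 0.0, 0, 7.0), ct("g", "mut", 8.0, 0, 5.0)]
        rel0 = relative_expression(recs, ("ctrl", 0.0))
        shifted = [CtRecord(r.gene, r.group, r.time, r.replicate,
                            r.ct_target + 1.0, r.ct_reference)
                   for r in [recs[1]]] + [recs[0]]
        rel1 = relative_expression(shifted, ("ctrl", 0.0))
        v0 = {(r.group, r.time): r.value for r in rel0}
        v1 = {(r.group, r.time): r.value for r in rel1}
        assert v1[("mut", 8.0)] == pytest.approx(v0[("mut", 8.0)] / 2.0)

    def test_reference_shift_invariance(self):
        recs = [ct("g", "ctrl", 0.0, 0, 7.0), ct("g", "mut", 8.0, 0, 4.5)]
        shifted = [CtRecord(r.gene, r.group, r.time, r.replicate,
                            r.ct_target + 3.0, r.ct_reference + 3.0)
                   for r in recs]
        v0 = [r.value for r in relative_expression(recs, ("ctrl", 0.0))]
        v1 = [r.value for r in relative_expression(shifted, ("ctrl", 0.0))]
        assert v0 == pytest.approx(v1, abs=1e-12)

    def test_absent_calibrator_is_config_error(self):
        with pytest.raises(ConfigError):
            relative_expression([ct("g", "mut", 8.0, 0, 5.0)], ("ctrl", 0.0))


def brute_force_consistent(letters, decisions):
    """Independent checker: letters agree with every tested pair's decision."""
    for pair, significant in decisions.items():
        a, b = sorted(pair)
        shared = set(letters[a]) & set(letters[b])
        if significant and shared:
            return False
        if not significant and not shared:
            return False
    return True


class TestLetterDisplay:
    def cells(self, values_by_cell):
        return [TimecourseSample(g, t, i, v)
                for (g, t), vals in values_by_cell.items()
                for i, v in enumerate(vals)]

    def test_identical_cells_share_a_letter(self):
        samples = self.cells({("wt", 0.0): [5.0, 5.0, 5.0],
                              ("wt", 2.0): [5.0, 5.0, 5.0]})
        out = windowed_letter_groups(samples)
        assert out.letters[("wt", 0.0)] == out.letters[("wt", 2.0)] == "a"

    def test_chain_ns_with_significant_ends(self):
        """A~B ns, B~C ns, A~C significant -> letters a / ab / b."""
        letters = insert_absorb_letters(
            ["A", "B", "C"], [frozenset(("A", "C"))])
        assert letters == {"A": "a", "B": "ab", "C": "b"}

    def test_all_pairs_significant_all_letters_distinct(self):
        samples = self.cells({("wt", 0.0): [1.0, 1.01, 0.99],
                              ("wt", 2.0): [10.0, 10.01, 9.99],
                              ("wt", 4.0): [20.0, 20.01, 19.99]})
        out = windowed_letter_groups(samples, window=4.0)
        vals = list(out.letters.values())
        assert len(set(vals)) == 3
        assert all(len(v) == 1 for v in vals)

    def test_window_limits_comparisons(self):
        samples = self.cells({("wt", 0.0): [1.0, 1.1], ("wt", 10.0): [9.0, 9.1]})
        out = windowed_letter_groups(samples, window=2.0)
        assert not out.decisions  # 10 hr apart: not compared
        out_all = windowed_letter_groups(samples, window=2.0, all_pairs=True)
        assert len(out_all.decisions) == 1

    def test_cross_group_compared_only_at_matched_times(self):
        samples = self.cells({("wt", 0.0): [1.0, 1.1], ("mut", 0.0): [9.0, 9.1],
                              ("mut", 4.0): [9.0, 9.2]})
        out = windowed_letter_groups(samples, window=2.0)
        tested = {tuple(sorted(p)) for p in out.decisions}
        assert (("mut", 0.0), ("wt", 0.0)) in tested
        assert (("mut", 4.0), ("wt", 0.0)) not in tested

    def test_underreplicated_cell_excluded_with_warning(self):
        samples = self.cells({("wt", 0.0): [1.0, 1.1], ("wt", 2.0): [1.0, 1.2],
                              ("wt", 4.0): [3.0]})
        with pytest.warns(UserWarning, match="< 2 replicates"):
            out = windowed_letter_groups(samples)
        assert ("wt", 4.0) not in out.letters

    def test_holm_flag_never_adds_significance(self):
        rng = np.random.default_rng(5)
        samples = self.cells({
            ("wt", 2.0 * k): list(rng.normal(5.0 + k, 1.0, 4)) for k in range(5)
        })
        raw = windowed_letter_groups(samples, window=4.0)
        adj = windowed_letter_groups(samples, window=4.0, holm=True)
        sig_raw = {p for p, d in raw.decisions.items() if d}
        sig_adj = {p for p, d in adj.decisions.items() if d}
        assert sig_adj <= sig_raw

    def test_consistency_on_random_decision_matrices(self):
        """insert-and-absorb output always matches the decision matrix."""
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = rng.integers(3, 8)
            cells = [f"c{i}" for i in range(n)]
            decisions = {}
            sig = []
            for a, b in itertools.combinations(cells, 2):
                d = bool(rng.random() < 0.4)
                decisions[frozenset((a, b))] = d
                if d:
                    sig.append(frozenset((a, b)))
            letters = insert_absorb_letters(cells, sig)
            assert all(letters.values())
            assert brute_force_consistent(letters, decisions)

    def test_verify_rejects_tampered_assignment(self):
        samples = self.cells({("wt", 0.0): [1.0, 1.01, 0.99],
                              ("wt", 2.0): [10.0, 10.01, 9.99]})
        out = windowed_letter_groups(samples)
        bad = type(out)(letters={k: "a" for k in out.letters},
                        decisions=out.decisions, alpha=out.alpha)
        with pytest.raises(InvariantError):
            bad.verify()

    def test_to_frame_layout(self):
        samples = self.cells({("wt", 0.0): [1.0, 1.1], ("wt", 2.0): [1.0, 1.2]})
        df = windowed_letter_groups(samples).to_frame()
        assert list(df.columns) == ["group", "time", "letters"]
        assert len(df) == 2
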