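"""Search-effort arithmetic, best-of-k convergence, hard-to-recover nodes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from degenphy import (
    BootstrapRun,
    SearchRun,
    best_of_k_supports,
    bipartitions,
    convergence_report,
    hard_to_recover_nodes,
    recovery_fraction,
    replicates_needed,
    sim_bootstrap_run,
    sim_tree,
    within_threshold_set,
)

from conftest import trees_from_newicks


def make_run(newicks, scores):
    trees = trees_from_newicks(newicks)
    return SearchRun(trees, scores)


class TestWithinThreshold:
    def test_relative_arithmetic(self):
        run = make_run(["((A,B),(C,D),E);", "((A,C),(B,D),E);"], [-100000.0, -100000.5])
        # 0.5/100000 = 5e-6: excluded at 1e-6, included at 1e-5
        assert within_threshold_set(run, 1e-6) == [0]
        assert within_threshold_set(run, 1e-5) == [0, 1]

    def test_zero_threshold_best_only(self):
        run = make_run(["((A,B),(C,D),E);"] * 3, [-10.0, -9.0, -9.5])
        assert within_threshold_set(run, 0.0) == [1]

    def test_threshold_one_all(self):
        run = make_run(["((A,B),(C,D),E);"] * 3, [-10.0, -9.0, -17.0])
        assert within_threshold_set(run, 1.0) == [0, 1, 2]

    def test_monotone_nesting(self):
        rng = np.random.default_rng(0)
        scores = list(-1000 - rng.uniform(0, 5, size=20))
        run = make_run(["((A,B),(C,D),E);"] * 20, scores)
        sets = [set(within_threshold_set(run, t)) for t in (0, 1e-4, 1e-3, 1e-2, 1)]
        for small, big in zip(sets, sets[1:]):
            assert small <= big


class TestRecoveryAndReplicatesNeeded:
    def test_printed_search_effort_values(self):
        """The worked examples: 1827 and 19 hits out of 4608 replicates."""
        assert replicates_needed(1827 / 4608, 0.95) == 6
        assert replicates_needed(19 / 4608, 0.95) == 725

    def test_p_equals_confidence(self):
        assert replicates_needed(0.95, 0.95) == 1

    def test_recovery_fraction_counts(self):
        run = make_run(["((A,B),(C,D),E);"] * 4, [-10.0, -10.0, -10.0, -10.0])
        assert recovery_fraction(run, 0.0) == 1.0
        run2 = make_run(
            ["((A,B),(C,D),E);"] * 10,
            [-10.0] * 2 + [-11.0] * 8,
        )
        assert recovery_fraction(run2, 1e-3) == pytest.approx(0.2)

    @settings(derandomize=True, max_examples=60)
    @given(
        p1=st.floats(0.01, 0.98),
        dp=st.floats(0.001, 0.01),
        c1=st.floats(0.5, 0.98),
        dc=st.floats(0.001, 0.01),
    )
    def test_monotonicity(self, p1, dp, c1, dc):
        assert replicates_needed(p1 + dp, c1) <= replicates_needed(p1, c1)
        assert replicates_needed(p1, c1 + dc) >= replicates_needed(p1, c1)

    def test_empirical_confidence(self):
        """Monte-Carlo: batches of size n contain a success about 95% of the time."""
        from degenphy import sim_search_replicates

        p = 19 / 4608
        n = replicates_needed(p, 0.95)
        outcomes = sim_search_replicates(p, n * 2000, seed=123).reshape(2000, n)
        hit_rate = (outcomes.any(axis=1)).mean()
        assert hit_rate == pytest.approx(0.95, abs=0.02)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            replicates_needed(0.0, 0.95)
        with pytest.raises(ValueError):
            replicates_needed(0.5, 1.0)


class TestHardToRecover:
    def test_single_replicate_all_present(self):
        run = make_run(["((A,B),(C,D),E);"], [-10.0])
        out = hard_to_recover_nodes(run, [0.0, 1e-3, 1.0])
        for thr, presence in out.items():
            assert all(presence.values())

    def test_differing_clade_absent(self):
        run = make_run(
            ["((A,B),(C,D),E);", "((A,C),(B,D),E);"], [-1000.0, -1000.001]
        )
        out = hard_to_recover_nodes(run, [0.0, 1e-4])
        cd = frozenset({"C", "D"})
        assert out[0.0][cd] is True  # only the best tree
        assert out[1e-4][cd] is False  # both trees admitted, split conflicts

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        newicks = ["((A,B),(C,D),E);"] * 6 + ["((A,C),(B,D),E);"] * 4
        scores = list(-1000 - rng.uniform(0, 1, 10))
        run = make_run(newicks, scores)
        thresholds = [0.0, 1e-5, 1e-4, 1e-3, 1]
        out = hard_to_recover_nodes(run, thresholds)
        # once absent at some threshold, absent at all looser ones:
        # the presence sequence over widening thresholds is non-increasing
        for split in bipartitions(run.trees[run.best]):
            presence = [int(out[t][split]) for t in thresholds]
            assert presence == sorted(presence, reverse=True)


class TestBestOfK:
    def _toy_run(self):
        reference = sim_tree(8, seed=5)
        return reference, sim_bootstrap_run(
            reference, n_pseudoreplicates=40, k=15, pi_true=0.8, q_find=0.3, seed=9
        )

    def test_full_k_reproduces_best_per_pseudoreplicate(self):
        reference, run = self._toy_run()
        table = best_of_k_supports(run, reference, ks=[15])
        from degenphy import bootstrap_support

        best_trees = []
        for pseudo in run.pseudoreplicates:
            best_idx = max(range(len(pseudo)), key=lambda i: (pseudo[i][1], -i))
            best_trees.append(pseudo[best_idx][0])
        expected = bootstrap_support(reference, best_trees)
        # frozenset keys are list-like to pandas .loc: go through a dict
        col = dict(zip(table.index, table[15]))
        for split, value in col.items():
            assert value == pytest.approx(expected[split])

    def test_identical_replicates_constant_in_k(self):
        reference = sim_tree(6, seed=2)
        run = sim_bootstrap_run(reference, 20, k=5, pi_true=0.7, q_find=1.0, seed=3)
        table = best_of_k_supports(run, reference, ks=[1, 3, 5])
        assert (table[1] == table[5]).all() and (table[3] == table[5]).all()

    def test_selected_scores_nondecreasing_in_k(self):
        _, run = self._toy_run()
        for pseudo in run.pseudoreplicates:
            best_scores = [
                max(s for _, s in pseudo[:k]) for k in range(1, len(pseudo) + 1)
            ]
            assert best_scores == sorted(best_scores)

    def test_k_exceeding_replicates_rejected(self):
        reference, run = self._toy_run()
        with pytest.raises(ValueError):
            best_of_k_supports(run, reference, ks=[16])


class TestConvergenceReport:
    def test_constant_table_empty(self):
        table = pd.DataFrame({1: [80.0], 5: [80.0], 15: [80.0]},
                             index=[frozenset({"A", "B"})])
        assert convergence_report(table, delta=5).empty

    def test_printed_butterflies_row(self):
        """Support profile 76, 81, 82, 83 at k = 1, 5, 10, 15: k=1 lags by 7."""
        table = pd.DataFrame(
            {1: [76.0], 5: [81.0], 10: [82.0], 15: [83.0]},
            index=[frozenset({"A", "B"})],
        )
        report = convergence_report(table, delta=5)
        assert list(report["k"]) == [1]
        assert report.iloc[0]["difference"] == pytest.approx(-7.0)

    def test_flag_count_matches_hand_scan(self):
        idx = [frozenset({f"x{i}", f"y{i}"}) for i in range(5)]
        table = pd.DataFrame(
            {
                1: [50, 60, 70, 80, 90],
                5: [58, 62, 74, 80, 95],
                15: [60, 63, 74, 81, 96],
            },
            index=idx,
            dtype=float,
        )
        report = convergence_report(table, delta=5)
        # hand scan: rows 0 (50 vs 60 at k=1, 58 vs 60 not >=5), 2 (70 vs 74 no),
        # 4 (90 vs 96 at k=1 is 6): flags at (row0,k1), (row4,k1)
        flagged = {(tuple(sorted(r.edge)), r.k) for r in report.itertuples()}
        assert flagged == {(("x0", "y0"), 1), (("x4", "y4"), 1)}
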