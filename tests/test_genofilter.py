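"""Coverage, IBS-pruning, locus and admixture filters."""

import numpy as np
import pandas as pd
import pytest

from larvaconnect.genofilter import (
    FilterConfig,
    assign_lineages,
    coverage_filter,
    ibs_distance,
    locus_filters,
    prune_relatives,
)
from larvaconnect.genotypes import GenotypeSimConfig, MISSING, simulate_genotypes


class TestCoverageFilter:
    def test_all_equal_discards_nobody(self):
        kept, discarded, _ = coverage_filter(np.full(20, 0.8))
        assert discarded.size == 0 and kept.size == 20

    def test_single_low_outlier_discarded(self):
        df = np.array([0.9] * 99 + [0.1])
        kept, discarded, cutoff = coverage_filter(df)
        # direct mean/SD computation: cutoff = 0.892 - 3*0.0796 = 0.653
        assert discarded.tolist() == [99]
        assert cutoff == pytest.approx(df.mean() - 3 * df.std(), abs=1e-12)

    def test_single_pass_rule(self):
        """Removing a passing individual does not change verdicts under the
        original statistics: the rule uses one fixed cutoff."""
        df = np.array([0.9] * 50 + [0.2])
        _, discarded, cutoff = coverage_filter(df)
        verdicts = df < cutoff
        subset = np.delete(df, 3)  # drop a passing individual
        assert np.array_equal(np.delete(verdicts, 3), subset < cutoff)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            coverage_filter([0.5])


class TestIBSDistance:
    def test_identical_homozygotes_are_distance_zero(self):
        d = np.array([[0, 2, 0, 2], [0, 2, 0, 2]], dtype=np.int8)
        assert ibs_distance(d)[0, 1] == 0.0

    def test_opposite_homozygotes_are_distance_one(self):
        d = np.array([[0, 0, 2], [2, 2, 0]], dtype=np.int8)
        assert ibs_distance(d)[0, 1] == 1.0

    def test_identical_heterozygotes_contribute_half(self):
        d = np.array([[1, 1, 1, 1], [1, 1, 1, 1]], dtype=np.int8)
        assert ibs_distance(d)[0, 1] == pytest.approx(0.5)

    def test_missing_loci_excluded_pairwise(self):
        d = np.array([[0, 2, MISSING], [0, MISSING, 2]], dtype=np.int8)
        assert ibs_distance(d)[0, 1] == 0.0  # only locus 0 co-called

    def test_no_cocalled_locus_rejected(self):
        d = np.array([[0, MISSING], [MISSING, 2]], dtype=np.int8)
        with pytest.raises(ValueError, match="co-called"):
            ibs_distance(d)

    def test_sampled_mode_mean_matches_expectation(self):
        """Monte-Carlo oracle: the expected-mode distance equals the mean
        of sampled-mode distances within 3 SE over 10^4 replicates."""
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(2, 100)).astype(np.int8)
        expected = ibs_distance(d, mode="expected")[0, 1]
        reps = np.array(
            [ibs_distance(d, mode="sampled", seed=s)[0, 1] for s in range(10_000)]
        )
        se = reps.std(ddof=1) / np.sqrt(reps.size)
        assert abs(reps.mean() - expected) < 3 * se + 1e-4

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(6, 50)).astype(np.int8)
        m = ibs_distance(d)
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m) == 0)


class TestPruneRelatives:
    def test_all_distant_keeps_everyone(self):
        d = np.full((4, 4), 0.3)
        np.fill_diagonal(d, 0.0)
        kept, pruned = prune_relatives(d, np.ones(4))
        assert kept.tolist() == [0, 1, 2, 3] and pruned == []

    def test_replicate_pair_keeps_higher_coverage_member(self):
        d = np.array([[0.0, 0.01, 0.4], [0.01, 0.0, 0.4], [0.4, 0.4, 0.0]])
        kept, pruned = prune_relatives(d, coverage=[0.5, 0.9, 0.7])
        assert kept.tolist() == [1, 2]
        assert pruned == [[0, 1]]

    def test_coverage_tie_broken_by_lexicographic_id(self):
        d = np.array([[0.0, 0.01], [0.01, 0.0]])
        kept, _ = prune_relatives(d, coverage=[0.8, 0.8], ids=["zzz", "aaa"])
        assert kept.tolist() == [1]  # "aaa" wins the tie

    def test_single_linkage_chain_forms_one_cluster(self):
        """A-B 0.10, B-C 0.10, A-C 0.30: one cluster under single linkage,
        one representative kept (hand-run linkage oracle)."""
        d = np.array([[0.0, 0.10, 0.30], [0.10, 0.0, 0.10], [0.30, 0.10, 0.0]])
        kept, pruned = prune_relatives(d, coverage=[0.9, 0.5, 0.6])
        assert kept.tolist() == [0]
        assert pruned == [[0, 1, 2]]

    def test_threshold_is_strict(self):
        d = np.array([[0.0, 0.15], [0.15, 0.0]])
        kept, _ = prune_relatives(d, coverage=[0.5, 0.5], threshold=0.15)
        assert kept.size == 2  # exactly at the threshold is NOT below it

    def test_planted_replicates_pruned_across_seeds(self):
        """End-to-end recovery: IBS + single-linkage pruning removes
        exactly one member of every planted replicate pair and nothing
        else, across seeds."""
        for seed in range(10):
            data = simulate_genotypes(GenotypeSimConfig(seed=seed, n_loci=3000))
            dist = ibs_distance(data)
            kept, pruned_clusters = prune_relatives(
                dist, data.depth_fraction, ids=data.individuals
            )
            pruned = set(range(data.n_individuals)) - set(kept.tolist())
            rep_pairs = {
                frozenset((i, int(data.replicate_of[i])))
                for i in np.nonzero(data.replicate_of >= 0)[0]
            }
            # one pruned per replicate pair
            for pair in rep_pairs:
                assert len(pair & pruned) == 1
            # nothing outside the replicate pairs is pruned
            rep_members = set().union(*rep_pairs)
            assert pruned <= rep_members


class TestLocusFilters:
    def _data(self, col):
        # 10 individuals; the tested locus is the single column
        return np.array(col, dtype=np.int8).reshape(-1, 1)

    def test_low_call_rate_dropped_regardless_of_mac(self):
        col = [1] * 4 + [MISSING] * 6  # called in 40%
        assert not locus_filters(self._data(col))[0]

    def test_mac_four_dropped_mac_five_kept(self):
        base = [2] * 20
        mac4 = self._data(base[:-4] + [1] * 4)
        mac5 = self._data(base[:-5] + [1] * 5)
        assert not locus_filters(mac4)[0]
        assert locus_filters(mac5)[0]

    def test_monomorphic_dropped(self):
        assert not locus_filters(self._data([2] * 20))[0]
        assert not locus_filters(self._data([0] * 20))[0]

    def test_idempotent(self):
        d = simulate_genotypes(GenotypeSimConfig(seed=3, n_loci=500))
        keep = locus_filters(d)
        again = locus_filters(d.dosages[:, keep])
        assert again.all()


class TestFilterReport:
    def test_report_names_rules_for_every_discard(self):
        from larvaconnect.genofilter import filter_report

        data = simulate_genotypes(
            GenotypeSimConfig(seed=2, n_loci=300, low_coverage_outliers=2, low_coverage_value=0.05)
        )
        table, lines = filter_report(data)
        assert table["discarded_low_coverage"].sum() == 2
        assert sum("individual" in l and "coverage" in l for l in lines) == 2
        n_loci_dropped = (~locus_filters(data)).sum()
        assert sum(l.startswith("locus") for l in lines) == n_loci_dropped


class TestAssignLineages:
    COLS = ["edulis_Skagerrak", "edulis_NorthSea", "trossulus", "galloprovincialis"]

    def _table(self, rows):
        return pd.DataFrame(rows, columns=self.COLS)

    def test_pure_single_cluster(self):
        mem, pure = assign_lineages(self._table([[1.0, 0, 0, 0]]), "edulis_Skagerrak")
        assert mem.iloc[0].tolist() == [True, False, False, False]
        assert pure.tolist() == [0]

    def test_even_split_is_dual_member_and_impure(self):
        mem, pure = assign_lineages(self._table([[0.5, 0.5, 0, 0]]), "edulis_Skagerrak")
        assert mem.iloc[0].tolist() == [True, True, False, False]
        assert pure.size == 0

    def test_mild_introgression_stays_pure(self):
        # non-target sum 0.20 < 0.25 and no other coefficient reaches 0.25
        mem, pure = assign_lineages(
            self._table([[0.80, 0.10, 0.06, 0.04]]), "edulis_Skagerrak"
        )
        assert mem.iloc[0].tolist() == [True, False, False, False]
        assert pure.tolist() == [0]

    def test_recovers_planted_pure_subset_from_simulator_truth(self):
        data = simulate_genotypes(GenotypeSimConfig(seed=4))
        q = pd.DataFrame(data.true_admixture, columns=["c0", "c1", "c2", "c3"])
        _, pure = assign_lineages(q, "c0")
        truth = np.nonzero(1.0 - data.true_admixture[:, 0] < 0.25)[0]
        assert pure.tolist() == truth.tolist()

    def test_malformed_rows_rejected(self):
        with pytest.raises(ValueError):
            assign_lineages(self._table([[0.5, 0.2, 0, 0]]), "trossulus")

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FilterConfig(ibs_prune_threshold=1.5)
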