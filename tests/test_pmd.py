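import itertools

import numpy as np
import pytest

from pmdda import (
    IonCluster,
    PMDRecord,
    assign_rt_groups,
    build_and_merge_clusters,
    compute_pmd_frequency,
    pick_precursors,
    prune_by_correlation,
    reduce_redundant_peaks,
    round_pmd,
    select_high_frequency_pmds,
    select_precursors,
)
from conftest import make_table


def table_with(mz, rt, study):
    return make_table(mz, rt, study)


class TestRtGrouping:
    def test_gap_separates_groups(self):
        t = table_with([100, 101, 102, 103], [100, 101, 102, 200], [[1, 1, 1]] * 4)
        g = assign_rt_groups(t, rt_cutoff=10)
        ids = g.group_ids
        assert ids[0] == ids[1] == ids[2] != ids[3]

    def test_single_feature_single_group(self):
        t = table_with([100], [50], [[1, 1, 1]])
        assert len(assign_rt_groups(t).groups()) == 1

    def test_single_linkage_chains_within_cutoff(self):
        # consecutive gaps of 8 s < cutoff chain into one group under single linkage
        t = table_with([100, 101, 102, 103], [0, 8, 16, 24], [[1, 1, 1]] * 4)
        g = assign_rt_groups(t, rt_cutoff=10, method="single")
        assert len(g.groups()) == 1

    def test_complete_linkage_bounds_group_diameter(self):
        # same chain splits under the default diameter-bounded rule
        t = table_with([100, 101, 102, 103], [0, 8, 16, 24], [[1, 1, 1]] * 4)
        g = assign_rt_groups(t, rt_cutoff=10)
        for idx in g.groups().values():
            assert t.rt[idx].max() - t.rt[idx].min() <= 10

    def test_every_feature_assigned_exactly_once(self):
        rng = np.random.default_rng(5)
        t = table_with(rng.uniform(100, 900, 50), rng.uniform(30, 930, 50),
                       np.ones((50, 3)))
        g = assign_rt_groups(t)
        assert sum(len(v) for v in g.groups().values()) == 50


class TestPmdFrequency:
    def test_sodium_pair_rounds_to_na_exchange_mass(self):
        # 203.0526 - 181.0707 = 21.9819 -> 21.98, the Na/H exchange distance
        t = table_with([181.0707, 203.0526], [100, 100], [[1, 1, 1]] * 2)
        recs = compute_pmd_frequency(t, assign_rt_groups(t))
        assert recs == [PMDRecord(21.98, 1)]

    def test_replicated_pattern_counts_once_per_group(self):
        # the same PMD in 3 disjoint RT groups -> frequency 3
        mz, rt = [], []
        for k in range(3):
            mz += [100.0 + k, 121.9819 + k]
            rt += [100.0 * (k + 1)] * 2
        t = table_with(mz, rt, [[1, 1, 1]] * 6)
        recs = compute_pmd_frequency(t, assign_rt_groups(t))
        assert PMDRecord(21.98, 3) in recs

    def test_multiple_copies_in_one_group_count_once(self):
        # ladder 100, 121.98, 143.96: PMD 21.98 occurs twice but counts once
        t = table_with([100.0, 121.9819, 143.9638], [100] * 3, [[1, 1, 1]] * 3)
        recs = {r.pmd: r.frequency for r in compute_pmd_frequency(t, assign_rt_groups(t))}
        assert recs[21.98] == 1

    def test_sorted_by_descending_frequency(self, default_dataset):
        pos, _, _ = default_dataset
        recs = compute_pmd_frequency(pos, assign_rt_groups(pos))
        freqs = [r.frequency for r in recs]
        assert freqs == sorted(freqs, reverse=True)

    @pytest.mark.parametrize("delta,expected", [(21.9819, 21.98), (18.0106, 18.01), (1.0034, 1.00), (2.015, 2.02)])
    def test_rounding_half_away_from_zero(self, delta, expected):
        assert round_pmd(delta) == expected


class TestHighFrequencySelection:
    def test_explicit_cutoff(self):
        recs = [PMDRecord(21.98, 50), PMDRecord(18.01, 40), PMDRecord(3.37, 1)]
        assert select_high_frequency_pmds(recs, freq_cutoff=10) == {21.98, 18.01}

    def test_all_below_cutoff_empty(self):
        recs = [PMDRecord(3.37, 1), PMDRecord(5.5, 2)]
        assert select_high_frequency_pmds(recs, freq_cutoff=10) == set()

    def test_auto_elbow_cuts_at_largest_gap(self):
        # brute-force gap scan of {50,40,39,2,1}: largest drop is 39 -> 2
        recs = [PMDRecord(21.98, 50), PMDRecord(18.01, 40), PMDRecord(1.00, 39),
                PMDRecord(5.11, 2), PMDRecord(3.37, 1)]
        assert select_high_frequency_pmds(recs) == {21.98, 18.01, 1.00}

    def test_auto_mode_never_keeps_singletons(self):
        recs = [PMDRecord(1.0, 1), PMDRecord(2.0, 1)]
        assert select_high_frequency_pmds(recs) == set()

    def test_empty_records(self):
        assert select_high_frequency_pmds([]) == set()


def brute_force_components(mz, high_pmds):
    """Transitive closure of the pairwise high-PMD relation (oracle)."""
    n = len(mz)
    adj = {i: {i} for i in range(n)}
    for i, j in itertools.combinations(range(n), 2):
        if round_pmd(abs(mz[i] - mz[j])) in high_pmds:
            adj[i].add(j)
            adj[j].add(i)
    comps, seen = [], set()
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        comps.append(comp)
    return comps


class TestRedundantPeakReduction:
    def test_adduct_and_water_loss_collapse_to_one_component(self):
        # A (most intense), B = A + 21.98 (Na), C = A - 18.01 (water loss)
        t = table_with([181.07, 203.05, 163.06], [100, 100, 100],
                       [[10, 10, 10], [3, 3, 3], [2, 2, 2]])
        ind, comps = reduce_redundant_peaks(t, assign_rt_groups(t), {21.98, 18.01})
        assert comps == [{"F1", "F2", "F3"}]
        assert ind == {"F1"}

    def test_no_qualifying_pairs_all_independent(self):
        t = table_with([100.0, 150.0, 200.0], [100] * 3, [[1, 1, 1]] * 3)
        ind, comps = reduce_redundant_peaks(t, assign_rt_groups(t), {21.98})
        assert ind == {"F1", "F2", "F3"} and len(comps) == 3

    def test_two_disjoint_pairs_two_components(self):
        t = table_with([100.0, 121.9819, 300.0, 321.9819], [100] * 4,
                       [[5, 5, 5], [1, 1, 1], [4, 4, 4], [1, 1, 1]])
        ind, comps = reduce_redundant_peaks(t, assign_rt_groups(t), {21.98})
        assert len(comps) == 2 and ind == {"F1", "F3"}

    def test_empty_high_pmds_all_independent(self):
        t = table_with([100.0, 121.9819], [100, 100], [[1, 1, 1]] * 2)
        ind, _ = reduce_redundant_peaks(t, assign_rt_groups(t), set())
        assert ind == {"F1", "F2"}

    @pytest.mark.parametrize("seed", range(5))
    def test_components_match_brute_force_closure(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        mz = np.sort(rng.uniform(100, 500, n))
        # seed some true high-PMD pairs
        high = {21.98, 18.01}
        for k in range(min(3, n - 1)):
            mz[k + 1] = mz[k] + rng.choice([21.9819, 18.0106])
        t = table_with(mz, [100] * n, rng.uniform(1, 10, (n, 3)))
        _, comps = reduce_redundant_peaks(t, assign_rt_groups(t), high)
        oracle = brute_force_components(mz, high)
        oracle_ids = {frozenset(f"F{i + 1}" for i in c) for c in oracle}
        assert {frozenset(c) for c in comps} == oracle_ids


class TestClusterMerging:
    def test_shared_ion_merges_clusters(self):
        t = table_with([100, 110, 120], [50, 50, 50], [[5, 5, 5], [1, 1, 1], [3, 3, 3]])
        clusters = build_and_merge_clusters({"F1", "F3"}, [{"F1", "F2"}, {"F2", "F3"}], t)
        assert len(clusters) == 1
        assert clusters[0].members == {"F1", "F2", "F3"}
        assert clusters[0].base_peak == "F1"  # most intense of the merged bases

    def test_disjoint_components_unchanged(self):
        t = table_with([100, 110], [50, 60], [[5, 5, 5], [1, 1, 1]])
        clusters = build_and_merge_clusters({"F1", "F2"}, [{"F1"}, {"F2"}], t)
        assert len(clusters) == 2

    def test_singleton_independent_peak(self):
        t = table_with([100], [50], [[5, 5, 5]])
        clusters = build_and_merge_clusters({"F1"}, [{"F1"}], t)
        assert clusters[0].members == {"F1"} and clusters[0].base_peak == "F1"


class TestCorrelationPruning:
    def test_scaled_member_retained(self):
        t = table_with([100, 110], [50, 50], [[1, 2, 3, 4], [2, 4, 6, 8]])
        c = prune_by_correlation(IonCluster({"F1", "F2"}, "F1"), t)
        assert c.members == {"F1", "F2"}

    def test_anticorrelated_member_removed(self):
        t = table_with([100, 110], [50, 50], [[1, 2, 3, 4], [9, 7, 5, 3]])
        c = prune_by_correlation(IonCluster({"F1", "F2"}, "F1"), t)
        assert c.members == {"F1"}

    def test_exact_boundary_retained(self):
        # construct r exactly 0.9 against base [1,2,3]: centered base x=[-1,0,1],
        # orthogonal y=[1,-2,1]; member = base + b*y with b chosen so r=0.9
        b = np.sqrt(2 * (1 - 0.81) / (0.81 * 6))
        member = np.array([1.0, 2.0, 3.0]) + b * np.array([1.0, -2.0, 1.0])
        t = table_with([100, 110], [50, 50], [[1, 2, 3], list(member)])
        r = np.corrcoef([1, 2, 3], member)[0, 1]
        assert r == pytest.approx(0.9, abs=1e-12)
        c = prune_by_correlation(IonCluster({"F1", "F2"}, "F1"), t)
        assert c.members == {"F1", "F2"}

    def test_zero_variance_member_removed_with_warning(self):
        t = table_with([100, 110], [50, 50], [[1, 2, 3], [5, 5, 5]])
        with pytest.warns(UserWarning, match="zero-variance"):
            c = prune_by_correlation(IonCluster({"F1", "F2"}, "F1"), t)
        assert c.members == {"F1"}

    def test_too_few_study_samples_skips_with_warning(self):
        t = table_with([100, 110], [50, 50], [[1, 2], [9, 1]])
        with pytest.warns(UserWarning, match="skipped"):
            c = prune_by_correlation(IonCluster({"F1", "F2"}, "F1"), t)
        assert c.members == {"F1", "F2"}


class TestPrecursorElection:
    def test_most_intense_member_elected(self):
        t = table_with([100, 110], [50, 50], [[1e6] * 3, [5e5] * 3])
        prec = select_precursors([IonCluster({"F1", "F2"}, "F1")], t)
        assert list(prec["id"]) == ["F1"]

    def test_intensity_tie_breaks_to_lower_mz(self):
        t = table_with([110.0, 100.0], [50, 50], [[7, 7, 7], [7, 7, 7]])
        prec = select_precursors([IonCluster({"F1", "F2"}, "F1")], t)
        assert list(prec["id"]) == ["F2"]

    def test_empty_cluster_is_error(self):
        t = table_with([100], [50], [[1, 1, 1]])
        cluster = IonCluster({"F1"}, "F1")
        cluster.members = set()
        with pytest.raises(ValueError, match="empty cluster"):
            select_precursors([cluster], t)

    def test_output_sorted_by_rt_then_mz(self):
        t = table_with([300.0, 100.0], [80, 20], [[1, 1, 1], [1, 1, 1]])
        prec = select_precursors(
            [IonCluster({"F1"}, "F1"), IonCluster({"F2"}, "F2")], t
        )
        assert list(prec["rt"]) == [20.0, 80.0]


class TestPipelineInvariants:
    def test_counts_nest(self, default_dataset):
        from pmdda import apply_qc_filters

        pos, _, _ = default_dataset
        filtered = apply_qc_filters(pos)
        prec, clusters, diag = pick_precursors(filtered)
        assert len(prec) == len(clusters)
        assert len(clusters) <= len(diag["independent"]) <= filtered.n_features

    def test_precursor_is_cluster_intensity_maximum(self, default_dataset):
        from pmdda import apply_qc_filters

        pos, _, _ = default_dataset
        filtered = apply_qc_filters(pos)
        _, clusters, _ = pick_precursors(filtered)
        mean_int = filtered.mean_study_intensity()
        for c in clusters:
            assert c.precursor in c.members
            best = max(mean_int[filtered.index_of(m)] for m in c.members)
            assert mean_int[filtered.index_of(c.precursor)] == best

    def test_sodium_pmd_ranks_top3(self, default_dataset):
        pos, _, _ = default_dataset
        recs = compute_pmd_frequency(pos, assign_rt_groups(pos))
        top3 = {r.pmd for r in recs[:3]}
        assert 21.98 in top3
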