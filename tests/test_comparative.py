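import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mucopep.comparative import (
    PresenceMatrix,
    anova_screen,
    call_presence,
    correspondence_analysis,
    filter_proteins_two_peptides,
    hcluster,
    high_abundance_flags,
    kmodes,
    mean_center,
    partition_core_variable,
    pattern_contingency,
)
from mucopep.io import AbundanceTable


def make_table(arr, species, replicates, peptides=None):
    cols = pd.MultiIndex.from_product(
        [species, replicates], names=["species", "replicate"]
    )
    idx = peptides or [f"p{i}" for i in range(len(arr))]
    return AbundanceTable(pd.DataFrame(np.asarray(arr, float), index=idx, columns=cols))


def random_table(rng, n_peptides=30, n_species=4, n_reps=3):
    mask = rng.integers(0, 2, (n_peptides, n_species))
    arr = rng.lognormal(1.0, 0.8, (n_peptides, n_species, n_reps)) * mask[:, :, None]
    return make_table(
        arr.reshape(n_peptides, -1),
        [f"s{j}" for j in range(n_species)],
        [f"r{k}" for k in range(n_reps)],
    )


class TestPresence:
    def test_max_rule(self):
        t = make_table([[0.0, 5.2]], ["spA"], ["r1", "r2"])
        assert call_presence(t).presence.loc["p0", "spA"] == 1

    def test_all_zero_absent(self):
        t = make_table([[0.0, 0.0]], ["spA"], ["r1", "r2"])
        assert call_presence(t).presence.loc["p0", "spA"] == 0

    def test_agrees_with_brute_force_max(self, rng):
        t = random_table(rng)
        pm = call_presence(t)
        for pid in t.peptide_ids:
            for sp in t.species:
                cells = [
                    t.intensities.loc[pid, (sp, rep)]
                    for rep in t.intensities[sp].columns
                ]
                assert pm.presence.loc[pid, sp] == int(max(cells) > 0)


class TestMeanCenter:
    def test_simple_column(self):
        t = make_table([[1.0], [2.0], [3.0]], ["spA"], ["r1"])
        centered = mean_center(t)
        np.testing.assert_allclose(
            centered.intensities.to_numpy().ravel(), [-1.0, 0.0, 1.0]
        )

    def test_detected_mean_zero_and_idempotent(self, rng):
        t = random_table(rng)
        c1 = mean_center(t)
        arr = c1.intensities.to_numpy()
        det = t.intensities.to_numpy() > 0
        for j in range(arr.shape[1]):
            if det[:, j].any():
                assert abs(arr[det[:, j], j].mean()) < 1e-9
        c2 = mean_center(c1)
        np.testing.assert_allclose(c2.intensities.to_numpy(), arr, atol=1e-12)

    def test_empty_column_warns_and_unchanged(self):
        t = make_table([[0.0, 1.0], [0.0, 3.0]], ["spA"], ["r1", "r2"])
        with pytest.warns(UserWarning, match="no detected peptide"):
            centered = mean_center(t)
        assert (centered.intensities[("spA", "r1")] == 0).all()


class TestAnovaScreen:
    def test_identical_group_means_not_significant(self):
        block = [1.0, 2.0, 3.0]
        t = make_table([block + block + block], ["a", "b", "c"], ["r1", "r2", "r3"])
        res = anova_screen(t)
        assert res.loc["p0", "F"] == pytest.approx(0.0, abs=1e-12)
        assert not res.loc["p0", "significant"]

    def test_two_groups_f_equals_t_squared(self, rng):
        vals = rng.normal(5, 1, 6)
        t = make_table([vals], ["a", "b"], ["r1", "r2", "r3"])
        res = anova_screen(t)
        tstat, pval = stats.ttest_ind(vals[:3], vals[3:], equal_var=True)
        assert res.loc["p0", "F"] == pytest.approx(tstat**2)
        assert res.loc["p0", "p_value"] == pytest.approx(pval)

    def test_three_groups_match_f_tail_oracle(self, rng):
        vals = rng.normal(3, 1, (5, 9))
        t = make_table(vals, ["a", "b", "c"], ["r1", "r2", "r3"])
        res = anova_screen(t)
        for i in range(5):
            groups = vals[i].reshape(3, 3)
            gm = vals[i].mean()
            ssb = sum(3 * (g.mean() - gm) ** 2 for g in groups)
            ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
            F = (ssb / 2) / (ssw / 6)
            p = stats.f.sf(F, 2, 6)
            assert res.iloc[i]["F"] == pytest.approx(F, rel=1e-9)
            assert res.iloc[i]["p_value"] == pytest.approx(p, rel=1e-9)

    def test_insufficient_replication_skipped(self):
        t = make_table([[1.0, 2.0]], ["a", "b"], ["r1"])
        with pytest.warns(UserWarning, match="skipped"):
            res = anova_screen(t)
        assert np.isnan(res.loc["p0", "F"])


class TestPartitionCoreVariable:
    def test_small_example(self):
        presence = pd.DataFrame(
            [[1, 1], [1, 0], [0, 1]], index=["p1", "p2", "p3"], columns=["sA", "sB"]
        )
        core, variable, counts = partition_core_variable(PresenceMatrix(presence))
        assert core == ["p1"]
        assert set(variable) == {"p2", "p3"}
        assert counts.loc["p1"] == 2

    def test_partition_properties(self, rng):
        presence = pd.DataFrame(
            rng.integers(0, 2, (40, 5)),
            index=[f"p{i}" for i in range(40)],
            columns=list("abcde"),
        )
        pm = PresenceMatrix(presence)
        core, variable, counts = partition_core_variable(pm)
        detected = set(presence.index[presence.sum(axis=1) > 0])
        assert set(core) | set(variable) == detected
        assert set(core) & set(variable) == set()
        # idempotent / order-invariant
        shuffled = PresenceMatrix(presence.sample(frac=1, random_state=0))
        core2, variable2, _ = partition_core_variable(shuffled)
        assert set(core2) == set(core) and set(variable2) == set(variable)


class TestHCluster:
    def test_identical_rows_merge_at_zero(self):
        df = pd.DataFrame([[1.0, 0.0], [1.0, 0.0], [5.0, 5.0]])
        Z = hcluster(df)
        assert Z[0, 2] == 0.0
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_merge_order_matches_nearest_pair_oracle(self):
        pts = pd.DataFrame([[0.0], [1.0], [10.0], [10.5]])
        Z = hcluster(pts, method="complete")
        # exhaustive: nearest pair is (2,3) at 0.5, then (0,1) at 1.0,
        # then complete-linkage merge at max distance 10.5
        assert {int(Z[0, 0]), int(Z[0, 1])} == {2, 3}
        assert Z[0, 2] == pytest.approx(0.5)
        assert {int(Z[1, 0]), int(Z[1, 1])} == {0, 1}
        assert Z[1, 2] == pytest.approx(1.0)
        assert Z[2, 2] == pytest.approx(10.5)

    def test_complete_linkage_heights_monotone(self, rng):
        df = pd.DataFrame(rng.normal(size=(12, 4)))
        Z = hcluster(df, method="complete")
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_binary_metric_on_presence(self):
        presence = pd.DataFrame([[1, 0, 1], [1, 0, 1], [0, 1, 0]])
        Z = hcluster(PresenceMatrix(presence), metric="binary")
        assert Z[0, 2] == 0.0


def exhaustive_kmodes_cost(X: np.ndarray, k: int) -> int:
    """Global minimum simple-matching cost over all k-partitions (k=2 only).

    For a fixed partition the optimal mode minimizes each column
    independently: cost per column = min(#ones, #zeros) among members.
    """
    assert k == 2
    n = len(X)
    best = None
    for mask in range(1, 2 ** (n - 1)):  # fix row 0 in cluster 0; skip empty
        members = [[], []]
        for i in range(n):
            members[(mask >> i) & 1].append(i)
        cost = 0
        for rows in members:
            sub = X[rows]
            ones = sub.sum(axis=0)
            cost += int(np.minimum(ones, len(rows) - ones).sum())
        best = cost if best is None else min(best, cost)
    return best


class TestKModes:
    def test_simple_matching_dissimilarity(self):
        from mucopep.comparative import _matching_dissim

        assert _matching_dissim(np.array([[1, 0, 1]]), np.array([1, 1, 1]))[0] == 1

    def test_pure_groups_cost_zero(self):
        rows = np.array([[1, 0, 1]] * 4 + [[0, 1, 0]] * 3)
        pa = kmodes(pd.DataFrame(rows), k=2, seed=0)
        assert pa.cost == 0
        modes = {tuple(m) for m in pa.modes.to_numpy()}
        assert modes == {(1, 0, 1), (0, 1, 0)}

    def test_matches_exhaustive_minimum(self, rng):
        X = rng.integers(0, 2, (8, 7))
        pa = kmodes(pd.DataFrame(X), k=2, seed=1, n_restarts=10)
        assert pa.cost == exhaustive_kmodes_cost(X, 2)

    def test_every_row_assigned_once(self, rng):
        X = pd.DataFrame(rng.integers(0, 2, (20, 5)))
        pa = kmodes(X, k=3, seed=0)
        assert len(pa.assignment) == 20
        assert set(pa.assignment.unique()) <= set(range(3))

    def test_k_exceeding_distinct_rows_rejected(self):
        X = pd.DataFrame([[1, 0], [1, 0], [0, 1]])
        with pytest.raises(ValueError, match="distinct"):
            kmodes(X, k=3)


class TestPatternContingency:
    def test_single_pattern_count(self):
        presence = pd.DataFrame(
            [[1], [1], [1]], index=["a", "b", "c"], columns=["spA"]
        )
        pm = PresenceMatrix(presence)
        pa = kmodes(presence, k=1, seed=0)
        table = pattern_contingency(pa, pm)
        assert table.loc[0, "spA"] == 3

    def test_recount_oracle(self, rng):
        presence = pd.DataFrame(
            rng.integers(0, 2, (25, 4)),
            index=[f"p{i}" for i in range(25)],
            columns=list("wxyz"),
        )
        pm = PresenceMatrix(presence)
        pa = kmodes(presence, k=3, seed=2)
        table = pattern_contingency(pa, pm)
        for g in range(3):
            ids = pa.assignment.index[pa.assignment == g]
            for sp in "wxyz":
                assert table.loc[g, sp] == presence.loc[ids, sp].sum()


class TestCorrespondenceAnalysis:
    def test_total_inertia_equals_chi_square_over_n(self, rng):
        N = rng.integers(1, 30, (5, 4)).astype(float)
        ca = correspondence_analysis(pd.DataFrame(N))
        chi2 = stats.chi2_contingency(N, correction=False).statistic
        assert abs(ca.total_inertia - chi2 / N.sum()) < 1e-9

    def test_2x2_single_dimension(self):
        ca = correspondence_analysis(pd.DataFrame([[10.0, 2.0], [3.0, 9.0]]))
        assert len(ca.principal_inertias) == 1
        assert ca.explained_percent[0] == pytest.approx(100.0)

    def test_inertias_match_eigendecomposition_oracle(self, rng):
        for _ in range(5):
            N = rng.integers(1, 25, (4, 3)).astype(float)
            ca = correspondence_analysis(pd.DataFrame(N))
            P = N / N.sum()
            r, c = P.sum(axis=1), P.sum(axis=0)
            S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
            eigvals = np.sort(np.linalg.eigvalsh(S.T @ S))[::-1][:2]
            np.testing.assert_allclose(ca.principal_inertias, eigvals, atol=1e-9)

    def test_cos2_sums_to_one_and_explained_to_100(self, rng):
        N = rng.integers(1, 40, (6, 5)).astype(float)
        ca = correspondence_analysis(pd.DataFrame(N))
        np.testing.assert_allclose(ca.row_cos2.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(ca.col_cos2.sum(axis=1), 1.0, atol=1e-9)
        assert abs(ca.explained_percent.sum() - 100.0) < 1e-9
        assert (np.diff(ca.principal_inertias) <= 1e-12).all()

    def test_independent_table_has_zero_inertia(self):
        N = np.outer([2.0, 3.0, 5.0], [1.0, 4.0, 2.0, 3.0])
        ca = correspondence_analysis(pd.DataFrame(N))
        assert ca.total_inertia == pytest.approx(0.0, abs=1e-12)

    def test_matches_reference_implementation(self, rng):
        """Cross-check coordinates against scikit-bio's CA on the same table."""
        skbio_ordination = pytest.importorskip("skbio.stats.ordination")
        N = pd.DataFrame(
            rng.integers(1, 30, (6, 4)).astype(float),
            index=[f"g{i}" for i in range(6)],
            columns=[f"s{j}" for j in range(4)],
        )
        ca = correspondence_analysis(N)
        ref = skbio_ordination.ca(N, scaling=2)  # scaling 2: column-principal
        np.testing.assert_allclose(
            ca.principal_inertias,
            ref.proportion_explained.to_numpy() * ca.total_inertia,
            atol=1e-9,
        )
        # principal column coordinates agree up to per-axis sign
        ours = ca.col_coords.to_numpy()
        theirs = ref.features.to_numpy()[:, : ours.shape[1]]
        for j in range(ours.shape[1]):
            assert np.allclose(ours[:, j], theirs[:, j], atol=1e-8) or np.allclose(
                ours[:, j], -theirs[:, j], atol=1e-8
            )

    def test_all_zero_rows_dropped_with_warning(self):
        N = pd.DataFrame([[5.0, 1.0], [0.0, 0.0], [2.0, 6.0]])
        with pytest.warns(UserWarning, match="all-zero"):
            ca = correspondence_analysis(N)
        assert len(ca.row_coords) == 2

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            correspondence_analysis(pd.DataFrame([[1.0, 2.0, 3.0]]))


class TestUtilities:
    def test_protein_two_peptide_filter(self):
        mapping = pd.DataFrame(
            {
                "protein_accession": ["A", "A", "B", "C", "C", "C"],
                "peptide_id": ["p1", "p2", "p3", "p4", "p4", "p5"],
            }
        )
        kept = filter_proteins_two_peptides(mapping)
        assert set(kept["protein_accession"]) == {"A", "C"}
        assert kept.set_index("protein_accession").loc["C", "n_peptides"] == 2

    def test_high_abundance_flags(self, small_abundance):
        flags = high_abundance_flags(small_abundance, threshold=4.0)
        assert flags.loc["p2", "spA"] == 1
        assert flags.loc["p1", "spA"] == 0
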