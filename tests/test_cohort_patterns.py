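import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from miredit import cohort_patterns as cp
from miredit.synthetic_data import simulate_level_matrix

from _oracles import mannwhitney_enumerated_p, pearson_brute


def make_matrix(data, sites, cells, types):
    levels = pd.DataFrame(data, index=sites, columns=cells)
    return cp.EditingMatrix(levels=levels, cell_types=pd.Series(types, index=cells))


class TestMinSamples:
    @pytest.mark.parametrize(
        "n, frac, expected", [(448, 0.05, 23), (100, 0.05, 5), (19, 0.05, 1)]
    )
    def test_ceiling_of_fraction(self, n, frac, expected):
        assert cp.min_samples(n, frac) == expected

    def test_invalid_arguments_rejected(self):
        with pytest.raises(cp.CohortError):
            cp.min_samples(0)
        with pytest.raises(cp.CohortError):
            cp.min_samples(10, 0.0)


class TestCombine:
    def _profiles(self, n_cells, sig_in, covered_in):
        from miredit.reference_io import SiteKey
        from miredit.site_calling import SampleProfile, SiteCall

        key = SiteKey("p1", 10, "A", "G")
        profiles = []
        for i in range(n_cells):
            calls = []
            cov = {}
            if i in sig_in:
                calls.append(
                    SiteCall(key=key, level=0.5, k=50, n=100, raw_support=50,
                             raw_coverage=100, p=1e-30, p_adj=1e-29, significant=True,
                             mean_weight=1.0, arm="5p", tail_fraction=0.0)
                )
                cov[("p1", 10)] = 100.0
            elif i in covered_in:
                cov[("p1", 10)] = 50.0
            profiles.append(
                SampleProfile(sample_id=f"c{i:03d}", cell_type="T", calls=calls,
                              coverage=cov, total_qualified_reads=1000)
            )
        return profiles

    def test_prevalence_threshold_excludes_and_includes(self):
        below = self._profiles(100, sig_in=set(range(4)), covered_in=set())
        assert cp.combine_samples(below).levels.shape[0] == 0
        at = self._profiles(100, sig_in=set(range(5)), covered_in=set())
        assert cp.combine_samples(at).levels.shape[0] == 1

    def test_na_for_uncovered_zero_for_covered(self):
        profiles = self._profiles(40, sig_in=set(range(30)), covered_in={30, 31})
        m = cp.combine_samples(profiles)
        assert m.levels.iloc[0, 30] == 0.0
        assert np.isnan(m.levels.iloc[0, 35])

    def test_duplicate_cell_ids_rejected(self):
        profiles = self._profiles(10, sig_in=set(range(10)), covered_in=set())
        profiles[1] = profiles[0]
        with pytest.raises(cp.CohortError):
            cp.combine_samples(profiles)


class TestPCA:
    def test_two_clouds_separate_on_pc1(self):
        rng = np.random.default_rng(0)
        n = 30
        data = rng.normal(0.1, 0.02, size=(5, 2 * n)).clip(0, 1)
        data[0, :n] += 0.7  # one site separates the first n cells
        m = make_matrix(data, [f"s{i}" for i in range(5)],
                        [f"c{i}" for i in range(2 * n)], ["A"] * n + ["B"] * n)
        res = cp.pca(m, n_components=2)
        pc1 = res.scores["PC1"].to_numpy()
        thresh = pc1.mean()
        assert ((pc1[:n] > thresh).all() and (pc1[n:] < thresh).all()) or (
            (pc1[:n] < thresh).all() and (pc1[n:] > thresh).all()
        )
        assert res.explained_variance_ratio[0] > 0.5

    def test_duplicated_cells_get_identical_scores(self):
        rng = np.random.default_rng(1)
        data = rng.random((4, 6))
        data[:, 3] = data[:, 0]
        m = make_matrix(data, list("abcd"), [f"c{i}" for i in range(6)], ["T"] * 6)
        res = cp.pca(m, n_components=2)
        assert np.allclose(res.scores.iloc[0], res.scores.iloc[3])

    def test_variance_fractions_sorted_and_bounded(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.random((6, 10)), [f"s{i}" for i in range(6)],
                        [f"c{i}" for i in range(10)], ["T"] * 10)
        res = cp.pca(m, n_components=4)
        v = res.explained_variance_ratio
        assert (np.diff(v) <= 1e-12).all() and v.sum() <= 1 + 1e-9


class TestBicluster:
    def test_identical_cells_merge_first(self):
        data = np.array([[0.1, 0.1, 0.9], [0.2, 0.2, 0.8]])
        m = make_matrix(data, ["s1", "s2"], ["c1", "c2", "c3"], ["T"] * 3)
        res = cp.hier_bicluster(m)
        assert res.col_linkage[0][2] == 0.0  # first merge at distance zero
        i, j = res.col_order.index("c1"), res.col_order.index("c2")
        assert abs(i - j) == 1  # the identical pair sits adjacent

    def test_block_matrix_recovers_groups(self):
        rng = np.random.default_rng(3)
        data = rng.normal(0.05, 0.01, size=(6, 20)).clip(0, 1)
        data[:3, :10] += 0.6
        data[3:, 10:] += 0.6
        m = make_matrix(data, [f"s{i}" for i in range(6)],
                        [f"c{i}" for i in range(20)], ["T"] * 20)
        res = cp.hier_bicluster(m)
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(res.col_linkage, 2, criterion="maxclust")
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_column_permutation_preserves_topology(self):
        rng = np.random.default_rng(4)
        data = rng.random((5, 8))
        cells = [f"c{i}" for i in range(8)]
        m1 = cp.hier_bicluster(make_matrix(data, list("abcde"), cells, ["T"] * 8))
        perm = rng.permutation(8)
        m2 = cp.hier_bicluster(
            make_matrix(data[:, perm], list("abcde"), [cells[i] for i in perm], ["T"] * 8)
        )
        # same merge heights regardless of column order
        assert np.allclose(sorted(m1.col_linkage[:, 2]), sorted(m2.col_linkage[:, 2]))

    def test_newick_export_contains_all_leaves(self):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.random((3, 4)), list("abc"), list("wxyz"), ["T"] * 4)
        res = cp.hier_bicluster(m)
        nwk = cp.linkage_to_newick(res.col_linkage, list(m.levels.columns))
        assert nwk.endswith(";") and all(c in nwk for c in "wxyz")


class TestSpecificity:
    def test_indicator_equal_levels_fully_specific(self):
        cells = [f"c{i}" for i in range(20)]
        types = ["A"] * 5 + ["B"] * 15
        data = np.array([[1.0] * 5 + [0.0] * 15])
        res = cp.cell_type_specific_sites(make_matrix(data, ["s1"], cells, types))
        byct = {r.cell_type: r for r in res}
        assert byct["A"].r == pytest.approx(1.0) and byct["A"].specific
        assert not byct["B"].specific

    def test_constant_site_not_specific(self):
        cells = [f"c{i}" for i in range(10)]
        data = np.full((1, 10), 0.3)
        res = cp.cell_type_specific_sites(
            make_matrix(data, ["s1"], cells, ["A"] * 5 + ["B"] * 5)
        )
        assert all(np.isnan(r.r) and not r.specific for r in res)

    def test_planted_site_matches_bruteforce_pearson(self):
        rng = np.random.default_rng(6)
        cells = [f"c{i}" for i in range(50)]
        types = (["A"] * 10 + ["B"] * 10 + ["C"] * 10 + ["D"] * 10 + ["E"] * 10)
        levels = np.where(
            np.array(types) == "B", rng.normal(0.8, 0.05, 50).clip(0, 1), 0.0
        )[None, :]
        res = cp.cell_type_specific_sites(make_matrix(levels, ["s1"], cells, types))
        rb = next(r for r in res if r.cell_type == "B")
        indicator = (np.array(types) == "B").astype(float)
        assert rb.r == pytest.approx(pearson_brute(indicator, levels[0]), abs=1e-12)
        assert rb.specific


class TestVarianceGroups:
    @pytest.mark.parametrize(
        "std, group",
        [(0.34, "high"), (0.39, "high"), (0.33, "high"), (0.21, "medium"),
         (0.28, "medium"), (0.25, "medium"), (0.10, "low"), (0.13, "low"),
         (0.05, "low"), (0.0, "zero"), (0.2, "low"), (0.3, "medium")],
    )
    def test_tier_thresholds(self, std, group):
        assert cp.variance_group(std) == group

    def test_population_std_within_types(self):
        cells = [f"c{i}" for i in range(4)]
        data = np.array([[0.5 - 0.34, 0.5 + 0.34, 0.5 - 0.1, 0.5 + 0.1]])
        m = make_matrix(data, ["s1"], cells, ["A", "A", "B", "B"])
        res = {(r.cell_type): r for r in cp.variance_groups(m)}
        assert res["A"].std == pytest.approx(0.34) and res["A"].group == "high"
        assert res["B"].std == pytest.approx(0.10) and res["B"].group == "low"

    def test_tier_recovery_at_cohort_scale(self):
        """Generating stds 0.05/0.25/0.35 land in their tier >= 90% of cases."""
        hits = total = 0
        for seed in range(5):
            m = simulate_level_matrix(
                seed, {"T": 100},
                {"low": 0.5, "med": 0.5, "high": 0.5},
                {"low": 0.05, "med": 0.25, "high": 0.35},
            )
            res = {r.site: r.group for r in cp.variance_groups(m)}
            for site, want in [("low", "low"), ("med", "medium"), ("high", "high")]:
                total += 1
                hits += res[site] == want
        assert hits / total >= 0.9


class TestMannWhitney:
    def test_identical_groups_p_one(self):
        _, p = cp.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_separated_groups_exact_p(self):
        _, p = cp.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    @settings(max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_exact_branch_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(1, 6)), int(rng.integers(1, 6))
        vals = rng.permutation(100)[: n + m].astype(float)
        x, y = list(vals[:n]), list(vals[n:])
        _, p = cp.mann_whitney_u(x, y)
        assert p == pytest.approx(mannwhitney_enumerated_p(x, y), abs=1e-12)

    def test_exact_and_asymptotic_agree_at_n8(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            vals = rng.permutation(1000)[:16].astype(float)
            x, y = list(vals[:8]), list(vals[8:])
            _, p_exact = cp.mann_whitney_u(x, y)
            from scipy.stats import mannwhitneyu

            p_asym = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            assert abs(p_exact - p_asym) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(cp.CohortError):
            cp.mann_whitney_u([], [1.0])


class TestDifferential:
    def test_planted_shift_detected_with_direction(self):
        rng = np.random.default_rng(7)
        n = 30
        cells = [f"c{i}" for i in range(2 * n)]
        types = ["GBM"] * n + ["nESC"] * n
        shifted = np.concatenate(
            [rng.normal(0.6, 0.05, n), rng.normal(0.05, 0.02, n)]
        ).clip(0, 1)
        flat = rng.normal(0.3, 0.05, 2 * n).clip(0, 1)
        m = make_matrix(np.vstack([shifted, flat]), ["hot", "cold"], cells, types)
        res = cp.differential_editing(m, reference_type="nESC")
        by_site = {r.site: r for r in res}
        assert by_site["hot"].significant and by_site["hot"].direction == "higher"
        assert not by_site["cold"].significant

    def test_bh_preserves_p_ranks(self):
        rng = np.random.default_rng(8)
        data = rng.random((6, 20))
        m = make_matrix(data, [f"s{i}" for i in range(6)],
                        [f"c{i}" for i in range(20)], ["A"] * 10 + ["B"] * 10)
        res = cp.differential_editing(m, reference_type="B")
        pairs = sorted((r.p, r.p_adj) for r in res)
        # BH is monotone: ordering by raw p never reverses the adjusted p
        assert all(
            a[1] <= b[1] + 1e-15 for a, b in zip(pairs, pairs[1:])
        )

    def test_missing_reference_rejected(self):
        m = make_matrix(np.zeros((1, 4)), ["s"], list("abcd"), ["A"] * 4)
        with pytest.raises(cp.CohortError):
            cp.differential_editing(m, reference_type="Z")
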