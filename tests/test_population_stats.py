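from collections import Counter

import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
import scipy.stats
from scipy.spatial.distance import squareform

from koalamhc.genotype import KoalaProfile
from koalamhc.stats import (
    allele_association,
    build_presence_matrix,
    chi_squared_test,
    complete_linkage,
    fisher_exact_2x2,
    gower_dissimilarity,
    linkage_to_newick,
)

from .oracles import (
    naive_chi_squared,
    naive_complete_linkage_heights,
    naive_cophenetic,
    naive_fisher,
)


def profile(name, **calls):
    return KoalaProfile(name, {k: frozenset(v) for k, v in calls.items()})


class TestPresenceMatrix:
    def test_basic_encoding(self):
        m = build_presence_matrix(
            [profile("k1", L={"A"}), profile("k2", L={"A", "B"})]
        )
        assert list(m.columns) == ["L*A", "L*B"]
        assert m.loc["k1"].tolist() == [1, 0]
        assert m.loc["k2"].tolist() == [1, 1]

    def test_identical_profiles_identical_rows(self):
        m = build_presence_matrix(
            [profile("k1", L={"A", "B"}), profile("k2", L={"A", "B"})]
        )
        assert (m.loc["k1"] == m.loc["k2"]).all()

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            build_presence_matrix([])

    def test_study_population_allele_columns(self, tables):
        """The captive population carries 37 distinct alleles over six loci."""
        m = build_presence_matrix(list(tables.profiles.values()))
        assert m.shape[1] == 37
        per_locus = Counter(c.split("*")[0] for c in m.columns)
        assert per_locus == {
            "UA": 7, "UC": 5, "DAB": 10, "DBB": 8, "DCB": 3, "DMB": 4
        }


class TestGower:
    def test_examples(self):
        m = build_presence_matrix(
            [profile("a", L={"A", "C"}), profile("b", L={"A", "C"}),
             profile("c", L={"B", "D"})]
        )
        d = gower_dissimilarity(m)
        assert d[0, 1] == 0.0          # identical rows
        assert d[0, 2] == 1.0          # complementary rows
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_half_mismatch(self):
        import pandas as pd

        m = pd.DataFrame([[1, 0, 1, 0], [1, 1, 1, 1]], index=["a", "b"])
        assert gower_dissimilarity(m)[0, 1] == 0.5

    def test_matches_direct_count_and_triangle(self):
        rng = np.random.default_rng(20)
        x = rng.integers(0, 2, size=(8, 12))
        import pandas as pd

        d = gower_dissimilarity(pd.DataFrame(x))
        for i in range(8):
            for j in range(8):
                assert d[i, j] == pytest.approx(np.mean(x[i] != x[j]))
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


class TestCompleteLinkage:
    def test_three_point_example(self):
        d = np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        Z = complete_linkage(d)
        assert set(Z[0, :2]) == {0, 1} and Z[0, 2] == 0.1
        assert Z[1, 2] == 0.9

    def test_tied_distances_deterministic(self):
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0)
        Z1 = complete_linkage(d)
        Z2 = complete_linkage(d)
        assert np.array_equal(Z1, Z2)
        assert (Z1[:, 2] == 0.5).all()
        assert set(Z1[0, :2]) == {0, 1}  # lowest pair index merges first

    def test_heights_nondecreasing_and_match_oracles(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            n = 6
            cond = rng.random(n * (n - 1) // 2)
            d = squareform(cond)
            Z = complete_linkage(d)
            assert (np.diff(Z[:, 2]) >= -1e-12).all()
            # naive recursive oracle: same merge heights and cophenetic pairs
            assert np.allclose(sorted(Z[:, 2]), naive_complete_linkage_heights(d))
            coph = dict(naive_cophenetic(d))
            mine = squareform(sch.cophenet(Z))
            for (i, j), h in coph.items():
                assert mine[i, j] == pytest.approx(h)
            # independent route: scipy's own complete linkage
            assert np.allclose(
                sch.cophenet(Z), sch.cophenet(sch.linkage(cond, "complete"))
            )

    def test_permutation_invariance_of_heights(self):
        rng = np.random.default_rng(22)
        d = squareform(rng.random(15))
        perm = rng.permutation(6)
        Z1 = complete_linkage(d)
        Z2 = complete_linkage(d[np.ix_(perm, perm)])
        assert np.allclose(sorted(Z1[:, 2]), sorted(Z2[:, 2]))

    def test_asymmetric_input_rejected(self):
        d = np.array([[0, 1.0], [0.5, 0]])
        with pytest.raises(ValueError):
            complete_linkage(d)

    def test_newick_export_heights(self):
        d = np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        nwk = linkage_to_newick(complete_linkage(d), ["a", "b", "c"])
        assert nwk.endswith(";") and "a:0.1" in nwk and "c:0.9" in nwk


class TestFisher:
    def test_study_association_table(self):
        # DBB*03 carriage: 5/8 cancer vs 0/6 natural deaths
        assert fisher_exact_2x2([[5, 3], [0, 6]]) == pytest.approx(0.031, abs=5e-4)

    def test_symmetric_minimal_table(self):
        assert fisher_exact_2x2([[1, 0], [0, 1]]) == 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])

    def test_matches_enumeration_and_scipy_on_random_tables(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            t = rng.integers(0, 13, size=(2, 2))
            p = fisher_exact_2x2(t)
            assert p == pytest.approx(float(naive_fisher(t.tolist())), rel=1e-9)
            assert p == pytest.approx(scipy.stats.fisher_exact(t)[1], rel=1e-7)

    def test_large_counts_route(self):
        t = [[400, 200], [150, 350]]
        assert fisher_exact_2x2(t) == pytest.approx(
            scipy.stats.fisher_exact(t)[1], rel=1e-6
        )


class TestChiSquared:
    def test_table_at_expectation(self):
        stat, df, p = chi_squared_test([[10, 10], [10, 10]])
        assert stat == pytest.approx(0) and p == pytest.approx(1)

    def test_degrees_of_freedom(self):
        table = [[i + 1, i + 2] for i in range(30)]  # 30 groups x 2 outcomes
        _, df, _ = chi_squared_test(table)
        assert df == 29

    def test_statistic_matches_direct_summation(self):
        rng = np.random.default_rng(24)
        t = rng.integers(1, 20, size=(3, 4))
        stat, df, p = chi_squared_test(t)
        assert stat == pytest.approx(naive_chi_squared(t.tolist()))
        assert df == 6
        assert p == pytest.approx(scipy.stats.chi2.sf(stat, df))

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_test([[0, 0], [1, 2]])


def deceased_cohort():
    """Synthetic profiles shaped like the deceased-koala subset: 8 cancer
    (5 DBB*03 carriers) and 6 natural deaths (no carriers)."""
    profiles, outcomes = [], {}
    for i in range(8):
        calls = {"DBB": {"03", "01"} if i < 5 else {"01", "02"}}
        profiles.append(profile(f"cancer{i}", **calls))
        outcomes[f"cancer{i}"] = "cancer"
    for i in range(6):
        profiles.append(profile(f"natural{i}", DBB={"01", "02"}))
        outcomes[f"natural{i}"] = "natural"
    return profiles, outcomes


class TestAssociation:
    def test_dbb03_cancer_association(self):
        profiles, outcomes = deceased_cohort()
        res = allele_association(profiles, outcomes, "DBB", "03",
                                 groups=("cancer", "natural"))
        assert res.prevalence_pct == {"cancer": 63, "natural": 0}
        assert res.p_value == pytest.approx(0.031, abs=5e-4)
        assert res.table[:, 0].tolist() == [5, 3]
        assert res.table[:, 1].tolist() == [0, 6]

    def test_all_carriers_degenerate(self):
        profiles = [profile(f"k{i}", DBB={"03"}) for i in range(6)]
        outcomes = {f"k{i}": "cancer" if i < 3 else "natural" for i in range(6)}
        res = allele_association(profiles, outcomes, "DBB", "03",
                                 groups=("cancer", "natural"))
        assert res.p_value == 1.0

    def test_unknown_allele_rejected(self):
        profiles, outcomes = deceased_cohort()
        with pytest.raises(ValueError):
            allele_association(profiles, outcomes, "DBB", "99")

    def test_permuted_labels_lose_signal(self):
        profiles, outcomes = deceased_cohort()
        observed = allele_association(
            profiles, outcomes, "DBB", "03", groups=("cancer", "natural")
        ).p_value
        rng = np.random.default_rng(25)
        names = list(outcomes)
        ps = []
        for _ in range(200):
            labels = rng.permutation([outcomes[n] for n in names])
            perm = dict(zip(names, labels))
            ps.append(
                allele_association(
                    profiles, perm, "DBB", "03", groups=("cancer", "natural")
                ).p_value
            )
        assert observed == pytest.approx(0.031, abs=5e-4)
        assert np.median(ps) > observed  # signal vanishes under permutation
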