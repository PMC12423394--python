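import numpy as np
import pytest
from oracles import aucell_bruteforce, gsva_bruteforce

from isenics import (
    AucellParams,
    ExpressionMatrix,
    GsvaParams,
    InsufficientOverlapError,
    SignedGeneSet,
    ValidationError,
    aucell_score,
    gsva_score,
    icss,
)
from conftest import random_matrix


class TestGsva:
    def test_matches_bruteforce_on_fixed_small_matrix(self, small_matrix):
        """5 genes x 4 units, 2-gene set: vectorised walk equals the
        independently coded 5-step random walk, per unit."""
        oracle = gsva_bruteforce([list(r) for r in small_matrix.values])
        expected = oracle([True, True, False, False, False])
        got = gsva_score(small_matrix, {"G1", "G2"})
        np.testing.assert_allclose(got.values, expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, rng.integers(3, 7), rng.integers(3, 6))
        k = rng.integers(2, m.n_genes + 1)
        genes = set(rng.choice(m.gene_ids, size=k, replace=False))
        oracle = gsva_bruteforce([list(r) for r in m.values])
        expected = oracle([g in genes for g in m.gene_ids])
        got = gsva_score(m, genes)
        np.testing.assert_allclose(got.values, expected, atol=1e-12)

    def test_all_genes_in_set_walk_never_steps_down(self, small_matrix):
        got = gsva_score(small_matrix, set(small_matrix.gene_ids))
        np.testing.assert_allclose(got.values, 1.0, atol=1e-12)

    def test_identical_units_get_identical_scores(self):
        col = np.array([1.0, 5.0, 2.0, 8.0])
        m = ExpressionMatrix(
            ["A", "B", "C", "D"], ["u1", "u2", "u3"],
            np.column_stack([col, col, col * 2]),
        )
        got = gsva_score(m, {"A", "D"})
        assert got.values[0] == got.values[1]

    def test_unit_permutation_permutes_scores(self, small_matrix):
        perm = [2, 0, 3, 1]
        permuted = ExpressionMatrix(
            small_matrix.gene_ids,
            [small_matrix.unit_ids[i] for i in perm],
            small_matrix.values[:, perm],
        )
        base = gsva_score(small_matrix, {"G1", "G3"}).values
        got = gsva_score(permuted, {"G1", "G3"}).values
        np.testing.assert_allclose(got, base[perm], atol=1e-12)

    def test_monotone_transform_of_statistic_preserves_scores(self, small_matrix):
        """Scores depend only on within-unit rankings of the cross-unit
        statistic: cubing all (positive) expression values, a strictly
        increasing per-gene transform, preserves ranks hence scores up to
        kernel smoothing differences -- checked with kcdf='none' where the
        statistic is the value itself."""
        params = GsvaParams(kcdf="none")
        base = gsva_score(small_matrix, {"G2", "G5"}, params).values
        cubed = ExpressionMatrix(
            small_matrix.gene_ids, small_matrix.unit_ids, small_matrix.values**3
        )
        got = gsva_score(cubed, {"G2", "G5"}, params).values
        np.testing.assert_allclose(got, base, atol=1e-12)

    def test_zero_variance_gene_handled_by_bandwidth_floor(self):
        values = np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0], [4.0, 1.0, 2.0]])
        m = ExpressionMatrix(["A", "B", "C"], ["u1", "u2", "u3"], values)
        got = gsva_score(m, {"A", "B"})
        assert np.all(np.isfinite(got.values))

    def test_too_few_genes_errors(self, small_matrix):
        with pytest.raises(InsufficientOverlapError):
            gsva_score(small_matrix, {"G1"})

    def test_too_few_units_errors(self):
        m = ExpressionMatrix(["A", "B"], ["u1", "u2"], np.ones((2, 2)))
        with pytest.raises(ValidationError, match="3 units"):
            gsva_score(m, {"A", "B"})

    def test_gseapy_rank_concordance(self):
        """Loose cross-check against the independent gseapy GSVA port:
        per-unit scores should be strongly rank-concordant."""
        gseapy = pytest.importorskip("gseapy")
        import pandas as pd
        from scipy.stats import spearmanr

        rng = np.random.default_rng(7)
        m = random_matrix(rng, 60, 25)
        genes = set(rng.choice(m.gene_ids, size=12, replace=False))
        ours = gsva_score(m, genes).values
        df = pd.DataFrame(np.log2(m.values + 1), index=m.gene_ids, columns=m.unit_ids)
        res = gseapy.gsva(data=df, gene_sets={"S": sorted(genes)}, kcdf="Gaussian",
                          outdir=None, seed=1, min_size=1)
        theirs = res.res2d.set_index("Name").loc[m.unit_ids, "ES"].astype(float).to_numpy()
        rho = spearmanr(ours, theirs).statistic
        assert rho > 0.8


class TestAucell:
    def test_enumeration_fixture(self):
        """10 genes, 2-gene set at ranks 1 and 5, window 0.5: step-sum
        1+1+1+1+2 = 6 against maximal 1+2+2+2+2 = 9."""
        values = np.array([[10.0], [9.0], [8.0], [7.0], [6.0],
                           [5.0], [4.0], [3.0], [2.0], [1.0]])
        m = ExpressionMatrix([f"G{i}" for i in range(10)], ["u"], values)
        got = aucell_score(m, {"G0", "G4"}, AucellParams(top_fraction=0.5))
        assert got.values[0] == pytest.approx(6 / 9, abs=1e-12)

    def test_perfect_and_excluded_units(self):
        values = np.array([[9.0, 1.0], [8.0, 2.0], [1.0, 8.0], [2.0, 9.0]])
        m = ExpressionMatrix(["A", "B", "C", "D"], ["top", "bottom"], values)
        got = aucell_score(m, {"A", "B"}, AucellParams(top_fraction=0.5))
        assert got.values[0] == 1.0
        assert got.values[1] == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        m = random_matrix(rng, int(rng.integers(4, 21)), int(rng.integers(1, 6)))
        k = int(rng.integers(1, m.n_genes))
        genes = set(rng.choice(m.gene_ids, size=k, replace=False))
        frac = float(rng.uniform(0.1, 1.0))
        expected = aucell_bruteforce(
            [list(r) for r in m.values], [g in genes for g in m.gene_ids], frac
        )
        got = aucell_score(m, genes, AucellParams(top_fraction=frac))
        np.testing.assert_allclose(got.values, expected, atol=1e-12)
        assert np.all(got.values >= 0) and np.all(got.values <= 1)

    def test_promoting_an_inset_gene_never_decreases_score(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            m = random_matrix(rng, 12, 1)
            genes = {"G2", "G7"}
            params = AucellParams(top_fraction=0.5)
            base = aucell_score(m, genes, params).values[0]
            # move G7 to the top rank of the single unit
            boosted = m.values.copy()
            boosted[7, 0] = boosted[:, 0].max() + 1
            m2 = ExpressionMatrix(m.gene_ids, m.unit_ids, boosted)
            assert aucell_score(m2, genes, params).values[0] >= base - 1e-12

    def test_random_seeded_tie_rule_is_deterministic(self):
        m = ExpressionMatrix(["A", "B", "C", "D"], ["u"], np.ones((4, 1)))
        params = AucellParams(top_fraction=0.5, tie_rule="random_seeded", seed=3)
        a = aucell_score(m, {"A", "B"}, params).values
        b = aucell_score(m, {"A", "B"}, params).values
        np.testing.assert_array_equal(a, b)

    def test_empty_intersection_errors(self, small_matrix):
        with pytest.raises(InsufficientOverlapError):
            aucell_score(small_matrix, {"NOPE"})


class TestIcss:
    def test_identical_pos_and_neg_content_gives_zero(self, small_matrix):
        """If the positive and negative sets had identical members (two
        names, same list), the difference score would be exactly zero; the
        type itself forbids overlap, so the engines are differenced directly."""
        pos = gsva_score(small_matrix, {"G1", "G2"}, signature="A", component="positive")
        neg = gsva_score(small_matrix, {"G1", "G2"}, signature="B", component="negative")
        np.testing.assert_array_equal(pos.values - neg.values, 0.0)

    @pytest.mark.parametrize("method", ["gsva", "aucell"])
    def test_antisymmetry_under_signature_swap(self, small_matrix, signed_set, method):
        swapped = SignedGeneSet(
            signed_set.name, signed_set.negative, signed_set.positive
        )
        a = icss(small_matrix, signed_set, method).values
        b = icss(small_matrix, swapped, method).values
        np.testing.assert_allclose(a, -b, atol=1e-12)

    def test_unsigned_signature_returns_positive_score(self, small_matrix):
        s = SignedGeneSet("UNS", {"G1", "G2", "G3"})
        sv = icss(small_matrix, s, "gsva")
        np.testing.assert_array_equal(
            sv.values, gsva_score(small_matrix, {"G1", "G2", "G3"}).values
        )
        assert sv.negative_component is None

    def test_components_retained_for_audit(self, small_matrix, signed_set):
        sv = icss(small_matrix, signed_set, "gsva")
        np.testing.assert_allclose(
            sv.values,
            sv.positive_component.values - sv.negative_component.values,
            atol=1e-15,
        )

    def test_planted_upregulation_separates_groups(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(11)
        n = 200
        values = np.exp(rng.normal(2.0, 0.5, size=(30, n)))
        planted = np.zeros(n, dtype=bool)
        planted[:100] = True
        values[np.ix_(range(8), np.flatnonzero(planted))] *= 2.0
        m = ExpressionMatrix(
            [f"G{i}" for i in range(30)], [f"u{j}" for j in range(n)], values
        )
        s = SignedGeneSet("S", {f"G{i}" for i in range(8)})
        sv = icss(m, s, "gsva")
        p = mannwhitneyu(sv.values[planted], sv.values[~planted]).pvalue
        assert sv.values[planted].mean() > sv.values[~planted].mean()
        assert p < 1e-6
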