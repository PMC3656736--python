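import numpy as np
import pytest

from clonalgp import (
    GenotypeMatrix,
    RelationshipMatrix,
    filter_markers,
    impute,
    impute_gene_content,
    impute_major_homozygote,
    impute_stochastic_frequency,
    imputation_accuracy_comparison,
    missing_fraction,
    recode_to_minor,
    summarize_markers,
)

NA = np.nan


def _gm(dosage, clone_ids=None, marker_ids=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    return GenotypeMatrix(
        clone_ids or [f"c{i}" for i in range(n)],
        marker_ids or [f"m{j}" for j in range(m)],
        dosage,
    )


class TestSummaryAndFilter:
    def test_toy_matrix_flags(self):
        # m0 monomorphic; m1 20% missing; m2, m3 clean
        geno = _gm(
            [
                [0, NA, 1, 2],
                [0, 1, 0, 1],
                [0, 2, 1, 0],
                [0, 1, 2, 1],
                [0, 0, 1, 2],
            ]
        )
        rep = summarize_markers(geno)
        pm = rep.per_marker.set_index("marker_id")
        assert bool(pm.loc["m0", "monomorphic"])
        assert pm.loc["m1", "missing_frac"] == pytest.approx(0.2)
        filtered, frep = filter_markers(geno, max_missing=0.15)
        assert (frep.n_monomorphic, frep.n_high_missing, frep.n_informative) == (1, 1, 2)
        assert list(filtered.marker_ids) == ["m2", "m3"]

    def test_missing_fraction_threshold_is_strict(self):
        # exactly 15% missing survives; strictly more is dropped
        col = [1.0] * 17 + [0.0, 2.0] + [NA] * 3  # 3/20 = 0.15
        geno = _gm(np.array([col, col]).T, marker_ids=["keep", "also"])
        _, rep = filter_markers(geno, max_missing=0.15)
        assert rep.n_high_missing == 0

    def test_fully_missing_marker_is_monomorphic_flagged(self):
        geno = _gm([[NA, 1], [NA, 0]])
        rep = summarize_markers(geno)
        assert bool(rep.per_marker.loc[0, "monomorphic"])

    def test_filter_idempotent(self, base_dataset):
        once, rep1 = filter_markers(base_dataset.genotypes)
        twice, rep2 = filter_markers(once)
        assert list(twice.marker_ids) == list(once.marker_ids)
        assert rep2.n_monomorphic == 0 and rep2.n_high_missing == 0

    def test_max_missing_one_drops_only_monomorphic(self):
        geno = _gm([[0, NA, 1], [0, 1, 0], [0, 2, NA]])
        filtered, rep = filter_markers(geno, max_missing=1.0)
        assert rep.n_monomorphic == 1 and rep.n_high_missing == 0
        assert filtered.n_markers == 2

    def test_empty_result_raises(self):
        geno = _gm([[1], [1]])
        with pytest.raises(ValueError):
            filter_markers(geno)

    def test_missing_fraction_values(self):
        assert missing_fraction(_gm([[0, 1], [2, 1]])) == 0.0
        d = np.ones((10, 20))
        d[0, 0] = d[1, 1] = NA
        assert missing_fraction(_gm(d)) == pytest.approx(0.01)


def test_recode_to_minor_flips_majority_coding():
    geno = _gm([[2, 0, 1], [2, 1, 1], [1, 0, 1]])  # m0 freq 5/6, m1 freq 1/6, m2 tie 0.5
    recoded, flip = recode_to_minor(geno)
    assert list(flip) == [True, False, False]
    assert (recoded.allele_frequencies() <= 0.5).all()
    np.testing.assert_array_equal(recoded.dosage[:, 2], geno.dosage[:, 2])


@pytest.fixture(scope="module")
def masked_with_A(base_dataset, A_clones):
    from clonalgp import filter_markers

    filtered, _ = filter_markers(base_dataset.genotypes)
    return filtered, A_clones


class TestImputationCommon:
    @pytest.mark.parametrize(
        "method", ["stochastic", "major_homozygote",
                   "gene_content_scaled", "gene_content_truncated"]
    )
    def test_observed_cells_untouched_and_range(self, masked_with_A, method):
        geno, A = masked_with_A
        out = impute(geno, method, A=A, seed=3)
        obs = ~geno.mask
        np.testing.assert_array_equal(out.dosage[obs], geno.dosage[obs])
        assert out.is_complete
        assert out.dosage.min() >= 0 and out.dosage.max() <= 2

    def test_unknown_method_rejected(self, masked_with_A):
        with pytest.raises(ValueError, match="unknown"):
            impute(masked_with_A[0], "nearest_neighbour")


class TestStochasticImputation:
    def test_degenerate_locus_imputes_its_only_class(self):
        geno = _gm([[1], [1], [NA]])
        assert impute_stochastic_frequency(geno, 0).dosage[2, 0] == 1

    def test_seed_reproducibility(self, masked_with_A):
        geno, _ = masked_with_A
        a = impute_stochastic_frequency(geno, 5)
        b = impute_stochastic_frequency(geno, 5)
        np.testing.assert_array_equal(a.dosage, b.dosage)

    def test_class_frequencies_preserved(self):
        """10000 draws from observed class frequencies (1/4, 1/2, 1/4)."""
        observed = [[0.0], [1.0], [1.0], [2.0]]
        dosage = np.array(observed + [[NA]] * 10000)
        geno = _gm(dosage)
        out = impute_stochastic_frequency(geno, 11)
        counts = np.bincount(out.dosage[4:, 0].astype(int), minlength=3)
        p = np.array([0.25, 0.5, 0.25])
        se = np.sqrt(10000 * p * (1 - p))
        assert np.all(np.abs(counts - 10000 * p) < 4 * se)

    def test_allele_frequency_unbiased_over_replicates(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.3, size=(60, 5)).astype(float)
        d[rng.random(d.shape) < 0.2] = NA
        geno = _gm(d)
        obs_freq = geno.allele_frequencies()
        diffs = []
        for r in range(200):
            imp = impute_stochastic_frequency(geno, r)
            diffs.append(imp.allele_frequencies() - obs_freq)
        diffs = np.asarray(diffs)
        sem = diffs.std(axis=0, ddof=1) / np.sqrt(len(diffs))
        assert np.all(np.abs(diffs.mean(axis=0)) < 4 * sem + 1e-4)

    def test_no_observed_genotypes_raises(self):
        with pytest.raises(ValueError, match="no observed"):
            impute_stochastic_frequency(_gm([[NA], [NA]]), 0)


class TestMajorHomozygoteImputation:
    def test_missing_becomes_zero(self):
        out = impute_major_homozygote(_gm([[NA, 1], [2, NA]]))
        assert out.dosage[0, 0] == 0 and out.dosage[1, 1] == 0

    def test_complete_matrix_identity(self, base_dataset):
        geno = base_dataset.genotypes_complete
        np.testing.assert_array_equal(
            impute_major_homozygote(geno).dosage, geno.dosage
        )


class TestGeneContentImputation:
    def test_unrelated_individual_gets_locus_mean(self):
        A = RelationshipMatrix(["a", "b", "c"], np.eye(3))
        geno = _gm([[0.0], [2.0], [NA]], clone_ids=["a", "b", "c"])
        out = impute_gene_content(geno, A, variant="truncated")
        assert out.dosage[2, 0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_henderson_system_oracle(self, rng):
        """Predictions equal the jointly solved mixed-model equations."""
        A = RelationshipMatrix(
            ["s", "d", "o1", "o2"],
            np.array(
                [
                    [1.0, 0.0, 0.5, 0.5],
                    [0.0, 1.0, 0.5, 0.5],
                    [0.5, 0.5, 1.0, 0.5],
                    [0.5, 0.5, 0.5, 1.0],
                ]
            ),
        )
        h2 = 0.99
        lam = (1 - h2) / h2
        x_obs = np.array([2.0, 1.0, 2.0])  # s, d, o1 observed; o2 missing
        W = np.zeros((3, 4))
        W[0, 0] = W[1, 1] = W[2, 2] = 1.0
        Ainv = np.linalg.inv(A.values)
        C = np.zeros((5, 5))
        C[0, 0] = 3.0
        C[0, 1:] = W.sum(axis=0)
        C[1:, 0] = W.sum(axis=0)
        C[1:, 1:] = W.T @ W + lam * Ainv
        sol = np.linalg.solve(C, np.concatenate([[x_obs.sum()], W.T @ x_obs]))
        expected = sol[0] + sol[4]
        geno = _gm([[2.0], [1.0], [2.0], [NA]], clone_ids=["s", "d", "o1", "o2"])
        out = impute_gene_content(geno, A, variant="truncated")
        assert out.dosage[3, 0] == pytest.approx(expected, abs=1e-8)

    def test_clone_mate_limit(self):
        """A missing clone of an observed genotype inherits its value."""
        A = RelationshipMatrix(
            ["t1", "t2", "u"],
            np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]]),
        )
        geno = _gm([[2.0], [NA], [0.0]], clone_ids=["t1", "t2", "u"])
        out = impute_gene_content(geno, A, heritability=0.9999)
        assert out.dosage[1, 0] == pytest.approx(2.0, abs=1e-2)

    def test_monomorphic_zero_locus(self):
        A = RelationshipMatrix(["a", "b", "c"], np.eye(3))
        geno = _gm([[0.0], [0.0], [NA]], clone_ids=["a", "b", "c"])
        out = impute_gene_content(geno, A)
        assert out.dosage[2, 0] == pytest.approx(0.0, abs=1e-9)

    def test_variants_stay_in_range_and_differ_only_at_missing(self, masked_with_A):
        geno, A = masked_with_A
        scaled = impute_gene_content(geno, A, variant="scaled")
        trunc = impute_gene_content(geno, A, variant="truncated")
        obs = ~geno.mask
        np.testing.assert_array_equal(scaled.dosage[obs], trunc.dosage[obs])
        for out in (scaled, trunc):
            assert out.dosage.min() >= 0 and out.dosage.max() <= 2

    def test_requires_A(self, masked_with_A):
        with pytest.raises(ValueError, match="requires"):
            impute(masked_with_A[0], "gene_content_scaled")


def test_zero_missing_input_makes_all_methods_agree(tiny_dataset):
    from clonalgp import build_numerator_relationship

    geno = tiny_dataset.genotypes  # missing_rate = 0
    assert geno.is_complete
    A = build_numerator_relationship(tiny_dataset.pedigree).submatrix(geno.clone_ids)
    table = imputation_accuracy_comparison(
        geno, tiny_dataset.phenotypes, A, seed=1
    ).set_index("method")
    accs = table["mean_accuracy"]
    assert accs.max() - accs.min() < 1e-12
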