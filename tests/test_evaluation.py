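import numpy as np
import pandas as pd
import pytest

from clonalgp import (
    BreedingValueSet,
    build_G_allele_frequency,
    build_G_regression,
    compute_ebv1,
    compute_ebv2,
    compute_gebv,
    ensure_invertible,
    make_cv_scheme,
    run_cross_validation,
    scatter_outputs,
    within_family_correlation,
)


@pytest.fixture(scope="module")
def study(base_dataset, A_clones, imputed_genotypes):
    families = base_dataset.pedigree.family_of()
    G_freq = ensure_invertible(build_G_allele_frequency(imputed_genotypes), A_clones)
    G_reg, _ = build_G_regression(imputed_genotypes, A_clones)
    G_reg = ensure_invertible(G_reg, A_clones)
    return base_dataset, A_clones, G_freq, G_reg, families


class TestCVScheme:
    def test_train90_partition_sizes(self, study):
        data, _, _, _, families = study
        clones = list(data.genotypes.clone_ids)
        scheme = make_cv_scheme(clones, families, "train90", "within_family", 6, 1)
        for train, val in scheme.replicates:
            assert sorted(train + val) == sorted(clones)
            assert set(train).isdisjoint(val)
            assert abs(len(val) - 17) <= 2

    def test_train50_splits_every_family(self, study):
        data, _, _, _, families = study
        clones = list(data.genotypes.clone_ids)
        scheme = make_cv_scheme(clones, families, "train50", "within_family", 2, 5)
        for train, val in scheme.replicates:
            for fam in set(families.values()):
                members = [c for c in clones if families[c] == fam]
                if len(members) >= 2:
                    assert any(c in train for c in members)
                    assert any(c in val for c in members)

    def test_same_seed_reproduces_partitions(self, study):
        data, _, _, _, families = study
        clones = list(data.genotypes.clone_ids)
        a = make_cv_scheme(clones, families, "train90", "random", 3, 9)
        b = make_cv_scheme(clones, families, "train90", "random", 3, 9)
        assert a.replicates == b.replicates

    def test_full_training_fraction_rejected(self, study):
        data, _, _, _, families = study
        clones = list(data.genotypes.clone_ids)
        with pytest.raises(ValueError):
            make_cv_scheme(clones, families, 1.0, "random", 1, 0)

    def test_unknown_names_rejected(self, study):
        data, _, _, _, families = study
        clones = list(data.genotypes.clone_ids)
        with pytest.raises(ValueError):
            make_cv_scheme(clones, families, "train75", "random", 1, 0)
        with pytest.raises(ValueError):
            make_cv_scheme(clones, families, "train90", "by_site", 1, 0)


class TestBreedingValueFlavors:
    def test_ebv1_deterministic_and_tracks_truth(self, study):
        data = study[0]
        a = compute_ebv1(data.phenotypes)
        b = compute_ebv1(data.phenotypes)
        pd.testing.assert_frame_equal(a.table, b.table)
        truth = data.truth.breeding_values
        r = np.corrcoef(a.values_for(truth.index), truth.values)[0, 1]
        assert r > 0.9  # heavy clonal replication: EBV1 is close to the true BV

    def test_ebv2_validation_full_sibs_identical(self, study):
        data, A = study[0], study[1]
        families = data.pedigree.families()
        (sire, dam), members = max(families.items(), key=lambda kv: len(kv[1]))
        val = members[:4]
        bvs = compute_ebv2(data.phenotypes, A, val)
        vals = bvs.values_for(val)
        np.testing.assert_allclose(vals, vals[0], atol=1e-8)

    def test_ebv2_empty_validation_equals_full_ablup(self, study):
        data, A = study[0], study[1]
        full = compute_ebv2(data.phenotypes, A, [])
        again = compute_ebv2(data.phenotypes, A, ())
        pd.testing.assert_frame_equal(full.table, again.table)
        assert len(full.table) == len(A)

    def test_gebv_with_A_equals_ebv2(self, study):
        """A-equivalence at the evaluation layer: K=A GBLUP is pedigree BLUP."""
        data, A = study[0], study[1]
        val = list(data.genotypes.clone_ids[:10])
        ebv2 = compute_ebv2(data.phenotypes, A, val)
        gebv = compute_gebv(data.phenotypes, A, val, method="mme",
                            vc=ebv2.meta["vc"])
        np.testing.assert_allclose(
            gebv.values_for(A.ids), ebv2.values_for(A.ids), atol=1e-8
        )

    def test_gebv_validation_full_sibs_differ(self, study):
        data, _, G_freq, _, _ = study
        families = data.pedigree.families()
        members = max(families.values(), key=len)
        val = members[:4]
        bvs = compute_gebv(data.phenotypes, G_freq, val, "selection_index")
        assert np.std(bvs.values_for(val)) > 1e-4

    def test_validation_phenotypes_cannot_leak(self, study):
        """Canary: perturbing validation phenotypes changes no prediction."""
        data, A, G_freq, _, _ = study
        val = list(data.genotypes.clone_ids[:12])
        perturbed = data.phenotypes.copy()
        hit = perturbed["clone_id"].isin(val)
        perturbed.loc[hit, "volume"] += 100.0
        for fn, K in ((compute_ebv2, A), (compute_gebv, G_freq)):
            a = fn(data.phenotypes, K, val)
            b = fn(perturbed, K, val)
            pd.testing.assert_frame_equal(a.table, b.table)


@pytest.fixture(scope="module")
def report(study):
    data, A, G_freq, G_reg, families = study
    scheme = make_cv_scheme(
        data.genotypes.clone_ids, families, "train90", "within_family", 3, 2
    )
    return run_cross_validation(data.phenotypes, A, G_freq, G_reg, scheme)


class TestCrossValidation:
    def test_correlations_in_range_and_positive(self, report):
        r = report.per_replicate
        cols = ["r_GEBVa_EBV1", "r_GEBVb_EBV1", "r_GEBVa_EBV2", "r_GEBVb_EBV2"]
        assert (r[cols].abs() <= 1.0).all().all()
        assert (r[cols].mean() > 0).all()

    def test_means_are_plain_replicate_averages(self, report):
        m = report.means()
        assert m["r_GEBVa_EBV1"] == pytest.approx(
            report.per_replicate["r_GEBVa_EBV1"].mean()
        )

    def test_invariant_to_clone_ordering(self, study):
        data, A, G_freq, G_reg, families = study
        scheme = make_cv_scheme(
            data.genotypes.clone_ids, families, "train90", "within_family", 2, 3
        )
        base = run_cross_validation(data.phenotypes, A, G_freq, G_reg, scheme)
        order = list(reversed(list(A.ids)))
        shuffled = run_cross_validation(
            data.phenotypes.sample(frac=1.0, random_state=0),
            A.submatrix(order),
            G_freq.submatrix(order),
            G_reg.submatrix(order),
            scheme,
        )
        for col in ("r_GEBVa_EBV1", "r_GEBVb_EBV2"):
            np.testing.assert_allclose(
                base.per_replicate[col], shuffled.per_replicate[col], atol=1e-6
            )

    def test_tiny_validation_sets_skipped(self, study, caplog):
        data, A, G_freq, G_reg, families = study
        scheme = make_cv_scheme(
            data.genotypes.clone_ids, families, "train90", "within_family", 1, 4
        )
        scheme.replicates = [(scheme.replicates[0][0], scheme.replicates[0][1][:2])]
        report = run_cross_validation(data.phenotypes, A, G_freq, G_reg, scheme)
        assert report.per_replicate.empty


class TestWithinFamilyCorrelation:
    def test_constant_within_family_predictor_scores_zero(self):
        fams = {f"c{i}": ("f1" if i < 3 else "f2") for i in range(6)}
        pred = pd.Series([1.0, 1.0, 1.0, 2.0, 2.0, 2.0], index=list(fams))
        ref = pd.Series(np.arange(6.0), index=list(fams))
        assert within_family_correlation(pred, ref, fams) == 0.0

    def test_perfect_within_family_agreement(self):
        fams = {f"c{i}": ("f1" if i < 3 else "f2") for i in range(6)}
        ref = pd.Series([0.0, 1.0, 2.0, 5.0, 6.0, 7.0], index=list(fams))
        pred = 10.0 + 2.0 * ref
        assert within_family_correlation(pred, ref, fams) == pytest.approx(1.0)


class TestScatterOutputs:
    def _bvs(self, values, method):
        table = pd.DataFrame(
            {"value": values, "se": 0.1, "accuracy": 0.9},
            index=[f"c{i}" for i in range(len(values))],
        )
        table.index.name = "clone_id"
        return BreedingValueSet(table=table, method=method)

    def test_identical_sets_correlate_perfectly(self):
        a = self._bvs([1.0, 2.0, 3.0], "EBV1")
        b = self._bvs([1.0, 2.0, 3.0], "GEBVa")
        _, corr = scatter_outputs({"EBV1": a, "GEBVa": b})
        assert corr.loc["EBV1", "GEBVa"] == pytest.approx(1.0)

    def test_anticorrelated_sets(self):
        a = self._bvs([1.0, 2.0, 3.0], "EBV1")
        b = self._bvs([3.0, 2.0, 1.0], "GEBVa")
        _, corr = scatter_outputs({"EBV1": a, "GEBVa": b})
        assert corr.loc["EBV1", "GEBVa"] == pytest.approx(-1.0)

    def test_family_column_and_pairing(self, study):
        data = study[0]
        e1 = compute_ebv1(data.phenotypes)
        pairs, corr = scatter_outputs(
            {"EBV1": e1, "EBV1b": e1}, families=data.pedigree.family_of()
        )
        assert {"clone_id", "EBV1", "EBV1b", "family"} <= set(pairs.columns)
        assert corr.loc["EBV1", "EBV1b"] == pytest.approx(1.0)
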