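"""Cohort eligibility, feature assembly, SMOTE, outcome model, recommender."""

import numpy as np
import pandas as pd
import pytest

from mirpan import (
    ClassifierSpec,
    ClinicalRecord,
    ExpressionDataset,
    SimulationConfig,
    assemble_features,
    assemble_matrix,
    build_catalog,
    filter_cohort,
    fit_encoders,
    generate_cohort,
    recommend,
    self_training_update,
    smote_balance,
    train_prognosis,
)
from mirpan.datasets import OutcomeCoefficients
from mirpan.prognosis import PrognosisModel


def record(pid, **kw):
    defaults = dict(
        patient_id=pid, gender="female", age=60.0, ethnicity="group a",
        cancer_type="A", treatment_id="X", outcome="remission", followup_days=400,
    )
    defaults.update(kw)
    return ClinicalRecord(**defaults)


def toy_cohort_20():
    """20 records designed so exactly 13 survive the three rules:
    3 fall to rule 1 (incomplete / short follow-up), then cancer type C
    (4 records) falls to rule 2, leaving A x 7 and B x 6 whose treatments
    X (7) and Y (6) both stay above the minimum."""
    records = [
        record("r0", ethnicity=None),
        record("r1", cancer_type="B", treatment_id="Y", followup_days=200),
        record("r2", treatment_id=None),
    ]
    for i in range(4):
        records.append(record(f"a{i}", treatment_id="X"))
    for i in range(3):
        records.append(record(f"a{4+i}", treatment_id="Y"))
    for i in range(3):
        records.append(record(f"b{i}", cancer_type="B", treatment_id="X"))
    for i in range(3):
        records.append(record(f"b{3+i}", cancer_type="B", treatment_id="Y"))
    for i in range(4):
        records.append(record(f"c{i}", cancer_type="C", treatment_id="X" if i % 2 else "Y"))
    assert len(records) == 20
    return records


class TestFilterCohort:
    def test_toy_table_leaves_hand_computed_survivors(self):
        survivors, audit = filter_cohort(toy_cohort_20())
        assert len(survivors) == 13
        assert {r.patient_id for r in survivors} == {f"a{i}" for i in range(7)} | {
            f"b{i}" for i in range(6)
        }

    def test_reapplication_is_fixed_point(self):
        survivors, _ = filter_cohort(toy_cohort_20())
        again, audit = filter_cohort(survivors)
        assert [r.patient_id for r in again] == [r.patient_id for r in survivors]
        assert audit == []

    def test_missing_field_reason_logged(self):
        _, audit = filter_cohort(toy_cohort_20())
        reasons = {a["patient_id"]: a["reason"] for a in audit}
        assert "incomplete" in reasons["r0"]
        assert "follow-up" in reasons["r1"]

    def test_small_cancer_type_dropped_entirely(self):
        _, audit = filter_cohort(toy_cohort_20())
        dropped_c = [a for a in audit if a["patient_id"].startswith("c")]
        assert len(dropped_c) == 4
        assert all("cancer type C" in a["reason"] for a in dropped_c)

    def test_cascading_treatment_drop(self):
        """Dropping a sparse treatment can push a cancer type below the
        minimum; the filter must iterate to the fixed point."""
        records = []
        # type A: 5 records, 4 on X and 1 on Z; type B: 5 records on Y
        for i in range(4):
            records.append(record(f"a{i}", treatment_id="X"))
        records.append(record("a4", treatment_id="Z"))
        for i in range(5):
            records.append(record(f"b{i}", cancer_type="B", treatment_id="Y"))
        survivors, _ = filter_cohort(records)
        # Z (1 record) dropped -> A has 4 -> A dropped -> X gone too
        assert {r.patient_id for r in survivors} == {f"b{i}" for i in range(5)}

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError, match="survive"):
            filter_cohort([record("solo")])


@pytest.fixture(scope="module")
def fitted_parts(prognosis_cohort):
    cohort = prognosis_cohort
    catalog = build_catalog(cohort.treatments)
    eligible, _ = filter_cohort(cohort.clinical, cohort.expression, catalog)
    encoders = fit_encoders(
        eligible, cohort.expression, cohort.planted["signature_features"], catalog=catalog
    )
    return cohort, catalog, eligible, encoders


class TestAssembleFeatures:
    def test_vectors_differ_only_in_treatment_block(self, fitted_parts):
        cohort, catalog, eligible, encoders = fitted_parts
        rec = eligible[0]
        clusters = catalog.cluster_ids
        v1 = assemble_features(rec, cohort.expression, catalog, encoders,
                               treatment_coords=catalog.coordinates[clusters[0]])
        v2 = assemble_features(rec, cohort.expression, catalog, encoders,
                               treatment_coords=catalog.coordinates[clusters[1]])
        np.testing.assert_array_equal(v1[:-3], v2[:-3])
        assert not np.array_equal(v1[-3:], v2[-3:])

    def test_one_hot_blocks_sum_to_one_and_decode(self, fitted_parts):
        cohort, catalog, eligible, encoders = fitted_parts
        rec = eligible[3]
        frame = assemble_matrix([rec], cohort.expression, catalog, encoders)
        row = frame.iloc[0]
        for prefix, levels, value in [
            ("gender", encoders.gender_levels, rec.gender),
            ("ethnicity", encoders.ethnicity_levels, rec.ethnicity),
            ("cancer_type", encoders.cancer_type_levels, rec.cancer_type),
        ]:
            block = row[[f"{prefix}:{v}" for v in levels]]
            assert block.sum() == 1.0
            assert block.idxmax() == f"{prefix}:{value}"  # round-trip decode

    def test_unseen_category_yields_zero_block(self, fitted_parts):
        cohort, catalog, eligible, encoders = fitted_parts
        rec = record(eligible[0].patient_id, ethnicity="group z",
                     cancer_type=eligible[0].cancer_type,
                     treatment_id=eligible[0].treatment_id)
        v = assemble_features(rec, cohort.expression, catalog, encoders)
        start = len(encoders.mirna_features) + 1 + len(encoders.gender_levels)
        eth = v[start : start + len(encoders.ethnicity_levels)]
        assert eth.sum() == 0.0

    def test_column_order_documented_and_fixed(self, fitted_parts):
        cohort, catalog, eligible, encoders = fitted_parts
        cols = encoders.column_names()
        assert cols[-3:] == ["treatment:x", "treatment:y", "treatment:z"]
        assert cols[0].startswith("mirna:")
        frame = assemble_matrix(eligible[:2], cohort.expression, catalog, encoders)
        assert list(frame.columns) == cols


class TestSmote:
    def test_balanced_input_is_identity(self):
        X = np.arange(12).reshape(6, 2).astype(float)
        y = np.array(["a", "b"] * 3)
        Xb, yb = smote_balance(X, y, seed=0)
        np.testing.assert_array_equal(Xb, X)
        np.testing.assert_array_equal(yb, y)

    def test_two_minority_points_interpolate_on_segment(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [5.0, 0.0], [6.0, 0.0], [7.0, 0.0], [8.0, 0.0]])
        y = np.array(["m", "m", "M", "M", "M", "M"])
        Xb, yb = smote_balance(X, y, k=1, seed=1)
        synthetic = Xb[6:]
        assert synthetic.shape == (2, 2)
        for s in synthetic:
            # on the segment between (0,0) and (1,1): coordinates equal, in [0,1]
            assert s[0] == pytest.approx(s[1])
            assert 0.0 <= s[0] <= 1.0

    def test_class_counts_equal_after_balancing(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 4))
        y = np.array(["min"] * 8 + ["maj"] * 22)
        _, yb = smote_balance(X, y, seed=2)
        counts = pd.Series(yb).value_counts()
        assert counts["min"] == counts["maj"]

    def test_synthetic_points_in_minority_convex_hull_per_coordinate(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.uniform(2, 3, size=(6, 3)), rng.uniform(-9, -7, size=(20, 3))])
        y = np.array(["min"] * 6 + ["maj"] * 20)
        Xb, yb = smote_balance(X, y, seed=3)
        synthetic = Xb[26:]
        lo, hi = X[:6].min(axis=0), X[:6].max(axis=0)
        assert ((synthetic >= lo - 1e-12) & (synthetic <= hi + 1e-12)).all()

    def test_singleton_minority_rejected(self):
        X = np.zeros((4, 2))
        y = np.array(["m", "M", "M", "M"])
        with pytest.raises(ValueError, match="minority"):
            smote_balance(X, y)


class TestTrainPrognosis:
    def test_test_partition_untouched_by_smote(self, fitted_parts):
        cohort, catalog, eligible, _ = fitted_parts
        with_m, without_m = train_prognosis(
            eligible, cohort.expression, catalog,
            mirna_features=cohort.planted["signature_features"], seed=0,
        )
        n_test = len(eligible) - int(round(0.75 * len(eligible)))
        assert int(with_m.report.confusion.to_numpy().sum()) == n_test
        assert int(without_m.report.confusion.to_numpy().sum()) == n_test

    def test_null_outcome_gives_chance_accuracy(self):
        config = SimulationConfig(
            n_classes=2, samples_per_class=(150, 150), n_features=20,
            n_informative=5, class_effect_size=1.0, missing_feature_fraction=0.0,
            n_treatments=3,
            outcome_coefficients=OutcomeCoefficients.null(),
            seed=21,
        )
        cohort = generate_cohort(config)
        catalog = build_catalog(cohort.treatments)
        eligible, _ = filter_cohort(cohort.clinical, cohort.expression, catalog)
        with_m, _ = train_prognosis(
            eligible, cohort.expression, catalog,
            mirna_features=cohort.planted["signature_features"], seed=0,
        )
        assert with_m.report.overall_accuracy == pytest.approx(0.5, abs=0.12)

    def test_uncalibrated_spec_rejected(self, fitted_parts):
        cohort, catalog, eligible, _ = fitted_parts
        with pytest.raises(ValueError, match="calibrated"):
            train_prognosis(
                eligible, cohort.expression, catalog,
                spec=ClassifierSpec(family="svm_radial"),
            )


@pytest.fixture(scope="module")
def trained(fitted_parts):
    cohort, catalog, eligible, _ = fitted_parts
    model, _ = train_prognosis(
        eligible, cohort.expression, catalog,
        mirna_features=cohort.planted["signature_features"], seed=0,
    )
    return cohort, catalog, eligible, model


class TestRecommend:

    def test_top_k_one_is_argmax_of_full_ranking(self, trained):
        cohort, catalog, eligible, model = trained
        full = recommend(eligible[0], model, top_k=len(catalog.cluster_ids))
        top1 = recommend(eligible[0], model, top_k=1)
        assert top1.ranking[0] == full.ranking[0]

    def test_probabilities_sorted_non_increasing(self, trained):
        _, catalog, eligible, model = trained
        result = recommend(eligible[1], model, top_k=len(catalog.cluster_ids))
        probs = [p for _, p in result.ranking]
        assert probs == sorted(probs, reverse=True)

    def test_invariant_to_catalog_enumeration_order(self, trained):
        cohort, catalog, eligible, model = trained
        import copy

        shuffled = copy.copy(catalog)
        shuffled.coordinates = dict(reversed(list(catalog.coordinates.items())))
        a = recommend(eligible[2], model, catalog=catalog, top_k=3)
        b = recommend(eligible[2], model, catalog=shuffled, top_k=3)
        assert a.ranking == b.ranking

    def test_treatment_blind_model_ranks_by_cluster_id(self, fitted_parts):
        cohort, catalog, eligible, encoders = fitted_parts

        class Blind:
            classes_ = np.array(["recurrence", "remission"])

            def predict_proba(self, X):
                return np.tile([0.3, 0.7], (len(X), 1))

        model = PrognosisModel(
            classifier=Blind(), encoders=encoders, catalog=catalog,
            include_mirna=True, expression=cohort.expression,
            train_X=np.zeros((1, 1)), train_y=np.array(["remission"]),
        )
        result = recommend(eligible[0], model, top_k=len(catalog.cluster_ids))
        assert [c for c, _ in result.ranking] == catalog.cluster_ids


class TestSelfTraining:
    @pytest.fixture()
    def stub_model(self, fitted_parts):
        cohort, catalog, eligible, encoders = fitted_parts

        class Stub:
            classes_ = np.array(["recurrence", "remission"])

            def __init__(self, probs):
                self.probs = np.asarray(probs)

            def predict_proba(self, X):
                return self.probs[: len(X)]

            def get_params(self, deep=True):
                return {"probs": self.probs}

            def set_params(self, **kw):
                return self

            def fit(self, X, y):
                self.fitted_n_ = len(X)
                return self

        def make(probs):
            return PrognosisModel(
                classifier=Stub(probs), encoders=encoders, catalog=catalog,
                include_mirna=True, expression=cohort.expression,
                train_X=np.zeros((4, 2)), train_y=np.array(["remission"] * 2 + ["recurrence"] * 2),
            )

        return make

    def test_all_below_threshold_is_noop(self, stub_model):
        model = stub_model([[0.5, 0.5], [0.4, 0.6]])
        updated, audit = self_training_update(model, np.zeros((2, 2)))
        assert updated is model
        assert all(not a["admitted"] for a in audit)

    def test_exactly_at_threshold_not_admitted(self, stub_model):
        model = stub_model([[0.05, 0.95]])
        updated, audit = self_training_update(model, np.zeros((1, 2)), threshold=0.95)
        assert updated is model
        assert audit[0]["probability"] == pytest.approx(0.95)
        assert not audit[0]["admitted"]

    def test_above_threshold_admitted_with_pseudo_label(self, stub_model):
        model = stub_model([[0.96, 0.04], [0.5, 0.5]])
        updated, audit = self_training_update(model, np.zeros((2, 2)), threshold=0.95)
        assert audit[0]["admitted"] and audit[0]["pseudo_label"] == "recurrence"
        assert not audit[1]["admitted"]
        assert updated.train_X.shape[0] == 5  # 4 originals + 1 admitted
        np.testing.assert_array_equal(updated.train_y[:4], model.train_y)

    def test_separable_pool_does_not_degrade_accuracy(self, fitted_parts):
        cohort, catalog, eligible, _ = fitted_parts
        pool, held, train = eligible[:80], eligible[80:160], eligible[160:]
        model, _ = train_prognosis(
            train, cohort.expression, catalog,
            mirna_features=cohort.planted["signature_features"], seed=0,
        )
        X_held = assemble_matrix(held, cohort.expression, catalog, model.encoders).to_numpy()
        y_held = np.array([r.outcome for r in held])
        before = np.mean(model.classifier.predict(X_held) == y_held)
        X_pool = assemble_matrix(pool, cohort.expression, catalog, model.encoders).to_numpy()
        updated, _ = self_training_update(model, X_pool)
        after = np.mean(updated.classifier.predict(X_held) == y_held)
        assert after >= before - 0.02
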