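"""Type-split classification, hyperparameter search, conflict resolution."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ssetopo import geometry
from ssetopo.correspondence import (
    ClassifierSpec,
    build_training_set,
    predict_correspondence,
    resolve_conflicts,
    train,
    tune_hyperparameters,
)
from ssetopo.errors import ConfigError, InputError
from ssetopo.pipeline import RunConfig, match_protein
from ssetopo.sse_io import DensityStick
from ssetopo.synthetic import SimulationConfig, generate_model, simulate_protein

from conftest import stick_from, straight_sse

KINDS = ("voronoi_1nn", "svm_linear", "svm_rbf", "random_forest")


def small_model(n_h=3, n_s=2, seed=0):
    return generate_model(SimulationConfig(n_helices=n_h, n_strands=n_s, seed=seed))


class TestClassifierSpec:
    def test_defaults_filled(self):
        spec = ClassifierSpec(kind="svm_rbf")
        assert spec.hyperparameters["C"] > 0 and spec.hyperparameters["gamma"] > 0

    @pytest.mark.parametrize(
        "kind, params",
        [("svm_linear", {"C": -1}), ("svm_rbf", {"gamma": 0}),
         ("random_forest", {"min_split": 1}), ("voronoi_1nn", {"metric": "cosine"})],
    )
    def test_invalid_params_rejected(self, kind, params):
        with pytest.raises(ConfigError):
            ClassifierSpec(kind=kind, hyperparameters=params)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigError):
            ClassifierSpec(kind="perceptron")


class TestBuildTrainingSet:
    def test_sample_counts(self):
        ts = build_training_set(small_model(3, 0), "helix", k=16, J=5,
                                sigma_aug=0.5, seed=1)
        assert len(ts.samples) == 15
        labels = ts.labels
        assert sorted(set(labels)) == ["H1", "H2", "H3"]
        assert all(labels.count(c) == 5 for c in set(labels))

    def test_type_split(self):
        ts = build_training_set(small_model(4, 2), "strand", k=8, J=1, seed=1)
        assert sorted(set(ts.labels)) == ["S1", "S2"]

    def test_j1_unperturbed(self):
        model = small_model(2, 0)
        ts = build_training_set(model, "helix", k=16, J=1, sigma_aug=99.0, seed=1)
        for (fv, label), sse in zip(ts.samples, model):
            np.testing.assert_array_equal(
                fv.values, geometry.featurize(sse, 16).values
            )

    def test_missing_type_rejected(self):
        with pytest.raises(InputError, match="no model SSEs"):
            build_training_set(small_model(2, 0), "strand", k=8)

    def test_augmentation_seeded(self):
        a = build_training_set(small_model(), "helix", k=16, J=4, seed=9)
        b = build_training_set(small_model(), "helix", k=16, J=4, seed=9)
        np.testing.assert_array_equal(a.matrix(scaled=False), b.matrix(scaled=False))


class TestTuneHyperparameters:
    def test_single_configuration(self):
        spec = tune_hyperparameters(
            [], "svm_linear", {"C": [1.0]}, lambda s, ts: [90.0]
        )
        assert spec.tuned and spec.hyperparameters["C"] == 1.0

    def test_tie_goes_to_first_in_sorted_grid_order(self):
        spec = tune_hyperparameters(
            [], "svm_linear", {"C": [0.1, 10.0]}, lambda s, ts: [50.0]
        )
        assert spec.hyperparameters["C"] == 0.1

    def test_best_mean_wins(self):
        spec = tune_hyperparameters(
            [], "svm_rbf", {"C": [1.0], "gamma": [0.01, 0.1]},
            lambda s, ts: [100.0 if s.hyperparameters["gamma"] == 0.1 else 10.0],
        )
        assert spec.hyperparameters["gamma"] == 0.1

    def test_voronoi_is_parameter_free(self):
        with pytest.raises(ConfigError, match="parameter-free"):
            tune_hyperparameters([], "voronoi_1nn", {"k": [1]}, lambda s, ts: [0])

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigError):
            tune_hyperparameters([], "svm_linear", {}, lambda s, ts: [0])

    def test_failing_configuration_excluded(self):
        def eval_fn(spec, ts):
            if spec.hyperparameters["C"] == 0.1:
                raise RuntimeError("boom")
            return [75.0]

        spec = tune_hyperparameters([], "svm_linear", {"C": [0.1, 1.0]}, eval_fn)
        assert spec.hyperparameters["C"] == 1.0


class TestTrainPredict:
    def test_voronoi_exact_hit(self):
        model = small_model(3, 0)
        ts = build_training_set(model, "helix", k=16, J=1, seed=0)
        pred = train(ts, ClassifierSpec(kind="voronoi_1nn"))
        fv = geometry.featurize(model[1], 16, scaler=ts.scaler)
        label, conf = pred.predict(fv.values)
        assert label == "H2"
        assert conf == pytest.approx(0.0, abs=1e-9)

    def test_empty_training_set_rejected(self):
        ts = build_training_set(small_model(1, 0), "helix", k=16, J=1, seed=0)
        ts.samples = []
        with pytest.raises(InputError):
            train(ts, ClassifierSpec(kind="voronoi_1nn"))

    def test_margin_kinds_require_augmentation(self):
        ts = build_training_set(small_model(3, 0), "helix", k=16, J=1, seed=0)
        with pytest.raises(ConfigError, match="J >= 2"):
            train(ts, ClassifierSpec(kind="svm_linear"))

    @pytest.mark.parametrize("kind", KINDS)
    def test_training_samples_self_classify(self, kind):
        # well-separated classes (placement spacing >> sigma_aug): every kind
        # must label a training prototype as itself — cross-checked against a
        # brute-force nearest-class-centroid search
        model = small_model(4, 3, seed=2)
        J = 1 if kind == "voronoi_1nn" else 6
        spec = ClassifierSpec(
            kind=kind,
            hyperparameters={"n_trees": 30} if kind == "random_forest" else {},
        )
        for sse_type in ("helix", "strand"):
            k = 16 if sse_type == "helix" else 8
            ts = build_training_set(model, sse_type, k=k, J=J, sigma_aug=0.75, seed=3)
            pred = train(ts, spec)
            X = ts.matrix()
            y = np.asarray(ts.labels)
            for sse in (m for m in model if m.sse_type == sse_type):
                fv = geometry.featurize(sse, k, scaler=ts.scaler)
                label, _ = pred.predict(fv.values)
                brute = y[np.argmin(cdist(fv.values[None, :], X)[0])]
                assert label == sse.sse_id == brute

    def test_voronoi_matches_exhaustive_nearest_search(self):
        sim = simulate_protein(
            SimulationConfig(n_helices=6, n_strands=0, noise_sigma=1.0, seed=5)
        )
        ts = build_training_set(sim.model_sses, "helix", k=16, J=1, seed=0)
        pred = train(ts, ClassifierSpec(kind="voronoi_1nn"))
        X = ts.matrix()
        y = np.asarray(ts.labels)
        for stick in sim.sticks:
            fv = geometry.featurize(stick, 16, scaler=ts.scaler)
            label, conf = pred.predict(fv.values)
            d = cdist(fv.values[None, :], X)[0]
            assert label == y[np.argmin(d)]
            assert conf == pytest.approx(-d.min(), abs=1e-9)

    def test_feature_length_mismatch_detected(self):
        ts = build_training_set(small_model(3, 0), "helix", k=16, J=1, seed=0)
        pred = train(ts, ClassifierSpec(kind="voronoi_1nn"))
        with pytest.raises(InputError, match="feature length"):
            pred.predict(np.zeros(10))


class TestPredictCorrespondence:
    def _predictors(self, model):
        out = {}
        for sse_type, k in (("helix", 16), ("strand", 8)):
            if any(s.sse_type == sse_type for s in model):
                ts = build_training_set(model, sse_type, k=k, J=1, seed=0)
                out[sse_type] = train(ts, ClassifierSpec(kind="voronoi_1nn"))
        return out

    def test_noise_free_identity(self):
        sim = simulate_protein(SimulationConfig(n_helices=4, n_strands=3, seed=6))
        raw = predict_correspondence(sim.sticks, self._predictors(sim.model_sses))
        truth = {v: s for s, v, _ in sim.truth.pairs}
        for a in raw:
            assert a.label == truth[a.stick_id]

    def test_distant_stick_rejected_with_threshold(self):
        model = small_model(3, 0)
        far = DensityStick("V1", "helix",
                           np.array([[500.0, 500, 500], [510, 500, 500]]))
        raw = predict_correspondence([far], self._predictors(model),
                                     reject_threshold=-50.0)
        assert raw[0].rejected and raw[0].label is None

    def test_untrained_type_goes_unmatched(self):
        model = small_model(3, 0)
        stick = DensityStick("V1", "strand", np.array([[0.0, 0, 0], [3, 0, 0]]))
        raw = predict_correspondence([stick], self._predictors(model))
        assert raw[0].rejected

    def test_duplicate_sticks_both_claim_same_label(self):
        model = small_model(3, 0)
        s1 = stick_from(model[0], "V1")
        s2 = stick_from(model[0], "V2")
        raw = predict_correspondence([s1, s2], self._predictors(model))
        assert raw[0].label == raw[1].label == model[0].sse_id


class TestResolveConflicts:
    def _predictors(self, model):
        ts = build_training_set(model, "helix", k=16, J=1, seed=0)
        return {"helix": train(ts, ClassifierSpec(kind="voronoi_1nn"))}

    def test_one_to_one_input_passes_through_with_scores(self):
        sim = simulate_protein(SimulationConfig(n_helices=4, n_strands=0, seed=8))
        raw = predict_correspondence(sim.sticks, self._predictors(sim.model_sses))
        out = resolve_conflicts(raw, sim.model_sses, 16)
        assert {(p.sse_id, p.stick_id) for p in out.pairs} == {
            (s, v) for s, v, _ in sim.truth.pairs
        }
        assert all(p.score is not None and p.score >= 0 for p in out.pairs)

    def test_exact_copy_wins_contest(self):
        model = small_model(3, 0)
        exact = stick_from(model[0], "V1")
        offset = stick_from(model[0], "V2")
        offset.axis_points = offset.axis_points + 1.0
        raw = predict_correspondence([exact, offset], self._predictors(model))
        out = resolve_conflicts(raw, model, 16)
        winner = {p.sse_id: p.stick_id for p in out.pairs}
        assert winner[model[0].sse_id] == "V1"
        # loser falls back to its next-best unclaimed label
        assert "V2" in {p.stick_id for p in out.pairs} | set(out.unmatched_sticks)

    def test_loser_without_threshold_label_goes_unmatched(self):
        model = small_model(2, 0)
        exact = stick_from(model[0], "V1")
        dup = stick_from(model[0], "V2")
        raw = predict_correspondence([exact, dup], self._predictors(model),
                                     reject_threshold=-1.0)
        out = resolve_conflicts(raw, model, 16, reject_threshold=-1.0)
        assert out.unmatched_sticks == ["V2"]

    def test_cardinality_conservation(self):
        sim = simulate_protein(
            SimulationConfig(n_helices=6, n_strands=5, noise_sigma=1.5,
                             drop_prob=0.2, fragment_prob=0.3, seed=13)
        )
        matches = match_protein(sim.model_sses, sim.sticks, RunConfig())
        n, m = len(sim.sticks), len(sim.model_sses)
        assert len(matches.pairs) + len(matches.unmatched_sticks) == n
        assert len(matches.pairs) + len(matches.unmatched_sses) == m
        matches.validate(
            sse_ids={s.sse_id for s in sim.model_sses},
            stick_ids={s.stick_id for s in sim.sticks},
        )


def test_f1_non_increasing_with_noise_for_all_kinds():
    """Mean F1 over seeded replicates must not rise as stick noise grows."""
    from ssetopo.evaluation import evaluate_correspondence

    for kind in KINDS:
        means = []
        for sigma in (0.0, 1.0, 2.0):
            scores = []
            for rep in range(4):
                sim = simulate_protein(
                    SimulationConfig(n_helices=5, n_strands=4,
                                     noise_sigma=sigma, seed=300 + rep)
                )
                matches = match_protein(
                    sim.model_sses, sim.sticks, RunConfig().with_kind(kind)
                )
                scores.append(evaluate_correspondence(matches, sim.truth).f1)
            means.append(np.mean(scores))
        for lo, hi in zip(means[1:], means[:-1]):
            assert lo <= hi + 2.0
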