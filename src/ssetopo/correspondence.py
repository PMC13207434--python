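"""SSE correspondence as type-split supervised classification.

Each model SSE is its own class: the classifier for a given type (helix or
strand) is trained on labelled geometric feature vectors of the model SSEs of
that type, and every density stick of that type is then classified to retrieve
the model SSE it depicts.  Keeping helices and strands in separate classifiers
rules out cross-type confusion by construction.

Because one SSE naturally contributes exactly one training sample, kinds that
need more than one sample per class (margin- and ensemble-based) are trained
on seeded jitter augmentation: each class receives J feature vectors — the
unperturbed one plus J−1 replicas whose resampled coordinates carry isotropic
Gaussian noise σ_aug.  The 1-NN (Voronoi) classifier is parameter-free and
uses the single unperturbed sample per class.

Raw per-stick predictions may collide (several sticks claiming one SSE).
Conflicts are resolved greedily with the orientation-free DTW cost against the
SSE's resampled Cα trace: the cheapest stick keeps the label, losers fall back
to their next-best still-unclaimed label (subject to the optional rejection
threshold) or end up unmatched.  The result is a one-to-one matching in which
every stick and every model SSE is accounted for.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import geometry
from .errors import ConfigError, InputError, InvariantError
from .orientation import orientation_free_cost
from .sse_io import natural_id_key

logger = logging.getLogger(__name__)

__all__ = [
    "CLASSIFIER_KINDS",
    "DEFAULT_GRIDS",
    "ClassifierSpec",
    "TrainingSet",
    "MatchRecord",
    "CorrespondenceSet",
    "RawAssignment",
    "FittedPredictor",
    "build_training_set",
    "tune_hyperparameters",
    "train",
    "predict_correspondence",
    "resolve_conflicts",
]

CLASSIFIER_KINDS = ("svm_linear", "svm_rbf", "random_forest", "voronoi_1nn")

#: Candidate hyperparameter values for benchmark-level grid search.
DEFAULT_GRIDS = {
    "svm_linear": {"C": [0.1, 1.0, 10.0, 100.0]},
    "svm_rbf": {"C": [0.1, 1.0, 10.0, 100.0], "gamma": [0.001, 0.01, 0.1, 1.0]},
    "random_forest": {
        "n_trees": [100, 300],
        "max_depth": [None, 10, 20],
        "min_split": [2, 5],
    },
}

_DEFAULT_PARAMS = {
    "svm_linear": {"C": 1.0},
    # gamma ~ 1/n_features is the standard heuristic for standardized inputs
    "svm_rbf": {"C": 1.0, "gamma": 0.01},
    "random_forest": {"n_trees": 100, "max_depth": None, "min_split": 2},
    "voronoi_1nn": {"metric": "euclidean"},
}


@dataclass
class ClassifierSpec:
    """Which classifier family to use, with its hyperparameters."""

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    tuned: bool = False

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ConfigError(f"unknown classifier kind {self.kind!r}")
        params = dict(_DEFAULT_PARAMS[self.kind])
        params.update(self.hyperparameters)
        self.hyperparameters = params
        hp = self.hyperparameters
        if self.kind in ("svm_linear", "svm_rbf") and hp["C"] <= 0:
            raise ConfigError("C must be > 0")
        if self.kind == "svm_rbf" and hp["gamma"] <= 0:
            raise ConfigError("gamma must be > 0")
        if self.kind == "random_forest":
            if hp["n_trees"] < 1:
                raise ConfigError("n_trees must be >= 1")
            if hp["min_split"] < 2:
                raise ConfigError("min_split must be >= 2")
        if self.kind == "voronoi_1nn" and hp["metric"] != "euclidean":
            raise ConfigError("voronoi_1nn distance metric is fixed to Euclidean")


@dataclass
class TrainingSet:
    """Labelled feature samples for one SSE type, plus the scaler fit on them."""

    sse_type: str
    samples: list  # of (FeatureVector, sse_id label)
    k: int
    scaler: StandardScaler
    replicas: int
    sigma_aug: float
    seed: int

    @property
    def labels(self) -> list:
        return [label for _fv, label in self.samples]

    def matrix(self, scaled: bool = True) -> np.ndarray:
        X = np.vstack([fv.values for fv, _ in self.samples])
        return self.scaler.transform(X) if scaled else X


@dataclass
class MatchRecord:
    sse_id: str
    stick_id: str
    score: float | None = None
    direction: int = 0  # +1 / -1, 0 = unset


@dataclass
class CorrespondenceSet:
    """The matching M: one-to-one pairs plus unmatched SSEs and sticks."""

    pairs: list = field(default_factory=list)
    unmatched_sses: list = field(default_factory=list)
    unmatched_sticks: list = field(default_factory=list)

    def validate(self, sse_ids=None, stick_ids=None) -> None:
        """Check one-to-one-ness, and completeness against given universes."""
        seen_s = set()
        seen_v = set()
        for p in self.pairs:
            if p.sse_id in seen_s or p.stick_id in seen_v:
                raise InvariantError("correspondence set is not one-to-one")
            seen_s.add(p.sse_id)
            seen_v.add(p.stick_id)
        for sid in self.unmatched_sses:
            if sid in seen_s:
                raise InvariantError(f"SSE {sid} both matched and unmatched")
            seen_s.add(sid)
        for vid in self.unmatched_sticks:
            if vid in seen_v:
                raise InvariantError(f"stick {vid} both matched and unmatched")
            seen_v.add(vid)
        if sse_ids is not None and seen_s != set(sse_ids):
            raise InvariantError("correspondence set does not cover all model SSEs")
        if stick_ids is not None and seen_v != set(stick_ids):
            raise InvariantError("correspondence set does not cover all sticks")


@dataclass
class RawAssignment:
    """Pre-resolution classifier output for one stick (possibly many-to-one)."""

    stick: object  # DensityStick
    label: str | None
    confidence: float | None
    class_scores: dict = field(default_factory=dict)
    rejected: bool = False
    reason: str = ""

    @property
    def stick_id(self) -> str:
        return self.stick.stick_id


# ---------------------------------------------------------------------------
# training


def build_training_set(
    model_sses,
    sse_type: str,
    k: int,
    J: int = 1,
    sigma_aug: float = 0.75,
    seed: int = 0,
) -> TrainingSet:
    """Labelled training set for one SSE type with jitter augmentation.

    Every SSE of the type yields J samples carrying its ``sse_id`` as class
    label: the unperturbed feature vector plus J−1 replicas whose resampled
    coordinates receive isotropic Gaussian noise ``sigma_aug`` (drawn from a
    generator seeded with ``seed``).  The standardization scaler is fit on the
    full training matrix and stored for reuse at prediction time.
    """
    selected = [s for s in model_sses if s.sse_type == sse_type]
    if not selected:
        raise InputError(f"no model SSEs of type {sse_type!r}")
    if J < 1:
        raise ConfigError("J must be >= 1")
    rng = np.random.default_rng(seed)
    samples = []
    for sse in selected:
        fv = geometry.featurize(sse, k)
        samples.append((fv, sse.sse_id))
        if J > 1:
            base = geometry.resample_polyline(sse.calpha_coords, k)
            for _ in range(J - 1):
                jittered = base + rng.normal(0.0, sigma_aug, size=base.shape)
                rep = geometry.assemble_feature(
                    jittered,
                    geometry.compute_axis(jittered),
                    geometry.polyline_length(jittered),
                    sse.residue_count,
                    k,
                )
                samples.append((rep, sse.sse_id))
    X = np.vstack([fv.values for fv, _ in samples])
    scaler = StandardScaler().fit(X)
    return TrainingSet(
        sse_type=sse_type,
        samples=samples,
        k=k,
        scaler=scaler,
        replicas=J,
        sigma_aug=sigma_aug,
        seed=seed,
    )


def _expand_grid(grid: dict):
    """Deterministic grid expansion: keys sorted, values in listed order."""
    keys = sorted(grid)
    for combo in itertools.product(*(grid[key] for key in keys)):
        yield dict(zip(keys, combo))


def tune_hyperparameters(training_sets, kind: str, grid: dict, eval_fn) -> ClassifierSpec:
    """Benchmark-level grid search: pick the configuration with the highest
    mean F1 across proteins.

    ``eval_fn(spec, training_sets)`` must return one F1 per protein.  Every
    configuration in the (sorted-key) grid is evaluated exhaustively; ties go
    to the earlier configuration; configurations whose evaluation fails are
    logged and excluded.  The 1-NN kind is parameter-free and cannot be tuned.
    """
    if kind == "voronoi_1nn":
        raise ConfigError("voronoi_1nn is a parameter-free classifier")
    if not grid:
        raise ConfigError("empty hyperparameter grid")
    best_spec = None
    best_mean = -np.inf
    for params in _expand_grid(grid):
        spec = ClassifierSpec(kind=kind, hyperparameters=params)
        try:
            scores = list(eval_fn(spec, training_sets))
        except Exception as exc:
            logger.warning("grid configuration %s failed: %s", params, exc)
            continue
        mean = float(np.mean(scores))
        if mean > best_mean:
            best_mean = mean
            best_spec = ClassifierSpec(kind=kind, hyperparameters=params, tuned=True)
    if best_spec is None:
        raise ConfigError("every grid configuration failed evaluation")
    return best_spec


class FittedPredictor:
    """A trained per-type classifier with its featurization context.

    ``predict(feature_values)`` returns (label, confidence) where higher
    confidence is always better: negative nearest-sample distance for 1-NN,
    decision value for SVMs, class vote fraction for the forest.
    ``class_scores`` exposes the full per-class ranking used for next-best
    reassignment during conflict resolution.
    """

    def __init__(self, spec: ClassifierSpec, training_set: TrainingSet):
        self.spec = spec
        self.sse_type = training_set.sse_type
        self.k = training_set.k
        self.scaler = training_set.scaler
        self._X = training_set.matrix(scaled=True)
        self._y = np.asarray(training_set.labels)
        self.classes_ = sorted(set(training_set.labels), key=natural_id_key)
        self._fit(training_set)

    def _fit(self, training_set: TrainingSet) -> None:
        hp = self.spec.hyperparameters
        kind = self.spec.kind
        self._clf = None
        if len(self.classes_) == 1:
            return  # degenerate: always predict the lone class
        if kind == "voronoi_1nn":
            clf = KNeighborsClassifier(n_neighbors=1, algorithm="brute",
                                       metric="euclidean")
        elif kind == "svm_linear":
            clf = SVC(kernel="linear", C=hp["C"], decision_function_shape="ovr")
        elif kind == "svm_rbf":
            clf = SVC(kernel="rbf", C=hp["C"], gamma=hp["gamma"],
                      decision_function_shape="ovr")
        elif kind == "random_forest":
            clf = RandomForestClassifier(
                n_estimators=hp["n_trees"],
                max_depth=hp["max_depth"],
                min_samples_split=hp["min_split"],
                random_state=training_set.seed,
            )
        else:  # pragma: no cover — guarded by ClassifierSpec
            raise ConfigError(f"unknown kind {kind!r}")
        clf.fit(self._X, self._y)
        self._clf = clf

    def _check_vector(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if values.shape != (self._X.shape[1],):
            raise InputError(
                f"feature length {values.shape} does not match predictor "
                f"dimension {self._X.shape[1]} (inconsistent resample count k?)"
            )
        return values

    def class_scores(self, values: np.ndarray) -> dict:
        """Per-class score, higher = better, on the classifier's own scale."""
        x = self._check_vector(values)[None, :]
        if self.spec.kind == "voronoi_1nn" or self._clf is None:
            dists = cdist(x, self._X, "euclidean")[0]
            return {
                c: -float(dists[self._y == c].min()) for c in self.classes_
            }
        if self.spec.kind == "random_forest":
            proba = self._clf.predict_proba(x)[0]
            return dict(zip(self._clf.classes_, map(float, proba)))
        dec = self._clf.decision_function(x)
        if dec.ndim == 1:  # binary: signed distance, positive favors classes_[1]
            v = float(dec[0])
            c0, c1 = self._clf.classes_
            return {c0: -v, c1: v}
        return dict(zip(self._clf.classes_, map(float, dec[0])))

    def predict(self, values: np.ndarray):
        """(label, confidence) for one already-scaled feature vector."""
        x = self._check_vector(values)
        scores = self.class_scores(x)
        if self._clf is None:
            label = self.classes_[0]
        else:
            label = str(self._clf.predict(x[None, :])[0])
        return label, scores[label]

    def ranked_labels(self, values: np.ndarray) -> list:
        """Classes from best to worst score; ties broken by label order."""
        scores = self.class_scores(values)
        return sorted(scores, key=lambda c: (-scores[c], natural_id_key(c)))


def train(training_set: TrainingSet, spec: ClassifierSpec) -> FittedPredictor:
    """Fit the requested classifier on a (scaled) training set.

    Kinds that rely on internal structure beyond a single prototype require
    J ≥ 2 augmented samples per class when more than one class is present.
    """
    if not training_set.samples:
        raise InputError("cannot train on an empty training set")
    if (
        spec.kind in ("svm_linear", "svm_rbf", "random_forest")
        and training_set.replicas < 2
        and len(set(training_set.labels)) > 1
    ):
        raise ConfigError(
            f"{spec.kind} needs J >= 2 augmented samples per class "
            f"(got J={training_set.replicas})"
        )
    return FittedPredictor(spec, training_set)


# ---------------------------------------------------------------------------
# prediction and conflict resolution


def predict_correspondence(
    sticks,
    predictors: dict,
    reject_threshold: float | None = None,
) -> list:
    """Classify every stick with its type's predictor.

    Sticks of a type with no trained predictor go straight to unmatched
    (logged).  When ``reject_threshold`` is set, sticks whose confidence is
    worse (lower) than the threshold are marked unmatched.  The output may be
    many-to-one; see :func:`resolve_conflicts`.
    """
    raw = []
    for stick in sticks:
        predictor = predictors.get(stick.sse_type)
        if predictor is None:
            logger.warning(
                "stick %s: no trained predictor for type %s — unmatched",
                stick.stick_id, stick.sse_type,
            )
            raw.append(RawAssignment(stick=stick, label=None, confidence=None,
                                     rejected=True, reason="no predictor"))
            continue
        fv = geometry.featurize(stick, predictor.k, scaler=predictor.scaler)
        label, confidence = predictor.predict(fv.values)
        scores = predictor.class_scores(fv.values)
        rejected = reject_threshold is not None and confidence < reject_threshold
        raw.append(
            RawAssignment(
                stick=stick,
                label=None if rejected else label,
                confidence=confidence,
                class_scores=scores,
                rejected=rejected,
                reason="below rejection threshold" if rejected else "",
            )
        )
    return raw


def resolve_conflicts(
    raw,
    model_sses,
    k,
    reject_threshold: float | None = None,
) -> CorrespondenceSet:
    """Turn raw (possibly many-to-one) assignments into a one-to-one matching.

    Whenever a label is claimed by more than one stick, the stick with the
    smaller orientation-free DTW cost (min of forward and reversed alignment)
    against that SSE's resampled Cα trace keeps it; cost ties break by
    lexicographic stick id.  Losers move to their next-best label among the
    labels not currently claimed by anyone, provided its score clears the
    rejection threshold; otherwise they join the unmatched sticks.  Pair
    scores in the result are the orientation-free DTW costs.

    ``k`` is the resample count for the reference traces — an int, or a
    mapping {'helix': k, 'strand': k}.
    """
    sse_by_id = {s.sse_id: s for s in model_sses}

    def k_for(sse) -> int:
        if isinstance(k, dict):
            return k[sse.sse_type]
        return int(k)

    traces = {
        s.sse_id: geometry.resample_polyline(s.calpha_coords, k_for(s))
        for s in model_sses
    }

    cost_cache: dict = {}

    def dtw_of(assignment: RawAssignment, label: str) -> float:
        key = (assignment.stick_id, label)
        if key not in cost_cache:
            cost_cache[key] = orientation_free_cost(
                traces[label], assignment.stick.axis_points
            )
        return cost_cache[key]

    unmatched_sticks = [a.stick_id for a in raw if a.label is None]
    active = {a.stick_id: a for a in raw if a.label is not None}
    current = {a.stick_id: a.label for a in active.values()}
    # candidate rankings, best first, excluding labels of the wrong type
    rankings = {
        sid: sorted(
            a.class_scores,
            key=lambda c, a=a: (-a.class_scores[c], natural_id_key(c)),
        )
        for sid, a in active.items()
    }

    while True:
        claims: dict = {}
        for sid, label in current.items():
            claims.setdefault(label, []).append(sid)
        contested = {lb: sids for lb, sids in claims.items() if len(sids) > 1}
        if not contested:
            break
        claimed_labels = set(claims)
        for label in sorted(contested, key=natural_id_key):
            sids = contested[label]
            ranked = sorted(
                sids, key=lambda sid: (dtw_of(active[sid], label), sid)
            )
            for loser in ranked[1:]:
                a = active[loser]
                next_label = None
                for cand in rankings[loser]:
                    if cand in claimed_labels:
                        continue
                    if (
                        reject_threshold is not None
                        and a.class_scores[cand] < reject_threshold
                    ):
                        continue
                    next_label = cand
                    break
                if next_label is None:
                    del current[loser]
                    unmatched_sticks.append(loser)
                    logger.info("stick %s: no remaining label — unmatched", loser)
                else:
                    current[loser] = next_label
                    claimed_labels.add(next_label)

    pairs = [
        MatchRecord(
            sse_id=label,
            stick_id=sid,
            score=dtw_of(active[sid], label),
        )
        for sid, label in current.items()
    ]
    pairs.sort(key=lambda p: natural_id_key(p.sse_id))
    matched_sses = {p.sse_id for p in pairs}
    result = CorrespondenceSet(
        pairs=pairs,
        unmatched_sses=sorted(
            (sid for sid in sse_by_id if sid not in matched_sses),
            key=natural_id_key,
        ),
        unmatched_sticks=sorted(unmatched_sticks, key=natural_id_key),
    )
    result.validate(
        sse_ids=set(sse_by_id),
        stick_ids={a.stick_id for a in raw},
    )
    return result
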