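"""The six benchmarked classifiers behind one common interface.

Models and their fixed hyperparameters:

1. ``kmeans``      — k-means, k=3, max_iter=100, best of 10 restarts.
2. ``pam``         — partitioning around medoids, k=3, Euclidean distance.
3. ``rf``          — random forest, 500 trees, mtry = floor(sqrt(p)) = 6;
                     class probability = fraction of trees voting the class.
4. ``nb``          — naive Bayes with Gaussian class-conditional densities;
                     a Laplace smoothing parameter (default 1) is recorded
                     but inert for continuous predictors.
5. ``mlp_classic`` — multilayer perceptron 15-10-5, logistic activations,
                     cross-entropy loss, resilient backpropagation with
                     weight backtracking (Rprop+), step limit 100000.
6. ``mlp_modern``  — multilayer perceptron 15-10-5, relu hidden / softmax
                     output, categorical cross-entropy, Adam.

All traits are min-max normalized to [0, 1] before modelling so distance
based methods weigh every trait equally.  The unsupervised models never
see class labels until their clusters are aligned to classes by optimal
assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.exceptions import ConvergenceWarning

from rootclass.synthetic_roots import CLASS_LABELS

# ---------------------------------------------------------------------------
# normalization


@dataclass(frozen=True)
class NormalizationParams:
    """Per-trait min and max learned on training data."""

    y_min: np.ndarray
    y_max: np.ndarray
    columns: tuple[str, ...] | None = None


def _as_matrix(X) -> tuple[np.ndarray, tuple[str, ...] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(X.columns)
    return np.asarray(X, dtype=float), None


def fit_minmax(X) -> NormalizationParams:
    """Learn y_min/y_max per trait: y_nor = (y - y_min) / (y_max - y_min)."""
    arr, cols = _as_matrix(X)
    if arr.size == 0:
        raise ValueError("empty training matrix")
    if np.isnan(arr).any():
        bad = np.flatnonzero(np.isnan(arr).any(axis=0))
        names = [cols[i] for i in bad] if cols else list(bad)
        raise ValueError(f"NaN in input columns: {names}")
    return NormalizationParams(arr.min(axis=0), arr.max(axis=0), cols)


def apply_minmax(X, params: NormalizationParams) -> np.ndarray:
    """Apply min-max scaling; constant training columns map to 0.

    Values outside the training range extrapolate beyond [0, 1] on purpose
    (no clipping), so test data is transformed, not censored.
    """
    arr, _ = _as_matrix(X)
    span = params.y_max - params.y_min
    out = np.zeros_like(arr, dtype=float)
    nz = span != 0
    out[:, nz] = (arr[:, nz] - params.y_min[nz]) / span[nz]
    return out


# ---------------------------------------------------------------------------
# clustering


def cluster_kmeans(X, k: int = 3, max_iter: int = 100, seed: int = 0,
                   n_start: int = 10) -> np.ndarray:
    """k-means cluster labels (Lloyd's algorithm, best of ``n_start``)."""
    X = np.asarray(X, dtype=float)
    if k > len(X):
        raise ValueError(f"k={k} exceeds n={len(X)} points")
    km = KMeans(n_clusters=k, n_init=n_start, max_iter=max_iter,
                algorithm="lloyd", random_state=seed)
    return km.fit_predict(X)


def _pam_objective(dist: np.ndarray, medoids: np.ndarray) -> float:
    return dist[:, medoids].min(axis=1).sum()


def cluster_pam(X, k: int = 3, metric: str = "euclidean", seed: int = 0,
                n_start: int = 10, return_medoids: bool = False):
    """Partitioning around medoids (BUILD + SWAP), best of ``n_start`` inits.

    The first initialisation is the greedy BUILD; the rest are random
    medoid draws.  Medoids are always data points; the total dissimilarity
    to medoids never increases across swaps.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n} points")
    if metric != "euclidean":
        raise ValueError("only euclidean distance is supported")
    diff = X[:, None, :] - X[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    rng = np.random.default_rng(seed)

    def build() -> list[int]:
        meds = [int(np.argmin(dist.sum(axis=1)))]
        while len(meds) < k:
            cur = dist[:, meds].min(axis=1)
            gains = np.maximum(cur[None, :] - dist, 0).sum(axis=1)
            gains[meds] = -np.inf
            meds.append(int(np.argmax(gains)))
        return meds

    def swap(meds: list[int]) -> tuple[np.ndarray, float]:
        meds = list(meds)
        best = _pam_objective(dist, np.array(meds))
        improved = True
        while improved:
            improved = False
            for mi in range(k):
                for h in range(n):
                    if h in meds:
                        continue
                    trial = list(meds)
                    trial[mi] = h
                    obj = _pam_objective(dist, np.array(trial))
                    if obj < best - 1e-12:
                        best, meds, improved = obj, trial, True
        return np.array(meds), best

    inits = [build()] + [list(rng.choice(n, size=k, replace=False))
                         for _ in range(n_start - 1)]
    best_meds, best_obj = None, np.inf
    for init in inits:
        meds, obj = swap(init)
        if obj < best_obj:
            best_meds, best_obj = meds, obj
    labels = np.argmin(dist[:, best_meds], axis=1)
    if return_medoids:
        return labels, best_meds
    return labels


def align_clusters(cluster_labels, true_labels,
                   classes: tuple[str, ...] = CLASS_LABELS) -> np.ndarray:
    """Map cluster ids to class labels by optimal one-to-one assignment.

    The assignment over all permutations maximizes total agreement with
    the provided labels; deterministic.
    """
    cluster_labels = np.asarray(cluster_labels)
    true_labels = np.asarray(true_labels)
    if len(cluster_labels) != len(true_labels):
        raise ValueError("label vectors differ in length")
    clusters = np.unique(cluster_labels)
    if len(clusters) > len(classes):
        raise ValueError("more clusters than classes")
    agree = np.zeros((len(clusters), len(classes)))
    for i, c in enumerate(clusters):
        for j, lbl in enumerate(classes):
            agree[i, j] = np.sum((cluster_labels == c) & (true_labels == lbl))
    ri, ci = linear_sum_assignment(-agree)
    mapping = {clusters[i]: classes[j] for i, j in zip(ri, ci)}
    return np.array([mapping[c] for c in cluster_labels])


# ---------------------------------------------------------------------------
# specs and prediction results


@dataclass(frozen=True)
class ModelSpec:
    """Name + hyperparameters + supervision flag for one benchmark model."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    supervised: bool = True


def default_mtry(n_traits: int = 38) -> int:
    """Number of candidate variables per random-forest split: floor(sqrt(p))."""
    return int(np.floor(np.sqrt(n_traits)))


DEFAULT_MODEL_SPECS: tuple[ModelSpec, ...] = (
    ModelSpec("kmeans", {"k": 3, "max_iter": 100, "n_start": 10}, supervised=False),
    ModelSpec("pam", {"k": 3, "metric": "euclidean", "n_start": 10}, supervised=False),
    ModelSpec("rf", {"ntree": 500, "mtry": default_mtry(38)}),
    ModelSpec("nb", {"laplace": 1}),
    ModelSpec("mlp_classic", {"layers": (15, 10, 5), "activation": "logistic",
                              "step_limit": 100000, "grad_threshold": 0.01,
                              "eta_plus": 1.2, "eta_minus": 0.5,
                              "delta0": 0.1, "delta_max": 50.0}),
    ModelSpec("mlp_modern", {"layers": (15, 10, 5), "activation": "relu",
                             "batch_size": 32, "max_epochs": 200}),
)


@dataclass
class PredictionResult:
    """Per-root class probabilities, argmax class, and max probability."""

    probabilities: tuple[float, float, float]  # in CLASS_LABELS order
    predicted_class: str = ""
    max_probability: float = 0.0

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if (p < -1e-12).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be nonnegative and sum to 1")
        i = int(np.argmax(p))  # first max wins: tie-break order B < T < TB
        self.predicted_class = CLASS_LABELS[i]
        self.max_probability = float(p[i])


# ---------------------------------------------------------------------------
# supervised models


class _SupervisedModel:
    """fit / predict_proba wrapper shared by the four supervised models."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        self.classes_ = CLASS_LABELS
        self.feature_names_: tuple[str, ...] | None = None

    def _check_y(self, y) -> np.ndarray:
        y = np.asarray(y)
        present = np.unique(y)
        bad = set(present) - set(CLASS_LABELS)
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")
        if len(present) < 2:
            raise ValueError("training labels contain a single class")
        return y

    def _check_X(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if self.feature_names_ is not None:
                missing = set(self.feature_names_) - set(X.columns)
                if missing:
                    raise ValueError(f"missing trait columns: {sorted(missing)}")
                X = X[list(self.feature_names_)]
            return X.to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_ = tuple(X.columns)
        y = self._check_y(y)
        Xa = self._check_X(X)
        if not np.isfinite(Xa).all():
            raise ValueError("non-finite values in trait matrix")
        self._fit(Xa, y)
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self._proba(self._check_X(X))

    def predict(self, X) -> list[PredictionResult]:
        return [PredictionResult(tuple(row)) for row in self.predict_proba(X)]


class RandomForestModel(_SupervisedModel):
    """Random forest whose class probability is the tree-vote fraction."""

    def _fit(self, X, y):
        hp = self.spec.hyperparameters
        self._est = RandomForestClassifier(
            n_estimators=hp.get("ntree", 500),
            max_features=hp.get("mtry", default_mtry(X.shape[1])),
            random_state=self.seed)
        self._est.fit(X, y)

    def _proba(self, X):
        # vote fractions: each tree casts one vote for its predicted class;
        # tree predictions index into self._est.classes_
        votes = np.zeros((len(X), len(self._est.classes_)))
        for tree in self._est.estimators_:
            pred = tree.predict(X).astype(int)
            votes[np.arange(len(X)), pred] += 1
        votes /= len(self._est.estimators_)
        col = [list(self._est.classes_).index(c) for c in CLASS_LABELS]
        return votes[:, col]

    @property
    def feature_importances_(self):
        """Mean impurity (Gini) decrease per trait."""
        return self._est.feature_importances_


class NaiveBayesModel(_SupervisedModel):
    """Gaussian naive Bayes; the recorded Laplace parameter smooths only
    categorical likelihoods and is inert for continuous traits."""

    def _fit(self, X, y):
        self.laplace = self.spec.hyperparameters.get("laplace", 1)
        self._est = GaussianNB()
        self._est.fit(X, y)

    def _proba(self, X):
        p = self._est.predict_proba(X)
        col = [list(self._est.classes_).index(c) for c in CLASS_LABELS]
        return p[:, col]


class ModernMLPModel(_SupervisedModel):
    """15-10-5 perceptron, relu hidden / softmax output, Adam optimizer."""

    def _fit(self, X, y):
        hp = self.spec.hyperparameters
        self._est = MLPClassifier(
            hidden_layer_sizes=hp.get("layers", (15, 10, 5)),
            activation="relu", solver="adam",
            batch_size=min(hp.get("batch_size", 32), len(X)),
            max_iter=hp.get("max_epochs", 200),
            n_iter_no_change=10, random_state=self.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self._est.fit(X, y)

    def _proba(self, X):
        p = self._est.predict_proba(X)
        col = [list(self._est.classes_).index(c) for c in CLASS_LABELS]
        return p[:, col]


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class ClassicMLPModel(_SupervisedModel):
    """15-10-5 perceptron with logistic activations trained by Rprop+.

    Resilient backpropagation adapts one step size per weight from the
    sign of the gradient (grow by eta+ on agreement, shrink by eta- on a
    sign flip) and backtracks the previous step when the error increased
    after a sign flip.  Training stops when the largest absolute gradient
    falls below ``grad_threshold`` or after ``step_limit`` steps; hitting
    the limit issues a warning and returns the model as-is.
    """

    def _fit(self, X, y):
        hp = self.spec.hyperparameters
        layers = list(hp.get("layers", (15, 10, 5)))
        self.step_limit = int(hp.get("step_limit", 100000))
        self.grad_threshold = float(hp.get("grad_threshold", 0.01))
        eta_p = hp.get("eta_plus", 1.2)
        eta_m = hp.get("eta_minus", 0.5)
        d0 = hp.get("delta0", 0.1)
        d_max = hp.get("delta_max", 50.0)
        d_min = 1e-6

        rng = np.random.default_rng(self.seed)
        sizes = [X.shape[1], *layers, len(CLASS_LABELS)]
        W = [rng.normal(0, 0.5, (sizes[i], sizes[i + 1])) for i in range(len(sizes) - 1)]
        b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        T = np.zeros((len(y), len(CLASS_LABELS)))
        for j, c in enumerate(CLASS_LABELS):
            T[np.asarray(y) == c, j] = 1.0

        def forward(Xa):
            acts = [Xa]
            for Wi, bi in zip(W, b):
                acts.append(_sigmoid(acts[-1] @ Wi + bi))
            return acts

        def gradients():
            acts = forward(X)
            out = acts[-1]
            # logistic output with per-node cross-entropy: delta = o - t
            delta = out - T
            gW, gb = [], []
            for li in range(len(W) - 1, -1, -1):
                gW.insert(0, acts[li].T @ delta)
                gb.insert(0, delta.sum(axis=0))
                if li > 0:
                    delta = (delta @ W[li].T) * acts[li] * (1.0 - acts[li])
            eps = 1e-12
            err = -np.sum(T * np.log(out + eps) + (1 - T) * np.log(1 - out + eps))
            return gW, gb, err

        params = W + b
        deltas = [np.full_like(p, d0) for p in params]
        prev_g = [np.zeros_like(p) for p in params]
        prev_step = [np.zeros_like(p) for p in params]
        prev_err = np.inf
        self.converged_ = False
        for step in range(self.step_limit):
            gW, gb, err = gradients()
            grads = gW + gb
            gmax = max(np.abs(g).max() for g in grads)
            if gmax < self.grad_threshold:
                self.converged_ = True
                self.n_steps_ = step
                break
            for p, g, d, pg, ps in zip(params, grads, deltas, prev_g, prev_step):
                sign = np.sign(g)
                agree = pg * g
                d[agree > 0] = np.minimum(d[agree > 0] * eta_p, d_max)
                d[agree < 0] = np.maximum(d[agree < 0] * eta_m, d_min)
                step_w = -sign * d
                if err > prev_err:  # weight backtracking on sign change
                    flip = agree < 0
                    step_w[flip] = -ps[flip]
                g = g.copy()
                g[agree < 0] = 0.0  # skip adaptation next step after a flip
                p += step_w
                ps[...] = step_w
                pg[...] = g
            prev_err = err
        else:
            self.n_steps_ = self.step_limit
            warnings.warn(
                f"Rprop+ reached the step limit ({self.step_limit}) without "
                "converging; returning the model as-is", stacklevel=2)
        self._W, self._b = W, b
        self._forward = forward

    def _proba(self, X):
        a = X
        for Wi, bi in zip(self._W, self._b):
            a = _sigmoid(a @ Wi + bi)
        total = a.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return a / total


# ---------------------------------------------------------------------------
# unsupervised models behind the same interface


class UnsupervisedModel:
    """Clustering model that plugs into the common evaluation interface.

    ``fit`` clusters the (unlabeled) matrix; ``align`` afterwards maps the
    clusters to class labels using truths supplied by the harness, so the
    model itself never sees labels during clustering.  New points are
    assigned to the nearest centroid (k-means) or medoid (PAM) and receive
    a one-hot probability triple.
    """

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        self.classes_ = CLASS_LABELS
        self.feature_names_ = None

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            self.feature_names_ = tuple(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        hp = self.spec.hyperparameters
        k = hp.get("k", 3)
        if self.spec.name == "kmeans":
            self.cluster_labels_ = cluster_kmeans(
                X, k=k, max_iter=hp.get("max_iter", 100), seed=self.seed,
                n_start=hp.get("n_start", 10))
            self._centers = np.stack([X[self.cluster_labels_ == c].mean(axis=0)
                                      for c in range(k)])
        elif self.spec.name == "pam":
            self.cluster_labels_, meds = cluster_pam(
                X, k=k, metric=hp.get("metric", "euclidean"), seed=self.seed,
                n_start=hp.get("n_start", 10), return_medoids=True)
            self._centers = X[meds]
        else:
            raise ValueError(f"unknown unsupervised model {self.spec.name!r}")
        return self

    def align(self, true_labels) -> np.ndarray:
        """Assign class names to clusters by optimal agreement; returns the
        aligned class label per fitted point."""
        aligned = align_clusters(self.cluster_labels_, true_labels)
        self._cluster_to_class = {}
        for c in np.unique(self.cluster_labels_):
            self._cluster_to_class[int(c)] = aligned[self.cluster_labels_ == c][0]
        return aligned

    def predict_proba(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        d = ((np.asarray(X, float)[:, None, :] - self._centers[None]) ** 2).sum(-1)
        nearest = np.argmin(d, axis=1)
        out = np.zeros((len(X), len(CLASS_LABELS)))
        for i, c in enumerate(nearest):
            cls = self._cluster_to_class[int(c)]
            out[i, CLASS_LABELS.index(cls)] = 1.0
        return out

    def predict(self, X) -> list[PredictionResult]:
        return [PredictionResult(tuple(row)) for row in self.predict_proba(X)]


_MODEL_CLASSES = {
    "rf": RandomForestModel,
    "nb": NaiveBayesModel,
    "mlp_classic": ClassicMLPModel,
    "mlp_modern": ModernMLPModel,
}


def make_model(spec: ModelSpec, seed: int = 0):
    """Instantiate the model named by ``spec`` with a reproducible seed."""
    if spec.name in ("kmeans", "pam"):
        return UnsupervisedModel(spec, seed)
    try:
        return _MODEL_CLASSES[spec.name](spec, seed)
    except KeyError:
        raise ValueError(f"unknown model {spec.name!r}") from None


def train_rf(X, y, ntree: int = 500, mtry: int | None = None, seed: int = 0):
    mtry = default_mtry(np.shape(X)[1]) if mtry is None else mtry
    return RandomForestModel(ModelSpec("rf", {"ntree": ntree, "mtry": mtry}),
                             seed).fit(X, y)


def train_nb(X, y, laplace: int = 1):
    return NaiveBayesModel(ModelSpec("nb", {"laplace": laplace})).fit(X, y)


def train_mlp_classic(X, y, spec: ModelSpec | None = None, seed: int = 0):
    return ClassicMLPModel(spec or DEFAULT_MODEL_SPECS[4], seed).fit(X, y)


def train_mlp_modern(X, y, spec: ModelSpec | None = None, seed: int = 0):
    return ModernMLPModel(spec or DEFAULT_MODEL_SPECS[5], seed).fit(X, y)


def predict(model, X) -> list[PredictionResult]:
    """Per-root prediction results from any fitted benchmark model."""
    return model.predict(X)
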