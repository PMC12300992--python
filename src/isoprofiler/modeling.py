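"""The 4-algorithm x 4-representation classifier matrix.

Algorithms: support vector machine (SVM), random forest (RF), k-nearest
neighbors (KNN), Gaussian process (GP). Representations: the four from
:mod:`isoprofiler.chemstruct`. SVM and GP accept a Tanimoto kernel on binary
fingerprints (the Jaccard kernel, which is positive semi-definite); KNN uses
Jaccard distance on bits and Euclidean distance on descriptors.

Hyperparameter selection is an exhaustive grid search scored by mean
Matthews correlation over a 5-fold stratified cross-validation; robustness
is then assessed with 10 repeated stratified 80/20 train/validation splits
(Monte-Carlo CV — the protocol's "10-fold CV"); the final model is refitted
on the full training set.

Training rows are canonicalized (sorted by canonical SMILES) before any fit,
so fitted models and their predictions are invariant to the order in which
training compounds are supplied.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import rdkit
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process import kernels as gp_kernels
from sklearn.model_selection import ParameterGrid, StratifiedKFold, StratifiedShuffleSplit
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from . import chemstruct, metrics
from .chemstruct import DESCRIPTOR_NAMES, ReprId, Scaler, Structure
from .curation import Label, LabeledCompound
from .keys881 import KEYSET_VERSION


# SVC's built-in Platt calibration is the chosen probability path; silence
# the scikit-learn 1.9 migration notice about its spelling
warnings.filterwarnings(
    "ignore", message=".*`probability` parameter was deprecated.*", category=FutureWarning
)


class ModelBundleError(RuntimeError):
    """Raised when a saved model bundle cannot be loaded safely."""


class Algorithm(str, enum.Enum):
    SVM = "SVM"
    RF = "RF"
    KNN = "KNN"
    GP = "GP"


def tanimoto_kernel(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Gram matrix of Tanimoto similarities between rows of two bit matrices.

    G[i, j] = j / (k + m - j) with j the shared on-bit count. Rows with no
    on-bits get similarity 0 everywhere (including the diagonal), the
    convention for the undefined 0/0 case.
    """
    A = np.asarray(A)
    B = np.asarray(B)
    for M in (A, B):
        if not np.isin(M, (0, 1)).all():
            raise ValueError("tanimoto_kernel requires binary {0,1} matrices")
    A = A.astype(np.float64)
    B = B.astype(np.float64)
    inter = A @ B.T
    ra = A.sum(axis=1)[:, None]
    rb = B.sum(axis=1)[None, :]
    denom = ra + rb - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        G = np.where(denom > 0, inter / np.where(denom > 0, denom, 1.0), 0.0)
    return G


class TanimotoGPKernel(gp_kernels.Kernel):
    """Tanimoto (Jaccard) kernel usable inside a Gaussian-process classifier.

    Hyperparameter-free; combine with a WhiteKernel for observation noise.
    """

    def __init__(self):
        pass

    def __call__(self, X, Y=None, eval_gradient=False):
        Y = X if Y is None else Y
        K = tanimoto_kernel(X, Y)
        if eval_gradient:
            return K, np.empty((K.shape[0], K.shape[1], 0))
        return K

    def diag(self, X):
        X = np.asarray(X)
        return np.where(X.sum(axis=1) > 0, 1.0, 0.0)

    def is_stationary(self) -> bool:
        return False


@dataclass(frozen=True)
class ModelSpec:
    algorithm: Algorithm
    repr_id: ReprId
    hyperparams: tuple[tuple[str, object], ...]
    seed: int = 0

    @property
    def params(self) -> dict:
        return dict(self.hyperparams)

    @staticmethod
    def make(algorithm, repr_id, hyperparams: dict, seed: int = 0) -> "ModelSpec":
        return ModelSpec(
            Algorithm(algorithm),
            ReprId(repr_id),
            tuple(sorted(hyperparams.items())),
            seed,
        )


@dataclass
class CVReport:
    fold_scores: list[float]
    mean: float
    std: float
    best_hyperparams: dict | None = None
    grid_results: list[tuple[dict, float]] = field(default_factory=list)


def default_hyperparams(algorithm: Algorithm, repr_id: ReprId) -> dict:
    """Sensible single-point defaults when no grid search is requested."""
    bits = ReprId(repr_id).is_bits
    return {
        Algorithm.SVM: {"C": 10.0, "kernel": "tanimoto" if bits else "rbf"},
        Algorithm.RF: {"n_estimators": 300, "max_features": "sqrt"},
        Algorithm.KNN: {"n_neighbors": 5, "weights": "distance"},
        Algorithm.GP: {"gp_kernel": "tanimoto" if bits else "rbf_white"},
    }[Algorithm(algorithm)]


def default_grid(algorithm: Algorithm, repr_id: ReprId) -> list[dict]:
    """The full configurable search grids, simpler settings first."""
    bits = ReprId(repr_id).is_bits
    algorithm = Algorithm(algorithm)
    if algorithm is Algorithm.SVM:
        kernels = ["linear", "poly2", "poly3", "rbf", "sigmoid"]
        if bits:
            kernels.append("tanimoto")
        return list(ParameterGrid({"kernel": kernels, "C": [0.1, 1.0, 10.0, 100.0]}))
    if algorithm is Algorithm.RF:
        return list(
            ParameterGrid(
                {"n_estimators": [100, 300, 500], "max_features": ["sqrt", "log2", 0.3]}
            )
        )
    if algorithm is Algorithm.KNN:
        return list(
            ParameterGrid({"n_neighbors": [1, 3, 5, 7, 9], "weights": ["uniform", "distance"]})
        )
    gp = ["dot_white", "rbf_white", "matern15_white", "matern25_white", "rq_white"]
    if bits:
        gp = ["tanimoto", "tanimoto_white"] + gp[1:2]  # proximity kernels suit bits
    return [{"gp_kernel": k} for k in gp]


def _gp_kernel(name: str) -> gp_kernels.Kernel:
    white = gp_kernels.WhiteKernel(noise_level=1e-3)
    base = {
        "tanimoto": TanimotoGPKernel(),
        "tanimoto_white": TanimotoGPKernel() + white,
        "dot_white": gp_kernels.DotProduct() + white,
        "rbf_white": gp_kernels.RBF(length_scale=1.0) + white,
        "rbf": gp_kernels.RBF(length_scale=1.0),
        "matern15_white": gp_kernels.Matern(nu=1.5) + white,
        "matern25_white": gp_kernels.Matern(nu=2.5) + white,
        "rq_white": gp_kernels.RationalQuadratic() + white,
    }
    if name not in base:
        raise ValueError(f"unknown GP kernel {name!r}")
    return base[name]


def build_estimator(spec: ModelSpec):
    """Instantiate the scikit-learn estimator for a model specification."""
    p = spec.params
    bits = spec.repr_id.is_bits
    if spec.algorithm is Algorithm.SVM:
        kernel = p.get("kernel", "rbf")
        kwargs = dict(C=p.get("C", 1.0), probability=True, random_state=spec.seed)
        if kernel == "tanimoto":
            if not bits:
                raise ValueError("Tanimoto kernel requires a bit representation")
            return SVC(kernel=tanimoto_kernel, **kwargs)
        if kernel in ("poly2", "poly3"):
            return SVC(kernel="poly", degree=int(kernel[-1]), **kwargs)
        return SVC(kernel=kernel, **kwargs)
    if spec.algorithm is Algorithm.RF:
        return RandomForestClassifier(
            n_estimators=p.get("n_estimators", 300),
            max_features=p.get("max_features", "sqrt"),
            random_state=spec.seed,
            n_jobs=1,
        )
    if spec.algorithm is Algorithm.KNN:
        return KNeighborsClassifier(
            n_neighbors=p.get("n_neighbors", 5),
            weights=p.get("weights", "uniform"),
            metric="jaccard" if bits else "euclidean",
        )
    return GaussianProcessClassifier(
        kernel=_gp_kernel(p.get("gp_kernel", "rbf_white")),
        n_restarts_optimizer=0,
        random_state=spec.seed,
    )


def _sorted_compounds(compounds: list[LabeledCompound]) -> list[LabeledCompound]:
    return sorted(compounds, key=lambda c: (c.structure.canonical_smiles, c.label.value))


def _design_matrix(
    structures: list[Structure], repr_id: ReprId, scaler: Scaler | None
) -> np.ndarray:
    X = chemstruct.featurize_matrix(structures, repr_id)
    if repr_id is ReprId.PHYSCHEM:
        if scaler is None:
            raise ValueError("descriptor representation requires a fitted scaler")
        return chemstruct.apply_scaler(scaler, X)
    return X.astype(bool) if repr_id.is_bits else X


def _labels_vector(compounds: list[LabeledCompound]) -> np.ndarray:
    return np.array([1 if c.label is Label.ACTIVE else 0 for c in compounds], dtype=int)


def _fit_and_score(spec, X_train, y_train, X_val, y_val, scale: bool) -> float:
    if scale:
        scaler = chemstruct.fit_scaler(X_train)
        X_train = chemstruct.apply_scaler(scaler, X_train)
        X_val = chemstruct.apply_scaler(scaler, X_val)
    est = build_estimator(spec)
    est.fit(X_train, y_train)
    return metrics.mcc_score(y_val, est.predict(X_val))


def grid_search(
    algorithm,
    repr_id,
    train_set: list[LabeledCompound],
    grid: list[dict] | None = None,
    seed: int = 0,
    cv_folds: int = 5,
) -> tuple[ModelSpec, CVReport]:
    """Exhaustive grid search, winner = max mean fold MCC.

    Ties are broken deterministically in favor of the earlier grid entry
    (grids list simpler configurations first).
    """
    algorithm = Algorithm(algorithm)
    repr_id = ReprId(repr_id)
    if grid is None:
        grid = default_grid(algorithm, repr_id)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    compounds = _sorted_compounds(train_set)
    structures = [c.structure for c in compounds]
    y = _labels_vector(compounds)
    X_raw = chemstruct.featurize_matrix(structures, repr_id)
    if repr_id.is_bits:
        X_raw = X_raw.astype(bool)
    scale = repr_id is ReprId.PHYSCHEM
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X_raw, y))

    best: tuple[float, ModelSpec, list[float]] | None = None
    results = []
    for params in grid:
        spec = ModelSpec.make(algorithm, repr_id, params, seed=seed)
        scores = [
            _fit_and_score(spec, X_raw[tr], y[tr], X_raw[va], y[va], scale)
            for tr, va in splits
        ]
        mean = metrics.mean_defined(scores)
        results.append((params, mean))
        if best is None or mean > best[0]:
            best = (mean, spec, scores)
    mean, spec, scores = best
    report = CVReport(
        fold_scores=scores,
        mean=mean,
        std=float(np.std([s for s in scores if not np.isnan(s)])),
        best_hyperparams=spec.params,
        grid_results=results,
    )
    return spec, report


def repeated_cv(
    spec: ModelSpec,
    train_set: list[LabeledCompound],
    cycles: int = 10,
    seed: int = 0,
    classic_kfold: bool = False,
) -> CVReport:
    """Robustness check: repeated stratified 80/20 random splits (default),
    scoring MCC on each held-out 20%; ``classic_kfold`` switches to disjoint
    k-fold partitions instead."""
    compounds = _sorted_compounds(train_set)
    y = _labels_vector(compounds)
    X_raw = chemstruct.featurize_matrix([c.structure for c in compounds], spec.repr_id)
    if spec.repr_id.is_bits:
        X_raw = X_raw.astype(bool)
    scale = spec.repr_id is ReprId.PHYSCHEM
    if classic_kfold:
        splitter = StratifiedKFold(n_splits=cycles, shuffle=True, random_state=seed)
    else:
        splitter = StratifiedShuffleSplit(n_splits=cycles, test_size=0.2, random_state=seed)
    scores = [
        _fit_and_score(spec, X_raw[tr], y[tr], X_raw[va], y[va], scale)
        for tr, va in splitter.split(X_raw, y)
    ]
    return CVReport(
        fold_scores=scores,
        mean=metrics.mean_defined(scores),
        std=float(np.std([s for s in scores if not np.isnan(s)])),
    )


@dataclass
class TrainedProfilerModel:
    """A fitted classifier bundled with everything screening needs.

    Carries the min-max scaler (descriptor models only), the training-set
    881-bit key fingerprints for downstream novelty filtering, and the
    labeling threshold of the dataset it was trained on.
    """

    spec: ModelSpec
    estimator: object
    scaler: Scaler | None
    train_keys: np.ndarray
    train_X: np.ndarray  # design matrix in the model's own representation
    threshold_pki: float
    isoform: str

    def predict_proba(self, structures: list[Structure]) -> np.ndarray:
        """Probability of the active class, one value per structure."""
        X = _design_matrix(structures, self.spec.repr_id, self.scaler)
        proba = self.estimator.predict_proba(X)
        active_col = int(np.flatnonzero(self.estimator.classes_ == 1)[0])
        return proba[:, active_col]

    def predict(self, structures: list[Structure], cutoff: float = 0.5) -> np.ndarray:
        return (self.predict_proba(structures) >= cutoff).astype(int)


def train_final(
    spec: ModelSpec,
    train_set: list[LabeledCompound],
    threshold_pki: float = 0.0,
    isoform: str = "",
) -> TrainedProfilerModel:
    """Fit the final model on the full training set."""
    compounds = _sorted_compounds(train_set)
    y = _labels_vector(compounds)
    if len(set(y)) < 2:
        raise ValueError("degenerate single-class training set")
    structures = [c.structure for c in compounds]
    scaler = None
    if spec.repr_id is ReprId.PHYSCHEM:
        scaler = chemstruct.fit_scaler(
            chemstruct.featurize_matrix(structures, ReprId.PHYSCHEM)
        )
    X = _design_matrix(structures, spec.repr_id, scaler)
    est = build_estimator(spec)
    est.fit(X, y)
    train_keys = chemstruct.featurize_matrix(structures, ReprId.KEYS_881)
    return TrainedProfilerModel(
        spec=spec,
        estimator=est,
        scaler=scaler,
        train_keys=train_keys,
        train_X=np.asarray(X),
        threshold_pki=threshold_pki,
        isoform=isoform,
    )


def evaluate(model: TrainedProfilerModel, test_set: list[LabeledCompound]) -> metrics.MetricSet:
    """Full metric set of a trained model on a held-out labeled set."""
    compounds = _sorted_compounds(test_set)
    y = _labels_vector(compounds)
    preds = model.predict([c.structure for c in compounds])
    return metrics.metric_set(metrics.confusion(y, preds))


def save_model(model: TrainedProfilerModel, path: str | Path) -> None:
    """Persist a model bundle: JSON-able manifest plus fitted state."""
    manifest = {
        "format": "isoprofiler-model-1",
        "algorithm": model.spec.algorithm.value,
        "repr_id": model.spec.repr_id.value,
        "hyperparams": model.spec.params,
        "seed": model.spec.seed,
        "threshold_pki": model.threshold_pki,
        "isoform": model.isoform,
        "descriptor_names": list(DESCRIPTOR_NAMES),
        "keyset_version": KEYSET_VERSION,
        "rdkit_version": rdkit.__version__,
    }
    joblib.dump(
        {
            "manifest": manifest,
            "estimator": model.estimator,
            "scaler": model.scaler,
            "train_keys": model.train_keys,
            "train_X": model.train_X,
        },
        path,
        compress=3,
    )


def load_model(path: str | Path) -> TrainedProfilerModel:
    """Load a model bundle, refusing on manifest or toolkit mismatch."""
    payload = joblib.load(path)
    manifest = payload.get("manifest", {})
    if manifest.get("format") != "isoprofiler-model-1":
        raise ModelBundleError("unrecognized model bundle format")
    if manifest["rdkit_version"] != rdkit.__version__:
        raise ModelBundleError(
            f"bundle was built with RDKit {manifest['rdkit_version']}, "
            f"running {rdkit.__version__}"
        )
    if manifest["keyset_version"] != KEYSET_VERSION:
        raise ModelBundleError("substructure-key dictionary version mismatch")
    if tuple(manifest["descriptor_names"]) != DESCRIPTOR_NAMES:
        raise ModelBundleError("descriptor list mismatch between bundle and toolkit")
    spec = ModelSpec.make(
        manifest["algorithm"], manifest["repr_id"], manifest["hyperparams"], manifest["seed"]
    )
    return TrainedProfilerModel(
        spec=spec,
        estimator=payload["estimator"],
        scaler=payload["scaler"],
        train_keys=payload["train_keys"],
        train_X=payload["train_X"],
        threshold_pki=manifest["threshold_pki"],
        isoform=manifest["isoform"],
    )
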