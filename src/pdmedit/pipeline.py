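"""The composite classifier: MENN editing followed by an ensemble backend.

Training proceeds in two stages.  First the training samples are optionally
edited with multi-edit nearest-neighbor, which removes samples a cross-
partition k-NN misclassifies (the non-discriminative recordings).  The
retained samples then train one of five backends: the closed-form
decorrelated RVFL ensemble (dnne), a random forest (rf, 500 trees), linear
or RBF support vector machines, or plain k-NN.  Prediction is per-sample;
a subject-level decision is the majority vote over that subject's samples.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from . import dnne as _dnne
from .dataset_io import Dataset, ScalerParams, standardize_fit
from .menn import EditTrace, MennError, multi_edit

__all__ = [
    "BACKENDS",
    "MennParams",
    "PipelineConfig",
    "TrainedPipeline",
    "PipelineError",
    "derive_seed",
    "train_pipeline",
    "predict_samples",
    "predict_subjects",
]

BACKENDS = ("dnne", "rf", "svm_linear", "svm_rbf", "knn")

_BACKEND_DEFAULTS = {
    "dnne": {"M": 5, "L": 20, "lam": 0.5},
    "rf": {"n_estimators": 500},
    "svm_linear": {"C": 1.0},
    "svm_rbf": {"C": 1.0, "gamma": "scale"},
    "knn": {"k": 1},
}


class PipelineError(RuntimeError):
    """Training or prediction failure with backend context."""


def derive_seed(seed: int, counter: int) -> int:
    """Deterministic child seed for component ``counter`` of a pipeline run.

    Children are spawned from ``SeedSequence([seed, counter])`` and reduced
    below 2**31.  Counters: 0 = MENN, 1 = backend, 2 = subsampling; the
    evaluation protocols use counters >= 16 for per-fold seeds.
    """
    ss = np.random.SeedSequence([int(seed), int(counter)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class MennParams:
    s: int = 4
    k: int = 1
    max_iter: int = 20
    stratify: bool = False


@dataclass(frozen=True)
class PipelineConfig:
    """Everything that determines a trained pipeline (given the data)."""

    backend: str = "rf"
    use_menn: bool = True
    menn: MennParams = field(default_factory=MennParams)
    backend_params: dict = field(default_factory=dict)
    scale_features: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise PipelineError(f"unknown backend {self.backend!r}")

    def resolved_backend_params(self) -> dict:
        params = dict(_BACKEND_DEFAULTS[self.backend])
        params.update(self.backend_params)
        return params

    def with_seed(self, seed: int) -> "PipelineConfig":
        return PipelineConfig(
            backend=self.backend,
            use_menn=self.use_menn,
            menn=self.menn,
            backend_params=dict(self.backend_params),
            scale_features=self.scale_features,
            seed=seed,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("menn"), dict):
            d["menn"] = MennParams(**d["menn"])
        return cls(**d)


@dataclass
class TrainedPipeline:
    config: PipelineConfig
    edit_trace: EditTrace | None
    scaler: ScalerParams | None
    model: object
    training_summary: dict

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "TrainedPipeline":
        return joblib.load(path)


def _fit_backend(name: str, params: dict, X: np.ndarray, y: np.ndarray, seed: int):
    if name == "dnne":
        return _dnne.dnne_train(
            X, y, seed=seed, scale=False, **params
        )
    if name == "rf":
        p = dict(params)
        return RandomForestClassifier(
            max_features="sqrt", random_state=seed, **p
        ).fit(X, y)
    if name == "svm_linear":
        return SVC(kernel="linear", random_state=seed, **params).fit(X, y)
    if name == "svm_rbf":
        return SVC(kernel="rbf", random_state=seed, **params).fit(X, y)
    if name == "knn":
        p = dict(params)
        k = p.pop("k", 1)
        return KNeighborsClassifier(n_neighbors=k, **p).fit(X, y)
    raise PipelineError(f"unknown backend {name!r}")


def train_pipeline(train: Dataset, config: PipelineConfig) -> TrainedPipeline:
    """Edit (optionally), scale (optionally), and fit the backend.

    MENN always runs on z-scored features (editing is Euclidean) even when
    ``scale_features`` is off for a scale-invariant backend.  If editing
    would empty a class the guard aborts training with a diagnostic.
    All randomness fans out deterministically from ``config.seed``.
    """
    if len(np.unique(train.y)) < 2:
        raise PipelineError("training data must contain both classes")

    counts_before = {
        "healthy": int(np.sum(train.y == 0)),
        "patient": int(np.sum(train.y == 1)),
    }
    trace = None
    retained = train
    if config.use_menn:
        trace = multi_edit(
            train,
            s=config.menn.s,
            k=config.menn.k,
            seed=derive_seed(config.seed, 0),
            max_iter=config.menn.max_iter,
            stratify=config.menn.stratify,
            standardize=True,
        )
        if trace.guard_triggered and trace.n_retained == 0:
            raise PipelineError("MENN editing left no usable training set")
        retained = train.subset(np.flatnonzero(trace.retained_mask))
        if len(np.unique(retained.y)) < 2:
            raise PipelineError("MENN editing emptied a class; training aborted")

    scaler = None
    X = retained.X
    if config.scale_features:
        scaler = standardize_fit(retained)
        X = scaler.transform(X)

    try:
        model = _fit_backend(
            config.backend,
            config.resolved_backend_params(),
            X,
            retained.y,
            derive_seed(config.seed, 1),
        )
    except Exception as exc:  # surface backend name per contract
        raise PipelineError(f"backend {config.backend!r} failed: {exc}") from exc

    counts_after = {
        "healthy": int(np.sum(retained.y == 0)),
        "patient": int(np.sum(retained.y == 1)),
    }
    return TrainedPipeline(
        config=config,
        edit_trace=trace,
        scaler=scaler,
        model=model,
        training_summary={
            "before": counts_before,
            "after": counts_after,
            "n_removed": counts_before["healthy"]
            + counts_before["patient"]
            - counts_after["healthy"]
            - counts_after["patient"],
        },
    )


def predict_samples(
    pipeline: TrainedPipeline, data: Dataset
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-sample labels (and scores where the backend provides them)."""
    X = data.X
    if pipeline.scaler is not None:
        X = pipeline.scaler.transform(X)
    name = pipeline.config.backend
    if name == "dnne":
        scores, labels = _dnne.dnne_predict(pipeline.model, X)
        return labels, scores
    model = pipeline.model
    labels = np.asarray(model.predict(X)).astype(int)
    scores = None
    if hasattr(model, "predict_proba") and name in ("rf", "knn"):
        scores = model.predict_proba(X)[:, list(model.classes_).index(1)]
    elif hasattr(model, "decision_function"):
        scores = model.decision_function(X)
    return labels, scores


def predict_subjects(
    pipeline: TrainedPipeline, data: Dataset, tie_rule: str = "patient"
) -> dict[str, int]:
    """Majority vote of each subject's sample predictions.

    ``tie_rule`` resolves an exactly split vote: "patient" (default,
    favors sensitivity), "healthy", or "by-mean-score" (mean backend score
    against the 0.5 / 0.0 cut, falling back to patient if no scores).
    """
    labels, scores = predict_samples(pipeline, data)
    out: dict[str, int] = {}
    sids = data.subject_ids.astype(str)
    for sid in np.unique(sids):
        mask = sids == sid
        votes = labels[mask]
        n_pat = int(votes.sum())
        n_heal = int(len(votes) - n_pat)
        if n_pat > n_heal:
            out[sid] = 1
        elif n_pat < n_heal:
            out[sid] = 0
        else:
            if tie_rule == "patient":
                out[sid] = 1
            elif tie_rule == "healthy":
                out[sid] = 0
            elif tie_rule == "by-mean-score":
                if scores is None:
                    out[sid] = 1
                else:
                    cut = 0.5 if pipeline.config.backend in ("dnne", "rf", "knn") else 0.0
                    out[sid] = int(float(np.mean(scores[mask])) >= cut)
            else:
                raise PipelineError(f"unknown tie rule {tie_rule!r}")
    return out
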