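"""Evaluation protocols: confusion metrics, LOO / LOSO / subject-independent
cross-validation, repeated runs, and between-algorithm significance tests.

The protocols differ in what a training fold may contain:

* ``loo`` — leave-one-*sample*-out; the other samples of the same subject
  stay in training, so within-subject similarity can leak.
* ``loso`` — the same per-sample predictions, aggregated per subject by
  majority vote (a subject is "patient" if most of its samples are).
* ``independent`` — all samples of the predicted sample's subject are held
  out from training, removing within-subject leakage; reported at sample
  level or additionally voted per subject.

Comparing ``loo`` against ``independent`` accuracy quantifies the leakage a
strong subject effect induces.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataset_io import Dataset
from .pipeline import (
    PipelineConfig,
    PipelineError,
    derive_seed,
    predict_samples,
    train_pipeline,
)

__all__ = [
    "MetricsReport",
    "CVResult",
    "ComparisonReport",
    "confusion_metrics",
    "run_loo",
    "run_loso",
    "run_independent",
    "repeated_runs",
    "summarize_runs",
    "compare_algorithms",
    "check_fold_hygiene",
]


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and the three headline ratios (patient = positive).

    Ratios with a zero denominator are NaN, never silently 0 — e.g. the
    specificity of an all-patient test set is undefined.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float

    def to_dict(self) -> dict:
        return {
            "TP": self.tp,
            "TN": self.tn,
            "FP": self.fp,
            "FN": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def confusion_metrics(y_true, y_pred) -> MetricsReport:
    """Accuracy, sensitivity (TPR) and specificity (TNR) from binary labels."""
    y_true = np.asarray(y_true).astype(int).ravel()
    y_pred = np.asarray(y_pred).astype(int).ravel()
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    if len(y_true) == 0:
        raise ValueError("empty input")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))

    def _ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return MetricsReport(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        accuracy=_ratio(tp + tn, tp + fp + tn + fn),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
    )


@dataclass
class CVResult:
    """Predictions and metrics from one cross-validation run.

    ``fold_id`` gives each sample's fold; ``train_indices[f]`` records the
    exact training rows of fold ``f`` so fold hygiene is auditable after
    the fact.  ``subject_pred`` is present for subject-voted protocols.
    """

    protocol: str
    y_true: np.ndarray
    y_pred: np.ndarray
    subject_ids: np.ndarray
    fold_id: np.ndarray
    train_indices: list[np.ndarray]
    sample_metrics: MetricsReport
    subject_true: dict[str, int] | None = None
    subject_pred: dict[str, int] | None = None
    subject_metrics: MetricsReport | None = None
    config: PipelineConfig | None = None
    seed: int = 0
    failed_folds: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "protocol": self.protocol,
            "seed": self.seed,
            "sample_metrics": self.sample_metrics.to_dict(),
            "n_samples": int(len(self.y_true)),
            "failed_folds": list(self.failed_folds),
        }
        if self.subject_metrics is not None:
            d["subject_metrics"] = self.subject_metrics.to_dict()
        return d


def check_fold_hygiene(result: CVResult) -> None:
    """Raise AssertionError if any fold violates the protocol's contract.

    Every sample is predicted exactly once; no sample trains its own fold;
    for subject-independent protocols no same-subject sample does either.
    """
    n = len(result.y_true)
    seen = np.zeros(n, dtype=int)
    sids = result.subject_ids.astype(str)
    for f, train_idx in enumerate(result.train_indices):
        test_idx = np.flatnonzero(result.fold_id == f)
        seen[test_idx] += 1
        overlap = np.intersect1d(test_idx, train_idx)
        assert overlap.size == 0, f"fold {f} trains on its own test samples"
        if result.protocol.startswith("independent"):
            test_subjects = set(sids[test_idx])
            train_subjects = set(sids[train_idx])
            assert not (test_subjects & train_subjects), (
                f"fold {f} trains on subjects it predicts"
            )
    assert np.all(seen == 1), "each sample must be predicted exactly once"
    # metric identity: accuracy is the prevalence-weighted mean of sens/spec
    for rep in (result.sample_metrics, result.subject_metrics):
        if rep is None:
            continue
        p, nneg = rep.tp + rep.fn, rep.tn + rep.fp
        if p and nneg:
            lhs = rep.accuracy * (p + nneg)
            rhs = rep.sensitivity * p + rep.specificity * nneg
            assert abs(lhs - rhs) < 1e-9, "metric identity violated"


def _run_folds(
    data: Dataset, config: PipelineConfig, folds: list[np.ndarray], protocol: str
) -> CVResult:
    """Generic engine: for each fold, train on the complement, predict the fold.

    The pipeline (including MENN editing) is re-trained inside every fold;
    per-fold seeds derive from ``config.seed`` and the fold index.
    """
    n = data.n_samples
    y_pred = np.full(n, -1, dtype=int)
    fold_id = np.full(n, -1, dtype=int)
    train_indices: list[np.ndarray] = []
    failed: list[int] = []
    all_idx = np.arange(n)
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx, assume_unique=True)
        train_indices.append(train_idx)
        fold_id[test_idx] = f
        fold_config = config.with_seed(derive_seed(config.seed, 16 + f))
        try:
            pipe = train_pipeline(data.subset(train_idx), fold_config)
            labels, _ = predict_samples(pipe, data.subset(test_idx))
        except PipelineError as exc:
            warnings.warn(f"fold {f} failed: {exc}")
            failed.append(f)
            continue
        y_pred[test_idx] = labels
    ok = y_pred >= 0
    if not ok.any():
        raise PipelineError("every cross-validation fold failed")
    metrics = confusion_metrics(data.y[ok], y_pred[ok])
    return CVResult(
        protocol=protocol,
        y_true=data.y.copy(),
        y_pred=y_pred,
        subject_ids=data.subject_ids.copy(),
        fold_id=fold_id,
        train_indices=train_indices,
        sample_metrics=metrics,
        config=config,
        seed=config.seed,
        failed_folds=failed,
    )


def _vote_subjects(result: CVResult, tie_rule: str = "patient") -> None:
    sids = result.subject_ids.astype(str)
    ok = result.y_pred >= 0
    true_d: dict[str, int] = {}
    pred_d: dict[str, int] = {}
    for sid in np.unique(sids):
        mask = (sids == sid) & ok
        if not mask.any():
            continue
        true_d[sid] = int(result.y_true[mask][0])
        votes = result.y_pred[mask]
        n_pat = int(votes.sum())
        n_heal = len(votes) - n_pat
        if n_pat > n_heal:
            pred_d[sid] = 1
        elif n_pat < n_heal:
            pred_d[sid] = 0
        else:
            pred_d[sid] = 1 if tie_rule == "patient" else 0
    subjects = sorted(true_d)
    result.subject_true = true_d
    result.subject_pred = pred_d
    result.subject_metrics = confusion_metrics(
        [true_d[s] for s in subjects], [pred_d[s] for s in subjects]
    )


def run_loo(data: Dataset, config: PipelineConfig) -> CVResult:
    """Leave-one-sample-out: N folds, each training on the other N-1 samples
    (same-subject samples included — the leakage-prone classical protocol)."""
    if data.n_samples < 2 or len(np.unique(data.y)) < 2:
        raise ValueError("need >= 2 samples and both classes")
    folds = [np.array([i]) for i in range(data.n_samples)]
    return _run_folds(data, config, folds, "loo")


def run_loso(
    data: Dataset, config: PipelineConfig, tie_rule: str = "patient"
) -> CVResult:
    """LOO per-sample predictions aggregated per subject by majority vote."""
    if len(data.subjects) < 2:
        raise ValueError("need >= 2 subjects")
    result = run_loo(data, config)
    result.protocol = "loso"
    _vote_subjects(result, tie_rule)
    return result


def run_independent(
    data: Dataset,
    config: PipelineConfig,
    level: str = "sample",
    tie_rule: str = "patient",
) -> CVResult:
    """Subject-independent protocol: one fold per subject; a fold's training
    set excludes *every* sample of the predicted subject."""
    if level not in ("sample", "subject"):
        raise ValueError("level must be 'sample' or 'subject'")
    if len(data.subjects) < 2 or len(np.unique(data.y)) < 2:
        raise ValueError("need >= 2 subjects and both classes")
    sids = data.subject_ids.astype(str)
    folds = [np.flatnonzero(sids == str(s)) for s in data.subjects]
    result = _run_folds(data, config, folds, f"independent_{level}")
    if level == "subject":
        _vote_subjects(result, tie_rule)
    return result


_PROTOCOLS = {
    "loo": run_loo,
    "loso": run_loso,
    "independent_sample": lambda d, c: run_independent(d, c, "sample"),
    "independent_subject": lambda d, c: run_independent(d, c, "subject"),
}


def repeated_runs(
    data: Dataset,
    config: PipelineConfig,
    protocol: str,
    n_runs: int,
    base_seed: int = 0,
) -> list[CVResult]:
    """Run a protocol ``n_runs`` times with seeds ``base_seed+1..base_seed+n``.

    Each run re-randomizes both the MENN partitions and the backend through
    its run seed.  Failed runs are recorded and skipped with a warning.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if protocol not in _PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}")
    results = []
    for r in range(1, n_runs + 1):
        try:
            results.append(
                _PROTOCOLS[protocol](data, config.with_seed(base_seed + r))
            )
        except PipelineError as exc:
            warnings.warn(f"run {r} failed: {exc}")
    if not results:
        raise PipelineError("all repeated runs failed")
    return results


def summarize_runs(reports: list[MetricsReport]) -> dict:
    """Mean / Std / Best per metric over run-level reports (NaN excluded,
    with the excluded count surfaced)."""
    out: dict = {}
    for name in ("accuracy", "sensitivity", "specificity"):
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        finite = vals[np.isfinite(vals)]
        out[name] = {
            "mean": float(np.mean(finite)) if finite.size else float("nan"),
            "std": float(np.std(finite)) if finite.size else float("nan"),
            "best": float(np.max(finite)) if finite.size else float("nan"),
            "n_undefined": int(len(vals) - len(finite)),
        }
    out["n_runs"] = len(reports)
    return out


@dataclass(frozen=True)
class ComparisonReport:
    """Per-metric two-sided Welch p-values between two algorithms' runs."""

    p_values: dict
    degenerate: dict
    n_a: int
    n_b: int
    test: str = "welch_t_two_sided"

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "p_values": self.p_values,
            "degenerate": self.degenerate,
        }


def compare_algorithms(
    runs_a: list[MetricsReport], runs_b: list[MetricsReport]
) -> ComparisonReport:
    """Welch's unequal-variance two-sided t-test per metric over run-level
    values.  Two constant, equal samples give p = 1 by convention (flagged);
    a metric undefined in every run gives NaN."""
    if len(runs_a) < 2 or len(runs_b) < 2:
        raise ValueError("need >= 2 runs per algorithm")
    p_values: dict = {}
    degenerate: dict = {}
    for name in ("accuracy", "sensitivity", "specificity"):
        a = np.array([getattr(r, name) for r in runs_a], dtype=float)
        b = np.array([getattr(r, name) for r in runs_b], dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2:
            p_values[name] = float("nan")
            degenerate[name] = True
            continue
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            p_values[name] = 1.0
            degenerate[name] = True
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat = stats.ttest_ind(a, b, equal_var=False)
        p = float(stat.pvalue)
        p_values[name] = 1.0 if math.isnan(p) else p
        degenerate[name] = math.isnan(p)
    return ComparisonReport(
        p_values=p_values, degenerate=degenerate, n_a=len(runs_a), n_b=len(runs_b)
    )
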