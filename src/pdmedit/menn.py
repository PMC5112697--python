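"""Multi-edit nearest-neighbor (MENN) instance selection.

Editing removes training samples that a reference nearest-neighbor
classifier misclassifies, so the retained set better represents each
class's region.  The multi-edit variant partitions the data into ``s``
disjoint subsets, classifies each subset with a k-NN trained on the *next*
subset (circularly), deletes every misclassified sample, and repeats with a
fresh random partition until a full pass removes nothing.

Asymptotically, each editing round squares the exponent in the conditional
error of the nearest-neighbor rule, driving it from the classical
``1 - sum_i p_i^2`` at no editing toward the Bayes floor ``min_i p_i``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .dataset_io import Dataset, fit_scaler

__all__ = [
    "EditTrace",
    "IterationRecord",
    "MennError",
    "partition_samples",
    "edit_pass",
    "multi_edit",
    "knn_predict",
    "asymptotic_edit_error",
]


class MennError(ValueError):
    """Invalid editing parameters or degenerate input."""


@dataclass(frozen=True)
class IterationRecord:
    """One outer editing iteration: the partition used and what it removed."""

    iteration: int
    removed: tuple[int, ...]  # original-dataset indices
    assignment: tuple[int, ...]  # subset index per *retained* sample, in order


@dataclass
class EditTrace:
    """Full audit record of a multi-edit run.

    ``retained_mask`` indexes the input dataset; ``converged`` is True when
    the final pass removed nothing; ``guard_triggered`` is True when a pass
    was withheld because applying it would have emptied a class.
    """

    retained_mask: np.ndarray
    iterations: list[IterationRecord]
    s: int
    k: int
    seed: int
    max_iter: int
    converged: bool
    guard_triggered: bool = False

    @property
    def n_retained(self) -> int:
        return int(self.retained_mask.sum())

    @property
    def n_removed(self) -> int:
        return int((~self.retained_mask).sum())

    def to_json(self) -> str:
        return json.dumps(
            {
                "retained_mask": self.retained_mask.astype(int).tolist(),
                "iterations": [
                    {
                        "iteration": it.iteration,
                        "removed": list(it.removed),
                        "assignment": list(it.assignment),
                    }
                    for it in self.iterations
                ],
                "s": self.s,
                "k": self.k,
                "seed": self.seed,
                "max_iter": self.max_iter,
                "converged": self.converged,
                "guard_triggered": self.guard_triggered,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "EditTrace":
        d = json.loads(text)
        return cls(
            retained_mask=np.asarray(d["retained_mask"], dtype=bool),
            iterations=[
                IterationRecord(
                    it["iteration"], tuple(it["removed"]), tuple(it["assignment"])
                )
                for it in d["iterations"]
            ],
            s=d["s"],
            k=d["k"],
            seed=d["seed"],
            max_iter=d["max_iter"],
            converged=d["converged"],
            guard_triggered=d["guard_triggered"],
        )


def partition_samples(
    n: int,
    s: int,
    seed: int,
    *,
    allow_small_s: bool = False,
    y: np.ndarray | None = None,
) -> np.ndarray:
    """Randomly assign ``n`` samples to ``s`` subsets of near-equal size.

    Subset sizes differ by at most one; the assignment is a deterministic
    function of ``(n, s, seed)``.  The classical constraint ``s > 3`` is
    enforced unless ``allow_small_s``.  If ``y`` is given the split is
    stratified: each class is partitioned separately (optional variant; the
    default procedure partitions the pooled samples).
    """
    if s <= 3 and not allow_small_s:
        raise MennError(f"s={s} violates the s > 3 constraint (set allow_small_s)")
    if s < 1:
        raise MennError("s must be positive")
    if n < s:
        raise MennError(f"cannot split {n} samples into {s} nonempty subsets")
    rng = np.random.default_rng(seed)
    if y is None:
        assignment = np.empty(n, dtype=int)
        assignment[rng.permutation(n)] = np.arange(n) % s
        return assignment
    y = np.asarray(y)
    assignment = np.empty(n, dtype=int)
    offset = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        sub = np.empty(len(idx), dtype=int)
        sub[rng.permutation(len(idx))] = (np.arange(len(idx)) + offset) % s
        assignment[idx] = sub
        offset += len(idx)
    return assignment


def knn_predict(
    X_train: np.ndarray, y_train: np.ndarray, X_query: np.ndarray, k: int = 1
) -> np.ndarray:
    """Deterministic Euclidean k-NN with documented tie rules.

    Distance ties resolve toward the lowest training-row index (stable
    argsort); vote ties (even ``k``) resolve toward the patient class (1).
    """
    if len(X_train) == 0:
        raise MennError("empty training set for k-NN")
    if k < 1:
        raise MennError("k must be >= 1")
    k_eff = min(k, len(X_train))
    d = cdist(np.atleast_2d(X_query), np.atleast_2d(X_train))
    nn = np.argsort(d, axis=1, kind="stable")[:, :k_eff]
    votes = np.asarray(y_train)[nn].sum(axis=1)
    return (2 * votes >= k_eff).astype(int)


def edit_pass(
    X: np.ndarray, y: np.ndarray, assignment: np.ndarray, k: int = 1
) -> np.ndarray:
    """One editing sweep: classify each subset with a k-NN trained on the next.

    Subset ``i`` is validated against a k-NN trained on subset ``(i+1) mod s``
    (the circular rule); returns the sorted array of misclassified row
    indices (positions within ``X``).
    """
    assignment = np.asarray(assignment)
    s = int(assignment.max()) + 1
    removed: list[int] = []
    for i in range(s):
        val_idx = np.flatnonzero(assignment == i)
        train_idx = np.flatnonzero(assignment == (i + 1) % s)
        if len(train_idx) == 0:
            raise MennError(f"training subset {(i + 1) % s} is empty")
        if len(val_idx) == 0:
            continue
        pred = knn_predict(X[train_idx], y[train_idx], X[val_idx], k=k)
        removed.extend(val_idx[pred != np.asarray(y)[val_idx]].tolist())
    return np.array(sorted(removed), dtype=int)


def multi_edit(
    data: Dataset,
    s: int = 4,
    k: int = 1,
    seed: int = 0,
    max_iter: int = 20,
    *,
    stratify: bool = False,
    allow_small_s: bool = False,
    standardize: bool = True,
) -> EditTrace:
    """Iterated editing with a fresh random partition each round.

    Each outer iteration draws a new partition (seed advanced by the
    iteration index), runs :func:`edit_pass`, and drops the misclassified
    samples.  Stops when a pass removes nothing (``converged``), at
    ``max_iter``, or — the viability guard — *before* applying a pass that
    would leave a class empty, in which case the trace is flagged and marked
    unconverged.

    Distances are computed on z-scored features by default (editing is
    Euclidean; raw acoustic features have wildly different scales).
    """
    if data.n_samples == 0:
        raise MennError("empty dataset")
    X = data.X
    if standardize:
        X = fit_scaler(X).transform(X)
    y = data.y
    n = data.n_samples

    retained = np.arange(n)
    iterations: list[IterationRecord] = []
    converged = False
    guard = False
    for t in range(max_iter):
        if len(retained) < s:
            guard = True
            break
        assignment = partition_samples(
            len(retained),
            s,
            seed + t,
            allow_small_s=allow_small_s,
            y=y[retained] if stratify else None,
        )
        removed_local = edit_pass(X[retained], y[retained], assignment, k=k)
        removed_orig = retained[removed_local]
        keep = np.setdiff1d(retained, removed_orig, assume_unique=True)
        # viability guard: never let a pass empty a class
        if len(keep) == 0 or len(np.unique(y[keep])) < 2:
            guard = True
            break
        iterations.append(
            IterationRecord(
                iteration=t,
                removed=tuple(int(i) for i in removed_orig),
                assignment=tuple(int(a) for a in assignment),
            )
        )
        retained = keep
        if len(removed_orig) == 0:
            converged = True
            break

    mask = np.zeros(n, dtype=bool)
    mask[retained] = True
    return EditTrace(
        retained_mask=mask,
        iterations=iterations,
        s=s,
        k=k,
        seed=seed,
        max_iter=max_iter,
        converged=converged,
        guard_triggered=guard,
    )


def asymptotic_edit_error(
    posteriors, M: int, form: str = "corrected"
) -> float:
    """Asymptotic conditional error of the M-times-edited NN rule at a point.

    With class posteriors ``p_i`` at ``x``, the un-edited nearest-neighbor
    rule has asymptotic conditional error ``1 - sum_i p_i^2``.  Each editing
    round squares the effective exponent.  Two published forms are exposed:

    ``corrected`` (default)
        ``1 - sum_i p_i^(2^M + 1) / sum_i p_i^(2^M)``, which decreases
        monotonically in ``M`` (for a unique posterior maximum) and converges
        to the Bayes floor ``min_i p_i``.
    ``printed``
        ``1 - sum_i p_i^(2^(M+1)) / sum_i p_i^(2^M)``, a variant seen in
        print whose numerator exponent doubles rather than increments; it
        degenerates to 1 as ``M`` grows and is kept only for reference.

    Both coincide at ``M = 0``.  Computed in a scaled form that is stable
    for large ``M`` (the raw powers underflow).
    """
    p = np.asarray(posteriors, dtype=float)
    if p.ndim != 1 or len(p) < 2:
        raise MennError("posteriors must be a vector of >= 2 class probabilities")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise MennError("posteriors must be nonnegative and sum to 1")
    if M < 0:
        raise MennError("edit count M must be nonnegative")
    a = 2.0**M
    pmax = p.max()
    if pmax == 0:
        raise MennError("degenerate posterior vector")
    t = (p / pmax) ** a  # in (0, 1], exact 1 at the argmax
    den = t.sum()
    if form == "corrected":
        num = (t * p).sum()
        return float(1.0 - num / den)
    if form == "printed":
        num = (pmax**a) * (t * t).sum()
        return float(1.0 - num / den)
    raise MennError(f"unknown form {form!r}")
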