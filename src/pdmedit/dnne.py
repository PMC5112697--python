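"""Closed-form decorrelated ensembles of random-feature (RVFL-style) networks.

The ensemble consists of M single-hidden-layer networks with L sigmoid
neurons each.  Hidden weights and biases are random and fixed; only the
output weights are learned, and they are learned *jointly*: a negative-
correlation penalty with strength ``lam`` couples the networks through a
single (M*L) x (M*L) linear system

    H_corr @ B_ens = T_h

whose entries are hidden-neuron co-activation sums ``phi`` scaled by
``C1 = 1 - 2*lam*(M-1)^2/M^2`` on same-network blocks and
``C2 = 2*lam*(M-1)/M^2`` on cross-network blocks.  At ``lam = 0`` the
system decouples into M independent least-squares fits; at large ``lam``
and M the matrix ``C1`` turns negative and the system may become indefinite,
which the solver handles with escalating ridge stabilization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .dataset_io import ScalerParams, fit_scaler

__all__ = [
    "DnneError",
    "RVFLEnsembleSpec",
    "NormalSystem",
    "SolverNote",
    "RidgePolicy",
    "DNNEModel",
    "c_constants",
    "index_map",
    "flatten_index",
    "hidden_activations",
    "build_normal_system",
    "solve_output_weights",
    "dnne_train",
    "dnne_predict",
    "dnne_grid_search",
]


class DnneError(ValueError):
    """Invalid ensemble parameters or a numerically unusable system."""


def c_constants(lam: float, M: int) -> tuple[float, float]:
    """Penalty constants of the joint normal system.

    ``C1 = 1 - 2*lam*(M-1)^2 / M^2`` scales same-network co-activation
    terms, ``C2 = 2*lam*(M-1) / M^2`` the cross-network ones.  They satisfy
    ``C1 + (M-1)*C2 = 1`` for every ``lam``; note C1 < 0 is possible.
    C1 is evaluated through that conservation identity (algebraically
    identical to its closed form) so the identity is exact in floating
    point.
    """
    if not (0.0 <= lam <= 1.0):
        raise DnneError(f"lam={lam} outside [0, 1]")
    if M < 2:
        raise DnneError(f"M={M} must be >= 2")
    c2 = 2.0 * lam * (M - 1) / M**2
    c1 = 1.0 - (M - 1) * c2
    return c1, c2


def index_map(p: int, L: int) -> tuple[int, int]:
    """Map a 1-based flat index ``p`` to (network m, neuron n), both 1-based:
    ``m = ceil(p / L)``, ``n = ((p - 1) mod L) + 1``."""
    if p < 1:
        raise DnneError(f"flat index {p} out of range")
    m = math.ceil(p / L)
    n = (p - 1) % L + 1
    return m, n


def flatten_index(m: int, n: int, L: int) -> int:
    """Inverse of :func:`index_map`: ``p = (m - 1) * L + n`` (all 1-based)."""
    if not (1 <= n <= L) or m < 1:
        raise DnneError(f"(m={m}, n={n}) out of range for L={L}")
    return (m - 1) * L + n


@dataclass
class RVFLEnsembleSpec:
    """Random hidden layer of an M-network ensemble.

    ``hidden_weights`` has shape (M, L, d) and ``hidden_biases`` (M, L),
    both drawn from Uniform(-1, 1) deterministically from ``seed`` —
    independently per (network, neuron), so that decorrelation across
    networks is meaningful.
    """

    M: int
    L: int
    d: int
    lam: float
    seed: int
    hidden_weights: np.ndarray = field(repr=False, default=None)
    hidden_biases: np.ndarray = field(repr=False, default=None)
    base_function: str = "sigmoid"

    def __post_init__(self) -> None:
        if self.M < 2 or self.L < 1 or self.d < 1:
            raise DnneError("require M >= 2, L >= 1, d >= 1")
        if not (0.0 <= self.lam <= 1.0):
            raise DnneError("lam must lie in [0, 1]")
        if self.base_function != "sigmoid":
            raise DnneError(f"unsupported base function {self.base_function!r}")
        if self.hidden_weights is None:
            rng = np.random.default_rng(self.seed)
            self.hidden_weights = rng.uniform(-1, 1, size=(self.M, self.L, self.d))
            self.hidden_biases = rng.uniform(-1, 1, size=(self.M, self.L))

    def to_dict(self) -> dict:
        return {
            "M": self.M,
            "L": self.L,
            "d": self.d,
            "lam": self.lam,
            "seed": self.seed,
            "base_function": self.base_function,
        }


@dataclass(frozen=True)
class NormalSystem:
    """The joint linear system ``H_corr @ B = T_h`` of the ensemble fit."""

    H_corr: np.ndarray
    T_h: np.ndarray
    M: int
    L: int
    lam: float


@dataclass
class SolverNote:
    """Record of how the normal system was solved (for audit)."""

    method: str  # "direct", "ridge", or "pinv"
    condition: float
    ridge_eps: list[float] = field(default_factory=list)
    residual_inf: float = float("nan")


@dataclass(frozen=True)
class RidgePolicy:
    """Stabilization schedule for ill-conditioned normal systems:
    jitter ``eps * mean(diag) * I`` starting at ``eps0``, escalating by
    ``factor`` up to ``eps_max``, then a pseudo-inverse fallback."""

    cond_threshold: float = 1e10
    eps0: float = 1e-8
    eps_max: float = 1e-2
    factor: float = 10.0


@dataclass
class DNNEModel:
    """A fitted decorrelated ensemble: spec + joint output weights.

    ``B_ens`` is ordered network-major: beta_11..beta_1L, beta_21.., so that
    flat position ``(m-1)*L + n`` (1-based) holds neuron n of network m.
    """

    spec: RVFLEnsembleSpec
    B_ens: np.ndarray
    scaler: ScalerParams | None
    threshold: float = 0.5
    solver_note: SolverNote | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "spec": self.spec.to_dict(),
                "B_ens": self.B_ens.tolist(),
                "scaler": None if self.scaler is None else self.scaler.to_dict(),
                "threshold": self.threshold,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DNNEModel":
        d = json.loads(text)
        spec = RVFLEnsembleSpec(**d["spec"])
        return cls(
            spec=spec,
            B_ens=np.asarray(d["B_ens"], dtype=float),
            scaler=None
            if d["scaler"] is None
            else ScalerParams.from_dict(d["scaler"]),
            threshold=d["threshold"],
        )


def hidden_activations(spec: RVFLEnsembleSpec, X: np.ndarray) -> np.ndarray:
    """Hidden-output matrix G of shape (N, M*L).

    Column ``(m-1)*L + n`` (1-based) holds ``sigmoid(w_mn . x + b_mn)`` for
    neuron n of network m; every entry lies strictly in (0, 1).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != spec.d:
        raise DnneError(
            f"feature dimension {X.shape[1]} != spec dimension {spec.d}"
        )
    W = spec.hidden_weights.reshape(spec.M * spec.L, spec.d)
    b = spec.hidden_biases.reshape(spec.M * spec.L)
    return expit(X @ W.T + b)


def build_normal_system(
    G: np.ndarray,
    y: np.ndarray,
    lam: float,
    M: int,
    L: int,
    row_masks: np.ndarray | None = None,
) -> NormalSystem:
    """Assemble ``H_corr`` and ``T_h`` from hidden activations and targets.

    ``phi((i,j),(k,l)) = sum_n g_ij(x_n) g_kl(x_n)`` and
    ``phi(i,j) = sum_n g_ij(x_n) y_n``; entry (p, q) of ``H_corr`` is
    ``C1 * phi`` when p and q index the same network and ``C2 * phi``
    otherwise.

    ``row_masks`` (optional, shape (M, N) boolean) restricts which training
    rows contribute to each network's sums — the per-network subsampling
    ("bagging") variant; a phi term between networks i and k then sums over
    rows visible to both.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if G.ndim != 2 or G.shape[1] != M * L:
        raise DnneError(f"G must have M*L = {M * L} columns")
    if G.shape[0] != len(y):
        raise DnneError("G and y disagree on the number of samples")
    if not (np.all(np.isfinite(G)) and np.all(np.isfinite(y))):
        raise DnneError("non-finite entries in G or y")
    c1, c2 = c_constants(lam, M)
    net = np.repeat(np.arange(M), L)

    if row_masks is None:
        Phi = G.T @ G
        T_h = G.T @ y
    else:
        row_masks = np.asarray(row_masks, dtype=float)
        if row_masks.shape != (M, G.shape[0]):
            raise DnneError("row_masks must have shape (M, N)")
        Phi = np.empty((M * L, M * L))
        for i in range(M):
            for kk in range(i, M):
                w = row_masks[i] * row_masks[kk]
                block = G[:, i * L : (i + 1) * L].T @ (
                    w[:, None] * G[:, kk * L : (kk + 1) * L]
                )
                Phi[i * L : (i + 1) * L, kk * L : (kk + 1) * L] = block
                Phi[kk * L : (kk + 1) * L, i * L : (i + 1) * L] = block.T
        T_h = np.concatenate(
            [
                G[:, i * L : (i + 1) * L].T @ (row_masks[i] * y)
                for i in range(M)
            ]
        )

    same = net[:, None] == net[None, :]
    H = np.where(same, c1, c2) * Phi
    return NormalSystem(H_corr=H, T_h=T_h, M=M, L=L, lam=lam)


def solve_output_weights(
    system: NormalSystem, ridge_policy: RidgePolicy | None = None
) -> tuple[np.ndarray, SolverNote]:
    """Solve ``H_corr @ B = T_h``, stabilizing ill-conditioned systems.

    Direct solve when the condition estimate is below the policy threshold;
    otherwise escalate ridge jitter ``eps * mean(diag) * I`` (eps from
    ``eps0`` up to ``eps_max`` by ``factor``), recording each step; final
    fallback is a pseudo-inverse least-squares solve.
    """
    policy = ridge_policy or RidgePolicy()
    H, T = system.H_corr, system.T_h
    if not (np.all(np.isfinite(H)) and np.all(np.isfinite(T))):
        raise DnneError("non-finite normal system")
    cond = float(np.linalg.cond(H))
    note = SolverNote(method="direct", condition=cond)
    scale = float(np.abs(np.diag(H)).mean()) or 1.0

    def _residual(B: np.ndarray) -> float:
        return float(np.abs(H @ B - T).max())

    if cond < policy.cond_threshold:
        B = np.linalg.solve(H, T)
        note.residual_inf = _residual(B)
        return B, note

    eps = policy.eps0
    while eps <= policy.eps_max * (1 + 1e-12):
        note.ridge_eps.append(eps)
        Hr = H + eps * scale * np.eye(len(T))
        if np.linalg.cond(Hr) < policy.cond_threshold:
            B = np.linalg.solve(Hr, T)
            if np.all(np.isfinite(B)):
                note.method = "ridge"
                note.residual_inf = _residual(B)
                return B, note
        eps *= policy.factor
    B = np.linalg.pinv(H) @ T
    if not np.all(np.isfinite(B)):
        raise DnneError("normal-system solve failed after all stabilizations")
    note.method = "pinv"
    note.residual_inf = _residual(B)
    return B, note


def dnne_train(
    X: np.ndarray,
    y: np.ndarray,
    M: int = 5,
    L: int = 20,
    lam: float = 0.5,
    seed: int = 0,
    *,
    scale: bool = True,
    bagging_fraction: float | None = None,
    ridge_policy: RidgePolicy | None = None,
    threshold: float = 0.5,
) -> DNNEModel:
    """Fit the closed-form decorrelated ensemble on {0,1}-labelled data.

    Features are z-scored (fitted here) unless ``scale=False``; labels are
    used directly as regression targets.  ``bagging_fraction`` switches on
    the optional per-network row-subsampling mode (each network sees only a
    random fraction of the training rows in its phi sums); the default is
    the shared-data closed form.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(float).ravel()
    if len(np.unique(y)) < 2:
        raise DnneError("training labels contain a single class")
    scaler = fit_scaler(X) if scale else None
    Xs = scaler.transform(X) if scaler is not None else X
    spec = RVFLEnsembleSpec(M=M, L=L, d=X.shape[1], lam=lam, seed=seed)
    G = hidden_activations(spec, Xs)
    row_masks = None
    if bagging_fraction is not None:
        if not (0.0 < bagging_fraction <= 1.0):
            raise DnneError("bagging_fraction must lie in (0, 1]")
        rng = np.random.default_rng(seed + 1)
        n = len(y)
        n_keep = max(2, int(round(bagging_fraction * n)))
        row_masks = np.zeros((M, n), dtype=bool)
        for i in range(M):
            row_masks[i, rng.choice(n, size=n_keep, replace=False)] = True
    system = build_normal_system(G, y, lam, M, L, row_masks=row_masks)
    B, note = solve_output_weights(system, ridge_policy)
    return DNNEModel(
        spec=spec, B_ens=B, scaler=scaler, threshold=threshold, solver_note=note
    )


def dnne_predict(
    model: DNNEModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble scores and hard labels for new samples.

    The score is the mean of the M base-network outputs,
    ``(1/M) * sum_ij beta_ij g_ij(x)``; label 1 (patient) iff the score
    reaches the model threshold.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.spec.d:
        raise DnneError("feature dimension mismatch")
    Xs = model.scaler.transform(X) if model.scaler is not None else X
    G = hidden_activations(model.spec, Xs)
    scores = G @ model.B_ens / model.spec.M
    labels = (scores >= model.threshold).astype(int)
    return scores, labels


def dnne_grid_search(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray | None = None,
    M_grid=range(2, 16),
    L_grid=range(5, 51),
    lam_grid=tuple(round(0.1 * i, 1) for i in range(11)),
    inner_cv: int = 5,
    seed: int = 0,
    boosting_threshold=None,
    **train_kwargs,
):
    """Exhaustive (M, L, lam) search scored by inner-CV mean accuracy.

    Folds are grouped by subject when ``groups`` is given (GroupKFold),
    else stratified.  Ties break toward smaller M, then L, then lam.
    Returns ``(best_params, table)`` where ``table`` is a pandas DataFrame
    with one row per evaluated cell (failed cells carry NaN scores).

    ``boosting_threshold`` is accepted for config compatibility but has no
    referent in the closed-form fit; it is ignored with a warning.
    """
    import warnings

    import pandas as pd
    from sklearn.model_selection import GroupKFold, StratifiedKFold

    if boosting_threshold is not None:
        warnings.warn(
            "boosting_threshold has no effect on the closed-form ensemble "
            "fit and is ignored"
        )

    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(int).ravel()
    if groups is not None:
        groups = np.asarray(groups)
        splitter = GroupKFold(n_splits=min(inner_cv, len(np.unique(groups))))
        folds = list(splitter.split(X, y, groups))
    else:
        splitter = StratifiedKFold(
            n_splits=inner_cv, shuffle=True, random_state=seed
        )
        folds = list(splitter.split(X, y))

    records = []
    best = None  # (score, M, L, lam)
    for M in M_grid:
        for L in L_grid:
            for lam in lam_grid:
                accs = []
                failed = False
                for tr, te in folds:
                    if len(np.unique(y[tr])) < 2:
                        failed = True
                        break
                    model = dnne_train(
                        X[tr], y[tr], M=M, L=L, lam=lam, seed=seed, **train_kwargs
                    )
                    _, pred = dnne_predict(model, X[te])
                    accs.append(float(np.mean(pred == y[te])))
                score = float("nan") if failed else float(np.mean(accs))
                records.append(
                    {"M": M, "L": L, "lam": lam, "score": score, "failed": failed}
                )
                if not failed:
                    cand = (-score, M, L, lam)
                    if best is None or cand < best:
                        best = cand
    table = pd.DataFrame.from_records(records)
    if best is None:
        raise DnneError("every grid cell failed (degenerate inner folds)")
    _, M, L, lam = best
    return {"M": M, "L": L, "lam": lam}, table
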