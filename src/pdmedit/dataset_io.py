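"""Domain types, delimited-text I/O and a subject-structured synthetic generator.

The data model mirrors dysphonia-screening studies in which each subject
(healthy control or patient) contributes many short speech recordings, each
summarised as a fixed-length acoustic feature vector.  All samples of one
subject share that subject's diagnosis label, which is what makes
subject-aware cross-validation (and its leakage pitfalls) meaningful.
"""

from __future__ import annotations

import csv
import enum
import io
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SampleKind",
    "Dataset",
    "ColumnLayout",
    "SAKAR_TRAIN_LAYOUT",
    "SAKAR_TEST_LAYOUT",
    "ScalerParams",
    "SyntheticConfig",
    "ParseError",
    "ValidationError",
    "load_sakar_table",
    "read_csv_dataset",
    "write_csv_dataset",
    "generate_synthetic",
    "bayes_error_rate",
    "standardize_fit",
    "standardize_apply",
    "fit_scaler",
]


class ParseError(ValueError):
    """A malformed row in a delimited-text table (carries the 1-based line number)."""


class ValidationError(ValueError):
    """A structurally valid table that violates a dataset invariant."""


class SampleKind(str, enum.Enum):
    """Taxonomy of speech-sample types recorded per subject."""

    VOWEL = "vowel"
    NUMBER = "number"
    WORD = "word"
    SENTENCE = "sentence"
    UNKNOWN = "unknown"


@dataclass
class Dataset:
    """A sample-major feature table with subject structure.

    Attributes
    ----------
    subject_ids : array of str, one per sample.
    X : float array of shape (n_samples, d); all entries finite.
    y : int array in {0, 1}; 0 = healthy, 1 = patient.  Every sample of a
        subject carries the same label.
    sample_kind : optional array of :class:`SampleKind` values.
    contaminated : optional boolean array; set by the synthetic generator to
        mark samples drawn from the opposite class's distribution
        (ground-truth "non-discriminative" samples).
    """

    subject_ids: np.ndarray
    X: np.ndarray
    y: np.ndarray
    sample_kind: np.ndarray | None = None
    contaminated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValidationError("feature matrix must be 2-D")
        n = self.X.shape[0]
        if len(self.subject_ids) != n or len(self.y) != n:
            raise ValidationError("subject_ids, X and y must have equal length")
        if n and not np.all(np.isfinite(self.X)):
            raise ValidationError("features must be finite")
        if n and not np.isin(self.y, (0, 1)).all():
            raise ValidationError("labels must be 0 (healthy) or 1 (patient)")
        self._check_subject_labels()

    def _check_subject_labels(self) -> None:
        for sid in np.unique(self.subject_ids.astype(str)):
            labels = set(self.y[self.subject_ids.astype(str) == sid].tolist())
            if len(labels) > 1:
                raise ValidationError(
                    f"subject {sid!r} has conflicting labels {sorted(labels)}"
                )

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def subjects(self) -> np.ndarray:
        """Unique subject identifiers in first-appearance order."""
        _, idx = np.unique(self.subject_ids.astype(str), return_index=True)
        return self.subject_ids[np.sort(idx)]

    def subset(self, indices) -> "Dataset":
        """A new Dataset restricted to ``indices`` (order preserved)."""
        indices = np.asarray(indices)
        return Dataset(
            subject_ids=self.subject_ids[indices],
            X=self.X[indices],
            y=self.y[indices],
            sample_kind=None if self.sample_kind is None else self.sample_kind[indices],
            contaminated=None
            if self.contaminated is None
            else self.contaminated[indices],
        )


@dataclass(frozen=True)
class ColumnLayout:
    """Describes where subject id, features and label live in a delimited row.

    All positions are 0-based column indices; ``feature_cols`` is an
    inclusive ``(first, last)`` range.  Columns named in ``ignore_cols``
    (e.g. a clinical severity score) are skipped.
    """

    id_col: int = 0
    feature_cols: tuple[int, int] = (1, 26)
    label_col: int = 27
    ignore_cols: tuple[int, ...] = ()

    @property
    def d(self) -> int:
        return self.feature_cols[1] - self.feature_cols[0] + 1

    @property
    def min_columns(self) -> int:
        cols = [self.id_col, self.feature_cols[1], self.label_col, *self.ignore_cols]
        return max(cols) + 1


#: UCI deposit, training file: id, 26 features, UPDRS severity (ignored), class.
SAKAR_TRAIN_LAYOUT = ColumnLayout(0, (1, 26), 28, (27,))
#: UCI deposit, test file: id, 26 features, class.
SAKAR_TEST_LAYOUT = ColumnLayout(0, (1, 26), 27)


def _split_row(line: str) -> list[str]:
    if "," in line:
        return next(csv.reader(io.StringIO(line)))
    return line.split()


def load_sakar_table(
    path,
    layout: ColumnLayout = SAKAR_TRAIN_LAYOUT,
    *,
    has_header: bool = False,
    label_map: dict | None = None,
) -> Dataset:
    """Read a delimited feature table in the UCI dysphonia-dataset convention.

    Parameters
    ----------
    path : file path to a comma- or whitespace-delimited text table.
    layout : where the subject id, feature block and label column live.
    has_header : skip the first line.
    label_map : optional mapping from raw label strings to {0, 1}; by default
        labels must already be numeric 0/1.

    Raises
    ------
    ParseError
        for a row with too few columns or a non-numeric feature, naming the
        1-based line number.
    ValidationError
        if any subject carries conflicting labels.
    """
    subject_ids: list[str] = []
    rows: list[list[float]] = []
    labels: list[int] = []
    f0, f1 = layout.feature_cols
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if has_header and lineno == 1:
                continue
            line = line.strip()
            if not line:
                continue
            fields = _split_row(line)
            if len(fields) < layout.min_columns:
                raise ParseError(
                    f"line {lineno}: expected at least {layout.min_columns} "
                    f"columns, found {len(fields)}"
                )
            feats = []
            for c in range(f0, f1 + 1):
                try:
                    v = float(fields[c])
                except ValueError:
                    raise ParseError(
                        f"line {lineno}: non-numeric feature {fields[c]!r} "
                        f"in column {c}"
                    ) from None
                feats.append(v)
            raw_label = fields[layout.label_col].strip()
            if label_map is not None:
                if raw_label not in label_map:
                    raise ParseError(
                        f"line {lineno}: label {raw_label!r} not in label_map"
                    )
                lab = int(label_map[raw_label])
            else:
                try:
                    lab = int(float(raw_label))
                except ValueError:
                    raise ParseError(
                        f"line {lineno}: non-numeric label {raw_label!r}"
                    ) from None
            if lab not in (0, 1):
                raise ParseError(f"line {lineno}: label {lab} outside {{0, 1}}")
            subject_ids.append(fields[layout.id_col].strip())
            rows.append(feats)
            labels.append(lab)
    if not rows:
        raise ValidationError(f"no data rows found in {path}")
    return Dataset(
        subject_ids=np.array(subject_ids, dtype=object),
        X=np.array(rows, dtype=float),
        y=np.array(labels, dtype=int),
    )


def write_csv_dataset(data: Dataset, path) -> None:
    """Serialize a Dataset as CSV with header ``subject_id,f1..fd,label``."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", *[f"f{i + 1}" for i in range(data.d)], "label"])
        for sid, row, lab in zip(data.subject_ids, data.X, data.y):
            w.writerow([sid, *[repr(float(v)) for v in row], int(lab)])


def read_csv_dataset(path) -> Dataset:
    """Read a CSV produced by :func:`write_csv_dataset`."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
    d = len(header) - 2
    layout = ColumnLayout(0, (1, d), d + 1)
    return load_sakar_table(path, layout, has_header=True)


# ---------------------------------------------------------------------------
# Standardization


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature z-score parameters fitted on a training fold.

    ``scale`` uses the population standard deviation; constant features get
    scale 1 so they transform to exactly 0 (degenerate rule, documented).
    """

    location: np.ndarray
    scale: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.location) / self.scale

    def inverse(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.scale + self.location

    def to_dict(self) -> dict:
        return {"location": self.location.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerParams":
        return cls(np.asarray(d["location"], float), np.asarray(d["scale"], float))


def fit_scaler(X: np.ndarray) -> ScalerParams:
    """Fit z-score parameters on a raw feature matrix (population std)."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValidationError("cannot fit a scaler on an empty matrix")
    loc = X.mean(axis=0)
    scale = X.std(axis=0)  # ddof=0
    scale = np.where(scale > 0, scale, 1.0)
    return ScalerParams(location=loc, scale=scale)


def standardize_fit(train: Dataset) -> ScalerParams:
    """Fit z-score parameters on a training Dataset."""
    if train.n_samples == 0:
        raise ValidationError("cannot standardize an empty dataset")
    return fit_scaler(train.X)


def standardize_apply(params: ScalerParams, data: Dataset) -> Dataset:
    """Return a copy of ``data`` with features transformed by ``params``."""
    return replace(data, X=params.transform(data.X))


# ---------------------------------------------------------------------------
# Synthetic generator


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for a subject-clustered two-class dataset.

    The generator emulates the structure of the reference speech corpus:
    two diagnostic classes, ``subjects_per_class`` subjects each,
    ``samples_per_subject`` recordings per subject, features of dimension
    ``d``.  Class separation acts along the first coordinate only; subjects
    add a shared Gaussian offset to all their samples (subject effect), and a
    fraction ``contamination`` of each subject's samples are instead drawn
    from the *opposite* class's sample distribution while keeping the
    subject's label — these are the non-discriminative recordings that
    instance selection is meant to remove.

    Defaults match the reference corpus shape (20 + 20 subjects, 26 samples
    per subject, 26 features) with a separation giving single-sample Bayes
    error 0.25 before contamination, and a 15 % contaminated fraction.
    """

    subjects_per_class: int = 20
    samples_per_subject: int = 26
    d: int = 26
    class_separation: float = 1.5086
    subject_sd: float = 1.0
    noise_sd: float = 0.5
    contamination: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.subjects_per_class < 1 or self.samples_per_subject < 1:
            raise ValidationError("subject and sample counts must be positive")
        if self.d < 1:
            raise ValidationError("feature dimension must be positive")
        if self.class_separation < 0 or self.subject_sd < 0:
            raise ValidationError("separation and subject sd must be nonnegative")
        if self.noise_sd <= 0:
            raise ValidationError("noise sd must be positive")
        if not (0 <= self.contamination < 1):
            raise ValidationError("contamination must lie in [0, 1)")


def generate_synthetic(config: SyntheticConfig) -> Dataset:
    """Draw a subject-clustered dataset; bit-reproducible given the config.

    For class ``c`` each subject has center ``mu = c*delta*e1 + eta`` with
    ``eta ~ N(0, subject_sd^2 I)``; samples are ``mu + eps`` with
    ``eps ~ N(0, noise_sd^2 I)``.  ``floor(contamination * m)`` samples per
    subject are replaced by draws from the opposite class's marginal sample
    distribution (fresh subject offset included) and flagged.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.samples_per_subject
    n_cont = int(math.floor(config.contamination * m))
    e1 = np.zeros(config.d)
    e1[0] = 1.0

    ids, rows, labels, flags = [], [], [], []
    for c in (0, 1):
        centers = c * config.class_separation * e1 + rng.normal(
            0.0, config.subject_sd, size=(config.subjects_per_class, config.d)
        )
        for u in range(config.subjects_per_class):
            sid = f"{'H' if c == 0 else 'P'}{u + 1:02d}"
            eps = rng.normal(0.0, config.noise_sd, size=(m, config.d))
            samples = centers[u] + eps
            cont_mask = np.zeros(m, dtype=bool)
            if n_cont:
                cont_idx = rng.choice(m, size=n_cont, replace=False)
                # opposite-class marginal: fresh subject offset + noise
                eta = rng.normal(
                    0.0, config.subject_sd, size=(n_cont, config.d)
                )
                eps_c = rng.normal(0.0, config.noise_sd, size=(n_cont, config.d))
                samples[cont_idx] = (
                    (1 - c) * config.class_separation * e1 + eta + eps_c
                )
                cont_mask[cont_idx] = True
            ids.extend([sid] * m)
            rows.append(samples)
            labels.extend([c] * m)
            flags.append(cont_mask)
    return Dataset(
        subject_ids=np.array(ids, dtype=object),
        X=np.vstack(rows),
        y=np.array(labels, dtype=int),
        contaminated=np.concatenate(flags),
    )


def bayes_error_rate(config: SyntheticConfig) -> float:
    """Closed-form single-sample Bayes error for the generator's mixture.

    Marginally over subjects, an uncontaminated class-``c`` sample is
    ``N(c*delta*e1, (subject_sd^2 + noise_sd^2) I)``; the optimal rule
    thresholds the first coordinate at ``delta/2``, giving per-component
    error ``p = Phi(-delta / (2*sigma))``.  A contaminated sample is drawn
    from the other component, so the achievable error under the optimal
    rule is ``(1-rho)*p + rho*(1-p)``.
    """
    from scipy.stats import norm

    sigma = math.hypot(config.subject_sd, config.noise_sd)
    if config.class_separation == 0:
        p = 0.5
    else:
        p = float(norm.cdf(-config.class_separation / (2.0 * sigma)))
    # effective contaminated fraction after the per-subject floor
    m = config.samples_per_subject
    rho = math.floor(config.contamination * m) / m
    return (1.0 - rho) * p + rho * (1.0 - p)
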