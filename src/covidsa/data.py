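"""Feature-table I/O and the synthetic multi-class generator.

Two on-disk dialects are supported: the UCI-HAR layout (whitespace-separated
real-valued feature matrix, one sample per row, plus a one-integer-per-line
label file with 1-based classes) and generic CSV with a header row and a
label column.  The synthetic generator emulates a smartphone-sensor activity
table — several classes, a block of class-informative features, a block of
redundant linear mixtures and a block of pure noise — so every other module
is testable without downloading anything.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CLASS_NAMES",
    "FeatureDataset",
    "SynthSpec",
    "stratified_split_indices",
    "load_ucihar",
    "write_ucihar",
    "load_csv",
    "generate_synthetic",
]

# Activity abbreviations of the six-class smartphone benchmark:
# walking, walking-upstairs, walking-downstairs, sitting, standing, laying.
DEFAULT_CLASS_NAMES = ("WK", "WU", "WD", "ST", "SD", "LD")

UCIHAR_N_FEATURES = 561


@dataclass(frozen=True)
class FeatureDataset:
    """Train/test feature matrices with integer class labels.

    Labels are 0-based indices into ``class_names`` in memory; the 1-based
    convention of the on-disk label files is converted at the I/O boundary.
    """

    train_x: np.ndarray
    train_y: np.ndarray
    test_x: np.ndarray
    test_y: np.ndarray
    feature_names: tuple[str, ...]
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        for name in ("train_x", "test_x"):
            m = getattr(self, name)
            if m.ndim != 2:
                raise ValueError(f"{name} must be 2-D")
            if not np.isfinite(m).all():
                raise ValueError(f"{name} contains non-finite entries")
        if self.train_x.shape[1] != self.test_x.shape[1]:
            raise ValueError("train and test feature counts differ")
        if len(self.feature_names) != self.train_x.shape[1]:
            raise ValueError("feature_names length mismatch")
        for name in ("train_y", "test_y"):
            y = getattr(self, name)
            if y.size and (y.min() < 0 or y.max() >= len(self.class_names)):
                raise ValueError(f"{name} contains labels outside the class range")

    @property
    def n_features(self) -> int:
        return self.train_x.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self, partition: str = "train") -> np.ndarray:
        y = self.train_y if partition == "train" else self.test_y
        return np.bincount(y, minlength=self.n_classes)


@dataclass(frozen=True)
class SynthSpec:
    """Shape and difficulty of a generated multi-class feature table.

    ``class_separation`` is the exact pairwise Euclidean distance between
    class means in the informative subspace (unit within-class variance).
    The default 7.0 puts the generator in its identifiable regime: masks
    containing the informative block reach near-zero holdout error, so the
    subset-size penalty strips class-independent noise columns, while
    dropping an informative marker still produces measurable class
    confusion.  Redundant features are unit-norm random mixtures of the
    informative ones plus N(0, noise_sd^2); noise features are
    class-independent N(0, 1).  The default train fraction mirrors the
    published 71.39/28.61 split of the smartphone benchmark.
    """

    n_classes: int = 6
    n_per_class: int = 200
    n_informative: int = 8
    n_redundant: int = 8
    n_noise: int = 24
    class_separation: float = 7.0
    noise_sd: float = 1.0
    train_fraction: float = 0.7139
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_per_class < 2:
            raise ValueError("need at least 2 samples per class")
        if self.n_informative < 1:
            raise ValueError("need at least 1 informative feature")
        if self.n_redundant < 0 or self.n_noise < 0:
            raise ValueError("feature counts must be non-negative")
        if self.class_separation <= 0:
            raise ValueError("class_separation must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise


def stratified_split_indices(
    y: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/eval split by largest-remainder allocation.

    The total training size is round(train_fraction * n); each class first
    receives floor(train_fraction * n_c) training rows and the remaining
    slots go to the classes with the largest fractional parts (ties to the
    lower class index).  Every class's proportion is preserved within one
    sample, and the overall fraction within one sample of the target.
    """
    y = np.asarray(y)
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    classes = np.unique(y)
    targets = {c: train_fraction * np.sum(y == c) for c in classes}
    n_train = {c: int(np.floor(t)) for c, t in targets.items()}
    total = int(round(train_fraction * y.size))
    shortfall = total - sum(n_train.values())
    # assign leftover slots by largest fractional remainder
    order = sorted(classes, key=lambda c: (-(targets[c] - n_train[c]), c))
    for c in order[: max(shortfall, 0)]:
        n_train[c] += 1
    train_idx, test_idx = [], []
    for c in classes:
        idx = rng.permutation(np.flatnonzero(y == c))
        train_idx.extend(idx[: n_train[c]])
        test_idx.extend(idx[n_train[c]:])
    return np.sort(np.array(train_idx, dtype=np.int64)), np.sort(
        np.array(test_idx, dtype=np.int64)
    )


def _read_matrix(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            try:
                row = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise ValueError(
                    f"{path}:{lineno}: expected {width} columns, found {len(row)}"
                )
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: empty feature file")
    return np.asarray(rows, dtype=float)


def _read_labels(path: Path, n_classes: int) -> np.ndarray:
    labels = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            try:
                v = int(s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer label {s!r}") from None
            if not 1 <= v <= n_classes:
                raise ValueError(
                    f"{path}:{lineno}: label {v} outside 1..{n_classes}"
                )
            labels.append(v - 1)  # to 0-based
    if not labels:
        raise ValueError(f"{path}: empty label file")
    return np.asarray(labels, dtype=np.int64)


def _find(directory: Path, *candidates: str) -> Path:
    for c in candidates:
        p = directory / c
        if p.is_file():
            return p
    raise FileNotFoundError(
        f"none of {candidates} found under {directory}"
    )


def load_ucihar(
    directory: str | os.PathLike, class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES
) -> FeatureDataset:
    """Load a dataset stored in the UCI-HAR dialect.

    Accepts either the flat layout (``X_train.txt`` etc. in ``directory``)
    or the distribution layout (``train/X_train.txt``, ``test/X_test.txt``).
    When the feature matrix has the benchmark's 561 columns, labels must be
    the six activity classes.
    """
    directory = Path(directory)
    train_x = _read_matrix(_find(directory, "X_train.txt", "train/X_train.txt"))
    train_y = _read_labels(_find(directory, "y_train.txt", "train/y_train.txt"), len(class_names))
    test_x = _read_matrix(_find(directory, "X_test.txt", "test/X_test.txt"))
    test_y = _read_labels(_find(directory, "y_test.txt", "test/y_test.txt"), len(class_names))
    if train_x.shape[0] != train_y.size:
        raise ValueError("training feature and label row counts differ")
    if test_x.shape[0] != test_y.size:
        raise ValueError("test feature and label row counts differ")
    if train_x.shape[1] == UCIHAR_N_FEATURES and len(class_names) != 6:
        raise ValueError("a 561-feature table must carry the six activity classes")
    names = tuple(f"f{j + 1}" for j in range(train_x.shape[1]))
    return FeatureDataset(train_x, train_y, test_x, test_y, names, tuple(class_names))


def write_ucihar(dataset: FeatureDataset, directory: str | os.PathLike, fmt: str = "%.6f") -> None:
    """Write a dataset in the flat UCI-HAR dialect (labels back to 1-based)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / "X_train.txt", dataset.train_x, fmt=fmt)
    np.savetxt(directory / "y_train.txt", dataset.train_y + 1, fmt="%d")
    np.savetxt(directory / "X_test.txt", dataset.test_x, fmt=fmt)
    np.savetxt(directory / "y_test.txt", dataset.test_y + 1, fmt="%d")


def load_csv(
    path: str | os.PathLike,
    label_column: str,
    train_fraction: float = 0.7139,
    seed: int = 0,
    partition_column: str | None = None,
) -> FeatureDataset:
    """Load a generic delimited table with a header row and a label column.

    If ``partition_column`` names a column of ``train``/``test`` markers it
    defines the split; otherwise a stratified split at ``train_fraction`` is
    drawn with the given seed.  Label values (any hashable) become class
    names in sorted order.
    """
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    if label_column not in df.columns:
        raise ValueError(f"{path}: missing label column {label_column!r}")
    labels_raw = df[label_column]
    feature_cols = [c for c in df.columns if c not in (label_column, partition_column)]
    try:
        x = df[feature_cols].to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric feature cell ({exc})") from None
    classes = sorted(labels_raw.unique(), key=str)
    class_names = tuple(str(c) for c in classes)
    y = labels_raw.map({c: i for i, c in enumerate(classes)}).to_numpy(dtype=np.int64)

    if partition_column is not None:
        part = df[partition_column].astype(str).str.lower()
        tr = np.flatnonzero(part == "train")
        te = np.flatnonzero(part == "test")
        if tr.size == 0 or te.size == 0:
            raise ValueError(f"{path}: partition column must mark both train and test rows")
    else:
        tr, te = stratified_split_indices(y, train_fraction, np.random.default_rng(seed))
    return FeatureDataset(
        x[tr], y[tr], x[te], y[te], tuple(feature_cols), class_names
    )


def _marker_centers(n_classes: int, n_dim: int, side: float) -> np.ndarray:
    """Class means in a one-vs-rest marker layout.

    Feature j is assigned as a marker of class ``j mod n_classes``; each
    class's marker block is scaled to norm side/sqrt(2), so every pair of
    class means (disjoint marker supports) is exactly ``side`` apart.  The
    layout mirrors how engineered activity features behave (a feature is
    elevated for one activity) and concentrates each class's identity on
    specific coordinates, which keeps individual informative features
    relevant to the classifier instead of mutually substitutable.
    """
    if n_dim < n_classes - 1:
        raise ValueError(
            f"{n_classes} equidistant class means need >= {n_classes - 1} informative features"
        )
    if n_dim == n_classes - 1:
        # too few coordinates for one marker per class: regular simplex
        v = np.eye(n_classes) - 1.0 / n_classes
        q, _ = np.linalg.qr(v.T)
        return v @ q[:, : n_classes - 1] * (side / np.sqrt(2.0))
    centers = np.zeros((n_classes, n_dim))
    norm = side / np.sqrt(2.0)
    owners = np.arange(n_dim) % n_classes
    for c in range(n_classes):
        cols = np.flatnonzero(owners == c)
        centers[c, cols] = norm / np.sqrt(cols.size)
    return centers


def generate_synthetic(spec: SynthSpec) -> tuple[FeatureDataset, np.ndarray]:
    """Generate a multi-class feature table plus its ground-truth mask.

    Informative features are class-conditional Gaussians with unit variance
    and equidistant class means; redundant features are unit-norm random
    linear combinations of the informative block plus Gaussian noise; noise
    features are standard Gaussians independent of the class.  Returns the
    dataset and the 0/1 informative-column mask for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_classes * spec.n_per_class
    y = np.repeat(np.arange(spec.n_classes), spec.n_per_class)

    centers = _marker_centers(spec.n_classes, spec.n_informative, spec.class_separation)
    x_inf = centers[y] + rng.standard_normal((n, spec.n_informative))

    blocks = [x_inf]
    if spec.n_redundant:
        w = rng.standard_normal((spec.n_informative, spec.n_redundant))
        w /= np.linalg.norm(w, axis=0, keepdims=True)
        blocks.append(x_inf @ w + spec.noise_sd * rng.standard_normal((n, spec.n_redundant)))
    if spec.n_noise:
        blocks.append(rng.standard_normal((n, spec.n_noise)))
    x = np.hstack(blocks)

    names = (
        [f"inf_{j}" for j in range(spec.n_informative)]
        + [f"red_{j}" for j in range(spec.n_redundant)]
        + [f"noise_{j}" for j in range(spec.n_noise)]
    )
    class_names = (
        DEFAULT_CLASS_NAMES
        if spec.n_classes == 6
        else tuple(f"C{i + 1}" for i in range(spec.n_classes))
    )
    tr, te = stratified_split_indices(y, spec.train_fraction, rng)
    dataset = FeatureDataset(x[tr], y[tr], x[te], y[te], tuple(names), class_names)
    truth = np.zeros(spec.n_features, dtype=np.uint8)
    truth[: spec.n_informative] = 1
    return dataset, truth
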