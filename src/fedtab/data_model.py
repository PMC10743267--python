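"""Typed tabular container and dataset plumbing.

The whole pipeline trades in a single currency, :class:`FeatureTable`: an
ID-carrying matrix of real-valued cytology features plus a binary diagnosis
label per record (0 = benign, 1 = malignant).  This module covers loading the
Wisconsin Diagnostic dialect, label encoding, missing/duplicate cleaning,
seeded 70:15:15 splitting and IID client sharding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class FedtabError(Exception):
    """Base class for all package errors."""


class ParseError(FedtabError):
    """Malformed input file."""


class EncodingError(FedtabError):
    """Unknown diagnosis token."""


class ConfigError(FedtabError):
    """Invalid configuration value."""


class DegenerateDataError(FedtabError):
    """An operation left no usable records."""


#: canonical wdbc column order: ten morphology features x {mean, se, worst}
WDBC_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{base}_{kind}"
    for kind in ("mean", "se", "worst")
    for base in (
        "radius",
        "texture",
        "perimeter",
        "area",
        "smoothness",
        "compactness",
        "concavity",
        "concave_points",
        "symmetry",
        "fractal_dimension",
    )
)

LABEL_MAP = {"B": 0, "M": 1}
BENIGN, MALIGNANT = 0, 1


@dataclass(frozen=True)
class FeatureTable:
    """Labelled record set: ids, an (n, d) feature matrix and 0/1 labels."""

    ids: np.ndarray  # (n,) opaque record identifiers (str)
    features: np.ndarray  # (n, d) float64
    feature_names: tuple[str, ...]
    labels: np.ndarray  # (n,) int, values in {0, 1}

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=object)
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels, dtype=int)
        if X.ndim != 2:
            raise ConfigError("features must be a 2-D matrix")
        if len(ids) != len(X) or len(y) != len(X):
            raise ConfigError("ids, features and labels must have equal length")
        if X.shape[1] != len(self.feature_names):
            raise ConfigError("feature_names must match feature arity")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ConfigError("feature_names must be unique")
        if len(y) and not np.isin(y, (0, 1)).all():
            raise ConfigError("labels must be 0 (benign) or 1 (malignant)")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> dict[int, int]:
        return {c: int((self.labels == c).sum()) for c in (0, 1)}

    def take(self, index: np.ndarray | Sequence[int]) -> "FeatureTable":
        idx = np.asarray(index, dtype=int)
        return replace(
            self, ids=self.ids[idx], features=self.features[idx], labels=self.labels[idx]
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(self.feature_names))
        df.insert(0, "id", self.ids)
        df["diagnosis"] = self.labels
        return df

    def to_csv(self, path: str | Path) -> None:
        """Write the headed-CSV dialect (id, features..., diagnosis in {0,1})."""
        self.to_frame().to_csv(path, index=False)


class MissingStrategy(str, Enum):
    DROP_ROW = "drop_row"
    IMPUTE_MEDIAN = "impute_median"


class DuplicateStrategy(str, Enum):
    DROP = "drop"
    KEEP = "keep"


@dataclass(frozen=True)
class CleaningPolicy:
    missing_strategy: MissingStrategy = MissingStrategy.DROP_ROW
    duplicate_strategy: DuplicateStrategy = DuplicateStrategy.DROP

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "missing_strategy", MissingStrategy(self.missing_strategy)
        )
        object.__setattr__(
            self, "duplicate_strategy", DuplicateStrategy(self.duplicate_strategy)
        )


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test proportions; the pipeline default is 70:15:15."""

    train_frac: float = 0.70
    val_frac: float = 0.15
    test_frac: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.train_frac, self.val_frac, self.test_frac)
        if any(f < 0 for f in fracs):
            raise ConfigError("split fractions must be nonnegative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ConfigError(f"split fractions must sum to 1, got {sum(fracs)}")


def encode_labels(raw: Iterable[str]) -> np.ndarray:
    """Map diagnosis tokens B -> 0 (benign), M -> 1 (malignant)."""
    out = []
    for i, tok in enumerate(raw):
        if tok not in LABEL_MAP:
            raise EncodingError(f"unknown diagnosis token {tok!r} at position {i}")
        out.append(LABEL_MAP[tok])
    return np.asarray(out, dtype=int)


def decode_labels(labels: Iterable[int]) -> list[str]:
    rev = {v: k for k, v in LABEL_MAP.items()}
    return [rev[int(v)] for v in labels]


def load_table(
    path: str | Path, dialect: str = "uci_wdbc", feature_names: Sequence[str] | None = None
) -> FeatureTable:
    """Load a labelled feature table.

    ``uci_wdbc``: headerless comma-separated lines of 32 fields
    (ID, diagnosis in {B, M}, 30 floats).  ``headed_csv``: a CSV with an ``id``
    column, named feature columns and a ``diagnosis`` column in {0, 1} or {B, M}.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if dialect == "uci_wdbc":
        return _load_uci_wdbc(path, feature_names)
    if dialect == "headed_csv":
        return _load_headed_csv(path)
    raise ConfigError(f"unknown dialect {dialect!r}")


def _load_uci_wdbc(path: Path, feature_names: Sequence[str] | None) -> FeatureTable:
    ids, raw_labels, rows = [], [], []
    n_feat = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: expected >=3 fields, got {len(fields)}")
            if n_feat is None:
                n_feat = len(fields) - 2
            elif len(fields) - 2 != n_feat:
                raise ParseError(
                    f"line {lineno}: expected {n_feat + 2} fields, got {len(fields)}"
                )
            ids.append(fields[0])
            raw_labels.append(fields[1])
            try:
                rows.append([float(v) for v in fields[2:]])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-numeric feature value ({exc})")
    if not rows:
        raise ParseError(f"{path}: no data lines")
    names = tuple(feature_names) if feature_names else (
        WDBC_FEATURE_NAMES if n_feat == 30 else tuple(f"f{i}" for i in range(n_feat))
    )
    return FeatureTable(
        ids=np.asarray(ids, dtype=object),
        features=np.asarray(rows, dtype=float),
        feature_names=names,
        labels=encode_labels(raw_labels),
    )


def _load_headed_csv(path: Path) -> FeatureTable:
    df = pd.read_csv(path)
    if "diagnosis" not in df.columns:
        raise ParseError(f"{path}: headed_csv requires a 'diagnosis' column")
    if len(df) == 0:
        raise ParseError(f"{path}: no data rows")
    ids = (
        df["id"].astype(str).to_numpy(dtype=object)
        if "id" in df.columns
        else np.asarray([str(i) for i in range(len(df))], dtype=object)
    )
    diag = df["diagnosis"]
    if diag.dtype == object:
        labels = encode_labels(diag.tolist())
    else:
        labels = diag.to_numpy(dtype=int)
    feat_cols = [c for c in df.columns if c not in ("id", "diagnosis")]
    return FeatureTable(
        ids=ids,
        features=df[feat_cols].to_numpy(dtype=float),
        feature_names=tuple(feat_cols),
        labels=labels,
    )


def load_wdbc() -> FeatureTable:
    """The bundled Wisconsin Diagnostic table: 569 records, 30 features.

    Sourced from scikit-learn's packaged copy of the UCI data and relabelled to
    the benign=0 / malignant=1 convention, with the canonical wdbc column names.
    """
    from sklearn.datasets import load_breast_cancer

    data = load_breast_cancer()
    labels = 1 - data.target  # sklearn: 0 = malignant, 1 = benign
    ids = np.asarray([str(i) for i in range(len(labels))], dtype=object)
    return FeatureTable(
        ids=ids,
        features=np.asarray(data.data, dtype=float),
        feature_names=WDBC_FEATURE_NAMES,
        labels=np.asarray(labels, dtype=int),
    )


def clean(table: FeatureTable, policy: CleaningPolicy | None = None) -> FeatureTable:
    """Resolve missing cells and duplicated rows per policy.

    Missing cells (NaN) are either dropped row-wise or imputed with the column
    median of the complete rows; duplicate feature+label rows keep their first
    occurrence when dropped.  Outlier handling lives in :mod:`fedtab.preprocessing`.
    """
    policy = policy or CleaningPolicy()
    X = table.features
    missing_mask = np.isnan(X).any(axis=1)
    out = table
    if missing_mask.any():
        if policy.missing_strategy is MissingStrategy.DROP_ROW:
            out = out.take(np.flatnonzero(~missing_mask))
        else:
            complete = X[~missing_mask]
            if len(complete) == 0:
                raise DegenerateDataError("no complete rows to impute medians from")
            medians = np.median(complete, axis=0)
            filled = X.copy()
            rr, cc = np.nonzero(np.isnan(X))
            filled[rr, cc] = medians[cc]
            out = replace(out, features=filled)
    if policy.duplicate_strategy is DuplicateStrategy.DROP:
        df = pd.DataFrame(out.features)
        df["__y"] = out.labels
        keep = ~df.duplicated(keep="first").to_numpy()
        if not keep.all():
            out = out.take(np.flatnonzero(keep))
    if len(out) == 0:
        raise DegenerateDataError("cleaning removed every record")
    return out


def split(
    table: FeatureTable, spec: SplitSpec | None = None
) -> tuple[FeatureTable, FeatureTable, FeatureTable]:
    """Seeded shuffle then floor(train), floor(val), remainder partition."""
    spec = spec or SplitSpec()
    n = len(table)
    if n < 3 and min(spec.train_frac, spec.val_frac, spec.test_frac) > 0:
        raise ConfigError("need >= 3 records for a three-way split")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    n_train = int(np.floor(spec.train_frac * n))
    n_val = int(np.floor(spec.val_frac * n))
    return (
        table.take(order[:n_train]),
        table.take(order[n_train : n_train + n_val]),
        table.take(order[n_train + n_val :]),
    )


def partition_clients(
    table: FeatureTable, n_clients: int, seed: int = 0
) -> list[FeatureTable]:
    """IID sharding: seeded shuffle, then contiguous near-equal blocks."""
    if n_clients < 1:
        raise ConfigError("n_clients must be >= 1")
    if n_clients > len(table):
        raise ConfigError("more clients than records")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(table))
    return [table.take(chunk) for chunk in np.array_split(order, n_clients)]
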