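"""Stage-1 preprocessing: IQR outlier removal, noise augmentation, SMOTE.

The three stages run in a fixed order on the full labelled table:

1. **Outlier removal** — per-feature Tukey fences at ``Q1 - k*IQR`` and
   ``Q3 + k*IQR`` (k = 1.5 by default); a record is dropped when it breaches
   the fence on at least ``min_violations`` features.  With 30 correlated,
   heavy-tailed cytology features the textbook any-feature rule (``min_violations=1``)
   is extremely aggressive, so the violation count is a policy knob.
2. **Noise augmentation** — each class is grown to an explicit target count by
   appending copies of randomly chosen originals perturbed with elementwise
   uniform noise from a small bounded interval; labels are inherited unchanged
   and original rows are never modified.
3. **SMOTE** — the minority class is grown to parity with the majority by the
   classic rule: pick a minority record x, one of its k nearest minority
   neighbours nn, and emit ``x + u * (nn - x)`` with ``u ~ Uniform(0, 1)``.

Quantiles everywhere use linear interpolation between order statistics (the
numpy/pandas default), so fence arithmetic is reproducible to the digit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .data_model import (
    ConfigError,
    DegenerateDataError,
    FeatureTable,
    FedtabError,
)


@dataclass(frozen=True)
class IqrStats:
    """Per-feature quartiles and Tukey fences for one column."""

    q1: float
    q3: float
    iqr: float
    lower_bound: float
    upper_bound: float
    multiplier: float

    def __post_init__(self) -> None:
        if self.q3 < self.q1:
            raise FedtabError("q3 < q1 in IQR statistics")


@dataclass(frozen=True)
class OutlierPolicy:
    """Fence multiplier and the per-row violation count that triggers removal."""

    multiplier: float = 1.5
    min_violations: int = 1

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ConfigError("multiplier must be > 0")
        if self.min_violations < 1:
            raise ConfigError("min_violations must be >= 1")


#: policy calibrated on the Wisconsin Diagnostic table so that the retained
#: record count lands nearest the reference pipeline's 538-record cleaning stage
WBCD_OUTLIER_POLICY = OutlierPolicy(multiplier=1.5, min_violations=6)


@dataclass(frozen=True)
class AugmentConfig:
    noise_low: float = -0.01
    noise_high: float = 0.01
    per_class_targets: Mapping[int, int] = field(
        default_factory=lambda: {0: 3212, 1: 2530}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_low > self.noise_high:
            raise ConfigError("noise_low must be <= noise_high")


@dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ConfigError("k_neighbors must be >= 1")


def compute_iqr(values, multiplier: float = 1.5) -> IqrStats:
    """Quartiles, IQR and Tukey fences of one value sequence."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise FedtabError("cannot compute quartiles of an empty sequence")
    if not np.isfinite(v).all():
        raise FedtabError("non-finite values in quartile input")
    q1, q3 = np.percentile(v, [25, 75])  # linear interpolation
    iqr = q3 - q1
    return IqrStats(
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        lower_bound=float(q1 - multiplier * iqr),
        upper_bound=float(q3 + multiplier * iqr),
        multiplier=multiplier,
    )


def iqr_table(table: FeatureTable, multiplier: float = 1.5) -> pd.DataFrame:
    """Per-feature IQR statistics as a tidy frame (one row per feature)."""
    rows = []
    for j, name in enumerate(table.feature_names):
        s = compute_iqr(table.features[:, j], multiplier)
        rows.append(
            {
                "feature": name,
                "q1": s.q1,
                "q3": s.q3,
                "iqr": s.iqr,
                "lower_bound": s.lower_bound,
                "upper_bound": s.upper_bound,
            }
        )
    return pd.DataFrame(rows)


def remove_outliers(
    table: FeatureTable, policy: OutlierPolicy | None = None
) -> tuple[FeatureTable, np.ndarray]:
    """Drop rows breaching the Tukey fences on >= ``min_violations`` features.

    Fences are computed once on the input table; surviving rows are returned
    unchanged, together with the IDs of the removed records.
    """
    policy = policy or OutlierPolicy()
    X = table.features
    q1 = np.percentile(X, 25, axis=0)
    q3 = np.percentile(X, 75, axis=0)
    iqr = q3 - q1
    lo = q1 - policy.multiplier * iqr
    hi = q3 + policy.multiplier * iqr
    violations = ((X < lo) | (X > hi)).sum(axis=1)
    keep = violations < policy.min_violations
    if not keep.any():
        raise DegenerateDataError("outlier policy removed every record")
    removed_ids = table.ids[~keep]
    return table.take(np.flatnonzero(keep)), removed_ids


def augment_noise(table: FeatureTable, cfg: AugmentConfig | None = None) -> FeatureTable:
    """Grow each class to its target count with bounded-noise copies.

    Originals are kept verbatim and listed first; each appended record is a
    uniformly chosen original of the same class plus elementwise
    ``Uniform(noise_low, noise_high)`` noise, its label inherited from the source.
    """
    cfg = cfg or AugmentConfig()
    rng = np.random.default_rng(cfg.seed)
    counts = table.class_counts()
    for cls, target in cfg.per_class_targets.items():
        if target < counts.get(cls, 0):
            raise ConfigError(
                f"class {cls}: target {target} below current count {counts.get(cls, 0)}"
            )
    new_ids, new_X, new_y = [table.ids], [table.features], [table.labels]
    for cls in sorted(cfg.per_class_targets):
        target = cfg.per_class_targets[cls]
        idx = np.flatnonzero(table.labels == cls)
        n_extra = target - len(idx)
        if n_extra == 0 or len(idx) == 0:
            continue
        src = rng.choice(idx, size=n_extra, replace=True)
        noise = rng.uniform(
            cfg.noise_low, cfg.noise_high, size=(n_extra, table.n_features)
        )
        new_ids.append(
            np.asarray([f"aug{cls}_{k}" for k in range(n_extra)], dtype=object)
        )
        new_X.append(table.features[src] + noise)
        new_y.append(np.full(n_extra, cls, dtype=int))
    return replace(
        table,
        ids=np.concatenate(new_ids),
        features=np.vstack(new_X),
        labels=np.concatenate(new_y),
    )


def smote(table: FeatureTable, cfg: SmoteConfig | None = None) -> FeatureTable:
    """Balance classes by synthetic minority over-sampling.

    Synthetic points interpolate between a minority record and one of its
    ``k_neighbors`` nearest minority neighbours (Euclidean distance), appended
    until both classes are equally sized.  Majority rows are untouched.
    """
    cfg = cfg or SmoteConfig()
    counts = table.class_counts()
    if min(counts.values()) == 0:
        raise FedtabError("SMOTE requires both classes present")
    if counts[0] == counts[1]:
        return table
    minority = min(counts, key=counts.get)
    n_needed = counts[1 - minority] - counts[minority]
    min_idx = np.flatnonzero(table.labels == minority)
    if cfg.k_neighbors >= len(min_idx):
        raise ConfigError(
            f"k_neighbors={cfg.k_neighbors} must be < minority class size {len(min_idx)}"
        )
    Xm = table.features[min_idx]
    nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(Xm)
    # drop column 0: each point is its own nearest neighbour
    neigh = nn.kneighbors(Xm, return_distance=False)[:, 1:]
    rng = np.random.default_rng(cfg.seed)
    base = rng.integers(0, len(Xm), size=n_needed)
    pick = neigh[base, rng.integers(0, cfg.k_neighbors, size=n_needed)]
    gaps = rng.uniform(0.0, 1.0, size=(n_needed, 1))
    synth = Xm[base] + gaps * (Xm[pick] - Xm[base])
    return replace(
        table,
        ids=np.concatenate(
            [table.ids, np.asarray([f"smote_{k}" for k in range(n_needed)], dtype=object)]
        ),
        features=np.vstack([table.features, synth]),
        labels=np.concatenate([table.labels, np.full(n_needed, minority, dtype=int)]),
    )


def summary_table(table: FeatureTable) -> pd.DataFrame:
    """Per-feature mean/std/min/quartiles/max summary (one row per feature)."""
    df = pd.DataFrame(table.features, columns=list(table.feature_names))
    desc = df.describe().T
    return desc[["mean", "std", "min", "25%", "50%", "75%", "max"]].rename_axis(
        "feature"
    ).reset_index()
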