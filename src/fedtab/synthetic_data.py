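"""WBCD-like synthetic table generator.

Emulates the marginal structure of the cleaned Wisconsin Diagnostic cytology
table: 30 positive-scale features, each drawn from a truncated normal whose
summary statistics (mean, std, min, max) come from a packaged per-feature
profile, with a binary diagnosis label and a tunable between-class mean shift.

Only marginals are emulated — the profile publishes no covariance, and the
pipeline's correctness tests need marginal realism and controllable
separability, not the real cytology correlation structure.  Truncation biases
the mean of a naive truncated normal, so the generator solves for the location
parameter that makes each feature's *post-truncation* mean hit its configured
target exactly.

``generate_toy`` produces plain two-Gaussian blobs for unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_model import ConfigError, FeatureTable

#: benign-class mean is clamped this fraction of the range away from the bounds
_EDGE_MARGIN = 0.02


@lru_cache(maxsize=1)
def default_profile() -> pd.DataFrame:
    """Packaged per-feature (mean, std, min, max) profile of the cytology table."""
    with resources.files("fedtab.data").joinpath("wbcd_profile.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True)
class SynthConfig:
    n_benign: int = 357
    n_malignant: int = 212
    n_features: int = 30
    feature_profiles: pd.DataFrame | None = None  # defaults to the packaged profile
    separation: float = 1.0  # malignant mean = benign mean + separation * std
    informative: tuple[int, ...] | None = None  # features that receive the shift
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_benign < 0 or self.n_malignant < 0:
            raise ConfigError("class counts must be >= 0")
        if self.separation < 0:
            raise ConfigError("separation must be >= 0")

    def resolved_profile(self) -> pd.DataFrame:
        prof = self.feature_profiles if self.feature_profiles is not None else default_profile()
        if len(prof) != self.n_features:
            raise ConfigError(
                f"profile has {len(prof)} features but n_features={self.n_features}"
            )
        if (prof["std"] < 0).any() or (prof["min"] > prof["max"]).any():
            raise ConfigError("profile requires std >= 0 and min <= max per feature")
        return prof


def _truncnorm_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location whose [lo, hi]-truncated normal has the given mean."""

    def mean_at(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    span = max(hi - lo, sd)
    return optimize.brentq(
        lambda loc: mean_at(loc) - target_mean, lo - 50 * sd - span, hi + 50 * sd + span
    )


def _sample_feature(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    if sd == 0 or lo == hi:
        return np.full(n, np.clip(mean, lo, hi))
    margin = _EDGE_MARGIN * (hi - lo)
    target = float(np.clip(mean, lo + margin, hi - margin))
    loc = _truncnorm_loc(target, sd, lo, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)


def generate(cfg: SynthConfig | None = None) -> FeatureTable:
    """Draw a labelled table with profile-matched marginals per class.

    Benign features target the profile means; malignant features target
    ``mean + separation * std`` per informative feature (clamped inside the
    truncation interval).  All values respect the [min, max] bounds exactly,
    class counts equal the config exactly, and rows are seed-shuffled.
    """
    cfg = cfg or SynthConfig()
    prof = cfg.resolved_profile()
    rng = np.random.default_rng(cfg.seed)
    informative = (
        set(cfg.informative) if cfg.informative is not None else set(range(cfg.n_features))
    )
    blocks, labels = [], []
    for cls, n in ((0, cfg.n_benign), (1, cfg.n_malignant)):
        cols = []
        for j, row in prof.iterrows():
            shift = cfg.separation * row["std"] if (cls == 1 and j in informative) else 0.0
            cols.append(
                _sample_feature(
                    rng, n, row["mean"] + shift, row["std"], row["min"], row["max"]
                )
            )
        blocks.append(np.column_stack(cols) if n else np.empty((0, cfg.n_features)))
        labels.append(np.full(n, cls, dtype=int))
    X = np.vstack(blocks)
    y = np.concatenate(labels)
    order = rng.permutation(len(y))
    ids = np.asarray([f"synth_{i}" for i in range(len(y))], dtype=object)
    return FeatureTable(
        ids=ids,
        features=X[order],
        feature_names=tuple(prof["feature"]),
        labels=y[order],
    )


def generate_toy(n: int, d: int, separation: float, seed: int = 0) -> FeatureTable:
    """Balanced two-Gaussian blobs in d dimensions, class centroids
    ``separation`` standard deviations apart."""
    if n < 2 or d < 1:
        raise ConfigError("need n >= 2 and d >= 1")
    rng = np.random.default_rng(seed)
    n0 = n - n // 2
    n1 = n // 2
    shift = np.full(d, separation / np.sqrt(d))
    X = np.vstack(
        [rng.normal(0.0, 1.0, size=(n0, d)), rng.normal(0.0, 1.0, size=(n1, d)) + shift]
    )
    y = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    order = rng.permutation(n)
    return FeatureTable(
        ids=np.asarray([f"toy_{i}" for i in range(n)], dtype=object),
        features=X[order],
        feature_names=tuple(f"x{j}" for j in range(d)),
        labels=y[order],
    )
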