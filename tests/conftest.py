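import numpy as np
import pytest

from fedtab import (
    AugmentConfig,
    FeatureTable,
    SmoteConfig,
    WBCD_OUTLIER_POLICY,
    augment_noise,
    load_wdbc,
    remove_outliers,
    smote,
)


@pytest.fixture(scope="session")
def wbcd() -> FeatureTable:
    """The bundled Wisconsin Diagnostic table (569 records, 30 features)."""
    return load_wdbc()


@pytest.fixture(scope="session")
def wbcd_preprocessed(wbcd) -> FeatureTable:
    """WBCD after the full preprocessing chain with reference parameters."""
    table, _ = remove_outliers(wbcd, WBCD_OUTLIER_POLICY)
    table = augment_noise(
        table, AugmentConfig(per_class_targets={0: 3212, 1: 2530}, seed=7)
    )
    return smote(table, SmoteConfig(seed=7))


def make_table(X, y, names=None) -> FeatureTable:
    """Small helper: wrap arrays into a FeatureTable with running IDs."""
    X = np.asarray(X, dtype=float)
    names = tuple(names) if names else tuple(f"f{j}" for j in range(X.shape[1]))
    return FeatureTable(
        ids=np.asarray([str(i) for i in range(len(X))], dtype=object),
        features=X,
        feature_names=names,
        labels=np.asarray(y, dtype=int),
    )
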