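"""Federation orchestration: client rounds and server-side aggregation.

Two aggregation rules are provided, mirroring a genuine ambiguity in how
federated tabular classifiers are built:

* ``prediction_sum`` — the server never touches weights; per record it sums the
  clients' probability rows and takes the argmax (soft voting).  Clients
  retrain from scratch each round, so successive rounds are independent
  replicates of the same collaborative classifier.
* ``weight_average`` — classic FedAvg: every parameter array of the global
  model is the equal-weighted arithmetic mean of the client arrays (input
  z-scoring statistics included); in later rounds clients warm-start from the
  current global model, and the server can optionally fine-tune the average on
  the pooled training data.

Data flow per round: the table is sharded IID across clients, each client makes
its own 70:15:15 train/val/test split and runs the local training loop; global
metrics are computed on the union of the client test splits, which by
construction is disjoint from all client training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import (
    ConfigError,
    DegenerateDataError,
    FedtabError,
    FeatureTable,
    SplitSpec,
    partition_clients,
    split,
)
from .local_model import (
    LocalModel,
    NetworkSpec,
    TrainConfig,
    TrainingHistory,
    build_model,
    predict_proba,
    train_local,
)
from .metrics import MetricsReport, report_from_labels


@dataclass(frozen=True)
class FederationConfig:
    n_clients: int = 2
    n_rounds: int = 3
    aggregation: str = "prediction_sum"  # or "weight_average"
    split: SplitSpec = field(default_factory=SplitSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    hidden_sizes: tuple[int, ...] = (64, 32, 16)
    fc_size: int = 8
    global_finetune: bool = False  # weight_average only: refit mean on pooled train
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clients < 1:
            raise ConfigError("n_clients must be >= 1")
        if self.n_rounds < 1:
            raise ConfigError("n_rounds must be >= 1")
        if self.aggregation not in ("prediction_sum", "weight_average"):
            raise ConfigError("aggregation must be prediction_sum or weight_average")


@dataclass
class FederatedModel:
    aggregation: str
    clients: list[LocalModel]  # ensemble handle (prediction_sum)
    averaged: LocalModel | None = None  # weight_average result

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.aggregation == "prediction_sum":
            return aggregate_predictions(self.clients, X)
        p = predict_proba(self.averaged, X)
        return np.where(p[:, 1] > p[:, 0], 1, 0)


@dataclass
class RoundResult:
    round_index: int
    client_histories: list[TrainingHistory]
    report: MetricsReport
    n_test: int


def aggregate_predictions(models: list[LocalModel], X: np.ndarray) -> np.ndarray:
    """Sum client probability rows, then argmax; ties resolve to class 0."""
    if not models:
        raise FedtabError("need at least one client model")
    combined = sum(predict_proba(m, X) for m in models)
    # strict > so an exact tie keeps the benign label
    return np.where(combined[:, 1] > combined[:, 0], 1, 0)


def aggregate_weights(models: list[LocalModel]) -> LocalModel:
    """Equal-weighted arithmetic mean of every parameter array across clients."""
    if not models:
        raise FedtabError("need at least one client model")
    spec = models[0].spec
    if any(m.spec != spec for m in models):
        raise FedtabError("all client models must share an identical NetworkSpec")
    n = len(models)
    weights = [
        (
            sum(m.weights[i][0] for m in models) / n,
            sum(m.weights[i][1] for m in models) / n,
        )
        for i in range(len(models[0].weights))
    ]
    out = LocalModel(spec=spec, weights=weights, trained=True)
    if all(m.input_mean is not None for m in models):
        out.input_mean = sum(m.input_mean for m in models) / n
        out.input_std = sum(m.input_std for m in models) / n
    return out


def _client_tables(
    table: FeatureTable, cfg: FederationConfig, round_seed: int
) -> list[tuple[FeatureTable, FeatureTable, FeatureTable]]:
    shards = partition_clients(table, cfg.n_clients, seed=round_seed)
    out = []
    for ci, shard in enumerate(shards):
        if len(np.unique(shard.labels)) < 2:
            raise DegenerateDataError(f"client {ci}: shard contains a single class")
        spec = SplitSpec(
            cfg.split.train_frac,
            cfg.split.val_frac,
            cfg.split.test_frac,
            seed=round_seed + 1000 + ci,
        )
        out.append(split(shard, spec))
    return out


def run_federation(
    table: FeatureTable,
    cfg: FederationConfig | None = None,
    train_transform=None,
) -> tuple[list[RoundResult], FederatedModel]:
    """Run ``n_rounds`` of client training + server aggregation on a table.

    The table is expected to be preprocessed and feature-selected.  Returns the
    per-round results (client histories plus global test metrics) and the final
    federated model.  ``train_transform``, if given, is applied to each client's
    training split only (leak-safe augmentation/balancing hook); validation and
    test splits are never transformed.
    """
    cfg = cfg or FederationConfig()
    spec = NetworkSpec(
        input_dim=table.n_features,
        hidden_sizes=cfg.hidden_sizes,
        fc_size=cfg.fc_size,
    )
    results: list[RoundResult] = []
    fed: FederatedModel | None = None
    global_model: LocalModel | None = None

    for rnd in range(cfg.n_rounds):
        round_seed = cfg.seed + 10_000 * rnd
        parts = _client_tables(table, cfg, round_seed)
        clients, histories = [], []
        for ci, (tr, va, te) in enumerate(parts):
            if train_transform is not None:
                tr = train_transform(tr)
            if cfg.aggregation == "weight_average" and global_model is not None:
                model = global_model.copy()
            else:
                model = build_model(spec, seed=round_seed + ci)
            tcfg = TrainConfig(
                epochs=cfg.train.epochs,
                batch_size=cfg.train.batch_size,
                patience=cfg.train.patience,
                learning_rate=cfg.train.learning_rate,
                beta1=cfg.train.beta1,
                beta2=cfg.train.beta2,
                eps=cfg.train.eps,
                seed=round_seed + 100 + ci,
            )
            model, hist = train_local(model, tr, va, tcfg)
            clients.append(model)
            histories.append(hist)

        if cfg.aggregation == "weight_average":
            averaged = aggregate_weights(clients)
            if cfg.global_finetune:
                pooled_train = _concat([tr for tr, _, _ in parts])
                pooled_val = _concat([va for _, va, _ in parts])
                averaged, _ = train_local(averaged, pooled_train, pooled_val, cfg.train)
            fed = FederatedModel(
                aggregation=cfg.aggregation, clients=clients, averaged=averaged
            )
            global_model = averaged
        else:
            fed = FederatedModel(aggregation=cfg.aggregation, clients=clients)

        test_union = _concat([te for _, _, te in parts])
        y_pred = fed.predict(test_union.features)
        results.append(
            RoundResult(
                round_index=rnd,
                client_histories=histories,
                report=report_from_labels(test_union.labels, y_pred),
                n_test=len(test_union),
            )
        )
    return results, fed


def _concat(tables: list[FeatureTable]) -> FeatureTable:
    first = tables[0]
    return FeatureTable(
        ids=np.concatenate([t.ids for t in tables]),
        features=np.vstack([t.features for t in tables]),
        feature_names=first.feature_names,
        labels=np.concatenate([t.labels for t in tables]),
    )
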