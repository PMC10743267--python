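"""End-to-end pipeline: load -> clean -> outliers -> augment -> SMOTE ->
L1 selection -> federation -> metrics, with a run manifest for provenance.

A single master seed fans out to stage-specific seeds by fixed offsets so any
stage can be rerun in isolation and reproduce the full run's behaviour.

Default protocol note: augmentation and SMOTE run once on the full table
before client sharding (matching the reference study's common-augmented-dataset
protocol, which lets augmented near-duplicates of training records reach the
test union).  ``leak_safe=True`` instead applies both steps to each client's
training split only, after splitting.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import __version__
from .data_model import (
    CleaningPolicy,
    FeatureTable,
    SplitSpec,
    clean,
    load_table,
    load_wdbc,
)
from .federation import FederationConfig, FederatedModel, RoundResult, run_federation
from .feature_selection import L1Config, select_and_reduce
from .local_model import TrainConfig, save_model
from .metrics import report_to_frame
from .preprocessing import (
    AugmentConfig,
    OutlierPolicy,
    SmoteConfig,
    WBCD_OUTLIER_POLICY,
    augment_noise,
    remove_outliers,
    smote,
)
from .synthetic_data import SynthConfig, generate

# stage-seed offsets from the master seed
SEED_OFFSETS = {"augment": 11, "smote": 23, "l1": 37, "federation": 53}


@dataclass
class PipelineConfig:
    """Resolved configuration for one end-to-end run."""

    data_path: str | None = None  # None -> bundled Wisconsin Diagnostic table
    dialect: str = "uci_wdbc"
    seed: int = 0
    cleaning: CleaningPolicy = field(default_factory=CleaningPolicy)
    outlier: OutlierPolicy = field(default_factory=lambda: WBCD_OUTLIER_POLICY)
    augment_targets: Mapping[int, int] = field(
        default_factory=lambda: {0: 3212, 1: 2530}
    )
    noise_low: float = -0.01
    noise_high: float = 0.01
    smote_k: int = 5
    l1: L1Config = field(default_factory=L1Config)
    federation: FederationConfig = field(default_factory=FederationConfig)
    leak_safe: bool = False

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        seed = int(raw.get("seed", 0))
        out = raw.get("outlier", {})
        aug = raw.get("augment", {})
        sm = raw.get("smote", {})
        l1 = raw.get("l1", {})
        fed = raw.get("federation", {})
        lam = l1.get("lambda", "grid")
        return cls(
            data_path=raw.get("data", {}).get("path"),
            dialect=raw.get("data", {}).get("dialect", "uci_wdbc"),
            seed=seed,
            outlier=OutlierPolicy(
                multiplier=float(out.get("multiplier", 1.5)),
                min_violations=int(
                    out.get("min_violations", WBCD_OUTLIER_POLICY.min_violations)
                ),
            ),
            augment_targets={
                int(k): int(v) for k, v in aug.get("targets", {0: 3212, 1: 2530}).items()
            },
            noise_low=float(aug.get("noise_low", -0.01)),
            noise_high=float(aug.get("noise_high", 0.01)),
            smote_k=int(sm.get("k", 5)),
            l1=L1Config(
                lambda_=lam if lam == "grid" else float(lam),
                standardize=bool(l1.get("standardize", True)),
            ),
            federation=FederationConfig(
                n_clients=int(fed.get("clients", 2)),
                n_rounds=int(fed.get("rounds", 3)),
                aggregation=fed.get("aggregation", "prediction_sum"),
                train=TrainConfig(
                    epochs=int(fed.get("epochs", 70)),
                    batch_size=int(fed.get("batch_size", 32)),
                    patience=fed.get("patience", 10),
                    learning_rate=float(fed.get("learning_rate", 1e-3)),
                ),
                global_finetune=bool(fed.get("global_finetune", False)),
                seed=seed + SEED_OFFSETS["federation"],
            ),
            leak_safe=bool(raw.get("leak_safe", False)),
        )


@dataclass
class RunManifest:
    version: str
    seed: int
    config: dict
    stage_counts: dict[str, int]
    class_counts: dict[str, dict[int, int]]
    selected_features: list[str]
    lambda_: float
    rounds: list[dict]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)

    def check_chain(self) -> None:
        """Stage record counts must chain: cleaning stages never add records,
        augmentation stages never remove them."""
        sc = self.stage_counts
        shrinking = ["loaded", "cleaned", "outliers_removed"]
        growing = ["outliers_removed", "augmented", "balanced"]
        for prev, nxt in zip(shrinking, shrinking[1:]):
            if prev in sc and nxt in sc and sc[nxt] > sc[prev]:
                raise ValueError(f"stage {nxt} added records over {prev}")
        for prev, nxt in zip(growing, growing[1:]):
            if prev in sc and nxt in sc and sc[nxt] < sc[prev]:
                raise ValueError(f"stage {nxt} removed records from {prev}")


def _leak_safe_transform(cfg: PipelineConfig, reference: FeatureTable):
    """Per-client training-shard augmentation + balancing, scaled from the
    global targets proportionally to the shard's class counts."""
    ref_counts = reference.class_counts()
    ratios = {
        c: cfg.augment_targets.get(c, ref_counts[c]) / max(ref_counts[c], 1)
        for c in (0, 1)
    }

    def transform(tr: FeatureTable) -> FeatureTable:
        counts = tr.class_counts()
        targets = {
            c: max(int(round(ratios[c] * counts[c])), counts[c]) for c in (0, 1)
        }
        out = augment_noise(
            tr,
            AugmentConfig(
                noise_low=cfg.noise_low,
                noise_high=cfg.noise_high,
                per_class_targets=targets,
                seed=cfg.seed + SEED_OFFSETS["augment"],
            ),
        )
        return smote(out, SmoteConfig(k_neighbors=cfg.smote_k, seed=cfg.seed + SEED_OFFSETS["smote"]))

    return transform


def run_pipeline(
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    table: FeatureTable | None = None,
) -> tuple[RunManifest, list[RoundResult], FederatedModel]:
    """Execute the full pipeline and return (manifest, round results, model).

    ``table`` overrides data loading (used for synthetic runs); otherwise
    ``cfg.data_path`` is loaded, or the bundled Wisconsin Diagnostic table if
    no path is configured.  When ``out_dir`` is given, the manifest, per-round
    metric tables and client model archives are written there.
    """
    cfg = cfg or PipelineConfig()
    stage_counts: dict[str, int] = {}
    class_counts: dict[str, dict[int, int]] = {}

    if table is None:
        table = (
            load_wdbc()
            if cfg.data_path is None
            else load_table(cfg.data_path, cfg.dialect)
        )
    stage_counts["loaded"] = len(table)
    class_counts["loaded"] = table.class_counts()

    table = clean(table, cfg.cleaning)
    stage_counts["cleaned"] = len(table)

    table, _removed = remove_outliers(table, cfg.outlier)
    stage_counts["outliers_removed"] = len(table)
    class_counts["outliers_removed"] = table.class_counts()

    if not cfg.leak_safe:
        counts = table.class_counts()
        targets = {
            c: max(cfg.augment_targets.get(c, counts[c]), counts[c]) for c in (0, 1)
        }
        table = augment_noise(
            table,
            AugmentConfig(
                noise_low=cfg.noise_low,
                noise_high=cfg.noise_high,
                per_class_targets=targets,
                seed=cfg.seed + SEED_OFFSETS["augment"],
            ),
        )
        stage_counts["augmented"] = len(table)
        class_counts["augmented"] = table.class_counts()
        table = smote(
            table, SmoteConfig(k_neighbors=cfg.smote_k, seed=cfg.seed + SEED_OFFSETS["smote"])
        )
        stage_counts["balanced"] = len(table)
        class_counts["balanced"] = table.class_counts()

    reduced, fit = select_and_reduce(table, cfg.l1, seed=cfg.seed + SEED_OFFSETS["l1"])
    stage_counts["selected_features"] = reduced.n_features

    transform = _leak_safe_transform(cfg, reduced) if cfg.leak_safe else None
    # master-seed fan-out: the federation seed is always derived, so a run is
    # fully determined by cfg.seed
    fed_cfg = dataclasses.replace(
        cfg.federation, seed=cfg.seed + SEED_OFFSETS["federation"]
    )
    results, fed = run_federation(reduced, fed_cfg, train_transform=transform)

    manifest = RunManifest(
        version=__version__,
        seed=cfg.seed,
        config=_config_dict(cfg),
        stage_counts=stage_counts,
        class_counts=class_counts,
        selected_features=list(reduced.feature_names),
        lambda_=fit.lambda_,
        rounds=[
            {
                "round": r.round_index,
                "n_test": r.n_test,
                **{k: v for k, v in r.report.as_dict().items()},
            }
            for r in results
        ],
    )
    if out_dir is not None:
        _write_outputs(Path(out_dir), manifest, results, fed)
    return manifest, results, fed


def run_synthetic_pipeline(
    synth: SynthConfig | None = None,
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
):
    """Full pipeline on a generated table (no augmentation targets rescaling)."""
    synth = synth or SynthConfig()
    cfg = cfg or PipelineConfig(augment_targets={})
    return run_pipeline(cfg, out_dir=out_dir, table=generate(synth))


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["cleaning"] = {
        "missing_strategy": cfg.cleaning.missing_strategy.value,
        "duplicate_strategy": cfg.cleaning.duplicate_strategy.value,
    }
    d["augment_targets"] = {str(k): v for k, v in cfg.augment_targets.items()}
    return d


def _write_outputs(out_dir, manifest, results, fed) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "manifest.json").write_text(manifest.to_json())
    import pandas as pd

    pd.DataFrame(manifest.rounds).to_csv(out_dir / "round_metrics.csv", index=False)
    for r in results:
        report_to_frame(r.report).to_csv(
            out_dir / f"round_{r.round_index}_report.csv", index=False
        )
    for ci, model in enumerate(fed.clients):
        save_model(model, out_dir / f"client_{ci}_model.json")
    if fed.averaged is not None:
        save_model(fed.averaged, out_dir / "global_model.json")
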