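"""High-level modelling interface in the Model / Results idiom.

:class:`DTAModel` binds a pair table and entity dictionaries to an
architecture and split; :meth:`DTAModel.fit` runs the training protocol and
returns a :class:`DTAResults` carrying the fitted parameters, the training
history, train/val/test metrics and a ``summary()`` table.  Prediction,
interpretability and screening hang off the results object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import AffinityRecord, EntityDictionary
from .errors import ConfigError, DomainError
from .interaction_model import CrossAttentionRegressor, ModelConfig
from .interpretability import (
    AttentionMap,
    AttributionProfile,
    OcclusionConfig,
    ShapResult,
    extract_cross_attention,
    occlude_scan,
    shap_segments,
)
from .metrics import MetricBundle
from .screening import RefinementRules, ScreenMatrix, refine_rankings, score_panel
from .splits import SplitAssignment
from .training import (
    TrainingConfig,
    TrainingHistory,
    evaluate_split,
    train_model,
)


class DTAModel:
    """An affinity regression problem: data + architecture + split.

    Parameters
    ----------
    records : list of AffinityRecord
        The observations to regress.
    dicts : EntityDictionary
        id -> SMILES and id -> sequence lookups covering every record.
    split : SplitAssignment
        Train/val/test membership over the record indices.
    config : ModelConfig, optional
        Architecture; desk-scale defaults if omitted.
    """

    def __init__(
        self,
        records: Sequence[AffinityRecord],
        dicts: EntityDictionary,
        split: SplitAssignment,
        config: ModelConfig | None = None,
    ):
        if not records:
            raise DomainError("no records")
        dicts.validate(records)
        split.validate_partition(len(records))
        self.records = list(records)
        self.dicts = dicts
        self.split = split
        self.config = config or ModelConfig()

    @classmethod
    def from_dataframe(
        cls,
        pairs: pd.DataFrame,
        drugs: dict[str, str],
        proteins: dict[str, str],
        split: SplitAssignment,
        config: ModelConfig | None = None,
    ) -> "DTAModel":
        records = [
            AffinityRecord(str(r.drug_id), str(r.protein_id), float(r.affinity))
            for r in pairs.itertuples(index=False)
        ]
        return cls(records, EntityDictionary(drugs=dict(drugs),
                                             proteins=dict(proteins)),
                   split, config)

    def fit(self, training: TrainingConfig | None = None, **overrides
            ) -> "DTAResults":
        training = training or TrainingConfig()
        if overrides:
            training = TrainingConfig(**{**training.to_dict(), **overrides})
        net = CrossAttentionRegressor(self.config)
        net, history = train_model(
            net, self.records, self.dicts, self.split, training
        )
        return DTAResults(model=self, network=net, history=history,
                          training_config=training)


@dataclass
class DTAResults:
    """Fitted affinity model: parameters, history, metrics, diagnostics."""

    model: DTAModel
    network: CrossAttentionRegressor
    history: TrainingHistory
    training_config: TrainingConfig
    _metrics: dict[str, MetricBundle] = field(default_factory=dict)

    # -- estimates & diagnostics -------------------------------------------
    def metrics(self, subset: str = "test") -> MetricBundle:
        if subset not in ("train", "val", "test"):
            raise ConfigError(f"unknown subset {subset!r}")
        if subset not in self._metrics:
            indices = self.model.split.subsets()[subset]
            self._metrics[subset] = evaluate_split(
                self.network, self.model.records, self.model.dicts, indices
            )
        return self._metrics[subset]

    def predict(self, smiles: str, sequence: str) -> float:
        return self.network.predict_pair(smiles, sequence)

    def predict_records(self, indices: Sequence[int] | None = None) -> np.ndarray:
        from .training import _tokenize_records, predict_records as _predict

        if indices is None:
            indices = range(len(self.model.records))
        dt, pt = _tokenize_records(self.model.records, self.model.dicts)
        return _predict(self.network, self.model.records, list(indices), dt, pt)

    def summary(self) -> str:
        split = self.model.split
        cfg = self.model.config
        lines = [
            "Drug-target affinity regression results",
            "=" * 55,
            f"records: {len(self.model.records)}   "
            f"split: {split.mode}/{split.axis} seed={split.seed}",
            f"subsets: train={len(split.train)} val={len(split.val)} "
            f"test={len(split.test)}",
            f"architecture: d_model={cfg.d_model} heads={cfg.n_heads} "
            f"interaction={cfg.interaction_mode}",
            f"encoders: drug={cfg.drug_encoder} protein={cfg.protein_encoder}",
            f"trained epochs: {len(self.history.epochs)} "
            f"(best epoch {self.history.best_epoch}, "
            f"val RMSE {self.history.best_val_rmse:.4f})",
            "-" * 55,
            f"{'subset':<8}{'RMSE':>8}{'Pearson':>10}{'Spearman':>10}"
            f"{'CI':>8}{'n':>7}",
        ]
        for subset in ("train", "val", "test"):
            if not self.model.split.subsets()[subset]:
                continue
            m = self.metrics(subset)
            lines.append(
                f"{subset:<8}{m.rmse:>8.4f}{m.pearson:>10.4f}"
                f"{m.spearman:>10.4f}{m.ci:>8.4f}{m.n:>7d}"
            )
        return "\n".join(lines)

    # -- interpretability ---------------------------------------------------
    def occlusion(self, smiles: str, sequence: str, axis: str,
                  config: OcclusionConfig | None = None) -> AttributionProfile:
        return occlude_scan(self.network, smiles, sequence, axis, config)

    def shap(self, smiles: str, sequence: str, axis: str,
             **kwargs) -> ShapResult:
        return shap_segments(self.network, smiles, sequence, axis, **kwargs)

    def attention_map(self, smiles: str, sequence: str,
                      direction: str = "d_to_p") -> AttentionMap:
        return extract_cross_attention(self.network, smiles, sequence, direction)

    # -- screening ----------------------------------------------------------
    def screen(self, targets: dict[str, str], library: dict[str, str]
               ) -> ScreenMatrix:
        return score_panel(self.network, targets, library)

    def screen_refined(
        self, targets: dict[str, str], library: dict[str, str],
        rules: RefinementRules,
    ) -> tuple[dict[str, list[tuple[str, float]]], dict]:
        return refine_rankings(self.screen(targets, library).scores, rules)

    # -- persistence ---------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.network.state_dict())
        with open(directory / "config.json", "w") as fh:
            json.dump(
                {
                    "model": self.model.config.to_dict(),
                    "training": self.training_config.to_dict(),
                    "best_epoch": self.history.best_epoch,
                    "best_val_rmse": self.history.best_val_rmse,
                },
                fh,
                indent=1,
            )

    @staticmethod
    def load_network(directory: str | Path) -> CrossAttentionRegressor:
        directory = Path(directory)
        with open(directory / "config.json") as fh:
            payload = json.load(fh)
        net = CrossAttentionRegressor(ModelConfig.from_dict(payload["model"]))
        with np.load(directory / "weights.npz") as data:
            net.load_state_dict({k: data[k] for k in data.files})
        net.eval()
        return net
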