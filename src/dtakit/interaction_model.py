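"""The encode–interact–predict regressor.

Both encoder outputs are projected into a shared latent space of width
``d_model``; masked multi-head cross-attention then refines one or both
modalities (drug queries interrogating the protein context and/or vice
versa), after which mask-aware mean pooling, concatenation and an MLP head
produce the scalar affinity.  Interaction modes:

``bidirectional``  Z_{d<-p} = MHA(Z_d, Z_p, Z_p; M_p) and
                   Z_{p<-d} = MHA(Z_p, Z_d, Z_d; M_d)
``d_to_p``         only the drug side is updated (drug queries)
``p_to_d``         only the protein side is updated (protein queries)
``none``           the projected matrices are pooled directly

The ``none`` mode is the attention-free ablation; encoder backends are the
other ablation axis and are chosen in :class:`ModelConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .encoding import (
    DRUG_VOCAB,
    PROTEIN_VOCAB,
    EncoderOutput,
    SequenceEncoder,
    TokenSequence,
    make_encoder,
    tokenize_drug,
    tokenize_protein,
)
from .errors import ConfigError, DomainError, ShapeError
from .nn import (
    MLP,
    Linear,
    MaskedMultiHeadAttention,
    Module,
    Tensor,
    build_additive_mask,
    concat,
    masked_mean_pool,
)

INTERACTION_MODES = ("bidirectional", "d_to_p", "p_to_d", "none")


@dataclass
class ModelConfig:
    """Architecture configuration; 1024-wide latents with 8 heads are the
    full-scale setting, the small defaults here run on a CPU in seconds."""

    d_model: int = 32
    n_heads: int = 4
    interaction_mode: str = "bidirectional"
    head_widths: tuple[int, ...] = (64, 32)
    dropout: float = 0.1
    drug_encoder: str = "conv"
    protein_encoder: str = "conv"
    drug_encoder_config: dict = field(default_factory=dict)
    protein_encoder_config: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.interaction_mode not in INTERACTION_MODES:
            raise ConfigError(
                f"unknown interaction mode {self.interaction_mode!r}; "
                f"choose from {INTERACTION_MODES}"
            )
        if self.d_model % self.n_heads != 0:
            raise ConfigError("d_model must be divisible by n_heads")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["head_widths"] = list(self.head_widths)
        return d

    @classmethod
    def from_dict(cls, payload: dict) -> "ModelConfig":
        payload = dict(payload)
        if "head_widths" in payload:
            payload["head_widths"] = tuple(payload["head_widths"])
        return cls(**payload)


def project(enc: EncoderOutput, layer: Linear) -> tuple[Tensor, np.ndarray]:
    """Linear projection into the shared latent space; mask propagated."""
    if enc.hidden.shape[-1] != layer.W.shape[0]:
        raise ShapeError(
            f"encoder width {enc.hidden.shape[-1]} != projection input "
            f"width {layer.W.shape[0]}"
        )
    return layer(enc.hidden), enc.mask


def masked_mha(
    q_in, k_in, v_in, additive_mask: np.ndarray, block: MaskedMultiHeadAttention
) -> Tensor:
    """Single-pair functional form of the attention block: inputs are
    (L, d_model) matrices and an (L_q, L_kv) additive mask (0 / -inf rows)."""
    q = q_in if isinstance(q_in, Tensor) else Tensor(q_in)
    k = k_in if isinstance(k_in, Tensor) else Tensor(k_in)
    v = v_in if isinstance(v_in, Tensor) else Tensor(v_in)
    if q.ndim != 2 or k.ndim != 2 or v.ndim != 2:
        raise ShapeError("masked_mha expects (L, d_model) matrices")
    if additive_mask.shape != (q.shape[0], k.shape[0]):
        raise ShapeError("additive mask must be (L_q, L_kv)")
    key_mask = (additive_mask[0] >= 0).astype(np.float64)[None, :]
    out = block(q.reshape(1, *q.shape), k.reshape(1, *k.shape),
                v.reshape(1, *v.shape), key_mask)
    return out.reshape(out.shape[1], out.shape[2])


class CrossAttentionRegressor(Module):
    """Assembled model: encoders -> projections -> interaction -> pooling ->
    concatenation -> MLP head."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.rng = rng
        self.drug_encoder: SequenceEncoder = make_encoder(
            "drug", config.drug_encoder, rng, **config.drug_encoder_config
        )
        self.protein_encoder: SequenceEncoder = make_encoder(
            "protein", config.protein_encoder, rng, **config.protein_encoder_config
        )
        d = config.d_model
        self.proj_drug = Linear(self.drug_encoder.hidden_size, d, rng, "proj_drug")
        self.proj_protein = Linear(
            self.protein_encoder.hidden_size, d, rng, "proj_protein"
        )
        self.attn_d_from_p = None
        self.attn_p_from_d = None
        if config.interaction_mode in ("bidirectional", "d_to_p"):
            self.attn_d_from_p = MaskedMultiHeadAttention(
                d, config.n_heads, rng, "attn_d_from_p"
            )
        if config.interaction_mode in ("bidirectional", "p_to_d"):
            self.attn_p_from_d = MaskedMultiHeadAttention(
                d, config.n_heads, rng, "attn_p_from_d"
            )
        self.head = MLP(2 * d, config.head_widths, config.dropout, rng, "head")

    # -- forward ------------------------------------------------------------
    def forward_batch(
        self,
        drug_ids: np.ndarray,
        drug_mask: np.ndarray,
        protein_ids: np.ndarray,
        protein_mask: np.ndarray,
    ) -> Tensor:
        """(B,) predictions from padded id/mask batches."""
        enc_d = self.drug_encoder(drug_ids, drug_mask)
        enc_p = self.protein_encoder(protein_ids, protein_mask)
        z_d, m_d = project(enc_d, self.proj_drug)
        z_p, m_p = project(enc_p, self.proj_protein)
        mode = self.config.interaction_mode
        out_d, out_p = z_d, z_p
        if mode in ("bidirectional", "d_to_p"):
            out_d = self.attn_d_from_p(z_d, z_p, z_p, m_p)
        if mode in ("bidirectional", "p_to_d"):
            out_p = self.attn_p_from_d(z_p, z_d, z_d, m_d)
        v_d = masked_mean_pool(out_d, m_d)
        v_p = masked_mean_pool(out_p, m_p)
        r = concat([v_d, v_p], axis=-1)
        y = self.head(r)
        return y.reshape(y.shape[0])

    def cross_attend(
        self, z_d: Tensor, z_p: Tensor, m_d: np.ndarray, m_p: np.ndarray
    ) -> tuple[Tensor, Tensor]:
        """Interaction step alone (mode from the config)."""
        mode = self.config.interaction_mode
        out_d, out_p = z_d, z_p
        if mode in ("bidirectional", "d_to_p"):
            out_d = self.attn_d_from_p(z_d, z_p, z_p, m_p)
        if mode in ("bidirectional", "p_to_d"):
            out_p = self.attn_p_from_d(z_p, z_d, z_d, m_d)
        return out_d, out_p

    # -- convenience --------------------------------------------------------
    def predict_tokens(
        self, drugs: list[TokenSequence], proteins: list[TokenSequence]
    ) -> np.ndarray:
        """Inference on a list of token sequences (padded batch internally)."""
        if len(drugs) != len(proteins):
            raise DomainError("drug and protein lists must have equal length")
        was_training = self.training
        self.eval()
        try:
            ids_d, m_d = pad_batch(drugs, DRUG_VOCAB.pad_id)
            ids_p, m_p = pad_batch(proteins, PROTEIN_VOCAB.pad_id)
            out = self.forward_batch(ids_d, m_d, ids_p, m_p).data.copy()
        finally:
            self.train(was_training)
        return out

    def predict_pair(self, smiles: str, sequence: str) -> float:
        """Full pipeline on raw strings -> scalar affinity prediction."""
        return float(
            self.predict_tokens([tokenize_drug(smiles)], [tokenize_protein(sequence)])[0]
        )

    # -- parameter grouping for differential learning rates ------------------
    def parameter_groups(self) -> dict[str, list]:
        """'encoders' (backbone fine-tuning group) vs 'new_modules'
        (randomly initialised projection/attention/head group)."""
        encoder_params = (
            self.drug_encoder.parameters() + self.protein_encoder.parameters()
        )
        encoder_ids = {id(p) for p in encoder_params}
        rest = [p for p in self.parameters() if id(p) not in encoder_ids]
        return {"encoders": encoder_params, "new_modules": rest}


def pad_batch(
    sequences: list[TokenSequence], pad_id: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pad token sequences to the batch maximum; returns (ids, mask) arrays."""
    if not sequences:
        raise DomainError("empty batch")
    L = max(len(s) for s in sequences)
    padded = [s.padded(L, pad_id) for s in sequences]
    return (
        np.stack([p.ids for p in padded]),
        np.stack([p.mask for p in padded]),
    )


def mse_loss(y, y_hat) -> Tensor:
    """(1/N) sum (y - y_hat)^2; y may be a plain array, y_hat a Tensor."""
    y_arr = np.asarray(y if not isinstance(y, Tensor) else y.data, dtype=np.float64)
    if not isinstance(y_hat, Tensor):
        y_hat = Tensor(y_hat)
    if y_arr.size == 0 or y_arr.shape != y_hat.shape:
        raise DomainError(
            f"mse_loss needs equal non-empty shapes, got {y_arr.shape} vs {y_hat.shape}"
        )
    diff = y_hat - y_arr
    return (diff * diff).mean()


__all__ = [
    "ModelConfig",
    "CrossAttentionRegressor",
    "project",
    "masked_mha",
    "build_additive_mask",
    "masked_mean_pool",
    "pad_batch",
    "mse_loss",
    "INTERACTION_MODES",
]
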