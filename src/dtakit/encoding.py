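"""Tokenization and pluggable sequence encoders.

SMILES strings are tokenized at the level of SMILES atoms/symbols (two-letter
elements such as Cl/Br kept whole) with a built-in character vocabulary, so
no pretrained tokenizer download is needed.  Protein sequences are tokenized
one residue per token over the 20 standard residues plus X/U/B/Z.  Drug
sequences are bounded to 256 tokens and proteins to 1024 (prefix kept on
truncation); every token sequence carries a binary validity mask that
downstream layers must respect.

Encoders are registered per modality; the defaults are trainable
embedding + 1D-convolution stacks small enough to fit on a CPU in seconds.
Adapters for pretrained chemical/protein language models can be registered
through the same registry when such a backend is available.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DomainError, ParseError
from .nn import Conv1dSame, Embedding, Module, Tensor

log = logging.getLogger(__name__)

DRUG_MAX_LEN = 256
PROTEIN_MAX_LEN = 1024

# SMILES token pattern: bracket atoms, two-letter halogens, ring-bond digits
# (incl. %nn), bonds, branches, aromatic atoms.
_SMILES_TOKEN = re.compile(
    r"(\[[^\]]+\]|Br|Cl|%\d{2}|[A-IK-PR-Zb-ik-pr-y]|[0-9]|[=#\-\+\(\)/\\\.@:~\*\$])"
)

PAD, UNK, MASK = "<pad>", "<unk>", "<mask>"

_DRUG_VOCAB_TOKENS = [
    PAD, UNK, MASK,
    "C", "c", "N", "n", "O", "o", "S", "s", "P", "p", "B", "F", "I",
    "Cl", "Br",
    "1", "2", "3", "4", "5", "6", "7", "8", "9", "0",
    "=", "#", "-", "+", "(", ")", "/", "\\", ".", "@", ":", "*",
    "[nH]", "[NH]", "[O-]", "[N+]", "[C@H]", "[C@@H]", "[S+]", "[Se]",
]

PROTEIN_RESIDUES = "ACDEFGHIKLMNPQRSTVWYXUBZ"
_PROTEIN_VOCAB_TOKENS = [PAD, UNK, MASK] + list(PROTEIN_RESIDUES)


@dataclass
class Vocabulary:
    tokens: list[str]
    index: dict[str, int] = field(init=False)

    def __post_init__(self):
        self.index = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self):
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return self.index[PAD]

    @property
    def unk_id(self) -> int:
        return self.index[UNK]

    @property
    def mask_id(self) -> int:
        return self.index[MASK]

    @classmethod
    def from_file(cls, path) -> "Vocabulary":
        with open(path) as fh:
            tokens = [line.rstrip("\n") for line in fh if line.strip()]
        return cls(tokens)


DRUG_VOCAB = Vocabulary(_DRUG_VOCAB_TOKENS)
PROTEIN_VOCAB = Vocabulary(_PROTEIN_VOCAB_TOKENS)


@dataclass
class TokenSequence:
    """Integer token ids plus the binary validity mask.

    ``special_positions`` marks non-content tokens (currently only produced
    by padding-free tokenizers when a backend adds specials); content
    positions are the perturbation axes of the interpretability module.
    ``token_spans`` maps each content token back to its (start, end) character
    span in the original string (end exclusive), for hotspot reporting.
    """

    ids: np.ndarray
    mask: np.ndarray
    kind: str  # "drug" | "protein"
    special_positions: frozenset[int] = frozenset()
    token_spans: tuple[tuple[int, int], ...] = ()
    truncated_from: int | None = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.intp)
        self.mask = np.asarray(self.mask, dtype=np.float64)
        if self.ids.shape != self.mask.shape:
            raise DomainError("ids and mask must have equal length")
        if self.mask.sum() == 0:
            raise DomainError("token sequence must have at least one valid position")

    def __len__(self):
        return len(self.ids)

    @property
    def content_positions(self) -> list[int]:
        return [
            i for i in range(len(self.ids))
            if self.mask[i] == 1 and i not in self.special_positions
        ]

    def padded(self, length: int, pad_id: int) -> "TokenSequence":
        if length < len(self.ids):
            raise DomainError("cannot pad below current length")
        ids = np.full(length, pad_id, dtype=np.intp)
        ids[: len(self.ids)] = self.ids
        mask = np.zeros(length)
        mask[: len(self.mask)] = self.mask
        return TokenSequence(ids, mask, self.kind, self.special_positions,
                             self.token_spans, self.truncated_from)


def smiles_tokens(smiles: str) -> list[tuple[str, int, int]]:
    """Split a SMILES string into (token, start, end) triples."""
    out = []
    pos = 0
    while pos < len(smiles):
        m = _SMILES_TOKEN.match(smiles, pos)
        if m is None:
            raise ParseError(f"untokenizable SMILES at position {pos + 1}: {smiles!r}")
        out.append((m.group(0), m.start(), m.end()))
        pos = m.end()
    return out


def tokenize_drug(
    smiles: str, vocabulary: Vocabulary = DRUG_VOCAB, max_len: int = DRUG_MAX_LEN
) -> TokenSequence:
    """Tokenize a SMILES string; unknown tokens map to <unk> (logged),
    sequences longer than 256 tokens keep the prefix."""
    if not smiles:
        raise DomainError("empty SMILES string")
    toks = smiles_tokens(smiles)
    truncated_from = None
    if len(toks) > max_len:
        truncated_from = len(toks)
        toks = toks[:max_len]
    ids = []
    n_unk = 0
    for tok, _, _ in toks:
        tid = vocabulary.index.get(tok)
        if tid is None:
            tid = vocabulary.unk_id
            n_unk += 1
        ids.append(tid)
    if n_unk:
        log.info("drug tokenizer: %d token(s) mapped to %s in %r", n_unk, UNK, smiles)
    return TokenSequence(
        ids=np.array(ids), mask=np.ones(len(ids)), kind="drug",
        token_spans=tuple((s, e) for _, s, e in toks), truncated_from=truncated_from,
    )


def tokenize_protein(
    sequence: str, vocabulary: Vocabulary = PROTEIN_VOCAB,
    max_len: int = PROTEIN_MAX_LEN,
) -> TokenSequence:
    """One token per residue; illegal characters raise naming the position."""
    if not sequence:
        raise DomainError("empty protein sequence")
    for i, ch in enumerate(sequence):
        if ch not in vocabulary.index or ch in (PAD, UNK, MASK):
            raise ParseError(f"illegal residue {ch!r} at position {i + 1}")
    truncated_from = len(sequence) if len(sequence) > max_len else None
    seq = sequence[:max_len]
    ids = np.array([vocabulary.index[ch] for ch in seq])
    return TokenSequence(
        ids=ids, mask=np.ones(len(ids)), kind="protein",
        token_spans=tuple((i, i + 1) for i in range(len(seq))),
        truncated_from=truncated_from,
    )


@dataclass
class EncoderOutput:
    """Per-token hidden states with the propagated validity mask."""

    hidden: Tensor  # (B, L, h)
    mask: np.ndarray  # (B, L)

    @property
    def h(self) -> int:
        return self.hidden.shape[-1]


class SequenceEncoder(Module):
    """Backend contract: (ids, mask) -> EncoderOutput with the same mask."""

    kind: str = ""
    hidden_size: int = 0
    pretrained: bool = False  # pretrained weights get the low fine-tuning LR

    def __call__(self, ids: np.ndarray, mask: np.ndarray) -> EncoderOutput:
        raise NotImplementedError


class ConvEncoder(SequenceEncoder):
    """Embedding + stacked same-padded 1D convolutions with ReLU.

    Embeddings are multiplied by the validity mask before and after each
    convolution, so padded positions are exactly zero and can never leak
    into valid positions — the padding-invariance contract holds exactly.
    """

    def __init__(
        self,
        kind: str,
        vocab_size: int,
        hidden_size: int = 32,
        n_layers: int = 2,
        kernel: int = 5,
        rng: np.random.Generator | None = None,
        name: str | None = None,
        pretrained: bool = False,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        name = name or f"{kind}_encoder"
        self.kind = kind
        self.hidden_size = hidden_size
        self.pretrained = pretrained
        self.embedding = Embedding(vocab_size, hidden_size, rng, f"{name}.emb")
        self.convs = [
            Conv1dSame(hidden_size, hidden_size, kernel, rng, f"{name}.conv{i}")
            for i in range(n_layers)
        ]

    def __call__(self, ids: np.ndarray, mask: np.ndarray) -> EncoderOutput:
        mask = np.asarray(mask, dtype=np.float64)
        m = mask[..., None]
        x = self.embedding(ids) * m
        for conv in self.convs:
            x = conv(x).relu() * m
        return EncoderOutput(hidden=x, mask=mask)


class IdentityEmbeddingEncoder(SequenceEncoder):
    """Embedding-lookup-only backend (deterministic; used in unit tests and
    as the cheapest possible baseline)."""

    def __init__(self, kind: str, vocab_size: int, hidden_size: int = 8,
                 rng: np.random.Generator | None = None, name: str | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.kind = kind
        self.hidden_size = hidden_size
        self.embedding = Embedding(vocab_size, hidden_size, rng,
                                   name or f"{kind}_encoder.emb")

    def __call__(self, ids: np.ndarray, mask: np.ndarray) -> EncoderOutput:
        mask = np.asarray(mask, dtype=np.float64)
        return EncoderOutput(hidden=self.embedding(ids) * mask[..., None], mask=mask)


_ENCODER_REGISTRY: dict[tuple[str, str], type | callable] = {}


def register_encoder(kind: str, backend_name: str, factory) -> None:
    """Register an encoder factory for a modality; factories receive
    (rng, **config) and must return a SequenceEncoder."""
    _ENCODER_REGISTRY[(kind, backend_name)] = factory


def make_encoder(kind: str, backend_name: str, rng: np.random.Generator,
                 **config) -> SequenceEncoder:
    factory = _ENCODER_REGISTRY.get((kind, backend_name))
    if factory is None:
        available = sorted(b for k, b in _ENCODER_REGISTRY if k == kind)
        raise ConfigError(
            f"no {kind} encoder backend named {backend_name!r}; "
            f"registered: {available}"
        )
    return factory(rng, **config)


register_encoder(
    "drug", "conv",
    lambda rng, **cfg: ConvEncoder("drug", len(DRUG_VOCAB), rng=rng, **cfg),
)
register_encoder(
    "protein", "conv",
    lambda rng, **cfg: ConvEncoder("protein", len(PROTEIN_VOCAB), rng=rng, **cfg),
)
register_encoder(
    "drug", "embedding",
    lambda rng, **cfg: IdentityEmbeddingEncoder("drug", len(DRUG_VOCAB), rng=rng, **cfg),
)
register_encoder(
    "protein", "embedding",
    lambda rng, **cfg: IdentityEmbeddingEncoder(
        "protein", len(PROTEIN_VOCAB), rng=rng, **cfg
    ),
)
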