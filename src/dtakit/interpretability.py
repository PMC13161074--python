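"""Perturbation and attribution analysis for a trained pair model.

Three complementary views of one (drug, protein) prediction:

* sliding-window occlusion (window 15 on the drug token axis, 21 on the
  protein residue axis, stride 1): each window is replaced by the masking
  operator (tokenizer mask token for drugs, residue 'X' for proteins) and
  the signed change in prediction recorded;
* segment-level Shapley values (segments of 4 drug tokens / 20 residues)
  against an all-masked baseline, exact over all coalitions when the number
  of segments M <= 12, otherwise permutation-sampled;
* head-averaged cross-attention maps captured from the drug-to-protein (or
  protein-to-drug) attention block, with padded positions removed.

Window scores are projected to positions by the max-|delta| rule (each
position inherits the signed score of the covering window with the largest
absolute effect).  Special tokens are never occluded and never form
segments; protein coordinates are reported 1-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .encoding import (
    DRUG_VOCAB,
    PROTEIN_VOCAB,
    TokenSequence,
    tokenize_drug,
    tokenize_protein,
)
from .errors import ConfigError, DomainError
from .interaction_model import CrossAttentionRegressor, pad_batch

EXACT_SHAP_MAX_SEGMENTS = 12


@dataclass
class OcclusionConfig:
    w_d: int = 15
    w_p: int = 21
    stride: int = 1

    def window(self, axis: str) -> int:
        return self.w_d if axis == "drug" else self.w_p


@dataclass
class AttributionProfile:
    axis: str
    window_scores: list[tuple[int, int, float]]  # (start, end) exclusive, signed delta
    position_scores: np.ndarray  # per content position, signed max-|delta|
    baseline_prediction: float
    provenance: dict = field(default_factory=dict)


@dataclass
class ShapResult:
    axis: str
    segments: list[tuple[int, int]]  # content-coordinate (start, end) exclusive
    phi0: float
    phi: np.ndarray
    full_prediction: float
    estimator: dict = field(default_factory=dict)


@dataclass
class AttentionMap:
    per_head: np.ndarray  # (H, n_drug_valid, n_protein_valid)
    head_average: np.ndarray
    drug_positions: list[int]  # original token indices of retained rows
    protein_positions: list[int]  # original token indices of retained columns


def _pair_tokens(model, smiles: str, sequence: str
                 ) -> tuple[TokenSequence, TokenSequence]:
    return tokenize_drug(smiles), tokenize_protein(sequence)


def _predict_variants(
    model: CrossAttentionRegressor,
    drugs: list[TokenSequence],
    proteins: list[TokenSequence],
    batch_size: int = 128,
) -> np.ndarray:
    out = np.empty(len(drugs))
    for start in range(0, len(drugs), batch_size):
        out[start : start + batch_size] = model.predict_tokens(
            drugs[start : start + batch_size], proteins[start : start + batch_size]
        )
    return out


def _masked_copy(tokens: TokenSequence, positions: list[int]) -> TokenSequence:
    """Replace token ids at the given positions with the masking operator."""
    ids = tokens.ids.copy()
    mask_id = DRUG_VOCAB.mask_id if tokens.kind == "drug" else PROTEIN_VOCAB.index["X"]
    ids[positions] = mask_id
    return TokenSequence(ids, tokens.mask.copy(), tokens.kind,
                         tokens.special_positions, tokens.token_spans,
                         tokens.truncated_from)


def occlude_scan(
    model: CrossAttentionRegressor,
    smiles: str,
    sequence: str,
    axis: str,
    config: OcclusionConfig | None = None,
) -> AttributionProfile:
    """Sliding-window occlusion along one axis; the other modality untouched.

    delta_i = y_hat(original) - y_hat(occluded window i), signed.
    """
    config = config or OcclusionConfig()
    if axis not in ("drug", "protein"):
        raise DomainError(f"axis must be 'drug' or 'protein', got {axis!r}")
    drug, protein = _pair_tokens(model, smiles, sequence)
    target = drug if axis == "drug" else protein
    content = target.content_positions
    w = config.window(axis)
    if w > len(content):
        raise DomainError(
            f"window {w} longer than content length {len(content)}"
        )
    starts = list(range(0, len(content) - w + 1, config.stride))
    variants_d, variants_p = [], []
    for s in starts:
        masked = _masked_copy(target, content[s : s + w])
        if axis == "drug":
            variants_d.append(masked)
            variants_p.append(protein)
        else:
            variants_d.append(drug)
            variants_p.append(masked)
    baseline = float(model.predict_tokens([drug], [protein])[0])
    preds = _predict_variants(model, variants_d, variants_p)
    deltas = baseline - preds

    window_scores = [(s, s + w, float(d)) for s, d in zip(starts, deltas)]
    position_scores = np.zeros(len(content))
    best_abs = np.full(len(content), -1.0)
    for (s, e, d) in window_scores:
        span = slice(s, e)
        better = np.abs(d) > best_abs[span]
        position_scores[span] = np.where(better, d, position_scores[span])
        best_abs[span] = np.maximum(best_abs[span], abs(d))
    return AttributionProfile(
        axis=axis,
        window_scores=window_scores,
        position_scores=position_scores,
        baseline_prediction=baseline,
        provenance={
            "window": w,
            "stride": config.stride,
            "position_rule": "max_abs_delta",
            "mask": "mask_token" if axis == "drug" else "X",
        },
    )


def _segment_bounds(n_content: int, segment_size: int) -> list[tuple[int, int]]:
    """Contiguous segments; a trailing partial segment keeps its residues."""
    if n_content < 1:
        raise DomainError("no content positions to segment")
    bounds = [
        (s, min(s + segment_size, n_content))
        for s in range(0, n_content, segment_size)
    ]
    return bounds


def _shapley_exact(f_values: dict[frozenset, float], M: int) -> np.ndarray:
    phi = np.zeros(M)
    fact = math.factorial
    for m in range(M):
        others = [j for j in range(M) if j != m]
        for size in range(M):
            weight = fact(size) * fact(M - size - 1) / fact(M)
            for coalition in combinations(others, size):
                s = frozenset(coalition)
                phi[m] += weight * (f_values[s | {m}] - f_values[s])
    return phi


def shap_segments(
    model: CrossAttentionRegressor,
    smiles: str,
    sequence: str,
    axis: str,
    segment_size: int | None = None,
    n_perm: int = 200,
    seed: int = 0,
) -> ShapResult:
    """Segment-level Shapley values with an all-masked baseline.

    Exact enumeration of all 2^M coalitions when M <= 12; otherwise a
    permutation-sampling estimator with recorded n_perm and seed.
    """
    if axis not in ("drug", "protein"):
        raise DomainError(f"axis must be 'drug' or 'protein', got {axis!r}")
    if segment_size is None:
        segment_size = 4 if axis == "drug" else 20
    drug, protein = _pair_tokens(model, smiles, sequence)
    target = drug if axis == "drug" else protein
    content = target.content_positions
    bounds = _segment_bounds(len(content), segment_size)
    M = len(bounds)
    seg_positions = [content[s:e] for s, e in bounds]

    def coalition_tokens(kept: frozenset) -> TokenSequence:
        masked_positions = [
            p for m in range(M) if m not in kept for p in seg_positions[m]
        ]
        return _masked_copy(target, masked_positions)

    def batch_eval(coalitions: list[frozenset]) -> np.ndarray:
        variants = [coalition_tokens(c) for c in coalitions]
        if axis == "drug":
            return _predict_variants(model, variants, [protein] * len(variants))
        return _predict_variants(model, [drug] * len(variants), variants)

    if M <= EXACT_SHAP_MAX_SEGMENTS:
        all_coalitions = [
            frozenset(c) for size in range(M + 1) for c in combinations(range(M), size)
        ]
        values = dict(zip(all_coalitions, batch_eval(all_coalitions)))
        phi = _shapley_exact(values, M)
        phi0 = float(values[frozenset()])
        full = float(values[frozenset(range(M))])
        estimator = {"kind": "exact", "n_coalitions": len(all_coalitions)}
    else:
        rng = np.random.default_rng(seed)
        phi = np.zeros(M)
        empty = frozenset()
        phi0 = float(batch_eval([empty])[0])
        full = float(batch_eval([frozenset(range(M))])[0])
        for _ in range(n_perm):
            order = rng.permutation(M)
            coalitions = [frozenset(order[:k]) for k in range(M + 1)]
            vals = batch_eval(coalitions)
            for k, m in enumerate(order):
                phi[m] += vals[k + 1] - vals[k]
        phi /= n_perm
        estimator = {"kind": "sampled", "n_perm": n_perm, "seed": seed}
    return ShapResult(
        axis=axis,
        segments=bounds,
        phi0=phi0,
        phi=phi,
        full_prediction=full,
        estimator=estimator,
    )


def extract_cross_attention(
    model: CrossAttentionRegressor,
    smiles: str,
    sequence: str,
    direction: str = "d_to_p",
) -> AttentionMap:
    """Capture per-head cross-attention weights from an instrumented forward
    pass; rows/columns at padded positions removed, original indices kept."""
    if direction == "d_to_p":
        block = model.attn_d_from_p
    elif direction == "p_to_d":
        block = model.attn_p_from_d
    else:
        raise ConfigError(f"unknown attention direction {direction!r}")
    if block is None:
        raise ConfigError(
            f"interaction mode {model.config.interaction_mode!r} has no "
            f"{direction} attention pathway"
        )
    drug, protein = _pair_tokens(model, smiles, sequence)
    block.capture_weights = True
    try:
        before = float(model.predict_tokens([drug], [protein])[0])
        weights = block.last_weights[0]  # (H, L_q, L_kv)
        block.capture_weights = False
        block.last_weights = None
        after = float(model.predict_tokens([drug], [protein])[0])
    finally:
        block.capture_weights = False
    if before != after:  # capture must not alter the prediction
        raise RuntimeError("attention capture changed the model prediction")
    if direction == "d_to_p":
        q_pos = [i for i, m in enumerate(drug.mask) if m == 1]
        k_pos = [j for j, m in enumerate(protein.mask) if m == 1]
        drug_positions, protein_positions = q_pos, k_pos
    else:
        q_pos = [i for i, m in enumerate(protein.mask) if m == 1]
        k_pos = [j for j, m in enumerate(drug.mask) if m == 1]
        drug_positions, protein_positions = k_pos, q_pos
    trimmed = weights[:, q_pos][:, :, k_pos]
    return AttentionMap(
        per_head=trimmed,
        head_average=trimmed.mean(axis=0),
        drug_positions=drug_positions,
        protein_positions=protein_positions,
    )


@dataclass
class Hotspot:
    start: int  # 1-based inclusive, original coordinates
    end: int  # inclusive
    score: float
    matched_substring: str | None = None


def map_hotspots(
    scores: np.ndarray,
    top_k: int = 3,
    window: int | None = None,
    positions: list[int] | None = None,
    source_string: str | None = None,
    token_spans: tuple[tuple[int, int], ...] | None = None,
) -> list[Hotspot]:
    """Top-k non-overlapping maximal intervals of a per-position score track.

    Interval score is the mean |score| over a sliding window (window defaults
    to min(len, 8)); ties broken by leftmost start.  ``positions`` maps track
    indices to original token/residue indices (0-based); output coordinates
    are 1-based inclusive.  For drug axes, pass the SMILES and token spans to
    recover the matched substring.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise DomainError("empty score track")
    if window is None:
        window = min(len(scores), 8)
    window = min(window, len(scores))
    magnitude = np.abs(scores)
    window_means = np.convolve(magnitude, np.ones(window) / window, mode="valid")
    order = sorted(range(len(window_means)), key=lambda s: (-window_means[s], s))
    chosen: list[int] = []
    for s in order:
        if all(s + window <= c or s >= c + window for c in chosen):
            chosen.append(s)
        if len(chosen) == top_k:
            break
    hotspots = []
    for s in chosen:
        idx = list(range(s, s + window))
        orig = [positions[i] if positions else i for i in idx]
        sub = None
        if source_string is not None and token_spans is not None:
            spans = [token_spans[i] for i in orig if i < len(token_spans)]
            if spans:
                sub = source_string[spans[0][0] : spans[-1][1]]
        hotspots.append(
            Hotspot(
                start=orig[0] + 1,
                end=orig[-1] + 1,
                score=float(window_means[s]),
                matched_substring=sub,
            )
        )
    return hotspots


def top_windows(profile: AttributionProfile, top_k: int = 1) -> list[Hotspot]:
    """Top-k non-overlapping occlusion windows ranked by |delta|.

    The window score is the signed prediction change when that window is
    masked, so the window interval itself — not the broad max-projection
    track, which smears a sharp effect over every covering window — is the
    natural hotspot unit.  Ties break leftmost; coordinates 1-based
    inclusive in content space.
    """
    if not profile.window_scores:
        raise DomainError("profile has no window scores")
    order = sorted(profile.window_scores, key=lambda w: (-abs(w[2]), w[0]))
    chosen: list[tuple[int, int, float]] = []
    for start, end, delta in order:
        if all(end <= s or start >= e for s, e, _ in chosen):
            chosen.append((start, end, delta))
        if len(chosen) == top_k:
            break
    return [Hotspot(start=s + 1, end=e, score=d) for s, e, d in chosen]


def attention_column_profile(att: AttentionMap) -> np.ndarray:
    """Per-protein-position attention received, summed over drug tokens of
    the head-averaged map (a residue-level saliency track)."""
    return att.head_average.sum(axis=0)
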