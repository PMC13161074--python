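"""Virtual screening: score a target panel against a compound library,
z-score per target, rank, and apply the visualization-refinement rules.

Refinement runs in the stated order: (1) rapalog-class compounds are removed
from every target's ranking except the designated rapalog target (MTOR);
(2) promiscuous compounds — those appearing in the top-k (default 20) of at
least ``promiscuity_target_count`` (default 10) targets, counted on the
rapalog-filtered rankings — are removed everywhere; (3) the top
``clean_list_length`` (default 10) per target is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .interaction_model import CrossAttentionRegressor
from .encoding import tokenize_drug, tokenize_protein

log = logging.getLogger(__name__)


@dataclass
class ScreenMatrix:
    """Predicted affinity matrix, targets x compounds; NaN marks entries
    whose inputs could not be scored."""

    scores: pd.DataFrame  # index: target ids, columns: compound ids
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def target_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class RefinementRules:
    rapalog_ids: frozenset[str] = frozenset()
    rapalog_target: str = "MTOR"
    promiscuity_top_k: int = 20
    promiscuity_target_count: int = 10
    clean_list_length: int = 10

    def __post_init__(self):
        if min(self.promiscuity_top_k, self.promiscuity_target_count,
               self.clean_list_length) < 1:
            raise DomainError("refinement counts must be positive")


def score_panel(
    model: CrossAttentionRegressor,
    targets: dict[str, str],
    library: dict[str, str],
    batch_size: int = 128,
) -> ScreenMatrix:
    """scores[t][c] = predicted affinity of compound c against target t.

    Untokenizable entries are collected in the failure report and their
    matrix cells left missing.  Over-length proteins must arrive
    pre-truncated or domain-extracted upstream.
    """
    failures: dict[str, str] = {}
    drug_tokens = {}
    for cid, smiles in library.items():
        try:
            drug_tokens[cid] = tokenize_drug(smiles)
        except Exception as exc:  # noqa: BLE001 - per-entry error report
            failures[f"compound:{cid}"] = str(exc)
    protein_tokens = {}
    for tid, seq in targets.items():
        try:
            protein_tokens[tid] = tokenize_protein(seq)
        except Exception as exc:  # noqa: BLE001
            failures[f"target:{tid}"] = str(exc)
    tids = list(targets)
    cids = list(library)
    matrix = pd.DataFrame(np.nan, index=tids, columns=cids)
    pairs = [
        (t, c) for t in tids for c in cids
        if t in protein_tokens and c in drug_tokens
    ]
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start : start + batch_size]
        preds = model.predict_tokens(
            [drug_tokens[c] for _, c in chunk],
            [protein_tokens[t] for t, _ in chunk],
        )
        for (t, c), y in zip(chunk, preds):
            matrix.loc[t, c] = y
    if failures:
        log.warning("screening: %d entries failed tokenization", len(failures))
    return ScreenMatrix(scores=matrix, failures=failures)


def row_zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per row: subtract the mean, divide by the sample standard deviation.
    Missing cells are ignored; a constant row raises naming the target."""
    out = matrix.copy().astype(float)
    for target, row in matrix.iterrows():
        values = row.dropna()
        if values.nunique() < 2:
            raise DomainError(f"constant score row for target {target!r}")
        out.loc[target] = (row - values.mean()) / values.std(ddof=1)
    return out


def rank_targets(matrix: pd.DataFrame) -> dict[str, list[tuple[str, float]]]:
    """Descending score ranking per target; ties by compound id; missing
    cells excluded."""
    rankings = {}
    for target, row in matrix.iterrows():
        values = row.dropna()
        ranked = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
        rankings[target] = [(c, float(s)) for c, s in ranked]
    return rankings


def refine_rankings(
    matrix: pd.DataFrame, rules: RefinementRules
) -> tuple[dict[str, list[tuple[str, float]]], dict]:
    """Apply rapalog and promiscuity refinement; returns per-target clean
    top lists plus an exclusion report."""
    base = rank_targets(matrix)
    # step 1: rapalogs only on the designated target
    filtered = {
        target: [
            (c, s) for c, s in ranking
            if c not in rules.rapalog_ids or target == rules.rapalog_target
        ]
        for target, ranking in base.items()
    }
    # step 2: promiscuity count on the rapalog-filtered rankings
    appearances: dict[str, int] = {}
    for ranking in filtered.values():
        for c, _ in ranking[: rules.promiscuity_top_k]:
            appearances[c] = appearances.get(c, 0) + 1
    promiscuous = {
        c for c, n in appearances.items() if n >= rules.promiscuity_target_count
    }
    clean = {
        target: [(c, s) for c, s in ranking if c not in promiscuous][
            : rules.clean_list_length
        ]
        for target, ranking in filtered.items()
    }
    report = {
        "rapalogs_restricted_to": rules.rapalog_target,
        "rapalog_ids": sorted(rules.rapalog_ids),
        "promiscuous_excluded": sorted(promiscuous),
        "promiscuity_rule": (
            f"top-{rules.promiscuity_top_k} of >= "
            f"{rules.promiscuity_target_count} targets"
        ),
    }
    return clean, report
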