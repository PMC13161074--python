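"""Benchmark-shaped synthetic data with a known affinity mechanism.

Drugs are grammar-sampled valid SMILES built by concatenating curated
fragments at single bonds; a designated "warhead" fragment (an
acrylamide-like Michael acceptor) is planted in a controlled fraction of
the library.  Proteins are random residue strings with a fixed motif
planted in a controlled fraction at a recorded position.  Affinity follows

    y = mu0 + gamma * 1[warhead] * 1[motif]
        + beta_d * len_frac(drug) + beta_p * len_frac(protein)
        + Normal(0, sigma^2)

so the dominant signal is the warhead-motif co-occurrence (an interaction a
pair model must learn), with mild length nuisance terms keeping the target
continuous.  Defaults put affinities on a pKd-like 5-8 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from rdkit import Chem

from .data_io import AffinityRecord, EntityDictionary
from .errors import DomainError
from .encoding import smiles_tokens

# Curated fragments: each starts and ends at an atom with spare valence so
# plain concatenation stays a valid SMILES; ring-bond digit '1' is renumbered
# per molecule to avoid collisions.  Halogens sit in branches for the same
# reason.
FRAGMENTS = [
    "C", "CC", "CCC", "CO", "CN", "CCO", "CCN", "COC", "CNC", "CSC",
    "C(C)C", "C(C)(C)C", "C(=O)", "C(=O)O", "C(=O)N", "C(O)", "C(N)",
    "C(F)", "C(Cl)", "C(Br)", "C(F)(F)", "C=C", "C=CC", "C(=O)C",
    "c1ccccc1", "c1ccncc1", "c1ccc(cc1)", "C1CCCCC1", "C1CCNCC1",
    "c1ccsc1", "c1ccoc1",
]

WARHEAD = "C=CC(=O)N"  # acrylamide-like Michael-acceptor fragment
MOTIF = "HKCWYDMF"  # planted protein binding motif

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticSpec:
    n_drugs: int = 40
    n_proteins: int = 40
    pair_density: float = 0.5
    warhead: str = WARHEAD
    motif: str = MOTIF
    p_warhead: float = 0.5
    p_motif: float = 0.5
    mu0: float = 5.0
    gamma: float = 2.0
    beta_d: float = 0.5
    beta_p: float = 0.5
    sigma: float = 0.1
    n_fragments: tuple[int, int] = (2, 5)
    protein_length: tuple[int, int] = (60, 120)
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_warhead, self.p_motif):
            if not 0.0 <= p <= 1.0:
                raise DomainError("probabilities must lie in [0, 1]")
        if not 0.0 < self.pair_density <= 1.0:
            raise DomainError("pair_density must lie in (0, 1]")
        if self.sigma < 0:
            raise DomainError("noise sigma must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_fragments"] = list(self.n_fragments)
        d["protein_length"] = list(self.protein_length)
        return d


@dataclass
class GroundTruth:
    """Per-entity indicators and the generating parameters."""

    drug_has_warhead: dict[str, bool] = field(default_factory=dict)
    protein_has_motif: dict[str, bool] = field(default_factory=dict)
    motif_position: dict[str, int | None] = field(default_factory=dict)  # 0-based
    drug_len_frac: dict[str, float] = field(default_factory=dict)
    protein_len_frac: dict[str, float] = field(default_factory=dict)
    spec: dict = field(default_factory=dict)

    def bayes_prediction(self, drug_id: str, protein_id: str) -> float:
        """Noise-free affinity under the generating mechanism."""
        s = self.spec
        return (
            s["mu0"]
            + s["gamma"]
            * float(self.drug_has_warhead[drug_id] and self.protein_has_motif[protein_id])
            + s["beta_d"] * self.drug_len_frac[drug_id]
            + s["beta_p"] * self.protein_len_frac[protein_id]
        )


def _renumber_rings(fragments: list[str]) -> str:
    """Concatenate fragments, renumbering ring-bond digit '1' per fragment."""
    out = []
    ring = 0
    for frag in fragments:
        if "1" in frag:
            ring += 1
            if ring > 9:
                raise DomainError("too many ring fragments in one molecule")
            frag = frag.replace("1", str(ring))
        out.append(frag)
    return "".join(out)


def _sample_smiles(rng: np.random.Generator, spec: SyntheticSpec,
                   with_warhead: bool) -> str:
    n = rng.integers(spec.n_fragments[0], spec.n_fragments[1] + 1)
    frags = [FRAGMENTS[i] for i in rng.integers(0, len(FRAGMENTS), size=n)]
    if with_warhead:
        frags.insert(int(rng.integers(0, len(frags) + 1)), spec.warhead)
    smiles = _renumber_rings(frags)
    if Chem.MolFromSmiles(smiles) is None:  # pragma: no cover - grammar is safe
        raise DomainError(f"generated invalid SMILES {smiles!r}")
    return smiles


def _sample_protein(rng: np.random.Generator, spec: SyntheticSpec,
                    with_motif: bool) -> tuple[str, int | None]:
    length = int(rng.integers(spec.protein_length[0], spec.protein_length[1] + 1))
    seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=length))
    if not with_motif:
        return seq, None
    if length < len(spec.motif):
        raise DomainError("protein length below motif length")
    pos = int(rng.integers(0, length - len(spec.motif) + 1))
    return seq[:pos] + spec.motif + seq[pos + len(spec.motif):], pos


def _len_frac(value: int, bounds: tuple[int, int]) -> float:
    lo, hi = bounds
    if hi == lo:
        return 0.0
    return float(np.clip((value - lo) / (hi - lo), 0.0, 1.0))


def generate_benchmark(
    spec: SyntheticSpec,
) -> tuple[list[AffinityRecord], EntityDictionary, GroundTruth]:
    """Sample the full synthetic benchmark; fully reproducible by spec.seed."""
    for token, _, _ in smiles_tokens(spec.warhead):
        pass  # raises if the warhead cannot be tokenized
    for ch in spec.motif:
        if ch not in AMINO_ACIDS:
            raise DomainError(f"motif residue {ch!r} outside the standard alphabet")

    rng = np.random.default_rng(spec.seed)
    truth = GroundTruth(spec=spec.to_dict())
    dicts = EntityDictionary()

    warhead_flags = rng.random(spec.n_drugs) < spec.p_warhead
    for i in range(spec.n_drugs):
        did = f"D{i:04d}"
        smiles = _sample_smiles(rng, spec, bool(warhead_flags[i]))
        dicts.drugs[did] = smiles
        truth.drug_has_warhead[did] = bool(warhead_flags[i])
        n_tokens = len(smiles_tokens(smiles))
        truth.drug_len_frac[did] = _len_frac(
            n_tokens, (spec.n_fragments[0], spec.n_fragments[1] * 8)
        )

    motif_flags = rng.random(spec.n_proteins) < spec.p_motif
    for j in range(spec.n_proteins):
        pid = f"P{j:04d}"
        seq, pos = _sample_protein(rng, spec, bool(motif_flags[j]))
        dicts.proteins[pid] = seq
        truth.protein_has_motif[pid] = bool(motif_flags[j])
        truth.motif_position[pid] = pos
        truth.protein_len_frac[pid] = _len_frac(len(seq), spec.protein_length)

    drug_ids = sorted(dicts.drugs)
    protein_ids = sorted(dicts.proteins)
    all_pairs = [(d, p) for d in drug_ids for p in protein_ids]
    n_sample = max(1, int(round(spec.pair_density * len(all_pairs))))
    chosen = rng.choice(len(all_pairs), size=n_sample, replace=False)
    records = []
    for k in sorted(chosen):
        d, p = all_pairs[k]
        y = truth.bayes_prediction(d, p)
        if spec.sigma > 0:
            y += rng.normal(0.0, spec.sigma)
        records.append(AffinityRecord(d, p, float(y)))
    return records, dicts, truth


def make_toy_entities(kind: str, n: int, seed: int = 0) -> dict[str, str]:
    """Small valid SMILES or residue strings for unit tests."""
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    spec = SyntheticSpec(seed=seed)
    for i in range(n):
        if kind == "drug":
            out[f"d{i}"] = _sample_smiles(rng, spec, with_warhead=bool(i % 2))
        elif kind == "protein":
            length = int(rng.integers(20, 40))
            out[f"p{i}"] = "".join(
                AMINO_ACIDS[j] for j in rng.integers(0, 20, size=length)
            )
        else:
            raise DomainError(f"unknown kind {kind!r}")
    return out
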