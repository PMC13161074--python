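"""Leakage auditing across split boundaries.

Chemical side: Morgan fingerprints (radius 2, 2048 bits), Tanimoto
nearest-train similarity, and Bemis–Murcko scaffold overlap.  Protein side:
best local-alignment hit of each test sequence against the training set,
summarised as mean best-hit identity and the fraction of test sequences whose
best hit exceeds 50% identity.  The training side of an audit is conventionally
the union of the train and validation subsets.

RDKit stands behind the fingerprint and scaffold primitives; Biopython's
PairwiseAligner stands behind both alignment flavours.  An external search
tool (e.g. BLASTp) can be plugged in through ``homology_audit(backend=...)``
and must return the same per-test-sequence hit tuples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

from .errors import DomainError, InvalidStructureError

RDLogger.DisableLog("rdApp.*")  # RDKit parse chatter; failures raise instead


@dataclass
class AuditReport:
    """Residual cross-split similarity statistics for one split/fold."""

    scaffold_overlap_rate: float | None = None
    nn_similarity_mean: float | None = None
    nn_similarity_median: float | None = None
    nn_similarity_p95: float | None = None
    n_train_entities: int = 0
    n_test_entities: int = 0
    mean_best_hit_identity: float | None = None
    frac_over_50_identity: float | None = None
    n_invalid: int = 0
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


# --------------------------------------------------------------------------
# chemical axis
# --------------------------------------------------------------------------

_MORGAN_CACHE: dict[tuple[int, int], object] = {}


def _mol(smiles: str):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidStructureError(f"unparsable SMILES: {smiles!r}")
    return mol


def morgan_fingerprint(smiles: str, radius: int = 2, nbits: int = 2048) -> frozenset[int]:
    """Morgan fingerprint as the set of on-bits (radius 2, 2048 bits default)."""
    key = (radius, nbits)
    gen = _MORGAN_CACHE.get(key)
    if gen is None:
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
        _MORGAN_CACHE[key] = gen
    fp = gen.GetFingerprint(_mol(smiles))
    return frozenset(fp.GetOnBits())


def tanimoto(a: frozenset[int] | set[int], b: frozenset[int] | set[int]) -> float:
    """|a ∩ b| / |a ∪ b|; 0.0 when both sets are empty."""
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def murcko_scaffold(smiles: str) -> str:
    """Canonical Bemis–Murcko scaffold SMILES; empty for acyclic molecules."""
    return MurckoScaffold.MurckoScaffoldSmiles(mol=_mol(smiles))


def scaffold_overlap_rate(
    test_smiles: Sequence[str], train_smiles: Sequence[str]
) -> tuple[float, int]:
    """Fraction of valid test compounds whose scaffold occurs in the train
    scaffold set.  Empty scaffolds (acyclic molecules) compare equal to each
    other.  Returns (rate, n_invalid)."""
    n_invalid = 0
    train_scaffolds: set[str] = set()
    for smi in train_smiles:
        try:
            train_scaffolds.add(murcko_scaffold(smi))
        except InvalidStructureError:
            n_invalid += 1
    hits = 0
    n_valid_test = 0
    for smi in test_smiles:
        try:
            scaf = murcko_scaffold(smi)
        except InvalidStructureError:
            n_invalid += 1
            continue
        n_valid_test += 1
        hits += scaf in train_scaffolds
    if n_valid_test == 0:
        raise DomainError("no valid test compounds for scaffold overlap")
    return hits / n_valid_test, n_invalid


def nearest_train_similarity(
    test_smiles: Sequence[str], train_smiles: Sequence[str]
) -> tuple[np.ndarray, AuditReport]:
    """Per-test-compound maximum Tanimoto similarity to any train compound,
    with mean / median / 95th percentile (linear interpolation) summaries."""
    n_invalid = 0
    train_fps = []
    for smi in train_smiles:
        try:
            train_fps.append(morgan_fingerprint(smi))
        except InvalidStructureError:
            n_invalid += 1
    if not train_fps:
        raise DomainError("no valid train compounds for similarity audit")
    maxima = []
    for smi in test_smiles:
        try:
            fp = morgan_fingerprint(smi)
        except InvalidStructureError:
            n_invalid += 1
            continue
        maxima.append(max(tanimoto(fp, t) for t in train_fps))
    if not maxima:
        raise DomainError("no valid test compounds for similarity audit")
    maxima = np.asarray(maxima, dtype=float)
    report = AuditReport(
        nn_similarity_mean=float(maxima.mean()),
        nn_similarity_median=float(np.median(maxima)),
        nn_similarity_p95=float(np.percentile(maxima, 95)),  # linear interpolation
        n_train_entities=len(train_fps),
        n_test_entities=len(maxima),
        n_invalid=n_invalid,
        provenance={"fingerprint": "morgan_r2_2048", "percentile": "linear"},
    )
    return maxima, report


# --------------------------------------------------------------------------
# protein axis
# --------------------------------------------------------------------------


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _identity_over_alignment(alignment) -> tuple[float, int]:
    """(identical columns / alignment length incl. gap columns, aligned query length)."""
    a, b = str(alignment[0]), str(alignment[1])
    identical = sum(x == y and x != "-" for x, y in zip(a, b))
    length = len(a)
    query_cols = sum(x != "-" for x in a)
    return identical / length, query_cols


def global_identity(seq_a: str, seq_b: str) -> float:
    """Global end-to-end percent identity: identical aligned columns over the
    full alignment length including gap columns (match +1 / mismatch -1 /
    linear gap -1 scoring)."""
    if not seq_a or not seq_b:
        raise DomainError("global identity requires non-empty sequences")
    alignment = _global_aligner().align(seq_a, seq_b)[0]
    identity, _ = _identity_over_alignment(alignment)
    return identity


def _internal_best_hit(
    test_seq: str, train_seqs: dict[str, str], coverage_min: float
) -> tuple[str, float, float]:
    """Best local-alignment hit (train_id, identity, coverage), preferring
    hits with query coverage >= coverage_min, else the overall best."""
    aligner = _local_aligner()
    hits: list[tuple[str, float, float, float]] = []
    for tid, seq in train_seqs.items():
        alignments = aligner.align(test_seq, seq)
        try:
            best = alignments[0]
        except IndexError:  # no positive-scoring local alignment at all
            hits.append((tid, 0.0, 0.0, -np.inf))
            continue
        identity, query_cols = _identity_over_alignment(best)
        coverage = query_cols / len(test_seq)
        hits.append((tid, identity, coverage, best.score))
    covered = [h for h in hits if h[2] >= coverage_min]
    pool = covered if covered else hits
    tid, identity, coverage, _ = max(pool, key=lambda h: (h[3], h[0]))
    return tid, identity, coverage


def homology_audit(
    test_seqs: dict[str, str],
    train_seqs: dict[str, str],
    coverage_min: float = 0.70,
    backend: Callable[[str, dict[str, str], float], tuple[str, float, float]] | None = None,
) -> AuditReport:
    """Best-hit homology audit of test sequences against the training set.

    ``backend`` may replace the internal local-alignment search (e.g. with an
    external BLASTp wrapper) and must return (train_id, identity, coverage)
    for one test sequence.
    """
    if not test_seqs or not train_seqs:
        raise DomainError("homology audit requires non-empty sequence sets")
    search = backend or _internal_best_hit
    identities = []
    for seq in test_seqs.values():
        _, identity, _ = search(seq, train_seqs, coverage_min)
        identities.append(identity)
    identities = np.asarray(identities, dtype=float)
    return AuditReport(
        n_train_entities=len(train_seqs),
        n_test_entities=len(test_seqs),
        mean_best_hit_identity=float(identities.mean()),
        frac_over_50_identity=float(np.mean(identities > 0.50)),
        provenance={
            "search": "internal_local_blosum62" if backend is None else "external",
            "coverage_min": coverage_min,
        },
    )
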