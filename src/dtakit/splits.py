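"""Split construction: warm (pair-level), entity-disjoint cold, and
similarity-controlled cold splits.

A cold split partitions the *unique entities* on one axis (drugs or
proteins) 8:1:1 and lets every record follow its entity, so test entities
never occur in training.  A similarity-controlled split additionally
single-links entities whose pairwise similarity strictly exceeds a threshold
into clusters and assigns whole clusters greedily to subsets, so that no
cross-subset entity pair is more similar than the threshold.

Rounding of entity counts uses largest-remainder with a minimum of one
entity per subset; the greedy cluster assignment processes clusters in
descending pair count (ties by cluster id) and fills the subset with the
largest remaining pair deficit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .audit import global_identity, morgan_fingerprint, tanimoto
from .data_io import AffinityRecord, EntityDictionary
from .errors import DomainError

log = logging.getLogger(__name__)

SUBSETS = ("train", "val", "test")


@dataclass
class SplitAssignment:
    """Train/val/test membership at record (pair) level, with provenance."""

    train: list[int]
    val: list[int]
    test: list[int]
    mode: str = "warm"  # warm | entity_cold | similarity_cold
    axis: str = "pair"  # pair | drug | protein
    seed: int = 0
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    threshold: float | None = None
    warnings: list[str] = field(default_factory=list)

    def subsets(self) -> dict[str, list[int]]:
        return {"train": self.train, "val": self.val, "test": self.test}

    def validate_partition(self, n_records: int) -> None:
        seen = sorted(self.train + self.val + self.test)
        if seen != list(range(n_records)):
            raise DomainError("subsets do not partition the record indices")

    def to_dict(self) -> dict:
        return {
            "train": list(map(int, self.train)),
            "val": list(map(int, self.val)),
            "test": list(map(int, self.test)),
            "provenance": {
                "mode": self.mode,
                "axis": self.axis,
                "seed": self.seed,
                "ratios": list(self.ratios),
                "threshold": self.threshold,
            },
            "warnings": self.warnings,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SplitAssignment":
        prov = payload.get("provenance", {})
        return cls(
            train=list(payload["train"]),
            val=list(payload["val"]),
            test=list(payload["test"]),
            mode=prov.get("mode", "warm"),
            axis=prov.get("axis", "pair"),
            seed=prov.get("seed", 0),
            ratios=tuple(prov.get("ratios", (0.8, 0.1, 0.1))),
            threshold=prov.get("threshold"),
            warnings=list(payload.get("warnings", [])),
        )


@dataclass
class SimilarityCluster:
    """A connected component of the >threshold similarity graph."""

    cluster_id: str
    members: frozenset[str]
    pair_count: int = 0


def _check_ratios(ratios: Sequence[float]) -> tuple[float, float, float]:
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise DomainError(f"need three positive ratios, got {ratios}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise DomainError(f"ratios must sum to 1, got {ratios}")
    return ratios


def largest_remainder_counts(n: int, ratios: Sequence[float], min_per_subset: int = 1
                             ) -> tuple[int, int, int]:
    """Apportion n items to three subsets by largest-remainder rounding,
    guaranteeing at least `min_per_subset` per subset."""
    if n < 3 * min_per_subset:
        raise DomainError(f"cannot split {n} items into three non-empty subsets")
    quotas = np.array([n * r for r in ratios])
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in range(remainder):
        counts[order[i]] += 1
    # enforce the minimum by taking from the largest subset
    for i in range(3):
        while counts[i] < min_per_subset:
            donor = int(np.argmax(counts))
            counts[donor] -= 1
            counts[i] += 1
    return tuple(int(c) for c in counts)


def make_warm_split(
    records: Sequence[AffinityRecord],
    ratios: Sequence[float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Random pair-level partition at the given ratios (8:1:1 default)."""
    ratios = _check_ratios(ratios)
    n = len(records)
    counts = largest_remainder_counts(n, ratios)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = sorted(int(i) for i in perm[: counts[0]])
    val = sorted(int(i) for i in perm[counts[0] : counts[0] + counts[1]])
    test = sorted(int(i) for i in perm[counts[0] + counts[1] :])
    return SplitAssignment(train, val, test, mode="warm", axis="pair",
                           seed=seed, ratios=ratios)


def _records_by_entity(records: Sequence[AffinityRecord], axis: str
                       ) -> dict[str, list[int]]:
    if axis not in ("drug", "protein"):
        raise DomainError(f"axis must be 'drug' or 'protein', got {axis!r}")
    key = "drug_id" if axis == "drug" else "protein_id"
    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(getattr(rec, key), []).append(i)
    return groups


def make_entity_cold_split(
    records: Sequence[AffinityRecord],
    dicts: EntityDictionary | None = None,
    axis: str = "drug",
    ratios: Sequence[float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Entity-disjoint cold split: unique entities on the axis are randomly
    partitioned 8:1:1 and each record follows its entity's subset."""
    ratios = _check_ratios(ratios)
    groups = _records_by_entity(records, axis)
    entities = sorted(groups)
    if len(entities) < 3:
        raise DomainError(
            f"need at least 3 unique {axis} entities, got {len(entities)}"
        )
    counts = largest_remainder_counts(len(entities), ratios)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(entities))
    buckets: dict[str, list[int]] = {"train": [], "val": [], "test": []}
    bounds = (counts[0], counts[0] + counts[1])
    for rank, ent_idx in enumerate(perm):
        subset = "train" if rank < bounds[0] else "val" if rank < bounds[1] else "test"
        buckets[subset].extend(groups[entities[ent_idx]])
    return SplitAssignment(
        sorted(buckets["train"]), sorted(buckets["val"]), sorted(buckets["test"]),
        mode="entity_cold", axis=axis, seed=seed, ratios=ratios,
    )


# --------------------------------------------------------------------------
# similarity-controlled splits
# --------------------------------------------------------------------------


def cluster_entities(
    entities: dict[str, object],
    similarity_fn: Callable[[object, object], float],
    threshold: float,
) -> list[SimilarityCluster]:
    """Single-linkage connected components of the graph with an edge wherever
    similarity is *strictly greater* than the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise DomainError(f"threshold must be in [0, 1], got {threshold}")
    ids = sorted(entities)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if similarity_fn(entities[a], entities[b]) > threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    components: dict[str, set[str]] = {}
    for eid in ids:
        components.setdefault(find(eid), set()).add(eid)
    clusters = [
        SimilarityCluster(cluster_id=min(members), members=frozenset(members))
        for members in components.values()
    ]
    return sorted(clusters, key=lambda c: c.cluster_id)


def greedy_assign_clusters(
    clusters: Sequence[SimilarityCluster],
    ratios: Sequence[float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[dict[str, str], list[str], dict[str, float]]:
    """Assign whole clusters to subsets, matching the target *pair-level*
    ratios.  Clusters are processed in descending pair count (ties by
    cluster id); each goes to the subset with the largest remaining pair
    deficit (ties in deficit resolved train > val > test).

    Returns (cluster_id -> subset, warnings, achieved pair fractions).
    """
    ratios = _check_ratios(ratios)
    total_pairs = sum(c.pair_count for c in clusters)
    if total_pairs == 0:
        raise DomainError("clusters carry no pairs")
    targets = {s: r * total_pairs for s, r in zip(SUBSETS, ratios)}
    filled = {s: 0.0 for s in SUBSETS}
    assignment: dict[str, str] = {}
    order = sorted(clusters, key=lambda c: (-c.pair_count, c.cluster_id))
    for cluster in order:
        deficits = {s: targets[s] - filled[s] for s in SUBSETS}
        subset = max(SUBSETS, key=lambda s: deficits[s])  # first max wins ties
        assignment[cluster.cluster_id] = subset
        filled[subset] += cluster.pair_count
    achieved = {s: filled[s] / total_pairs for s in SUBSETS}
    warnings = []
    for s, r in zip(SUBSETS, ratios):
        # whole-cluster assignment missed the target badly (>25% relative)
        if abs(achieved[s] - r) > 0.25 * r:
            warnings.append(
                f"achieved {s} pair fraction {achieved[s]:.3f} far from target {r:.3f}"
                " (ratio unattainable with whole-cluster assignment)"
            )
            log.warning(warnings[-1])
    return assignment, warnings, achieved


def make_similarity_cold_split(
    records: Sequence[AffinityRecord],
    dicts: EntityDictionary,
    axis: str,
    threshold: float,
    ratios: Sequence[float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Similarity-controlled cold split: cluster entities by Tanimoto over
    Morgan fingerprints (drug axis) or global sequence identity (protein
    axis), then greedily assign whole clusters to subsets."""
    groups = _records_by_entity(records, axis)
    if axis == "drug":
        reps = {d: morgan_fingerprint(dicts.drugs[d]) for d in groups}
        sim = tanimoto
    else:
        reps = {p: dicts.proteins[p] for p in groups}
        sim = global_identity
    clusters = cluster_entities(reps, sim, threshold)
    for cluster in clusters:
        cluster.pair_count = sum(len(groups[m]) for m in cluster.members)
    assignment, warnings, _ = greedy_assign_clusters(clusters, ratios, seed)
    buckets: dict[str, list[int]] = {"train": [], "val": [], "test": []}
    for cluster in clusters:
        subset = assignment[cluster.cluster_id]
        for member in sorted(cluster.members):
            buckets[subset].extend(groups[member])
    split = SplitAssignment(
        sorted(buckets["train"]), sorted(buckets["val"]), sorted(buckets["test"]),
        mode="similarity_cold", axis=axis, seed=seed, ratios=_check_ratios(ratios),
        threshold=threshold, warnings=warnings,
    )
    return split


def entity_sets(
    records: Sequence[AffinityRecord], split: SplitAssignment, axis: str
) -> dict[str, set[str]]:
    """Unique entity ids per subset — the raw material of leakage checks."""
    key = "drug_id" if axis == "drug" else "protein_id"
    return {
        name: {getattr(records[i], key) for i in idx}
        for name, idx in split.subsets().items()
    }
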