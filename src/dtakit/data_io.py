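"""Reading and writing the standard inputs: pair tables, SMILES dictionaries,
FASTA protein sets, split files — plus the affinity transform.

Affinity conventions
--------------------
Davis-style data records dissociation constants Kd; the regression target is
pKd = -log10(Kd in molar).  KIBA-style data ships a unified KIBA score that is
used as-is.  Which convention applies is a declared property of the input
(``affinity_unit``), never inferred from the numbers.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .errors import DomainError, FormatError, ParseError

log = logging.getLogger(__name__)

#: 20 standard residues plus the ambiguity codes kept for masking consistency
#: (X doubles as the occlusion masking character).
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XUBZ")

PAIR_COLUMNS = ("drug_id", "protein_id", "affinity")


@dataclass(frozen=True)
class AffinityRecord:
    """One (drug, protein, affinity) observation — the unit records are
    split on and the model regresses."""

    drug_id: str
    protein_id: str
    affinity: float

    def __post_init__(self):
        if not self.drug_id or not self.protein_id:
            raise ValueError("ids must be non-empty")
        if not math.isfinite(self.affinity):
            raise ValueError(f"affinity must be finite, got {self.affinity}")


@dataclass
class EntityDictionary:
    """id -> SMILES for drugs, id -> amino-acid sequence for proteins."""

    drugs: dict[str, str] = field(default_factory=dict)
    proteins: dict[str, str] = field(default_factory=dict)

    def validate(self, records: Iterable[AffinityRecord]) -> None:
        for rec in records:
            if rec.drug_id not in self.drugs:
                raise FormatError(f"drug id {rec.drug_id!r} not in dictionary")
            if rec.protein_id not in self.proteins:
                raise FormatError(f"protein id {rec.protein_id!r} not in dictionary")
        for pid, seq in self.proteins.items():
            check_protein_sequence(seq, pid)
        for did, smi in self.drugs.items():
            if not smi:
                raise FormatError(f"empty SMILES for drug {did!r}")


def check_protein_sequence(seq: str, name: str = "") -> None:
    if not seq:
        raise FormatError(f"empty protein sequence {name!r}")
    for i, ch in enumerate(seq):
        if ch not in PROTEIN_ALPHABET:
            raise ParseError(
                f"illegal residue {ch!r} at position {i + 1} in sequence {name!r}"
            )


def kd_to_pkd(kd_nanomolar: float) -> float:
    """pKd = -log10(Kd [M]) for a Kd given in nanomolar units."""
    if kd_nanomolar <= 0:
        raise DomainError(f"Kd must be positive, got {kd_nanomolar}")
    return -math.log10(kd_nanomolar * 1e-9)


def read_pair_table(path: str | Path, dialect: str = "tsv") -> list[AffinityRecord]:
    """Read a pair table; columns drug_id, protein_id, affinity required.

    Row order is preserved; duplicate (drug, protein) pairs are allowed but
    reported to the log.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise FormatError(f"unknown dialect {dialect!r}")
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: file has no header") from exc
    missing = [c for c in PAIR_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records: list[AffinityRecord] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        raw = getattr(row, "affinity")
        try:
            affinity = float(raw)
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"{path}: non-numeric affinity {raw!r} at data row {i + 1}"
            ) from exc
        records.append(
            AffinityRecord(str(row.drug_id), str(row.protein_id), affinity)
        )
    if not records:
        log.warning("%s: pair table is empty", path)
    n_dup = len(records) - len({(r.drug_id, r.protein_id) for r in records})
    if n_dup:
        log.info("%s: %d duplicate (drug, protein) pairs", path, n_dup)
    return records


def write_pair_table(records: Iterable[AffinityRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(r.drug_id, r.protein_id, r.affinity) for r in records],
        columns=list(PAIR_COLUMNS),
    )
    frame.to_csv(path, sep="\t", index=False)


def read_entity_table(path: str | Path, dialect: str = "tsv") -> dict[str, str]:
    """Read an id -> sequence/SMILES two-column table (no header required
    beyond ``id`` and the value column; first two columns are used)."""
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise FormatError(f"unknown dialect {dialect!r}")
    frame = pd.read_csv(path, sep=sep, dtype=str)
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: expected at least two columns")
    ids = frame.iloc[:, 0].tolist()
    values = frame.iloc[:, 1].tolist()
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate entity ids")
    return dict(zip((str(i) for i in ids), (str(v) for v in values)))


def write_entity_table(entities: dict[str, str], path: str | Path,
                       value_column: str = "smiles") -> None:
    pd.DataFrame(
        list(entities.items()), columns=["id", value_column]
    ).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {id: sequence}; multi-line records concatenated, the header
    token before the first whitespace is the id."""
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq)
        if record.id in out:
            raise FormatError(f"{path}: duplicate FASTA id {record.id!r}")
        if not seq:
            raise FormatError(f"{path}: empty sequence for {record.id!r}")
        out[record.id] = seq
    return out


def write_fasta(proteins: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteins.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_split(path: str | Path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    for key in ("train", "val", "test"):
        if key not in payload:
            raise FormatError(f"{path}: split file missing {key!r}")
    return payload


def write_split(split, path: str | Path) -> None:
    """Serialise a SplitAssignment (or a plain dict) as JSON."""
    payload = split if isinstance(split, dict) else split.to_dict()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def dataset_dimensions(
    records: list[AffinityRecord],
) -> dict[str, int]:
    """Pair/entity counts of a loaded benchmark (e.g. to verify a release)."""
    return {
        "n_pairs": len(records),
        "n_drugs": len({r.drug_id for r in records}),
        "n_proteins": len({r.protein_id for r in records}),
    }
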