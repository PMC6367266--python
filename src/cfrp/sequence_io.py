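"""Sequence and pair-table I/O for ncRNA-protein interaction datasets.

Reads multi-record FASTA files for RNAs and proteins, a three-column
pair/label table (rna_id, protein_id, label), and supports sampling of
negative (non-interacting) pairs from the RNA x protein cross product
excluding all known pairs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO

RNA_ALPHABET = "ACGU"
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

Kind = Literal["rna", "protein"]


@dataclass(frozen=True)
class SequenceRecord:
    """One RNA or protein sequence: identifier plus residue string."""

    id: str
    residues: str
    kind: Kind

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.kind not in ("rna", "protein"):
            raise ValueError(f"unknown sequence kind {self.kind!r}")

    def nonstandard_residues(self) -> set[str]:
        """Residues outside the declared alphabet (kept, flagged here)."""
        alphabet = RNA_ALPHABET if self.kind == "rna" else PROTEIN_ALPHABET
        return set(self.residues) - set(alphabet)


@dataclass(frozen=True)
class PairRecord:
    """One labelled RNA-protein pair; label 1 = interaction, 0 = none."""

    rna_id: str
    protein_id: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(
                f"pair ({self.rna_id}, {self.protein_id}): label must be 0 or 1, "
                f"got {self.label!r}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.rna_id, self.protein_id)


@dataclass
class InteractionDataset:
    """RNA and protein collections plus an ordered list of labelled pairs."""

    rnas: list[SequenceRecord]
    proteins: list[SequenceRecord]
    pairs: list[PairRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._rna_map = _index_records(self.rnas)
        self._protein_map = _index_records(self.proteins)
        self.validate_pairs(self.pairs)

    @property
    def rna_map(self) -> dict[str, SequenceRecord]:
        return self._rna_map

    @property
    def protein_map(self) -> dict[str, SequenceRecord]:
        return self._protein_map

    @property
    def n_positive(self) -> int:
        return sum(1 for p in self.pairs if p.label == 1)

    @property
    def n_negative(self) -> int:
        return sum(1 for p in self.pairs if p.label == 0)

    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.pairs], dtype=int)

    def validate_pairs(self, pairs: Iterable[PairRecord]) -> None:
        missing_rna = sorted({p.rna_id for p in pairs} - self._rna_map.keys())
        missing_prot = sorted({p.protein_id for p in pairs} - self._protein_map.keys())
        if missing_rna or missing_prot:
            raise KeyError(
                "pairs reference unknown ids: "
                f"rnas={missing_rna or 'none'} proteins={missing_prot or 'none'}"
            )
        seen: set[tuple[str, str]] = set()
        for p in self.pairs:
            if p.key in seen:
                raise ValueError(f"duplicate pair {p.key}")
            seen.add(p.key)


def _index_records(records: Sequence[SequenceRecord]) -> dict[str, SequenceRecord]:
    index: dict[str, SequenceRecord] = {}
    for rec in records:
        if rec.id in index:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        index[rec.id] = rec
    return index


def read_fasta(path: str | Path, kind: Kind) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into SequenceRecords.

    RNA sequences are uppercased and T is mapped to U so DNA-convention
    files are accepted. Duplicate ids and empty sequences are hard errors;
    residues outside the alphabet are retained on the record (they are
    handled downstream according to the k-mer ambiguity policy).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        residues = str(entry.seq).upper()
        if kind == "rna":
            residues = residues.replace("T", "U")
        records.append(SequenceRecord(id=entry.id, residues=residues, kind=kind))
    _index_records(records)  # raises on duplicate ids
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.residues}\n")


def _sniff_pairs_table(path: Path) -> tuple[str, bool]:
    """Return (delimiter, has_header) for a 3-column pairs file."""
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"pairs file {path} is empty")
    delimiter = "\t" if "\t" in first else ","
    third = first.rstrip("\n").split(delimiter)[-1].strip()
    try:
        int(third)
    except ValueError:
        return delimiter, True  # non-numeric third field: header line
    return delimiter, False  # numeric: data line (bad labels error later)


def read_pairs(
    path: str | Path,
    rnas: Sequence[SequenceRecord],
    proteins: Sequence[SequenceRecord],
) -> InteractionDataset:
    """Read a 3-column (rna_id, protein_id, label) table into a dataset.

    Tab or comma delimited; a header line is auto-detected by a non-binary
    third field. Every id must resolve against the given collections.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"pairs file not found: {path}")
    delimiter, has_header = _sniff_pairs_table(path)
    pairs: list[PairRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for i, row in enumerate(reader):
            if not row or (i == 0 and has_header):
                continue
            if len(row) != 3:
                raise ValueError(f"{path}:{i + 1}: expected 3 columns, got {len(row)}")
            rna_id, protein_id, label_str = (c.strip() for c in row)
            if label_str not in ("0", "1"):
                raise ValueError(
                    f"{path}:{i + 1}: label must be 0 or 1, got {label_str!r}"
                )
            pairs.append(PairRecord(rna_id, protein_id, int(label_str)))
    return InteractionDataset(rnas=list(rnas), proteins=list(proteins), pairs=pairs)


def write_pairs(dataset: InteractionDataset, path: str | Path) -> None:
    """Write the pair table as TSV with header."""
    with open(path, "w") as fh:
        fh.write("rna_id\tprotein_id\tlabel\n")
        for p in dataset.pairs:
            fh.write(f"{p.rna_id}\t{p.protein_id}\t{p.label}\n")


def sample_negative_pairs(
    dataset: InteractionDataset, n_negatives: int, seed: int
) -> InteractionDataset:
    """Augment a dataset with uniformly sampled non-interacting pairs.

    Negatives are drawn uniformly without replacement from the RNA x protein
    cross product, excluding every pair already present in the dataset.
    Reproducible given ``seed``.
    """
    n_rna, n_prot = len(dataset.rnas), len(dataset.proteins)
    existing = {p.key for p in dataset.pairs}
    feasible = n_rna * n_prot - len(existing)
    if n_negatives > feasible:
        raise ValueError(
            f"cannot sample {n_negatives} negatives: only {feasible} "
            "non-present pairs exist in the cross product"
        )
    rna_ids = [r.id for r in dataset.rnas]
    prot_ids = [p.id for p in dataset.proteins]
    rna_idx = {rid: i for i, rid in enumerate(rna_ids)}
    prot_idx = {pid: i for i, pid in enumerate(prot_ids)}
    existing_codes = {rna_idx[r] * n_prot + prot_idx[p] for (r, p) in existing}
    rng = np.random.default_rng(seed)
    total = n_rna * n_prot
    if total <= 1_000_000 or n_negatives > feasible // 2:
        # enumerate the complement when the feasible set is small or dense
        candidates = np.array(
            [c for c in range(total) if c not in existing_codes], dtype=np.int64
        )
        chosen = rng.choice(candidates, size=n_negatives, replace=False)
    else:
        chosen_set: set[int] = set()
        while len(chosen_set) < n_negatives:
            draw = rng.integers(0, total, size=2 * (n_negatives - len(chosen_set)))
            for code in draw:
                code = int(code)
                if code not in existing_codes and code not in chosen_set:
                    chosen_set.add(code)
                    if len(chosen_set) == n_negatives:
                        break
        chosen = np.array(sorted(chosen_set), dtype=np.int64)
        chosen = rng.permutation(chosen)
    negatives = [
        PairRecord(rna_ids[int(c) // n_prot], prot_ids[int(c) % n_prot], 0)
        for c in chosen
    ]
    return InteractionDataset(
        rnas=list(dataset.rnas),
        proteins=list(dataset.proteins),
        pairs=list(dataset.pairs) + negatives,
    )
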