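"""Base k-mer frequency features for RNA and reduced-alphabet proteins.

The RNA base feature is the vector of overlapping m-mer frequencies over
the alphabet ACGU (4^m entries). The protein base feature first translates
the sequence into a 7-letter reduced alphabet — the physiochemical 7-group
partition of the 20 amino acids ({A,G,V}, {I,L,F,P}, {Y,M,T,S}, {H,N,Q,W},
{R,K}, {D,E}, {C}) — then counts overlapping n-grams over the group digits
1..7 (7^n entries).

Two normalizations are exposed: ``windows`` divides counts by the number of
(valid) windows L-k+1 so the vector is a frequency distribution, ``length``
divides by the raw sequence length L.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .sequence_io import SequenceRecord

RNA_ALPHABET = "ACGU"
GROUP_DIGITS = "1234567"

#: The 7-group amino-acid partition (group 1..7, in order).
AMINO_GROUPS: tuple[str, ...] = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")

#: Amino-acid letter -> group digit character.
GROUP_OF: dict[str, str] = {
    aa: str(g + 1) for g, members in enumerate(AMINO_GROUPS) for aa in members
}

#: Sentinel used for nonstandard residues under the skip_window policy.
AMBIGUOUS_SENTINEL = "X"


@dataclass(frozen=True)
class KmerConfig:
    """k-mer lengths and counting conventions.

    m, n: window lengths for RNA and (reduced) protein respectively.
    normalization: 'windows' divides by the number of counted windows,
        'length' divides by the sequence length.
    ambiguity_policy: 'skip_window' drops windows containing a residue
        outside the alphabet (denominator reduced accordingly under
        'windows'); 'error' raises on any such residue.
    """

    m: int = 4
    n: int = 3
    normalization: Literal["windows", "length"] = "windows"
    ambiguity_policy: Literal["skip_window", "error"] = "skip_window"

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ValueError("k-mer lengths m and n must be >= 1")
        if self.normalization not in ("windows", "length"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.ambiguity_policy not in ("skip_window", "error"):
            raise ValueError(f"unknown ambiguity policy {self.ambiguity_policy!r}")


@dataclass(frozen=True)
class BaseFeatureVector:
    """Normalized k-mer frequency vector for one sequence."""

    owner_id: str
    kind: Literal["rna", "protein"]
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values and names must align")


def kmer_names(alphabet: str, k: int) -> tuple[str, ...]:
    """All length-k strings over ``alphabet`` in lexicographic order."""
    return tuple("".join(t) for t in itertools.product(alphabet, repeat=k))


def reduce_protein_alphabet(
    seq: SequenceRecord | str, ambiguity_policy: str = "skip_window"
) -> str:
    """Translate a protein sequence into the 7-group digit string.

    Output length equals input length. Nonstandard residues (X, B, Z, U...)
    raise under policy 'error'; under 'skip_window' they are retained as a
    sentinel so windows containing them can be skipped downstream.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    owner = seq.id if isinstance(seq, SequenceRecord) else "<str>"
    out = []
    for ch in residues:
        digit = GROUP_OF.get(ch)
        if digit is None:
            if ambiguity_policy == "error":
                raise ValueError(
                    f"protein {owner}: nonstandard residue {ch!r} "
                    "(ambiguity_policy='error')"
                )
            digit = AMBIGUOUS_SENTINEL
        out.append(digit)
    return "".join(out)


def _count_kmers(
    s: str, k: int, alphabet: str, owner: str, policy: str
) -> tuple[np.ndarray, int]:
    """Counts of overlapping k-mers, base-|alphabet| encoded.

    Returns (counts vector of length |alphabet|^k, number of valid windows).
    Base-encoding over the sorted alphabet makes the vector index order the
    lexicographic k-mer order.
    """
    idx = {c: i for i, c in enumerate(alphabet)}
    base = len(alphabet)
    counts = np.zeros(base**k, dtype=np.float64)
    if len(s) < k:
        raise ValueError(
            f"sequence {owner!r} (length {len(s)}) is shorter than k-mer length {k}"
        )
    invalid = set(s) - set(alphabet)
    if invalid and policy == "error":
        raise ValueError(
            f"sequence {owner!r}: residues {sorted(invalid)} outside alphabet "
            f"{alphabet!r} (ambiguity_policy='error')"
        )
    valid = 0
    for i in range(len(s) - k + 1):
        code = 0
        ok = True
        for ch in s[i : i + k]:
            j = idx.get(ch)
            if j is None:
                ok = False
                break
            code = code * base + j
        if ok:
            counts[code] += 1
            valid += 1
    return counts, valid


def _normalize(
    counts: np.ndarray, valid_windows: int, seq_len: int, normalization: str, owner: str
) -> np.ndarray:
    if normalization == "windows":
        if valid_windows == 0:
            raise ValueError(
                f"sequence {owner!r}: no valid windows to count "
                "(all contain nonstandard residues)"
            )
        return counts / valid_windows
    return counts / seq_len


def rna_kmer_vector(seq: SequenceRecord, config: KmerConfig) -> BaseFeatureVector:
    """Normalized m-mer frequency vector of an RNA sequence (length 4^m)."""
    if seq.kind != "rna":
        raise ValueError(f"sequence {seq.id!r} is not RNA")
    residues = seq.residues.upper().replace("T", "U")
    counts, valid = _count_kmers(
        residues, config.m, RNA_ALPHABET, seq.id, config.ambiguity_policy
    )
    values = _normalize(counts, valid, len(residues), config.normalization, seq.id)
    return BaseFeatureVector(
        owner_id=seq.id,
        kind="rna",
        values=values,
        names=kmer_names(RNA_ALPHABET, config.m),
    )


def protein_kmer_vector(seq: SequenceRecord, config: KmerConfig) -> BaseFeatureVector:
    """Normalized n-gram frequency vector over the 7-group reduced string
    of a protein sequence (length 7^n)."""
    if seq.kind != "protein":
        raise ValueError(f"sequence {seq.id!r} is not protein")
    reduced = reduce_protein_alphabet(seq, config.ambiguity_policy)
    counts, valid = _count_kmers(
        reduced, config.n, GROUP_DIGITS, seq.id, config.ambiguity_policy
    )
    values = _normalize(counts, valid, len(reduced), config.normalization, seq.id)
    return BaseFeatureVector(
        owner_id=seq.id,
        kind="protein",
        values=values,
        names=kmer_names(GROUP_DIGITS, config.n),
    )
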