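"""Subfamily alignments, interfacial-position maps and column statistics.

The unit of analysis is an :class:`AlignedSubfamily`: a gap-aware amino-acid
multiple sequence alignment of the orthologs of one interaction-specificity
subgroup, on one side of a heterophilic family (here labelled ``DIP`` and
``Dpr``).  Alignments are restricted to interfacial columns through a
:class:`PositionMap`, which ties a family-wide interfacial numbering (1..P)
to protein-specific (UniProt-style) residue numbers and 0-based alignment
columns of a reference sequence.

Frequencies are computed over a fixed 21-symbol alphabet: the 20 standard
amino acids plus the gap character ``-``, which is counted as a symbol of its
own rather than discarded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
#: 21-symbol alphabet: 20 amino acids + gap, in fixed order.
ALPHABET: str = AMINO_ACIDS + GAP

_SYMBOL_INDEX: dict[str, int] = {s: i for i, s in enumerate(ALPHABET)}

DIP = "DIP"
DPR = "Dpr"
SIDES = (DIP, DPR)


class AlignmentError(ValueError):
    """Malformed alignment input (ragged rows, bad symbols, duplicate ids)."""


def symbol_index(symbol: str) -> int:
    """Index of *symbol* in the 21-letter alphabet; raises on anything else."""
    try:
        return _SYMBOL_INDEX[symbol]
    except KeyError:
        raise AlignmentError(f"symbol {symbol!r} is not in the 21-letter alphabet")


@dataclass(frozen=True)
class AlignedSubfamily:
    """A subgroup MSA tagged with its family side and subgroup identity."""

    family_side: str
    subgroup_id: str
    sequence_ids: tuple[str, ...]
    rows: tuple[str, ...]
    reference_id: str | None = None

    def __post_init__(self) -> None:
        if self.family_side not in SIDES:
            raise AlignmentError(
                f"family_side must be one of {SIDES}, got {self.family_side!r}"
            )
        if not self.rows:
            raise AlignmentError(f"subfamily {self.subgroup_id!r}: empty alignment")
        if len(self.sequence_ids) != len(self.rows):
            raise AlignmentError("sequence_ids and rows must have equal counts")
        if len(set(self.sequence_ids)) != len(self.sequence_ids):
            seen: set[str] = set()
            dup = next(s for s in self.sequence_ids if s in seen or seen.add(s))
            raise AlignmentError(f"duplicate sequence id {dup!r}")
        width = len(self.rows[0])
        if width < 1:
            raise AlignmentError("alignment rows must have length >= 1")
        for sid, row in zip(self.sequence_ids, self.rows):
            if len(row) != width:
                raise AlignmentError(
                    f"ragged alignment: record {sid!r} has length {len(row)}, "
                    f"expected {width}"
                )
            for col, ch in enumerate(row):
                if ch not in _SYMBOL_INDEX:
                    raise AlignmentError(
                        f"record {sid!r}, column {col}: symbol {ch!r} "
                        "is not in the 21-letter alphabet"
                    )

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def column(self, index: int) -> str:
        if not 0 <= index < self.length:
            raise IndexError(f"column {index} out of range [0, {self.length})")
        return "".join(row[index] for row in self.rows)

    def as_array(self) -> np.ndarray:
        """(n_sequences, length) array of alphabet indices."""
        return np.array(
            [[_SYMBOL_INDEX[ch] for ch in row] for row in self.rows], dtype=np.int8
        )


@dataclass(frozen=True)
class FrequencyProfile:
    """Per-column symbol frequencies over the 21-letter alphabet."""

    column: int
    freqs: np.ndarray
    n_sequences: int

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        if freqs.shape != (len(ALPHABET),):
            raise ValueError(f"freqs must have shape (21,), got {freqs.shape}")
        if (freqs < 0).any():
            raise ValueError("frequencies must be non-negative")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies must sum to 1, got {freqs.sum()!r}")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be positive")

    @classmethod
    def from_counts(cls, column: int, counts: Mapping[str, int]) -> "FrequencyProfile":
        n = sum(counts.values())
        freqs = np.zeros(len(ALPHABET))
        for sym, c in counts.items():
            freqs[symbol_index(sym)] = c / n
        return cls(column=column, freqs=freqs, n_sequences=n)

    def frequency(self, symbol: str) -> float:
        return float(self.freqs[symbol_index(symbol)])

    @property
    def amino_acid_freqs(self) -> np.ndarray:
        """The 20 amino-acid frequencies (gap dropped, NOT renormalized)."""
        return self.freqs[:-1]

    @property
    def gap_freq(self) -> float:
        return float(self.freqs[-1])

    def modal_residues(self) -> frozenset[str]:
        """All amino acids achieving the maximum frequency; gap excluded.

        Empty for an all-gap column.
        """
        aa = self.amino_acid_freqs
        top = aa.max()
        if top <= 0.0:
            return frozenset()
        return frozenset(AMINO_ACIDS[i] for i in np.flatnonzero(aa == top))


@dataclass(frozen=True)
class PositionMapEntry:
    family_position: int
    protein_id: str
    residue_number: int
    alignment_column: int


@dataclass(frozen=True)
class PositionMap:
    """Family-wide interfacial numbering tied to per-protein coordinates."""

    entries: tuple[PositionMapEntry, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty position map rejected")
        seen_fp: set[tuple[str, int]] = set()
        seen_col: set[tuple[str, int]] = set()
        for e in self.entries:
            if e.family_position < 1:
                raise ValueError(f"family_position must be >= 1, got {e.family_position}")
            key = (e.protein_id, e.family_position)
            if key in seen_fp:
                raise ValueError(f"duplicate (protein_id, family_position) {key}")
            seen_fp.add(key)
            ckey = (e.protein_id, e.alignment_column)
            if ckey in seen_col:
                raise ValueError(f"duplicate alignment column {ckey}")
            seen_col.add(ckey)
        # each mapped protein must cover 1..P without holes
        for pid in {e.protein_id for e in self.entries}:
            fps = sorted(e.family_position for e in self.entries if e.protein_id == pid)
            if fps != list(range(1, len(fps) + 1)):
                raise ValueError(
                    f"protein {pid!r}: family positions {fps} do not cover 1..P"
                )

    def proteins(self) -> set[str]:
        return {e.protein_id for e in self.entries}

    def columns_for(self, protein_id: str) -> list[tuple[int, int]]:
        """(family_position, alignment_column) pairs, ascending family position."""
        pairs = [
            (e.family_position, e.alignment_column)
            for e in self.entries
            if e.protein_id == protein_id
        ]
        if not pairs:
            raise KeyError(f"protein {protein_id!r} absent from position map")
        return sorted(pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.family_position, e.protein_id, e.residue_number, e.alignment_column)
                for e in self.entries
            ],
            columns=["family_position", "protein_id", "residue_number", "alignment_column"],
        )


@dataclass(frozen=True)
class AsaRecord:
    """Per-residue change in accessible surface area upon complex formation."""

    protein_id: str
    residue_number: int
    delta_asa: float

    def __post_init__(self) -> None:
        if self.delta_asa < 0:
            raise ValueError(
                f"{self.protein_id} residue {self.residue_number}: "
                f"delta_asa must be >= 0, got {self.delta_asa}"
            )


# ---------------------------------------------------------------------------
# I/O


def read_aligned_fasta(path: str | Path, family_side: str, subgroup_id: str,
                       reference_id: str | None = None) -> AlignedSubfamily:
    """Read an aligned FASTA file into an :class:`AlignedSubfamily`.

    Letters are uppercased; sequence order is preserved.  Ragged alignments,
    empty files and symbols outside the 21-letter alphabet are hard errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no FASTA records found")
    ids = tuple(r.id for r in records)
    rows = tuple(str(r.seq).upper() for r in records)
    return AlignedSubfamily(
        family_side=family_side,
        subgroup_id=subgroup_id,
        sequence_ids=ids,
        rows=rows,
        reference_id=reference_id,
    )


def write_aligned_fasta(msa: AlignedSubfamily, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(msa.sequence_ids, msa.rows):
            fh.write(f">{sid}\n{row}\n")


def read_position_map(path: str | Path) -> PositionMap:
    """Read a tab-separated position map with the standard header."""
    df = pd.read_csv(path, sep="\t")
    required = ["family_position", "protein_id", "residue_number", "alignment_column"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing position-map columns {missing}")
    entries = tuple(
        PositionMapEntry(
            family_position=int(r.family_position),
            protein_id=str(r.protein_id),
            residue_number=int(r.residue_number),
            alignment_column=int(r.alignment_column),
        )
        for r in df.itertuples()
    )
    return PositionMap(entries=entries)


def write_position_map(pmap: PositionMap, path: str | Path) -> None:
    pmap.to_frame().to_csv(path, sep="\t", index=False)


def read_asa_table(path: str | Path) -> list[AsaRecord]:
    df = pd.read_csv(path, sep="\t")
    required = ["protein_id", "residue_number", "delta_asa"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing ASA columns {missing}")
    return [
        AsaRecord(str(r.protein_id), int(r.residue_number), float(r.delta_asa))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Operations


def assign_interfacial_positions(asa: Iterable[AsaRecord]) -> dict[str, set[int]]:
    """Residue numbers with strictly positive buried surface, per protein.

    A residue is interfacial when its accessible surface area changes upon
    complex formation; delta_asa == 0 means no burial and is excluded.
    """
    out: dict[str, set[int]] = {}
    seen: set[tuple[str, int]] = set()
    for rec in asa:
        key = (rec.protein_id, rec.residue_number)
        if key in seen:
            raise ValueError(f"duplicate ASA record for {key}")
        seen.add(key)
        out.setdefault(rec.protein_id, set())
        if rec.delta_asa > 0:
            out[rec.protein_id].add(rec.residue_number)
    return out


def extract_interfacial_columns(msa: AlignedSubfamily, pmap: PositionMap) -> AlignedSubfamily:
    """Restrict *msa* to the mapped interfacial columns of its reference.

    Output columns are ordered by ascending family position; row count is
    unchanged.
    """
    if msa.reference_id is None or msa.reference_id not in pmap.proteins():
        raise ValueError(
            f"reference sequence {msa.reference_id!r} absent from position map"
        )
    pairs = pmap.columns_for(msa.reference_id)
    cols = [c for _, c in pairs]
    bad = [c for c in cols if c >= msa.length]
    if bad:
        raise ValueError(
            f"mapped columns {bad} beyond alignment length {msa.length}"
        )
    rows = tuple("".join(row[c] for c in cols) for row in msa.rows)
    return AlignedSubfamily(
        family_side=msa.family_side,
        subgroup_id=msa.subgroup_id,
        sequence_ids=msa.sequence_ids,
        rows=rows,
        reference_id=msa.reference_id,
    )


def column_frequency_profile(msa: AlignedSubfamily, column: int) -> FrequencyProfile:
    """Exact symbol frequencies at *column*; gap counted as its own symbol."""
    col = msa.column(column)
    counts = np.zeros(len(ALPHABET))
    for ch in col:
        counts[_SYMBOL_INDEX[ch]] += 1
    return FrequencyProfile(
        column=column, freqs=counts / len(col), n_sequences=len(col)
    )


def profile_matrix(msa: AlignedSubfamily) -> np.ndarray:
    """(length, 21) frequency matrix for all columns at once."""
    arr = msa.as_array()
    mat = np.zeros((msa.length, len(ALPHABET)))
    for j in range(msa.length):
        mat[j] = np.bincount(arr[:, j], minlength=len(ALPHABET))
    return mat / msa.n_sequences


def mean_pairwise_identity(msa: AlignedSubfamily) -> float:
    """Average pairwise percent identity over all unordered row pairs.

    Columns gapped in both rows of a pair are excluded from numerator and
    denominator; a gap against a residue counts as a mismatch.
    """
    if msa.n_sequences < 2:
        raise ValueError("mean pairwise identity needs at least 2 sequences")
    arr = msa.as_array()
    gap_idx = _SYMBOL_INDEX[GAP]
    idents = []
    for i, j in itertools.combinations(range(msa.n_sequences), 2):
        a, b = arr[i], arr[j]
        comparable = ~((a == gap_idx) & (b == gap_idx))
        n_comp = int(comparable.sum())
        if n_comp == 0:
            raise ValueError(
                f"rows {msa.sequence_ids[i]!r} and {msa.sequence_ids[j]!r} "
                "share no comparable columns"
            )
        matches = int(((a == b) & comparable & (a != gap_idx)).sum())
        idents.append(matches / n_comp * 100.0)
    return float(np.mean(idents))
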