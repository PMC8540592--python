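"""Nucleic-acid and codon-level primitives.

All internal computation is on the RNA alphabet {A, C, G, U}; DNA input is
normalized on ingest (T -> U, case folded). Coordinates are 0-based with
half-open windows. Positions *relative to the start codon* follow the
convention i = 0 at the first nucleotide of the start codon, negative
upstream; an offset i maps to transcript index ``len(utr5) + i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator, Sequence

from Bio.Data import CodonTable

from .errors import (
    ConstraintError,
    InternalStopError,
    SequenceAlphabetError,
    WindowError,
)

RNA_ALPHABET = frozenset("ACGU")

#: Start codons recognized by the initiator-tRNA energy table.
START_CODONS = ("AUG", "GUG")


def normalize_to_rna(raw: str) -> str:
    """Normalize a raw nucleotide string to the uppercase RNA alphabet.

    T is replaced by U and case is folded; length is preserved. Ambiguity
    codes (IUPAC N, R, Y, ...) and any non-nucleotide characters are
    rejected with the 0-based position of the first offender.

    Idempotent: normalizing an already-normalized sequence is a no-op.
    """
    out = raw.upper().replace("T", "U")
    for pos, ch in enumerate(out):
        if ch not in RNA_ALPHABET:
            raise SequenceAlphabetError(
                f"non-ACGT/U character {raw[pos]!r} at position {pos}"
            )
    return out


def reverse_complement(rna: str) -> str:
    """Reverse complement on the RNA alphabet."""
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    return "".join(comp[c] for c in reversed(rna))


@lru_cache(maxsize=None)
def _table(table_id: int) -> CodonTable.CodonTable:
    # RNA table: codons written with U
    return CodonTable.unambiguous_rna_by_id[table_id]


@dataclass(frozen=True)
class Protein:
    """An amino-acid sequence (one-letter codes), no internal stop symbol.

    ``terminal_stop`` records whether the source coding sequence carried a
    trailing stop codon that was stripped during translation.
    """

    residues: str
    terminal_stop: bool = False

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.residues

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CodingSequence:
    """A start-to-end coding region on the RNA alphabet.

    Invariants enforced at construction: length is a positive multiple of 3,
    the first codon is a recognized start codon (AUG or GUG), and no in-frame
    stop codon occurs before the final codon. A terminal stop codon is
    permitted; :func:`translate` strips and flags it.
    """

    rna: str
    table_id: int = 1

    def __post_init__(self) -> None:
        rna = normalize_to_rna(self.rna)
        object.__setattr__(self, "rna", rna)
        if len(rna) == 0 or len(rna) % 3 != 0:
            raise ConstraintError(
                f"coding sequence length {len(rna)} is not a positive multiple of 3"
            )
        if rna[:3] not in START_CODONS:
            raise ConstraintError(
                f"first codon {rna[:3]} is not a recognized start codon "
                f"{'/'.join(START_CODONS)}"
            )
        stops = _table(self.table_id).stop_codons
        for idx in range(0, self.codon_count - 1):
            codon = rna[3 * idx : 3 * idx + 3]
            if codon in stops:
                raise InternalStopError(f"in-frame stop codon {codon} at codon {idx}")

    @property
    def codon_count(self) -> int:
        return len(self.rna) // 3

    @property
    def start_codon(self) -> str:
        return self.rna[:3]

    def codon(self, idx: int) -> str:
        return self.rna[3 * idx : 3 * idx + 3]

    def codons(self) -> Iterator[str]:
        for idx in range(self.codon_count):
            yield self.codon(idx)


def translate(cds: CodingSequence) -> Protein:
    """Translate a coding sequence, one residue per codon.

    The start codon is translated as methionine regardless of whether it is
    AUG or GUG (initiator-tRNA reading). A terminal stop codon, if present,
    is dropped and flagged on the returned :class:`Protein`.
    """
    table = _table(cds.table_id)
    stops = set(table.stop_codons)
    residues = []
    terminal_stop = False
    for idx, codon in enumerate(cds.codons()):
        if codon in stops:
            if idx == cds.codon_count - 1:
                terminal_stop = True
                break
            raise InternalStopError(f"in-frame stop codon {codon} at codon {idx}")
        residues.append("M" if idx == 0 else table.forward_table[codon])
    return Protein("".join(residues), terminal_stop=terminal_stop)


def synonymous_single_nt_variants(
    cds: CodingSequence, codon_range: tuple[int, int]
) -> list[CodingSequence]:
    """All coding sequences one nucleotide away from *cds* with the same protein.

    ``codon_range`` is a half-open ``[first, last)`` interval of codon
    indices; the start codon (codon 0) is never mutable and including it is a
    :class:`ConstraintError`. The returned list is exhaustive over all
    single-nucleotide swaps inside the range that preserve the translation
    (hence introduce no stop codon) and is free of duplicates.
    """
    first, last = codon_range
    if first < 1:
        raise ConstraintError("codon 0 (the start codon) is never mutable")
    if last > cds.codon_count or first >= last:
        raise ConstraintError(
            f"codon range [{first}, {last}) invalid for {cds.codon_count} codons"
        )
    table = _table(cds.table_id)
    stops = set(table.stop_codons)
    variants: list[CodingSequence] = []
    rna = cds.rna
    for ci in range(first, last):
        codon = cds.codon(ci)
        is_terminal_stop = ci == cds.codon_count - 1 and codon in stops
        aa = None if is_terminal_stop else table.forward_table[codon]
        for k in range(3):
            for nt in "ACGU":
                if nt == codon[k]:
                    continue
                new_codon = codon[:k] + nt + codon[k + 1 :]
                if is_terminal_stop:
                    if new_codon not in stops:
                        continue
                else:
                    if new_codon in stops or table.forward_table[new_codon] != aa:
                        continue
                pos = 3 * ci + k
                variants.append(
                    CodingSequence(rna[:pos] + nt + rna[pos + 1 :], cds.table_id)
                )
    return variants


@dataclass(frozen=True)
class Construct:
    """An expression transcript: 5'UTR + CDS with SD and start-codon anchors.

    ``sd_offset`` is the signed position *i* of the SD anchor (the 5'-most
    nucleotide of the SD motif) relative to the first nucleotide of the start
    codon; negative means upstream. The SD motif must occur in the 5'UTR at
    exactly that position.
    """

    name: str
    utr5: str
    cds: CodingSequence
    sd_sequence: str
    sd_offset: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "utr5", normalize_to_rna(self.utr5))
        object.__setattr__(self, "sd_sequence", normalize_to_rna(self.sd_sequence))
        if len(self.utr5) == 0:
            raise ConstraintError("empty 5'UTR")
        if len(self.sd_sequence) == 0:
            raise ConstraintError("empty SD sequence")
        start = len(self.utr5) + self.sd_offset
        end = start + len(self.sd_sequence)
        if start < 0 or end > len(self.utr5):
            raise ConstraintError(
                f"SD offset {self.sd_offset} places the SD motif outside the 5'UTR"
            )
        if self.utr5[start:end] != self.sd_sequence:
            raise ConstraintError(
                f"SD motif {self.sd_sequence} not found in the 5'UTR at offset "
                f"{self.sd_offset} (found {self.utr5[start:end]})"
            )

    @property
    def transcript(self) -> str:
        return self.utr5 + self.cds.rna

    @property
    def start_index(self) -> int:
        """Transcript index of the first nucleotide of the start codon."""
        return len(self.utr5)

    def with_cds(self, cds: CodingSequence, name: str | None = None) -> "Construct":
        return Construct(
            name=name if name is not None else self.name,
            utr5=self.utr5,
            cds=cds,
            sd_sequence=self.sd_sequence,
            sd_offset=self.sd_offset,
        )


@dataclass(frozen=True)
class Transcript:
    """An annotated transcript with coordinate mapping helpers."""

    sequence: str
    start_index: int
    sd_index: int

    def rel_to_abs(self, i: int) -> int:
        """Map a position relative to the start codon to a transcript index."""
        idx = self.start_index + i
        if not 0 <= idx < len(self.sequence):
            raise WindowError(
                f"relative position {i} maps to transcript index {idx}, outside "
                f"[0, {len(self.sequence)})"
            )
        return idx

    def abs_to_rel(self, idx: int) -> int:
        if not 0 <= idx < len(self.sequence):
            raise WindowError(f"transcript index {idx} out of range")
        return idx - self.start_index


def build_transcript(c: Construct) -> Transcript:
    """Assemble the annotated transcript of a construct (UTR + CDS, no gaps)."""
    return Transcript(
        sequence=c.transcript,
        start_index=c.start_index,
        sd_index=c.start_index + c.sd_offset,
    )
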