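"""Sequence and table I/O for band-specific SELEX-seq experiments.

The selection library is a 72-nt oligonucleotide: an 18-nt 5' flank, a 35-nt
random insert, and a 19-nt 3' flank.  The flanks are constant (they carry the
PCR-primer and sequencing-adapter function), so raw reads are reduced to
inserts by anchoring on short terminal segments of the flanks rather than by
alignment.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FLANK5 = "ACGACGCTCTTCCGATCT"
FLANK3 = "GATCGGAAGAGCACACGTC"
INSERT_LENGTH = 35

_DNA = set("ACGTN")


class ParseError(ValueError):
    """A sequence file violated its format or a record invariant."""


@dataclasses.dataclass
class Read:
    """One sequencing read: id, DNA sequence, optional per-base quality."""

    id: str
    sequence: str
    quality: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"read {self.id!r}: empty sequence")
        bad = set(self.sequence) - _DNA
        if bad:
            raise ParseError(f"read {self.id!r}: non-DNA characters {sorted(bad)}")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ParseError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )


@dataclasses.dataclass
class ReadSet:
    """Fixed-length inserts recovered for one condition / gel band.

    ``condition`` is a free label (e.g. ``POU1+BOB1/ternary``); ``inserts``
    are plain A/C/G/T strings of length ``insert_length``.
    """

    condition: str
    inserts: list[str]
    insert_length: int = INSERT_LENGTH

    def __post_init__(self) -> None:
        for ins in self.inserts:
            if len(ins) != self.insert_length:
                raise ValueError(
                    f"insert length {len(ins)} != {self.insert_length} in "
                    f"set {self.condition!r}"
                )
            if set(ins) - set("ACGT"):
                raise ValueError(f"ambiguous base in insert {ins!r}")

    def __len__(self) -> int:
        return len(self.inserts)


@dataclasses.dataclass
class TrimPolicy:
    """How raw reads are reduced to inserts.

    The terminal ``anchor_length`` bases of the 5' flank and the leading
    ``anchor_length`` bases of the 3' flank are located in the read, each
    tolerating up to ``max_anchor_mismatches`` substitutions; the enclosed
    segment is accepted iff it has ``required_insert_length`` bases, none
    of them N.
    """

    flank5: str = FLANK5
    flank3: str = FLANK3
    anchor_length: int = 8
    max_anchor_mismatches: int = 1
    required_insert_length: int = INSERT_LENGTH

    def __post_init__(self) -> None:
        if self.anchor_length < 6:
            raise ValueError("anchor_length must be >= 6")
        if self.anchor_length > min(len(self.flank5), len(self.flank3)):
            raise ValueError("anchor_length exceeds flank length")
        if self.max_anchor_mismatches < 0:
            raise ValueError("max_anchor_mismatches must be >= 0")
        if self.required_insert_length <= 0:
            raise ValueError("required_insert_length must be > 0")

    @property
    def anchor5(self) -> str:
        return self.flank5[-self.anchor_length:]

    @property
    def anchor3(self) -> str:
        return self.flank3[: self.anchor_length]


def read_sequences(path: str | Path, format: str = "fasta") -> list[Read]:
    """Parse a FASTA or FASTQ file into :class:`Read` records, in file order.

    Sequences are upper-cased.  FASTQ qualities use the Sanger encoding.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}; expected 'fasta' or 'fastq'")
    reads: list[Read] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), format)):
            qual = rec.letter_annotations.get("phred_quality")
            reads.append(
                Read(
                    id=rec.id,
                    sequence=str(rec.seq).upper(),
                    quality=list(qual) if qual is not None else None,
                )
            )
    except ParseError:
        raise
    except ValueError as exc:  # Biopython signals malformed records this way
        raise ParseError(f"record {len(reads)}: {exc}") from exc
    return reads


def write_sequences(
    reads: Iterable[Read], path: str | Path, format: str = "fasta"
) -> None:
    """Write reads as FASTA or FASTQ (Sanger qualities)."""
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        if format == "fastq":
            qual = r.quality if r.quality is not None else [40] * len(r.sequence)
            rec.letter_annotations["phred_quality"] = qual
        records.append(rec)
    SeqIO.write(records, str(path), format)


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _find_anchor(seq: str, anchor: str, max_mm: int, start: int = 0) -> int:
    """Leftmost offset >= start where anchor matches with <= max_mm mismatches, else -1."""
    k = len(anchor)
    for off in range(start, len(seq) - k + 1):
        if _mismatches(seq[off : off + k], anchor) <= max_mm:
            return off
    return -1


def trim_reads(
    reads: Sequence[Read],
    policy: TrimPolicy | None = None,
    condition: str = "unlabeled",
) -> tuple[ReadSet, int]:
    """Trim raw reads to fixed-length inserts; return (ReadSet, rejected count).

    Rejection is data, not an error: accepted + rejected == len(reads) always.
    A read is rejected when either anchor is absent, the enclosed segment has
    the wrong length, or it contains an N.
    """
    policy = policy or TrimPolicy()
    a5, a3 = policy.anchor5, policy.anchor3
    accepted: list[str] = []
    rejected = 0
    for read in reads:
        seq = read.sequence
        p5 = _find_anchor(seq, a5, policy.max_anchor_mismatches)
        if p5 < 0:
            rejected += 1
            continue
        insert_start = p5 + policy.anchor_length
        p3 = _find_anchor(seq, a3, policy.max_anchor_mismatches, start=insert_start)
        if p3 < 0:
            rejected += 1
            continue
        insert = seq[insert_start:p3]
        if len(insert) != policy.required_insert_length or "N" in insert:
            rejected += 1
            continue
        accepted.append(insert)
    return (
        ReadSet(
            condition=condition,
            inserts=accepted,
            insert_length=policy.required_insert_length,
        ),
        rejected,
    )


def write_table(rows: pd.DataFrame | list[dict], path: str | Path) -> None:
    """Write tabular records as TSV with a header row; deterministic columns."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
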