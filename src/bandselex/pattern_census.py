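"""Degenerate-pattern k-mer census of SELEX insert sets.

Octamer-site variants are tabulated with the degenerate IUPAC word
``ANNNNAAN`` (1024 concrete 8-mers): the fixed A's at positions 1, 6 and 7
pin the highly conserved positions of the octamer ATGCAAAT while leaving the
variable positions 2-5 and 8 free.  Fixing those positions also suppresses
double counting: a frame shifted against a matched word can itself match
only if the word's own bases under the shifted frame's fixed positions are
all A, and the word's reverse complement matches the pattern only when the
word carries T at positions 2, 3 and 8.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Literal, NamedTuple

import numpy as np
import pandas as pd

from .seqio import ReadSet

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

DEFAULT_PATTERN_WORD = "ANNNNAAN"

StrandMode = Literal["forward", "both"]
CountMode = Literal["per_read", "per_occurrence"]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclasses.dataclass(frozen=True)
class DegeneratePattern:
    """An IUPAC word with enumeration and window-matching semantics."""

    word: str = DEFAULT_PATTERN_WORD

    def __post_init__(self) -> None:
        bad = [c for c in self.word if c not in IUPAC]
        if bad:
            raise ValueError(f"invalid IUPAC character(s) {bad} in {self.word!r}")
        if not self.word:
            raise ValueError("empty pattern")

    @property
    def length(self) -> int:
        return len(self.word)

    @property
    def cardinality(self) -> int:
        n = 1
        for c in self.word:
            n *= len(IUPAC[c])
        return n

    @property
    def position_sets(self) -> tuple[frozenset, ...]:
        return tuple(frozenset(IUPAC[c]) for c in self.word)

    def matches(self, word: str) -> bool:
        """True iff ``word`` is a concrete realization of the pattern."""
        if len(word) != self.length:
            return False
        return all(b in IUPAC[c] for b, c in zip(word, self.word))


def enumerate_pattern(pattern: DegeneratePattern) -> list[str]:
    """All concrete DNA words matching the pattern, lexicographic, unique."""
    choices = [sorted(IUPAC[c]) for c in pattern.word]
    return ["".join(p) for p in itertools.product(*choices)]


class Occurrence(NamedTuple):
    """One pattern match: window start (original insert coordinates),
    strand ('+'/'-'), and the matched word in pattern orientation."""

    offset: int
    strand: str
    word: str


def match_pattern(
    insert: str,
    pattern: DegeneratePattern,
    strand_mode: StrandMode = "both",
) -> list[Occurrence]:
    """All pattern occurrences in an insert, in scan order.

    The forward strand is scanned 5'->3' first; with ``strand_mode='both'``
    the reverse complement is then scanned 5'->3'.  Matched words are always
    reported in pattern orientation; offsets refer to the window start on
    the original insert.
    """
    k = pattern.length
    sets = pattern.position_sets
    occs: list[Occurrence] = []
    n = len(insert)
    if n < k:
        return occs
    for off in range(n - k + 1):
        window = insert[off : off + k]
        if all(b in s for b, s in zip(window, sets)):
            occs.append(Occurrence(off, "+", window))
    if strand_mode == "both":
        rc = reverse_complement(insert)
        for off in range(n - k + 1):
            window = rc[off : off + k]
            if all(b in s for b, s in zip(window, sets)):
                occs.append(Occurrence(n - k - off, "-", window))
    return occs


@dataclasses.dataclass
class FrequencyTable:
    """Per-word counts and relative frequencies (%) for one insert set.

    Relative frequencies are percentages of *matched* words (denominator
    is the total match count), so they sum to 100 over the pattern's word
    universe; the matched fraction of reads is carried separately.
    """

    pattern: DegeneratePattern
    set_label: str
    counts: dict[str, int]
    matched_reads: int
    total_reads: int

    @property
    def rel_freq(self) -> dict[str, float]:
        total = sum(self.counts.values())
        if total == 0:
            return {}
        return {w: 100.0 * c / total for w, c in self.counts.items()}

    def rel_freq_of(self, word: str) -> float:
        return self.rel_freq.get(word, 0.0)

    def to_frame(self) -> pd.DataFrame:
        rel = self.rel_freq
        rows = [
            {"word": w, "count": c, "rel_freq_percent": rel.get(w, 0.0)}
            for w, c in sorted(
                self.counts.items(), key=lambda wc: (-wc[1], wc[0])
            )
        ]
        return pd.DataFrame(rows, columns=["word", "count", "rel_freq_percent"])


def census(
    readset: ReadSet,
    pattern: DegeneratePattern | None = None,
    count_mode: CountMode = "per_read",
    strand_mode: StrandMode = "both",
) -> FrequencyTable:
    """Tabulate pattern-matching words over an insert set.

    ``per_read`` attributes at most one word per read — the first occurrence
    in scan order — reflecting that a selected 35-mer was enriched by one
    binding event; ``per_occurrence`` counts every window match.
    """
    pattern = pattern or DegeneratePattern()
    counts: dict[str, int] = {}
    matched_reads = 0
    for insert in readset.inserts:
        occs = match_pattern(insert, pattern, strand_mode)
        if not occs:
            continue
        matched_reads += 1
        if count_mode == "per_read":
            occs = occs[:1]
        for occ in occs:
            counts[occ.word] = counts.get(occ.word, 0) + 1
    return FrequencyTable(
        pattern=pattern,
        set_label=readset.condition,
        counts=counts,
        matched_reads=matched_reads,
        total_reads=len(readset.inserts),
    )


class TopRanking(NamedTuple):
    entries: list[tuple[str, float]]  # (word, rel_freq %) descending
    cumulative_share: float  # summed rel_freq of the returned words, %


def top_n(table: FrequencyTable, n: int) -> TopRanking:
    """Top-n words by relative frequency; ties broken lexicographically.

    Only words with count > 0 are ranked.  The cumulative share is the
    summed relative frequency (%) of the returned list.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rel = table.rel_freq
    ranked = sorted(rel.items(), key=lambda wf: (-wf[1], wf[0]))
    ranked = [(w, f) for w, f in ranked if table.counts.get(w, 0) > 0][:n]
    return TopRanking(ranked, sum(f for _, f in ranked))


@dataclasses.dataclass
class PositionalComposition:
    """Per-position base percentages over matched words (k x 4)."""

    matrix: pd.DataFrame  # index 1..k, columns A C G T, percentages
    n_sites: int

    @property
    def defined(self) -> bool:
        return self.n_sites > 0

    def percent(self, position: int, base: str) -> float:
        return float(self.matrix.loc[position, base])


def positional_composition(
    readset: ReadSet,
    pattern: DegeneratePattern | None = None,
    count_mode: CountMode = "per_read",
    strand_mode: StrandMode = "both",
) -> PositionalComposition:
    """Base composition (%) at each pattern position over matched words."""
    pattern = pattern or DegeneratePattern()
    table = census(readset, pattern, count_mode, strand_mode)
    return composition_from_counts(table.counts, pattern.length)


def composition_from_counts(
    counts: dict[str, int], k: int
) -> PositionalComposition:
    """Positional composition from a word -> count map of k-mers."""
    bases = list("ACGT")
    mat = np.zeros((k, 4), dtype=float)
    n_sites = 0
    for word, c in counts.items():
        n_sites += c
        for i, b in enumerate(word):
            mat[i, bases.index(b)] += c
    if n_sites > 0:
        mat = 100.0 * mat / n_sites
    df = pd.DataFrame(mat, index=pd.RangeIndex(1, k + 1, name="position"),
                      columns=bases)
    return PositionalComposition(matrix=df, n_sites=n_sites)


def composition_frame(comp: PositionalComposition) -> pd.DataFrame:
    """TSV-ready frame: position, A, C, G, T."""
    return comp.matrix.reset_index()


def frequency_frame(table: FrequencyTable) -> pd.DataFrame:
    return table.to_frame()


def shift_admissible(word: str, shift: int, pattern: DegeneratePattern) -> bool:
    """Can a frame shifted by ``shift`` (+right/-left) against a matched word
    also match, for some choice of flanking bases?

    Only the word's own bases constrain the shifted frame: every shifted
    pattern position that lands inside the word must accept the word's base
    there.  Positions hanging over the flanks are free.
    """
    k = pattern.length
    sets = pattern.position_sets
    for j in range(k):  # position j of the shifted frame
        i = j + shift  # corresponding index in the original word
        if 0 <= i < k and word[i] not in sets[j]:
            return False
    return True


def rc_matches(word: str, pattern: DegeneratePattern) -> bool:
    """Does the reverse complement of a word itself match the pattern?"""
    return pattern.matches(reverse_complement(word))
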