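"""Known POU-element motif classes and consensus scanning.

The catalog covers the motif classes characterized for POU-domain factor
complexes with and without the BOB1 coactivator:

* octamer ``ATGCAAAT`` — the canonical monomeric site; BOB1-permissive.
* MORE family — dimeric element ``ATG[C/A]AT [A/T]x0-2 AT[T/G]CAT`` split
  into three fixed-gap variants (MORE, MORE+1, MORE+2); the MORE dimer
  configuration is refractory to BOB1.
* PORE ``ATTTGAAATGCAAAT`` — palindromic dimeric element (two inverted
  octamers overlapping by one base); BOB1-permissive.
"""

from __future__ import annotations

import dataclasses
import itertools
import re
from typing import Literal

import pandas as pd

from .pattern_census import IUPAC, reverse_complement
from .seqio import ReadSet

StrandMode = Literal["forward", "both"]


@dataclasses.dataclass(frozen=True)
class MotifDefinition:
    """A consensus motif: left half-site, optional internal gap, right half-site.

    Monomeric motifs have an empty ``right`` and a zero gap.  The gap of the
    MORE family admits only A/T, the hallmark two-AT spacing of that element.
    """

    name: str
    left: str  # IUPAC
    gap_range: tuple[int, int] = (0, 0)
    gap_alphabet: frozenset = frozenset("AT")
    right: str = ""  # IUPAC
    complex_class: Literal["monomer", "dimer"] = "monomer"
    clamp_permissive: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.gap_range
        if lo < 0 or hi < lo:
            raise ValueError(f"bad gap_range {self.gap_range}")
        if self.complex_class == "monomer" and (self.right or hi > 0):
            raise ValueError("monomer motifs have no right half-site or gap")
        for c in self.left + self.right:
            if c not in IUPAC:
                raise ValueError(f"invalid IUPAC character {c!r}")

    @property
    def min_span(self) -> int:
        return len(self.left) + self.gap_range[0] + len(self.right)

    @property
    def max_span(self) -> int:
        return len(self.left) + self.gap_range[1] + len(self.right)

    def regex(self) -> re.Pattern:
        def cls(iupac: str) -> str:
            return "".join(
                f"[{IUPAC[c]}]" if len(IUPAC[c]) > 1 else IUPAC[c] for c in iupac
            )

        lo, hi = self.gap_range
        gap = ""
        if hi > 0:
            gap = f"[{''.join(sorted(self.gap_alphabet))}]{{{lo},{hi}}}"
        return re.compile(cls(self.left) + gap + cls(self.right))

    def realizations(self) -> list[str]:
        """Every concrete DNA string matching the consensus (oracle helper)."""
        def expand(iupac: str) -> list[str]:
            return ["".join(p) for p in itertools.product(*(IUPAC[c] for c in iupac))]

        lefts, rights = expand(self.left), expand(self.right or "")
        out = []
        for g in range(self.gap_range[0], self.gap_range[1] + 1):
            gaps = ["".join(p) for p in
                    itertools.product(*([sorted(self.gap_alphabet)] * g))] or [""]
            out.extend(l + m + r for l in lefts for m in gaps for r in rights)
        return out


def default_catalog() -> list[MotifDefinition]:
    """The five motif classes scanned by default."""
    more_kwargs = dict(
        left="ATGMAT",  # ATG[C/A]AT
        right="ATKCAT",  # AT[T/G]CAT
        gap_alphabet=frozenset("AT"),
        complex_class="dimer",
        clamp_permissive=False,
    )
    return [
        MotifDefinition(name="octamer", left="ATGCAAAT",
                        complex_class="monomer", clamp_permissive=True),
        MotifDefinition(name="MORE", gap_range=(0, 0), **more_kwargs),
        MotifDefinition(name="MORE+1", gap_range=(1, 1), **more_kwargs),
        MotifDefinition(name="MORE+2", gap_range=(2, 2), **more_kwargs),
        MotifDefinition(name="PORE", left="ATTTGAAATGCAAAT",
                        complex_class="dimer", clamp_permissive=True),
    ]


def motif_by_name(name: str, catalog: list[MotifDefinition] | None = None) -> MotifDefinition:
    for m in catalog or default_catalog():
        if m.name == name:
            return m
    raise KeyError(name)


@dataclasses.dataclass
class MotifReport:
    """Scan result for one motif over one read set."""

    motif: str
    set_label: str
    matched_reads: int
    total_reads: int
    examples: list[str]  # up to a few matched substrings

    @property
    def frequency(self) -> float:
        """Percent of reads containing at least one match."""
        if self.total_reads == 0:
            return 0.0
        return 100.0 * self.matched_reads / self.total_reads


def read_matches_motif(
    insert: str,
    motif: MotifDefinition,
    strand_mode: StrandMode = "both",
    max_mismatches: int = 0,
) -> str | None:
    """First motif match on the insert (forward strand first), or None.

    ``max_mismatches`` relaxes the consensus by a per-window substitution
    budget (0 = exact consensus, the default; mainly for the fixed-length
    PORE).  Returns the matched substring.
    """
    if max_mismatches == 0:
        rx = motif.regex()
        m = rx.search(insert)
        if m is None and strand_mode == "both":
            m = rx.search(reverse_complement(insert))
        return m.group(0) if m else None
    strands = [insert]
    if strand_mode == "both":
        strands.append(reverse_complement(insert))
    realizations = motif.realizations()
    for seq in strands:
        for r in realizations:
            k = len(r)
            for off in range(len(seq) - k + 1):
                window = seq[off : off + k]
                if sum(a != b for a, b in zip(window, r)) <= max_mismatches:
                    return window
    return None


def scan_motif(
    readset: ReadSet,
    motif: MotifDefinition,
    strand_mode: StrandMode = "both",
    max_mismatches: int = 0,
    max_examples: int = 5,
) -> MotifReport:
    """Fraction of reads (%) containing >= 1 consensus match."""
    matched = 0
    examples: list[str] = []
    for insert in readset.inserts:
        m = read_matches_motif(insert, motif, strand_mode, max_mismatches)
        if m is not None:
            matched += 1
            if len(examples) < max_examples:
                examples.append(m)
    return MotifReport(
        motif=motif.name,
        set_label=readset.condition,
        matched_reads=matched,
        total_reads=len(readset.inserts),
        examples=examples,
    )


def motif_frequency_matrix(
    readsets: list[ReadSet],
    catalog: list[MotifDefinition] | None = None,
    strand_mode: StrandMode = "both",
) -> pd.DataFrame:
    """Motif x read-set table of frequencies (%), catalog order preserved."""
    catalog = catalog or default_catalog()
    data = {
        rs.condition: [scan_motif(rs, m, strand_mode).frequency for m in catalog]
        for rs in readsets
    }
    return pd.DataFrame(data, index=pd.Index([m.name for m in catalog], name="motif"))
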