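"""Condition comparisons: frequency differences, fold changes, composition
deltas, and correlation of sequence frequencies with gel-band intensities.

All comparisons are descriptive, mirroring how band-specific SELEX sets are
contrasted: the top-ranked census words of two conditions are aligned over
the union of both top lists (so words collapsing to zero in one condition —
the most informative cases — are retained), and per-word differences and
fold changes are reported.  Fold *reduction* is reported both as the raw
ratio a/b and as direction plus magnitude max/min, matching the usual
"n-fold reduction" phrasing.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pattern_census import FrequencyTable, PositionalComposition, top_n


class InsufficientDataError(ValueError):
    """Fewer paired observations than a correlation requires."""


@dataclasses.dataclass
class FoldChange:
    ratio: float  # a / b; meaningless when not defined
    defined: bool  # False iff denominator frequency is 0

    @property
    def direction(self) -> str:
        if not self.defined or self.ratio == 1.0:
            return "unchanged" if self.defined else "undefined"
        return "up" if self.ratio > 1.0 else "down"

    @property
    def magnitude(self) -> float:
        """Fold magnitude >= 1 (a 0.25 ratio is a 4-fold reduction)."""
        if not self.defined or self.ratio == 0.0:
            return math.inf if self.defined else math.nan
        return max(self.ratio, 1.0 / self.ratio)


def fold_change(a: FrequencyTable, b: FrequencyTable, word: str) -> FoldChange:
    """Relative-frequency ratio of one word between two census tables."""
    if not a.pattern.matches(word):
        raise ValueError(f"{word!r} does not match pattern {a.pattern.word}")
    fa, fb = a.rel_freq_of(word), b.rel_freq_of(word)
    if fb == 0.0:
        return FoldChange(ratio=math.inf if fa > 0 else math.nan, defined=False)
    return FoldChange(ratio=fa / fb, defined=True)


@dataclasses.dataclass
class ComparisonResult:
    """Per-word contrast of two frequency tables over their top-N union."""

    label_a: str
    label_b: str
    table: pd.DataFrame  # word, freq_a, freq_b, diff_points, fold, fold_defined,
    #                      fold_direction, fold_magnitude; by descending |diff|


def compare_tables(
    a: FrequencyTable, b: FrequencyTable, n: int = 100
) -> ComparisonResult:
    """Align the union of both tables' top-n words; difference (percentage
    points, a - b) and fold change (a / b) per word, ordered by |difference|."""
    if a.pattern.word != b.pattern.word:
        raise ValueError(
            f"pattern mismatch: {a.pattern.word} vs {b.pattern.word}"
        )
    words = sorted(
        {w for w, _ in top_n(a, n).entries} | {w for w, _ in top_n(b, n).entries}
    )
    rows = []
    for w in words:
        fa, fb = a.rel_freq_of(w), b.rel_freq_of(w)
        fc = fold_change(a, b, w)
        rows.append(
            {
                "word": w,
                "freq_a": fa,
                "freq_b": fb,
                "diff_points": fa - fb,
                "fold": fc.ratio,
                "fold_defined": fc.defined,
                "fold_direction": fc.direction,
                "fold_magnitude": fc.magnitude,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "word", "freq_a", "freq_b", "diff_points", "fold",
            "fold_defined", "fold_direction", "fold_magnitude",
        ],
    )
    if len(df):
        df = df.reindex(
            df["diff_points"].abs().sort_values(ascending=False, kind="stable").index
        ).reset_index(drop=True)
    return ComparisonResult(label_a=a.set_label, label_b=b.set_label, table=df)


def composition_delta(
    a: PositionalComposition, b: PositionalComposition
) -> pd.DataFrame:
    """Elementwise percentage-point difference a - b (k x 4); row sums are 0."""
    if a.matrix.shape != b.matrix.shape:
        raise ValueError(
            f"shape mismatch {a.matrix.shape} vs {b.matrix.shape}"
        )
    return a.matrix - b.matrix


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN when either vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise InsufficientDataError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    return float(stats.pearsonr(x, y).statistic)


@dataclasses.dataclass
class IntensityTable:
    """Densitometry signals: one row per (sequence label, condition)."""

    frame: pd.DataFrame  # columns: sequence, condition, signal

    def __post_init__(self) -> None:
        required = {"sequence", "condition", "signal"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"missing column(s) {sorted(missing)}")
        if (self.frame["signal"] < 0).any():
            raise ValueError("signals must be >= 0")
        if self.frame.duplicated(["sequence", "condition"]).any():
            raise ValueError("(sequence, condition) pairs must be unique")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IntensityTable":
        return cls(pd.read_csv(path, sep="\t"))

    def for_condition(self, condition: str) -> pd.DataFrame:
        return self.frame[self.frame["condition"] == condition]


@dataclasses.dataclass
class CorrelationResult:
    r: float
    n: int
    pairs: pd.DataFrame  # sequence, rel_freq_percent, signal


def correlate_frequencies_with_intensities(
    table: FrequencyTable, intensities: IntensityTable, condition: str
) -> CorrelationResult:
    """Pearson r between census relative frequencies and band intensities,
    paired by sequence label; the paired rows are returned for audit."""
    sub = intensities.for_condition(condition)
    rows = [
        {
            "sequence": seq,
            "rel_freq_percent": table.rel_freq_of(seq),
            "signal": float(sig),
        }
        for seq, sig in zip(sub["sequence"], sub["signal"])
        if table.pattern.matches(seq)
    ]
    if len(rows) < 3:
        raise InsufficientDataError(
            f"only {len(rows)} sequence(s) shared between census and "
            f"intensities for condition {condition!r}; need >= 3"
        )
    pairs = pd.DataFrame(rows, columns=["sequence", "rel_freq_percent", "signal"])
    r = pearson(pairs["rel_freq_percent"], pairs["signal"])
    return CorrelationResult(r=r, n=len(pairs), pairs=pairs)
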