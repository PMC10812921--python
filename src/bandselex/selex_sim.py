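"""Seeded simulator of band-specific EMSA-SELEX selection.

A random 35-mer library is carried through rounds of bind -> gel-band
excision -> PCR amplification.  Binding is modeled with three "channels"
per molecule, one per electrophoretic band class:

* **monomer** — best octamer-like site under a position-specific affinity
  matrix (PSAM): the affinity of a window is the product of per-position
  relative affinities, with the consensus ATGCAAAT scoring 1.
* **dimer** — presence of a MORE-family or PORE dimeric element, each with
  a configured relative affinity.
* **ternary** — the coactivator-clamp channel, available only when BOB1 is
  present: the clamp multiplies the monomeric site affinity by a gain
  factor but imposes its own sequence requirements (A strictly required at
  octamer position 5; T disfavored at positions 3 and 4).  PORE dimers
  admit the clamp; MORE dimers are refractory (ternary weight 0).

Each molecule runs at one mobility per round: it is assigned to a single
band with probability proportional to its channel weights, and a molecule
assigned to the excised band is retained with the occupancy probability
a / (a + s), where s is the selection stringency.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import seqio
from .motif_catalog import MotifDefinition, default_catalog
from .pattern_census import reverse_complement
from .seqio import Read, ReadSet

BASES = "ACGT"
BANDS = ("monomer", "dimer", "ternary")
OCTAMER_CONSENSUS = "ATGCAAAT"

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i


class SimulationCollapseError(RuntimeError):
    """A selection round retained zero molecules."""


def encode_inserts(inserts: Sequence[str], length: int) -> np.ndarray:
    """(N, length) int8 codes, A=0 C=1 G=2 T=3."""
    if len(inserts) == 0:
        return np.empty((0, length), dtype=np.int8)
    raw = np.frombuffer("".join(inserts).encode(), dtype=np.uint8)
    return _ENCODE[raw].reshape(len(inserts), length)


def decode_inserts(codes: np.ndarray) -> list[str]:
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    flat = lut[codes].tobytes().decode()
    L = codes.shape[1]
    return [flat[i : i + L] for i in range(0, len(flat), L)]


@dataclasses.dataclass
class Psam:
    """Position-specific affinity matrix for the 8-bp octamer-like site.

    ``matrix[p, b]`` is the relative affinity contribution of base b at
    position p+1; the best base at every position scores 1, so the
    reference (consensus) word has affinity product exactly 1.
    """

    matrix: np.ndarray  # (8, 4) floats in (0, 1]
    reference: str = OCTAMER_CONSENSUS

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.reference), 4):
            raise ValueError("PSAM shape must be (site length, 4)")
        if not np.allclose(self.matrix.max(axis=1), 1.0):
            raise ValueError("each PSAM position must have max entry 1")
        if (self.matrix < 0).any():
            raise ValueError("PSAM entries must be non-negative")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


def default_psam() -> Psam:
    """Octamer PSAM with conserved A1/A6/A7 and variable positions 2-5, 8.

    Entries encode qualitative preference tiers calibrated against the
    statistics a POU-only selection is known to produce (a broad census in
    which the consensus holds only a few percent of matched words, the top
    100 of the 1024 pattern words roughly half the mass, and ~80% A at
    octamer position 5): ~0.08 for the highly conserved positions 1, 6, 7;
    0.7 for the well-tolerated T substitutions at positions 3 and 4 (the
    clamp, not the POU domain, is what penalizes them); 0.5 for T5 and the
    fairly variable alternatives at positions 2, 3, 4 and 8.
    """
    rows = {
        1: dict(A=1.00, C=0.08, G=0.08, T=0.08),
        2: dict(A=0.50, C=0.50, G=0.50, T=1.00),
        3: dict(A=0.50, C=0.50, G=1.00, T=0.70),
        4: dict(A=0.50, C=1.00, G=0.50, T=0.70),
        5: dict(A=1.00, C=0.12, G=0.12, T=0.50),
        6: dict(A=1.00, C=0.08, G=0.08, T=0.20),
        7: dict(A=1.00, C=0.08, G=0.08, T=0.12),
        8: dict(A=0.50, C=0.50, G=0.50, T=1.00),
    }
    mat = np.array([[rows[p][b] for b in BASES] for p in range(1, 9)])
    return Psam(matrix=mat)


def flat_psam(length: int = 8) -> Psam:
    """Neutral PSAM: every base scores 1 everywhere (no selection signal)."""
    return Psam(matrix=np.ones((length, 4)), reference="A" * length)


@dataclasses.dataclass
class ClampRule:
    """Sequence requirements the BOB1 clamp adds on top of the POU site.

    ``multipliers`` maps (octamer position 1-8, base) to a weight factor
    applied to the site affinity in the ternary channel: 0 forbids
    (default: T at position 5), values in (0,1) disfavor (default: T at
    positions 3 and 4).  ``clamp_gain`` is the stabilization factor the
    clamp confers on a fully permissive site.
    """

    clamp_gain: float = 5.0
    multipliers: dict[tuple[int, str], float] = dataclasses.field(
        default_factory=lambda: {(5, "T"): 0.0, (3, "T"): 0.25, (4, "T"): 0.25}
    )

    def __post_init__(self) -> None:
        if self.clamp_gain <= 1:
            raise ValueError("clamp_gain must be > 1")
        if any(v < 0 for v in self.multipliers.values()):
            raise ValueError("clamp multipliers must be non-negative")

    def matrix(self, length: int = 8) -> np.ndarray:
        mat = np.ones((length, 4))
        for (pos, base), mult in self.multipliers.items():
            mat[pos - 1, BASES.index(base)] = mult
        return mat

    def word_multiplier(self, word: str) -> float:
        out = 1.0
        for (pos, base), mult in self.multipliers.items():
            if word[pos - 1] == base:
                out *= mult
        return out


@dataclasses.dataclass
class BindingModel:
    """Ground-truth binding model: PSAM + dimer elements + clamp."""

    psam: Psam = dataclasses.field(default_factory=default_psam)
    clamp: ClampRule = dataclasses.field(default_factory=ClampRule)
    more_affinity: float = 0.8
    pore_affinity: float = 0.4
    catalog: list[MotifDefinition] = dataclasses.field(default_factory=default_catalog)

    def more_motifs(self) -> list[MotifDefinition]:
        return [m for m in self.catalog if m.name.startswith("MORE")]

    def pore_motif(self) -> MotifDefinition | None:
        for m in self.catalog:
            if m.name == "PORE":
                return m
        return None


@dataclasses.dataclass(frozen=True)
class Condition:
    """One selection arm: which POU factor, BOB1 presence, excised band."""

    factor: Literal["POU1", "POU2"] = "POU1"
    bob1: bool = False
    band: Literal["monomer", "dimer", "ternary"] | None = None

    @property
    def effective_band(self) -> str:
        # by default the POU-only arm excises the monomer band and the
        # +BOB1 arm the ternary (supershift) band, as in the gel protocol
        if self.band is not None:
            return self.band
        return "ternary" if self.bob1 else "monomer"

    @property
    def label(self) -> str:
        return self.factor + ("+BOB1" if self.bob1 else "")


DEFAULT_CONDITIONS = (
    Condition("POU1", bob1=False),
    Condition("POU1", bob1=True),
    Condition("POU2", bob1=False),
    Condition("POU2", bob1=True),
)


@dataclasses.dataclass
class SimulationConfig:
    library_size: int = 20_000
    insert_length: int = 35
    rounds: int = 4
    conditions: tuple[Condition, ...] = DEFAULT_CONDITIONS
    selection_stringency: float = 1.0
    pcr_copy_target: int | None = None  # None -> library_size
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")
        if self.library_size < 1:
            raise ValueError("library_size must be >= 1")
        if self.insert_length < 8:
            raise ValueError("insert_length must fit an octamer site")

    @property
    def copy_target(self) -> int:
        return self.pcr_copy_target or self.library_size


# ---------------------------------------------------------------------------
# affinity machinery

def site_affinity(word: str, psam: Psam) -> float:
    """Product-of-positions affinity of one site; consensus scores 1."""
    codes = encode_inserts([word], psam.length)[0]
    if (codes < 0).any():
        raise ValueError(f"non-ACGT base in {word!r}")
    return float(np.prod(psam.matrix[np.arange(psam.length), codes]))


def _best_window_scores(codes: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """Per-molecule max product score over all windows on both strands.

    ``codes`` is (N, L); ``weight`` a (k, 4) multiplicative matrix.
    """
    k = weight.shape[0]
    best = np.zeros(codes.shape[0])
    for strand_codes in (codes, (3 - codes)[:, ::-1]):
        win = sliding_window_view(strand_codes, k, axis=1)  # (N, W, k)
        scores = weight[np.arange(k), win].prod(axis=2)
        best = np.maximum(best, scores.max(axis=1))
    return best


def _motif_hits(inserts: Sequence[str], motifs: list[MotifDefinition]) -> np.ndarray:
    """Boolean per insert: any of the motifs matches on either strand."""
    if not motifs:
        return np.zeros(len(inserts), dtype=bool)
    regexes = [m.regex() for m in motifs]
    hits = np.zeros(len(inserts), dtype=bool)
    for i, ins in enumerate(inserts):
        rc = None
        for rx in regexes:
            if rx.search(ins):
                hits[i] = True
                break
            if rc is None:
                rc = reverse_complement(ins)
            if rx.search(rc):
                hits[i] = True
                break
    return hits


def _clamped_max_outside_more(
    insert: str, weight: np.ndarray, more_motifs: list[MotifDefinition]
) -> float:
    """Best clamped window score over windows not overlapping a MORE span.

    A MORE-bound dimer is refractory to the clamp, so octamer-like windows
    inside a MORE footprint cannot seed a ternary complex.
    """
    k = weight.shape[0]
    regexes = [m.regex() for m in more_motifs]
    best = 0.0
    for seq in (insert, reverse_complement(insert)):
        spans = []
        for rx in regexes:
            for m in rx.finditer(seq):
                spans.append((m.start(), m.end()))
        for off in range(len(seq) - k + 1):
            if any(off < e and off + k > s for s, e in spans):
                continue
            codes = encode_inserts([seq[off : off + k]], k)[0]
            best = max(best, float(np.prod(weight[np.arange(k), codes])))
    return best


def channel_weights(
    inserts: Sequence[str], model: BindingModel, bob1: bool, insert_length: int
) -> np.ndarray:
    """(N, 3) array of [monomer, dimer, ternary] channel weights."""
    codes = encode_inserts(inserts, insert_length)
    mono = _best_window_scores(codes, model.psam.matrix)
    clamp_weight = model.psam.matrix * model.clamp.matrix(model.psam.length)
    clamped = _best_window_scores(codes, clamp_weight)
    more_hit = _motif_hits(inserts, model.more_motifs())
    pore = model.pore_motif()
    pore_hit = _motif_hits(inserts, [pore] if pore else [])
    dimer = np.maximum(
        more_hit * model.more_affinity, pore_hit * model.pore_affinity
    )
    if bob1:
        # clamp sites inside a refractory MORE footprint are unavailable
        for i in np.flatnonzero(more_hit):
            clamped[i] = _clamped_max_outside_more(
                inserts[i], clamp_weight, model.more_motifs()
            )
        ternary = model.clamp.clamp_gain * np.maximum(
            clamped, pore_hit * model.pore_affinity
        )
    else:
        ternary = np.zeros_like(mono)
    return np.column_stack([mono, dimer, ternary])


def read_affinity(
    insert: str, model: BindingModel, condition: Condition
) -> tuple[float, str, str]:
    """(best channel affinity, best complex class, best site sequence).

    The best site is the highest-scoring octamer window (in its strand
    orientation as scored) for monomer/ternary, or the matched dimer
    element for the dimer channel.
    """
    ch = channel_weights([insert], model, condition.bob1, len(insert))[0]
    best_idx = int(np.argmax(ch))
    best_class = BANDS[best_idx]
    k = model.psam.length
    weight = model.psam.matrix
    if best_class == "ternary":
        weight = weight * model.clamp.matrix(k)
    best_site, best_score = "", -1.0
    for seq in (insert, reverse_complement(insert)):
        for off in range(len(seq) - k + 1):
            w = seq[off : off + k]
            s = float(
                np.prod(weight[np.arange(k), encode_inserts([w], k)[0]])
            )
            if s > best_score:
                best_score, best_site = s, w
    if best_class == "dimer":
        from .motif_catalog import read_matches_motif

        for m in model.catalog:
            if m.complex_class == "dimer":
                hit = read_matches_motif(insert, m)
                if hit:
                    best_site = hit
                    break
    return float(ch[best_idx]), best_class, best_site


# ---------------------------------------------------------------------------
# selection rounds

@dataclasses.dataclass
class RoundLog:
    condition: str
    round: int
    n_input: int
    n_selected: int

    @property
    def selected_fraction(self) -> float:
        return self.n_selected / self.n_input if self.n_input else 0.0


@dataclasses.dataclass
class GroundTruth:
    """Everything needed to audit the simulation against its model."""

    model: BindingModel
    round_logs: list[RoundLog] = dataclasses.field(default_factory=list)
    final_classes: dict[str, list[str]] = dataclasses.field(default_factory=dict)

    def word_affinity(self, word: str, duplex: bool = True) -> float:
        """True relative affinity of the molecule carrying ``word``.

        The selected molecule is double-stranded: a census word read off one
        strand presents its reverse complement on the other, so the duplex
        affinity is the max over both orientations (``duplex=False`` gives
        the single-orientation value).
        """
        a = site_affinity(word, self.model.psam)
        if duplex:
            a = max(a, site_affinity(reverse_complement(word), self.model.psam))
        return a


def select_round(
    library: Sequence[str],
    model: BindingModel,
    condition: Condition,
    band: str,
    stringency: float,
    rng: np.random.Generator,
) -> list[str]:
    """One bind/excise step.

    Each molecule partitions to exactly one band per round, sampled
    proportionally to its channel weights (a molecule runs at a single gel
    mobility).  A molecule assigned to the excised band is then retained
    with the occupancy probability a / (a + stringency), where a is the
    molecule's *site* affinity for that band's complex — for the ternary
    band this is the clamp-modulated site affinity without the clamp gain.
    The gain expresses the stability advantage of the clamped complex and
    so governs which band a permissive molecule runs in, but occupancy
    competition among clamp-permissive molecules is still set by their
    POU-site affinities; folding the gain into the retention term would
    saturate a/(a+s) and erase that competition.
    """
    if len(library) == 0:
        raise ValueError("empty library")
    band_idx = BANDS.index(band)
    unique, inverse = np.unique(np.asarray(library), return_inverse=True)
    ch_u = channel_weights(list(unique), model, condition.bob1, len(library[0]))
    ch = ch_u[inverse]  # (N, 3)
    retention = ch.copy()
    retention[:, BANDS.index("ternary")] /= model.clamp.clamp_gain
    total = ch.sum(axis=1)
    n = len(library)
    u_band = rng.random(n)
    u_keep = rng.random(n)
    keep = np.zeros(n, dtype=bool)
    alive = total > 0
    if alive.any():
        probs = ch[alive] / total[alive, None]
        assigned = (u_band[alive, None] > probs.cumsum(axis=1)).sum(axis=1)
        a = retention[alive, :][np.arange(alive.sum()), assigned]
        keep_alive = (assigned == band_idx) & (u_keep[alive] < a / (a + stringency))
        keep[np.flatnonzero(alive)] = keep_alive
    selected = [library[i] for i in np.flatnonzero(keep)]
    if not selected:
        raise SimulationCollapseError(
            f"round retained zero molecules (condition {condition.label}, "
            f"band {band}, stringency {stringency})"
        )
    return selected


def amplify(
    selected: Sequence[str], target_size: int, rng: np.random.Generator
) -> list[str]:
    """Error-free PCR resampling with replacement to target_size copies."""
    if len(selected) == 0:
        raise ValueError("cannot amplify an empty pool")
    idx = rng.integers(0, len(selected), size=target_size)
    return [selected[i] for i in idx]


def random_library(
    size: int, insert_length: int, rng: np.random.Generator
) -> list[str]:
    """Uniform random inserts over the 4-letter alphabet."""
    codes = rng.integers(0, 4, size=(size, insert_length), dtype=np.int8)
    return decode_inserts(codes)


def best_site_words(
    inserts: Sequence[str],
    model: BindingModel,
    condition: Condition,
) -> list[str]:
    """Per-read highest-scoring octamer window, in its scored orientation.

    Uses the clamp-modulated matrix for +BOB1 conditions, so this is the
    site-aligned readout a motif logo of the excised band would show
    (contrast with the census, which reports the first pattern-matching
    window whether or not it is the bound site).
    """
    if len(inserts) == 0:
        return []
    weight = model.psam.matrix
    if condition.bob1:
        weight = weight * model.clamp.matrix(model.psam.length)
    k = model.psam.length
    codes = encode_inserts(inserts, len(inserts[0]))
    best_words: list[str] = []
    strands = [codes, (3 - codes)[:, ::-1]]
    scores = []
    for sc in strands:
        win = sliding_window_view(sc, k, axis=1)
        scores.append(weight[np.arange(k), win].prod(axis=2))
    stacked = np.concatenate(scores, axis=1)  # (N, 2W)
    W = scores[0].shape[1]
    arg = stacked.argmax(axis=1)
    for i, a in enumerate(arg):
        strand, off = divmod(int(a), W)
        row = strands[strand][i, off : off + k]
        best_words.append("".join(BASES[b] for b in row))
    return best_words


def best_site_composition(
    readset: ReadSet, model: BindingModel, condition: Condition
):
    """Positional base composition (%) over per-read best binding sites."""
    from .pattern_census import composition_from_counts

    words = best_site_words(readset.inserts, model, condition)
    counts: dict[str, int] = {}
    for w in words:
        counts[w] = counts.get(w, 0) + 1
    return composition_from_counts(counts, model.psam.length)


def _classify_reads(
    inserts: Sequence[str],
    model: BindingModel,
    condition: Condition,
    insert_length: int,
) -> list[str]:
    """Per-read argmax complex class, computed on unique sequences."""
    if len(inserts) == 0:
        return []
    unique, inverse = np.unique(np.asarray(inserts), return_inverse=True)
    ch = channel_weights(list(unique), model, condition.bob1, insert_length)
    best = ch.argmax(axis=1)[inverse]
    return [BANDS[i] for i in best]


@dataclasses.dataclass
class ConditionResult:
    condition: Condition
    rounds: list[ReadSet]  # rounds[0] = initial library, rounds[r] = after round r

    @property
    def final(self) -> ReadSet:
        return self.rounds[-1]


@dataclasses.dataclass
class SelexResult:
    config: SimulationConfig
    model: BindingModel
    per_condition: dict[str, ConditionResult]
    ground_truth: GroundTruth

    def final_set(self, label: str) -> ReadSet:
        return self.per_condition[label].final


def run_selex(
    config: SimulationConfig, model: BindingModel | None = None
) -> SelexResult:
    """Run the full multi-round, multi-condition selection.

    All randomness derives from ``config.seed`` via a seed-sequence fan-out:
    child 0 draws the shared initial library (one synthesis serves every
    arm, as on the bench) and child i+1 drives condition i's selection and
    amplification stream.  Identical configs give byte-identical outputs.
    """
    model = model or BindingModel()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(1 + len(config.conditions))
    lib_rng = np.random.Generator(np.random.PCG64(children[0]))
    initial = random_library(config.library_size, config.insert_length, lib_rng)
    truth = GroundTruth(model=model)
    per_condition: dict[str, ConditionResult] = {}
    for ci, cond in enumerate(config.conditions):
        rng = np.random.Generator(np.random.PCG64(children[1 + ci]))
        band = cond.effective_band
        sets = [
            ReadSet(
                condition=f"{cond.label}|{band}|round0",
                inserts=list(initial),
                insert_length=config.insert_length,
            )
        ]
        lib = initial
        for r in range(1, config.rounds + 1):
            selected = select_round(
                lib, model, cond, band, config.selection_stringency, rng
            )
            truth.round_logs.append(
                RoundLog(cond.label, r, len(lib), len(selected))
            )
            lib = amplify(selected, config.copy_target, rng)
            sets.append(
                ReadSet(
                    condition=f"{cond.label}|{band}|round{r}",
                    inserts=lib,
                    insert_length=config.insert_length,
                )
            )
        truth.final_classes[cond.label] = _classify_reads(
            sets[-1].inserts, model, cond, config.insert_length
        )
        per_condition[cond.label] = ConditionResult(condition=cond, rounds=sets)
    return SelexResult(
        config=config, model=model, per_condition=per_condition, ground_truth=truth
    )


def emit_raw_reads(
    readset: ReadSet,
    path: str | Path,
    flank5: str = seqio.FLANK5,
    flank3: str = seqio.FLANK3,
) -> None:
    """Wrap inserts with the constant flanks and write 72-nt FASTQ reads."""
    reads = [
        Read(
            id=f"{readset.condition.replace('|', '_')}_{i}",
            sequence=flank5 + ins + flank3,
            quality=[40] * (len(flank5) + len(ins) + len(flank3)),
        )
        for i, ins in enumerate(readset.inserts)
    ]
    seqio.write_sequences(reads, path, "fastq")
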