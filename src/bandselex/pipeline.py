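"""Pipeline orchestration: simulate -> trim -> census -> motifs -> compare
-> correlate, with a config file, a run log, and a hashed artifact manifest.

One seed in the config fans out to every stochastic stage through a numpy
seed-sequence derivation (simulation streams are spawned per condition
inside the simulator; the synthetic densitometry noise uses its own spawned
stream), so a rerun with the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import compare_stats, motif_catalog, pattern_census, selex_sim, seqio
from .compare_stats import IntensityTable
from .pattern_census import DegeneratePattern
from .selex_sim import BindingModel, Condition, SimulationConfig
from .seqio import ReadSet, TrimPolicy


@dataclasses.dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    trim: TrimPolicy = dataclasses.field(default_factory=TrimPolicy)
    pattern: DegeneratePattern = dataclasses.field(default_factory=DegeneratePattern)
    count_mode: str = "per_read"
    strand_mode: str = "both"
    top: int = 100
    comparisons: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    intensities_path: Path | None = None
    synthesize_intensities: bool = True

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        self.simulation.seed = self.seed
        if self.intensities_path is not None:
            p = Path(self.intensities_path)
            if not p.exists():
                raise FileNotFoundError(f"intensity table not found: {p}")
            self.intensities_path = p

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = dict(raw.get("simulation", {}))
        conds = tuple(
            Condition(
                factor=c.get("factor", "POU1"),
                bob1=bool(c.get("bob1", False)),
                band=c.get("band"),
            )
            for c in sim_raw.pop("conditions", [])
        ) or selex_sim.DEFAULT_CONDITIONS
        sim = SimulationConfig(conditions=conds, **sim_raw)
        trim = TrimPolicy(**raw.get("trim", {}))
        pattern = DegeneratePattern(
            raw.get("pattern", {}).get("word", pattern_census.DEFAULT_PATTERN_WORD)
        )
        return cls(
            outdir=Path(raw.get("outdir", "bandselex_out")),
            seed=int(raw.get("seed", 0)),
            simulation=sim,
            trim=trim,
            pattern=pattern,
            count_mode=raw.get("pattern", {}).get("count_mode", "per_read"),
            strand_mode=raw.get("pattern", {}).get("strand_mode", "both"),
            top=int(raw.get("pattern", {}).get("top", 100)),
            comparisons=[tuple(p) for p in raw.get("comparisons", [])],
            intensities_path=raw.get("intensities"),
            synthesize_intensities=bool(raw.get("synthesize_intensities", True)),
        )


@dataclasses.dataclass
class Manifest:
    """Artifact paths (relative to outdir) with SHA-256 content hashes."""

    entries: dict[str, str]

    def to_json(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.entries, fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# probe set used for the synthetic gel: the consensus octamer plus two
# informative single mutants (T8->A, permissive; T5, clamp-refractory),
# mirroring how a validation EMSA panel is designed
EMSA_PROBE_PANEL = ("ATGCAAAT", "ATGCAAAA", "ATGCTAAT")


def synthetic_intensities(
    truth: selex_sim.GroundTruth,
    words: Sequence[str],
    conditions: Sequence[Condition],
    rng: np.random.Generator,
    scale: float = 1000.0,
    noise_sd_fraction: float = 0.02,
) -> IntensityTable:
    """Synthetic densitometry stand-in for gel-band quantification.

    Signals are generated from the ground-truth binding model — the
    band-channel weight of each sequence (ternary clamp rules applied for
    +BOB1 arms) times a scale, plus small Gaussian noise — emulating how
    band intensity tracks complex affinity.
    """
    model = truth.model
    rows = []
    for cond in conditions:
        for w in words:
            a = selex_sim.site_affinity(w, model.psam)
            if cond.bob1:
                a *= model.clamp.word_multiplier(w) * model.clamp.clamp_gain
            signal = a * scale + rng.normal(0.0, noise_sd_fraction * scale)
            rows.append(
                {
                    "sequence": w,
                    "condition": cond.label,
                    "signal": max(signal, 0.0),
                }
            )
    return IntensityTable(pd.DataFrame(rows))


def run_pipeline(config: PipelineConfig) -> Manifest:
    """Execute all stages in dependency order and hash every artifact."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "stages": {}}
    artifacts: list[Path] = []

    # -- simulate ----------------------------------------------------------
    result = selex_sim.run_selex(config.simulation)
    raw_paths: dict[str, Path] = {}
    for label, cres in result.per_condition.items():
        safe = label.replace("+", "_")
        p = out / f"raw_{safe}.fastq"
        selex_sim.emit_raw_reads(
            cres.final, p, config.trim.flank5, config.trim.flank3
        )
        raw_paths[label] = p
        artifacts.append(p)
    log["stages"]["simulate"] = {
        "library_size": config.simulation.library_size,
        "rounds": config.simulation.rounds,
        "conditions": list(result.per_condition),
    }

    # -- trim --------------------------------------------------------------
    readsets: dict[str, ReadSet] = {}
    trim_log = {}
    for label, p in raw_paths.items():
        reads = seqio.read_sequences(p, "fastq")
        rs, rejected = seqio.trim_reads(reads, config.trim, condition=label)
        readsets[label] = rs
        trim_log[label] = {
            "input": len(reads), "accepted": len(rs), "rejected": rejected
        }
    log["stages"]["trim"] = trim_log

    # -- census ------------------------------------------------------------
    tables: dict[str, pattern_census.FrequencyTable] = {}
    census_log = {}
    for label, rs in readsets.items():
        table = pattern_census.census(
            rs, config.pattern, config.count_mode, config.strand_mode
        )
        tables[label] = table
        safe = label.replace("+", "_")
        fp = out / f"census_{safe}.tsv"
        seqio.write_table(table.to_frame(), fp)
        artifacts.append(fp)
        comp = pattern_census.positional_composition(
            rs, config.pattern, config.count_mode, config.strand_mode
        )
        cp = out / f"composition_{safe}.tsv"
        seqio.write_table(pattern_census.composition_frame(comp), cp)
        artifacts.append(cp)
        ranking = pattern_census.top_n(table, config.top) if table.counts else None
        census_log[label] = {
            "matched_reads": table.matched_reads,
            "total_reads": table.total_reads,
            "top_cumulative_share": ranking.cumulative_share if ranking else 0.0,
        }
    log["stages"]["census"] = census_log

    # -- motifs ------------------------------------------------------------
    matrix = motif_catalog.motif_frequency_matrix(
        list(readsets.values()), strand_mode=config.strand_mode
    )
    mp = out / "motif_frequencies.tsv"
    seqio.write_table(matrix.reset_index(), mp)
    artifacts.append(mp)

    # -- compare -----------------------------------------------------------
    pairs = config.comparisons or _default_pairs(list(readsets))
    for la, lb in pairs:
        res = compare_stats.compare_tables(tables[la], tables[lb], config.top)
        safe = f"{la}_vs_{lb}".replace("+", "_")
        cp = out / f"compare_{safe}.tsv"
        seqio.write_table(res.table, cp)
        artifacts.append(cp)
    log["stages"]["compare"] = [list(p) for p in pairs]

    # -- correlate ---------------------------------------------------------
    intensities: IntensityTable | None = None
    if config.intensities_path is not None:
        intensities = IntensityTable.from_tsv(config.intensities_path)
    elif config.synthesize_intensities:
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(config.seed).spawn(64)[-1])
        )
        intensities = synthetic_intensities(
            result.ground_truth, EMSA_PROBE_PANEL,
            [c.condition for c in result.per_condition.values()], rng,
        )
    corr_rows = []
    if intensities is not None:
        for label, table in tables.items():
            try:
                corr = compare_stats.correlate_frequencies_with_intensities(
                    table, intensities, label
                )
            except compare_stats.InsufficientDataError:
                continue
            corr_rows.append({"condition": label, "pearson_r": corr.r, "n": corr.n})
    if corr_rows:
        cp = out / "correlations.tsv"
        seqio.write_table(pd.DataFrame(corr_rows), cp)
        artifacts.append(cp)
    log["stages"]["correlate"] = corr_rows

    # -- log + manifest ----------------------------------------------------
    lp = out / "run_log.yaml"
    with open(lp, "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    artifacts.append(lp)
    manifest = Manifest(
        entries={str(p.relative_to(out)): _sha256(p) for p in artifacts}
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def _default_pairs(labels: list[str]) -> list[tuple[str, str]]:
    """+BOB1 arm vs matching POU-only arm, for every factor present."""
    pairs = []
    for label in labels:
        if label.endswith("+BOB1") and label[: -len("+BOB1")] in labels:
            pairs.append((label, label[: -len("+BOB1")]))
    return pairs


def make_fixtures(seed: int = 0, outdir: str | Path = "fixtures") -> dict[str, Path]:
    """Write the small worked-example inputs used by the docs and tests.

    Constructed 72-nt reads with known inserts, a hand-countable census
    input, and a toy intensity table; everything parses under the default
    trim policy with zero rejects.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.Generator(np.random.PCG64(seed))
    paths: dict[str, Path] = {}

    # four inserts: 3 x canonical octamer, 1 x single-mutant octamer
    def pad(core: str) -> str:
        fill = "".join(rng.choice(list("CG"), size=35 - len(core)))
        return core + fill

    inserts = [pad("ATGCAAAT"), pad("ATGCAAAT"), pad("ATGCAAAT"), pad("ATGCTAAT")]
    reads = [
        seqio.Read(id=f"toy_{i}", sequence=seqio.FLANK5 + ins + seqio.FLANK3)
        for i, ins in enumerate(inserts)
    ]
    fp = out / "toy_reads.fasta"
    seqio.write_sequences(reads, fp, "fasta")
    paths["reads"] = fp

    # hand-counted census expectation: 75% / 25%
    expected = pd.DataFrame(
        {
            "word": ["ATGCAAAT", "ATGCTAAT"],
            "count": [3, 1],
            "rel_freq_percent": [75.0, 25.0],
        }
    )
    ep = out / "toy_census_expected.tsv"
    seqio.write_table(expected, ep)
    paths["census_expected"] = ep

    intens = pd.DataFrame(
        {
            "sequence": ["ATGCAAAT", "ATGCTAAT", "ATTTAAAT"] * 2,
            "condition": ["POU1"] * 3 + ["POU1+BOB1"] * 3,
            "signal": [1000.0, 420.0, 180.0, 5000.0, 0.0, 60.0],
        }
    )
    ip = out / "toy_intensities.tsv"
    seqio.write_table(intens, ip)
    paths["intensities"] = ip
    return paths
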