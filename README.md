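# bandselex

Band-specific SELEX-seq simulation and sequence-preference analysis for
POU-domain transcription factors with the BOB1 coactivator.

## The problem

OCT1 and OCT2 (the POU1/POU2 DNA-binding domains) recognize the octamer
element `A1 T2 G3 C4 A5 A6 A7 T8` and a broad halo of variants. The
lymphocyte-specific coactivator BOB1 (OCA-B/OBF1) joins the POU–DNA complex
as a molecular clamp — but only on a subset of sites: it strictly requires
adenine at octamer position 5, disfavors thymines at positions 3 and 4, is
recruited by PORE-type dimers, and is refractory to MORE-type dimers. In a
gel-shift (EMSA) SELEX experiment these complexes run as distinct bands, so
excising one band per selection round recovers the sequence preferences of
one specific complex: the POU monomer, the POU dimer, or the ternary
POU–BOB1 assembly.

This package is for computational biologists who want to analyze such
band-specific selection data — or to study the method itself with a fully
controlled synthetic ground truth. It provides:

- **`selex_sim`** — a seeded simulator of multi-round band-specific
  selection from a random 35-mer library, under a position-specific
  affinity matrix (PSAM) with dimer elements and a coactivator-clamp rule;
- **`seqio`** — FASTA/FASTQ I/O and flank-anchored trimming of raw 72-nt
  reads (18-nt 5′ flank + 35-nt insert + 19-nt 3′ flank) to inserts;
- **`pattern_census`** — degenerate-pattern word census (`ANNNNAAN`,
  1024 concrete words), rankings, and positional base composition;
- **`motif_catalog`** — consensus scanning for the octamer, the MORE
  family `ATG[C/A]AT [A/T]{0–2} AT[T/G]CAT`, and the PORE
  `ATTTGAAATGCAAAT`;
- **`compare_stats`** — pairwise condition comparisons, fold changes,
  composition deltas, and Pearson correlation of census frequencies
  against EMSA band intensities;
- a `bandselex` command-line pipeline tying the stages together with a
  config file, deterministic seeding, and a hashed artifact manifest.

## The model

The affinity of an octamer-like site *w* is a product over positions,
`a(w) = Π_p M[p, w_p]`, with the consensus normalized to `a(ATGCAAAT) = 1`
(a PSAM). Each library molecule carries three channel weights:

- monomer: best `a(w)` over all 28 windows on both strands;
- dimer: MORE/PORE presence × their relative affinities;
- ternary (BOB1 present): `γ · max(a(w)·c(w), a_PORE)`, where `c(w)`
  multiplies clamp rules (`c = 0` for T5; `0.25` for T3 or T4) and the
  clamp gain γ > 1 expresses the stability advantage of the clamped
  complex. Sites inside a MORE footprint are excluded — the MORE dimer
  configuration is refractory to the clamp.

Each round, a molecule runs at a single gel mobility: it is assigned to one
band with probability proportional to its channel weights. A molecule in
the excised band is retained with occupancy probability `a/(a + s)`
(stringency `s`, default 1), where `a` is the *site* affinity of that
band's complex (the clamp gain drives band partitioning, not retention —
see `docs/methods.md`). Retained molecules are PCR-resampled back to
constant pool size, and the cycle repeats (default four rounds).

## Worked example

```python
import bandselex as bx

cfg = bx.SimulationConfig(
    library_size=20_000, rounds=4,
    conditions=(bx.Condition("POU1"), bx.Condition("POU1", bob1=True)),
    seed=1,
)
result = bx.run_selex(cfg)
for label, arm in result.per_condition.items():
    table = bx.census(arm.final)
    ranking = bx.top_n(table, 100)
    print(f"{label}: canonical octamer {table.rel_freq_of('ATGCAAAT'):.1f}% "
          f"of matched words; top-100 share {ranking.cumulative_share:.1f}%")

matrix = bx.motif_frequency_matrix([arm.final for arm in result.per_condition.values()])
print(matrix.round(2))
```

prints

```
POU1: canonical octamer 15.5% of matched words; top-100 share 85.4%
POU1+BOB1: canonical octamer 19.9% of matched words; top-100 share 97.4%
         POU1|monomer|round4  POU1+BOB1|ternary|round4
motif
octamer                19.54                      26.4
MORE                    0.00                       0.0
MORE+1                  0.00                       0.0
MORE+2                  0.00                       0.0
PORE                    0.00                       0.0
```

Reading this: after four monomer-band rounds the canonical octamer is the
top census word (15.5% of all `ANNNNAAN`-matching words); adding the BOB1
clamp and excising the ternary band instead concentrates selection further
onto clamp-permissive sites (19.9% census share, and 26.4% of reads carry
the exact octamer vs 19.5% without BOB1). MORE-family dimer elements are
absent from the ternary band, as the clamp-refractory model dictates.

The same pipeline runs from a shell:

```
bandselex simulate --seed 1 --library-size 20000 --rounds 4 --outdir out/
bandselex trim out/raw_POU1.fastq --out out/inserts_POU1.fasta
bandselex census out/inserts_POU1.fasta --pattern ANNNNAAN --top 100 --out out/census.tsv
bandselex pipeline --config examples/demo.yaml
```

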