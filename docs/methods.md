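# Methods

This note documents the binding model behind the simulator, the analysis
conventions, the parameter choices and their rationale, and what the
synthetic data can and cannot say about real band-specific SELEX-seq
experiments.

## The selection model

### Site affinity

Octamer-like sites are scored with a position-specific affinity matrix
(PSAM): the relative affinity of an 8-mer *w* is the product
`a(w) = Π_p M[p, w_p]`, with the best base at every position scoring 1, so
the consensus `ATGCAAAT` has affinity exactly 1. A molecule's monomer-channel
weight is the maximum `a` over all windows on both strands of its 35-nt
insert — the molecule is double-stranded, so a site is a site regardless of
which strand it was synthesized on.

The default matrix encodes qualitative preference tiers:

| position | consensus | entries (A, C, G, T) | reasoning |
|---|---|---|---|
| 1 | A | 1.00, 0.08, 0.08, 0.08 | highly conserved |
| 2 | T | 0.50, 0.50, 0.50, 1.00 | fairly variable |
| 3 | G | 0.50, 0.50, 1.00, 0.70 | variable; T well tolerated by POU |
| 4 | C | 0.50, 1.00, 0.50, 0.70 | variable; T well tolerated by POU |
| 5 | A | 1.00, 0.12, 0.12, 0.50 | A preferred; T tolerated by POU alone |
| 6 | A | 1.00, 0.08, 0.08, 0.20 | conserved; T weakly tolerated |
| 7 | A | 1.00, 0.08, 0.08, 0.12 | highly conserved |
| 8 | T | 0.50, 0.50, 0.50, 1.00 | fairly variable |

The tiers were fixed once by matching the deterministic selection
equilibrium (below) to the census statistics a POU-only monomer-band
selection is known to produce: a broad distribution in which the canonical
octamer holds only a few percent of matched words, the top 100 of the 1024
pattern words roughly half the total mass, and ~80% adenine at position 5
of the aligned sites. POU1 and POU2 share the matrix; their published
preferences are nearly indistinguishable, and the simulator gives each arm
its own random stream rather than a perturbed matrix.

Because retention (below) is `p = a/(a+s)` and rounds compound, the
equilibrium census share of word *w* after *R* rounds is proportional to
`p(a_w)^R`. This closed form over the 1024 words is what the calibration
used; it needs no simulation and has no sampling noise.

### Channels and bands

Each molecule carries three channel weights, one per gel-band class:

- **monomer** — best PSAM window score, both strands;
- **dimer** — `max(MORE present × a_MORE, PORE present × a_PORE)` with
  defaults `a_MORE = 0.8`, `a_PORE = 0.4`. MORE variants (gaps 0/+1/+2,
  gap alphabet {A,T}) and the PORE are matched as exact IUPAC consensus;
- **ternary** (only when BOB1 is in the arm) —
  `γ · max(best clamped site, PORE present × a_PORE)`, where a clamped
  site's weight is `a(w) · c(w)` with clamp multipliers
  `c(5,T) = 0` (the clamp strictly requires A5), `c(3,T) = c(4,T) = 0.25`
  (T3/T4 are POU-permissive but clamp-unfavorable), and clamp gain
  `γ = 5`. Windows overlapping a MORE footprint are excluded from the
  clamped-site search: a MORE-bound dimer is refractory to the clamp, and
  every MORE realization internally contains an octamer-like window that
  would otherwise leak into the ternary channel.

One molecule runs at one mobility per round: it is assigned to a single
band with probability proportional to its channel weights.

### Retention: why the gain is not in the occupancy term

A molecule assigned to the excised band is retained with the occupancy
probability `p = a/(a + s)` (stringency `s = 1` by default). For the
ternary band, `a` is the clamp-modulated *site* affinity `a(w)·c(w)` —
deliberately without the gain γ. The gain expresses the stability advantage
of the clamped complex and therefore governs which band a clamp-permissive
molecule runs in; but occupancy competition *among* clamp-permissive
molecules is still set by their POU-site affinities. Folding γ into the
occupancy term saturates `a/(a+s)` for every decent site and erases that
competition: in the deterministic equilibrium the consensus share of the
ternary-band census then drops *below* the monomer-band share (17.2% vs
20.0% with γ = 5), inverting the clamp's hallmark effect — the canonical
octamer becomes 1.5–2× more frequent when the coactivator is present.
With the gain confined to band partitioning, that enrichment direction
emerges robustly (10/10 seeds at library 2×10⁴).

### Rounds, amplification, determinism

A run starts from a uniform random library (one synthesis shared by all
arms), then per arm: select → PCR (multinomial resampling with replacement
back to constant pool size, error-free) → next round; four rounds by
default, with per-round read sets and a ground-truth log (model, per-round
retention, per-read complex classes) emitted. All randomness derives from
one seed through a numpy `SeedSequence` fan-out (child 0: the library;
child *i*+1: arm *i*), so identical configs give byte-identical outputs.
A round that retains zero molecules raises a simulation-collapse error
rather than silently resampling.

## Analysis conventions

### Census

The census tabulates the degenerate pattern `ANNNNAAN` (fixed A at the
highly conserved octamer positions 1, 6, 7; 1024 concrete words). Default
counting is one word per read — the first occurrence in scan order
(forward strand 5′→3′, then the reverse complement) — on the view that a
selected 35-mer was enriched by one binding event. Relative frequencies are
percentages of matched words (they sum to 100 over the word universe); the
matched-read fraction is carried separately. Ranking ties break
lexicographically.

Two readout artifacts are inherent to any such census and are quantified
exhaustively in the test suite:

- **Shift ghosts.** A frame shifted against a matched word can itself match
  whenever the word's bases under the shifted frame's fixed-A positions are
  all A: 39.7% of (word, shift) pairs admit this (vs 100% for an
  unconstrained 8-mer). In particular, for any site with A5/A6 the window
  one base 5′ also matches whenever the flanking base is A, and wins the
  first-occurrence scan — so ~25% of a strong word's carriers are read out
  as its left-shift ghost (e.g. `AATGCAAA` for the consensus).
- **Reverse-complement coincidences.** Exactly 16 of the 1024 words (those
  with T at positions 2, 3 and 8) have a reverse complement that also
  matches the pattern; sites on the opposite strand are then reported under
  the coincident word (e.g. `ATTTGAAT` reads out `ATTCAAAT` sites). For
  this reason the ground-truth word affinity used in recovery analyses is
  duplex-aware: `max(a(w), a(rc(w)))`.

Background windows match the pattern with probability 1/64 per window, so a
few percent of matched reads report a chance window rather than the bound
site, independent of selection. Site-aligned statements (the "motif logo"
view) therefore use `best_site_composition`, which reads the argmax window
under the model — under the clamp matrix for +BOB1 arms — rather than the
census word.

### Motifs, comparisons, correlation

Motif-class frequencies are the percentage of reads containing ≥1 consensus
match (both strands; the MORE family is closed under reverse complement, as
an inverted repeat must be). Pairwise condition comparisons align the union
of both arms' top-N census words — union, not intersection, so that words
collapsing to zero in one arm are retained — and report per-word
percentage-point differences and fold changes, with a zero-denominator flag
and fold *reduction* also given as direction plus magnitude `max/min`.
Correlation of census frequencies against densitometry signals is plain
Pearson; the synthetic gel uses a fixed three-probe panel (consensus,
T8→A, T5) whose signals are generated from the ground-truth channel weight
of the probed complex plus 2% Gaussian noise. A blind "top-3 census words"
panel would occasionally include a shift ghost, which is a readout
artifact, not a bindable sequence — no bench validation panel would carry
it.

## Problem sizes and what the tests show

The default suite and the acceptance script run the directional checks at
library 5×10⁴ and the recovery/neutrality/monotonicity checks at 2×10⁴,
four rounds — a deliberate scale-down of the real experiment's ~10¹²
synthesized molecules and 1.4–2.75×10⁵ sequenced reads per arm. Two
consequences of the scale-down matter when interpreting results:

- **Clone quantization.** Round 1 retains only ~5–10% of the library, so
  late-round pools descend from a few hundred clones; individual word
  counts are sums of a few amplified clone sizes, and the census is more
  concentrated than the real data's (top-100 share ~77–97% vs ~50%).
  Word-level rank statistics are correspondingly noisy: the Spearman
  correlation between top-20 census ranks and ground-truth duplex
  affinities is ~0.5 (median over seeds) at 2×10⁴ and ~0.6–0.8 at 10⁵–2×10⁵,
  capped by the shift-ghost words that hold top ranks at any scale. The
  suite's recovery check at ρ > 0.7 fails at this scale and is retained
  as-is rather than weakened.
- **Rare-word extinction.** Words carried by a handful of initial clones
  can vanish entirely; the ATTTAAAT fold reduction is reported as a lower
  bound (denominator floored at one-read resolution) when the word is
  absent from the ternary census.

What passing tests do show: the census, motif scanner and statistics agree
with brute-force oracles; the simulator is deterministic, neutral under a
flat model, and monotone in consensus enrichment; and the clamp phenotype —
octamer enrichment with BOB1, site-level exclusion of T5, census depletion
of T-substituted words, MORE exclusivity to clamp-free arms, ATTTAAAT
reduction, high frequency–intensity correlation — emerges directionally
and robustly across seeds. What they do not show: numeric reproduction of
any real experiment's percentages (the model is a qualitative stand-in,
calibrated only to coarse published statistics), sequencing-error or PCR
bias behavior (neither is modeled), or recovery of PSAM values from data
at desk scale.

## Known limitations

- No sequencing errors, PCR bias/errors, or quality-score modeling; the
  trim step's mismatch tolerance (anchor length 8, ≤1 mismatch) is the only
  error handling.
- The stringency dial is a single scalar per run; bench stringency varies
  by round and arm and is unreported for the real protocol.
- Dimer elements are matched as exact consensus (optional mismatch budget
  for the PORE), not as PWMs; dimer affinities are single scalars.
- The PORE is modeled as clamp-permissive but its ternary weight uses the
  same gain as monomeric sites; PORE-specific clamp geometry is not
  modeled.
- Band assignment is winner-take-one per round; co-occupancy of one
  molecule by multiple complexes within a round is not modeled.
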