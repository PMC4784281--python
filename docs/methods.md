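# Methods

`dropcirc` models and analyses droplet-partitioned circle sequencing: short
single-strand DNA fragments are circularized, amplified by rolling-circle
amplification (RCA) inside millions of picoliter droplets, sheared into
tandem-copy inserts, and sequenced as paired-end reads.  Because every insert
carries several copies of one circle, sequencing and polymerase errors can be
suppressed by intra-read redundancy, and because each droplet caps the yield
of the molecules it contains, amplification is far more uniform than bulk
RCA.  The package implements the full data-processing chain and a generative
simulator that closes the loop at desk scale.

## The processing model

**Merge.** Read 1 and the reverse complement of Read 2 are merged by their
longest sequence overlap whose Hamming mismatch fraction is at most
`max_mismatch_rate` (default 0.05, applied to the overlap only; scanning is
from the longest possible overlap down to `min_overlap`, default 10).
Because the physical insert (500–700 bp) is far longer than the two reads,
the mates never overlap positionally; they overlap *in phase*, modulo the
circle length, and the merged read is again a contiguous tandem copy of the
circle.  Within the overlap, disagreeing bases take the higher-quality call
and quality ties are masked to N.  A consequence of taking the longest
qualifying overlap is that the merged read has length `len(R1)+len(R2)−ov`
and does not always expose every circle offset twice; such reads fail the
next stage and are counted as consensus-stage rejections.  This is the
pipeline's main yield loss (roughly half of all pairs at 80–140 nt
fragments) and is a property of the read geometry, not a defect.

**Period detection.** The merged read is aligned against itself at every lag
`p` from `min_period` (default 20, fragments being 80–140 nt) to half the
read length; the smallest lag whose mismatch fraction over comparable
(non-N) positions is within the threshold is the circle length.  There is no
indel tolerance: a copy with an internal indel fails the lag test and the
read is rejected rather than risk a frame-shifted consensus.

**Consensus.** For each circle offset, all copies observing it are
collected (N observations are missing data).  The call requires *unanimity*:
an offset observed once, or observed with any disagreement, is hard-masked
to N and carries no evidence downstream — masking rather than down-weighting
because a downstream caller must never see a base that any copy disputed.
With two copies and per-base error rate *e*, a wrong base survives only when
both copies are hit by the same wrong base, probability *e²/3*; this is the
quantitative error-suppression core and is verified by the acceptance suite
against the analytic value.  The consensus quality of a kept offset is the
sum of the contributing Phred scores, capped at 60 (a reporting field only).

**Rotation-insensitive mapping.** A consensus sequence (CS) is the circle
read at an arbitrary phase, so every rotation on both strands is a placement
candidate.  The definitional mapper (`map_cs`) aligns each rotation to the
whole reference with edlib (banded edit distance; N matches anything at zero
cost and zero reward) and keeps the placement with the fewest
mismatches+indels.  The production mapper (`map_cs_seeded`) first collects
candidate windows from exact k-mer hits (k = 12) of the doubled unit —
`unit+unit` contains every rotation as a substring — and aligns rotations
only inside those windows; its exact agreement with the exhaustive mapper is
an acceptance property.  The acceptance threshold defaults to
`ceil(0.1 × unmasked length)`.  Minimal-cost ties on different strands, or
with starts at least one period apart, are ambiguous and rejected.  Ties
within one locus are circular-slide degeneracies: when the genome repeats a
fragment's boundary bases (probability 1/4 per base), the circle has several
exact placements whose starts differ by the repeat length and which no read
can distinguish.  They resolve deterministically to the smallest start —
deliberately a property of the locus rather than of the read's phase, so all
reads of one molecule resolve to the same breakpoint interval.  Because only
substitutions are called, indels are effectively twice as expensive as
mismatches: when the winning alignment contains indel columns, the
slide/indel neighborhood is rescanned for a gapless placement of any
rotation whose mismatch count is within the gapped cost plus its indel
columns, and that placement is adopted (unit-cost edit distance otherwise
returns representations that hide adjacent substitutions inside a
delete+insert pair, or shift clustered boundary substitutions into an
indel).  Genuine indel alignments, where every gapless placement is far
worse, are kept.

**Junction identity and variant calling.** The breakpoint of a circle on
the reference is its fragment interval; `(ref_id, start, end, strand)` is
the junction key, shared by all reads of one circularized molecule and, with
overwhelming probability, different between molecules.  Supporters whose
intervals lie within 2 bp of each other on the same strand chain into one
junction (`JUNCTION_SLACK`): consensus masking can erase the evidence that
distinguishes adjacent slide placements, so without the slack a single
molecule could masquerade as two.  The slack errs in the conservative
direction (two real molecules with near-identical shear boundaries count once).
A variant is a **1X allele** when one CS supports the alternate base and a
**2X allele** when supporters span at least two distinct junctions — two
independent circularization events — which suppresses both per-read errors
and single-molecule damage such as cytosine deamination.  A mismatch at the
very first or last aligned column of a CS is rotation-ambiguous (an
equal-cost slide relocates a terminal mismatch to the opposite end), so
terminal mismatching bases are excluded from allele evidence.  Call
frequency is alt support over CS depth at the site; calls below
`min_frequency` (default 0.02) are flagged `lowFreq`, not dropped.

## The simulator

One seed drives six named child streams (molecule origins, droplet
assignment, deamination, amplification, pair sampling, sequencing errors),
spawned from `numpy.random.SeedSequence` in a fixed order so stages are
individually reproducible.  The generative chain:

1. **Strains.** The reference is uniform-random; a minor strain is derived
   with a configurable number of SNPs and 1-bp indels (defaults 345 and 6 on
   100 kb).  Mixtures default to 1:10 minor:major.
2. **Molecules.** Fragments of 80–140 nt are drawn uniformly from either
   strain, on either strand; droplet assignment is uniform over `n_droplets`
   (30,000 molecules in 10,000 droplets by default: mean occupancy 3, the
   stated operating point).
3. **Deamination** happens once per molecule, before amplification, as C→T
   on the fragment's stored strand at `deamination_rate` per C site — so all
   copies inherit it, and minus-strand damage surfaces as G→A on the
   reference.
4. **Amplification.** Droplet mode gives each occupied droplet exactly
   `droplet_yield_copies` (default 300) split evenly among its occupants —
   the droplet's reagent-limited cap.  Bulk mode draws per-molecule
   log-normal factors (`bulk_dispersion`, default 1.0 log-units, chosen to
   reproduce heavy-tailed bulk depth ratios) normalised to the same grand
   total, modelling competitive amplification at equal total yield.
5. **Reads.** Each pair samples a molecule proportionally to its copy
   yield, takes a random-phase 500–700 bp tandem insert, injects polymerase
   errors independently per copied base (default 1e-5, phi29-like) and
   sequencing errors per read base (default 0.003), and emits 2×150 bp
   mates.  Qualities are Phred+33: Q37 for correct bases, Q20 at injected
   sequencing errors.

Every molecule, damage event, and read pair is recorded, so downstream
calls can be audited against ground truth.

What the simulator does **not** model: chemistry (primer annealing, phi29
processivity, chimera formation), sequence-context amplification bias,
quality-score miscalibration, and indel sequencing errors.  Passing tests
therefore demonstrate the correctness and statistical behaviour of the
*processing* under the stated generative assumptions, not performance on
real libraries, where context bias and damage spectra are richer.

## Evaluation statistics

* **Error rate** = alt CS observations at non-truth sites over assessed
  consensus bases; the 1X denominator is every piled base, the 2X
  denominator counts bases at sites with ≥2 distinct junctions (only there
  can a 2X call arise).  Per-base rather than per-site, documented here
  because the alternative reading is defensible.
* **Spectrum**: the 12 ordered reference-strand substitutions, complements
  not collapsed.
* **Depth statistics** exclude the first and last 100 bases, report depth
  CV as sample (n−1) standard deviation over mean in percent, the
  min/median/max depth ratio, and a LOWESS track of natural-log windowed
  ratios (10 bp windows, neighbourhood fraction 0.05, floored at 3 points).
* **Confusion** matches called (site, alt) pairs against the golden set;
  FPR = FP/(FP+TP) — against called positives, the only reading consistent
  with near-unity FPRs on sparse truth sets — and FNR = FN/(TP+FN).
* **FN bias classification**: an FN site at or below 30/80 of the mean
  depth is SEQ_Bias (sequence-context amplification bias), above it
  STR_Bias (strand bias).  The anchor is a 30× cut at 80× mean, generalized
  as a fixed fraction.
* **FP frequency histogram** bins at [0, 0.01), [0.01, 0.02], (0.02, 1],
  the boundary 0.02 belonging to the low-frequency mass.

## The acceptance studies

`dropcirc.studies` holds six self-contained desk-scale studies; the same
runners back `tests/test_acceptance.py` and `scripts/acceptance.py`, so
every reported number is recomputed end to end.  Problem sizes (kilobase
genomes, 10³–10⁵ read pairs) were chosen by power analysis so each
Monte-Carlo margin is wide at a few minutes of runtime on one CPU:

* **Identity**: a no-noise 1:1 run (10 kb, 50 SNPs, 5,000 pairs) must merge
  every pair, recover every consensus up to rotation with masking exactly
  where coverage < 2, place every CS correctly up to the slide degeneracy,
  and call perfectly at sites with CS depth ≥ 5.  A 1:1 mixture is used
  because identity is a correctness claim: at lopsided mixtures a site can
  lack minor-molecule consensus coverage for purely sampling reasons.  The
  molecule count (6,000) keeps enough independent molecules over every site
  that a site losing all variant-strain consensus coverage — a sampling
  zero, not a pipeline error — is vanishingly rare.
* **Error suppression**: 10⁶ two-copy offsets at e = 0.01; survival within
  3 s.d. of e²/3.
* **Mapping equivalence**: 1,000 random CSs with 0–3 mismatches from a
  100 kb genome; seeded = exhaustive on every CS.
* **2X specificity**: with only per-copy/per-read errors, no 2X call
  outside the truth set and none from a single molecule; adding deamination
  at 0.02 per C (chosen a priori so cross-molecule same-site collisions are
  abundant at ~18× depth) produces 2X false positives that are ≥ 90%
  C→T/G→A.
* **Uniformity**: five droplet/bulk replicate pairs at equal total yield;
  one-sided Mann-Whitney on depth CV.  Separately, one deep 1:10 run
  (200 kb, 600 SNPs, 125,000 pairs) subsampled to 6k–48k CSs shows FNR
  falling monotonically with CS number.
* **Frequency recovery**: a 1:10 mixture at ~100× depth; the mean per-site
  truth frequency must lie within a 99% normal-theory interval of the exact
  mixture fraction using the empirical between-site standard error (chosen
  over a pooled binomial interval because reads of one molecule are
  correlated, which a pooled interval ignores); the 0.02 filter must remove
  ≥ 2/3 of sequencing-error false positives while moving truth-site recall
  by < 2% absolute.

## Numerical and degenerate-input choices

Tie-breaks are deterministic everywhere: smallest start then smallest
rotation at a locus; subsamples are canonicalized by (ref, start, id).
Zero-depth or all-zero inputs yield absent (None) statistics, never 0.
Empty truth sets make FNR absent.  Periods are rejected, not guessed, when
the merged read is shorter than two minimum periods.  CSs more than half
masked are rejected before mapping.  Identical configuration and seed give
byte-identical pipeline outputs.

## Known limitations

* Indels are simulated in the minor strain but not called; truth indel loci
  are only excluded from error-rate denominators.
* Period detection has no indel tolerance, so RCA slippage products are
  discarded wholesale.
* The junction slack (2 bp) trades a little 2X sensitivity for molecule
  identity; genomes with long exact repeats would need a larger slack and
  would lose proportionally more.
* Coverage-bias mechanisms (GC, secondary structure) are not modelled, so
  depth-CV comparisons speak to partitioning, not to sequence context.
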