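# Methods

`strategykit` infers the transcription strategy of a lytic bacteriophage that
encodes its own σ factor, directly from the genome sequence and gene
annotations.  This note records the models and procedures, the parameters
that matter, and the design decisions taken where the problem was genuinely
open.

## Problem setting

Phages of this class (the Salmonella phage analysed during development, and
relatives such as phiEco32 and Xp10) organise their genes into two divergent
strand clusters separated — on the circularised genome — by a long
origin-spanning intergenic region.  Infection proceeds in three waves: host
RNA polymerase transcribes *early* genes from σ70-dependent promoters; an
anti-sigma factor then silences the host enzyme; the phage-encoded σ factor
takes over, driving *middle* genes from short core-motif promoters and
*late* (structural) genes from promoters carrying an additional TATA
element.  Recovering that program from sequence requires finding two very
different kinds of promoter: the host σ70 promoters (well-modelled,
weight-matrix territory) and the phage-σ promoters (unknown specificity,
well conserved, present in only a handful of copies).

## Phage-promoter discovery by pairwise local alignment

Multiple-local-sequence-alignment (MLSA) motif finders presume an ambiguous
motif present in a large fraction of the input sequences.  Phage-σ promoters
are the opposite: near-exact repeats in ~4 of ~30 intergenic regions.  The
discovery method is therefore pairwise:

1. **Intergenic extraction.** Upstream regions with an unfused gap strictly
   longer than 50 bp are extracted per downstream gene, oriented in the
   gene's transcription direction (promoters are not palindromic, so only
   the direct strand is ever scanned), and extended 5' by 30 bp into the
   upstream neighbour's 3' end, since promoters may overlap gene ends.  The
   `>50 bp` filter applies before fusion.  A gap between divergent genes
   yields one region per flanking downstream gene.  Negative gaps (nested
   genes) yield nothing.
2. **Anchor alignment.** The origin-spanning region — upstream of the
   structural ("+") cluster, and the region most likely to contain at least
   one promoter copy, since the cluster above it must be transcribed — is
   locally aligned against itself and against every other "+" region.  The
   aligner is an affine-gap Smith-Waterman (Gotoh recurrences, numpy
   row-sweeps with a lazy-F fixpoint), match +1, mismatch −3, gap open −5,
   extend −2, minimum hit length 7 bp, reporting all locally optimal
   non-overlapping hits deterministically (ties broken by smallest start).
   In self-comparisons the identity diagonal is excluded and mirror hits
   reported once.
3. **Hit filtering and consolidation.** Chance short matches are abundant
   (a 5 kb self-comparison contains hundreds of ≥7 bp coincidences), so
   hits are filtered by a pair E-value that treats the alignment score (in
   match units) as the length of an equivalent exact word; the threshold is
   10, the familiar default for reporting pairwise hits.  Surviving hits are
   merged by union-find (same-region intervals merge at ≥50 % overlap of the
   shorter; the two sides of each hit are linked), instances are put into a
   common ungapped frame by best-offset alignment against the longest
   instance, and a majority consensus is called over columns covered by at
   least half of the instances.
4. **Repeat significance.** A motif set with k instances of an L-bp
   consensus found in n bp gets E(k, L, n) = 4^L · P[Poisson(n·4^−L) ≥ k],
   the expected number of L-words occurring ≥ k times in n bp of uniform
   background.  Four 12-bp copies in 4.4 kb give E ≈ 3×10⁻⁹.  Sets with
   E > 10⁻³ are discarded.  A composition-matched variant is available.
5. **Supervised core scan.** The best set's consensus is trimmed to the
   12-bp frame with maximal per-column agreement; positions 3–8 are the core
   (consensus `TGATGT`).  All intergenic regions are rescanned for exact
   core occurrences, each reported as a 12-bp window (2 bp left flank, 4 bp
   right flank).  Windows are kept at p < 0.05, where p is the exact tail
   probability of the window's log-likelihood-ratio score against a
   pseudocounted (+0.5) profile of the long-motif instances, computed by
   dynamic programming over a discretised score grid (10⁻³ resolution) —
   no Monte-Carlo approximation.
6. **Classification.** A window is a *long (late)* motif iff its first two
   bases match `TG` with at most one mismatch **and** its last four bases
   are exactly `TATA`; otherwise it is a *short (middle)* motif.  This rule
   is induced from the published motif table and reproduces its 4/6
   partition exactly.  Anchor coordinates follow the table's convention:
   window start for long motifs, core start for short ones.

The scan covers all intergenic regions by default (short motifs occur
upstream of "-"-cluster genes), with a flag to restrict to one group.

## Host-σ70 promoter model

A composite consensus-zero model: 6-column log-odds matrices for the −35
(`TTGACA`) and −10 (`TATAAT`) hexamers, an optional 4-column matrix for the
−15 region immediately 5' of the −10, and a spacer score
log(freq(ℓ)/freq(17)) over the observed spacer support (within 15–20 bp).
Each log-odds column is shifted so its maximum is 0; hence the consensus
configuration with a 17-bp spacer scores exactly 0, all others below 0.
Absolute score values depend on the training alignment and are explicitly
not reproducible quantities; the reproducible object is the *strand bias*:
scanning the intergenic spans of a divergently organised genome on both
strands, there is a threshold at which predictions appear only on the
functional ("-") strand.  `threshold_by_strand_bias` finds it; given a
target "-"-strand count k it places the threshold at the k-th best
"-"-strand score (provided "+"-strand calls stay within the allowance),
otherwise it returns the most permissive threshold excluding "+"-strand
calls.  Same-strand predictions overlapping by more than half the shorter
interval are merged to the best scorer.

Training input is either a user-supplied alignment (TSV: −35, spacer
length, −10) or a sampled synthetic alignment (below).  Spacer-score
normalisation requires a 17-bp spacer in training; if absent the model
normalises at the modal length and records a warning.

## MLSA baseline

A classic Gibbs site sampler: one site per sequence, hold-one-out profile
(pseudocount 0.5, 0-order background estimated from the input), site sampled
proportionally to the profile/background likelihood ratio; every 20 sweeps a
phase-shift move translates all sites by the offset (±2) that maximises the
alignment score; after the final sweep an add/subtract cycle removes sites
with negative log-likelihood ratio and adds non-overlapping sites with
positive ratio, so the number of reported sites per sequence may differ
from one.  The sampler returns its final sampled state (no best-state
freezing: freezing makes independent restarts converge to the shared
dataset optimum, which would erase exactly the run-to-run disagreement the
robustness score is meant to measure).  Runs are bit-reproducible per seed.

Robustness of a restart ensemble is the mean pairwise fraction of matching
consensus positions at the best offset (|shift| ≤ 2).  High-copy planted
motifs give scores near 1; when the motif sits in only 4 of 40 sequences the
score collapses to the chance floor (~0.45 ± 0.06 per dataset — individual
datasets fluctuate, so the low-copy experiments average over independent
draws).

## Temporal classification

Each gene inherits the class of the nearest upstream same-strand promoter
within its strand cluster (σ70 → early, short motif → middle, long motif →
late), propagated operon-style to the cluster boundary — strand switches are
the only stop signals, since intrinsic terminators are not modelled.  A gene
downstream of both a σ70 and a middle promoter (canonically the σ-factor
gene) is labelled middle with a dual-promoter rationale.  Genes with no
upstream promoter in-cluster stay unassigned.  The strategy report lists the
promoter layout by coordinate, contiguous class blocks, per-class counts,
and a narrative skeleton; it flags failure when no promoters were supplied.

## Synthetic genomes

The generator emulates the studied genome architecture at reduced scale:
20 kb circular genome, uniform background, 5 "+" genes then 15 "-" genes
(log-normal lengths around 600 bp, 120 bp gaps), a ~1.6 kb + tail
origin-spanning intergenic region.  Planted features, all recorded in a
truth set with pipeline-convention anchors:

* four late motifs (`TGTGATGTTATA`) on the "+" side of the origin region,
  optional per-position mutation rate (default 0);
* eight σ70 promoters on the "-" strand upstream of the functional cluster:
  two exact consensus and six with one substitution in a weakly constrained
  column (consensus probability ≤ 0.6).  Spacers are 17 bp with random
  sequence — identical spacers would create long exact repeats that the
  pairwise search would rightly find.  The substitution placement implements
  the stated study condition that plants sit above the genomic background (a
  near-consensus background window is expected roughly once per genome, so
  unconstrained substitutions would drop below it on a sizeable fraction of
  genomes);
* three middle motifs (core + non-TATA tail) in the downstream "-" gaps.

σ70 training alignments are sampled from an independent-column model with
per-position consensus probabilities echoing the familiar conservation
profile of curated σ70 alignments (outer hexamer positions strongest) and a
{16: 0.2, 17: 0.6, 18: 0.2} spacer distribution.  This is a synthetic
stand-in for a curated large-scale alignment, not derived from real data.

What the simulator does **not** model: coding-sequence composition,
dinucleotide structure, real promoter-strength distributions, terminators,
and genome mosaicism.  Passing tests on simulated genomes therefore
demonstrate the machinery (extraction arithmetic, alignment statistics,
threshold logic, class propagation) under the stated conditions, not
performance on arbitrary real genomes.

## Numerical and protocol choices

* Coordinates: 1-based inclusive at every public surface (GenBank
  convention), 0-based half-open internally; circular wrap via modular
  arithmetic.
* Windows containing non-ACGT bases are skipped by all scanners, with
  counts logged.
* Exact p-values are computed on a 10⁻³ score grid; the observed score is
  discretised identically so its own mass is in the tail.
* Problem sizes in the test and acceptance runs: 20 kb genomes; Gibbs runs
  of 300 sweeps, 6–20 restarts; 500-promoter training samples; 300-replicate
  Monte-Carlo check of the E-value model at n = 10 kb.  These sizes make
  every stochastic check stable at its asserted tolerance.
* PWM parameter recovery is assessed as the mean absolute per-entry
  log-odds error against a 0.6-conservation reference model.  A per-entry
  maximum criterion is not statistically attainable at n = 500: a letter
  with frequency p has sd of log-frequency ≈ sqrt((1−p)/(n·p)) ≥ 0.11 for
  p ≤ 0.13, so some entry of a 48-entry matrix pair always exceeds 0.1.

## Known limitations

* The real-genome validation (151 genes / 30 "+", long motifs at their
  printed coordinates, the phiEco32 9-bp motif, the Xp10 43-bp repeats)
  requires the three GenBank records on disk; their accessions are not
  printed in the study and they are not redistributable here, so that check
  fails until the user supplies `data/phage_7-11.gb`, `data/phiEco32.gb`
  and `data/Xp10.gb`.
* The repeat E-value assumes an i.i.d. background; skewed or repetitive
  genomes inflate significance (use the composition-matched variant, or
  distrust marginal sets).
* The short-motif p < 0.05 filter admits occasional chance core matches —
  middle-promoter precision is inherently below 1, exactly as a supervised
  significance cut implies.
* Gene prediction and functional annotation are inputs, not computed.
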