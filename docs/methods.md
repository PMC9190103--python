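# Methods

This note records the models, decision rules and numerical choices behind
`ltrscout`, what the simulator does and does not emulate, and the known
limitations of each stage.

## LTR-pair detection

An intact LTR retrotransposon leaves two near-identical direct repeats.
Detection runs per chromosome in four stages:

1. **Seeding.** Every exact 20-mer (`seed_k`) is hashed by exact base-4
   encoding (so no hash collisions); position pairs (i, j) of equal 20-mers
   with spacing inside the element window (default 1,000–25,000 bp) become
   seeds. Hyper-repetitive 20-mers (> 25 occurrences) are skipped. Windows
   containing N never seed.
2. **Chaining.** Because the two copies of one LTR pair sit at a single
   spacing, seeds are bucketed into spacing bands (width 10 bp) and chained
   along the chromosome with gaps up to 1,000 bp.
3. **Boundary refinement.** From the chained block, boundaries extend
   outward by ungapped maximal-score extension (match +1, mismatch −2,
   X-drop 20): inside the repeat the score climbs, outside it falls at an
   expected −1.25/bp, so the maximal-score endpoint estimates the boundary.
   Boundaries then snap to the canonical `TG...CA` termini within ±8 bp:
   offsets where *both* copies show the terminus are preferred (chance
   agreement outside the repeat is ~1/256 per offset); if none exists —
   typically because a terminal base of the younger LTR mutated — a
   single-copy terminus is accepted. Residual boundary error is a few bp in
   roughly 1 of 30 simulated elements, almost always when a terminal
   dinucleotide was hit by mutation; those elements then usually fail TSD
   phasing, which is the dominant source of recall loss (~3–10%).
4. **Verification.** The two putative LTRs are globally aligned
   (Needleman–Wunsch, match +1, mismatch −1, gap open −2, extend −1);
   identity is matches over all columns including gap columns, and the pair
   is kept iff identity ≥ 0.80 with both lengths in [100, 5000] bp.

**Overlap resolution.** Back-translated coding cassettes of two related
elements can align above the 0.80 floor and form a spurious long-range
"bridge" candidate spanning both. Keeping the single best-scoring candidate
per overlap group would keep the bridge and drop both genuine pairs, so
the kept set is instead the mutually non-overlapping subset maximizing
total score (score = identity × total LTR length; weighted interval
scheduling). For two overlapping candidates this reduces to "higher score
wins"; for the bridge case the two genuine elements together outscore the
bridge.

**Strand.** A direct-repeat pair is strand-symmetric — the reverse
complement of a direct repeat is again a direct repeat — so one forward
pass finds elements of both orientations, and a reverse-complement pass
would only duplicate them. Strand is assigned downstream from PBS
orientation.

## Structural intactness

* **TSD** — the 5-bp flanks immediately outside the element are compared
  positionally (no alignment: 5 bp is too short for gaps to be
  meaningful); homology ≥ 0.60, i.e. ≥ 3 of 5 matches. The threshold is
  inclusive because a strict "greater than 60%" could only be met at 4/5
  on a 5-bp flank. TSD presence is orientation-symmetric and always
  evaluated on the forward strand.
* **PBS** — the genomic PBS equals the reverse complement of a tRNA
  3'-terminal segment. The window [5' LTR end, +10 bp] is scanned for
  ungapped matches of 8–40 bp at ≥ 90% complementarity against every
  bundled tRNA suffix; the best hit ranks by matched bases, then
  complementarity, then tRNA id (ranking by raw window length would let a
  perfect 12-mer lose to the same 12-mer padded with one mismatch).
* **PPT** — the longest 8–40 bp run with purine fraction ≥ 0.94 ending
  within 30 bp of the 3' LTR start; ties on length go to the run closest
  to the LTR. The 0.94 floor and 30-bp proximity window are this package's
  choices.
* **Domain scan** — the internal region is translated in six frames and
  each frame locally aligned (Smith–Waterman, BLOSUM62, gap open −11,
  extend −1 — the BLAST defaults) against the bundled references; hits
  need ≥ 35% identity over ≥ 50 aligned columns, and overlapping hits of
  one domain name collapse to the best score. Stops translate to `*`,
  which BLOSUM62 penalizes, so frames with interrupted ORFs simply score
  lower.
* **Orientation** — annotation runs on the forward orientation first; if
  no PBS is found, a reverse-complemented local view of the candidate is
  tried with the two LTRs' roles swapped. A PBS found there sets strand
  "−" and all evidence maps back to forward-genome coordinates.
* **Acceptance** is the conjunction TSD ∧ PBS ∧ PPT ∧ RT-domain ∧ LTR
  identity ≥ 0.80; a rejection records *every* failed criterion, not just
  the first.

**Classification.** Superfamily is read off the pol-domain order on the
element strand — integrase upstream of reverse transcriptase is *Copia*,
the converse is *Gypsy*, no integrase is *unknown*. When a domain name has
several non-overlapping hits, its cassette position is taken from the
best-scoring hit, so marginal spurious hits (at the 0.35 identity floor)
cannot flip the order. Family is the nearest RT exemplar by global protein
identity, constrained to the assigned superfamily, ties broken
lexicographically.

**Bundled references.** The domain consensus proteins, the per-family RT
exemplars and the tRNA set are *synthetic*: generated deterministically in
code from a fixed internal seed (`refs.py`). Family exemplars derive from
a per-superfamily RT backbone with 25% of residues substituted, keeping
within-superfamily exemplars ~55–60% identical — far enough apart that an
element built at ≥ 90% of one exemplar is unambiguously closest to it, and
close enough that every family RT still crosses the domain-scan reporting
floor. Users with curated references (e.g. from a domain database) can
pass their own sets; nothing in the algorithms assumes the synthetic ones.

## Insertion dating

Both LTRs are identical at integration, so their divergence clocks the
insertion. The pair is globally aligned and the Kimura two-parameter
distance computed over ungapped, N-free columns:

k = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q),  T = k / 2r,

with P the transition and Q the transversion proportion and
r = 1.3 × 10⁻⁸ substitutions/site/year (the standard rice intergenic
rate; configurable). Gap and N columns are excluded from both numerator
and denominator. Saturated pairs (1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0) are
reported with age *undefined* rather than clamped — no information is
destroyed and the caller decides. k = −0.0 is normalized to 0.0.

The simulator's mutation process uses the exact K2P transition
probabilities at distance k (rates α for transitions, β per transversion
type, κ = α/β, normalized so α + 2β = 1), which makes the estimator the
exact inverse of the generator in expectation; observed ts:tv is κ:2.
Estimated per-element k values at LTR length ~1 kb carry sampling noise of
roughly √(k/L), so single-element ages scatter while the mean over
hundreds of pairs recovers the target within a few percent.

## Phylogeny

Pairwise global protein alignment of RT domains gives d = 1 − identity
(identity over all columns, gaps included) — a pairwise stand-in for a
multiple alignment that preserves the grouping structure actually tested.
The tree is canonical neighbor-joining (Saitou–Nei Q-criterion):
deterministic tie-break toward the lexicographically smallest label pair,
negative branch lengths clamped to zero with the deficit moved to the
sister branch, final three nodes joined by the three-point formulas. NJ
replaces maximum likelihood deliberately: the analysis goal is family
grouping, not branch support. On additive matrices NJ provably recovers
the generating tree; the test suite verifies topology and path-length
round-trip against exhaustive enumeration (n ≤ 6) and an independent NJ
implementation. Clade purity counts, per family, the fraction of members
inside the largest single-family bipartition side; superfamily
separability asks whether one edge splits *Copia* from *Gypsy* leaves.

## ALE-seq evidence

Read pairs collapse to template fragments (union span; a fragment is
unique iff all its alignments are). Counting follows featureCounts
defaults: only unique fragments, ≥ 1 bp overlap with the element interval,
ambiguous fragments (overlapping two elements) discarded, mates counted
once. Normalization is reads per million uniquely mapped fragments (RPM);
the underlying study states only "normalized value", and RPM is this
package's choice, recorded in config. The junction window spans
[5' LTR end − 50 bp, PBS end + 30 bp] (strand-aware), sized so 30-bp reads
touching the LTR/PBS boundary are always captured.

Activity tiers: **strong** requires normalized ≥ `strong_rpm` (4,000) AND
junction reads ≥ `min_junction` (50); **moderate** requires normalized ≥
`moderate_rpm` (3,000). The numeric cutoffs are calibrated on the
simulator's default scenario — 2 active among 50 elements, 500 junction
fragments each, 100,000 background fragments on 2 Mb — where active
elements sit near 7,000 RPM with ~500 junction reads and background
elements near 1,600–3,500 RPM with ≲ 25 junction reads. The conjunction
makes strong calls robust: background RPM scales inversely with genome
size, but background junction reads stay near the Poisson expectation of
~4 per window, so a background element essentially cannot be called
strong. On genomes much smaller than 2 Mb many background elements cross
the moderate threshold; moderate calls are only meaningful at the
calibration's genome-to-library proportions.

## The simulator

`simulate.build_genome` implants, into uniform-composition random
chromosomes, elements of the form

TSD · 5'LTR · (0–6 bp offset) · PBS · spacer · cassette · spacer · PPT ·
(0–12 bp gap) · 3'LTR · TSD

with: 5-bp TSD duplicated exactly on both flanks; `TG...CA` LTRs of
300–1,000 bp; PBS = reverse complement of a bundled tRNA's 3'-terminal
12-mer; the family cassette back-translated with uniform synonymous codon
choice; a 12-bp pure-purine PPT; and the 3' LTR evolved from the 5' LTR
under K2P at the element's target divergence. Decoys: solo LTRs
(TSD + LTR + TSD), 3'-truncated copies (everything from the PPT on
removed, right flank random), and TSD-less copies whose right flank is
constructed to mismatch the left flank at *every* position — purely random
flanks would pass the ≥ 3/5 homology test ~10% of the time, which would
make "TSD-less" a probabilistic rather than structural property.
`generate_aleseq_reads` draws, per active element, paired 30-bp fragments
whose template starts uniformly in the 5' LTR and ends at the PBS 3' edge
(+0–10 bp), capped at the 3,000-bp template maximum, over uniform
background fragments (templates 60–300 bp); truth alignments are emitted
directly (simulator-as-mapper) and can also be written as SAM/FASTQ for
external mappers. All randomness flows from one mandatory seed; identical
configuration gives byte-identical FASTA/FASTQ/SAM/truth output.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: nested insertions, solo-LTR formation by
recombination (solo decoys are implanted, not derived), non-uniform base
composition and repeat landscapes of real genomes, sequencing errors, PCR
duplicates, multi-mapping reads (all simulated alignments are unique), and
genuine tRNA/domain sequence diversity. Detection recall on real genomes
will be lower than the ≥ 90% measured here, chiefly through nested and
degenerate elements.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the annotation workflow on
a 2-Mb genome with 30 intact elements and 20 decoys; dating recovery on
200 LTR pairs of 1 kb per divergence level; K2P oracle equivalence on
10,000 sampled 8-mer pairs; NJ on 100 random additive matrices (n ≤ 8,
with exhaustive verification at n ≤ 6); and activity calling on 20 seeded
replicates of the default scenario. These sizes were chosen as the
smallest at which each property is statistically meaningful.

## Known limitations

* Boundary refinement assumes substitution-only LTR divergence when
  extending (extension is ungapped); indel-rich old elements rely on the
  NW verification step and may get fuzzier boundaries.
* Nested elements are out of scope: the seed-chaining stage reports the
  non-overlapping maximal-total-score subset and will typically annotate
  the younger of two nested elements only.
* `count_reads` requires a non-overlapping annotation (guaranteed by the
  pipeline's own output; arbitrary external GFF3s with overlapping
  elements are rejected with an error rather than silently miscounted).
* Family assignment is only as good as the exemplar set; with the bundled
  synthetic exemplars it is a demonstration of the mechanism, not a
  biological claim.
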