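# Methods

## Junction databases

Gene models (BED12 or genePred text) define, per locus, an ordered set of
exons in transcript orientation; minus-strand exon sequences are
reverse-complemented before use, since reads derive from mRNA. For a read
length `RL` and a minimum exon overlap `mo` (default 4 bp), the arm length
is `RL − mo`: any ungapped placement of a read across the joint of a
`2·(RL − mo)`-mer junction then overlaps both exons by at least `mo`
bases. Geometries with `RL ≤ 2·mo` admit no spanning placement and are
rejected. For 25 bp reads this gives 21 bp arms and 42-mer junctions, and
`RL − 2·mo + 1 = 18` admissible offsets per junction; for 27 bp reads,
23 bp arms.

* **ESJ** enumerates every ordered same-locus exon pair (i, j), i < j.
  Pairs with j = i + 1 are *consecutive* junctions; j > i + 1 are
  *skipped* candidates. An exon shorter than one arm cannot donate a full
  arm, and any pair involving one is discarded outright (no padding).
  Redundancy is removed at the sequence level, keeping the
  lexicographically first junction id per duplicate — a deterministic
  choice; whether removal should be by sequence or by coordinate is an
  open convention and sequence-level was chosen because mapping cannot
  distinguish identical sequences anyway.
* **ERJ** draws, for each ESJ record, a uniformly random (locus, exon)
  pair from two distinct loci, joining arms with the same geometry. Draws
  colliding with an ESJ sequence or an earlier decoy are rejected and
  redrawn (up to 1000 attempts, then an error). The decoy database is
  kept exactly the same size as ESJ so raw count histograms are
  comparable without normalization (a scale factor exists for unequal
  databases).
* **rESJ** swaps the two arms of each ESJ record; swapped sequences
  identical to a real ESJ sequence are dropped, so |rESJ| ≤ |ESJ|. Both
  decoy classes preserve the base composition of real junction sequence,
  which pure per-nucleotide shuffling would not; `composition_profile`
  exposes the per-position A/C/G/T frequencies (positions −arm..−1 and
  1..arm around the joint) to verify this.

## Mapping and the MMES score

Reads are placed on junction sequences ungapped, scored by Hamming
distance with a mismatch budget (default 2); ambiguous bases always count
as mismatches. The mapper builds a pigeonhole seed index — the read is cut
into `max_mismatch + 1` chunks, so at least one chunk of any within-budget
placement matches exactly — and verifies candidates with vectorized
comparisons. It is exactly equivalent to scanning all (junction, offset)
pairs, which the test-suite asserts against a naive oracle. `hit_policy`
keeps either every within-budget placement (`all`) or only each read's
minimum-mismatch placements (`best`, the default, matching the behaviour
of the short-read aligners of the 25 bp era); a read is *uniquely mapped*
iff its best-hit set is a singleton. Alignments can be exported to and
ingested from SAM (NM/MD tags; gapped or untagged records are dropped with
a warning).

For a placement at offset `o`, the left arm of the read is
`L_arm = arm_len − o` and

```
N = min(L_arm − L_mismatch, R_arm − R_mismatch).
```

Bounds `mo − M ≤ N ≤ ⌊RL/2⌋` hold for every placement with M total
mismatches; adding a mismatch never increases N; mismatches confined to
the long arm leave N unchanged whenever the short arm still sets the
minimum. These laws are asserted exhaustively over all placements of a
25 bp read on a 42-mer with ≤ 2 mismatches.

## Empirical error model

Junction reads are histogrammed by (N, M) separately for the target and
decoy databases, and the per-read error rate is the clipped decoy/target
ratio with an additive pseudocount α = 1:

```
P_read(N, M) = min(1, (count_ERJ + α) / (count_ESJ + α)).
```

The pseudocount keeps empty cells defined (an unobserved cell is maximally
pessimistic, P_read = 1) and is deliberately not tuned. A junction's
pseudo p-value is the product of P_read over its covering reads, computed
and stored in log10 to avoid underflow at high coverage; adding a read can
only lower the p-value, so coverage and quality both accumulate evidence.
Calls use a boundary-inclusive threshold (pass iff p ≤ 0.01 by default).
The p-values are explicitly *pseudo* p-values — an evidence score on
[0, 1] calibrated by decoys — not frequentist tail probabilities, and no
additional multiplicity correction is applied: the decoy database plays
that role.

FDR at a threshold t is `#decoy junctions with p ≤ t / #target junctions
with p ≤ t`, clipped to [0, 1], with the full FDR-vs-threshold curve
available.

### Which reads contribute

On real data a conservative default is to let only uniquely mapped reads
contribute to p-values, and `score_junctions` defaults to that. The
simulation study, however, weights **every best-tied hit**: in a closed
world where each read's true junction is always present in the target
database, a non-specific placement can essentially only occur as a tie
with the true placement, so restricting to unique reads would empty the
very class of non-specific alignments the error model exists to calibrate
(every covered junction would be genuine and all precision comparisons
degenerate to 1.0). Real libraries contain reads from unannotated
transcription, paralogs and repeats whose true origin is *not* in the
database; tied hits are the simulator's analogue of that read class.

## Baselines

* **Read counting** accepts a junction iff R ≥ 2 (threshold
  configurable). For precision comparisons at a matched number of calls,
  the counting baseline ranks junctions by R with ties broken by id and
  takes the top k, where k is the number of junctions the empirical model
  called.
* **Logistic regression** summarises each junction's alignments into six
  features — read count, distinct offsets, maximum overhang
  (max over reads of min(L_arm, R_arm)), minimum and mean mismatch
  counts, and the Shannon entropy (bits) of the offset distribution —
  optionally adding the maximum MMES score as a seventh. The feature set
  is a reconstruction spanning the quantity and quality information of
  the alignments (six degrees of freedom), not a published list, and is
  flagged as such in reports. Training uses consecutive junctions with
  read support as positives and rESJ decoys with read support as
  negatives; skipped junctions are scored, never trained on. The fit is
  plain maximum likelihood by IRLS on internally z-scored features
  (zero-variance columns pass through), converged at a 1e-10 step
  tolerance; on (quasi-)separation the last stable iterate is kept and
  the model flagged, preserving the score ordering. Wald statistics and
  the likelihood-ratio test against the intercept-only model are
  reported. AUC uses the Mann–Whitney rank form with midranks and
  stratified junction-level k-fold cross-validation (default 10 folds,
  reduced to the minority-class size when necessary on small
  simulations).

## Random-match model

Under uniform i.i.d. DNA, the expected number of random hits per junction
per million reads is

```
X(RL, m) = 10⁶ · (RL − 2·mo + 1) · 4⁻ᴿᴸ · Σₖ₌₀..ₘ C(RL, k)·3ᵏ,
```

the admissible-offset count times the cumulative probability of matching
an RL-mer within m substitutions. X saturates at `10⁶ · (RL − 2·mo + 1)`
when m ≥ RL, falls monotonically with read length and rises with the
mismatch budget. A seeded Monte-Carlo estimator (random read/junction
pairs, counted placements, binomial standard error) cross-checks the
closed form. For 25 bp reads with 2 mismatches X ≈ 4.44×10⁻⁵, four orders
of magnitude above the 32 bp value ≈ 6.18×10⁻⁹ — read length dominates
junction-mapping specificity once MMES and the mismatch budget are fixed.

## The simulator

The generator emulates the 25 bp single-end, substitution-only regime:
reads are fixed length with no indels and constant placeholder quality
(the underlying aligner model allows no gaps at these lengths). Study
conditions, chosen once: 120 genes of 3–8 exons (80–300 bp) separated by
100–600 bp introns on a uniform random genome; every gene expresses its
full isoform and 30% of eligible genes (≥ 3 exons) also express an
isoform skipping one internal exon; expected reads per transcript are
log-uniform on [1, 1000] (Poisson realised), so one-read junctions — the
regime where counting and quality-based calling disagree most — are well
represented; per-base substitution probability 0.01, the typical error
rate of the short-read instruments this read length corresponds to.
Transcripts are simulated forward-strand. Ground truth records every
junction that at least one read spans with ≥ 4 bases on both sides — the
set a perfect mapper could recover. All stages draw from independent
streams of a single seed; outputs are byte-reproducible.

What the simulator deliberately lacks: GC/positional coverage bias,
position-dependent error profiles, paired ends, genomic repeats and
paralogy, and unannotated transcription. The last two matter for
interpretation: they are the main sources of non-specific junction
mapping in real data, so passing tests here demonstrate correctness of
the machinery and the *direction* of the method's advantages, not the
magnitudes seen on real libraries (precision contrasts in this closed
world are compressed toward 1).

Problem sizes used by the test-suite and the reproduction script — a
20-replicate study at the default conditions (~20k reads each) plus one
deep run (150 genes, ~110k reads) for distribution-shape checks — were
chosen to make the full study run in well under a minute while leaving
all statistical assertions comfortably powered.

## Known limitations

* **Decoy FDR is conservative in the closed world.** A junk placement on
  a decoy faces no competition (the read's true junction is absent from
  the decoy database), while a junk placement on a target junction must
  tie or beat the true placement under best-hit mapping. Across 20
  replicates the decoy estimate averages ~0.7% at p ≤ 0.01 against a
  truth-based false-discovery proportion of ~0.2% — an upper bound, as
  decoy calibration is generally used, but not an unbiased estimate.
  Making it unbiased would require competitive target–decoy mapping,
  which would destroy the separate decoy histograms the P_read estimator
  needs.
* Pseudo p-values are evidence scores, not calibrated tail probabilities;
  thresholds should be read through the decoy FDR curve, not as error
  probabilities.
* The logistic baseline's feature list is a reconstruction (see above).
* Sensitivity and specificity are reported only against simulated truth;
  against external transcript whitelists only PPV is computed, and it is
  a lower bound (whitelists under-represent low-abundance transcripts).
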