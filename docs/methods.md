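# Methods

## Problem and model

Candidate m⁶A sites are the adenines of DRACH 5-mers
(`[G/A/C][G/A]AC[U/A/C]`) on mature mRNA. Validated sites are a small
minority of candidates (≈10:1 negatives:positives at transcriptome
scale), and the proportion on any single transcript is unknown in
advance. The classifier is therefore trained on the complete imbalanced
candidate set with an asymmetric cost rather than on balanced
subsamples: a gradient-boosted tree ensemble (XGBoost, `binary:logistic`
objective, probability output) in which every positive example's
gradient is scaled by `positive_class_weight`.

Default hyperparameters: L2 leaf regularization λ = 700, maximum tree
depth 6, learning rate η = 0.1, 400 boosting rounds, positive class
weight 6, AUC as the training evaluation metric. The weight of 6 is kept
as the model's standard setting even though the nominal training
imbalance is ≈10:1; the config accepts the empirical ratio where a user
prefers it. The classification threshold is 0.5 on the predicted
probability (positive iff p ≥ 0.5) and is exposed in `RunConfig`.

## Coordinates and windows

All coordinates are 1-based and fully closed on the mature transcript.
Window positions are labeled −25…+25 with 0 at the candidate adenine
(flank 25, window length 51 nt; the reader accepts any odd length and
the pipeline asserts the configured one). Windows that overrun a
transcript end are padded with `N`: dropping edge candidates would
silently change sample counts, and `N` handling is defined exactly in
every encoder (below). Candidate enumeration is motif-complete — every
DRACH adenine becomes a row; overlapping motifs all count.

## Feature space (509 dimensions)

Block order is fixed: binary(204), cpd(153), density(51), kmer(80),
entropy(7), location(2), snp(12). Column names are block-qualified
(`binary.pos-25.A`, `kmer.3.GAC`, `snp.pos-2`, …) so importance reports
are self-describing; positional indices are an artifact of layout and
are never used as identifiers.

* **binary** — per-position one-hot, order A,C,G,U; `N` → (0,0,0,0).
* **cpd** — 3-bit chemical property (ring number, hydrogen-bond
  strength, functional group): A (1,1,1), C (0,0,1), G (1,0,0),
  U (0,1,0); `N` → (0,0,0). The density block is appended after the CPD
  bits, not interleaved.
* **density** — dᵢ = (occurrences of sᵢ in s₁…sᵢ)/i. An `N` position
  gets density 0 and never increments any letter's prefix count; the
  denominator stays the position index i.
* **kmer** — 2-mer and 3-mer frequencies, lexicographic A<C<G<U order.
  The denominator is the number of valid sliding windows (L−k+1 when no
  `N` is present); windows containing `N` are excluded from numerator
  and denominator alike.
* **entropy** — composition frequencies p_A, p_G, p_U, p_C over non-`N`
  characters, then Shannon entropy En = −Σ pᵢ log₂ pᵢ (0·log 0 := 0),
  relative entropy REn = −Σ pᵢ log₂(pᵢ/p₀) with uniform reference
  p₀ = 1/4, and information gain IGS = En − REn. **With this sign
  convention REn = En − 2, so IGS ≡ 2 bits for every window.** The
  definitions are implemented exactly as stated rather than silently
  "corrected" (e.g. to the positive KL divergence): a constant column is
  harmless to tree learners — it can never split — and fidelity of the
  feature definitions takes precedence. The identity is pinned by a
  regression test.
* **location** — absolute distance from the transcript start,
  position − 1 nt (the start site has distance 0; the definition fixes
  the origin the distance phrase leaves open), and the relative location
  (position − 1)/length ∈ [0,1). m⁶A enrichment near the stop codon
  makes these strongly informative.
* **snp** — the 0/1 variant state at the 12 selected window offsets, in
  their ranked order; a padded (out-of-transcript) offset is 0.

Because the motif fixes A at offset 0 and C at offset +1, the
corresponding one-hot/CPD columns are constant across all conforming
samples and legitimately earn zero importance.

## SNP-specificity selection

Per window offset, the per-sample SNP state (variant at that transcript
coordinate or not) forms a 2×2 table against the class label; the
two-sided Fisher's exact p-value ranks offsets by class specificity
(ascending p). Independently, greedy MRMR with the MID (difference)
criterion ranks offsets by selection order: first the offset maximizing
plug-in mutual information I(x; class) in bits, then repeatedly the
offset maximizing I(x; class) − (1/|S|) Σ_{s∈S} I(x; s). The "two-sided"
choice and the MID variant with plug-in MI over binary variables are the
package's concrete instantiations of the generically named tests.

The final rank is the average of the two; the k = 12 smallest averages
are selected. Deterministic tie-breaks (ties arise only in degenerate or
synthetic data): equal averages break by smaller Fisher rank, then
smaller |offset|, then the negative offset first; equal Fisher p-values
break by the same offset rule; MRMR score ties break by the same offset
rule; zero-entropy (constant) offsets are appended last in offset order.
A corpus with no SNP variation at all is flagged `degenerate` rather
than rejected. The selected offsets are persisted inside the model
artifact, and prediction-time assembly always reuses the training-time
offsets — selection is never re-run on test data (leakage guard). In
cross-validation the selection is re-run inside each training fold for
the same reason.

## Evaluation conventions

precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean,
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)). Degenerate
denominators yield 0 (precision with no predicted positives, recall with
no positives, MCC with any zero marginal, F1 when precision+recall = 0).
These conventions are required by per-transcript evaluation, where
individual transcripts routinely receive no predicted positives.
Per-transcript scores are averaged unweighted across transcripts.
AUROC/AUPRC are deliberately not headline outputs (hard-label
comparability under imbalance is the point), though probabilities are
available for anyone who wants them.

Imbalance-ratio benchmarks keep every positive and draw negatives
uniformly without replacement, seeded, to k× the positive count for
k = 1…9; subsets are not nested. A `--replicates`-style repetition can
be layered on by varying the seed.

## Synthetic corpora

The generator emulates exactly the structure the method exploits:

* transcript lengths lognormal with median 2000 nt (sd of log 0.35,
  floor 300 nt) — typical mature-mRNA scale;
* random uniform A/C/G/U sequence; DRACH candidates arise naturally
  (≈1.8% of positions);
* a synthetic stop codon at 0.8 of the length; positive labels drawn
  from the candidates with weights ∝ N(stop, 0.1·length), negatives
  uniform — the minimal structure that makes the location features
  informative;
* exact negative:positive ratio control (default 10:1) by keeping all
  drawn positives and sampling negatives;
* SNP variants drawn once per transcript coordinate: planted-offset
  coordinates of positive windows (default offsets {−2,−1,+2}) at rate
  0.30, all other window-covered coordinates at background rate 0.05.
  Coordinate-first drawing keeps the class-conditional rates exact even
  where neighbouring candidate windows overlap.

A truth record (planted offsets and rates, positive sites, seed) is
stored beside each corpus so recovery tests are self-describing.

What the generator does **not** emulate: real sequence-composition
signal around m⁶A sites (beyond the motif itself), secondary structure,
conservation, realistic SNP allele structure, or transcript-family
redundancy. Passing tests on these corpora therefore demonstrates that
the pipeline recovers planted location/SNP structure under the stated
imbalance — not that it attains real-data accuracy.

The worked-case fixtures (`cjun`, `hiv1`) are synthetic stand-ins: random
DRACH-conforming windows with the published class sizes (25+47 and
12+50) and an injected prediction vector realizing the published
confusion counts ((18,3,7,44) and (5,3,7,47)), used to exercise the
evaluation path end to end.

## Problem sizes and numerical choices

Desk-scale runs use corpora of ~900–2200 samples (26–55 transcripts) at
10:1; the planted-SNP recovery study uses ~2000 samples per seed, 20
seeds; the paired cost-sensitive/unweighted comparison uses ~1000
samples per seed (75/25 stratified split), 20 seeds, full 400-round
training on both arms. SNP-rate convergence is checked on a 2:1 corpus
with ~5000 positives so the ±0.02 band sits at ≈3 binomial standard
errors. Model persistence embeds the booster's own JSON serialization in
a versioned artifact; a reloaded model reproduces probabilities bitwise.
Training runs single-threaded with a fixed seed, making the whole
pipeline reproducible end to end.

## Full-scale reproduction

Reproducing the published transcriptome-scale tables requires the
original supplementary sample table (≈300k rows) and Ensembl GRCh38
SNP annotations mapped to transcript coordinates; both are file-based
inputs here (no live database queries). The CLI pipeline in the README
runs unchanged on such files: `scan`/`read_sample_table` →
`select-snp` → `extract-features` → `train` → `predict` → `evaluate`.
This path is supported but not part of the test suite, which is fully
synthetic by design.

## Known limitations

* The SNP feature block treats "any variant" as one bit; allele
  frequency and variant type are ignored.
* Fisher p-values are computed per position without multiplicity
  correction — they feed a rank fusion, not a significance claim.
* The constant IGS feature (see above) is definition-faithful dead
  weight.
* `N`-padded edge windows dilute composition-based blocks; they are a
  small minority of candidates on realistic transcript lengths.
* MRMR's plug-in mutual information is biased upward for tiny samples;
  with ≥ a few hundred samples per class the ordering is stable.
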