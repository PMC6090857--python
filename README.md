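# m6apred

Cost-sensitive prediction of N⁶-methyladenosine (m⁶A) sites in human
mature mRNA.

m⁶A is the most abundant internal mRNA modification; it concentrates in
3′ UTRs near the stop codon and follows the degenerate sequence consensus
**DRACH** = `[G/A/C][G/A]AC[U/A/C]`, with the methylated adenine at the
third position. Predicting which DRACH adenines are methylated is a
heavily imbalanced problem — on transcriptome-scale data roughly ten
DRACH adenines are unmethylated for every true site — and balanced-subsampling
predictors discard most of the negative evidence. This package instead
trains a **cost-sensitive gradient-boosted-tree classifier (XGBoost)** on
the *entire* imbalanced candidate set, weighting the positive class in the
binary log-loss objective (`scale_pos_weight = 6`, `lambda = 700`,
`max_depth = 6`, `eta = 0.1`, 400 rounds, AUC as training metric).

Each candidate adenine's 51-nt flanking window (±25 nt) is encoded into a
**509-dimension feature vector**:

| block | dims | content |
|---|---|---|
| binary | 204 | per-position one-hot (A,C,G,U) |
| cpd | 153 | 3-bit chemical property: ring number / H-bond strength / functional group |
| density | 51 | cumulative same-nucleotide prefix frequency *dᵢ = #{sⱼ = sᵢ, j ≤ i}/i* |
| kmer | 80 | 2-mer and 3-mer frequencies |
| entropy | 7 | composition *p*, Shannon entropy *En*, relative entropy *REn*, information gain *IGS* |
| location | 2 | absolute and relative distance from the transcript start |
| snp | 12 | SNP variant states (0/1) at the 12 most class-specific window offsets |

The SNP offsets are chosen on training data by fusing two rankings over
the 51 window positions — the two-sided **Fisher's exact test** p-value of
the variant×class 2×2 table, and the greedy **MRMR** (max-relevance
min-redundancy, MID criterion, plug-in mutual information) selection order
— and keeping the 12 positions with the smallest average rank. Evaluation
uses precision, recall, F1 and the Matthews correlation coefficient
(MCC), the metrics that remain informative under heavy class imbalance,
plus per-transcript averaging and an imbalance-ratio robustness benchmark
(test sets re-subsampled at negative:positive ratios 1:1 … 9:1).

A fully seeded synthetic-corpus generator reproduces the statistical
structure the method relies on (DRACH candidates, stop-codon-proximal
positives, class-conditional SNP rates, configurable imbalance), so the
whole pipeline is testable without any downloads.

## Worked example

```python
from m6apred import M6AClassifier, SimulationConfig, simulate_corpus

corpus = simulate_corpus(SimulationConfig(n_transcripts=26, random_seed=1))
clf = M6AClassifier(corpus.samples, corpus.snp_table)
res = clf.fit()
print(res.summary())
```

```
m6A cost-sensitive classifier
==============================================
training samples               880
  positives / negatives     80 / 800 (ratio 1:10.0)
features                       509
boosting rounds                400
positive class weight          6.0
L2 regularization            700.0
max tree depth                   6
learning rate                 0.10
selected SNP offsets    -2 +2 -1 +10 -10 +13 -25 +12 +5 -8 -20 +21
----------------------------------------------
split-count importance by feature block:
  kmer           2123
  density        1681
  binary         1167
  location        931
  snp             808
  cpd             439
  entropy         204
```

The corpus plants elevated SNP rates at window offsets −2, −1 and +2 in
positive windows; the fitted model recovers exactly those three at the
top of its selected offsets. Evaluating on an independently simulated
test corpus:

```python
test = simulate_corpus(SimulationConfig(n_transcripts=10, random_seed=99))
print(res.evaluate(test.samples, test.snp_table).as_dict())
# {'precision': 0.3636, 'recall': 0.3636, 'f1': 0.3636, 'mcc': 0.3}
```

At a 10:1 test imbalance an MCC of 0.30 is far above the 0 of chance-level
or all-negative prediction — the location and SNP structure carry the
class signal in these corpora (synthetic sequence composition is
uninformative by construction, unlike real transcripts).

The same pipeline is scriptable from a shell:

```sh
m6apred simulate --out sim/ --seed 5 --transcripts 50
m6apred select-snp --samples sim/samples.tsv --snp sim/snp.tsv --out rank.tsv
m6apred extract-features --samples sim/samples.tsv --snp sim/snp.tsv \
    --positions rank.tsv --out X.tsv
m6apred train --features X.tsv --positions rank.tsv --out model.json
m6apred predict --model model.json --features X.tsv --out pred.tsv
m6apred evaluate --labels sim/samples.tsv --pred pred.tsv --per-transcript
```

To run on real data, supply a sample table (TSV/CSV/XLSX with columns
`transcript_id, position, transcript_length, window, label`), or scan a
transcript FASTA with `m6apred scan` against a list of validated sites,
plus a per-transcript SNP position table (2-column TSV or minimal VCF in
transcript coordinates).

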