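# mimseq

Motif-independent sequence specificity for DNA sequence sets.

Sets of regulatory sequences — ChIP-seq peaks, enhancer calls, nucleosome-
depleted regions — often carry reproducible sequence signal even when no
single transcription-factor motif explains it. `mimseq` quantifies that
signal with the **Motif Independent Measure (MIM)**: a distance between the
pooled k-mer distribution of the target set and those of matched random
sequence sets, with an empirical significance test and a ranking of the
k-mers that carry the signal. It is aimed at regulatory genomicists who
want a motif-free answer to "is there sequence information in this set of
regions, and which words carry it?"

## The measure

Each sequence is scanned with a sliding window of width k (default 4).
A k-mer and its reverse complement read out the same double-stranded word,
so counts are pooled into canonical k-mers — for k = 4, the 256 words
collapse to m = 136 classes. A target set **S** of n sequences is pooled
into a probability vector P = (P_j), with P_j = Σᵢ c_ij / Σ_ij c_ij over the
per-sequence counts c_ij. A matched random set **R** (same n, same
per-sequence lengths) is pooled into Q the same way, and the sets are
compared with the halved symmetric Kullback–Leibler divergence, in bits:

    d_kl(S, R) = ½ [ Σ_j P_j log₂(P_j/Q_j) + Σ_j Q_j log₂(Q_j/P_j) ]

MIM is the expectation of d_kl(S, R) over random sets, estimated by
averaging over B of them (default B = 1000). Significance comes from the
null MIM distribution — the MIM value each random set itself attains,
computed leave-one-out among the B cached null profiles — through a
Gaussian-kernel density; p-values are one-sided and reported no smaller
than 0.001. Two alternative metrics are provided: the Hellinger distance
(bounded in [0,1], a true metric) and the component-wise Gaussian
Bhattacharyya distance built from per-sequence frequency means and
variances. Ranking the per-k-mer summands of d(P, Q) against the pooled
null distribution identifies the most informative k-mers.

Null sets can be drawn from i.i.d. background base probabilities, by
mononucleotide shuffling of the target sequences, or as length-matched
intervals sampled from a genome FASTA.

The package also ships the synthetic ChIP-seq benchmark used to validate
the measure: background sequences over A,C,G,T = 0.15/0.35/0.35/0.15 with
the motif TTGACA implanted from a position weight matrix whose mutation
rate ε runs from 0 (perfect motif, every column degenerate) to 0.25
(uniform columns, no motif).

## Worked example

Simulate a weak-motif dataset (200 sequences of 300 bp, motif implanted in
half of them at ε = 0.05), then score it against 100 background-matched
null sets:

```
$ mimseq simulate --epsilon 0.05 --n 200 --length 300 --n-implant 100 \
      --seed 7 --out sim
$ mimseq compute --input sim/sequences.fasta --metric kl -B 100 \
      --background-probs 0.15,0.35,0.35,0.15 --seed 7 --out mim
symmetric_kl    MIM=0.00387201  null_mean=0.0032306     null_sd=0.000289681     p=0.02586
```

The target's pooled 4-mer distribution sits 0.0039 bits from random — about
2 null standard deviations above the null mean of 0.0032 bits — giving an
empirical p-value of 0.026: detectable sequence specificity from a motif
occupying only 0.1 % of the bases. The k-mer ranking written alongside the
report starts with:

```
$ head -3 mim/ranking_symmetric_kl.tsv
kmer    contribution
GTCA    0.000216608
TCAA    0.000136063
```

GTCA and TCAA are canonical forms of TGAC and TTGA — substrings of the
implanted motif — recovered with no motif model in sight. A sweep over
motif strengths shows the dose–response and the loss of significance when
the "motif" is pure noise:

```
$ mimseq sweep --epsilons 0,0.1,0.25 --n 200 --length 300 --n-implant 100 \
      -B 100 --seed 7 --out sweep
 epsilon  mim_symmetric_kl  p_symmetric_kl
    0.00          0.004861        0.001000
    0.10          0.003595        0.131376
    0.25          0.003525        0.182822
```

Real data enter through `--input peaks.fasta` or `--bed peaks.bed --genome
genome.fa` (BED intervals are 0-based half-open; sequences are taken from
the forward strand, which loses nothing because canonical counting is
strand-symmetric).

The same machinery is available as a library, scikit-learn style:

```python
from mimseq import MIM, KmerCounter, read_fasta

est = MIM(metric="symmetric_kl", B=1000, random_state=0).fit(read_fasta("peaks.fa"))
est.mim_, est.p_value_, est.ranking_.top(5)

X = KmerCounter(k=4).fit().transform(["ACGTACGT", "TTGACATT"])  # (2, 136) counts
```

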