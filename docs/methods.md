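# Methods

## The measure

MIM treats a set of DNA sequences as a sample from an unknown sequence
model and asks how far its word composition sits from matched random
sequences. The unit of information is the canonical k-mer: a window of
width k read on either strand. With k = 4 there are 136 canonical classes
(120 complement pairs and 16 palindromes). Counting slides a window with
step 1; windows containing `N` are skipped; each valid window increments
exactly one canonical bin, so row sums equal valid-window counts and the
profile of a sequence equals that of its reverse complement by
construction. This is why BED-extracted sequences are always taken from
the forward reference strand — orientation carries no information at the
level of canonical counts.

A set is pooled into one probability vector (total counts over all
sequences, normalized). Pooling weights every valid window equally, so
longer sequences contribute proportionally more; this is the intended
behaviour for peak sets, where longer peaks contain more sequence.

Three distances compare a target pool P with a null pool Q:

* **Halved symmetric Kullback–Leibler divergence** (bits):
  `½[Σ P_j log₂(P_j/Q_j) + Σ Q_j log₂(Q_j/P_j)]` — the default, read as the
  expected number of extra bits needed to code samples from one
  distribution with a code built for the other.
* **Hellinger distance**: `sqrt(½ Σ (√P_j − √Q_j)²)` — bounded in [0,1]
  and a true metric (the triangle inequality is property-tested).
* **Gaussian Bhattacharyya distance**, summed over k-mers:
  `Σ_j (μ_Pj − μ_Qj)²/(4(σ_Pj + σ_Qj)) + ½ ln((σ_Pj+σ_Qj)/(2√(σ_Pj σ_Qj)))`,
  where μ and σ are the mean and *variance* (unbiased, n−1) of per-sequence
  relative frequencies. Unlike the other two it sees between-sequence
  dispersion, not only the pool; its absolute scale is therefore not
  comparable with the pooled metrics, and because per-sequence frequency
  variances shrink with sequence length its values depend strongly on the
  length of individual sequences. It is provided for concordance checks of
  significance calls rather than for absolute comparison.

MIM is the mean distance from the target to B independently generated null
sets. With everything held fixed, MIM does not converge to zero for a
signal-free target: two finite samples of N windows from the same
composition sit at an expected halved symmetric KL of about
(m−1)/(N·ln 2) bits. MIM values are therefore only comparable between sets
of similar total sequence content, and the significance test — not the raw
value — is the interpretable output.

## Null models and significance

Null sets always match the target's number of sequences and every
per-sequence length. Three generators:

* `background` — i.i.d. letters from fixed A/C/G/T probabilities. Default
  uniform; the synthetic benchmark uses its generative background.
* `shuffle` — each target sequence's letters permuted uniformly. Preserves
  per-sequence mononucleotide composition, so it tests for word-order
  information beyond composition.
* `genome` — length-matched intervals drawn from a genome FASTA, contigs
  weighted by length (restricted to contigs long enough for the requested
  interval), rejecting intervals with more than 10 % `N`. This is the
  appropriate null for real peak sets, where genomic background composition
  is itself structured.

Each null replicate b draws from an RNG stream derived from the master
seed and b (numpy `SeedSequence(seed, spawn_key=(b,))`), so runs are
reproducible and enlarging B leaves earlier replicates unchanged.

The null MIM value of each replicate is computed leave-one-out among the B
cached null profiles — the mean distance of null b to the other B−1 —
rather than by generating B fresh sets per replicate. The expectation is
identical and the cost is B profile computations instead of B². The
p-value is the upper-tail mass beyond the observed MIM of a Gaussian-kernel
density (Silverman bandwidth) fitted to the B null MIM values, floored at
0.001: below that, the resolution of a density estimated from O(1000)
points does not support finer distinctions. The test is one-sided because
only an excess of specificity is of interest. Calibration is verified by
test: a target drawn from the null model itself yields approximately
uniform p-values (Kolmogorov–Smirnov over 50 repetitions at B = 100).

Degenerate cases: if all null MIM values coincide, the p-value falls back
to the empirical rank (1 + #{null ≥ observed})/(1 + B); the same fallback
is used when B < 10, where a KDE is meaningless. B below 100 triggers a
warning in the CLI — point estimates remain unbiased but p-value
resolution degrades.

## Informative k-mers

All three distances decompose as sums over the 136 components (for
Hellinger, the decomposition is of the squared distance). Ranking the
summands of the distance between the target pool and the *pooled* null
aggregate (total counts over all B null sets — a single, well-estimated Q)
orders k-mers by their contribution to the signal. Ties break
lexicographically. For the Bhattacharyya ranking the null means and
variances are computed across all B·n null sequences in one streaming
pass.

## The synthetic benchmark

The generator emulates a transcription-factor ChIP-seq experiment with one
binding motif. Defaults, which define the benchmark conditions:

| parameter | default | meaning |
|---|---|---|
| `n_sequences` | 2000 | peak-like sequences per set |
| `length` | 500 bp | per-sequence length |
| `background_probs` | 0.15/0.35/0.35/0.15 | A/C/G/T generative background (GC-rich, as in regulatory DNA) |
| `consensus` | TTGACA | implanted motif |
| `epsilon` | — | per-position mutation rate in [0, 0.25] |
| `n_implant` | 1000 | sequences receiving one motif instance |

The PWM places probability 1−3ε on the consensus base of each column and ε
on the other three: ε = 0 is a perfect motif, ε = 0.25 indistinguishable
from uniform. Motif strength is summarized by the information content
Σ p log₂(p/q) against the generative background; at ε = 0.1 the TTGACA
motif carries 5.35 bits (the AT-rich consensus is rare under the GC-rich
background, which is what makes it informative). Implantation overwrites
`w` consecutive bases at a uniform offset, so sequence length is exactly
preserved and the null sets remain length-matched; each selected sequence
(chosen without replacement) receives exactly one instance. An implant log
(sequence id, offset, sampled word) is returned for ground-truth checks.

What the generator does *not* emulate: genomic background structure
(repeats, CpG islands, isochores), peak-length heterogeneity, multiple or
clustered motif instances, binding-strength-dependent implant probability,
and sequencing artifacts. Passing the benchmark therefore demonstrates
that the statistic detects and localizes subtle compositional signal in an
i.i.d. background — not that any particular real peak set is well
modelled. For real data the genome or shuffle nulls are the appropriate
comparison, and conclusions rest on the empirical p-value.

## Numerical choices

* **Canonical representative**: lexicographic minimum of word and reverse
  complement; each window counted once (not once per strand), preserving
  Σ counts = valid windows.
* **Pseudocount**: 1 per canonical bin when pooling counts into
  probabilities (default). At benchmark scale (~10⁶ windows against 136
  bins) the perturbation is negligible, and it guarantees finite KL.
  Pseudocount 0 is available for exact small examples; the KL rejects zero
  entries rather than returning infinity.
* **Variance floor**: 1e-12 in the Bhattacharyya terms, preventing
  division by zero and log of zero for constant columns.
* **Logarithms**: base 2 for KL (bits); natural log for the Bhattacharyya
  Gaussian form.
* **Hellinger**: computed with the outer square root (range [0,1]).
* **Counting**: sequences are encoded to integer codes and counted with
  vectorized `bincount`; sets of equal-length sequences (the simulator and
  all null generators) take a single matrix-shaped path.
* **Pairwise null distances**: computed with vectorized batch forms that
  are tested to agree with the scalar definitions to 1e-10.

## Scale used by the shipped checks

The test suite and `scripts/acceptance.py` run the benchmark at full
generation size (2000 × 500 bp) but with B = 100 null sets, and average
headline values over 5 simulation seeds; the calibration check uses
50-sequence × 100 bp sets over 50 repetitions. These sizes keep a complete
run within minutes on one CPU while leaving the MIM point estimate
unbiased (B affects only the variance of the estimate and the p-value
resolution).

## Known limitations

* MIM absolute values depend on total window count and on k; compare them
  only within a fixed design, or rely on the p-value.
* The KDE-based p-value is floored at 0.001 regardless of B; it is not an
  extreme-tail method.
* The Bhattacharyya variant's scale is dominated by per-sequence sampling
  variance and is best used for rank/significance concordance only.
* The genome null loads the genome index per replicate draw and is the
  slowest generator; it is intended for peak-set-sized inputs, not
  genome-wide scans.
* Gapped k-mers, dinucleotide-preserving shuffles and k > 8 are out of
  scope.
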