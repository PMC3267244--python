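"""The Motif Independent Measure (MIM).

MIM quantifies how specific the sequence content of a set of DNA sequences
is, without reference to any motif model.  The target set is pooled into a
canonical k-mer distribution P; B random sets matched in number and length
of sequences are pooled into distributions Q_1..Q_B; the MIM value is the
average distance d(P, Q_b).  Significance is assessed against the null MIM
distribution — the MIM value each random set itself attains, computed
leave-one-out among the B cached null profiles — via a Gaussian kernel
density estimate of the null; p-values are one-sided (upper tail) and
reported no smaller than 0.001, the resolution limit of the estimated
density.

Ranking the per-k-mer summands of d(P, Q), with Q pooled over all B null
sets, points at the most informative k-mers; for a set with an implanted
motif the top k-mers are substrings of the motif or its reverse complement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator

from . import distances as dist
from .io import SequenceSet
from .kmers import (
    AggregateDistribution,
    PerKmerStats,
    aggregate_distribution,
    enumerate_canonical_kmers,
    per_sequence_stats,
    profile_set,
)
from .nulls import NullSpec, generate_null_set

logger = logging.getLogger(__name__)

P_VALUE_FLOOR = 0.001


@dataclass(frozen=True)
class MIMResult:
    """Outcome of a MIM computation for one metric.

    Attributes
    ----------
    metric : the distance used
    mim : mean distance from the target to the B null profiles
    null_mean, null_sd : location and spread of the null MIM values
    p_value : one-sided upper-tail p, floored at 0.001
    B : number of null sets
    distances_to_nulls : distance from the target to each null profile
    null_mims : leave-one-out MIM value of each null set
    """

    metric: str
    mim: float
    null_mean: float
    null_sd: float
    p_value: float
    B: int
    distances_to_nulls: np.ndarray
    null_mims: np.ndarray

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "mim": self.mim,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "p_value": self.p_value,
            "B": self.B,
            "distances_to_nulls": self.distances_to_nulls.tolist(),
            "null_mims": self.null_mims.tolist(),
        }


@dataclass(frozen=True)
class KmerRanking:
    """Canonical k-mers ordered by decreasing contribution to the distance
    between the target and the pooled null distribution."""

    metric: str
    entries: tuple[tuple[str, float], ...]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("kmer\tcontribution\n")
            for kmer, value in self.entries:
                fh.write(f"{kmer}\t{value:.6g}\n")

    def top(self, n: int) -> list[str]:
        return [kmer for kmer, _ in self.entries[:n]]


def estimate_pvalue(observed: float, null_values: np.ndarray) -> float:
    """Upper-tail p-value of ``observed`` under a Gaussian-kernel density
    (Silverman bandwidth) fitted to ``null_values``, floored at 0.001.

    A degenerate null (all values identical) falls back to the empirical
    rank p-value ``(1 + #{null >= observed}) / (1 + B)``.
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size < 10:
        raise ValueError("need at least 10 null values to estimate a p-value")
    if np.ptp(null_values) == 0.0:
        p = (1.0 + (null_values >= observed).sum()) / (1.0 + null_values.size)
    else:
        kde = gaussian_kde(null_values, bw_method="silverman")
        p = float(kde.integrate_box_1d(observed, np.inf))
    return float(min(max(p, P_VALUE_FLOOR), 1.0))


def _loo_means(D: np.ndarray) -> np.ndarray:
    """Leave-one-out row means of a symmetric distance matrix with zero
    diagonal: entry b is the mean distance of null b to every other null."""
    B = D.shape[0]
    return D.sum(axis=1) / (B - 1)


class _NullProfiles:
    """Cached pooled distributions (and per-sequence stats) of B null sets."""

    def __init__(
        self,
        target: SequenceSet,
        spec: NullSpec,
        k: int,
        pseudocount: float,
        need_stats: bool,
    ):
        index = enumerate_canonical_kmers(k)
        m = index.size
        B = spec.B
        self.index = index
        self.probs = np.empty((B, m))
        self.means = np.empty((B, m)) if need_stats else None
        self.vars = np.empty((B, m)) if need_stats else None
        self.pooled_counts = np.zeros(m, dtype=np.int64)
        # streaming sums of per-sequence relative frequencies across all
        # null sequences, for pooled Bhattacharyya stats
        self._s1 = np.zeros(m)
        self._s2 = np.zeros(m)
        self._rows = 0
        for b in range(B):
            null_set = generate_null_set(target, spec, replicate=b)
            fm = profile_set(null_set, index)
            self.probs[b] = aggregate_distribution(fm, pseudocount).probs
            self.pooled_counts += fm.counts.sum(axis=0)
            if need_stats:
                st = per_sequence_stats(fm)
                self.means[b], self.vars[b] = st.means, st.variances
                rel = fm.relative()
                self._s1 += rel.sum(axis=0)
                self._s2 += (rel**2).sum(axis=0)
                self._rows += fm.n
            if (b + 1) % 100 == 0:
                logger.info("profiled %d/%d null sets", b + 1, B)
        self.pseudocount = pseudocount

    def pooled_aggregate(self) -> AggregateDistribution:
        total = self.pooled_counts.astype(float) + self.pseudocount
        return AggregateDistribution(self.index, total / total.sum(), self.pseudocount)

    def pooled_stats(self) -> PerKmerStats:
        n = self._rows
        mean = self._s1 / n
        var = (self._s2 - n * mean**2) / (n - 1)
        return PerKmerStats(self.index, mean, np.maximum(var, 0.0))


def _evaluate_metric(
    metric: str,
    target_probs: np.ndarray,
    target_stats: Optional[PerKmerStats],
    nulls: _NullProfiles,
) -> MIMResult:
    if metric == "symmetric_kl":
        d_obs = dist.rows_symmetric_kl(target_probs, nulls.probs)
        D = dist.pairwise_symmetric_kl(nulls.probs)
    elif metric == "hellinger":
        d_obs = dist.rows_hellinger(target_probs, nulls.probs)
        D = dist.pairwise_hellinger(nulls.probs)
    else:
        d_obs = dist.rows_bhattacharyya(
            target_stats.means, target_stats.variances, nulls.means, nulls.vars
        )
        D = dist.pairwise_bhattacharyya(nulls.means, nulls.vars)
    np.fill_diagonal(D, 0.0)
    null_mims = _loo_means(D)
    mim = float(d_obs.mean())
    if null_mims.size >= 10:
        p_value = estimate_pvalue(mim, null_mims)
    else:
        # too few nulls for a stable KDE: empirical rank p-value
        p_value = float(
            max((1.0 + (null_mims >= mim).sum()) / (1.0 + null_mims.size), P_VALUE_FLOOR)
        )
    return MIMResult(
        metric=metric,
        mim=mim,
        null_mean=float(null_mims.mean()),
        null_sd=float(null_mims.std(ddof=1)),
        p_value=p_value,
        B=nulls.probs.shape[0],
        distances_to_nulls=d_obs,
        null_mims=null_mims,
    )


def _rank_for_metric(
    metric: str,
    target_agg: AggregateDistribution,
    target_stats: Optional[PerKmerStats],
    nulls: _NullProfiles,
) -> KmerRanking:
    if metric == "bhattacharyya":
        contrib = dist.component_contributions(
            target_stats, nulls.pooled_stats(), metric
        )
    else:
        contrib = dist.component_contributions(
            target_agg, nulls.pooled_aggregate(), metric
        )
    kmers = nulls.index.kmers
    # descending contribution, ties broken lexicographically
    order = sorted(range(len(kmers)), key=lambda j: (-contrib[j], kmers[j]))
    entries = tuple((kmers[j], float(contrib[j])) for j in order)
    return KmerRanking(metric=metric, entries=entries)


def compute_mim_multi(
    target: SequenceSet,
    spec: NullSpec,
    metrics: Sequence[str] = ("symmetric_kl",),
    k: int = 4,
    pseudocount: float = 1.0,
    with_ranking: bool = False,
) -> dict[str, MIMResult] | tuple[dict[str, MIMResult], dict[str, KmerRanking]]:
    """Compute MIM for several metrics over one shared collection of null
    sets.  Sharing is free of statistical cost: null replicate b depends only
    on (seed, b), so single-metric runs with the same spec see identical
    nulls."""
    if target.n == 0:
        raise ValueError("target set is empty")
    for metric in metrics:
        dist.validate_metric(metric)
    need_stats = "bhattacharyya" in metrics
    index = enumerate_canonical_kmers(k)
    fm = profile_set(target, index)
    target_agg = aggregate_distribution(fm, pseudocount)
    target_stats = per_sequence_stats(fm) if need_stats and fm.n >= 2 else None
    nulls = _NullProfiles(target, spec, k, pseudocount, need_stats)
    results = {
        metric: _evaluate_metric(metric, target_agg.probs, target_stats, nulls)
        for metric in metrics
    }
    if not with_ranking:
        return results
    rankings = {
        metric: _rank_for_metric(metric, target_agg, target_stats, nulls)
        for metric in metrics
    }
    return results, rankings


def compute_mim(
    target: SequenceSet,
    spec: NullSpec,
    metric: str = "symmetric_kl",
    k: int = 4,
    pseudocount: float = 1.0,
) -> MIMResult:
    """Compute the MIM value, null summary and empirical p-value of a target
    sequence set under one metric.  Reproducible given ``spec.seed``."""
    return compute_mim_multi(target, spec, [metric], k, pseudocount)[metric]


def rank_kmers(
    target: SequenceSet,
    spec: NullSpec,
    metric: str = "symmetric_kl",
    k: int = 4,
    pseudocount: float = 1.0,
) -> KmerRanking:
    """Rank canonical k-mers by their contribution to the distance between
    the target distribution and the aggregate pooled over all B null sets."""
    _, rankings = compute_mim_multi(
        target, spec, [metric], k, pseudocount, with_ranking=True
    )
    return rankings[metric]


class MIM(BaseEstimator):
    """Motif Independent Measure estimator.

    ``fit`` profiles the sequences, generates B matched null sets, and
    computes the MIM value, its empirical p-value and the informative-k-mer
    ranking.  Follows the scikit-learn estimator protocol
    (``get_params`` / ``set_params`` / trailing-underscore attributes).

    Parameters
    ----------
    metric : {"symmetric_kl", "hellinger", "bhattacharyya"}, default "symmetric_kl"
    null : {"background", "shuffle", "genome"}, default "background"
    background_probs : tuple of 4 floats, default uniform
        A/C/G/T probabilities for the background null.
    B : int, default 1000
        Number of null sets.
    k : int, default 4
    pseudocount : float, default 1.0
        Per-k-mer smoothing added when pooling counts into probabilities.
    genome_path : str or None
        Genome FASTA, required for the genome null.
    random_state : int, default 0

    Attributes
    ----------
    result_ : MIMResult
    mim_ : float
    p_value_ : float
    null_mean_, null_sd_ : float
    ranking_ : KmerRanking

    Examples
    --------
    >>> from mimseq import MIM, generate_dataset, SyntheticSpec
    >>> seqs, _ = generate_dataset(SyntheticSpec(epsilon=0.0, n_sequences=100,
    ...                                          length=200, n_implant=50, seed=7))
    >>> est = MIM(B=50, background_probs=(0.15, 0.35, 0.35, 0.15),
    ...           random_state=7).fit(seqs)
    >>> est.p_value_
    0.001
    """

    def __init__(
        self,
        metric: str = "symmetric_kl",
        null: str = "background",
        background_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
        B: int = 1000,
        k: int = 4,
        pseudocount: float = 1.0,
        genome_path: Optional[str] = None,
        random_state: int = 0,
    ):
        self.metric = metric
        self.null = null
        self.background_probs = background_probs
        self.B = B
        self.k = k
        self.pseudocount = pseudocount
        self.genome_path = genome_path
        self.random_state = random_state

    def _null_spec(self) -> NullSpec:
        return NullSpec(
            generator=self.null,
            background_probs=tuple(self.background_probs),
            B=self.B,
            seed=self.random_state,
            genome_path=self.genome_path,
        )

    def fit(self, X, y=None):
        """Compute MIM for a sequence set.

        Parameters
        ----------
        X : SequenceSet or list of str
            The DNA sequences to score.
        """
        target = (
            X
            if isinstance(X, SequenceSet)
            else SequenceSet.from_raw((f"seq_{i}", s) for i, s in enumerate(X))
        )
        results, rankings = compute_mim_multi(
            target,
            self._null_spec(),
            [self.metric],
            k=self.k,
            pseudocount=self.pseudocount,
            with_ranking=True,
        )
        self.result_ = results[self.metric]
        self.ranking_ = rankings[self.metric]
        self.mim_ = self.result_.mim
        self.p_value_ = self.result_.p_value
        self.null_mean_ = self.result_.null_mean
        self.null_sd_ = self.result_.null_sd
        return self
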