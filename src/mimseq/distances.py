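"""Distribution distances between k-mer profiles.

Three distances quantify how far the canonical k-mer distribution of a
target sequence set sits from that of a random set:

* symmetric Kullback-Leibler divergence, in bits — the expected number of
  extra bits needed to code samples from one distribution with a code built
  for the other, averaged over the two directions;
* Hellinger distance — bounded in [0, 1] and a true metric (triangle
  inequality holds);
* Bhattacharyya distance in its univariate-Gaussian form, summed over
  k-mers — built from per-sequence frequency means and variances rather
  than pooled probabilities, so it also sees between-sequence dispersion.

Each distance decomposes as a sum over k-mers; the per-k-mer summands
(:func:`component_contributions`) rank the k-mers by how much signal they
carry.
"""

from __future__ import annotations

import numpy as np

from .kmers import AggregateDistribution, PerKmerStats

METRICS = ("symmetric_kl", "hellinger", "bhattacharyya")

#: variance floor for the Bhattacharyya terms (constant columns)
VAR_FLOOR = 1e-12


def validate_metric(name: str) -> str:
    if name not in METRICS:
        raise ValueError(f"unknown metric {name!r}; expected one of {METRICS}")
    return name


def _check_pair(p, q, cls) -> tuple[np.ndarray, np.ndarray]:
    if not isinstance(p, cls) or not isinstance(q, cls):
        raise TypeError(f"expected a pair of {cls.__name__}")
    if p.index != q.index:
        raise ValueError("distributions are defined on different k-mer indexes")
    if cls is AggregateDistribution:
        return p.probs, q.probs
    return p, q


def _symmetric_kl(p: np.ndarray, q: np.ndarray) -> float:
    return float(_kl_terms(p, q).sum())


def _kl_terms(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    if (p <= 0).any() or (q <= 0).any():
        raise ValueError(
            "symmetric KL requires strictly positive probabilities; "
            "use a positive pseudocount when pooling counts"
        )
    lg = np.log2(p / q)
    return 0.5 * (p * lg - q * lg)


def symmetric_kl(p: AggregateDistribution, q: AggregateDistribution) -> float:
    """Symmetric Kullback-Leibler divergence in bits:
    ``( KL(p||q) + KL(q||p) ) / 2`` with base-2 logarithms."""
    pa, qa = _check_pair(p, q, AggregateDistribution)
    return _symmetric_kl(pa, qa)


def _hellinger(p: np.ndarray, q: np.ndarray) -> float:
    return float(np.sqrt(0.5 * ((np.sqrt(p) - np.sqrt(q)) ** 2).sum()))


def hellinger(p: AggregateDistribution, q: AggregateDistribution) -> float:
    """Hellinger distance ``sqrt( (1/2) sum_j (sqrt p_j - sqrt q_j)^2 )``,
    bounded in [0, 1]; finite on zero entries."""
    pa, qa = _check_pair(p, q, AggregateDistribution)
    return _hellinger(pa, qa)


def _bhattacharyya_terms(
    mp: np.ndarray, vp: np.ndarray, mq: np.ndarray, vq: np.ndarray
) -> np.ndarray:
    vp = np.maximum(vp, VAR_FLOOR)
    vq = np.maximum(vq, VAR_FLOOR)
    s = vp + vq
    return (mp - mq) ** 2 / (4.0 * s) + 0.5 * np.log(s / (2.0 * np.sqrt(vp * vq)))


def bhattacharyya(stats_p: PerKmerStats, stats_q: PerKmerStats) -> float:
    """Gaussian Bhattacharyya distance summed over k-mers.

    Per k-mer j, with per-sequence frequency means mu and variances sigma:
    ``(mu_P - mu_Q)^2 / (4 (sigma_P + sigma_Q))
    + (1/2) ln( (sigma_P + sigma_Q) / (2 sqrt(sigma_P sigma_Q)) )``.
    Variances are floored at ``VAR_FLOOR``.
    """
    sp, sq = _check_pair(stats_p, stats_q, PerKmerStats)
    return float(
        _bhattacharyya_terms(sp.means, sp.variances, sq.means, sq.variances).sum()
    )


def component_contributions(p, q, metric: str) -> np.ndarray:
    """Per-k-mer summands of the chosen distance.

    For ``symmetric_kl`` and ``hellinger``, ``p`` and ``q`` are
    :class:`AggregateDistribution` and the contributions sum to the distance
    (to its square for Hellinger, whose outer square root is not additive).
    For ``bhattacharyya``, ``p`` and ``q`` are :class:`PerKmerStats` and the
    contributions are the per-k-mer Gaussian terms.
    """
    validate_metric(metric)
    if metric == "symmetric_kl":
        pa, qa = _check_pair(p, q, AggregateDistribution)
        return _kl_terms(pa, qa)
    if metric == "hellinger":
        pa, qa = _check_pair(p, q, AggregateDistribution)
        return 0.5 * (np.sqrt(pa) - np.sqrt(qa)) ** 2
    sp, sq = _check_pair(p, q, PerKmerStats)
    return _bhattacharyya_terms(sp.means, sp.variances, sq.means, sq.variances)


# ---------------------------------------------------------------------------
# vectorized batch forms used by the MIM engine (B x m arrays of pooled
# probabilities or per-sequence stats)

def pairwise_symmetric_kl(P: np.ndarray) -> np.ndarray:
    """All-pairs symmetric KL (bits) between the rows of ``P``."""
    logP = np.log2(P)
    h = (P * logP).sum(axis=1)
    cross = P @ logP.T  # cross[a, b] = sum_j P_a log2 P_b
    M = h[:, None] - cross  # KL(a || b)
    return 0.5 * (M + M.T)


def rows_symmetric_kl(p: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Symmetric KL (bits) between one distribution ``p`` and each row of ``Q``."""
    lg = np.log2(p[None, :] / Q)
    return 0.5 * ((p[None, :] * lg).sum(axis=1) - (Q * lg).sum(axis=1))


def pairwise_hellinger(P: np.ndarray) -> np.ndarray:
    S = np.sqrt(P)
    d2 = 0.5 * ((S[:, None, :] - S[None, :, :]) ** 2).sum(axis=2)
    return np.sqrt(d2)


def rows_hellinger(p: np.ndarray, Q: np.ndarray) -> np.ndarray:
    return np.sqrt(0.5 * ((np.sqrt(p)[None, :] - np.sqrt(Q)) ** 2).sum(axis=1))


def pairwise_bhattacharyya(M: np.ndarray, V: np.ndarray) -> np.ndarray:
    """All-pairs Gaussian Bhattacharyya distance from mean rows ``M`` and
    variance rows ``V``."""
    V = np.maximum(V, VAR_FLOOR)
    s = V[:, None, :] + V[None, :, :]
    num = (M[:, None, :] - M[None, :, :]) ** 2
    terms = num / (4.0 * s) + 0.5 * np.log(
        s / (2.0 * np.sqrt(V[:, None, :] * V[None, :, :]))
    )
    return terms.sum(axis=2)


def rows_bhattacharyya(
    m: np.ndarray, v: np.ndarray, M: np.ndarray, V: np.ndarray
) -> np.ndarray:
    v = np.maximum(v, VAR_FLOOR)
    V = np.maximum(V, VAR_FLOOR)
    s = v[None, :] + V
    terms = (m[None, :] - M) ** 2 / (4.0 * s) + 0.5 * np.log(
        s / (2.0 * np.sqrt(v[None, :] * V))
    )
    return terms.sum(axis=1)
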