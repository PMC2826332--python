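"""Evaluation utilities: modifier-recovery metrics, labeled-partition
tests and q-vector coherence.

``modifier_rank``/``bin_summary`` score the planted-modifier benchmark
(median rank of the true modifier per parameter bin and the fraction of
pairs where it ranks first).  ``labeled_partition_test`` asks whether a
fitted q-vector separates two known sample groups (Wilcoxon rank-sum).
``qvector_coherence`` asks whether q-vectors of pairs sharing a TF agree
more than random vectors do, as expected if the partition reflects TF
activity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .modifiers import ModifierScore
from .mixture import PartitionVector

__all__ = [
    "BinResult",
    "CoherenceResult",
    "modifier_rank",
    "bin_summary",
    "labeled_partition_test",
    "qvector_coherence",
]


@dataclass(frozen=True)
class BinResult:
    """Recovery metrics for one (f, α) benchmark bin."""

    f: float
    alpha: float
    median_rank: float
    top_rank_fraction: float
    n_pairs: int


@dataclass
class CoherenceResult:
    within_tf_taus: np.ndarray
    baseline_taus: np.ndarray
    p_value: float


def modifier_rank(scores: Sequence[ModifierScore], true_id: str) -> float:
    """Rank of the true modifier among the scored candidates.

    Ranks are average-rank over p-value ties; percentile = rank / N.
    """
    for s in scores:
        if s.gene_id == true_id:
            return s.rank
    raise ValueError(f"true modifier {true_id!r} not among scored candidates")


def bin_summary(ranks: Sequence[float], f: float, alpha: float) -> BinResult:
    """Median rank (midpoint convention) and strict top-rank fraction.

    A pair counts toward the top-rank fraction only when the true
    modifier's rank is exactly 1; a tie at the top (rank 1.5) does not.
    """
    r = np.asarray(ranks, dtype=float)
    if r.size == 0:
        raise ValueError("empty rank list")
    return BinResult(
        f=f,
        alpha=alpha,
        median_rank=float(np.median(r)),
        top_rank_fraction=float((r == 1.0).mean()),
        n_pairs=int(r.size),
    )


def labeled_partition_test(q: PartitionVector, labels) -> float:
    """Two-sided Wilcoxon rank-sum p comparing q between two label groups.

    ``labels`` is a boolean/binary vector aligned with q.  A small p
    indicates that the unsupervised soft partition recovers the known
    sample grouping.
    """
    lab = np.asarray(labels)
    if lab.shape != q.q.shape:
        raise ValueError("labels not aligned with partition vector")
    groups = np.unique(lab)
    if len(groups) != 2:
        raise ValueError("labels must define exactly two nonempty groups")
    a = q.q[lab == groups[0]]
    b = q.q[lab == groups[1]]
    if np.ptp(q.q) == 0.0:
        return 1.0  # identical q everywhere: no separation signal
    # exact null distribution for small compendia without ties
    method = (
        "exact"
        if len(q.q) <= 30 and len(np.unique(q.q)) == len(q.q)
        else "auto"
    )
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def qvector_coherence(
    q_vectors_by_tf: Mapping[str, Sequence[np.ndarray]],
    n_random: int = 1000,
    seed: int = 0,
) -> CoherenceResult:
    """Within-TF q-vector agreement versus a random baseline.

    Computes all pairwise Kendall taus between q-vectors sharing a TF, and
    the same number statistics between i.i.d. uniform random vectors of
    matching length (rank statistics make the baseline distribution
    immaterial).  Returns both distributions and a one-sided rank-sum p
    for a positive shift of the within-TF taus.
    """
    lengths = set()
    within = []
    for qs in q_vectors_by_tf.values():
        qs = [np.asarray(q, dtype=float) for q in qs]
        for q in qs:
            lengths.add(len(q))
        for i in range(len(qs)):
            for j in range(i + 1, len(qs)):
                within.append(float(stats.kendalltau(qs[i], qs[j]).statistic))
    if not within:
        raise ValueError("no TF with at least two q-vectors")
    if len(lengths) != 1:
        raise ValueError("q-vectors must share a common length")
    n = lengths.pop()
    rng = np.random.default_rng(seed)
    baseline = np.array(
        [
            float(stats.kendalltau(rng.uniform(size=n), rng.uniform(size=n)).statistic)
            for _ in range(n_random)
        ]
    )
    within = np.asarray(within)
    p = float(stats.mannwhitneyu(within, baseline, alternative="greater").pvalue)
    return CoherenceResult(within, baseline, p)
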