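"""Modifier-gene screening against a soft sample partition.

A candidate modifier is a gene whose expression differs between the
correlated and uncorrelated sample groups.  Because the partition is soft
(a probability q_k per sample), group sizes, means and standard deviations
are computed as q-weighted sums, giving a weighted two-sample t-statistic
that needs no arbitrary threshold on q.  Kendall's tau between q and the
candidate's expression is the non-parametric alternative for small
candidate sets.  Pair-level filters reproduce the screening pipeline:
a Bonferroni-corrected Kendall-tau co-expression prefilter, then windows
on the fitted mixing fraction f and aspect parameter |α|.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, PairData
from .mixture import MixtureFit, PartitionVector

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedMoments",
    "ModifierScore",
    "PairFilterConfig",
    "FilterResult",
    "weighted_moments",
    "weighted_t",
    "kendall_q_correlation",
    "rank_modifiers",
    "filter_pairs",
    "scores_to_frame",
]


@dataclass(frozen=True)
class WeightedMoments:
    """q-weighted group sizes, means and standard deviations.

    Standard deviations use the population convention
    σ_c² = Σ q_k (z_k − μ_c)² / n_c (and symmetrically with weights 1 − q).
    """

    n_c: float
    n_u: float
    mu_c: float
    mu_u: float
    sigma_c: float
    sigma_u: float


@dataclass(frozen=True)
class ModifierScore:
    gene_id: str
    statistic: float
    p_value: float
    p_corrected: float
    rank: float


@dataclass(frozen=True)
class PairFilterConfig:
    """Pair-retention thresholds for the genome-scale screen.

    Defaults are the strict screen (0.45 ≤ f ≤ 0.55, |α| ≥ 0.8 after a
    Bonferroni-corrected Kendall-tau prefilter at 0.05); a looser variant
    widens the f window to [0.3, 0.7].
    """

    tau_alpha: float = 0.05
    f_min: float = 0.45
    f_max: float = 0.55
    alpha_min: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_min <= self.f_max <= 1.0:
            raise ValueError("need 0 <= f_min <= f_max <= 1")
        if not 0.0 <= self.alpha_min <= 1.0:
            raise ValueError("need 0 <= alpha_min <= 1")


@dataclass
class FilterResult:
    retained: list[int]
    stage_counts: dict[str, int]


def _check_aligned(q: PartitionVector, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or len(z) != len(q.q):
        raise ValueError("candidate vector not aligned with partition vector")
    if len(z) < 3:
        raise ValueError("need at least 3 samples")
    return q.q, z


def weighted_moments(q: PartitionVector, z) -> WeightedMoments:
    """Weighted counts, means and standard deviations of both groups."""
    w, z = _check_aligned(q, z)
    n_c = float(w.sum())
    n_u = float(len(w) - n_c)
    if n_c == 0.0 or n_u == 0.0:
        raise ValueError("empty weighted partition (n_c or n_u is zero)")
    mu_c = float((w * z).sum() / n_c)
    mu_u = float(((1.0 - w) * z).sum() / n_u)
    var_c = float((w * (z - mu_c) ** 2).sum() / n_c)
    var_u = float(((1.0 - w) * (z - mu_u) ** 2).sum() / n_u)
    return WeightedMoments(n_c, n_u, mu_c, mu_u, np.sqrt(var_c), np.sqrt(var_u))


def _welch_from_moments(
    n_c: float, n_u: float, mu_c: float, mu_u: float, var_c: float, var_u: float
) -> tuple[float, float]:
    """Welch t and two-sided p from weighted moments.

    Bias-corrected variances s² = σ²·n/(n−1) and Welch–Satterthwaite df
    with the weighted counts in place of hard counts, so a binary q
    reproduces the standard Welch two-sample test exactly.
    """
    if n_c <= 1.0 or n_u <= 1.0:
        raise ValueError("weighted group sizes must exceed 1 for the t-test")
    s2_c = var_c * n_c / (n_c - 1.0)
    s2_u = var_u * n_u / (n_u - 1.0)
    se2 = s2_c / n_c + s2_u / n_u
    diff = mu_c - mu_u
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        warnings.warn("zero variance in both groups with unequal means",
                      RuntimeWarning, stacklevel=3)
        return float(np.sign(diff) * np.inf), 0.0
    t = diff / np.sqrt(se2)
    df = se2**2 / ((s2_c / n_c) ** 2 / (n_c - 1.0) + (s2_u / n_u) ** 2 / (n_u - 1.0))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), p


def weighted_t(q: PartitionVector, z) -> tuple[float, float]:
    """Weighted two-sample t-statistic and two-sided p-value.

    Tests whether the candidate's expression differs between the
    correlated (weights q) and uncorrelated (weights 1 − q) groups.
    """
    m = weighted_moments(q, z)
    return _welch_from_moments(
        m.n_c, m.n_u, m.mu_c, m.mu_u, m.sigma_c**2, m.sigma_u**2
    )


def _weighted_t_matrix(q: np.ndarray, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized weighted t over the rows of Z (genes × samples).

    A collapsed partition (weighted group size ≤ 1, e.g. after a fit with
    f̂ at a boundary) carries no grouping information: every candidate gets
    t = 0, p = 1 instead of an error, so genome-scale screens degrade
    gracefully.
    """
    w = q
    n = Z.shape[1]
    n_c = float(w.sum())
    n_u = float(n - n_c)
    if n_c <= 1.0 or n_u <= 1.0:
        logger.debug("collapsed partition (n_c=%.3g, n_u=%.3g); uninformative scores",
                     n_c, n_u)
        return np.zeros(len(Z)), np.ones(len(Z))
    mu_c = Z @ w / n_c
    mu_u = Z @ (1.0 - w) / n_u
    Z2w = (Z * Z) @ w
    Z2 = (Z * Z).sum(axis=1)
    var_c = Z2w / n_c - mu_c**2
    var_u = (Z2 - Z2w) / n_u - mu_u**2
    s2_c = np.maximum(var_c, 0.0) * n_c / (n_c - 1.0)
    s2_u = np.maximum(var_u, 0.0) * n_u / (n_u - 1.0)
    se2 = s2_c / n_c + s2_u / n_u
    diff = mu_c - mu_u
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / (
            (s2_c / n_c) ** 2 / (n_c - 1.0) + (s2_u / n_u) ** 2 / (n_u - 1.0)
        )
        p = 2.0 * stats.t.sf(np.abs(t), df)
    zero = se2 == 0.0
    t[zero] = np.where(diff[zero] == 0.0, 0.0, np.sign(diff[zero]) * np.inf)
    p[zero] = np.where(diff[zero] == 0.0, 1.0, 0.0)
    return t, p


def kendall_q_correlation(q: PartitionVector, z) -> tuple[float, float]:
    """Kendall tau-b between the partition vector and a candidate's expression.

    Uses the O(n log n) implementation; the p-value is exact for small n
    without ties and a normal approximation otherwise.
    """
    w, z = _check_aligned(q, z)
    if np.ptp(w) == 0.0 or np.ptp(z) == 0.0:
        raise ValueError("Kendall tau undefined for a constant vector")
    res = stats.kendalltau(w, z, method="auto")
    return float(res.statistic), float(res.pvalue)


def rank_modifiers(
    q: PartitionVector,
    m: ExpressionMatrix,
    method: str = "weighted_t",
    exclude: Iterable[str] = (),
) -> list[ModifierScore]:
    """Score and rank every candidate gene of the matrix against q.

    Candidates are all genes not in ``exclude``.  Scores carry two-sided
    p-values, Bonferroni correction by the number of candidates actually
    scored, and average-rank ties; the returned list is sorted by
    ascending p-value.
    """
    if not m.normalized:
        raise ValueError("matrix must be normalized before ranking")
    if list(q.sample_ids) != list(m.sample_ids):
        raise ValueError("partition vector not aligned with matrix samples")
    excl = set(exclude)
    idx = [i for i, g in enumerate(m.gene_ids) if g not in excl]
    if not idx:
        raise ValueError("empty candidate set")
    genes = [m.gene_ids[i] for i in idx]
    if method == "weighted_t":
        t, p = _weighted_t_matrix(q.q, m.values[idx])
        statistic = t
    elif method == "kendall":
        statistic = np.empty(len(idx))
        p = np.empty(len(idx))
        for j, i in enumerate(idx):
            statistic[j], p[j] = kendall_q_correlation(q, m.values[i])
    else:
        raise ValueError(f"unknown method: {method!r}")
    n_cand = len(genes)
    logger.debug("scored %d candidates with Bonferroni factor %d", n_cand, n_cand)
    ranks = stats.rankdata(p, method="average")
    order = np.argsort(p, kind="stable")
    return [
        ModifierScore(
            gene_id=genes[j],
            statistic=float(statistic[j]),
            p_value=float(p[j]),
            p_corrected=float(min(1.0, p[j] * n_cand)),
            rank=float(ranks[j]),
        )
        for j in order
    ]


def scores_to_frame(scores: Sequence[ModifierScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.gene_id, s.statistic, s.p_value, s.p_corrected, s.rank)
            for s in scores
        ],
        columns=["gene_id", "statistic", "p_value", "p_corrected", "rank"],
    )


def filter_pairs(
    fits: Sequence[MixtureFit],
    cfg: PairFilterConfig,
    pairs: Sequence[PairData],
) -> FilterResult:
    """Three-stage pair retention for the genome-scale screen.

    Stage 1 keeps pairs whose x–y Kendall tau passes a Bonferroni-corrected
    threshold (factor = number of pairs tested); stage 2 keeps
    f_min ≤ f̂ ≤ f_max; stage 3 keeps |α̂| ≥ alpha_min.  Returns retained
    indices (into ``fits``) and per-stage counts.
    """
    if len(fits) != len(pairs):
        raise ValueError("fits and pairs must be aligned")
    n = len(fits)
    counts = {"input": n}
    stage1 = []
    for i, pair in enumerate(pairs):
        p_tau = float(stats.kendalltau(pair.x, pair.y, method="auto").pvalue)
        if min(1.0, p_tau * n) <= cfg.tau_alpha:
            stage1.append(i)
    counts["after_tau_prefilter"] = len(stage1)
    stage2 = [i for i in stage1 if cfg.f_min <= fits[i].params.f <= cfg.f_max]
    counts["after_f_window"] = len(stage2)
    stage3 = [i for i in stage2 if abs(fits[i].params.alpha) >= cfg.alpha_min]
    counts["after_alpha_threshold"] = len(stage3)
    logger.info("pair filter stage counts: %s", counts)
    return FilterResult(retained=stage3, stage_counts=counts)
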