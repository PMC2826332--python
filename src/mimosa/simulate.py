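"""Synthetic TF–Gene–Modifier triplets with planted sample partitions.

Each triplet consists of a modifier M, a TF X and a target gene Y over
``n_samples`` expression samples.  M and X are i.i.d. standard normal.
A threshold m* = Φ⁻¹(f) splits the samples: where the modifier expression
m_k < m* the target is drawn standard normal (uncorrelated group, an
expected fraction f of samples); where m_k ≥ m* it is drawn from
N(−α·x_k, 1 − α²), the conditional p_c(y|x) of the correlated mixture
component.  Fitting the co-expression mixture to (X, Y) should therefore
recover (f, α), and the modifier is the gene whose expression tracks the
partition.

The benchmark generator tiles a grid of (f, α) bins with independent
triplets, assembles one genes × samples matrix (rows z-scored afterwards,
as for real data) and a truth table mapping each TF–Gene pair to its
planted modifier and bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, normalize_rows
from .mixture import ALPHA_CLAMP

__all__ = [
    "DEFAULT_F_GRID",
    "DEFAULT_ALPHA_GRID",
    "TripletSpec",
    "SyntheticTriplet",
    "alpha_from_aspect_ratio",
    "modifier_threshold",
    "generate_triplet",
    "generate_benchmark",
]

#: mixing fractions of the benchmark grid
DEFAULT_F_GRID: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 0.9)
#: aspect parameters of the benchmark grid (aspect ratios 2, 3 and 5)
DEFAULT_ALPHA_GRID: tuple[float, ...] = (0.6, 0.8, 0.923)


def alpha_from_aspect_ratio(r: float) -> float:
    """|α| = (r² − 1)/(r² + 1) for an aspect ratio r = σ_v/σ_u ≥ 1."""
    if r < 1.0:
        raise ValueError("aspect ratio must be >= 1")
    return (r * r - 1.0) / (r * r + 1.0)


def modifier_threshold(f: float) -> float:
    """Modifier-expression threshold m* = Φ⁻¹(f).

    Chosen so that a fraction f of standard-normal modifier values fall
    below threshold, i.e. an expected fraction f of samples is
    uncorrelated.
    """
    if not 0.0 < f < 1.0:
        raise ValueError(f"f must be in (0, 1), got {f}")
    return float(stats.norm.ppf(f))


@dataclass(frozen=True)
class TripletSpec:
    """Generative parameters of one TF–Gene–Modifier triplet."""

    f: float
    alpha: float
    n_samples: int
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 < self.f < 1.0:
            raise ValueError(f"f must be in (0, 1), got {self.f}")
        if not 0.0 < abs(self.alpha) <= ALPHA_CLAMP:
            raise ValueError(f"need 0 < |alpha| <= {ALPHA_CLAMP}, got {self.alpha}")
        if self.n_samples < 10:
            raise ValueError("need at least 10 samples")


@dataclass
class SyntheticTriplet:
    """One generated triplet plus its planted ground truth."""

    modifier_expr: np.ndarray
    tf_expr: np.ndarray
    gene_expr: np.ndarray
    m_star: float
    correlated_mask: np.ndarray
    spec: TripletSpec


def _draw_triplet(spec: TripletSpec, rng: np.random.Generator) -> SyntheticTriplet:
    m_star = modifier_threshold(spec.f)
    m = rng.standard_normal(spec.n_samples)
    x = rng.standard_normal(spec.n_samples)
    mask = m >= m_star
    y = np.empty(spec.n_samples)
    y[~mask] = rng.standard_normal(int((~mask).sum()))
    resid = rng.standard_normal(int(mask.sum()))
    y[mask] = -spec.alpha * x[mask] + np.sqrt(1.0 - spec.alpha**2) * resid
    return SyntheticTriplet(m, x, y, m_star, mask, spec)


def generate_triplet(spec: TripletSpec) -> SyntheticTriplet:
    """Generate one triplet, reproducibly from ``spec.seed``."""
    return _draw_triplet(spec, np.random.default_rng(spec.seed))


def generate_benchmark(
    f_values=DEFAULT_F_GRID,
    alpha_values=DEFAULT_ALPHA_GRID,
    triplets_per_bin: int = 100,
    n_samples: int = 300,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate the full planted-modifier benchmark.

    Returns a normalized expression matrix of
    ``3 × triplets_per_bin × (len(f_values)·len(alpha_values))`` unique
    genes × ``n_samples`` samples, and a truth table with columns
    ``pair_id, tf_id, gene_id, modifier_id, f, alpha, bin``.

    Gene identifiers encode bin and role (``b<bin>_t<trip>_{M,F,G}``) so
    truth joins never rely on row order.  Per-triplet random streams are
    derived from ``(seed, bin, triplet)`` so enlarging ``triplets_per_bin``
    never reshuffles earlier triplets.
    """
    bins = [(a, f) for a in alpha_values for f in f_values]
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    truth: list[dict] = []
    for b, (alpha, f) in enumerate(bins):
        for t in range(triplets_per_bin):
            stream = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(b, t))
            )
            spec = TripletSpec(f=f, alpha=alpha, n_samples=n_samples, seed=0)
            trip = _draw_triplet(spec, stream)
            stem = f"b{b:02d}_t{t:03d}"
            gene_ids += [f"{stem}_M", f"{stem}_F", f"{stem}_G"]
            rows += [trip.modifier_expr, trip.tf_expr, trip.gene_expr]
            truth.append(
                {
                    "pair_id": stem,
                    "tf_id": f"{stem}_F",
                    "gene_id": f"{stem}_G",
                    "modifier_id": f"{stem}_M",
                    "f": f,
                    "alpha": alpha,
                    "bin": b,
                }
            )
    sample_ids = [f"s{k:04d}" for k in range(n_samples)]
    matrix = ExpressionMatrix(gene_ids, sample_ids, np.vstack(rows))
    return normalize_rows(matrix), pd.DataFrame(truth)
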