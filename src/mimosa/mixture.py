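"""Two-component mixture model of gene-pair co-expression.

A pair's observations ``(x_k, y_k)`` (both z-scored) are modelled as a
mixture of an *uncorrelated* component — the product of two standard
normals,

    p_u(x, y) = exp(-(x² + y²)/2) / (2π),

and a *correlated* component built by rotating an axis-aligned Gaussian
through θ = ±π/4.  Requiring unit marginal variances fixes the axis
variances to σ_u² = 1 − |α| and σ_v² = 1 + |α|, leaving a single aspect
parameter α ∈ (−1, 1): α < 0 gives positively correlated data (θ = π/4),
α > 0 negatively correlated data (θ = −π/4), and the component is exactly
the unit-variance bivariate normal with correlation ρ = −α.  The mixing
fraction ``f`` is the fraction of samples drawn from the uncorrelated
component.  The model is fitted per pair by direct numerical maximum
likelihood, and the posterior probability that each sample belongs to the
correlated group yields a soft sample partition (the q-vector).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit, logit

from .expression import PairData

__all__ = [
    "ALPHA_CLAMP",
    "MixtureParams",
    "MixtureFit",
    "PartitionVector",
    "FitConfig",
    "uncorrelated_density",
    "correlated_density",
    "mixture_loglik",
    "fit_mixture",
    "partition_probabilities",
    "llr_statistic",
    "permutation_null_llr",
]

_LOG2PI = float(np.log(2.0 * np.pi))

#: |α| is kept strictly below 1 to avoid the degenerate σ_u = 0 component.
ALPHA_CLAMP = 1.0 - 1e-6


@dataclass(frozen=True)
class MixtureParams:
    """Mixture parameters (f, α).

    f is the mixing fraction of uncorrelated samples, α the aspect
    parameter of the correlated component.
    """

    f: float
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must be in [0, 1], got {self.f}")
        if abs(self.alpha) > ALPHA_CLAMP:
            raise ValueError(
                f"|alpha| must be <= {ALPHA_CLAMP} (degenerate otherwise), "
                f"got {self.alpha}"
            )

    @property
    def sigma_u2(self) -> float:
        return 1.0 - abs(self.alpha)

    @property
    def sigma_v2(self) -> float:
        return 1.0 + abs(self.alpha)

    @property
    def theta(self) -> float:
        """Rotation angle of the correlated component's long axis."""
        return np.pi / 4 if self.alpha < 0 else -np.pi / 4

    @property
    def aspect_ratio(self) -> float:
        """r = σ_v/σ_u ≥ 1; |α| = (r² − 1)/(r² + 1)."""
        return float(np.sqrt(self.sigma_v2 / self.sigma_u2))


@dataclass
class MixtureFit:
    """Result of maximum-likelihood fitting of one gene pair."""

    params: MixtureParams
    loglik: float
    converged: bool
    n_restarts_used: int
    loglik_null_f0: float
    alpha_null: float
    #: at α ≈ 0 both components coincide and f is unidentifiable
    degenerate: bool = field(default=False)
    #: parameters used for partitioning/screening: the ML estimate when its
    #: partition is usable, otherwise the best restart optimum with
    #: |α| above the degeneracy threshold and f away from the boundaries
    partition_params: MixtureParams | None = field(default=None)

    def __post_init__(self) -> None:
        if self.partition_params is None:
            self.partition_params = self.params


@dataclass
class PartitionVector:
    """Per-sample posterior probabilities of the correlated group."""

    q: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 1 or len(self.q) != len(self.sample_ids):
            raise ValueError("q and sample_ids must be aligned 1-d")
        if (self.q < -1e-12).any() or (self.q > 1 + 1e-12).any():
            raise ValueError("partition probabilities must lie in [0, 1]")
        self.q = np.clip(self.q, 0.0, 1.0)


@dataclass(frozen=True)
class FitConfig:
    """Numerical settings for the likelihood maximization.

    The likelihood is maximized over an unconstrained reparameterization
    f = logistic(a), α = tanh(b) with L-BFGS-B and an analytic gradient,
    restarted from a small grid of (f₀, α₀) combinations (the surface is
    multimodal in the sign of α) plus one start informed by the nested
    f = 0 fit.
    """

    f_starts: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 0.9)
    alpha_starts: tuple[float, ...] = (-0.8, -0.4, 0.4, 0.8)
    gtol: float = 1e-6
    max_iter: int = 500
    min_samples: int = 10
    degenerate_threshold: float = 0.05
    #: f window outside which a fit is treated as a boundary collapse
    #: (essentially all samples assigned to one component)
    f_usable_min: float = 0.02
    f_usable_max: float = 0.98


def uncorrelated_density(x, y):
    """Standard bivariate normal density of the uncorrelated component."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.exp(-(x * x + y * y) / 2.0) / (2.0 * np.pi)


def correlated_density(x, y, alpha: float):
    """Density of the correlated component.

    Constructed by rotation: u = x cosθ − y sinθ, v = x sinθ + y cosθ with
    independent zero-mean Gaussians of variance σ_u² = 1 − |α| and
    σ_v² = 1 + |α| (unit Jacobian).  Equals the unit-variance bivariate
    normal with correlation ρ = −α.
    """
    if abs(alpha) > ALPHA_CLAMP:
        raise ValueError(f"|alpha| must be <= {ALPHA_CLAMP}, got {alpha}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    theta = np.pi / 4 if alpha < 0 else -np.pi / 4
    su2 = 1.0 - abs(alpha)
    sv2 = 1.0 + abs(alpha)
    u = x * np.cos(theta) - y * np.sin(theta)
    v = x * np.sin(theta) + y * np.cos(theta)
    return np.exp(-u * u / (2 * su2) - v * v / (2 * sv2)) / (
        2.0 * np.pi * np.sqrt(su2 * sv2)
    )


def mixture_loglik(pair: PairData, params: MixtureParams) -> float:
    """Log likelihood Σ_k log[f·p_u(x_k,y_k) + (1−f)·p_c(x_k,y_k)]."""
    pu = uncorrelated_density(pair.x, pair.y)
    pc = correlated_density(pair.x, pair.y, params.alpha)
    return float(np.log(params.f * pu + (1.0 - params.f) * pc).sum())


def _neg_loglik_and_grad(theta, sx, sy, xy, pu):
    """Negative log likelihood and gradient in (a, b) coordinates.

    Uses the closed bivariate-normal form of the correlated component with
    ρ = −tanh(b); f = logistic(a).
    """
    a, b = theta
    f = expit(a)
    alpha = np.clip(np.tanh(b), -ALPHA_CLAMP, ALPHA_CLAMP)
    rho = -alpha
    c = 1.0 - rho * rho
    Q = sx - 2.0 * rho * xy + sy
    pc = np.exp(-_LOG2PI - 0.5 * np.log(c) - Q / (2.0 * c))
    # floor guards against joint underflow at f ~ 0, |alpha| ~ 1
    p = np.maximum(f * pu + (1.0 - f) * pc, 1e-300)
    with np.errstate(over="ignore"):
        nll = -float(np.log(p).sum())
        dl_df = float(((pu - pc) / p).sum())
        dlogpc_drho = rho / c + (xy * c - rho * Q) / (c * c)
        dl_dalpha = -float(((1.0 - f) * pc * dlogpc_drho / p).sum())
        grad = np.array(
            [-dl_df * f * (1.0 - f), -dl_dalpha * (1.0 - alpha * alpha)]
        )
    grad[~np.isfinite(grad)] = 0.0
    return nll, grad


def _fit_null_alpha(sx, sy, xy, n: int) -> tuple[float, float]:
    """MLE of α in the nested f = 0 model (all samples correlated)."""

    def nll(b: float) -> float:
        rho = -np.clip(np.tanh(b), -ALPHA_CLAMP, ALPHA_CLAMP)
        c = 1.0 - rho * rho
        return n * (_LOG2PI + 0.5 * np.log(c)) + float(
            ((sx - 2.0 * rho * xy + sy) / (2.0 * c)).sum()
        )

    res = optimize.minimize_scalar(nll, bounds=(-8.0, 8.0), method="bounded")
    return float(np.tanh(res.x)), -float(res.fun)


def _fit_bounded_signed(sx, sy, xy, pu, alpha_sign: float, cfg: "FitConfig"):
    """Likelihood maximization constrained to a usable, sign-consistent box.

    Fallback when every unconstrained restart collapses to a degenerate or
    boundary optimum: f is boxed inside the usable window and α to the
    sign identified by the overall correlation, |α| above the degeneracy
    threshold.
    """
    b_lo = float(np.arctanh(cfg.degenerate_threshold))
    b_hi = float(np.arctanh(ALPHA_CLAMP))
    bounds = [
        (float(logit(cfg.f_usable_min)), float(logit(cfg.f_usable_max))),
        (b_lo, b_hi) if alpha_sign > 0 else (-b_hi, -b_lo),
    ]
    start = np.array([0.0, alpha_sign * float(np.arctanh(0.4))])
    return optimize.minimize(
        _neg_loglik_and_grad,
        start,
        args=(sx, sy, xy, pu),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": cfg.max_iter, "gtol": cfg.gtol},
    )


def fit_mixture(pair: PairData, config: FitConfig | None = None) -> MixtureFit:
    """Fit (f, α) by maximum likelihood with grid restarts.

    Also fits the nested f = 0 model (only α free) whose likelihood feeds
    the log-likelihood-ratio diagnostic.  Returns the best local optimum
    over all restarts; if no restart reports convergence the best-seen
    parameters are still returned with ``converged=False``.

    In the weak-signal regime the likelihood maximum can be *degenerate*
    (α̂ ≈ 0, where the two components coincide and f is unidentifiable) or
    collapse to an f boundary (q nearly constant).  Such optima carry no
    partition information, so the fit also records ``partition_params``,
    used by the screening pipeline: the best restart optimum whose
    partition is *usable* (|α| above the degeneracy threshold, f inside
    the usable window), preferring optima whose α sign is consistent with
    the pair's overall correlation — marginally cov(x, y) = −(1−f)α, so
    the sign of α is identified by the sign of the empirical correlation.
    If no restart is usable, a bounded sign-consistent fit is used.  When
    the ML estimate itself is usable and sign-consistent the two coincide.
    """
    cfg = config or FitConfig()
    if pair.n_samples < cfg.min_samples:
        raise ValueError(
            f"need at least {cfg.min_samples} samples, got {pair.n_samples}"
        )
    x, y = pair.x, pair.y
    sx, sy, xy = x * x, y * y, x * y
    pu = np.exp(-_LOG2PI - (sx + sy) / 2.0)

    alpha_null, ll_null = _fit_null_alpha(sx, sy, xy, pair.n_samples)

    starts = [
        (float(logit(f0)), float(np.arctanh(a0)))
        for f0 in cfg.f_starts
        for a0 in cfg.alpha_starts
    ]
    # extra restart near the nested optimum guarantees loglik >= loglik_null_f0
    starts.append((float(logit(1e-3)), float(np.arctanh(alpha_null))))

    def usable(f: float, alpha: float) -> bool:
        return (
            abs(alpha) >= cfg.degenerate_threshold
            and cfg.f_usable_min <= f <= cfg.f_usable_max
        )

    # sign of alpha identified by the overall correlation: cov = -(1-f)*alpha
    with np.errstate(invalid="ignore"):
        alpha_sign = -float(np.sign(np.corrcoef(x, y)[0, 1]))

    best = None
    best_usable = None
    best_signed = None
    any_converged = False
    for s in starts:
        res = optimize.minimize(
            _neg_loglik_and_grad,
            np.asarray(s),
            args=(sx, sy, xy, pu),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": cfg.max_iter, "gtol": cfg.gtol},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
        if usable(float(expit(res.x[0])), float(np.tanh(res.x[1]))):
            if best_usable is None or res.fun < best_usable.fun:
                best_usable = res
            if float(np.sign(np.tanh(res.x[1]))) == alpha_sign and (
                best_signed is None or res.fun < best_signed.fun
            ):
                best_signed = res
    f_hat = float(expit(best.x[0]))
    alpha_hat = float(np.clip(np.tanh(best.x[1]), -ALPHA_CLAMP, ALPHA_CLAMP))
    loglik = -float(best.fun)
    if loglik < ll_null:
        # the nested boundary point f = 0 is an admissible candidate and
        # can dominate when the optimizer stalls near the boundary
        f_hat, alpha_hat, loglik = 0.0, alpha_null, ll_null
    params = MixtureParams(f_hat, alpha_hat)

    chosen = best_signed if best_signed is not None else best_usable
    if chosen is None and alpha_sign != 0.0:
        chosen = _fit_bounded_signed(sx, sy, xy, pu, alpha_sign, cfg)
    if chosen is None:
        partition_params = params
    else:
        partition_params = MixtureParams(
            float(expit(chosen.x[0])),
            float(np.clip(np.tanh(chosen.x[1]), -ALPHA_CLAMP, ALPHA_CLAMP)),
        )
    return MixtureFit(
        params=params,
        loglik=loglik,
        converged=any_converged,
        n_restarts_used=len(starts),
        loglik_null_f0=ll_null,
        alpha_null=alpha_null,
        degenerate=abs(alpha_hat) < cfg.degenerate_threshold,
        partition_params=partition_params,
    )


def partition_probabilities(pair: PairData, params: MixtureParams) -> PartitionVector:
    """Posterior probability q_k that sample k is in the correlated group.

    q_k = (1−f)·p_c(x_k,y_k) / [f·p_u(x_k,y_k) + (1−f)·p_c(x_k,y_k)].
    f = 0 forces q ≡ 1; f = 1 forces q ≡ 0.
    """
    pu = uncorrelated_density(pair.x, pair.y)
    pc = correlated_density(pair.x, pair.y, params.alpha)
    num = (1.0 - params.f) * pc
    q = num / (params.f * pu + num) if params.f < 1.0 else np.zeros_like(pu)
    return PartitionVector(q, list(pair.sample_ids))


def llr_statistic(fit: MixtureFit) -> float:
    """2·(L_full − L_{f=0}): the log-likelihood-ratio diagnostic.

    Nonnegative up to numerical tolerance (the f = 0 model is nested).
    Its null distribution is empirically non-χ²; use
    :func:`permutation_null_llr` for an empirical reference.
    """
    return 2.0 * (fit.loglik - fit.loglik_null_f0)


def permutation_null_llr(
    pair: PairData,
    n_perm: int,
    seed: int,
    config: FitConfig | None = None,
) -> np.ndarray:
    """LLR statistics after permuting y against x, n_perm times.

    Breaks the x–y dependence while preserving both marginals; seeded and
    reproducible.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty(n_perm)
    for i in range(n_perm):
        perm = PairData(pair.x, rng.permutation(pair.y), list(pair.sample_ids))
        out[i] = llr_statistic(fit_mixture(perm, config))
    return out
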