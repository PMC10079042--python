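"""Bayesian log-binomial two-group risk-ratio inference.

The model for a 2x2 epoch-by-event summary is

    a ~ Binomial(n1, p1),   c ~ Binomial(n2, p2)
    log p1 = alpha,         log p2 = alpha + beta

so ``exp(beta)`` is the risk ratio (after vs before).  The log link requires
fitted risks <= 1, i.e. the support constraint ``alpha <= 0`` and
``alpha + beta <= 0``.  Priors: Normal(mu, sigma) on beta — either elicited
from a published risk ratio and confidence interval, or the weakly
informative default Normal(0, 10) — and a Student-t(df=3) prior on the
intercept alpha, centred by default at the log pooled risk.

Posteriors are sampled by adaptive random-walk Metropolis (component-wise
Gaussian proposals, adaptation confined to burn-in so the post-burn-in
chains satisfy detailed balance) and cross-checked against a deterministic
two-dimensional grid-integration oracle.  Also here: the posterior
probability of risk reduction via a normal density fitted to the log-RR
draws, a single-event correction for zero cells, and the number needed to
scan with its Wald interval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .cohort import CohortSummary

logger = logging.getLogger(__name__)

#: Standard-normal 97.5% quantile used for all CI <-> sigma conversions.
Z975 = 1.959964

_FLAVOURS = ("informative", "weakly_informative", "improper_flat")


@dataclass(frozen=True)
class RRPrior:
    """Normal prior on the log risk ratio plus intercept-prior settings.

    ``intercept_location=None`` means "centre the intercept prior at the log
    pooled risk of the data being fitted" (resolved at fit time).  Flavour
    ``improper_flat`` ignores (mu, sigma) and places a constant prior on
    beta over the constrained support.
    """

    mu: float
    sigma: float
    intercept_df: int = 3
    intercept_location: float | None = None
    intercept_scale: float = 2.5
    flavour: str = "informative"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.intercept_scale <= 0:
            raise ValueError("intercept_scale must be positive")
        if self.intercept_df < 1:
            raise ValueError("intercept_df must be >= 1")
        if self.flavour not in _FLAVOURS:
            raise ValueError(f"flavour must be one of {_FLAVOURS}")


@dataclass(frozen=True)
class MCMCConfig:
    n_chains: int = 2
    n_iter: int = 1500
    n_burnin: int = 500
    proposal_scales: tuple[float, float] = (0.4, 0.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_iter, self.n_burnin) <= 0:
            raise ValueError("n_chains, n_iter, n_burnin must be positive")
        if min(self.proposal_scales) <= 0:
            raise ValueError("proposal scales must be positive")


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior of the risk ratio: median, equal-tailed 95% credible
    interval, probability of reduction (RR < 1), and sampler diagnostics."""

    rr_median: float
    cri_low: float
    cri_high: float
    prob_reduction: float
    rhat: float
    accept_rate: float
    samples: np.ndarray | None = None  # (n_chains, n_iter, 2) of (alpha, beta)
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.cri_low <= self.rr_median <= self.cri_high:
            raise ValueError("credible interval must bracket the median")
        if not 0.0 <= self.prob_reduction <= 1.0:
            raise ValueError("prob_reduction outside [0, 1]")

    @property
    def beta_draws(self) -> np.ndarray:
        if self.samples is None:
            raise ValueError("no retained draws on this summary")
        return self.samples[..., 1].reshape(-1)

    def to_dict(self) -> dict:
        return {
            "rr_median": self.rr_median,
            "cri_low": self.cri_low,
            "cri_high": self.cri_high,
            "prob_reduction": self.prob_reduction,
            "rhat": self.rhat,
            "accept_rate": self.accept_rate,
            "warnings": list(self.warnings),
        }


def elicit_normal_prior(
    rr_point: float, ci_low: float, ci_high: float, **intercept_kwargs
) -> RRPrior:
    """Normal prior on log-RR from a published point estimate and 95% CI.

    ``mu = ln(rr_point)``; ``sigma`` is the CI width on the log scale divided
    by ``2 * 1.959964``, i.e. the standard error implied by a symmetric
    normal interval.
    """
    if not 0 < ci_low <= rr_point <= ci_high:
        raise ValueError(
            "need 0 < ci_low <= rr_point <= ci_high on the risk-ratio scale"
        )
    return RRPrior(
        mu=math.log(rr_point),
        sigma=(math.log(ci_high) - math.log(ci_low)) / (2.0 * Z975),
        flavour="informative",
        **intercept_kwargs,
    )


def weakly_informative_prior(**intercept_kwargs) -> RRPrior:
    """The default prior for sensitivity ("flat") analyses: Normal(0, 10) on
    log-RR, Student-t(3, log pooled risk, 2.5) on the intercept."""
    return RRPrior(mu=0.0, sigma=10.0, flavour="weakly_informative", **intercept_kwargs)


def zero_event_correction(summary: CohortSummary) -> CohortSummary:
    """Replace any zero event count by a single event (denominator unchanged).

    Risk ratios are inestimable from a zero cell; adding one event to the
    affected group makes the effect estimable.  The returned summary carries
    ``zero_corrected=True`` when the rule fired.
    """
    a, c = summary.events
    if a > 0 and c > 0:
        return summary
    return replace(
        summary,
        events=(max(a, 1), max(c, 1)),
        zero_corrected=True,
    )


# ---------------------------------------------------------------------------
# Log posterior

def _log1mexp(x: float) -> float:
    """log(1 - exp(x)) for x < 0, numerically stable at both ends."""
    if x >= 0.0:
        return -math.inf
    if x > -0.6931471805599453:
        return math.log(-math.expm1(x))
    return math.log1p(-math.exp(x))


def _resolve_intercept_location(summary: CohortSummary, prior: RRPrior) -> float:
    if prior.intercept_location is not None:
        return prior.intercept_location
    a, c = summary.events
    n1, n2 = summary.totals
    pooled = (a + c + 0.5) / (n1 + n2 + 1.0)
    return math.log(pooled)


def _make_logpost(summary: CohortSummary, prior: RRPrior):
    """Closure computing the unnormalised log posterior of (alpha, beta)."""
    a, c = summary.events
    n1, n2 = summary.totals
    mu, sigma = prior.mu, prior.sigma
    improper = prior.flavour == "improper_flat"
    df = float(prior.intercept_df)
    loc = _resolve_intercept_location(summary, prior)
    scale = prior.intercept_scale
    # Student-t normalising constant is fixed; keep it for interpretability.
    t_const = (
        math.lgamma((df + 1.0) / 2.0)
        - math.lgamma(df / 2.0)
        - 0.5 * math.log(df * math.pi)
        - math.log(scale)
    )
    log = math.log
    inv_2s2 = 0.5 / (sigma * sigma)

    def logpost(alpha: float, beta: float) -> float:
        eta2 = alpha + beta
        if alpha > 0.0 or eta2 > 0.0:
            return -math.inf
        ll = a * alpha + c * eta2
        if n1 > a:
            ll += (n1 - a) * _log1mexp(alpha)
        if n2 > c:
            ll += (n2 - c) * _log1mexp(eta2)
        if not improper:
            d = beta - mu
            ll -= d * d * inv_2s2 + log(sigma)
        z = (alpha - loc) / scale
        ll += t_const - (df + 1.0) / 2.0 * math.log1p(z * z / df)
        return ll

    return logpost


def _initial_point(summary: CohortSummary, prior: RRPrior) -> tuple[float, float]:
    a, c = summary.events
    n1, n2 = summary.totals
    p1 = (a + 0.5) / (n1 + 1.0)
    p2 = (c + 0.5) / (n2 + 1.0)
    alpha = math.log(p1)
    beta = math.log(p2) - alpha
    if prior.flavour != "improper_flat":
        # Start inside the prior's bulk so near-degenerate priors still mix.
        lo, hi = prior.mu - 3.0 * prior.sigma, prior.mu + 3.0 * prior.sigma
        beta = min(max(beta, lo), hi)
    if alpha + beta > 0.0:
        alpha = min(alpha, -beta - 1e-6)
    return alpha, beta


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat over per-chain draws, shape (n_chains, n_iter)."""
    m, n = chains.shape
    half = n // 2
    seqs = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    within = seqs.var(axis=1, ddof=1).mean()
    if within == 0.0:
        return 1.0
    between = half * seqs.mean(axis=1).var(ddof=1)
    var_plus = (half - 1) / half * within + between / half
    return float(math.sqrt(var_plus / within))


def fit_logbinomial(
    summary: CohortSummary,
    prior: RRPrior,
    mcmc: MCMCConfig,
    keep_samples: bool = True,
) -> PosteriorSummary:
    """Sample the log-binomial posterior by adaptive random-walk Metropolis.

    Component-wise Gaussian proposals on (alpha, beta); per-coordinate
    proposal scales adapt toward ~35% acceptance during burn-in only, then
    stay fixed.  Chains are pooled after burn-in.  Identical inputs
    (including the seed) give an identical summary.
    """
    logpost = _make_logpost(summary, prior)
    total = mcmc.n_burnin + mcmc.n_iter
    all_draws = np.empty((mcmc.n_chains, mcmc.n_iter, 2))
    accepts = []
    window = 50

    for chain in range(mcmc.n_chains):
        rng = np.random.default_rng([int(mcmc.seed), chain])
        normals = rng.standard_normal((total, 2))
        log_unifs = np.log(rng.random((total, 2)))
        alpha, beta = _initial_point(summary, prior)
        # small seeded jitter to overdisperse chains
        alpha = min(alpha + 0.1 * normals[0, 0], -1e-8)
        if alpha + beta > 0.0:
            beta = -alpha - 1e-8
        current = logpost(alpha, beta)
        if not math.isfinite(current):
            raise RuntimeError("could not find a valid starting point")

        scales = [mcmc.proposal_scales[0], mcmc.proposal_scales[1]]
        win_acc = [0, 0]
        post_acc = 0
        for step in range(total):
            for j in (0, 1):
                if j == 0:
                    prop = logpost(alpha + scales[0] * normals[step, 0], beta)
                else:
                    prop = logpost(alpha, beta + scales[1] * normals[step, 1])
                if log_unifs[step, j] < prop - current:
                    if j == 0:
                        alpha += scales[0] * normals[step, 0]
                    else:
                        beta += scales[1] * normals[step, 1]
                    current = prop
                    win_acc[j] += 1
                    if step >= mcmc.n_burnin:
                        post_acc += 1
            if step < mcmc.n_burnin and (step + 1) % window == 0:
                for j in (0, 1):
                    rate = win_acc[j] / window
                    scales[j] = float(
                        np.clip(scales[j] * math.exp(1.2 * (rate - 0.35)), 1e-9, 10.0)
                    )
                win_acc = [0, 0]
            if step >= mcmc.n_burnin:
                all_draws[chain, step - mcmc.n_burnin] = (alpha, beta)
        accepts.append(post_acc / (2 * mcmc.n_iter))

    accept_rate = float(np.mean(accepts))
    beta_chains = all_draws[:, :, 1]
    rhat = _split_rhat(beta_chains)

    warnings: list[str] = []
    if not 0.1 <= accept_rate <= 0.6:
        msg = f"acceptance rate {accept_rate:.3f} outside [0.1, 0.6] after adaptation"
        warnings.append(msg)
        logger.warning(msg)
    if rhat > 1.05:
        msg = f"convergence warning: split R-hat {rhat:.3f} > 1.05"
        warnings.append(msg)
        logger.warning(msg)

    pooled_beta = beta_chains.reshape(-1)
    rr = np.exp(pooled_beta)
    lo, med, hi = np.percentile(rr, [2.5, 50.0, 97.5])
    return PosteriorSummary(
        rr_median=float(med),
        cri_low=float(lo),
        cri_high=float(hi),
        prob_reduction=posterior_prob_reduction(pooled_beta),
        rhat=rhat,
        accept_rate=accept_rate,
        samples=all_draws if keep_samples else None,
        warnings=tuple(warnings),
    )


def posterior_prob_reduction(beta_draws: np.ndarray) -> float:
    """P(RR < 1): normal density fitted by moments to the log-RR draws,
    evaluated as its cumulative probability below zero."""
    beta_draws = np.asarray(beta_draws, dtype=float)
    if beta_draws.size < 100:
        raise ValueError("need at least 100 retained draws")
    mean = float(beta_draws.mean())
    sd = float(beta_draws.std(ddof=1))
    if sd == 0.0:
        logger.warning("degenerate zero-variance draws; returning 0/1 by sign")
        return 1.0 if mean < 0 else 0.0
    return float(stats.norm.cdf(-mean / sd))


def sensitivity_flat(
    summary: CohortSummary, mcmc: MCMCConfig, improper: bool = False
) -> PosteriorSummary:
    """Sensitivity fit with the weakly-informative default prior.

    ``improper=True`` swaps in a truly flat (constant) prior on the log risk
    ratio over the constrained support.
    """
    prior = weakly_informative_prior()
    if improper:
        prior = replace(prior, flavour="improper_flat")
    return fit_logbinomial(summary, prior, mcmc)


# ---------------------------------------------------------------------------
# Grid-integration oracle

def grid_posterior_oracle(
    summary: CohortSummary, prior: RRPrior, n_grid: int = 801
) -> PosteriorSummary:
    """Deterministic posterior summaries by 2-D quadrature.

    Evaluates the unnormalised posterior on an ``n_grid x n_grid`` lattice
    over the constrained support, normalises numerically, and reads the
    marginal median/2.5%/97.5% of exp(beta) and P(beta < 0) off the marginal
    CDF.  Independent of the sampler; used to validate it.
    """
    a, c = summary.events
    n1, n2 = summary.totals
    p1 = (a + 0.5) / (n1 + 1.0)
    p2 = (c + 0.5) / (n2 + 1.0)
    alpha_hat = math.log(p1)
    beta_hat = math.log(p2) - alpha_hat
    se_a = math.sqrt((1.0 - p1) / (n1 * p1))
    se_b = math.sqrt(se_a**2 + (1.0 - p2) / (n2 * p2))

    loc = _resolve_intercept_location(summary, prior)
    # Centre and scale the grid on a normal approximation to the posterior
    # (precision-weighted combination of likelihood and prior), then take a
    # generous +/- 12 sd window so skew and heavy tails are captured.
    prec_a = 1.0 / se_a**2
    prec_a_prior = 1.0 / (3.0 * prior.intercept_scale**2)  # t3 variance = 3 scale^2
    var_a = 1.0 / (prec_a + prec_a_prior)
    mean_a = (alpha_hat * prec_a + loc * prec_a_prior) * var_a
    alpha_lo = mean_a - 12.0 * math.sqrt(var_a)
    alpha_hi = min(0.0, mean_a + 12.0 * math.sqrt(var_a))

    prec_b = 1.0 / se_b**2
    prec_b_prior = 0.0 if prior.flavour == "improper_flat" else 1.0 / prior.sigma**2
    var_b = 1.0 / (prec_b + prec_b_prior)
    mean_b = (beta_hat * prec_b + prior.mu * prec_b_prior) * var_b
    beta_lo = mean_b - 12.0 * math.sqrt(var_b)
    beta_hi = mean_b + 12.0 * math.sqrt(var_b)

    alpha = np.linspace(alpha_lo, alpha_hi, n_grid)
    beta = np.linspace(beta_lo, beta_hi, n_grid)
    A, B = np.meshgrid(alpha, beta, indexing="ij")
    eta2 = A + B

    with np.errstate(divide="ignore", invalid="ignore"):
        lp = a * A + c * eta2
        lp += (n1 - a) * np.log(-np.expm1(np.minimum(A, -1e-300)))
        lp += (n2 - c) * np.log(-np.expm1(np.minimum(eta2, -1e-300)))
        lp[(A > 0) | (eta2 > 0)] = -np.inf
        if prior.flavour != "improper_flat":
            lp -= 0.5 * ((B - prior.mu) / prior.sigma) ** 2
        lp += stats.t.logpdf(A, df=prior.intercept_df, loc=loc, scale=prior.intercept_scale)

    lp_max = lp.max()
    if not np.isfinite(lp_max):
        raise RuntimeError(
            "grid mass underflow: posterior support not captured; widen or "
            "rescale the grid"
        )
    density = np.exp(lp - lp_max)
    marginal = density.sum(axis=0)
    mass = marginal.sum()
    if mass <= 0 or not np.isfinite(mass):
        raise RuntimeError("grid mass underflow: widen or rescale the grid")
    weights = marginal / mass
    cdf = np.cumsum(weights) - weights / 2.0

    q_lo, q_med, q_hi = np.interp([0.025, 0.5, 0.975], cdf, beta)
    prob_reduction = float(np.interp(0.0, beta, cdf)) if beta[0] < 0 < beta[-1] else (
        1.0 if beta[-1] <= 0 else 0.0
    )
    return PosteriorSummary(
        rr_median=float(math.exp(q_med)),
        cri_low=float(math.exp(q_lo)),
        cri_high=float(math.exp(q_hi)),
        prob_reduction=prob_reduction,
        rhat=math.nan,
        accept_rate=math.nan,
        samples=None,
    )


# ---------------------------------------------------------------------------
# Number needed to scan

def number_needed_to_scan(
    summary: CohortSummary, rounding: str = "nearest"
) -> tuple[int, tuple[int, float]]:
    """Women scanned per undiagnosed breech prevented: ceil(1 / RD).

    RD is the before-minus-after risk difference; its Wald 95% interval
    (``RD +/- 1.959964 * SE``) is inverted to bound the NNS.  The point
    estimate always rounds up; interval endpoints round to the nearest
    integer by default, or outward (wider) with ``rounding="outward"``.
    If the lower RD bound is non-positive the NNS upper bound is infinite.
    """
    if rounding not in {"nearest", "outward"}:
        raise ValueError("rounding must be 'nearest' or 'outward'")
    a, c = summary.events
    n1, n2 = summary.totals
    prisk1, prisk2 = a / n1, c / n2
    rd = prisk1 - prisk2
    if rd <= 0:
        raise ValueError("no reduction; NNS undefined")
    se = math.sqrt(
        prisk1 * (1 - prisk1) / n1 + prisk2 * (1 - prisk2) / n2
    )
    rd_lo = rd - Z975 * se
    rd_hi = rd + Z975 * se
    nns = math.ceil(1.0 / rd)
    lo_exact = 1.0 / rd_hi
    hi_exact = 1.0 / rd_lo if rd_lo > 0 else math.inf
    if rounding == "nearest":
        lo = round(lo_exact)
        hi = round(hi_exact) if math.isfinite(hi_exact) else math.inf
    else:
        lo = math.floor(lo_exact)
        hi = math.ceil(hi_exact) if math.isfinite(hi_exact) else math.inf
    return nns, (int(lo), hi if not math.isfinite(hi_exact) else int(hi))
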