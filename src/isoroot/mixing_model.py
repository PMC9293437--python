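"""Bayesian isotope mixing model for depth-resolved root water uptake.

For each day the model infers the proportions p = (p₁, …, p_K) of tree
water drawn from K soil layers, given the day's xylem δ18O observations
(one per tree), the per-layer source means μ_k and SDs σ_k, and per-layer
water contents c_k that enter as concentration weights.

Model
-----
    p  ~ Dirichlet(α)                 (α from the fine-root depth profile)
    ξ  ~ Uniform(0, ξ_max)            (multiplicative residual factor)
    p′_k = p_k c_k / Σ_j p_j c_j      (concentration adjustment)
    x_i | p, ξ ~ Normal(Σ_k p′_k μ_k,  ξ · Σ_k p′²_k σ²_k)

The likelihood uses a residual × process error structure: the mixture
variance propagated from the source SDs ("process") is scaled by the free
factor ξ ("residual"), which lets the model inflate uncertainty when the
xylem data cannot be explained by any exact mixture of the sources.

Sampling is random-walk Metropolis on the additive log-ratio transform of
the simplex (z ∈ ℝ^{K−1}, p = softmax([z, 0])), with the Jacobian
Σ_k log p_k included in the target density, plus a Gaussian walk on ξ
rejected outside its prior bounds.  The proposal scales adapt towards a
~30 % acceptance rate during burn-in only, leaving the stationary
distribution untouched.  Multiple chains with distinct sub-seeds feed the
Gelman–Rubin convergence diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SourceDay",
    "PriorSpec",
    "MCMCSettings",
    "PosteriorDay",
    "build_prior",
    "concentration_adjust",
    "mixture_moments",
    "fit_day",
    "fit_season",
    "gelman_rubin",
]

#: Floor on the mixture variance (‰²) guarding ξ→0 / σ→0 corners.
VARIANCE_FLOOR = 1e-6


@dataclass(frozen=True)
class SourceDay:
    """Per-layer source summary for one day."""

    date: pd.Timestamp
    mu: np.ndarray  # per-layer mean δ18O, ‰
    sigma: np.ndarray  # per-layer SD, ‰
    concentration: np.ndarray  # per-layer mean VWC, m³ m⁻³
    n: np.ndarray | None = None

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        conc = np.asarray(self.concentration, dtype=float)
        if not (mu.shape == sigma.shape == conc.shape):
            raise ValueError("mu, sigma and concentration must have equal length")
        if np.any(sigma < 0):
            raise ValueError("source SDs must be non-negative")
        if np.any(conc <= 0):
            raise ValueError("source concentrations must be positive")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "concentration", conc)

    @property
    def k(self) -> int:
        return len(self.mu)


@dataclass(frozen=True)
class PriorSpec:
    """Dirichlet prior over source proportions, built from root fractions."""

    alpha: np.ndarray
    root_fractions: np.ndarray
    boundaries: np.ndarray

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=float)
        if np.any(alpha <= 0):
            raise ValueError("all Dirichlet concentrations must be positive")
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "root_fractions", np.asarray(self.root_fractions, dtype=float))
        object.__setattr__(self, "boundaries", np.asarray(self.boundaries, dtype=float))


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler configuration.

    The field-campaign defaults (100 000 iterations, 50 000 burn-in,
    thinning 50, three chains) retain 1000 draws per chain.
    """

    chain_length: int = 100_000
    burn_in: int = 50_000
    thin: int = 50
    n_chains: int = 3
    seed: int = 0
    xi_max: float = 20.0
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if not self.burn_in < self.chain_length:
            raise ValueError("burn_in must be smaller than chain_length")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.xi_max <= 0:
            raise ValueError("xi_max must be positive")


@dataclass(frozen=True)
class PosteriorDay:
    """Posterior over source proportions for one day."""

    date: pd.Timestamp
    draws: np.ndarray  # (n_draws, K) retained p draws, all chains pooled
    xi_draws: np.ndarray  # (n_draws,)
    mean: np.ndarray  # (K,)
    sd: np.ndarray  # (K,)
    rhat: np.ndarray  # (K + 1,) per-layer p then ξ
    converged: bool
    adjusted_mean: np.ndarray | None = None  # concentration-adjusted p′

    def quantiles(self, q: Sequence[float] = (0.025, 0.5, 0.975)) -> np.ndarray:
        """Per-layer posterior quantiles, shape (len(q), K)."""
        return np.quantile(self.draws, q, axis=0)


def build_prior(
    root_profile: Sequence[float],
    boundaries: Sequence[float],
    bin_width: float = 5.0,
) -> PriorSpec:
    """Aggregate a fine-root depth profile into per-layer Dirichlet weights.

    ``root_profile`` gives the fraction of fine-root biomass in successive
    ``bin_width``-cm bins from the surface down; ``boundaries`` partitions
    the same depth range into K layers.  Root mass is assumed uniform
    within a bin, so bins cut by a boundary split linearly.  The layer
    fractions r_k are scaled to α_k = K·r_k, keeping the total prior
    weight Σα = K equal to that of a flat Dirichlet(1, …, 1).
    """
    profile = np.asarray(root_profile, dtype=float)
    bounds = np.asarray(boundaries, dtype=float)
    if abs(profile.sum() - 1.0) > 1e-9:
        raise ValueError(f"root profile must sum to 1, got {profile.sum():.12f}")
    if np.any(np.diff(bounds) <= 0):
        raise ValueError("layer boundaries must be strictly increasing")
    top, bottom = bounds[0], bounds[-1]
    if abs(top - 0.0) > 1e-9 or abs(bottom - bin_width * len(profile)) > 1e-9:
        raise ValueError("boundaries must span the depth range covered by the profile")

    bin_edges = np.arange(len(profile) + 1, dtype=float) * bin_width
    k = len(bounds) - 1
    r = np.zeros(k)
    for i in range(k):
        lo, hi = bounds[i], bounds[i + 1]
        # overlap of [lo, hi) with each uniform-density bin
        overlap = np.clip(np.minimum(hi, bin_edges[1:]) - np.maximum(lo, bin_edges[:-1]), 0.0, None)
        r[i] = float(np.sum(profile * overlap / bin_width))
    r /= r.sum()
    if np.any(r <= 0):
        raise ValueError("a layer received zero root mass; the prior would forbid that source")
    return PriorSpec(alpha=k * r, root_fractions=r, boundaries=bounds)


def concentration_adjust(p: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Concentration-weighted proportions p′_k = p_k c_k / Σ_j p_j c_j."""
    p = np.asarray(p, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.all(c == 0):
        raise ValueError("all concentrations are zero")
    w = p * c
    return w / w.sum(axis=-1, keepdims=True)


def mixture_moments(
    p: np.ndarray,
    sources: SourceDay,
    xi: float = 1.0,
) -> tuple[float, float]:
    """Mixture mean and variance for proportions p under the error model.

    With p′ the concentration-adjusted proportions:
    μ_mix = Σ p′_k μ_k;  σ²_mix = ξ · Σ p′²_k σ²_k.
    """
    if xi < 0:
        raise ValueError("xi must be non-negative")
    p_adj = concentration_adjust(np.asarray(p, dtype=float), sources.concentration)
    mu_mix = float(p_adj @ sources.mu)
    var_mix = float(xi * np.sum(p_adj**2 * sources.sigma**2))
    return mu_mix, var_mix


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale-reduction factor R̂ for one scalar parameter.

    ``chains`` has shape (n_chains, n_draws).  R̂ = √[((n−1)/n·W + B/n)/W]
    with W the mean within-chain variance and B the between-chain variance
    of the chain means (times n).  Reported with the conventional floor of
    1 (identical chains give B = 0 and would otherwise yield √((n−1)/n)).
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("Gelman–Rubin needs at least two chains")
    m, n = arr.shape
    if n < 10:
        raise ValueError("Gelman–Rubin needs at least 10 draws per chain")
    w = float(np.mean(np.var(arr, axis=1, ddof=1)))
    b = float(n * np.var(np.mean(arr, axis=1), ddof=1))
    if w == 0:
        return 1.0
    rhat = np.sqrt(((n - 1) / n * w + b / n) / w)
    return max(1.0, float(rhat))


def _log_posterior(
    z: np.ndarray,
    xi: np.ndarray,
    obs: np.ndarray,
    mu: np.ndarray,
    sigma2: np.ndarray,
    conc: np.ndarray,
    alpha: np.ndarray,
    xi_max: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised log posterior over chains.

    ``z`` has shape (m, K−1) (ALR coordinates), ``xi`` shape (m,).
    Returns (log densities (m,), p (m, K)).
    """
    m = z.shape[0]
    zfull = np.concatenate([z, np.zeros((m, 1))], axis=1)
    zfull -= zfull.max(axis=1, keepdims=True)
    ez = np.exp(zfull)
    p = ez / ez.sum(axis=1, keepdims=True)
    logp_coords = np.log(p)

    # Dirichlet prior density + ALR Jacobian Σ log p_k
    log_prior = (alpha - 1.0) @ logp_coords.T + logp_coords.sum(axis=1)

    w = p * conc
    p_adj = w / w.sum(axis=1, keepdims=True)
    mu_mix = p_adj @ mu
    var_mix = xi * (p_adj**2 @ sigma2)
    var_mix = np.maximum(var_mix, VARIANCE_FLOOR)
    resid2 = (obs[None, :] - mu_mix[:, None]) ** 2
    log_lik = -0.5 * np.sum(resid2 / var_mix[:, None], axis=1) - 0.5 * len(obs) * np.log(
        2.0 * np.pi * var_mix
    )

    logpost = log_prior + log_lik
    logpost[(xi <= 0) | (xi >= xi_max)] = -np.inf
    return logpost, p


def fit_day(
    xylem_obs: Sequence[float],
    sources: SourceDay,
    prior: PriorSpec,
    settings: MCMCSettings = MCMCSettings(),
) -> PosteriorDay:
    """Sample the per-day posterior over source proportions.

    ``xylem_obs`` is the day's per-tree xylem δ18O (‰).  All chains run
    in lockstep with per-chain adaptive random-walk scales (adaptation
    frozen after burn-in); retained draws are pooled across chains after
    burn-in and thinning.
    """
    obs = np.asarray(xylem_obs, dtype=float)
    if obs.size < 1:
        raise ValueError("need at least one xylem observation")
    if not np.all(np.isfinite(obs)):
        raise ValueError("non-finite xylem observation")
    k = sources.k
    if len(prior.alpha) != k:
        raise ValueError("prior and sources disagree on the number of layers")
    if np.all(sources.sigma == 0):
        raise ValueError(
            "all source SDs are zero: the residual factor alone cannot define the "
            "mixture variance; supply a floor SD"
        )
    if not (np.all(np.isfinite(sources.mu)) and np.all(np.isfinite(sources.sigma))):
        raise ValueError("non-finite source summary")

    m = settings.n_chains
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(settings.seed)))
    mu = sources.mu
    sigma2 = sources.sigma**2
    conc = sources.concentration
    alpha = prior.alpha
    xi_max = settings.xi_max

    # over-dispersed starts: prior draws on p, spread ξ starts
    p0 = rng.dirichlet(alpha, size=m)
    z = np.log(p0[:, :-1]) - np.log(p0[:, -1:])
    xi = rng.uniform(0.2, 0.8, size=m) * xi_max

    step_z = np.full(m, 0.5)
    step_xi = np.full(m, 0.5)
    logpost, _ = _log_posterior(z, xi, obs, mu, sigma2, conc, alpha, xi_max)

    n_keep = (settings.chain_length - settings.burn_in) // settings.thin
    kept_p = np.empty((m, n_keep, k))
    kept_xi = np.empty((m, n_keep))
    accepts = np.zeros(m)
    adapt_window = 100
    kept = 0

    for it in range(settings.chain_length):
        z_prop = z + step_z[:, None] * rng.standard_normal((m, k - 1))
        xi_prop = xi + step_xi * rng.standard_normal(m)
        lp_prop, p_prop = _log_posterior(z_prop, xi_prop, obs, mu, sigma2, conc, alpha, xi_max)
        accept = np.log(rng.uniform(size=m)) < lp_prop - logpost
        z[accept] = z_prop[accept]
        xi[accept] = xi_prop[accept]
        logpost[accept] = lp_prop[accept]
        accepts += accept

        if it < settings.burn_in and (it + 1) % adapt_window == 0:
            rate = accepts / adapt_window
            factor = np.exp(np.clip(rate - 0.30, -0.5, 0.5))
            step_z *= factor
            step_xi *= factor
            accepts[:] = 0.0

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0 and kept < n_keep:
            zf = np.concatenate([z, np.zeros((m, 1))], axis=1)
            zf -= zf.max(axis=1, keepdims=True)
            ez = np.exp(zf)
            kept_p[:, kept, :] = ez / ez.sum(axis=1, keepdims=True)
            kept_xi[:, kept] = xi
            kept += 1

    kept_p = kept_p[:, :kept, :]
    kept_xi = kept_xi[:, :kept]

    rhat = np.empty(k + 1)
    if m >= 2 and kept >= 10:
        for j in range(k):
            rhat[j] = gelman_rubin(kept_p[:, :, j])
        rhat[k] = gelman_rubin(kept_xi)
    else:
        rhat[:] = np.nan
    converged = bool(np.all(np.isnan(rhat)) or np.nanmax(rhat) <= settings.rhat_threshold)

    draws = kept_p.reshape(-1, k)
    xi_draws = kept_xi.reshape(-1)
    mean = draws.mean(axis=0)
    sd = draws.std(axis=0, ddof=1)
    adjusted = concentration_adjust(draws, conc).mean(axis=0)
    return PosteriorDay(
        date=sources.date,
        draws=draws,
        xi_draws=xi_draws,
        mean=mean,
        sd=sd,
        rhat=rhat,
        converged=converged,
        adjusted_mean=adjusted,
    )


def fit_season(
    xylem_by_day: dict[pd.Timestamp, Sequence[float]],
    sources_by_day: dict[pd.Timestamp, SourceDay],
    prior: PriorSpec,
    settings: MCMCSettings = MCMCSettings(),
) -> tuple[dict[pd.Timestamp, PosteriorDay], list[pd.Timestamp]]:
    """Independent per-day fits over a season.

    Days lacking either xylem observations or a source summary are
    skipped and returned in the skip report.  Each day gets its own
    deterministic sub-seed derived from ``settings.seed`` and the day's
    ordinal, so results are independent of iteration order.
    """
    posteriors: dict[pd.Timestamp, PosteriorDay] = {}
    skipped: list[pd.Timestamp] = []
    all_days = sorted(set(xylem_by_day) | set(sources_by_day))
    for day in all_days:
        obs = xylem_by_day.get(day)
        src = sources_by_day.get(day)
        if obs is None or src is None or len(obs) == 0:
            skipped.append(day)
            continue
        day_seed = int(
            np.random.SeedSequence([settings.seed, pd.Timestamp(day).toordinal()]).generate_state(1)[0]
            % (2**31)
        )
        day_settings = MCMCSettings(
            chain_length=settings.chain_length,
            burn_in=settings.burn_in,
            thin=settings.thin,
            n_chains=settings.n_chains,
            seed=day_seed,
            xi_max=settings.xi_max,
            rhat_threshold=settings.rhat_threshold,
        )
        posteriors[day] = fit_day(obs, src, prior, day_settings)
    return posteriors, skipped


def posterior_table(posteriors: dict[pd.Timestamp, PosteriorDay]) -> pd.DataFrame:
    """Tidy summary: one row per (date, layer)."""
    rows = []
    for day in sorted(posteriors):
        post = posteriors[day]
        q = post.quantiles()
        for j in range(len(post.mean)):
            rows.append(
                {
                    "date": day,
                    "layer": j,
                    "mean": post.mean[j],
                    "sd": post.sd[j],
                    "q2.5": q[0, j],
                    "q50": q[1, j],
                    "q97.5": q[2, j],
                    "adjusted_mean": post.adjusted_mean[j] if post.adjusted_mean is not None else np.nan,
                    "r_hat": post.rhat[j],
                    "converged": post.converged,
                }
            )
    return pd.DataFrame(rows)
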