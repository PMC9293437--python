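"""Independent numerical oracles for the mixing-model tests.

Brute-force integration over a regular grid on the simplex (K ≤ 3) with
the residual factor ξ on a midpoint grid.  Deliberately shares no code
with the sampler.  The simplex mask keeps a half-step margin away from
the boundary: float roundoff can otherwise admit points with p_k ~ 1e-16
whose α_k < 1 Dirichlet singularity dominates the sum spuriously.
"""

from __future__ import annotations

import numpy as np

VARIANCE_FLOOR = 1e-6


def grid_posterior_mean(
    obs: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    conc: np.ndarray,
    alpha: np.ndarray,
    xi_max: float = 20.0,
    step: float = 0.01,
    n_xi: int = 50,
) -> np.ndarray:
    """Posterior mean of p by direct summation (K = 2 or 3 only)."""
    k = len(mu)
    if k == 2:
        p1 = np.arange(step / 2, 1, step)
        pts = np.stack([p1, 1 - p1], axis=1)
    elif k == 3:
        g = np.arange(step / 2, 1, step)
        a, b = np.meshgrid(g, g)
        mask = (1.0 - a - b) > step / 2 * 0.999
        pts = np.stack([a[mask], b[mask], 1 - a[mask] - b[mask]], axis=1)
    else:
        raise ValueError("grid oracle supports K <= 3 only")

    xi = np.linspace(xi_max / n_xi / 2, xi_max - xi_max / n_xi / 2, n_xi)
    log_prior = (alpha - 1.0) @ np.log(pts).T
    w = pts * conc
    p_adj = w / w.sum(axis=1, keepdims=True)
    mu_mix = p_adj @ mu
    var_proc = p_adj**2 @ sigma**2
    var = np.maximum(np.outer(xi, var_proc), VARIANCE_FLOOR)
    log_lik = np.zeros_like(var)
    for x in np.asarray(obs, dtype=float):
        log_lik += -0.5 * (x - mu_mix[None, :]) ** 2 / var - 0.5 * np.log(2 * np.pi * var)
    log_post = log_lik + log_prior[None, :]
    weight = np.exp(log_post - log_post.max())
    return (weight.sum(axis=0) @ pts) / weight.sum()
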