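"""Likelihood of observed selected/neutral SFS count ratios.

Per-bin counts are Poisson; each is approximated by a gaussian whose mean
and variance both equal the Poisson mean.  The ratio z = X1/X2 of two such
gaussians has the Hinkley / Diaz-Frances-Rubio density.  With numerator
mean beta * M and denominator mean M, writing delta = M**-0.5, the density
depends only on (beta, delta):

    a2   = (z**2 + beta) / (beta * M)
    b    = 1 + z
    c    = M * (1 + beta)
    f(z) = exp(-c/2) * sqrt(beta) / (pi * (z**2 + beta))
         + b * exp(b**2/(2*a2) - c/2) * erf(b / sqrt(2*a2))
           / (sqrt(2*pi*a2) * a2 * M * sqrt(beta))

Here beta = rho * F_g,i / N_i is the expected ratio in bin i (folded bins
use the paired sums) and delta = (N_i * theta)**-0.5 with theta the neutral
mutation parameter.  Both exponents are nonpositive (Cauchy-Schwarz), so
the evaluation cannot overflow even for delta down to 1e-4 and below.

Because theta is a nuisance parameter, the working density integrates
f over a prior uniform in log(theta) across [theta_hat/10, 10*theta_hat],
theta_hat being Watterson's estimate from the neutral spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf, gammaln

from .dfe_models import DFEModel
from .prf_expectations import ExpectationGrid, dfe_bin_expectations
from .sfs_core import SFS, RatioSpectrum

__all__ = [
    "RatioDensityParams",
    "ratio_density",
    "integrated_ratio_density",
    "loglik",
    "poisson_prf_loglik",
    "THETA_GRID_POINTS",
]

#: default number of nodes for the log-theta integration
THETA_GRID_POINTS = 24

_LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class RatioDensityParams:
    """Expected ratio beta, noise scale delta = (N_i * theta)**-0.5, and theta."""

    beta: float
    delta: float
    theta: float

    def __post_init__(self):
        if not (self.beta > 0 and self.delta > 0 and self.theta > 0):
            raise ValueError("beta, delta and theta must all be positive")


def _ratio_normals_pdf(z, beta, M):
    """Density of X1/X2, X1 ~ N(beta*M, beta*M), X2 ~ N(M, M), independent.

    Vectorized over any broadcastable combination of z, beta, M.
    """
    z = np.asarray(z, dtype=float)
    beta = np.asarray(beta, dtype=float)
    M = np.asarray(M, dtype=float)
    q = z * z + beta
    a2 = q / (beta * M)
    b = 1.0 + z
    c = M * (1.0 + beta)
    e2 = b * b / (2.0 * a2) - 0.5 * c  # <= 0
    term1 = np.exp(-0.5 * c) * np.sqrt(beta) / (np.pi * q)
    term2 = (
        b
        * np.exp(e2)
        * erf(b / np.sqrt(2.0 * a2))
        / (np.sqrt(2.0 * np.pi * a2) * a2 * M * np.sqrt(beta))
    )
    out = term1 + term2
    return np.maximum(out, 0.0)


def ratio_density(z, params: RatioDensityParams):
    """Ratio-of-gaussians density of an observed bin ratio z.

    The gaussian pair matched by this parameterization has denominator mean
    M = 1/delta**2 = N_i * theta (and numerator mean beta * M); in practice
    Watterson's theta_hat = S/a_n estimates theta/2 under the
    N_i*theta/2-per-bin counting convention, so M evaluated at theta_hat is
    the actual denominator Poisson mean.
    """
    return _ratio_normals_pdf(z, params.beta, params.delta**-2)


def _theta_nodes_weights(theta_hat: float, G: int):
    """G-point Gauss-Legendre rule for the normalized uniform-in-log prior
    on theta over [theta_hat/10, 10*theta_hat]."""
    lo, hi = np.log(theta_hat / 10.0), np.log(theta_hat * 10.0)
    x, w = np.polynomial.legendre.leggauss(G)
    mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
    return np.exp(mid + half * x), w * half / (hi - lo)


def integrated_ratio_density(
    z: float,
    i: int,
    model: DFEModel,
    rho: float,
    theta_hat: float,
    grid: ExpectationGrid,
    G: int = THETA_GRID_POINTS,
) -> float:
    """Working density p'(z | phi, rho): theta integrated out numerically.

    ``i`` is the 1-based bin index on ``grid`` (folded or unfolded per the
    grid's flag).
    """
    if theta_hat <= 0:
        raise ValueError("theta_hat must be positive")
    fg = dfe_bin_expectations(grid, model)
    beta = rho * fg[i - 1] / grid.N[i - 1]
    thetas, w = _theta_nodes_weights(theta_hat, G)
    M = grid.N[i - 1] * thetas
    return float(np.sum(w * _ratio_normals_pdf(z, beta, M)))


def _integrated_log_density(z, beta, N, theta_hat, G):
    """log p'(z) for vectors of bins; shape (bins,)."""
    thetas, w = _theta_nodes_weights(theta_hat, G)
    M = N[:, None] * thetas[None, :]
    dens = _ratio_normals_pdf(z[:, None], beta[:, None], M)
    p = dens @ w
    return np.log(np.maximum(p, _LOG_FLOOR))


def loglik(
    ratios: RatioSpectrum,
    model: DFEModel,
    rho: float,
    grid: ExpectationGrid,
    G: int = THETA_GRID_POINTS,
    expectations: np.ndarray | None = None,
) -> float:
    """Log-likelihood of the ratio spectrum: sum of log p' over valid bins.

    Bins with a zero selected count are excluded along with the masked
    zero-neutral bins: at an observed count of 0 the gaussian stand-in for
    the Poisson count has already failed, and a z = 0 observation makes the
    ratio density unbounded as beta -> 0 (each zero bin contributes
    ~ -log(beta)/2 while nonzero bins only pay +log(beta), so with enough
    zero bins the "likelihood" diverges at rho -> 0 instead of peaking at
    the truth).  The retained bin set depends only on the data, so nested
    fits remain comparable.

    ``expectations`` may supply a precomputed F_g vector on the grid's bins
    (used by optimizer loops); otherwise it is derived from ``model``.
    """
    if grid.n != ratios.n or grid.folded != ratios.folded:
        raise ValueError("grid does not match the ratio spectrum's n/folded")
    mask = ratios.valid_mask & (ratios.selected_counts > 0)
    if not mask.any():
        raise ValueError("no usable bins: every bin has a zero count")
    fg = dfe_bin_expectations(grid, model) if expectations is None else expectations
    beta = rho * fg / grid.N
    ll = _integrated_log_density(
        ratios.z[mask], beta[mask], grid.N[mask], ratios.theta_hat, G
    )
    return float(ll.sum())


def poisson_prf_loglik(
    counts: SFS,
    model: DFEModel,
    thetaS: float,
    grid: ExpectationGrid,
    expectations: np.ndarray | None = None,
) -> float:
    """Classic WF-PRF Poisson log-likelihood of per-bin counts k_i with
    means F_g,i * thetaS / 2 (for comparison tests against the ratio form)."""
    if grid.n != counts.n or grid.folded != counts.folded:
        raise ValueError("grid does not match the SFS's n/folded")
    fg = dfe_bin_expectations(grid, model) if expectations is None else expectations
    mean = fg * thetaS / 2.0
    k = counts.counts
    return float(np.sum(k * np.log(mean) - mean - gammaln(k + 1.0)))
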