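"""PRF simulator of selected/neutral SFS pairs and test harnesses.

Per-bin counts are independent Poisson draws: neutral means a_i * N_i *
theta / 2 and selected means a_i * F_g,i * rho * theta / 2, where the
optional shared distortion factors a_i stand in for demography and linked
selection (both spectra are multiplied by the same a_i, which is exactly
the regime in which the ratio method is supposed to cancel them).  Folding
is applied after drawing.  All randomness flows from the single config
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.stats import chi2, kstest
from sklearn.metrics import auc, roc_curve

from .dfe_models import DFEModel
from .inference import lrt_neutral
from .prf_expectations import dfe_bin_expectations, get_grid, neutral_expectations
from .ratio_likelihood import THETA_GRID_POINTS
from .sfs_core import SFS, fold, make_ratios

__all__ = [
    "SimConfig",
    "distortion_factors",
    "simulate_pair",
    "power_curve",
    "roc_analysis",
    "null_calibration",
]

DISTORTIONS = ("none", "smooth", "expansion", "bottleneck")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated selected/neutral SFS pair.

    ``rho`` is the true mutation-rate ratio (thetaS = rho * theta).
    ``distortion`` names a shared per-bin factor generator (see
    :func:`distortion_factors`) or may be an explicit positive array.
    """

    n: int
    theta: float
    rho: float = 1.0
    model: DFEModel = field(default_factory=lambda: DFEModel("fixed", {"gamma": 0.0}))
    folded: bool = True
    distortion: object = "none"
    reps: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.theta <= 0 or self.rho <= 0:
            raise ValueError("theta and rho must be positive")


def distortion_factors(kind, n_bins: int, rng) -> np.ndarray:
    """Named shared per-bin distortion factor generators.

    - ``none``: all ones.
    - ``smooth``: seeded log-gaussian, correlated across neighbouring bins.
    - ``expansion``: excess of rare variants (factors rise toward the
      singleton bin), the qualitative signature of population growth.
    - ``bottleneck``: depletion of intermediate-frequency bins.
    """
    if isinstance(kind, np.ndarray) or isinstance(kind, (list, tuple)):
        a = np.asarray(kind, dtype=float)
        if a.size != n_bins or np.any(a <= 0):
            raise ValueError("explicit distortion must give a positive factor per bin")
        return a
    i = np.arange(1, n_bins + 1)
    if kind == "none":
        return np.ones(n_bins)
    if kind == "smooth":
        raw = rng.normal(size=n_bins + 20)
        sm = uniform_filter1d(raw, size=11)[10:-10]
        sm = sm / max(np.std(sm), 1e-12) * 0.5  # log-sd ~ 0.5 -> a_i roughly in [0.2, 5]
        return np.exp(sm)
    if kind == "expansion":
        return 0.5 + 2.5 * np.exp(-6.0 * (i - 1) / n_bins)
    if kind == "bottleneck":
        mid = (n_bins + 1) / 2.0
        return 1.0 - 0.7 * np.exp(-((i - mid) ** 2) / (2.0 * (n_bins / 5.0) ** 2))
    raise ValueError(f"unknown distortion {kind!r} (choose from {DISTORTIONS})")


def _expected_means(config: SimConfig):
    """Unfolded per-bin Poisson means (selected, neutral) incl. distortion."""
    grid = get_grid(config.n, folded=False)
    fg = dfe_bin_expectations(grid, config.model)
    nn = neutral_expectations(config.n, folded=False)
    rng = np.random.default_rng([config.seed, 0x5F])  # distortion stream
    a = distortion_factors(config.distortion, config.n - 1, rng)
    sel = a * fg * config.rho * config.theta / 2.0
    neu = a * nn * config.theta / 2.0
    return sel, neu


def simulate_pair(config: SimConfig, rep: int = 0):
    """Draw one (selected SFS, neutral SFS) pair; folding is post-draw.

    ``rep`` indexes replicates within a config: the Poisson stream is seeded
    by (config.seed, rep) so replicate sets are reproducible element-wise.
    """
    sel_mean, neu_mean = _expected_means(config)
    rng = np.random.default_rng([config.seed, rep])
    sel = SFS(config.n, rng.poisson(sel_mean).astype(float), folded=False, label="selected")
    neu = SFS(config.n, rng.poisson(neu_mean).astype(float), folded=False, label="neutral")
    if config.folded:
        sel, neu = fold(sel), fold(neu)
    return sel, neu


def _lrt_stats(config: SimConfig, reps: int, grid, G: int, n_starts: int):
    stats = np.empty(reps)
    for r in range(reps):
        sel, neu = simulate_pair(config, rep=r)
        ratios = make_ratios(sel, neu)
        res = lrt_neutral(ratios, grid=grid, G=G, n_starts=n_starts, seed=config.seed + r)
        stats[r] = res.stat
    return stats


def power_curve(
    gammas,
    alphas=(0.05, 0.01, 0.001),
    *,
    n: int = 100,
    theta: float = 500.0,
    rho: float = 1.0,
    reps: int = 100,
    seed: int = 0,
    folded: bool = True,
    G: int = THETA_GRID_POINTS,
    n_starts: int = 2,
) -> pd.DataFrame:
    """Rejection fraction of the neutrality LRT per (gamma, alpha)."""
    grid = get_grid(n, folded)
    rows = []
    for j, g in enumerate(gammas):
        config = SimConfig(
            n=n,
            theta=theta,
            rho=rho,
            model=DFEModel("fixed", {"gamma": float(g)}),
            folded=folded,
            seed=seed + 1000 * j,
        )
        stats = _lrt_stats(config, reps, grid, G, n_starts)
        for a in alphas:
            cutoff = chi2.isf(a, 1)
            rows.append(
                {
                    "gamma": float(g),
                    "alpha": a,
                    "power": float(np.mean(stats > cutoff)),
                    "reps": reps,
                }
            )
    return pd.DataFrame(rows)


def roc_analysis(
    *,
    n_null: int = 100,
    n_alt: int = 100,
    gamma_range=(-100.0, 1.0),
    n: int = 100,
    theta: float = 500.0,
    rho: float = 1.0,
    seed: int = 0,
    folded: bool = True,
    G: int = THETA_GRID_POINTS,
    n_starts: int = 2,
):
    """ROC of the LRT statistic: null sims (gamma=0) vs alternative sims
    with gamma drawn uniformly from ``gamma_range``.  Returns
    (DataFrame of ROC points, AUC)."""
    if n_null < 1 or n_alt < 1:
        raise ValueError("both simulation sets must be nonempty")
    grid = get_grid(n, folded)
    rng = np.random.default_rng([seed, 0xA0C])
    null_cfg = SimConfig(n=n, theta=theta, rho=rho, folded=folded, seed=seed)
    null_stats = _lrt_stats(null_cfg, n_null, grid, G, n_starts)
    alt_stats = np.empty(n_alt)
    for r in range(n_alt):
        g = rng.uniform(*gamma_range)
        cfg = SimConfig(
            n=n,
            theta=theta,
            rho=rho,
            model=DFEModel("fixed", {"gamma": float(g)}),
            folded=folded,
            seed=seed + 7_000_000 + r,
        )
        sel, neu = simulate_pair(cfg, rep=0)
        res = lrt_neutral(
            make_ratios(sel, neu), grid=grid, G=G, n_starts=n_starts, seed=seed + r
        )
        alt_stats[r] = res.stat
    labels = np.r_[np.zeros(n_null), np.ones(n_alt)]
    scores = np.r_[null_stats, alt_stats]
    fpr, tpr, _ = roc_curve(labels, scores)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return points, float(auc(fpr, tpr))


def null_calibration(
    *,
    n: int = 100,
    theta: float = 500.0,
    rho: float = 1.0,
    reps: int = 500,
    seed: int = 0,
    folded: bool = True,
    G: int = THETA_GRID_POINTS,
    n_starts: int = 2,
):
    """Null distribution of 2*LLR vs chi-square 1 df.

    Returns (DataFrame with the sorted statistics and their empirical CDF,
    Kolmogorov-Smirnov distance to chi2(1), dict of tail rejection
    fractions at alpha in {0.05, 0.01, 0.001}).
    """
    if reps < 200:
        raise ValueError("null calibration needs at least 200 replicates")
    grid = get_grid(n, folded)
    config = SimConfig(n=n, theta=theta, rho=rho, folded=folded, seed=seed)
    stats = _lrt_stats(config, reps, grid, G, n_starts)
    order = np.sort(stats)
    ecdf = pd.DataFrame(
        {"stat": order, "ecdf": np.arange(1, reps + 1) / reps, "chi2_cdf": chi2.cdf(order, 1)}
    )
    ks = float(kstest(stats, chi2(1).cdf).statistic)
    tails = {a: float(np.mean(stats > chi2.isf(a, 1))) for a in (0.05, 0.01, 0.001)}
    return ecdf, ks, tails
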