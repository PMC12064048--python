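"""Wright-Fisher Poisson-random-field expectations per frequency bin.

Under the equilibrium WF diffusion, derived alleles with scaled selection
coefficient gamma = 2Ns sojourn at population frequency x with density
proportional to

    h(gamma, x) = (1 - exp(-2 gamma (1 - x))) / ((1 - exp(-2 gamma)) x (1 - x))

(the mutation-rate factor is deliberately factored out, so h here is
dimensionless and the neutral limit is h(0, x) = 1/x).  The expected number
of polymorphic sites with i copies in a sample of n is then

    F(gamma)_i = integral_0^1 h(gamma, x) C(n, i) x^i (1-x)^(n-i) dx

with the neutral closed form F(0)_i = 1/i.  Expected counts are
F_i * thetaS / 2.  Integrating F(gamma)_i over a distribution g(gamma) of
fitness effects gives the DFE-averaged expectation; this module caches
F(gamma)_i on a fixed gamma quadrature grid so that DFE fits only
re-evaluate the (cheap) density weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.interpolate import PchipInterpolator
from scipy.special import gammaln

from .dfe_models import DFEModel, dfe_pdf

__all__ = [
    "sojourn_density",
    "bin_expectation",
    "neutral_expectations",
    "build_grid",
    "get_grid",
    "dfe_bin_expectations",
    "ExpectationGrid",
    "GammaInterpolator",
]

_F_FLOOR = 1e-300  # strong-selection bins underflow doubles; keep F > 0
_SERIES_CUTOFF = 1e-6


def _psi(gamma: float, x: np.ndarray) -> np.ndarray:
    """h(gamma, x) * x * (1 - x): the sojourn density with the integrable
    endpoint factors removed.  psi(0, x) = 1 - x; psi is in [0, 1].

    Branches keep every exponent nonpositive so arbitrarily strong selection
    (|gamma| up to 1e5 and beyond) cannot overflow.
    """
    x = np.asarray(x, dtype=float)
    u = 2.0 * gamma
    if abs(gamma) < _SERIES_CUTOFF:
        # ratio of 3-term expansions of (1 - e^{-u(1-x)}) / (1 - e^{-u})
        om = 1.0 - x
        num = om * (1.0 - u * om / 2.0 + u * u * om * om / 6.0)
        den = 1.0 - u / 2.0 + u * u / 6.0
        return num / den
    if gamma > 0:
        return np.expm1(-u * (1.0 - x)) / np.expm1(-u)
    # gamma < 0: multiply through by e^{u} so exponents stay <= 0
    return np.exp(u * x) * np.expm1(u * (1.0 - x)) / np.expm1(u)


def sojourn_density(gamma: float, x) -> np.ndarray:
    """Dimensionless sojourn density h(gamma, x); neutral limit 1/x."""
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise ValueError("population frequency x must lie strictly in (0, 1)")
    out = _psi(gamma, x) / (x * (1.0 - x))
    return out if out.ndim else float(out)


def _log_binom(n: int, i: int) -> float:
    return gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)


def _unfolded_bin_expectation(gamma: float, i: int, n: int) -> float:
    lc = _log_binom(n, i)

    def integrand(x):
        with np.errstate(divide="ignore"):
            t = lc + (i - 1) * np.log(x) + (n - i - 1) * np.log1p(-x)
        return np.exp(t) * _psi(gamma, x)

    points = None
    if gamma < -100.0:
        # integrand mass concentrates on x ~ 1/(2|gamma|); guide the
        # subdivision so adaptive quadrature does not miss the spike
        s = 1.0 / (2.0 * abs(gamma))
        points = sorted({min(s, 0.5), min(10 * s, 0.5), min(100 * s, 0.9)})
    val, _ = integrate.quad(
        integrand, 0.0, 1.0, epsabs=1e-8, epsrel=1e-6, limit=200, points=points
    )
    return max(val, _F_FLOOR)


def bin_expectation(gamma: float, i: int, n: int, folded: bool = False) -> float:
    """F(gamma)_i by adaptive quadrature; folded bins pair i with n - i.

    The central folded bin i = n/2 (n even) is unpaired.  F(0)_i equals the
    neutral expectation (1/i unfolded) to quadrature tolerance.
    """
    hi = n // 2 if folded else n - 1
    if not 1 <= i <= hi:
        raise ValueError(f"bin index {i} invalid for n={n}, folded={folded}")
    val = _unfolded_bin_expectation(gamma, i, n)
    if folded and i != n - i:
        val += _unfolded_bin_expectation(gamma, n - i, n)
    return val


def neutral_expectations(n: int, folded: bool) -> np.ndarray:
    """Neutral per-bin expectations: 1/i unfolded; 1/i + 1/(n-i) folded
    (central bin 1/i only)."""
    if folded:
        i = np.arange(1, n // 2 + 1)
        out = 1.0 / i + 1.0 / (n - i)
        if n % 2 == 0:
            out[-1] = 1.0 / (n // 2)
        return out
    return 1.0 / np.arange(1, n)


@dataclass(frozen=True)
class ExpectationGrid:
    """Cached F(gamma)_i on a fixed gamma quadrature grid.

    ``F`` has shape (len(gamma_nodes), number of bins); ``gamma_weights``
    are quadrature weights such that ``weights @ (g(nodes)[:, None] * F)``
    approximates the DFE integral of F.  A node at gamma = 0 (zero weight)
    anchors the neutral column.  ``N`` is the neutral expectation vector.
    """

    n: int
    folded: bool
    gamma_nodes: np.ndarray
    gamma_weights: np.ndarray
    F: np.ndarray
    N: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.F.shape[1]

    def save(self, path) -> None:
        """Serialize to an .npz archive (grids take seconds to rebuild at
        large n; command-line reruns can reload instead)."""
        np.savez_compressed(
            path,
            n=self.n,
            folded=self.folded,
            gamma_nodes=self.gamma_nodes,
            gamma_weights=self.gamma_weights,
            F=self.F,
            N=self.N,
        )

    @classmethod
    def load(cls, path) -> "ExpectationGrid":
        with np.load(path) as archive:
            return cls(
                n=int(archive["n"]),
                folded=bool(archive["folded"]),
                gamma_nodes=archive["gamma_nodes"],
                gamma_weights=archive["gamma_weights"],
                F=archive["F"],
                N=archive["N"],
            )


def _gl_segments(a: float, b: float, total_points: int, per_decade_min: int = 6):
    """Composite Gauss-Legendre nodes/weights on log-spaced decade segments
    of [a, b] (0 < a < b), returned in the log variable u = ln(gamma)."""
    decades = np.log10(b / a)
    n_seg = max(1, int(np.ceil(decades)))
    k = max(per_decade_min, int(round(total_points / n_seg)))
    edges = np.linspace(np.log(a), np.log(b), n_seg + 1)
    xg, wg = np.polynomial.legendre.leggauss(k)
    us, ws = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        us.append(mid + half * xg)
        ws.append(half * wg)
    return np.concatenate(us), np.concatenate(ws)


def build_grid(
    n: int,
    folded: bool,
    gamma_lo: float = -1e5,
    gamma_hi: float = 1.0,
    nodes: int = 181,
) -> ExpectationGrid:
    """Build the cached F(gamma)_i grid for sample size n.

    Nodes concentrate near gamma = 0: per-decade Gauss-Legendre panels on
    log|gamma| from 1e-8 out to each range endpoint, a short linear panel
    across (-1e-8, +1e-8), and an explicit zero-weight node at gamma = 0.
    Deterministic for given arguments.
    """
    if nodes < 32:
        raise ValueError("nodes must be >= 32")
    if gamma_lo >= gamma_hi:
        raise ValueError("gamma_lo must be below gamma_hi")
    # panels reach down to |gamma| = 1e-8 so that DFEs with an integrable
    # power singularity at gamma -> 0 (inverted gamma, shape < 1, max 0)
    # are still integrated accurately
    eps = 1e-8
    dn = np.log10(max(abs(gamma_lo), eps) / eps)
    dp = np.log10(max(gamma_hi, eps) / eps) if gamma_hi > eps else 0.0
    n_center = 8
    budget = max(nodes - n_center - 1, 16)
    per_decade = budget / max(dn + dp, 1.0)

    gs, ws = [], []
    if gamma_lo < -eps:
        u, w = _gl_segments(eps, abs(gamma_lo), int(round(per_decade * dn)))
        gs.append(-np.exp(u))
        ws.append(w * np.exp(u))  # |d gamma| = e^u du
    c_lo, c_hi = max(gamma_lo, -eps), min(gamma_hi, eps)
    if c_hi > c_lo:
        xg, wg = np.polynomial.legendre.leggauss(n_center)
        mid, half = 0.5 * (c_lo + c_hi), 0.5 * (c_hi - c_lo)
        gs.append(mid + half * xg)
        ws.append(half * wg)
    if gamma_hi > eps:
        u, w = _gl_segments(eps, gamma_hi, int(round(per_decade * dp)))
        gs.append(np.exp(u))
        ws.append(w * np.exp(u))
    gs.append(np.array([0.0]))
    ws.append(np.array([0.0]))

    gamma_nodes = np.concatenate(gs)
    gamma_weights = np.concatenate(ws)
    order = np.argsort(gamma_nodes)
    gamma_nodes = gamma_nodes[order]
    gamma_weights = gamma_weights[order]

    n_bins = n // 2 if folded else n - 1
    F = np.empty((gamma_nodes.size, n_bins))
    N = neutral_expectations(n, folded)
    for j, g in enumerate(gamma_nodes):
        if g == 0.0:
            F[j] = N
        else:
            F[j] = [bin_expectation(g, i, n, folded) for i in range(1, n_bins + 1)]
    return ExpectationGrid(
        n=n, folded=folded, gamma_nodes=gamma_nodes, gamma_weights=gamma_weights, F=F, N=N
    )


_GRID_CACHE: dict = {}


def get_grid(
    n: int,
    folded: bool,
    gamma_lo: float = -1e5,
    gamma_hi: float = 1.0,
    nodes: int = 181,
) -> ExpectationGrid:
    """Memoized :func:`build_grid`; the fit loop shares one grid per (n, folded)."""
    key = (n, folded, gamma_lo, gamma_hi, nodes)
    if key not in _GRID_CACHE:
        _GRID_CACHE[key] = build_grid(n, folded, gamma_lo, gamma_hi, nodes)
    return _GRID_CACHE[key]


def dfe_bin_expectations(grid: ExpectationGrid, model: DFEModel) -> np.ndarray:
    """DFE-averaged expectations: integral of g(gamma) F(gamma)_i d gamma.

    A point mass at zero contributes its weight times the neutral
    expectation.  A fixed-gamma model bypasses the grid and evaluates
    F(gamma)_i exactly.  Warns if more than 1e-6 of the model's continuous
    mass lies outside the grid's gamma range.
    """
    if model.family == "fixed":
        g0 = model.params["gamma"]
        n_bins = grid.n_bins
        if g0 == 0.0:
            cont = grid.N.copy()
        else:
            cont = np.array(
                [bin_expectation(g0, i, grid.n, grid.folded) for i in range(1, n_bins + 1)]
            )
        return (1.0 - model.p_plus) * cont + model.p_plus * grid.N

    dens = dfe_pdf(model, grid.gamma_nodes)  # already scaled by 1 - p_plus
    w = grid.gamma_weights * dens
    mass = w.sum()
    if abs(mass - (1.0 - model.p_plus)) > 1e-6:
        warnings.warn(
            f"DFE mass outside the gamma grid range: quadrature mass {mass:.8f} "
            f"vs expected {1.0 - model.p_plus:.8f}",
            stacklevel=2,
        )
    out = w @ grid.F + model.p_plus * grid.N
    return np.maximum(out, _F_FLOOR)


class GammaInterpolator:
    """Fast F(gamma)_i evaluation by per-bin monotone interpolation.

    Interpolates log F against asinh(gamma) through the grid nodes (exact at
    every node, including the neutral anchor at gamma = 0).  Used by the
    fixed-gamma likelihood inside optimizer loops, where per-iteration
    adaptive quadrature would dominate run time.
    """

    def __init__(self, grid: ExpectationGrid):
        self.grid = grid
        self._interp = PchipInterpolator(
            np.arcsinh(grid.gamma_nodes), np.log(grid.F), axis=0, extrapolate=False
        )
        self._lo = grid.gamma_nodes[0]
        self._hi = grid.gamma_nodes[-1]

    def __call__(self, gamma: float) -> np.ndarray:
        g = float(np.clip(gamma, self._lo, self._hi))
        return np.exp(self._interp(np.arcsinh(g)))
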