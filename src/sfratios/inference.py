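"""Maximum-likelihood fitting of (rho, DFE) to SFS ratio spectra.

The optimizer works on unconstrained transformed coordinates (log for rho
and scale-like parameters, an affine logit for the point-mass weight, and
log-distance-from-maximum for location parameters bounded above), with
derivative-free Nelder-Mead refinement from multiple seeded starts.
Confidence intervals are profile-likelihood intervals at the chi-square
1-df cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from scipy.stats import chi2

from .dfe_models import DFEModel, dfe_mean, dfe_pdf
from .prf_expectations import ExpectationGrid, GammaInterpolator, get_grid
from .ratio_likelihood import THETA_GRID_POINTS, loglik
from .sfs_core import RatioSpectrum

__all__ = [
    "FitResult",
    "LRTResult",
    "fit",
    "fit_fixed_rho",
    "lrt_neutral",
    "estimate_lambda",
    "profile_ci",
    "compare_models",
]

#: starts whose final log-likelihoods differ by more than this are treated
#: as disagreeing (convergence flag)
START_AGREEMENT_TOL = 0.01

_ALPHAS = (0.05, 0.01, 0.001)

_INTERP_CACHE: dict[int, GammaInterpolator] = {}


def _interpolator(grid: ExpectationGrid) -> GammaInterpolator:
    key = id(grid)
    if key not in _INTERP_CACHE:
        _INTERP_CACHE[key] = GammaInterpolator(grid)
    return _INTERP_CACHE[key]


# ---------------------------------------------------------------------------
# parameter transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Param:
    """One free parameter: transformed <-> natural scale maps."""

    name: str
    inv: callable  # transformed -> natural
    fwd: callable  # natural -> transformed


def _log_param(name):
    return _Param(name, np.exp, np.log)


def _id_param(name):
    return _Param(name, lambda t: t, lambda v: v)


def _upper_bounded(name, m):
    # natural = m - exp(t): support (-inf, m)
    return _Param(name, lambda t: m - np.exp(t), lambda v: np.log(m - v))


def _pplus_param():
    # p_plus in [0, 0.5]
    return _Param(
        "p_plus",
        lambda t: 0.5 * expit(t),
        lambda v: logit(np.clip(v / 0.5, 1e-12, 1 - 1e-12)),
    )


def _family_layout(family: str, m: float, gamma_hi: float):
    """Free DFE parameters, their transforms, and seeded random starts
    (natural scale) for each family."""
    if family == "lognormal":
        params = [_id_param("mu"), _log_param("sigma")]

        def rand(rng):
            return {"mu": rng.uniform(0.0, 6.0), "sigma": rng.uniform(0.3, 3.0)}

        default = {"mu": 1.0, "sigma": 1.0}
    elif family == "gamma":
        params = [_upper_bounded("mean", m), _log_param("shape")]

        def rand(rng):
            return {
                "mean": m - np.exp(rng.uniform(np.log(0.1), np.log(1000.0))),
                "shape": np.exp(rng.uniform(np.log(0.3), np.log(3.0))),
            }

        default = {"mean": m - 5.0, "shape": 0.5}
    elif family == "normal":
        params = [_id_param("mean"), _log_param("sd")]

        def rand(rng):
            return {
                "mean": -np.exp(rng.uniform(np.log(0.1), np.log(100.0))),
                "sd": np.exp(rng.uniform(np.log(0.3), np.log(100.0))),
            }

        default = {"mean": -1.0, "sd": 2.0}
    elif family == "fixed":
        # gamma < gamma_hi so that expectations stay on the cached grid
        params = [_upper_bounded("gamma", gamma_hi)]

        def rand(rng):
            return {"gamma": -np.exp(rng.uniform(np.log(0.01), np.log(1000.0)))}

        default = {"gamma": -1.0}
    else:
        raise ValueError(f"unknown DFE family {family!r}")
    return params, rand, default


def _default_m(family: str) -> float:
    return 0.0 if family == "gamma" else 1.0


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Maximum-likelihood fit of (rho, DFE parameters [, p_plus])."""

    model: DFEModel
    rho_hat: float
    loglik: float
    aic: float
    K: int
    ci: dict = field(default_factory=dict)
    lambda_hat: float = np.nan
    mean_2Ns: float = np.nan
    converged: bool = False
    n_starts: int = 1
    seed: int = 0
    rho_fixed: bool = False
    _ctx: dict = field(default_factory=dict, repr=False, compare=False)

    def summary(self) -> str:
        lines = [
            f"family      : {self.model.describe()}",
            f"rho_hat     : {self.rho_hat:.6g}{' (fixed)' if self.rho_fixed else ''}",
            f"loglik      : {self.loglik:.6f}",
            f"K           : {self.K}",
            f"AIC         : {self.aic:.3f}",
            f"lambda_hat  : {self.lambda_hat:.6g}",
            f"mean 2Ns    : {self.mean_2Ns:.6g}",
            f"converged   : {self.converged}",
        ]
        for name, iv in self.ci.items():
            lines.append(f"ci[{name}]    : ({iv[0]:.6g}, {iv[1]:.6g})")
        return "\n".join(lines)


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of selection: null gamma = 0 vs free gamma."""

    stat: float
    df: int
    p_value: float
    reject_at: dict
    null_loglik: float = np.nan
    alt_loglik: float = np.nan


# ---------------------------------------------------------------------------
# objective machinery
# ---------------------------------------------------------------------------


class _Objective:
    """Negative integrated-ratio log-likelihood over transformed coordinates."""

    def __init__(
        self,
        ratios: RatioSpectrum,
        family: str,
        m: float,
        grid: ExpectationGrid,
        G: int,
        fixed_rho: float | None,
        fit_p_plus: bool,
        p_plus_value: float,
    ):
        self.ratios = ratios
        self.family = family
        self.m = m
        self.grid = grid
        self.G = G
        self.fixed_rho = fixed_rho
        self.fit_p_plus = fit_p_plus
        self.p_plus_value = p_plus_value
        gamma_hi = float(grid.gamma_nodes[-1])
        fam_params, self.rand_phi, self.default_phi = _family_layout(family, m, gamma_hi)
        self.params: list[_Param] = []
        if fixed_rho is None:
            self.params.append(_log_param("rho"))
        self.params += fam_params
        if fit_p_plus:
            self.params.append(_pplus_param())
        self.names = [p.name for p in self.params]
        self._interp = _interpolator(grid) if family == "fixed" else None

    # -- coordinate maps ------------------------------------------------

    def natural(self, x: np.ndarray) -> dict:
        return {p.name: float(p.inv(t)) for p, t in zip(self.params, x)}

    def transformed(self, values: dict) -> np.ndarray:
        return np.array([p.fwd(values[p.name]) for p in self.params])

    def model_of(self, values: dict) -> DFEModel:
        pp = values.get("p_plus", self.p_plus_value)
        phi = {
            k: v for k, v in values.items() if k not in ("rho", "p_plus")
        }
        return DFEModel(family=self.family, params=phi, m=self.m, p_plus=pp)

    # -- evaluation ------------------------------------------------------

    def neg_loglik(self, x: np.ndarray) -> float:
        values = self.natural(x)
        rho = self.fixed_rho if self.fixed_rho is not None else values["rho"]
        try:
            model = self.model_of(values)
        except ValueError:
            return np.inf
        pp = model.p_plus
        if self._interp is not None:
            cont = self._interp(model.params["gamma"])
            expectations = (1.0 - pp) * cont + pp * self.grid.N
        else:
            # inline the grid quadrature so escaping density mass can be
            # rejected: a DFE pushing most of its mass beyond the grid's
            # gamma range (possible for the unbounded normal family) would
            # otherwise shrink every expectation and send rho to infinity
            dens = dfe_pdf(model, self.grid.gamma_nodes)
            w = self.grid.gamma_weights * dens
            if w.sum() < 0.5 * (1.0 - pp):
                return np.inf
            expectations = np.maximum(w @ self.grid.F + pp * self.grid.N, 1e-300)
        try:
            ll = loglik(
                self.ratios, model, rho, self.grid, G=self.G, expectations=expectations
            )
        except (ValueError, FloatingPointError):
            return np.inf
        return -ll if np.isfinite(ll) else np.inf

    def start_vectors(self, n_starts: int, seed) -> list[np.ndarray]:
        rng = np.random.default_rng(seed)
        rho0 = max(self.ratios.X / self.ratios.Y, 1e-6)  # neutral-limit estimator
        starts = []
        for k in range(n_starts):
            phi = dict(self.default_phi) if k == 0 else self.rand_phi(rng)
            values = dict(phi)
            if self.fixed_rho is None:
                values["rho"] = rho0 if k == 0 else rho0 * np.exp(rng.uniform(-1.0, 1.0))
            if self.fit_p_plus:
                values["p_plus"] = 0.05 if k == 0 else rng.uniform(0.01, 0.45)
            starts.append(self.transformed(values))
        return starts


def _minimize(obj, x0: np.ndarray):
    res = optimize.minimize(
        obj,
        x0,
        method="Nelder-Mead",
        options={"fatol": 1e-8, "xatol": 1e-5, "maxiter": 400 * (len(x0) + 1)},
    )
    # restart the simplex once from the endpoint: Nelder-Mead can stall on
    # a degenerate simplex well away from the optimum
    res2 = optimize.minimize(
        obj,
        res.x,
        method="Nelder-Mead",
        options={"fatol": 1e-8, "xatol": 1e-5, "maxiter": 400 * (len(x0) + 1)},
    )
    return res2 if res2.fun <= res.fun else res


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def fit(
    ratios: RatioSpectrum,
    family: str = "lognormal",
    *,
    m: float | None = None,
    fit_p_plus: bool = False,
    p_plus: float = 0.0,
    fixed_rho: float | None = None,
    n_starts: int = 5,
    seed: int = 0,
    grid: ExpectationGrid | None = None,
    G: int = THETA_GRID_POINTS,
    nodes: int = 181,
    compute_ci: bool = False,
    ci_level: float = 0.95,
) -> FitResult:
    """Maximize the integrated-ratio log-likelihood over (rho, phi[, p_plus]).

    Parameters are searched on unconstrained transformed scales from
    ``n_starts`` seeded starts (the first start uses rho0 = X/Y, the
    neutral-limit estimator).  ``fixed_rho`` pins rho (excluded from K).
    ``fit_p_plus`` adds the point-mass weight (bounded in [0, 0.5]) as a
    free parameter; otherwise ``p_plus`` is held at the given value.
    """
    if int(ratios.valid_mask.sum()) < 3:
        raise ValueError("need at least 3 valid bins to fit")
    if fixed_rho is not None and fixed_rho <= 0:
        raise ValueError("fixed rho must be positive")
    if m is None:
        m = _default_m(family)
    if grid is None:
        grid = get_grid(ratios.n, ratios.folded, nodes=nodes)
    obj = _Objective(ratios, family, m, grid, G, fixed_rho, fit_p_plus, p_plus)

    results = []
    for x0 in obj.start_vectors(n_starts, seed):
        try:
            results.append(_minimize(obj.neg_loglik, x0))
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
    results = [r for r in results if np.isfinite(r.fun)]
    if not results:
        raise RuntimeError(
            f"optimization failed from all {n_starts} starts "
            f"(family={family}, n={ratios.n}, folded={ratios.folded})"
        )
    lls = np.array([-r.fun for r in results])
    best = results[int(np.argmax(lls))]
    converged = bool(np.max(lls) - np.min(lls) <= START_AGREEMENT_TOL)

    values = obj.natural(best.x)
    rho_hat = fixed_rho if fixed_rho is not None else values["rho"]
    model = obj.model_of(values)
    ll = -best.fun
    K = len(obj.params)
    result = FitResult(
        model=model,
        rho_hat=float(rho_hat),
        loglik=ll,
        aic=2.0 * K - 2.0 * ll,
        K=K,
        lambda_hat=estimate_lambda(rho_hat, ratios.X, ratios.Y),
        mean_2Ns=dfe_mean(model) if family != "fixed" else float(model.params["gamma"]),
        converged=converged,
        n_starts=n_starts,
        seed=seed,
        rho_fixed=fixed_rho is not None,
        _ctx={"objective": obj, "best_x": best.x.copy(), "ratios": ratios, "grid": grid},
    )
    if compute_ci:
        for name in obj.names:
            result.ci[name] = profile_ci(result, name, level=ci_level)
    return result


def fit_fixed_rho(
    ratios: RatioSpectrum, family: str, rho_fixed: float, **kwargs
) -> FitResult:
    """Fit with rho pinned to a transferred estimate (excluded from K)."""
    return fit(ratios, family, fixed_rho=rho_fixed, **kwargs)


def _fit_rho_only(
    ratios: RatioSpectrum, grid: ExpectationGrid, G: int
) -> tuple[float, float]:
    """Null model of the selection LRT: gamma = 0 fixed, rho free.

    Expectations reduce to the neutral vector, so beta_i = rho in every bin.
    Returns (rho_hat, loglik).
    """
    neutral = DFEModel("fixed", {"gamma": 0.0})

    def nll(logrho):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return -loglik(
                ratios, neutral, np.exp(logrho[0]), grid, G=G, expectations=grid.N
            )

    x0 = np.log(max(ratios.X / ratios.Y, 1e-6))
    res = optimize.minimize(
        nll, [x0], method="Nelder-Mead", options={"fatol": 1e-8, "xatol": 1e-6}
    )
    return float(np.exp(res.x[0])), float(-res.fun)


def lrt_neutral(
    ratios: RatioSpectrum,
    *,
    grid: ExpectationGrid | None = None,
    G: int = THETA_GRID_POINTS,
    n_starts: int = 3,
    seed: int = 0,
) -> LRTResult:
    """Likelihood-ratio test of neutrality with a single fixed-gamma DFE.

    Null: gamma = 0, rho free (1 parameter).  Alternative: (rho, gamma)
    free (2 parameters).  Twice the log-likelihood ratio is referred to the
    chi-square distribution with 1 df; the statistic is clipped at zero.
    """
    if grid is None:
        grid = get_grid(ratios.n, ratios.folded)
    _, ll0 = _fit_rho_only(ratios, grid, G)
    alt = fit(ratios, family="fixed", grid=grid, G=G, n_starts=n_starts, seed=seed)
    stat = 2.0 * (alt.loglik - ll0)
    if stat < -1e-6:
        warnings.warn(
            f"alternative log-likelihood below null by {-stat / 2:.3g}; clipping",
            stacklevel=2,
        )
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, 1))
    return LRTResult(
        stat=float(stat),
        df=1,
        p_value=p,
        reject_at={a: bool(stat > chi2.isf(a, 1)) for a in _ALPHAS},
        null_loglik=ll0,
        alt_loglik=alt.loglik,
    )


def estimate_lambda(rho_hat: float, X: float, Y: float) -> float:
    """Relative probability that a selected mutation goes unsampled:
    lambda_hat = rho_hat * Y / X."""
    if X <= 0 or Y <= 0:
        raise ValueError("X and Y must both be positive")
    return float(rho_hat) * Y / X


def profile_ci(fit_result: FitResult, parameter: str, level: float = 0.95):
    """Profile-likelihood confidence interval for one fitted parameter.

    Endpoints are where the profile log-likelihood drops by
    chi2.ppf(level, 1)/2 (1.92 for 95%) below the maximum, found by
    bisection to ~1e-3 relative.  An unbounded side is reported as
    +-inf (one-sided interval).
    """
    obj: _Objective = fit_result._ctx["objective"]
    best_x = fit_result._ctx["best_x"]
    if parameter not in obj.names:
        raise ValueError(f"parameter {parameter!r} not in fit ({obj.names})")
    idx = obj.names.index(parameter)
    free = [k for k in range(len(obj.names)) if k != idx]
    ll_max = fit_result.loglik
    target = ll_max - chi2.ppf(level, 1) / 2.0

    def profile_ll(t_val: float) -> float:
        if not free:
            x = best_x.copy()
            x[idx] = t_val
            return -obj.neg_loglik(x)

        def sub_nll(sub):
            x = best_x.copy()
            x[free] = sub
            x[idx] = t_val
            return obj.neg_loglik(x)

        res = optimize.minimize(
            sub_nll,
            best_x[free],
            method="Nelder-Mead",
            options={"fatol": 1e-8, "xatol": 1e-5},
        )
        return -res.fun

    inv = obj.params[idx].inv

    def endpoint(direction: float):
        step = 0.05
        t0 = best_x[idx]
        prev = t0
        for _ in range(60):
            t = t0 + direction * step
            if profile_ll(t) < target:
                root = optimize.brentq(
                    lambda tt: profile_ll(tt) - target, prev, t, xtol=1e-4
                )
                return float(inv(root)), False
            prev = t
            step *= 1.8
        return float(inv(prev)), True  # profile never crossed: unbounded side

    lo_val, lo_open = endpoint(-1.0)
    hi_val, hi_open = endpoint(+1.0)
    lo, hi = sorted([lo_val, hi_val])  # transforms may reverse orientation
    if lo_open or hi_open:
        warnings.warn(
            f"profile for {parameter!r} did not cross the cutoff on one side; "
            "interval is one-sided",
            stacklevel=2,
        )
    return (lo, hi)


def compare_models(fits: list[FitResult]) -> pd.DataFrame:
    """Rank fits of the same ratio spectrum by AIC (ascending)."""
    if not fits:
        raise ValueError("no fits to compare")
    ref = fits[0]._ctx["ratios"]
    for f in fits[1:]:
        r = f._ctx["ratios"]
        if (
            r.n != ref.n
            or r.folded != ref.folded
            or not np.array_equal(r.selected_counts, ref.selected_counts)
            or not np.array_equal(r.neutral_counts, ref.neutral_counts)
        ):
            raise ValueError("fits were made on different ratio spectra")
    rows = []
    for f in fits:
        row = {
            "model": f.model.describe(),
            "K": f.K,
            "loglik": f.loglik,
            "AIC": f.aic,
            "rho_hat": f.rho_hat,
            "lambda_hat": f.lambda_hat,
            "p_plus": f.model.p_plus,
            "mean_2Ns": f.mean_2Ns,
            "converged": f.converged,
        }
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("AIC", kind="stable").reset_index(drop=True)
    table["dAIC"] = table["AIC"] - table["AIC"].iloc[0]
    return table
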