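"""Distributions of fitness effects on the population-scaled 2Ns axis.

All continuous families are "inverted": a standard density on x > 0 is
reflected so that gamma = m - x, giving support (-inf, m].  The maximum m is
1 by default for the lognormal (allowing weakly beneficial and strictly
neutral mutations) and 0 or 1 for the gamma.  A point mass p_plus at
gamma = 0 can be mixed with any continuous family; the continuous part then
carries weight 1 - p_plus.

Families
--------
fixed      a single 2Ns value gamma (degenerate distribution)
lognormal  log(m - gamma) ~ Normal(mu, sigma)
gamma      (m - gamma) ~ Gamma(shape alpha, scale); the (mean, shape)
           parameterization sets scale = (m - mean) / alpha
normal     gamma ~ Normal(mean, sd), untruncated
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy import stats

__all__ = ["DFEModel", "dfe_pdf", "dfe_mean", "sample_gamma", "parse_model"]

_FAMILIES = ("fixed", "lognormal", "gamma", "normal")


@dataclass(frozen=True)
class DFEModel:
    """A 2Ns density: family, parameters, support maximum, point mass.

    ``params`` by family:

    - fixed: ``{"gamma": value}``
    - lognormal: ``{"mu": ..., "sigma": ...}`` for log(m - gamma)
    - gamma: ``{"mean": ..., "shape": ...}`` or ``{"shape": ..., "scale": ...}``
    - normal: ``{"mean": ..., "sd": ...}``

    ``p_plus`` is the weight of a point mass at 2Ns = 0, in [0, 0.5]
    (up to half the total density).
    """

    family: str
    params: dict = field(default_factory=dict)
    m: float = 1.0
    p_plus: float = 0.0

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown DFE family {self.family!r}")
        if not 0.0 <= self.p_plus <= 0.5:
            raise ValueError(f"p_plus must lie in [0, 0.5], got {self.p_plus}")
        p = dict(self.params)
        if self.family == "fixed":
            if "gamma" not in p:
                raise ValueError("fixed family requires params={'gamma': value}")
        elif self.family == "lognormal":
            if not {"mu", "sigma"} <= p.keys():
                raise ValueError("lognormal family requires mu and sigma")
            if p["sigma"] <= 0:
                raise ValueError("sigma must be positive")
        elif self.family == "gamma":
            if "shape" not in p:
                raise ValueError("gamma family requires a shape parameter")
            if p["shape"] <= 0:
                raise ValueError("shape must be positive")
            if "scale" in p:
                if p["scale"] <= 0:
                    raise ValueError("scale must be positive")
            elif "mean" in p:
                if p["mean"] >= self.m:
                    raise ValueError("gamma mean must lie below the maximum m")
            else:
                raise ValueError("gamma family requires mean or scale")
        elif self.family == "normal":
            if not {"mean", "sd"} <= p.keys():
                raise ValueError("normal family requires mean and sd")
            if p["sd"] <= 0:
                raise ValueError("sd must be positive")
        object.__setattr__(self, "params", p)

    # -- derived parameterizations ------------------------------------

    @property
    def gamma_scale(self) -> float:
        """Scale of the reflected gamma distribution (m - gamma)."""
        if self.family != "gamma":
            raise AttributeError("gamma_scale only defined for the gamma family")
        p = self.params
        if "scale" in p:
            return float(p["scale"])
        return (self.m - p["mean"]) / p["shape"]

    @property
    def gamma_mean(self) -> float:
        """Mean 2Ns of the untruncated gamma-family model (continuous part)."""
        if self.family != "gamma":
            raise AttributeError("gamma_mean only defined for the gamma family")
        return self.m - self.params["shape"] * self.gamma_scale

    def _reflected(self):
        """Frozen scipy distribution of x = m - gamma (continuous families)."""
        p = self.params
        if self.family == "lognormal":
            return stats.lognorm(s=p["sigma"], scale=np.exp(p["mu"]))
        if self.family == "gamma":
            return stats.gamma(a=p["shape"], scale=self.gamma_scale)
        raise AttributeError(f"no reflected form for family {self.family!r}")

    def describe(self) -> str:
        parts = [f"{k}={v:g}" for k, v in self.params.items()]
        parts.append(f"max={self.m:g}")
        if self.p_plus:
            parts.append(f"pzero={self.p_plus:g}")
        return f"{self.family}:" + ",".join(parts)


def dfe_pdf(model: DFEModel, gamma) -> np.ndarray:
    """Continuous-part density at 2Ns = gamma, scaled by (1 - p_plus).

    The point mass is never represented as a density value; it is carried
    separately by ``model.p_plus``.  The fixed family has no continuous part
    and raises.
    """
    g = np.asarray(gamma, dtype=float)
    w = 1.0 - model.p_plus
    if model.family == "fixed":
        raise ValueError("fixed family is a point mass; it has no density")
    if model.family == "normal":
        p = model.params
        out = w * stats.norm.pdf(g, loc=p["mean"], scale=p["sd"])
    else:
        x = model.m - g
        out = np.where(x > 0, w * model._reflected().pdf(np.maximum(x, 1e-300)), 0.0)
    return out if out.ndim else float(out)


def dfe_mean(model: DFEModel, lo: float = -1e5, hi: float = 1e-4) -> float:
    """Mean 2Ns by numerical integration of gamma * pdf over [lo, hi].

    The integral is NOT renormalized over the truncated range: mass outside
    [lo, hi] simply does not contribute.  Point-mass contributions
    (weight x location) are added for any mass location inside [lo, hi].
    A positive point mass at ``gamma_plus`` (weight p_plus) is supported to
    represent mixtures whose beneficial part is a spike rather than mass at
    zero; pass it via ``model.params['gamma_plus']``.  Published mixtures
    sometimes weight the continuous (deleterious) part by an explicit
    proportion p- rather than 1 - p_plus; pass ``model.params['p_neg']`` to
    use that weight here (ignored by everything except this mean).
    """
    if lo >= hi:
        raise ValueError(f"integration range invalid: lo={lo} >= hi={hi}")
    if model.family == "fixed":
        g0 = model.params["gamma"]
        return float(g0) if lo <= g0 <= hi else 0.0

    gamma_plus = model.params.get("gamma_plus", 0.0)
    point = model.p_plus * gamma_plus if lo <= gamma_plus <= hi else 0.0
    w_cont = model.params.get("p_neg", 1.0 - model.p_plus)

    if model.family == "normal":
        p = model.params
        val, _ = integrate.quad(
            lambda g: g * stats.norm.pdf(g, loc=p["mean"], scale=p["sd"]),
            lo,
            hi,
            limit=200,
        )
        return w_cont * val + point

    # reflected families: substitute u = log(m - gamma) for a well-scaled
    # integrand over many orders of magnitude of |2Ns|
    dist = model._reflected()
    x_lo = max(model.m - hi, 0.0)
    x_hi = model.m - lo
    if x_hi <= 0:
        return point
    u_hi = np.log(x_hi)
    u_lo = np.log(x_lo) if x_lo > 0 else u_hi - 60.0  # e^-60 ~ 0: below any support

    def integrand(u):
        x = np.exp(u)
        return (model.m - x) * dist.pdf(x) * x

    val, _ = integrate.quad(integrand, u_lo, u_hi, limit=400)
    return w_cont * val + point


def sample_gamma(model: DFEModel, k: int, seed) -> np.ndarray:
    """Draw k reproducible 2Ns values from the model (point mass included)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    if model.family == "fixed":
        draws = np.full(k, float(model.params["gamma"]))
    elif model.family == "normal":
        p = model.params
        draws = rng.normal(p["mean"], p["sd"], size=k)
    elif model.family == "lognormal":
        p = model.params
        draws = model.m - rng.lognormal(p["mu"], p["sigma"], size=k)
    else:  # gamma
        draws = model.m - rng.gamma(model.params["shape"], model.gamma_scale, size=k)
    if model.p_plus > 0:
        at_zero = rng.random(k) < model.p_plus
        draws[at_zero] = 0.0
    return draws


def parse_model(text: str) -> DFEModel:
    """Parse the config dialect, e.g. ``lognormal:mu=3.0,sigma=1.2,max=1,pzero=0.05``."""
    family, _, rest = text.partition(":")
    family = family.strip().lower()
    kwargs = {}
    params = {}
    if rest:
        for tok in rest.split(","):
            k, _, v = tok.partition("=")
            k = k.strip().lower()
            if not v:
                raise ValueError(f"malformed model token {tok!r} in {text!r}")
            val = float(v)
            if k == "max":
                kwargs["m"] = val
            elif k == "pzero":
                kwargs["p_plus"] = val
            else:
                params[k] = val
    if family == "gamma" and "m" not in kwargs:
        kwargs["m"] = 0.0
    return DFEModel(family=family, params=params, **kwargs)
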