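"""Parametric and flexible-spline survival models for extrapolation.

Fits the standard catalogue of survival families (exponential, Weibull,
Gompertz, gamma, log-logistic, log-normal, generalized gamma) and
Royston-Parmar spline models to right-censored data by maximum likelihood,
ranks them by AIC, and converts the chosen model into per-cycle survival
for the economic engine. A comparator arm without published curves is
derived by hazard-ratio anchoring: S_new(t) = S_base(t)**HR under
proportional hazards.

Royston-Parmar models express g(S(t)) as a restricted (natural) cubic
spline in log time, where g is the log cumulative hazard ("hazard" scale)
or the log cumulative odds of failure ("odds" scale). With zero interior
knots the spline is linear in log time and the model collapses to Weibull
(hazard scale) or log-logistic (odds scale) exactly. Beyond the boundary
knots the restricted basis is linear in log time by construction, which is
what makes the long-horizon tail well behaved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import RunConfig
from .reconstruct import PseudoIPD

logger = logging.getLogger(__name__)

PARAMETRIC_FAMILIES = (
    "exponential", "weibull", "gompertz", "gamma",
    "loglogistic", "lognormal", "generalized_gamma",
)

_BIG = 1e10


class FitError(RuntimeError):
    """Fit did not converge or produced an invalid model."""


# ---------------------------------------------------------------------------
# parametric family definitions: unconstrained parameter vector theta
# ---------------------------------------------------------------------------

def _exp_ll(theta, t, d):
    lam = math.exp(theta[0])
    return float(d.sum() * theta[0] - lam * t.sum())


def _weib_ll(theta, t, d):
    p, lam = math.exp(theta[0]), math.exp(theta[1])
    lt = np.log(t) - theta[1]
    z = np.exp(np.clip(p * lt, -700, 700))
    return float(np.sum(d * (theta[0] - theta[1] + (p - 1) * lt)) - z.sum())


def _gomp_ll(theta, t, d):
    lam, g = math.exp(theta[0]), theta[1]
    gt = np.clip(g * t, -500, 500)
    if abs(g) < 1e-9:
        H = lam * t * (1 + gt / 2)
    else:
        H = lam * (np.exp(gt) - 1.0) / g
    return float(np.sum(d * (theta[0] + gt)) - H.sum())


def _gamma_ll(theta, t, d):
    k, sc = math.exp(theta[0]), math.exp(theta[1])
    lp = stats.gamma.logpdf(t, k, scale=sc)
    ls = stats.gamma.logsf(t, k, scale=sc)
    return float(np.sum(np.where(d == 1, lp, ls)))


def _llog_ll(theta, t, d):
    p = math.exp(theta[0])
    lt = np.log(t) - theta[1]
    lu = np.clip(p * lt, -700, 700)
    log1pu = np.logaddexp(0.0, lu)
    return float(np.sum(d * (theta[0] - theta[1] + (p - 1) * lt - log1pu)) - log1pu.sum())


def _lnorm_ll(theta, t, d):
    mu, sig = theta[0], math.exp(theta[1])
    z = (np.log(t) - mu) / sig
    lp = -np.log(t) - theta[1] + stats.norm.logpdf(z)
    ls = stats.norm.logsf(z)
    return float(np.sum(np.where(d == 1, lp, ls)))


def _gg_ll(theta, t, d):
    a, c, sc = math.exp(theta[0]), theta[1], math.exp(theta[2])
    if abs(c) < 1e-3:
        return -_BIG
    lp = stats.gengamma.logpdf(t, a, c, scale=sc)
    ls = stats.gengamma.logsf(t, a, c, scale=sc)
    return float(np.sum(np.where(d == 1, lp, ls)))


def _exp_sf(params, t):
    return np.exp(-params["rate"] * t)


def _weib_sf(params, t):
    return np.exp(-np.power(t / params["scale"], params["shape"]))


def _gomp_sf(params, t):
    lam, g = params["rate"], params["shape"]
    if abs(g) < 1e-9:
        return np.exp(-lam * t)
    return np.exp(-lam * (np.exp(np.clip(g * t, -500, 500)) - 1.0) / g)


def _gamma_sf(params, t):
    return stats.gamma.sf(t, params["shape"], scale=params["scale"])


def _llog_sf(params, t):
    with np.errstate(divide="ignore"):
        u = np.power(t / params["scale"], params["shape"])
    return 1.0 / (1.0 + u)


def _lnorm_sf(params, t):
    with np.errstate(divide="ignore"):
        z = (np.log(np.maximum(t, 1e-300)) - params["mu"]) / params["sigma"]
    return stats.norm.sf(z)


def _gg_sf(params, t):
    return stats.gengamma.sf(t, params["a"], params["c"], scale=params["scale"])


_FAMILIES: dict[str, dict] = {
    "exponential": dict(
        ll=_exp_ll, sf=_exp_sf, names=[("rate", "log")],
        starts=lambda mt: [[math.log(1 / mt)]],
    ),
    "weibull": dict(
        ll=_weib_ll, sf=_weib_sf, names=[("shape", "log"), ("scale", "log")],
        starts=lambda mt: [[0.0, math.log(mt)], [math.log(1.5), math.log(mt)],
                           [math.log(0.7), math.log(mt)]],
    ),
    "gompertz": dict(
        ll=_gomp_ll, sf=_gomp_sf, names=[("rate", "log"), ("shape", "identity")],
        starts=lambda mt: [[math.log(1 / mt), 0.1], [math.log(1 / mt), -0.1]],
    ),
    "gamma": dict(
        ll=_gamma_ll, sf=_gamma_sf, names=[("shape", "log"), ("scale", "log")],
        starts=lambda mt: [[0.0, math.log(mt)], [math.log(2.0), math.log(mt / 2)]],
    ),
    "loglogistic": dict(
        ll=_llog_ll, sf=_llog_sf, names=[("shape", "log"), ("scale", "log")],
        starts=lambda mt: [[0.0, math.log(mt)], [math.log(1.5), math.log(mt)]],
    ),
    "lognormal": dict(
        ll=_lnorm_ll, sf=_lnorm_sf, names=[("mu", "identity"), ("sigma", "log")],
        starts=lambda mt: [[math.log(mt), 0.0], [math.log(mt), math.log(0.5)]],
    ),
    "generalized_gamma": dict(
        ll=_gg_ll, sf=_gg_sf,
        names=[("a", "log"), ("c", "identity"), ("scale", "log")],
        starts=lambda mt: [[0.0, 1.0, math.log(mt)], [math.log(2.0), 1.0, math.log(mt)],
                           [0.0, -1.0, math.log(mt)], [0.0, 0.5, math.log(mt)]],
    ),
}


# ---------------------------------------------------------------------------
# Royston-Parmar restricted cubic spline basis in log time
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RPBasis:
    """Restricted cubic spline basis: linear beyond the boundary knots."""

    boundary: tuple[float, float]
    interior: tuple[float, ...]

    def design(self, x: np.ndarray) -> np.ndarray:
        kmin, kmax = self.boundary
        cols = [np.ones_like(x), x]
        for kj in self.interior:
            lam = (kmax - kj) / (kmax - kmin)
            v = (np.maximum(x - kj, 0) ** 3
                 - lam * np.maximum(x - kmin, 0) ** 3
                 - (1 - lam) * np.maximum(x - kmax, 0) ** 3)
            cols.append(v)
        return np.column_stack(cols)

    def deriv(self, x: np.ndarray) -> np.ndarray:
        kmin, kmax = self.boundary
        cols = [np.zeros_like(x), np.ones_like(x)]
        for kj in self.interior:
            lam = (kmax - kj) / (kmax - kmin)
            v = 3 * (np.maximum(x - kj, 0) ** 2
                     - lam * np.maximum(x - kmin, 0) ** 2
                     - (1 - lam) * np.maximum(x - kmax, 0) ** 2)
            cols.append(v)
        return np.column_stack(cols)


def _rp_ll_factory(basis: RPBasis, scale: str, t: np.ndarray, d: np.ndarray):
    x = np.log(t)
    B = basis.design(x)
    Bd = basis.deriv(x)
    ev = d == 1

    def ll(gamma):
        s = B @ gamma
        sp = Bd @ gamma
        if np.any(sp[ev] <= 0):
            return -_BIG - float(np.sum(np.minimum(sp[ev], 0) ** 2))
        s = np.clip(s, -500, 500)
        if scale == "hazard":
            out = -np.exp(s)                      # censored contribution
            out[ev] += s[ev] + np.log(sp[ev]) - x[ev]
        else:  # odds
            log1pe = np.logaddexp(0.0, s)
            out = -log1pe
            out[ev] += np.log(sp[ev]) - x[ev] + s[ev] - log1pe[ev]
        return float(out.sum())

    return ll


def _rp_sf(params, t):
    basis: RPBasis = params["basis"]
    gamma = params["gamma"]
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t)
    pos = t > 0
    s = basis.design(np.log(t[pos])) @ gamma
    s = np.clip(s, -500, 500)
    if params["scale"] == "hazard":
        out[pos] = np.exp(-np.exp(s))
    else:
        out[pos] = 1.0 / (1.0 + np.exp(s))
    return out


# ---------------------------------------------------------------------------
# fit container
# ---------------------------------------------------------------------------

@dataclass
class SurvivalFit:
    """A fitted survival model with its likelihood, AIC and covariance."""

    family: str
    params: dict
    theta: np.ndarray
    param_names: list[tuple[str, str]]
    log_likelihood: float
    n_params: int
    n: int
    n_events: int
    cov: np.ndarray | None = None
    scale: str | None = None                 # rp_spline: "hazard" or "odds"
    knots: dict | None = None                # rp_spline: boundary + interior
    label: str = ""

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.log_likelihood

    def survival(self, times) -> np.ndarray:
        return survival_at(self, times)

    def confint(self, name: str, alpha: float = 0.05) -> tuple[float, float]:
        """Wald interval for a natural parameter (delta method on the
        unconstrained scale; log-parameterized quantities are exponentiated)."""
        if self.cov is None:
            raise FitError("no covariance available")
        idx = [n for n, _ in self.param_names].index(name)
        tf = self.param_names[idx][1]
        se = math.sqrt(max(self.cov[idx, idx], 0.0))
        z = stats.norm.ppf(1 - alpha / 2)
        lo, hi = self.theta[idx] - z * se, self.theta[idx] + z * se
        if tf == "log":
            return math.exp(lo), math.exp(hi)
        return lo, hi

    def describe(self) -> str:
        extra = f" ({self.scale}, {len(self.knots['interior'])} knots)" if self.knots else ""
        return f"{self.family}{extra}: loglik={self.log_likelihood:.3f} AIC={self.aic:.3f}"

    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "params": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                       for k, v in self.params.items() if k != "basis"},
            "log_likelihood": self.log_likelihood,
            "n_params": self.n_params,
            "aic": self.aic,
            "n": self.n,
            "n_events": self.n_events,
        }
        if self.scale:
            d["scale"] = self.scale
        if self.knots:
            d["knots"] = {k: list(v) for k, v in self.knots.items()}
        return d


def _numeric_hessian(f, x, step=1e-4):
    n = len(x)
    H = np.zeros((n, n))
    h = step * (1.0 + np.abs(x))
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
            xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
            xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h[i] * h[j])
    return H


def _maximize(ll, starts, gtol=1e-8):
    def neg(th):
        # line searches can probe wild parameter values; treat numeric
        # blow-ups as a very bad objective rather than crashing
        try:
            with np.errstate(all="ignore"):
                v = ll(th)
        except (OverflowError, FloatingPointError, ValueError):
            return _BIG
        return -v if np.isfinite(v) else _BIG

    best = None
    for x0 in starts:
        x0 = np.asarray(x0, dtype=float)
        res = optimize.minimize(neg, x0, method="BFGS",
                                options={"gtol": gtol, "maxiter": 500})
        res2 = optimize.minimize(neg, res.x, method="Nelder-Mead",
                                 options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 2000})
        cand = res2 if res2.fun < res.fun else res
        # polish once more with BFGS from the NM optimum
        res3 = optimize.minimize(neg, cand.x, method="BFGS",
                                 options={"gtol": gtol, "maxiter": 200})
        if res3.fun < cand.fun:
            cand = res3
        if best is None or cand.fun < best.fun:
            best = cand
    if best is None or not np.isfinite(best.fun) or best.fun >= _BIG / 2:
        raise FitError("optimizer failed to find a finite maximum")
    return best


def _check_ipd(ipd: PseudoIPD, min_events: int = 10):
    if ipd.n_events == 0:
        raise FitError("degenerate data: all records censored")
    if ipd.n_events < min_events:
        raise FitError(f"too few events ({ipd.n_events} < {min_events})")


def fit_parametric(ipd: PseudoIPD, family: str, min_events: int = 10) -> SurvivalFit:
    """Maximum-likelihood fit of one parametric family to right-censored data."""
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {PARAMETRIC_FAMILIES}")
    _check_ipd(ipd, min_events)
    spec = _FAMILIES[family]
    t, d = ipd.times, ipd.events
    mean_t = float(t[d == 1].mean())
    ll = lambda th: spec["ll"](th, t, d)
    best = _maximize(ll, spec["starts"](mean_t))
    theta = best.x
    H = _numeric_hessian(lambda th: -ll(th), theta)
    try:
        cov = np.linalg.pinv(H)
    except np.linalg.LinAlgError:
        cov = None
    params = {}
    for (name, tf), val in zip(spec["names"], theta):
        params[name] = math.exp(val) if tf == "log" else float(val)
    return SurvivalFit(
        family=family, params=params, theta=theta, param_names=spec["names"],
        log_likelihood=-best.fun, n_params=len(theta), n=len(ipd),
        n_events=ipd.n_events, cov=cov, label=family,
    )


def rp_knot_locations(ipd: PseudoIPD, n_interior: int) -> dict:
    """Knot placement on log uncensored event times.

    Boundary knots at the extreme event times; interior knots at the
    median (1 knot), 33/67% (2) or 25/50/75% (3) quantiles.
    """
    if not 0 <= n_interior <= 3:
        raise ValueError("interior knot count must be 0-3")
    x = np.log(ipd.times[ipd.events == 1])
    bmin, bmax = float(x.min()), float(x.max())
    if bmax <= bmin:
        raise FitError("cannot place boundary knots: all events at one time")
    qs = {0: [], 1: [0.5], 2: [1 / 3, 2 / 3], 3: [0.25, 0.5, 0.75]}[n_interior]
    interior = [float(np.quantile(x, q)) for q in qs]
    if len(set([bmin, *interior, bmax])) != n_interior + 2:
        raise FitError("tied knot locations; reduce knot count")
    return {"boundary": (bmin, bmax), "interior": tuple(interior)}


def fit_royston_parmar(
    ipd: PseudoIPD, n_interior_knots: int = 1, scale: str = "hazard",
    min_events: int = 10,
) -> SurvivalFit:
    """Fit a Royston-Parmar spline model on the hazard or odds scale."""
    if scale not in {"hazard", "odds"}:
        raise ValueError("scale must be 'hazard' or 'odds'")
    _check_ipd(ipd, min_events)
    knots = rp_knot_locations(ipd, n_interior_knots)
    basis = RPBasis(boundary=knots["boundary"], interior=knots["interior"])
    t, d = ipd.times, ipd.events
    ll = _rp_ll_factory(basis, scale, t, d)

    # seed from the 0-knot analytic limit (Weibull / log-logistic)
    seed_family = "weibull" if scale == "hazard" else "loglogistic"
    try:
        seed = fit_parametric(ipd, seed_family, min_events=min_events)
        p, lam = seed.params["shape"], seed.params["scale"]
        g0 = np.zeros(2 + n_interior_knots)
        g0[0], g0[1] = -p * math.log(lam), p
        starts = [g0]
        if n_interior_knots:
            g1 = g0.copy()
            g1[2:] = 1e-3
            starts.append(g1)
    except FitError:
        starts = [np.concatenate([[0.0, 1.0], np.zeros(n_interior_knots)])]

    best = _maximize(ll, starts)
    gamma = best.x

    # the spline must be non-decreasing in log time (a valid cumulative
    # hazard/odds); check on a dense grid spanning data and the linear tails
    bmin, bmax = knots["boundary"]
    grid = np.linspace(bmin - 1.0, bmax + 1.0, 400)
    sp = basis.deriv(grid) @ gamma
    if np.min(sp) <= 0:
        raise FitError(
            f"fitted spline non-monotone in log time "
            f"(min derivative {np.min(sp):.3g}); rejecting fit"
        )

    H = _numeric_hessian(lambda th: -ll(th), gamma)
    try:
        cov = np.linalg.pinv(H)
    except np.linalg.LinAlgError:
        cov = None
    names = [(f"gamma{i}", "identity") for i in range(len(gamma))]
    return SurvivalFit(
        family="rp_spline",
        params={"gamma": gamma.copy(), "basis": basis, "scale": scale},
        theta=gamma, param_names=names, log_likelihood=-best.fun,
        n_params=len(gamma), n=len(ipd), n_events=ipd.n_events, cov=cov,
        scale=scale, knots=knots,
        label=f"rp_{scale}_{n_interior_knots}k",
    )


def fit_catalogue(
    ipd: PseudoIPD,
    families: tuple[str, ...] = PARAMETRIC_FAMILIES,
    rp_knots: tuple[int, ...] = (1, 2, 3),
    rp_scales: tuple[str, ...] = ("hazard", "odds"),
) -> list[SurvivalFit]:
    """Fit every candidate model, skipping (and logging) failures."""
    fits: list[SurvivalFit] = []
    for fam in families:
        try:
            fits.append(fit_parametric(ipd, fam))
        except FitError as exc:
            logger.warning("%s %s: %s fit skipped: %s", ipd.arm, ipd.endpoint, fam, exc)
    for sc in rp_scales:
        for m in rp_knots:
            try:
                fits.append(fit_royston_parmar(ipd, m, sc))
            except FitError as exc:
                logger.warning("%s %s: rp_%s_%dk skipped: %s",
                               ipd.arm, ipd.endpoint, sc, m, exc)
    if not fits:
        raise FitError("no candidate model converged")
    return fits


def select_model(
    fits: list[SurvivalFit], override: str | None = None
) -> tuple[pd.DataFrame, SurvivalFit]:
    """Rank fits by AIC and pick the best (lowest AIC; parsimony on ties).

    *override* names a model to force, e.g. ``"rp_hazard,2"``, ``"weibull"``
    -- the hook for choosing on visual inspection rather than AIC alone.
    """
    if not fits:
        raise ValueError("empty fit list")
    rows = [
        {"model": f.label, "family": f.family, "scale": f.scale,
         "n_interior_knots": len(f.knots["interior"]) if f.knots else None,
         "n_params": f.n_params, "log_likelihood": f.log_likelihood, "aic": f.aic}
        for f in fits
    ]
    table = pd.DataFrame(rows).sort_values(
        ["aic", "n_params"], ignore_index=True
    )
    if override:
        chosen = _resolve_override(fits, override)
        logger.info("model override in effect: %s chosen over AIC rank", chosen.label)
    else:
        best_aic = table["aic"].iloc[0]
        near = [f for f in fits if f.aic <= best_aic + 0.01]
        chosen = min(near, key=lambda f: (f.n_params, f.aic))
    return table, chosen


def _resolve_override(fits: list[SurvivalFit], override: str) -> SurvivalFit:
    parts = [p.strip() for p in override.split(",")]
    if parts[0].startswith("rp_"):
        sc = parts[0].removeprefix("rp_")
        m = int(parts[1]) if len(parts) > 1 else 1
        for f in fits:
            if f.family == "rp_spline" and f.scale == sc and len(f.knots["interior"]) == m:
                return f
    else:
        for f in fits:
            if f.family == parts[0]:
                return f
    raise ValueError(f"override {override!r} matches no fitted model")


# ---------------------------------------------------------------------------
# evaluation, anchoring, extrapolation
# ---------------------------------------------------------------------------

def survival_at(fit: SurvivalFit, times) -> np.ndarray:
    """S(t) for the fitted model; S(0) = 1, values clamped to [0, 1]."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time")
    if fit.family == "rp_spline":
        s = _rp_sf(fit.params, t)
    else:
        s = _FAMILIES[fit.family]["sf"](fit.params, np.maximum(t, 0))
        s = np.where(t == 0, 1.0, s)
    return np.clip(s, 0.0, 1.0)


@dataclass
class AnchoredCurve:
    """A survival curve derived from a base curve via a hazard ratio."""

    base: np.ndarray
    hr: float
    result: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.hr <= 0:
            raise ValueError("hazard ratio must be > 0")
        self.base = np.asarray(self.base, dtype=float)
        if np.any((self.base < 0) | (self.base > 1)):
            raise ValueError("base survival outside [0, 1]")
        if np.any(np.diff(self.base) > 1e-12):
            raise ValueError("base survival must be non-increasing")
        self.result = apply_hazard_ratio(self.base, self.hr)


def apply_hazard_ratio(base_curve, hr: float) -> np.ndarray:
    """Proportional-hazards anchoring on the survival scale: S**HR."""
    if hr <= 0:
        raise ValueError("hazard ratio must be > 0")
    base = np.asarray(base_curve, dtype=float)
    return np.power(base, hr)


def extrapolate(fit_or_curve, config: RunConfig) -> np.ndarray:
    """Per-cycle survival over the model horizon (cycle-start evaluation).

    Accepts a :class:`SurvivalFit`, an :class:`AnchoredCurve`, or an
    explicit vector (padded/truncated to the horizon's cycle count).
    """
    n = config.n_cycles
    times = config.cycle_times()
    if isinstance(fit_or_curve, SurvivalFit):
        s = survival_at(fit_or_curve, times)
    elif isinstance(fit_or_curve, AnchoredCurve):
        s = fit_or_curve.result
    else:
        s = np.asarray(fit_or_curve, dtype=float)
    if len(s) < n:
        s = np.concatenate([s, np.full(n - len(s), s[-1])])
    s = np.clip(s[:n], 0.0, 1.0)
    s[0] = 1.0
    return np.minimum.accumulate(s)
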