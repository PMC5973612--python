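"""Degree-distribution model fitting and AICc selection.

Six candidate discrete models are fitted to the raw degree sequence of the
undirected projection by maximum likelihood, and compared with the Akaike
Information Criterion corrected for small samples,

    AICc = -2 logL + 2K + 2K(K+1) / (n - K - 1),

with n the number of nodes.  The cumulative (survival) form P(k) = fraction
of nodes with degree >= k is provided for presentation; likelihoods are
always evaluated on the raw sequence.

Models and their pmfs (kmin = minimum observed degree; no tail-threshold
optimization is attempted):

======================  ===========================================  ===
poisson                 Poisson(lambda), support k >= 0              K=1
exponential             (1-q) q^(k-kmin), q = exp(-1/kappa)          K=1
power_law               k^-alpha / zeta(alpha, kmin)                 K=1
truncated_power_law     k^-alpha exp(-k/kappa), numeric norm         K=2
lognormal               exp(-(ln k - mu)^2 / 2 sigma^2)/k, numeric   K=2
uniform                 1 / (kmax - kmin + 1) on [kmin, kmax]        K=2
======================  ===========================================  ===

The power-law, truncated power-law and lognormal models need strictly
positive degrees; on sequences containing isolated nodes they are flagged
unconverged and excluded from selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "MODELS",
    "CumulativeDegreeDistribution",
    "DegreeFitResult",
    "cumulative_distribution",
    "fit_model",
    "fit_all",
    "aicc",
    "select_model",
]

MODELS = (
    "poisson",
    "exponential",
    "power_law",
    "truncated_power_law",
    "lognormal",
    "uniform",
)

_N_PARAMS = {
    "poisson": 1,
    "exponential": 1,
    "power_law": 1,
    "truncated_power_law": 2,
    "lognormal": 2,
    "uniform": 2,
}


@dataclass(frozen=True)
class CumulativeDegreeDistribution:
    """Survival distribution: fraction of nodes with degree >= k."""

    k: np.ndarray
    p_ge: np.ndarray


@dataclass
class DegreeFitResult:
    """One fitted degree-distribution model."""

    model: str
    params: dict
    loglik: float
    n_params: int
    n: int
    aicc: float | None = None
    delta_aicc: float | None = None
    selected: bool = False
    converged: bool = True
    note: str = ""
    support: tuple | None = field(default=None, repr=False)  # (k values, pmf) for checks
    total_mass: float | None = field(default=None, repr=False)  # pmf sum incl. analytic tail


def cumulative_distribution(degrees) -> CumulativeDegreeDistribution:
    degrees = np.asarray(degrees)
    if degrees.size == 0:
        raise ValueError("empty degree sequence")
    if (degrees < 0).any():
        raise ValueError("negative degree")
    k = np.unique(degrees)
    p_ge = np.array([(degrees >= kk).mean() for kk in k])
    return CumulativeDegreeDistribution(k=k, p_ge=p_ge)


def aicc(loglik: float, K: int, n: int) -> float:
    if n <= K + 1:
        raise ValueError(f"AICc correction undefined for n={n} <= K+1={K + 1}")
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def _result(model, params, loglik, n, support=None, converged=True, note="",
            tail_mass=0.0) -> DegreeFitResult:
    K = _N_PARAMS[model]
    res = DegreeFitResult(
        model=model,
        params=params,
        loglik=float(loglik),
        n_params=K,
        n=n,
        converged=converged,
        note=note,
        support=support,
        total_mass=float(support[1].sum() + tail_mass) if support is not None else None,
    )
    if converged and np.isfinite(res.loglik):
        res.aicc = aicc(res.loglik, K, n)
    else:
        res.converged = False
    return res


def _failed(model, n, note) -> DegreeFitResult:
    return DegreeFitResult(
        model=model,
        params={},
        loglik=float("-inf"),
        n_params=_N_PARAMS[model],
        n=n,
        converged=False,
        note=note,
    )


def _fit_poisson(k, n):
    lam = float(k.mean())
    ll = float(stats.poisson.logpmf(k, lam).sum()) if lam > 0 else (0.0 if (k == 0).all() else -np.inf)
    grid = np.arange(0, max(int(k.max()) * 3 + 10, 50))
    return _result("poisson", {"lambda": lam}, ll, n,
                   support=(grid, stats.poisson.pmf(grid, lam)),
                   tail_mass=float(stats.poisson.sf(grid[-1], lam)))


def _fit_exponential(k, n, kmin):
    # geometric decay on k >= kmin: p(k) = (1 - q) q^(k - kmin), MLE in closed form
    m = float((k - kmin).mean())
    if m == 0.0:
        return _result("exponential", {"kappa": 0.0, "kmin": kmin}, 0.0, n,
                       support=(np.array([kmin]), np.array([1.0])))
    q = m / (1.0 + m)
    kappa = -1.0 / np.log(q)
    ll = n * np.log(1.0 - q) + float((k - kmin).sum()) * np.log(q)
    grid = np.arange(kmin, kmin + max(int(50 * (m + 1)), 50))
    pmf = (1.0 - q) * q ** (grid - kmin)
    return _result("exponential", {"kappa": float(kappa), "kmin": kmin}, ll, n,
                   support=(grid, pmf), tail_mass=float(q ** len(grid)))


def _fit_power_law(k, n, kmin):
    if kmin < 1:
        return _failed("power_law", n, "power law requires degrees >= 1")
    sum_log = float(np.log(k).sum())

    def nll(alpha):
        return alpha * sum_log + n * np.log(special.zeta(alpha, kmin))

    res = optimize.minimize_scalar(nll, bounds=(1.0 + 1e-6, 25.0), method="bounded")
    alpha = float(res.x)
    grid = np.arange(kmin, 50_000)
    z = special.zeta(alpha, kmin)
    pmf = grid.astype(float) ** (-alpha) / z
    tail = float(special.zeta(alpha, grid[-1] + 1) / z)
    return _result("power_law", {"alpha": alpha, "kmin": kmin}, -float(res.fun), n,
                   support=(grid, pmf), converged=bool(res.success), tail_mass=tail)


def _tpl_log_norm(alpha, kappa, kmin, kmax):
    upper = int(min(max(1000, 20 * kmax, 30 * kappa) + kmin, 200_000))
    grid = np.arange(kmin, upper + 1, dtype=float)
    logw = -alpha * np.log(grid) - grid / kappa
    return special.logsumexp(logw), grid, logw


def _fit_truncated_power_law(k, n, kmin, kmax):
    if kmin < 1:
        return _failed("truncated_power_law", n, "power law requires degrees >= 1")
    sum_log = float(np.log(k).sum())
    sum_k = float(k.sum())

    def nll(x):
        alpha, log_kappa = x
        kappa = np.exp(log_kappa)
        if not (0.0 <= alpha <= 25.0) or not (1e-3 <= kappa <= 1e4):
            return np.inf
        log_z, _, _ = _tpl_log_norm(alpha, kappa, kmin, kmax)
        return alpha * sum_log + sum_k / kappa + n * log_z

    # start from the pure power law's exponent and the mean excess as scale
    x0 = np.array([1.5, np.log(max(float((k - kmin).mean()) + 1.0, 1.5))])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
    alpha, kappa = float(res.x[0]), float(np.exp(res.x[1]))
    log_z, grid, logw = _tpl_log_norm(alpha, kappa, kmin, kmax)
    return _result(
        "truncated_power_law",
        {"alpha": alpha, "kappa": kappa, "kmin": kmin},
        -float(res.fun),
        n,
        support=(grid.astype(int), np.exp(logw - log_z)),
        converged=bool(res.success) and np.isfinite(res.fun),
    )


def _lognormal_log_norm(mu, sigma, kmin, kmax):
    upper = int(min(max(10_000, 100 * kmax), 200_000))
    grid = np.arange(kmin, upper + 1, dtype=float)
    logw = -((np.log(grid) - mu) ** 2) / (2.0 * sigma**2) - np.log(grid)
    return special.logsumexp(logw), grid, logw


def _fit_lognormal(k, n, kmin, kmax):
    if kmin < 1:
        return _failed("lognormal", n, "lognormal requires degrees >= 1")
    logk = np.log(k.astype(float))

    def nll(x):
        mu, log_sigma = x
        sigma = np.exp(log_sigma)
        if not (1e-3 <= sigma <= 5.0) or abs(mu) > 20:
            return np.inf
        log_z, _, _ = _lognormal_log_norm(mu, sigma, kmin, kmax)
        return float(((logk - mu) ** 2).sum()) / (2.0 * sigma**2) + float(logk.sum()) + n * log_z

    x0 = np.array([float(logk.mean()), np.log(max(float(logk.std()), 0.05))])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
    mu, sigma = float(res.x[0]), float(np.exp(res.x[1]))
    log_z, grid, logw = _lognormal_log_norm(mu, sigma, kmin, kmax)
    return _result(
        "lognormal",
        {"mu": mu, "sigma": sigma, "kmin": kmin},
        -float(res.fun),
        n,
        support=(grid.astype(int), np.exp(logw - log_z)),
        converged=bool(res.success) and np.isfinite(res.fun),
    )


def _fit_uniform(k, n, kmin, kmax):
    width = kmax - kmin + 1
    ll = -n * np.log(width)
    grid = np.arange(kmin, kmax + 1)
    return _result("uniform", {"kmin": kmin, "kmax": kmax}, ll, n,
                   support=(grid, np.full(width, 1.0 / width)))


def fit_model(degrees, model: str) -> DegreeFitResult:
    """Maximum-likelihood fit of one candidate model to a degree sequence."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    k = np.asarray(degrees, dtype=np.int64)
    if k.size < 5:
        raise ValueError("need at least 5 degrees to fit")
    if (k < 0).any():
        raise ValueError("negative degree")
    n = int(k.size)
    kmin, kmax = int(k.min()), int(k.max())
    if kmin == kmax and model not in ("uniform", "poisson"):
        return _failed(model, n, "degenerate support: single distinct degree")
    if model == "poisson":
        return _fit_poisson(k, n)
    if model == "exponential":
        return _fit_exponential(k, n, kmin)
    if model == "power_law":
        return _fit_power_law(k, n, kmin)
    if model == "truncated_power_law":
        return _fit_truncated_power_law(k, n, kmin, kmax)
    if model == "lognormal":
        return _fit_lognormal(k, n, kmin, kmax)
    return _fit_uniform(k, n, kmin, kmax)


def fit_all(degrees, models=MODELS) -> list[DegreeFitResult]:
    return [fit_model(degrees, m) for m in models]


def select_model(fits: list[DegreeFitResult]) -> DegreeFitResult:
    """Pick the minimal-AICc fit; ties go to fewer parameters, then model order.

    Unconverged fits are excluded but keep a NaN delta.  The winner's
    ``selected`` flag and every converged fit's ``delta_aicc`` are set in
    place.
    """
    usable = [f for f in fits if f.converged and f.aicc is not None]
    if not usable:
        raise ValueError("no converged fit to select from")
    order = {m: i for i, m in enumerate(MODELS)}
    best = min(usable, key=lambda f: (f.aicc, f.n_params, order[f.model]))
    for f in fits:
        f.selected = False
        f.delta_aicc = (f.aicc - best.aicc) if (f.converged and f.aicc is not None) else float("nan")
    best.selected = True
    return best
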