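"""Bayesian disproportionality: BCPNN information component and the
DuMouchel gamma-Poisson shrinker (MGPS).

BCPNN
-----
The information component is IC = log2 P(drug, event) / [P(drug) P(event)].
With Beta priors (alpha1 = beta1 = 1 on the margins, alpha = beta = 2 on the
joint, gamma11 = 1 with the dependence parameter

    gamma = gamma11 (N + alpha)(N + beta) / [(a+b+alpha1)(a+c+beta1)]

chosen so the prior IC expectation is zero), the posterior mean and variance
have closed forms:

    E(IC)  = log2 [ (a+gamma11)(N+alpha)(N+beta)
                    / ((N+gamma)(a+b+alpha1)(a+c+beta1)) ]
    V(IC)  = (ln 2)^-2 [ (N-a+gamma-gamma11) / ((a+gamma11)(1+N+gamma))
                       + (N-a-b+alpha-alpha1) / ((a+b+alpha1)(1+N+alpha))
                       + (N-a-c+beta-beta1)  / ((a+c+beta1)(1+N+beta)) ]

IC025 is the classic two-standard-deviation lower bound E(IC) - 2 sqrt(V).
These moments are a large-count approximation: for cells where the observed
count dwarfs a small expected count they shrink noticeably harder than the
exact Dirichlet posterior (see docs/methods.md).

MGPS
----
Each cell's observed count n is Poisson(lambda * e) with e the expected count
under independence and lambda the relative reporting rate.  The prior on
lambda is a two-component gamma mixture

    lambda ~ w Gamma(alpha1, beta1) + (1-w) Gamma(alpha2, beta2)   (rate form)

so marginally n follows a mixture of two negative binomials.  The five
hyperparameters are estimated by maximizing the summed log marginal
likelihood over all drug-event cells; the posterior for one cell is again a
gamma mixture, from which EBGM = 2^{E[log2 lambda]} (geometric mean) and the
5th posterior percentile EBGM05 follow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, special

from .contingency import ContingencyTable, StratumKey

__all__ = [
    "BcpnnResult",
    "compute_bcpnn",
    "MgpsHyperparams",
    "MgpsCell",
    "DEFAULT_MGPS_INIT",
    "marginal_loglik",
    "fit_mgps",
    "mgps_posterior",
    "stratified_expected",
    "simulate_cells",
]


# --------------------------------------------------------------------------
# BCPNN
# --------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class BcpnnResult:
    ic: float
    ic_sd: float
    ic025: float


def compute_bcpnn(
    t: ContingencyTable,
    *,
    alpha1: float = 1.0,
    beta1: float = 1.0,
    alpha: float = 2.0,
    beta: float = 2.0,
    gamma11: float = 1.0,
    n_sd: float = 2.0,
) -> BcpnnResult:
    """Closed-form posterior moments of the information component."""
    n = t.n_total
    if n == 0:
        raise ValueError("contingency table is empty (N = 0)")
    a = t.a
    row = t.a + t.b  # reports with the drug
    col = t.a + t.c  # reports with the event
    gamma = gamma11 * (n + alpha) * (n + beta) / ((row + alpha1) * (col + beta1))
    ic = math.log2(
        (a + gamma11) * (n + alpha) * (n + beta)
        / ((n + gamma) * (row + alpha1) * (col + beta1))
    )
    var = (
        (n - a + gamma - gamma11) / ((a + gamma11) * (1 + n + gamma))
        + (n - row + alpha - alpha1) / ((row + alpha1) * (1 + n + alpha))
        + (n - col + beta - beta1) / ((col + beta1) * (1 + n + beta))
    ) / (math.log(2) ** 2)
    sd = math.sqrt(var)
    return BcpnnResult(ic=ic, ic_sd=sd, ic025=ic - n_sd * sd)


# --------------------------------------------------------------------------
# MGPS
# --------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class MgpsHyperparams:
    """Two-component gamma-mixture prior (shape/rate form) with weight w."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma shape/rate parameters must be positive")
        if not 0.0 < self.w < 1.0:
            raise ValueError("mixture weight must be strictly inside (0, 1)")

    @property
    def mixture_mean(self) -> float:
        """Prior mean relative reporting rate E[lambda]."""
        return self.w * self.alpha1 / self.beta1 + (1 - self.w) * self.alpha2 / self.beta2

    def to_unconstrained(self) -> np.ndarray:
        return np.array([
            math.log(self.alpha1), math.log(self.beta1),
            math.log(self.alpha2), math.log(self.beta2),
            math.log(self.w / (1 - self.w)),
        ])

    @classmethod
    def from_unconstrained(cls, theta: np.ndarray) -> "MgpsHyperparams":
        la1, lb1, la2, lb2, lw = theta
        return cls(math.exp(la1), math.exp(lb1), math.exp(la2), math.exp(lb2),
                   1.0 / (1.0 + math.exp(-lw)))


#: DuMouchel's customary starting point for the hyperparameter search.
DEFAULT_MGPS_INIT = MgpsHyperparams(alpha1=0.2, beta1=0.1, alpha2=2.0, beta2=4.0, w=1.0 / 3.0)


@dataclass(frozen=True, slots=True)
class MgpsCell:
    """Posterior summary for one drug-event cell."""

    n: int
    e: float
    q: float  # posterior weight of mixture component 1
    ebgm: float
    ebgm05: float


def _log_nb(n: np.ndarray, e: np.ndarray, shape: float, rate: float) -> np.ndarray:
    """log pmf of the negative binomial marginal of Poisson(lambda e) with
    lambda ~ Gamma(shape, rate); success probability rate/(rate+e)."""
    return (
        special.gammaln(shape + n)
        - special.gammaln(shape)
        - special.gammaln(n + 1.0)
        + shape * (math.log(rate) - np.log(rate + e))
        + n * (np.log(e) - np.log(rate + e))
    )


def _log_mix(n: np.ndarray, e: np.ndarray, h: MgpsHyperparams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    l1 = _log_nb(n, e, h.alpha1, h.beta1) + math.log(h.w)
    l2 = _log_nb(n, e, h.alpha2, h.beta2) + math.log(1.0 - h.w)
    return np.logaddexp(l1, l2), l1, l2


def marginal_loglik(cells, h: MgpsHyperparams) -> float:
    """Summed log marginal likelihood of (n, e) cells under the mixture."""
    n, e = _as_cell_arrays(cells)
    return float(_log_mix(n, e, h)[0].sum())


def _as_cell_arrays(cells) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(cells, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("cells must be a sequence of (n, e) pairs")
    n, e = arr[:, 0], arr[:, 1]
    if np.any(e <= 0):
        raise ValueError("all expected counts e must be positive")
    return n, e


def fit_mgps(
    cells,
    init: MgpsHyperparams = DEFAULT_MGPS_INIT,
    *,
    n_restarts: int = 5,
    seed: int = 0,
) -> MgpsHyperparams:
    """Maximize the mixture marginal likelihood over the five hyperparameters.

    Optimization runs on the unconstrained scale (log for positives, logit
    for the weight) with L-BFGS-B, from ``init`` plus ``n_restarts`` seeded
    random perturbations to guard against local optima.  The returned prior
    never has lower likelihood than ``init`` (ascent contract).

    The search box is bounded to |theta| <= 12 (hyperparameters within
    e^-12..e^12): far outside any plausible prior, yet tight enough that the
    log-gamma differences in the likelihood stay numerically exact.  A
    candidate whose summed log pmf comes out positive — impossible for a
    discrete model, a symptom of cancellation — is rejected outright.
    """
    n, e = _as_cell_arrays(cells)
    with np.errstate(invalid="ignore"):
        ll_init = float(_log_mix(n, e, init)[0].sum())
    if not math.isfinite(ll_init):
        raise ValueError(
            "marginal likelihood is not finite at the initial hyperparameters; "
            "rescale the initialization to the data"
        )

    def neg_ll(theta: np.ndarray) -> float:
        try:
            h = MgpsHyperparams.from_unconstrained(theta)
        except (OverflowError, ValueError):
            return 1e300
        val = _log_mix(n, e, h)[0].sum()
        return 1e300 if not np.isfinite(val) else -float(val)

    rng = np.random.default_rng(seed)
    theta0 = np.clip(init.to_unconstrained(), -12.0, 12.0)
    starts = [theta0]
    for _ in range(n_restarts):
        starts.append(np.clip(theta0 + rng.normal(scale=1.0, size=5), -12.0, 12.0))

    bounds = [(-12.0, 12.0)] * 5
    best_h, best_ll = init, ll_init
    for start in starts:
        res = optimize.minimize(neg_ll, start, method="L-BFGS-B",
                                bounds=bounds, options={"maxiter": 500})
        cand_ll = -res.fun
        if not np.isfinite(cand_ll) or cand_ll > 0.0:
            continue  # positive total log pmf is a numerical artifact
        if cand_ll > best_ll:
            best_ll = cand_ll
            best_h = MgpsHyperparams.from_unconstrained(res.x)
    return best_h


def _posterior_q(n: float, e: float, h: MgpsHyperparams) -> float:
    nn = np.asarray([n], dtype=float)
    ee = np.asarray([e], dtype=float)
    tot, l1, _ = _log_mix(nn, ee, h)
    return float(np.exp(l1[0] - tot[0]))


def _mixture_cdf(x: float, n: float, e: float, q: float, h: MgpsHyperparams) -> float:
    """Posterior CDF of lambda at x: gamma-mixture with updated parameters."""
    if x <= 0:
        return 0.0
    c1 = special.gammainc(h.alpha1 + n, (h.beta1 + e) * x)
    c2 = special.gammainc(h.alpha2 + n, (h.beta2 + e) * x)
    return q * c1 + (1.0 - q) * c2


def mgps_posterior(n: int, e: float, h: MgpsHyperparams) -> MgpsCell:
    """Posterior mixture summary: component weight Q, EBGM and EBGM05.

    lambda | n  ~  Q Gamma(alpha1+n, beta1+e) + (1-Q) Gamma(alpha2+n, beta2+e)
    EBGM = exp(E[ln lambda]) via the digamma function; EBGM05 solves
    CDF(q) = 0.05 by bracketed root finding (tolerance ~1e-12 on the CDF).
    """
    if e <= 0:
        raise ValueError("expected count e must be positive")
    q = _posterior_q(n, e, h)
    mean_log = (
        q * (special.digamma(h.alpha1 + n) - math.log(h.beta1 + e))
        + (1 - q) * (special.digamma(h.alpha2 + n) - math.log(h.beta2 + e))
    )
    ebgm = math.exp(mean_log)

    def f(x: float) -> float:
        return _mixture_cdf(x, n, e, q, h) - 0.05

    hi = max((h.alpha1 + n) / (h.beta1 + e), (h.alpha2 + n) / (h.beta2 + e), 1e-6)
    while f(hi) < 0:
        hi *= 4.0
    lo = 1e-300
    ebgm05 = float(optimize.brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200))
    return MgpsCell(n=int(n), e=float(e), q=q, ebgm=ebgm, ebgm05=ebgm05)


def stratified_expected(tables: dict[StratumKey, ContingencyTable]) -> float:
    """Mantel-Haenszel-style expected count: sum over strata of
    (a_s + b_s)(a_s + c_s) / N_s, skipping empty strata."""
    e = 0.0
    for t in tables.values():
        if t.n_total > 0:
            e += (t.a + t.b) * (t.a + t.c) / t.n_total
    return e


def simulate_cells(
    h: MgpsHyperparams,
    n_cells: int,
    rng: np.random.Generator,
    *,
    e_log_mean: float = 0.5,
    e_log_sd: float = 1.0,
) -> np.ndarray:
    """Draw (n, e) cells from the MGPS generative model for recovery studies.

    Baseline expected counts e are lognormal; lambda comes from the gamma
    mixture; n ~ Poisson(lambda e).  Returns an array of shape (n_cells, 2).
    """
    e = rng.lognormal(mean=e_log_mean, sigma=e_log_sd, size=n_cells)
    comp1 = rng.random(n_cells) < h.w
    lam = np.where(
        comp1,
        rng.gamma(shape=h.alpha1, scale=1.0 / h.beta1, size=n_cells),
        rng.gamma(shape=h.alpha2, scale=1.0 / h.beta2, size=n_cells),
    )
    n = rng.poisson(lam * e)
    return np.column_stack([n.astype(float), e])
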