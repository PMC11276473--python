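"""Conventional latent profile analysis and a finite Bayesian comparator.

Conventional LPA is a finite mixture of Gaussians with profile-specific
means and a shared diagonal covariance (per-indicator variances, equal
across profiles), estimated by maximum likelihood with EM.  Model size is
chosen by AIC/BIC, by the parametric bootstrap likelihood ratio test
(BLRT), or — for the finite Bayesian variant with a symmetric Dirichlet
prior on the mixing weights — by comparing variational evidence lower
bounds across sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp
from sklearn.cluster import KMeans

from .io_config import IndicatorMatrix
from .dpm import PriorSpec

_LOG_2PI = np.log(2.0 * np.pi)
_VAR_FLOOR = 1e-6
_COLLAPSE_FRACTION = 1e-8


@dataclass
class LPAFit:
    """A fitted finite-mixture LPA model.

    n_params counts T*m profile means, m shared variances, and T-1 free
    mixing weights.
    """

    T: int
    means: np.ndarray  # T x m
    precisions: np.ndarray  # m, shared across profiles
    weights: np.ndarray  # T
    resp: np.ndarray  # n x T
    loglik: float
    n_params: int
    converged: bool
    seed: int
    loglik_trace: list = field(default_factory=list)
    elbo_trace: list = field(default_factory=list)

    @property
    def variances(self) -> np.ndarray:
        return 1.0 / self.precisions


@dataclass
class BlrtResult:
    """Bootstrap likelihood ratio test of T vs T+1 profiles.

    p_value uses the add-one estimator (1 + #{boot >= observed}) / (n_boot + 1),
    which never returns exactly zero.
    """

    observed_lr: float
    bootstrap_lrs: list
    p_value: float
    n_boot: int
    T: int = 0


def _as_matrix(data) -> np.ndarray:
    return data.values if isinstance(data, IndicatorMatrix) else np.asarray(data, float)


def _log_density(x, means, variances, log_weights):
    """n x T matrix of log(pi_t) + log N(x_i | mu_t, diag(var))."""
    const = -0.5 * (np.log(variances).sum() + x.shape[1] * _LOG_2PI)
    inv = 1.0 / variances
    quad = (
        (x**2 * inv).sum(axis=1)[:, None]
        - 2.0 * x @ (inv[:, None] * means.T)
        + ((means**2) * inv[None, :]).sum(axis=1)[None, :]
    )
    return log_weights[None, :] + const - 0.5 * quad


def mixture_loglik(x, means, variances, weights) -> float:
    """Observed-data log-likelihood of the shared-diagonal Gaussian mixture."""
    with np.errstate(divide="ignore"):
        lw = np.log(weights)
    return float(logsumexp(_log_density(x, means, variances, lw), axis=1).sum())


def _m_step(x, resp):
    n, m = x.shape
    nk = resp.sum(axis=0)
    means = (resp.T @ x) / nk[:, None]
    # shared per-indicator variance pooled across profiles
    sq = (x**2).sum(axis=0)
    variances = (sq - (nk[:, None] * means**2).sum(axis=0)) / n
    return nk / n, means, np.maximum(variances, _VAR_FLOOR)


def _em_init(x, T, rng):
    n = x.shape[0]
    km = KMeans(n_clusters=min(T, n), n_init=1, max_iter=10,
                random_state=int(rng.integers(2**31 - 1)))
    labels = km.fit_predict(x)
    resp = np.full((n, T), 1e-3)
    resp[np.arange(n), labels] = 1.0
    resp /= resp.sum(axis=1, keepdims=True)
    return _m_step(x, resp)


def _em_iterate(x, weights, means, variances, tol, max_iter):
    n = x.shape[0]
    prev = -np.inf
    converged = False
    trace = []
    for _ in range(max_iter):
        with np.errstate(divide="ignore"):
            lw = np.log(weights)
        logdens = _log_density(x, means, variances, lw)
        norm = logsumexp(logdens, axis=1)
        loglik = float(norm.sum())
        trace.append(loglik)
        resp = np.exp(logdens - norm[:, None])
        nk = resp.sum(axis=0)
        if np.any(nk < _COLLAPSE_FRACTION * n):
            return None  # collapsed component; caller re-initializes
        weights, means, variances = _m_step(x, resp)
        if loglik - prev < tol * (abs(prev) + 1e-12) and np.isfinite(prev):
            converged = True
            prev = loglik
            break
        prev = loglik
    # final E-step so resp/loglik match the returned parameters
    with np.errstate(divide="ignore"):
        lw = np.log(weights)
    logdens = _log_density(x, means, variances, lw)
    norm = logsumexp(logdens, axis=1)
    trace.append(float(norm.sum()))
    return (weights, means, variances, np.exp(logdens - norm[:, None]),
            float(norm.sum()), converged, trace)


def fit_em(
    data,
    T: int,
    n_restarts: int = 20,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> LPAFit:
    """Maximum-likelihood LPA with T profiles; best of n_restarts EM runs.

    Each restart starts from a (short) k-means partition under a distinct
    sub-seed and runs a capped "short EM" burst; only the best burst is then
    iterated to full convergence (the usual short-run/polish strategy).  A
    restart whose smallest class keeps responsibility mass below 1e-8 * n is
    re-initialized; if every attempt collapses the best available fit is
    returned flagged non-converged.
    """
    x = _as_matrix(data)
    n, m = x.shape
    if not 1 <= T <= n:
        raise ValueError(f"T must be in 1..n, got {T}")
    master = np.random.default_rng(seed)
    best = None
    any_ok = False
    short_iter = min(100, max_iter)
    short_tol = max(tol, 1e-6)
    for _ in range(n_restarts):
        out = None
        for _attempt in range(3):
            params = _em_init(x, T, master)
            out = _em_iterate(x, *params, short_tol, short_iter)
            if out is not None:
                break
        if out is None:
            continue
        any_ok = True
        if best is None or out[4] > best[4]:
            best = out
    if best is None:
        raise RuntimeError(f"EM failed to produce a fit with T={T}: every restart collapsed")
    # polish the winning restart to the full tolerance
    polished = _em_iterate(x, best[0], best[1], best[2], tol, max_iter)
    if polished is not None:
        short_trace = best[6]
        best = polished[:6] + (short_trace[:-1] + polished[6],)
    weights, means, variances, resp, loglik, converged, trace = best
    return LPAFit(
        T=T,
        means=means,
        precisions=1.0 / variances,
        weights=weights,
        resp=resp,
        loglik=loglik,
        n_params=T * m + m + (T - 1),
        converged=converged and any_ok,
        seed=seed,
        loglik_trace=trace,
    )


def information_criteria(fit: LPAFit, n: int) -> tuple[float, float]:
    """AIC and BIC of a fit: -2 loglik plus 2k or k ln(n). Lower is better."""
    if not np.isfinite(fit.loglik):
        raise ValueError("log-likelihood is not finite")
    aic = -2.0 * fit.loglik + 2.0 * fit.n_params
    bic = -2.0 * fit.loglik + fit.n_params * np.log(n)
    return float(aic), float(bic)


def sample_from_fit(fit: LPAFit, n: int, rng: np.random.Generator) -> np.ndarray:
    """Parametric-bootstrap draw of n participants from a fitted model."""
    labels = rng.choice(fit.T, size=n, p=fit.weights)
    sd = np.sqrt(fit.variances)
    return fit.means[labels] + rng.standard_normal((n, fit.means.shape[1])) * sd


def blrt(
    data,
    T: int,
    n_boot: int = 100,
    seed: int = 0,
    n_restarts: int = 20,
    n_restarts_boot: int = 4,
) -> BlrtResult:
    """Parametric bootstrap likelihood ratio test of T vs T+1 profiles.

    The observed statistic is 2*(loglik_{T+1} - loglik_T).  Each bootstrap
    replicate simulates data from the fitted T-profile model and refits both
    sizes (with fewer restarts, as is standard for the bootstrap inner loop).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    x = _as_matrix(data)
    n = x.shape[0]
    fit0 = fit_em(x, T, n_restarts=n_restarts, seed=seed)
    fit1 = fit_em(x, T + 1, n_restarts=n_restarts, seed=seed + 1)
    observed = 2.0 * (fit1.loglik - fit0.loglik)
    rng = np.random.default_rng(seed)
    boot = []
    for b in range(n_boot):
        xb = sample_from_fit(fit0, n, rng)
        sub = int(rng.integers(2**31 - 1))
        b0 = fit_em(xb, T, n_restarts=n_restarts_boot, seed=sub)
        b1 = fit_em(xb, T + 1, n_restarts=n_restarts_boot, seed=sub + 1)
        boot.append(2.0 * (b1.loglik - b0.loglik))
    boot = np.asarray(boot)
    p = (1.0 + np.sum(boot >= observed)) / (n_boot + 1.0)
    return BlrtResult(
        observed_lr=float(observed),
        bootstrap_lrs=boot.tolist(),
        p_value=float(p),
        n_boot=n_boot,
        T=T,
    )


# ---------------------------------------------------------------------------
# finite Bayesian LPA (variational, symmetric Dirichlet prior on weights)
# ---------------------------------------------------------------------------


class _FiniteVB:
    """Coordinate-ascent VB for the finite mixture with Dirichlet(1) weights.

    Mean/precision priors and their updates mirror the DPM fitter; only the
    membership prior differs (symmetric Dirichlet instead of stick-breaking).
    """

    def __init__(self, x, T, priors: PriorSpec, dirichlet_conc: float = 1.0):
        self.x = x
        self.x_sq = x**2
        self.n, self.m = x.shape
        self.T = T
        self.pr = priors
        self.conc = dirichlet_conc
        self.d = np.full(T, dirichlet_conc)
        self.mean_m = np.zeros((self.m, T))
        self.mean_v = np.full((self.m, T), priors.mean_variance_multiplier)
        self.xi_a = np.full(self.m, priors.precision_shape)
        self.xi_b = np.full(self.m, priors.precision_rate)
        self.resp = None

    @property
    def e_xi(self):
        return self.xi_a / self.xi_b

    @property
    def e_log_xi(self):
        return digamma(self.xi_a) - np.log(self.xi_b)

    @property
    def e_mu_sq(self):
        return self.mean_m**2 + self.mean_v

    def e_log_pi(self):
        return digamma(self.d) - digamma(self.d.sum())

    def update_resp(self):
        quad = (
            self.x_sq @ self.e_xi[:, None]
            - 2.0 * self.x @ (self.e_xi[:, None] * self.mean_m)
            + (self.e_xi[:, None] * self.e_mu_sq).sum(axis=0)[None, :]
        )
        log_rho = self.e_log_pi()[None, :] + 0.5 * (
            self.e_log_xi.sum() - self.m * _LOG_2PI
        ) - 0.5 * quad
        log_rho -= logsumexp(log_rho, axis=1, keepdims=True)
        self.resp = np.exp(log_rho)

    def update_params(self):
        counts = self.resp.sum(axis=0)
        self.d = self.conc + counts
        s = self.x.T @ self.resp
        a = 1.0 / self.pr.mean_variance_multiplier + counts[None, :]
        self.mean_m = s / a
        self.mean_v = 1.0 / (self.e_xi[:, None] * a)
        sq = self.x_sq.T @ self.resp
        resid = sq - 2.0 * self.mean_m * s + counts[None, :] * self.e_mu_sq
        self.xi_a = np.full(self.m, self.pr.precision_shape + 0.5 * (self.T + self.n))
        self.xi_b = (
            self.pr.precision_rate
            + 0.5 * self.e_mu_sq.sum(axis=1) / self.pr.mean_variance_multiplier
            + 0.5 * resid.sum(axis=1)
        )

    def elbo(self):
        pr = self.pr
        counts = self.resp.sum(axis=0)
        s = self.x.T @ self.resp
        sq = self.x_sq.T @ self.resp
        resid = sq - 2.0 * self.mean_m * s + counts[None, :] * self.e_mu_sq
        e_xi, e_log_xi = self.e_xi, self.e_log_xi
        ll = 0.5 * self.n * (e_log_xi.sum() - self.m * _LOG_2PI) - 0.5 * (
            e_xi[:, None] * resid
        ).sum()
        lz = float(counts @ self.e_log_pi())
        # symmetric Dirichlet(conc) prior on pi
        lpi = (
            gammaln(self.T * self.conc)
            - self.T * gammaln(self.conc)
            + (self.conc - 1.0) * self.e_log_pi().sum()
        )
        lxi = (
            pr.precision_shape * np.log(pr.precision_rate)
            - gammaln(pr.precision_shape)
            + (pr.precision_shape - 1.0) * e_log_xi
            - pr.precision_rate * e_xi
        ).sum()
        c = pr.mean_variance_multiplier
        lmu = (
            0.5 * self.T * (e_log_xi.sum() - self.m * np.log(2.0 * np.pi * c))
            - 0.5 * (e_xi[:, None] * self.e_mu_sq).sum() / c
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            hz = -np.sum(np.where(self.resp > 0, self.resp * np.log(self.resp), 0.0))
        d0 = self.d.sum()
        hpi = (
            gammaln(self.d).sum()
            - gammaln(d0)
            + (d0 - self.T) * digamma(d0)
            - ((self.d - 1.0) * digamma(self.d)).sum()
        )
        hxi = np.sum(
            self.xi_a - np.log(self.xi_b) + gammaln(self.xi_a)
            + (1.0 - self.xi_a) * digamma(self.xi_a)
        )
        hmu = 0.5 * np.sum(np.log(2.0 * np.pi * np.e * self.mean_v))
        return float(ll + lz + lpi + lxi + lmu + hz + hpi + hxi + hmu)


def fit_finite_bayes(
    data,
    T: int,
    priors: PriorSpec = PriorSpec(),
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_restarts: int = 5,
) -> tuple[LPAFit, float]:
    """Variational fit of the finite Bayesian LPA with T profiles.

    Returns a posterior summary in LPAFit form (posterior-mean parameters,
    responsibilities, mixture log-likelihood at those parameters) and the
    final ELBO, the quantity compared across T for model selection.
    """
    if T < 1:
        raise ValueError("T must be at least 1")
    x = _as_matrix(data)
    n = x.shape[0]
    master = np.random.default_rng(seed)
    best = None
    best_trace = None
    for _ in range(n_restarts):
        vb = _FiniteVB(x, T, priors)
        km = KMeans(n_clusters=min(T, n), n_init=1, max_iter=10,
                    random_state=int(master.integers(2**31 - 1)))
        labels = km.fit_predict(x)
        resp = np.full((n, T), 1e-3)
        resp[np.arange(n), labels] = 1.0
        vb.resp = resp / resp.sum(axis=1, keepdims=True)
        vb.update_params()
        trace = []
        for _i in range(max_iter):
            vb.update_resp()
            vb.update_params()
            elbo = vb.elbo()
            if trace and abs(elbo - trace[-1]) < tol * (abs(trace[-1]) + 1e-12):
                trace.append(elbo)
                break
            trace.append(elbo)
        if best is None or trace[-1] > best_trace[-1]:
            best, best_trace = vb, trace
    weights = best.d / best.d.sum()
    means = best.mean_m.T
    variances = best.xi_b / best.xi_a  # 1 / E[xi]
    fit = LPAFit(
        T=T,
        means=means,
        precisions=1.0 / variances,
        weights=weights,
        resp=best.resp,
        loglik=mixture_loglik(x, means, variances, weights),
        n_params=T * x.shape[1] + x.shape[1] + (T - 1),
        converged=True,
        seed=seed,
        elbo_trace=best_trace,
    )
    return fit, float(best_trace[-1])


# ---------------------------------------------------------------------------
# model selection across sizes
# ---------------------------------------------------------------------------

_CRITERIA = ("bic", "aic", "blrt", "finite_bayes_elbo")


def select_profiles(
    data,
    criterion: str = "bic",
    T_max: int = 8,
    n_restarts: int = 20,
    seed: int = 0,
    blrt_n_boot: int = 100,
    blrt_level: float = 0.05,
    blrt_n_restarts_boot: int = 4,
    priors: PriorSpec = PriorSpec(),
) -> tuple[int, pd.DataFrame]:
    """Choose the number of profiles and return the per-size criterion table.

    bic/aic: argmin over T = 1..T_max.  blrt: sequential stopping — the
    smallest T whose test against T+1 is non-significant at blrt_level.
    finite_bayes_elbo: argmax ELBO over T = 1..T_max.
    """
    if criterion not in _CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; choose from {_CRITERIA}")
    if T_max < 2:
        raise ValueError("T_max must be at least 2")
    x = _as_matrix(data)
    n = x.shape[0]
    rows = []

    if criterion == "blrt":
        selected = T_max
        for T in range(1, T_max):
            res = blrt(
                x, T, n_boot=blrt_n_boot, seed=seed + 1000 * T,
                n_restarts=n_restarts, n_restarts_boot=blrt_n_restarts_boot,
            )
            rows.append({"T": T, "vs": T + 1, "observed_lr": res.observed_lr,
                         "blrt_p": res.p_value})
            if res.p_value > blrt_level:
                selected = T
                break
        return selected, pd.DataFrame(rows)

    if criterion == "finite_bayes_elbo":
        for T in range(1, T_max + 1):
            _fit, elbo = fit_finite_bayes(x, T, priors=priors, seed=seed + T)
            rows.append({"T": T, "elbo": elbo})
        table = pd.DataFrame(rows)
        return int(table.loc[table["elbo"].idxmax(), "T"]), table

    for T in range(1, T_max + 1):
        fit = fit_em(x, T, n_restarts=n_restarts, seed=seed + T)
        aic, bic = information_criteria(fit, n)
        rows.append({"T": T, "loglik": fit.loglik, "aic": aic, "bic": bic})
    table = pd.DataFrame(rows)
    selected = int(table.loc[table[criterion].idxmin(), "T"])
    return selected, table
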