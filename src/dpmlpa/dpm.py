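"""Dirichlet process mixture latent profile analysis (DPM-LPA).

The model is a Gaussian mixture over standardized indicators with
profile-specific means, indicator-specific precisions shared across
profiles, and a Dirichlet process prior on profile membership:

    x_{j,i} | z_i = t  ~  N(mu_{j,t}, 1 / xi_j)
    xi_j               ~  Gamma(5, 5)          (shape-rate; prior mean 1)
    mu_{j,t} | xi_j    ~  N(0, 2 / xi_j)
    z_{1:n}            ~  DP(alpha),  alpha ~ Gamma(1, 1)

Inference is coordinate-ascent mean-field variational Bayes on a truncated
stick-breaking representation: independent factors for the responsibilities,
the stick proportions (Beta), the per-(indicator, profile) means (Gaussian),
the per-indicator precisions (Gamma), and the concentration alpha (Gamma).
Every update is conjugate/closed-form, so the evidence lower bound (ELBO) is
non-decreasing across iterations.

After fitting, components that are not the most probable profile for any
participant are treated as empty and dropped; the survivors are relabeled in
decreasing order of assigned count (profile 1 is the largest).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, digamma, gammaln, logsumexp
from sklearn.cluster import KMeans

from .io_config import IndicatorMatrix

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the conjugate priors (all strictly positive).

    Precisions get Gamma(shape, rate) priors; with standardized indicators the
    default Gamma(5, 5) centers the precision at 1.  Each profile mean gets a
    normal prior with variance ``mean_variance_multiplier / xi_j``.  The DP
    concentration alpha gets Gamma(alpha_shape, alpha_rate).
    """

    precision_shape: float = 5.0
    precision_rate: float = 5.0
    mean_variance_multiplier: float = 2.0
    alpha_shape: float = 1.0
    alpha_rate: float = 1.0

    def __post_init__(self):
        for name in (
            "precision_shape",
            "precision_rate",
            "mean_variance_multiplier",
            "alpha_shape",
            "alpha_rate",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class VariationalState:
    """Variational posterior factors from a truncated stick-breaking fit.

    resp: n x T_max responsibilities (rows sum to 1).
    stick_params: (T_max-1) x 2 Beta parameters for the stick proportions.
    mean_means / mean_vars: m x T_max location and variance of each Gaussian
        mean factor.
    precision_shape / precision_rate: m-vectors for the Gamma precision
        factors.
    alpha_params: (shape, rate) of the Gamma factor on alpha.
    elbo_trace: ELBO after each full coordinate sweep (non-decreasing).
    """

    resp: np.ndarray
    stick_params: np.ndarray
    mean_means: np.ndarray
    mean_vars: np.ndarray
    precision_shape: np.ndarray
    precision_rate: np.ndarray
    alpha_params: tuple
    elbo_trace: list = field(default_factory=list)
    seed: int = 0
    converged: bool = False

    @property
    def truncation(self) -> int:
        return self.resp.shape[1]


@dataclass
class ProfileSet:
    """Non-empty profiles extracted from a fit, largest first.

    means is T x m; precisions the shared m-vector (posterior means of xi);
    base_rates the mean renormalized responsibility per profile; counts the
    number of participants maximally assigned to each profile.
    """

    T: int
    means: np.ndarray
    precisions: np.ndarray
    base_rates: np.ndarray
    resp: np.ndarray
    counts: np.ndarray


def log_dp_prior(assignments: np.ndarray, alpha: float) -> float:
    """Log prior probability of a profile assignment under the Polya urn.

    For labels z_1..z_n with T occupied profiles of sizes n_t,

        p(z_{1:n}) = alpha^T prod_t (n_t - 1)! / [alpha (alpha+1) ... (n-1+alpha)]

    The value depends only on the multiset of profile sizes, so it is
    invariant to any permutation of participants.
    """
    z = np.asarray(assignments)
    if z.size == 0:
        raise ValueError("assignment vector is empty")
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    _, counts = np.unique(z, return_counts=True)
    n = z.size
    T = counts.size
    return (
        T * np.log(alpha)
        + gammaln(counts).sum()
        - (gammaln(n + alpha) - gammaln(alpha))
    )


def _init_resp(
    x: np.ndarray, truncation: int, k: int, rng: np.random.Generator
) -> np.ndarray:
    """K-means partition into k <= truncation clusters, softened with
    Dirichlet jitter over all components."""
    n = x.shape[0]
    k = min(k, n)
    if k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=1, random_state=int(rng.integers(2**31 - 1)))
        labels = km.fit_predict(x)
    resp = np.full((n, truncation), 1e-6)
    resp[np.arange(n), labels] = 1.0
    resp += 0.05 * rng.dirichlet(np.ones(truncation), size=n)
    return resp / resp.sum(axis=1, keepdims=True)


def _restart_ladder(truncation: int, n_restarts: int) -> list:
    """Initial cluster counts for the restarts: every small count (1..6),
    then a geometric ladder up to the truncation level, recycled.

    Coordinate ascent neither merges nor splits components reliably, so a
    start near the true profile count converges best; dense small counts
    plus sparse large ones cover the plausible range and the best final
    ELBO arbitrates."""
    small = list(range(1, min(6, truncation) + 1))
    geo = np.round(np.geomspace(min(8, truncation), truncation, num=3)).astype(int)
    ladder = sorted(set(small) | set(geo.tolist()))
    return [ladder[r % len(ladder)] for r in range(n_restarts)]


class _DPMState:
    """Mutable working state for one coordinate-ascent run."""

    def __init__(self, x: np.ndarray, priors: PriorSpec, truncation: int):
        self.x = x
        self.n, self.m = x.shape
        self.K = truncation
        self.pr = priors
        self.x_sq = x**2
        # factors, filled by updates
        self.resp = None
        self.gamma_a = np.ones(truncation - 1)
        self.gamma_b = np.ones(truncation - 1)
        self.w_a = priors.alpha_shape
        self.w_b = priors.alpha_rate
        self.mean_m = np.zeros((self.m, truncation))
        self.mean_v = np.full((self.m, truncation), priors.mean_variance_multiplier)
        self.xi_a = np.full(self.m, priors.precision_shape)
        self.xi_b = np.full(self.m, priors.precision_rate)

    # -- expectations -------------------------------------------------
    @property
    def e_xi(self):
        return self.xi_a / self.xi_b

    @property
    def e_log_xi(self):
        return digamma(self.xi_a) - np.log(self.xi_b)

    @property
    def e_alpha(self):
        return self.w_a / self.w_b

    @property
    def e_log_alpha(self):
        return digamma(self.w_a) - np.log(self.w_b)

    @property
    def e_mu_sq(self):
        return self.mean_m**2 + self.mean_v

    def _stick_logs(self):
        """E[log v_t] and E[log(1 - v_t)] for t < K (v_K is fixed at 1)."""
        dg_sum = digamma(self.gamma_a + self.gamma_b)
        e_log_v = digamma(self.gamma_a) - dg_sum
        e_log_1mv = digamma(self.gamma_b) - dg_sum
        return e_log_v, e_log_1mv

    def mix_log_weights(self):
        """E[log pi_t] under stick-breaking: log v_t + sum_{s<t} log(1-v_s)."""
        e_log_v, e_log_1mv = self._stick_logs()
        out = np.zeros(self.K)
        out[:-1] = e_log_v
        out[1:] += np.cumsum(e_log_1mv)
        return out

    # -- coordinate updates -------------------------------------------
    def update_resp(self):
        # E[(x - mu)^2 * xi] summed over indicators, for every (i, t)
        quad = (
            self.x_sq @ self.e_xi[:, None]  # n x 1
            - 2.0 * self.x @ (self.e_xi[:, None] * self.mean_m)  # n x K
            + (self.e_xi[:, None] * self.e_mu_sq).sum(axis=0)[None, :]
        )
        log_rho = self.mix_log_weights()[None, :] + 0.5 * (
            self.e_log_xi.sum() - self.m * _LOG_2PI
        ) - 0.5 * quad
        log_rho -= logsumexp(log_rho, axis=1, keepdims=True)
        self.resp = np.exp(log_rho)

    def update_sticks(self):
        counts = self.resp.sum(axis=0)  # N_t
        tail = np.cumsum(counts[::-1])[::-1]  # sum_{s>=t} N_s
        self.gamma_a = 1.0 + counts[:-1]
        self.gamma_b = self.e_alpha + tail[1:]

    def update_alpha(self):
        _, e_log_1mv = self._stick_logs()
        self.w_a = self.pr.alpha_shape + (self.K - 1)
        self.w_b = self.pr.alpha_rate - e_log_1mv.sum()

    def update_means(self):
        counts = self.resp.sum(axis=0)
        s = self.x.T @ self.resp  # m x K weighted sums
        a = 1.0 / self.pr.mean_variance_multiplier + counts[None, :]
        self.mean_m = s / a
        self.mean_v = 1.0 / (self.e_xi[:, None] * a)

    def update_precisions(self):
        counts = self.resp.sum(axis=0)
        s = self.x.T @ self.resp
        sq = self.x_sq.T @ self.resp  # m x K
        resid = sq - 2.0 * self.mean_m * s + counts[None, :] * self.e_mu_sq
        self.xi_a = np.full(
            self.m, self.pr.precision_shape + 0.5 * (self.K + self.n)
        )
        self.xi_b = (
            self.pr.precision_rate
            + 0.5 * self.e_mu_sq.sum(axis=1) / self.pr.mean_variance_multiplier
            + 0.5 * resid.sum(axis=1)
        )

    # -- objective ----------------------------------------------------
    def elbo(self) -> float:
        pr = self.pr
        counts = self.resp.sum(axis=0)
        s = self.x.T @ self.resp
        sq = self.x_sq.T @ self.resp
        resid = sq - 2.0 * self.mean_m * s + counts[None, :] * self.e_mu_sq
        e_xi, e_log_xi = self.e_xi, self.e_log_xi

        ll = 0.5 * self.n * (e_log_xi.sum() - self.m * _LOG_2PI) - 0.5 * (
            e_xi[:, None] * resid
        ).sum()

        lz = float(counts @ self.mix_log_weights())

        e_log_v, e_log_1mv = self._stick_logs()
        lv = (self.K - 1) * self.e_log_alpha + (self.e_alpha - 1.0) * e_log_1mv.sum()

        la = (
            pr.alpha_shape * np.log(pr.alpha_rate)
            - gammaln(pr.alpha_shape)
            + (pr.alpha_shape - 1.0) * self.e_log_alpha
            - pr.alpha_rate * self.e_alpha
        )

        lxi = (
            pr.precision_shape * np.log(pr.precision_rate)
            - gammaln(pr.precision_shape)
            + (pr.precision_shape - 1.0) * e_log_xi
            - pr.precision_rate * e_xi
        ).sum()

        c = pr.mean_variance_multiplier
        lmu = (
            0.5 * self.K * (e_log_xi.sum() - self.m * np.log(2.0 * np.pi * c))
            - 0.5 * (e_xi[:, None] * self.e_mu_sq).sum() / c
        )

        with np.errstate(divide="ignore", invalid="ignore"):
            hz = -np.sum(np.where(self.resp > 0, self.resp * np.log(self.resp), 0.0))
        hv = np.sum(
            betaln(self.gamma_a, self.gamma_b)
            - (self.gamma_a - 1.0) * digamma(self.gamma_a)
            - (self.gamma_b - 1.0) * digamma(self.gamma_b)
            + (self.gamma_a + self.gamma_b - 2.0) * digamma(self.gamma_a + self.gamma_b)
        )
        ha = _gamma_entropy(self.w_a, self.w_b)
        hxi = _gamma_entropy(self.xi_a, self.xi_b).sum() if np.ndim(self.xi_a) else 0.0
        hmu = 0.5 * np.sum(np.log(2.0 * np.pi * np.e * self.mean_v))

        return float(ll + lz + lv + la + lxi + lmu + hz + hv + ha + hxi + hmu)


def _gamma_entropy(a, b):
    return a - np.log(b) + gammaln(a) + (1.0 - a) * digamma(a)


def _run_one(
    x: np.ndarray,
    priors: PriorSpec,
    truncation: int,
    init_k: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    seed: int,
) -> VariationalState:
    st = _DPMState(x, priors, truncation)
    st.resp = _init_resp(x, truncation, init_k, rng)
    # bring parameter factors in line with the initial partition
    st.update_sticks()
    st.update_alpha()
    st.update_means()
    st.update_precisions()
    trace = []
    converged = False
    for _ in range(max_iter):
        st.update_resp()
        st.update_sticks()
        st.update_alpha()
        st.update_means()
        st.update_precisions()
        elbo = st.elbo()
        if trace and abs(elbo - trace[-1]) < tol * (abs(trace[-1]) + 1e-12):
            trace.append(elbo)
            converged = True
            break
        trace.append(elbo)
    return VariationalState(
        resp=st.resp,
        stick_params=np.column_stack([st.gamma_a, st.gamma_b]),
        mean_means=st.mean_m,
        mean_vars=st.mean_v,
        precision_shape=st.xi_a,
        precision_rate=st.xi_b,
        alpha_params=(float(st.w_a), float(st.w_b)),
        elbo_trace=trace,
        seed=seed,
        converged=converged,
    )


def extract_profiles(state: VariationalState) -> ProfileSet:
    """Drop empty components and relabel survivors largest-first.

    A component is retained iff it is the argmax responsibility for at least
    one participant (ties broken toward the lowest component index).  Retained
    profiles are ordered by decreasing assigned count, ties by original index;
    responsibilities are renormalized over the retained set and base rates are
    their column means.
    """
    resp = state.resp
    n = resp.shape[0]
    assign = resp.argmax(axis=1)  # np.argmax returns the lowest index on ties
    kept, counts = np.unique(assign, return_counts=True)
    order = np.lexsort((kept, -counts))  # count desc, original index asc
    kept, counts = kept[order], counts[order]
    sub = resp[:, kept]
    sub = sub / sub.sum(axis=1, keepdims=True)
    return ProfileSet(
        T=kept.size,
        means=state.mean_means[:, kept].T.copy(),
        precisions=state.precision_shape / state.precision_rate,
        base_rates=sub.mean(axis=0),
        resp=sub,
        counts=counts,
    )


def fit_dpm(
    data: IndicatorMatrix,
    priors: PriorSpec = PriorSpec(),
    truncation: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_restarts: int = 10,
) -> tuple[VariationalState, ProfileSet]:
    """Fit DPM-LPA by variational inference; return the best of n_restarts.

    Each restart gets a distinct sub-seed and starts from a k-means partition
    whose cluster count walks a geometric ladder from 1 up to the truncation
    level (coordinate ascent cannot reliably merge components, so coarse and
    fine starts are both needed); the restart with the highest final ELBO
    wins.  Convergence is declared when the relative ELBO change drops below
    ``tol``.
    """
    if truncation < 2:
        raise ValueError("truncation must be at least 2")
    if n_restarts < 1:
        raise ValueError("n_restarts must be at least 1")
    x = data.values if isinstance(data, IndicatorMatrix) else np.asarray(data, float)
    if not np.all(np.isfinite(x)):
        raise ValueError("data contain non-finite values")
    master = np.random.default_rng(seed)
    best = None
    failures = []
    ladder = _restart_ladder(truncation, n_restarts)
    for r in range(n_restarts):
        sub_seed = int(master.integers(2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        state = _run_one(x, priors, truncation, ladder[r], rng, tol, max_iter, sub_seed)
        final = state.elbo_trace[-1] if state.elbo_trace else -np.inf
        if not np.isfinite(final):
            failures.append((r, final))
            continue
        if best is None or final > best.elbo_trace[-1]:
            best = state
    if best is None:
        raise RuntimeError(f"all {n_restarts} restarts produced non-finite ELBOs: {failures}")
    return best, extract_profiles(best)
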