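"""Bayesian nonparametric latent-class capture-recapture (J >= 3 lists).

Multiple systems estimation infers the size N of a closed population from
the 2^J - 1 observable capture profiles of J lists. Heterogeneity (and the
between-list dependence it induces) is modelled with a latent-class
mixture: each individual belongs to class k with weight pi_k and is
captured by list j independently with probability lambda_kj, so the
probability of profile x is

    P(x) = sum_k pi_k * prod_j lambda_kj^{x_j} (1 - lambda_kj)^{1 - x_j}.

The class weights carry a truncated stick-breaking Dirichlet-process prior
pi_k = V_k * prod_{l<k} (1 - V_l), V_k ~ Beta(1, alpha), alpha ~ Gamma(a, b),
so the effective number of classes is learned from the data. Capture
probabilities have independent Beta(1, 1) priors, and the population size
carries the Jeffreys-type 1/N prior, under which the number of
never-captured individuals n0 has a negative-binomial full conditional.

Inference is by Gibbs sampling. Because the product-Bernoulli likelihood
depends on the data only through the profile counts, class memberships are
sampled as multinomial splits of each profile cell, which is exact and
makes an iteration O(K 2^J) regardless of sample size.

One sweep:
  1. split each observed profile count across classes with probability
     proportional to pi_k * prod_j lambda_kj^{x_j}(1-lambda_kj)^{1-x_j};
  2. compute p0 = sum_k pi_k prod_j (1 - lambda_kj) and draw
     n0 ~ NegBinom(n, 1 - p0) (the 1/N size-prior conditional);
  3. allocate the n0 zero-history individuals to classes with probability
     proportional to pi_k prod_j (1 - lambda_kj);
  4. lambda_kj ~ Beta(1 + captures, 1 + misses) from per-class tallies;
  5. V_k ~ Beta(1 + T_k, alpha + T_{>k}) with the truncation remainder
     assigned to class K; alpha ~ Gamma(a + K - 1, b - sum log(1 - V_k)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .capture_data import AggregateCaptureTable, all_profiles
from .results import EstimateResult

__all__ = [
    "NPLCMConfig",
    "NPLCMPosterior",
    "fit_nplcm",
    "summarize_posterior",
    "posterior_predictive_check",
    "m0_profile_mle",
]

_EPS = 1e-12


@dataclass(frozen=True)
class NPLCMConfig:
    """Sampler settings: truncation, priors, chain length, seed.

    ``max_classes`` truncates the stick-breaking representation (default
    min(2^J - 1, 10), resolved at fit time when left as None). The
    concentration alpha has a Gamma(``alpha_shape``, ``alpha_rate``) prior;
    capture probabilities are Beta(``lambda_a``, ``lambda_b``).
    """

    max_classes: int | None = None
    alpha_shape: float = 0.25
    alpha_rate: float = 0.25
    lambda_a: float = 1.0
    lambda_b: float = 1.0
    iterations: int = 100_000
    burn_in: int = 10_000
    thinning: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.max_classes is not None and self.max_classes < 1:
            raise ValueError("max_classes must be >= 1")
        if not (self.iterations > self.burn_in >= 0):
            raise ValueError("need iterations > burn_in >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if min(self.alpha_shape, self.alpha_rate, self.lambda_a, self.lambda_b) <= 0:
            raise ValueError("prior hyperparameters must be positive")

    def resolve_classes(self, n_sources: int) -> int:
        if self.max_classes is not None:
            return self.max_classes
        return min(2**n_sources - 1, 10)


@dataclass
class NPLCMPosterior:
    """Retained MCMC draws with summaries and diagnostics."""

    N: np.ndarray                      # (draws,) total-size draws, N = n + n0
    lam: np.ndarray                    # (draws, K, J) capture probabilities
    pi: np.ndarray                     # (draws, K) class weights
    alpha: np.ndarray                  # (draws,) DP concentration
    n_observed: int
    sources: tuple[str, ...]
    config: NPLCMConfig
    warnings_: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return len(self.N)

    def summary(self) -> dict[str, float]:
        q = np.percentile(self.N, [2.5, 50.0, 97.5])
        return {
            "median": float(q[1]),
            "mean": float(np.mean(self.N)),
            "ci_low": float(q[0]),
            "ci_high": float(q[2]),
        }

    def effective_sample_size(self) -> float:
        import arviz as az

        return float(az.ess(np.asarray(self.N, dtype=float)[None, :]))

    def draws_frame(self) -> pd.DataFrame:
        """Flat per-draw table (N, alpha, class weights) for external diagnostics."""
        df = pd.DataFrame({"N": self.N, "alpha": self.alpha})
        for k in range(self.pi.shape[1]):
            df[f"pi_{k + 1}"] = self.pi[:, k]
        return df


def _profile_matrix(table: AggregateCaptureTable) -> tuple[np.ndarray, np.ndarray]:
    """(profiles x sources) binary matrix and the matching count vector."""
    J = len(table.sources)
    profs = all_profiles(J)
    B = np.array([[int(c) for c in p] for p in profs], dtype=float)
    counts = np.array([table.counts[p] for p in profs], dtype=np.int64)
    return B, counts


def fit_nplcm(table: AggregateCaptureTable, config: NPLCMConfig | None = None) -> NPLCMPosterior:
    """Run the Gibbs sampler on an aggregate capture table.

    Returns thinned post-burn-in draws; bit-reproducible under a fixed
    ``config.seed``. Warns when J = 2 (the latent-class model is only
    weakly identified from two lists) and when the data are degenerate
    (a single nonzero profile).
    """
    config = config or NPLCMConfig()
    J = len(table.sources)
    if J < 2:
        raise ValueError("need at least 2 capture sources")
    n = table.n_observed
    if n < 1:
        raise ValueError("no observed individuals")
    warns: list[str] = []
    if J == 2:
        warns.append("only 2 sources: latent-class model weakly identified")
        warnings.warn(warns[-1], stacklevel=2)
    B, counts = _profile_matrix(table)
    if int(np.sum(counts > 0)) == 1:
        warns.append("degenerate table: a single nonzero capture profile")
        warnings.warn(warns[-1], stacklevel=2)

    K = config.resolve_classes(J)
    rng = np.random.default_rng(config.seed)
    P = len(counts)

    # initial state
    lam = rng.uniform(0.2, 0.8, size=(K, J))
    V = np.full(K, 0.5)
    V[-1] = 1.0
    alpha = config.alpha_shape / config.alpha_rate

    n_keep = (config.iterations - config.burn_in) // config.thinning
    N_draws = np.empty(n_keep, dtype=np.int64)
    lam_draws = np.empty((n_keep, K, J))
    pi_draws = np.empty((n_keep, K))
    alpha_draws = np.empty(n_keep)

    keep = 0
    for it in range(config.iterations):
        # stick-breaking weights with remainder on the last class
        log1mV = np.log1p(-np.clip(V[:-1], 0.0, 1.0 - _EPS))
        logpi = np.concatenate(([0.0], np.cumsum(log1mV))) + np.log(
            np.clip(np.append(V[:-1], 1.0), _EPS, 1.0)
        )
        # (1) multinomial split of each observed profile across classes
        loglam = np.log(np.clip(lam, _EPS, 1.0))
        log1mlam = np.log(np.clip(1.0 - lam, _EPS, 1.0))
        L = B @ loglam.T + (1.0 - B) @ log1mlam.T  # (P, K)
        W = L + logpi
        W -= W.max(axis=1, keepdims=True)
        W = np.exp(W)
        W /= W.sum(axis=1, keepdims=True)
        M = np.empty((P, K), dtype=np.int64)
        for p in range(P):
            M[p] = rng.multinomial(counts[p], W[p])

        # (2) never-captured count from the 1/N size-prior conditional
        pi = np.exp(logpi)
        q0 = np.exp(log1mlam.sum(axis=1))  # P(zero history | class)
        p0 = float(np.clip(np.dot(pi, q0), 0.0, 1.0 - _EPS))
        n0 = int(rng.negative_binomial(n, 1.0 - p0)) if p0 > 0.0 else 0

        # (3) allocate the zero-history individuals to classes
        if n0 > 0:
            probs0 = pi * q0
            probs0 /= probs0.sum()
            M0 = rng.multinomial(n0, probs0)
        else:
            M0 = np.zeros(K, dtype=np.int64)

        # (4) Beta full conditionals for the capture probabilities
        T = M.sum(axis=0) + M0  # class totals incl. unobserved
        S = M.T @ B             # (K, J) captures by class and source
        lam = rng.beta(config.lambda_a + S, config.lambda_b + (T[:, None] - S))

        # (5) stick-breaking fractions and DP concentration
        tail = np.cumsum(T[::-1])[::-1]  # T_k + T_{k+1} + ...
        V = np.empty(K)
        V[:-1] = rng.beta(1.0 + T[:-1], alpha + tail[1:])
        V[-1] = 1.0
        alpha = rng.gamma(
            config.alpha_shape + K - 1,
            1.0 / (config.alpha_rate - np.log1p(-np.clip(V[:-1], 0.0, 1.0 - _EPS)).sum()),
        )

        if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0 and keep < n_keep:
            N_draws[keep] = n + n0
            lam_draws[keep] = lam
            pi_draws[keep] = pi
            alpha_draws[keep] = alpha
            keep += 1

    return NPLCMPosterior(
        N=N_draws[:keep],
        lam=lam_draws[:keep],
        pi=pi_draws[:keep],
        alpha=alpha_draws[:keep],
        n_observed=n,
        sources=table.sources,
        config=config,
        warnings_=warns,
    )


def summarize_posterior(post: NPLCMPosterior, label: str = "3-source NPLCM") -> EstimateResult:
    """Posterior median with the central 95% credible interval."""
    if post.n_draws < 100:
        raise ValueError(f"only {post.n_draws} retained draws; need >= 100 to summarize")
    s = post.summary()
    meta = {
        "n_observed": post.n_observed,
        "mean": s["mean"],
        "n_draws": post.n_draws,
        "max_classes": post.config.resolve_classes(len(post.sources)),
        "iterations": post.config.iterations,
        "burn_in": post.config.burn_in,
        "thinning": post.config.thinning,
        "seed": post.config.seed,
        "warnings": list(post.warnings_),
    }
    return EstimateResult(
        label, s["median"], s["ci_low"], s["ci_high"], 0.95, "three-source", meta
    )


def posterior_predictive_check(
    post: NPLCMPosterior,
    table: AggregateCaptureTable,
    n_sims: int = 500,
    level: float = 0.95,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate profile tables from posterior draws; compare with the data.

    For each of ``n_sims`` retained draws a new population of the drawn
    size is simulated from the drawn mixture and reduced to observed
    profile counts. Returns one row per profile with the observed count,
    the central predictive interval and an ``outside`` flag.
    """
    rng = np.random.default_rng(seed)
    B, counts = _profile_matrix(table)
    P, J = B.shape
    idx = rng.choice(post.n_draws, size=min(n_sims, post.n_draws), replace=False)
    sims = np.zeros((len(idx), P), dtype=np.int64)
    for s, i in enumerate(idx):
        Ni = int(post.N[i])
        class_sizes = rng.multinomial(Ni, post.pi[i] / post.pi[i].sum())
        for k, nk in enumerate(class_sizes):
            if nk == 0:
                continue
            x = rng.random((nk, J)) < post.lam[i, k]
            code = x @ (1 << np.arange(J - 1, -1, -1))
            binc = np.bincount(code, minlength=2**J)
            sims[s] += binc[1:]  # drop the zero profile (unobservable)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(sims, [100 * alpha, 100 * (1 - alpha)], axis=0)
    profs = all_profiles(J)
    return pd.DataFrame(
        {
            "profile": profs,
            "observed": counts,
            "pred_low": lo,
            "pred_high": hi,
            "pred_mean": sims.mean(axis=0),
            "outside": (counts < lo) | (counts > hi),
        }
    )


def m0_profile_mle(table: AggregateCaptureTable, n_max: int | None = None) -> int:
    """Homogeneous-capture (M0) maximum-likelihood size by 1-D grid search.

    Profiles the likelihood of the equal-probability model over integer N:
    with x total captures over J lists and n observed individuals,
    p_hat(N) = x / (N J) and

        l(N) = log C(N, n) + x log p_hat + (N J - x) log(1 - p_hat).

    Serves as an independent closed-form check for the latent-class
    sampler in the homogeneous special case.
    """
    J = len(table.sources)
    n = table.n_observed
    x = sum(marg for marg in (table.marginal(s) for s in table.sources))
    if n_max is None:
        n_max = max(10 * n, n + 10)
    Ns = np.arange(n, n_max + 1, dtype=float)
    p = x / (Ns * J)
    p = np.clip(p, _EPS, 1.0 - _EPS)
    ll = (
        gammaln(Ns + 1)
        - gammaln(Ns - n + 1)
        + x * np.log(p)
        + (Ns * J - x) * np.log1p(-p)
    )
    return int(Ns[np.argmax(ll)])
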