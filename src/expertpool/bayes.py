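"""Bayesian hierarchical aggregation of log-odds best estimates.

The three-variance model pools a panel's best estimates on the log-odds
scale.  For participant ``i`` assessing claim ``c``::

    y_ic = logit(clip(B_ic))  ~  Normal(mu_c, sqrt(s_claim^2 + s_part^2 + v_ic))

with three additive variance components: a generic claim-level variance
``s_claim^2``, a generic participant-level variance ``s_part^2`` (both
shared scalars with uniform priors), and a fixed claim-participant
specific variance ``v_ic`` derived from the elicited interval, read as a
central 90% interval on the log-odds scale::

    v_ic = ((logit(clip(U_ic)) - logit(clip(L_ic))) / (2 z))^2,  z = 1.645

Priors are ``mu_c ~ Normal(m_c, prior_sd)`` and
``s_claim, s_part ~ Uniform(sigma_bounds)``.  The aggregated probability
for claim ``c`` is the posterior median of ``expit(mu_c)``.

The prior-informed variant supplies per-claim prior probabilities
(produced by an external model of study attributes) as ``m_c`` on the
log-odds scale; with all priors at 0.5 it reduces exactly to the
uninformative fit.

Note on identifiability: ``s_claim`` and ``s_part`` enter the likelihood
only through ``s_claim^2 + s_part^2`` and are therefore exchangeable a
posteriori; the total extra-interval variance is well identified, the
split between the two labels is informed only by the prior.

Sampling is a self-contained Gibbs-within-Metropolis scheme: the ``mu_c``
are conditionally conjugate and drawn exactly; the two standard
deviations take adaptive reflected random-walk Metropolis steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import expit, logit

from .panel import Panel, clip_probability

logger = logging.getLogger(__name__)

__all__ = ["TriVarModelSpec", "McmcSettings", "PosteriorSummary", "TriVarFit",
           "fit_bay_tri_var", "fit_bay_priors_agg"]

_V_FLOOR = 1e-6  # variance floor for degenerate (L == U) intervals
_RHAT_WARN = 1.05


@dataclass(frozen=True)
class TriVarModelSpec:
    """Hyperparameters of the three-variance hierarchical model."""

    prior_mean: Mapping[str, float] = field(default_factory=dict)  # log-odds
    prior_sd: float = 1.0
    sigma_bounds: tuple[float, float] = (0.0, 2.0)
    bound_coverage_z: float = 1.645
    eps_clip: float = 0.01

    def __post_init__(self):
        lo, hi = self.sigma_bounds
        if not (0 <= lo < hi):
            raise ValueError(f"sigma_bounds must satisfy 0 <= low < high, got {self.sigma_bounds}")
        if self.bound_coverage_z <= 0:
            raise ValueError("bound_coverage_z must be positive")
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be positive")


@dataclass(frozen=True)
class McmcSettings:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior of one claim's probability (inverse-logit of its mean)."""

    claim_id: str
    draws: np.ndarray  # post-warmup draws of expit(mu_c), all chains pooled
    point: float       # posterior median
    interval: tuple[float, float]  # central 95% credible interval
    diagnostics: dict  # {'rhat': float, 'ess': float} for mu_c


class TriVarFit(dict):
    """Mapping claim_id -> PosteriorSummary, plus variance-component draws."""

    sigma_claim_draws: np.ndarray
    sigma_part_draws: np.ndarray
    diagnostics: dict
    converged: bool


def _split_rhat(chains: np.ndarray) -> float:
    """Split potential-scale-reduction over an (n_chains, n_draws) array."""
    n = chains.shape[1] // 2
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    m, n = halves.shape
    cm = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean()
    B = n * cm.var(ddof=1)
    if W <= 0:
        return 1.0
    return float(np.sqrt((n - 1) / n + B / (W * n)))


def _ess(chains: np.ndarray) -> float:
    """Crude effective sample size from lag-autocorrelations (pooled chains)."""
    x = chains - chains.mean(axis=1, keepdims=True)
    n = x.shape[1]
    if x.std() == 0:
        return float(chains.size)
    acf_sum = 0.0
    for lag in range(1, min(n - 1, 200)):
        rho = np.mean(
            [np.dot(c[:-lag], c[lag:]) / np.dot(c, c) for c in x]
        )
        if rho < 0.05:
            break
        acf_sum += rho
    return float(chains.size / (1.0 + 2.0 * acf_sum))


def fit_bay_tri_var(
    panel: Panel,
    spec: TriVarModelSpec | None = None,
    mcmc: McmcSettings | None = None,
) -> TriVarFit:
    """Fit the three-variance model and summarise per-claim posteriors.

    Requires at least 2 claims and 2 participants (the shared variance
    components need replication) and elicited bounds (they fix ``v_ic``).
    Deterministic given ``mcmc.seed``.
    """
    spec = spec or TriVarModelSpec()
    mcmc = mcmc or McmcSettings()
    work = panel.analysis_round()
    df = work.assessments
    claims = work.claims
    if len(claims) < 2 or len(work.participants) < 2:
        raise ValueError(
            "the three-variance model needs >= 2 claims and >= 2 participants"
        )
    if not work.has_bounds:
        raise ValueError("the three-variance model requires elicited bounds")

    eps = spec.eps_clip
    y = logit(clip_probability(df["best"].to_numpy(), eps))
    lo = logit(clip_probability(df["lower"].to_numpy(), eps))
    hi = logit(clip_probability(df["upper"].to_numpy(), eps))
    v = np.maximum(((hi - lo) / (2.0 * spec.bound_coverage_z)) ** 2, _V_FLOOR)

    claim_index = {c: k for k, c in enumerate(claims)}
    cidx = df["claim_id"].map(claim_index).to_numpy()
    C = len(claims)
    m0 = np.array([spec.prior_mean.get(c, 0.0) for c in claims])
    tau0 = spec.prior_sd**2
    slo, shi = spec.sigma_bounds

    n_iter = mcmc.warmup + mcmc.draws
    rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)]

    mu_store = np.empty((mcmc.chains, mcmc.draws, C))
    sig_store = np.empty((mcmc.chains, mcmc.draws, 2))

    # per-claim index lists for vectorised Gibbs updates
    counts = np.bincount(cidx, minlength=C)

    for ch, rng in enumerate(rngs):
        # overdispersed init: empirical per-claim means + jitter
        mu = np.array([y[cidx == k].mean() for k in range(C)]) + rng.normal(0, 0.5, C)
        sig = np.clip(rng.uniform(slo + 0.1 * (shi - slo), slo + 0.6 * (shi - slo), 2), slo + 1e-3, shi - 1e-3)
        step = np.full(2, 0.2)
        acc = np.zeros(2)
        window = 50

        def loglik(sig2_sum, mu_vec):
            var = sig2_sum + v
            resid = y - mu_vec[cidx]
            return -0.5 * np.sum(np.log(var) + resid**2 / var)

        for it in range(n_iter):
            # Gibbs: mu_c | sigmas  (conjugate normal)
            var = sig[0] ** 2 + sig[1] ** 2 + v
            prec = np.bincount(cidx, weights=1.0 / var, minlength=C)
            mean_w = np.bincount(cidx, weights=y / var, minlength=C)
            post_prec = 1.0 / tau0 + prec
            post_mean = (m0 / tau0 + mean_w) / post_prec
            mu = post_mean + rng.normal(size=C) / np.sqrt(post_prec)

            # Metropolis on each sigma with reflection at the prior bounds
            cur_ll = loglik(sig[0] ** 2 + sig[1] ** 2, mu)
            for j in (0, 1):
                prop = sig.copy()
                cand = prop[j] + rng.normal(0, step[j])
                # reflect into (slo, shi)
                span = shi - slo
                cand = slo + abs((cand - slo) % (2 * span))
                if cand > shi:
                    cand = 2 * shi - slo - cand + slo  # fold back
                cand = min(max(cand, slo), shi)
                prop[j] = cand
                prop_ll = loglik(prop[0] ** 2 + prop[1] ** 2, mu)
                if np.log(rng.uniform()) < prop_ll - cur_ll:
                    sig = prop
                    cur_ll = prop_ll
                    acc[j] += 1

            # rotation move: resample the split of the (exchangeable) total
            # variance at fixed sigma_claim^2 + sigma_part^2.  The likelihood
            # is invariant and the uniform prior is symmetric in angle, so
            # the only rejection is the prior's box constraint.
            s_tot = float(np.hypot(sig[0], sig[1]))
            if s_tot > 0:
                phi = rng.uniform(0.0, np.pi / 2.0)
                cand = np.array([s_tot * np.cos(phi), s_tot * np.sin(phi)])
                if (cand >= slo).all() and (cand <= shi).all():
                    sig = cand

            # step-size adaptation during warmup, targeting ~44% acceptance
            if it < mcmc.warmup and (it + 1) % window == 0:
                rate = acc / window
                step *= np.exp((rate - 0.44) * 0.8)
                acc[:] = 0

            if it >= mcmc.warmup:
                k = it - mcmc.warmup
                mu_store[ch, k] = mu
                sig_store[ch, k] = sig

    # diagnostics and summaries
    diagnostics = {}
    for k, c in enumerate(claims):
        diagnostics[f"mu[{c}]"] = {
            "rhat": _split_rhat(mu_store[:, :, k]),
            "ess": _ess(mu_store[:, :, k]),
        }
    diagnostics["sigma_claim"] = {
        "rhat": _split_rhat(sig_store[:, :, 0]),
        "ess": _ess(sig_store[:, :, 0]),
    }
    diagnostics["sigma_part"] = {
        "rhat": _split_rhat(sig_store[:, :, 1]),
        "ess": _ess(sig_store[:, :, 1]),
    }
    bad = [k for k, d in diagnostics.items() if d["rhat"] > _RHAT_WARN]
    if bad:
        logger.warning("possible non-convergence (rhat > %.2f): %s", _RHAT_WARN, bad)

    fit = TriVarFit()
    for k, c in enumerate(claims):
        p_draws = expit(mu_store[:, :, k].reshape(-1))
        lo_hi = np.quantile(p_draws, [0.025, 0.975])
        fit[c] = PosteriorSummary(
            claim_id=c,
            draws=p_draws,
            point=float(np.median(p_draws)),
            interval=(float(lo_hi[0]), float(lo_hi[1])),
            diagnostics=diagnostics[f"mu[{c}]"],
        )
    fit.sigma_claim_draws = sig_store[:, :, 0].reshape(-1)
    fit.sigma_part_draws = sig_store[:, :, 1].reshape(-1)
    fit.diagnostics = diagnostics
    fit.converged = not bad
    return fit


def fit_bay_priors_agg(
    panel: Panel,
    claim_priors: Mapping[str, float],
    spec: TriVarModelSpec | None = None,
    mcmc: McmcSettings | None = None,
) -> TriVarFit:
    """Three-variance fit with externally supplied per-claim prior probabilities.

    ``claim_priors[c]`` (a probability) sets the prior mean of ``mu_c`` to
    ``logit(clip(claim_priors[c]))``.  A missing prior for any claim is an
    error.  With all priors equal to 0.5 this is exactly the
    uninformative fit (identical draws for identical seeds).
    """
    spec = spec or TriVarModelSpec()
    claims = panel.claims
    missing = [c for c in claims if c not in claim_priors]
    if missing:
        raise ValueError(f"claim_priors missing for claims {missing}")
    prior_mean = {
        c: float(logit(clip_probability(claim_priors[c], spec.eps_clip)))
        for c in claims
    }
    spec2 = TriVarModelSpec(
        prior_mean=prior_mean,
        prior_sd=spec.prior_sd,
        sigma_bounds=spec.sigma_bounds,
        bound_coverage_z=spec.bound_coverage_z,
        eps_clip=spec.eps_clip,
    )
    return fit_bay_tri_var(panel, spec2, mcmc)
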