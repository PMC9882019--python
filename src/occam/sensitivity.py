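"""Hierarchical estimation of likelihood- and complexity-term sensitivities.

Choices are modeled with a hierarchical logistic regression:

    P(choice = "up") = logistic(b0_j + bL_j dL + bD_j dD + bB_j dB
                                + bV_j dV + bR_j dR),

where the predictors are the up-minus-down differences of the maximum log
likelihood and of the four FIA penalty terms (nats), and j indexes
participants. Participant coefficients are partially pooled,
beta_j ~ Normal(mu, tau) componentwise, with weakly informative priors
(Normal(0, 5) on mu, half-Normal(2.5) on tau, on the standardized predictor
scale). Predictors enter the reported coefficients in nats, unstandardized,
so a likelihood coefficient of 1 with all relative sensitivities 1 is
exactly the FIA-posterior observer; an internal standardized parameterization
is used for sampling and back-transformed.

The *relative sensitivity* of a complexity term is the ratio of its
coefficient to the likelihood coefficient, computed per posterior draw
(never as a ratio of means): 0 is maximum-likelihood behavior, 1 is
Bayes-optimal weighting.

Within a single variant some predictors have zero variance (e.g. the
dimensionality difference in the volume variant); they are dropped from that
fit and reported as NaN. Per-trial mirror randomization is what makes the
sign-flipping trial-constant predictors identifiable against the up/down
bias intercept.

The lapse-extended model mixes the logistic with a uniform choice:
P = lam_j / 2 + (1 - lam_j) logistic(.), with logit(lam_j) partially pooled.

Posteriors are sampled with the package's vectorized HMC (analytic
gradients, non-centered hierarchy); R-hat and ESS come from arviz, and WAIC
is computed from pointwise log predictive densities in draw chunks.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
from scipy.stats import spearmanr

from . import hmc, taskgen

__all__ = [
    "TERMS",
    "DELTA_COLUMNS",
    "build_design",
    "HierarchicalFit",
    "fit_hierarchical",
    "fit_lapse",
    "likelihood_only",
    "relative_sensitivity",
    "compare_waic",
    "accuracy_sensitivity_corr",
]

TERMS = ("likelihood", "dimensionality", "boundary", "volume", "robustness")
DELTA_COLUMNS = ("delta_L", "delta_D", "delta_B", "delta_V", "delta_R")
_TERM_TO_COL = dict(zip(TERMS, DELTA_COLUMNS))


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(
    variant: taskgen.TaskVariant,
    batch: dict,
    choices: Optional[np.ndarray],
    participant_id: str,
) -> pd.DataFrame:
    """Regression rows for one participant's trials of one variant.

    Predictors are up-minus-down (model 2 minus model 1) differences of the
    maximum log likelihood and of each FIA term, from the evidence breakdown
    of both displayed models. Trials with a degenerate breakdown (non-finite
    robustness) are dropped; the count is stored in ``.attrs["n_dropped"]``.
    ``choices`` may be None to build a response-free design (the logistic
    planting path fills choices in later).
    """
    down, up = taskgen.pair_profiles(variant, batch["centroid"], batch["swapped"])
    deltas = {
        "delta_L": up["loglik_profile"] - down["loglik_profile"],
        "delta_D": up["t_dim"] - down["t_dim"],
        "delta_B": up["t_boundary"] - down["t_boundary"],
        "delta_V": up["t_volume"] - down["t_volume"],
        "delta_R": up["t_robustness"] - down["t_robustness"],
    }
    n = len(batch["centroid"])
    df = pd.DataFrame(
        {
            "participant_id": participant_id,
            "trial_id": np.arange(n),
            "variant": variant.name,
            **deltas,
            "true_model": batch["true_model"],
        }
    )
    if choices is not None:
        df["choice_up"] = (np.asarray(choices) == 2).astype(int)
    ok = np.isfinite(df[list(DELTA_COLUMNS)].to_numpy()).all(axis=1)
    out = df[ok].reset_index(drop=True)
    out.attrs["n_dropped"] = int(n - ok.sum())
    return out


# ---------------------------------------------------------------------------
# hierarchical logistic model (standardized scale)
# ---------------------------------------------------------------------------

def _softplus(w):
    """(softplus(w), sigmoid(w)): the value and its derivative, overflow-safe."""
    tau = np.logaddexp(0.0, w)
    return tau, expit(w)


def _inv_softplus(x):
    return float(x + np.log(-np.expm1(-x)))


class _HierLogistic:
    """Non-centered hierarchical logistic posterior with analytic gradients.

    Parameter vector per chain:
    ``[mu (P), w_tau (P), z (J*P)]`` and, with lapse,
    ``[..., mu_u, w_tau_u, zu (J)]``; beta_j = mu + tau * z_j with
    ``tau = softplus(w_tau)`` (bounded prior curvature in the sampled
    coordinate, unlike ``exp``).
    """

    MU_SD = 5.0
    TAU_SD = 2.5
    LAPSE_MU_LOC = -3.0
    LAPSE_MU_SD = 1.5
    LAPSE_TAU_SD = 1.0

    def __init__(self, X, y, starts, lapse=False):
        self.X = X                      # (R, P), intercept first, standardized
        self.y = y.astype(float)
        self.starts = starts            # row offsets per participant (contiguous)
        self.pidx = np.repeat(
            np.arange(len(starts)), np.diff(np.append(starts, len(y)))
        )
        self.J = len(starts)
        self.R, self.P = X.shape
        self.lapse = lapse
        self.dim = 2 * self.P + self.J * self.P + (2 + self.J if lapse else 0)

    def unpack(self, th):
        P, J = self.P, self.J
        mu = th[:, :P]
        ltau = th[:, P : 2 * P]
        z = th[:, 2 * P : 2 * P + J * P].reshape(th.shape[0], J, P)
        rest = th[:, 2 * P + J * P :]
        return mu, ltau, z, rest

    def beta(self, th):
        mu, wtau, z, _ = self.unpack(th)
        return mu[:, None, :] + _softplus(wtau)[0][:, None, :] * z

    def lam(self, th):
        if not self.lapse:
            return None
        _, _, _, rest = self.unpack(th)
        u = rest[:, 0][:, None] + _softplus(rest[:, 1])[0][:, None] * rest[:, 2:]
        return expit(u)                 # (C, J)

    def logp_grad(self, th):
        C = th.shape[0]
        P, J = self.P, self.J
        mu, wtau, z, rest = self.unpack(th)
        # tau = softplus(w): unlike exp, the half-Normal prior's curvature in
        # the sampled coordinate stays bounded for large w, which keeps the
        # leapfrog integrator stable
        tau, dtau = _softplus(wtau)
        beta = mu[:, None, :] + tau[:, None, :] * z      # (C, J, P)
        eta = np.einsum("rp,crp->cr", self.X, beta[:, self.pidx, :])
        p = expit(eta)

        if self.lapse:
            u_mu, u_wtau = rest[:, 0], rest[:, 1]
            zu = rest[:, 2:]
            u_tau, u_dtau = _softplus(u_wtau)
            u = u_mu[:, None] + u_tau[:, None] * zu
            lam = expit(u)                                # (C, J)
            lam_r = lam[:, self.pidx]
            prob = lam_r / 2.0 + (1.0 - lam_r) * p
            prob = np.clip(prob, 1e-12, 1.0 - 1e-12)
            loglik = self.y * np.log(prob) + (1 - self.y) * np.log1p(-prob)
            dldP = self.y / prob - (1 - self.y) / (1.0 - prob)
            w = dldP * (1.0 - lam_r) * p * (1.0 - p)      # d loglik / d eta
            dldu_r = dldP * (0.5 - p) * (lam_r * (1.0 - lam_r))
            g_u = np.add.reduceat(dldu_r, self.starts, axis=1)    # (C, J)
        else:
            loglik = self.y * eta - np.logaddexp(0.0, eta)
            w = self.y - p

        prod = self.X[None, :, :] * w[:, :, None]                  # (C, R, P)
        g_beta = np.add.reduceat(prod, self.starts, axis=1)        # (C, J, P)

        logp = loglik.sum(axis=1)
        # priors (constants dropped)
        logp += -(mu**2).sum(1) / (2 * self.MU_SD**2)
        logp += -(z**2).sum(axis=(1, 2)) / 2.0
        logp += -(tau**2).sum(1) / (2 * self.TAU_SD**2) + np.log(dtau).sum(1)

        g_mu = g_beta.sum(axis=1) - mu / self.MU_SD**2
        g_z = g_beta * tau[:, None, :] - z
        g_wtau = (
            (g_beta * z).sum(axis=1) - tau / self.TAU_SD**2
        ) * dtau + (1.0 - dtau)  # d/dw log sigmoid(w) = 1 - sigmoid(w)

        grads = [g_mu, g_wtau, g_z.reshape(C, J * P)]
        if self.lapse:
            logp += -((u_mu - self.LAPSE_MU_LOC) ** 2) / (2 * self.LAPSE_MU_SD**2)
            logp += -(zu**2).sum(1) / 2.0
            logp += -(u_tau**2) / (2 * self.LAPSE_TAU_SD**2) + np.log(u_dtau)
            g_umu = g_u.sum(axis=1) - (u_mu - self.LAPSE_MU_LOC) / self.LAPSE_MU_SD**2
            g_zu = g_u * u_tau[:, None] - zu
            g_uwtau = (
                (g_u * zu).sum(axis=1) - u_tau / self.LAPSE_TAU_SD**2
            ) * u_dtau + (1.0 - u_dtau)
            grads += [g_umu[:, None], g_uwtau[:, None], g_zu]
        grad = np.concatenate(grads, axis=1)
        return logp, grad

    def pointwise_loglik(self, th):
        """Per-row log predictive density for a batch of parameter vectors."""
        beta = self.beta(th)
        eta = np.einsum("rp,crp->cr", self.X, beta[:, self.pidx, :])
        if self.lapse:
            lam_r = self.lam(th)[:, self.pidx]
            prob = np.clip(lam_r / 2.0 + (1.0 - lam_r) * expit(eta), 1e-12, 1 - 1e-12)
            return self.y * np.log(prob) + (1 - self.y) * np.log1p(-prob)
        return self.y * eta - np.logaddexp(0.0, eta)


# ---------------------------------------------------------------------------
# fit container
# ---------------------------------------------------------------------------

@dataclass
class HierarchicalFit:
    """Posterior over population- and participant-level sensitivities."""

    terms: tuple                      # active predictor names (excl. intercept)
    participants: tuple
    mu: np.ndarray                    # (C, S, 1 + n_terms) original scale
    tau: np.ndarray                   # (C, S, 1 + n_terms) original scale
    beta: np.ndarray                  # (C, S, J, 1 + n_terms) original scale
    diagnostics: dict
    waic: dict
    converged: bool
    design_hash: str
    n_rows: int
    n_dropped: int
    lapse: Optional[np.ndarray] = None      # (C, S, J) lapse rates
    lapse_population: Optional[dict] = None
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0] * self.mu.shape[1]

    def term_index(self, term: str) -> int:
        return 1 + self.terms.index(term)

    def flat(self, arr) -> np.ndarray:
        return arr.reshape((-1,) + arr.shape[2:])


def _prepare(designs: pd.DataFrame):
    df = designs.sort_values(["participant_id", "trial_id"], kind="stable")
    if "choice_up" not in df:
        raise ValueError("designs must contain a choice_up column")
    participants = tuple(dict.fromkeys(df["participant_id"]))
    y = df["choice_up"].to_numpy(dtype=float)
    raw = df[list(DELTA_COLUMNS)].to_numpy(dtype=float)
    sds = raw.std(axis=0)
    active = [i for i in range(len(TERMS)) if sds[i] > 1e-10]
    terms = tuple(TERMS[i] for i in active)
    scales = np.concatenate([[1.0], sds[active]])
    X = np.column_stack([np.ones(len(df))] + [raw[:, i] / sds[i] for i in active])
    codes = pd.Categorical(df["participant_id"], categories=participants).codes
    starts = np.searchsorted(codes, np.arange(len(participants)))
    # identifies the *data* (participants, trials, responses), not the
    # predictor set, so nested models fit to the same choices compare as equal
    h = hashlib.sha1()
    h.update(y.tobytes())
    h.update(df["trial_id"].to_numpy(dtype=np.int64).tobytes())
    h.update(",".join(map(str, participants)).encode())
    return df, participants, y, X, scales, terms, starts, h.hexdigest()


def _streaming_waic(model: _HierLogistic, draws: np.ndarray, chunk: int = 64) -> dict:
    """WAIC from pointwise log predictive densities, chunked over draws."""
    flat = draws.reshape(-1, draws.shape[-1])
    S = flat.shape[0]
    R = model.R
    run_lse = np.full(R, -np.inf)
    s1 = np.zeros(R)
    s2 = np.zeros(R)
    for i in range(0, S, chunk):
        ll = model.pointwise_loglik(flat[i : i + chunk])      # (c, R)
        run_lse = np.logaddexp(run_lse, logsumexp(ll, axis=0))
        s1 += ll.sum(axis=0)
        s2 += (ll**2).sum(axis=0)
    lppd = run_lse - np.log(S)
    var = s2 / S - (s1 / S) ** 2
    p_waic = var * S / max(S - 1, 1)
    elpd_i = lppd - p_waic
    return {
        "elpd": float(elpd_i.sum()),
        "p_waic": float(p_waic.sum()),
        "waic": float(-2.0 * elpd_i.sum()),
        "se": float(np.sqrt(R * np.var(elpd_i))),
        "pointwise": elpd_i,
    }


def fit_hierarchical(
    designs: pd.DataFrame,
    *,
    chains: int = 4,
    n_warmup: int = 1000,
    n_draws: int = 1000,
    seed: int = 0,
    target_accept: float = 0.9,
    base_steps: int = 32,
    lapse: bool = False,
    rhat_threshold: float = 1.01,
) -> HierarchicalFit:
    """Fit the (optionally lapse-extended) hierarchical logistic regression.

    Requires >= 2 participants; convergence is judged by split-R-hat of all
    population-level parameters (threshold 1.01) and the absence of
    divergent transitions.
    """
    df, participants, y, X, scales, terms, starts, dhash = _prepare(designs)
    if len(participants) < 2:
        raise ValueError("need at least 2 participants for a hierarchical fit")
    model = _HierLogistic(X, y, starts, lapse=lapse)
    rng = np.random.default_rng(seed)
    theta0 = 0.1 * rng.standard_normal((chains, model.dim))
    theta0[:, model.P : 2 * model.P] = _inv_softplus(0.5)       # tau init
    if lapse:
        theta0[:, 2 * model.P + model.J * model.P] = model.LAPSE_MU_LOC
        theta0[:, 2 * model.P + model.J * model.P + 1] = _inv_softplus(0.3)
    res = hmc.sample(
        model.logp_grad,
        theta0,
        n_warmup,
        n_draws,
        rng,
        target_accept=target_accept,
        base_steps=base_steps,
        max_step_jitter=base_steps // 2,
    )
    C, S, _ = res.draws.shape
    P, J = model.P, model.J
    mu_std = res.draws[:, :, :P]
    tau_std = _softplus(res.draws[:, :, P : 2 * P])[0]
    z = res.draws[:, :, 2 * P : 2 * P + J * P].reshape(C, S, J, P)
    beta_std = mu_std[:, :, None, :] + tau_std[:, :, None, :] * z
    mu = mu_std / scales
    tau = tau_std / scales
    beta = beta_std / scales

    post = {
        "mu": mu,
        "tau": tau,
    }
    lapse_draws = None
    lapse_pop = None
    if lapse:
        off = 2 * P + J * P
        u_mu = res.draws[:, :, off]
        u_tau = _softplus(res.draws[:, :, off + 1])[0]
        zu = res.draws[:, :, off + 2 :]
        lapse_draws = expit(u_mu[:, :, None] + u_tau[:, :, None] * zu)
        lapse_pop = {"mean_rate": expit(u_mu), "mu": u_mu, "tau": u_tau}
        post["lapse_mu"] = u_mu[:, :, None]
        post["lapse_tau"] = u_tau[:, :, None]

    idata = az.from_dict(posterior=post)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rhat_max = float(max(np.nanmax(rhat[v].values) for v in rhat.data_vars))
    ess_min = float(min(np.nanmin(ess[v].values) for v in ess.data_vars))
    diagnostics = {
        "rhat_max": rhat_max,
        "ess_min": ess_min,
        "divergences": res.divergences,
        "accept_rate": res.accept_rate.mean(),
        "step_size": res.step_size,
    }
    converged = bool(rhat_max < rhat_threshold and res.divergences == 0)
    waic = _streaming_waic(model, res.draws)
    return HierarchicalFit(
        terms=terms,
        participants=participants,
        mu=mu,
        tau=tau,
        beta=beta,
        diagnostics=diagnostics,
        waic=waic,
        converged=converged,
        design_hash=dhash,
        n_rows=model.R,
        n_dropped=int(designs.attrs.get("n_dropped", 0)),
        lapse=lapse_draws,
        lapse_population=lapse_pop,
        meta={"scales": scales, "chains": C, "draws_per_chain": S, "seed": seed},
    )


def likelihood_only(designs: pd.DataFrame) -> pd.DataFrame:
    """The nested design with all four complexity predictors removed (zeroed)."""
    out = designs.copy()
    for col in DELTA_COLUMNS[1:]:
        out[col] = 0.0
    out.attrs.update(designs.attrs)
    return out


def fit_lapse(designs: pd.DataFrame, **kwargs) -> HierarchicalFit:
    """Lapse-extended fit: P = lam/2 + (1 - lam) * logistic(eta)."""
    kwargs.setdefault("lapse", True)
    return fit_hierarchical(designs, **kwargs)


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def _check_converged(fit: HierarchicalFit, force: bool):
    if not fit.converged and not force:
        raise RuntimeError(
            "fit did not converge "
            f"(rhat_max={fit.diagnostics['rhat_max']:.4f}, "
            f"divergences={fit.diagnostics['divergences']}); "
            "pass force=True to summarize anyway"
        )


def relative_sensitivity(
    fit: HierarchicalFit,
    guard: float = 1e-3,
    *,
    force: bool = False,
) -> dict:
    """Posterior relative sensitivities beta_term / beta_likelihood, per draw.

    Ratios are taken draw-by-draw at the population level (population-mean
    draws) and the participant level; draws with |likelihood coefficient|
    below ``guard`` are excluded and counted (a warning is attached if more
    than 1% are guarded). Terms absent from the fit report NaN.
    """
    _check_converged(fit, force)
    if "likelihood" not in fit.terms:
        raise ValueError("fit has no likelihood predictor; ratios undefined")
    iL = fit.term_index("likelihood")
    mu = fit.flat(fit.mu)
    beta = fit.flat(fit.beta)
    ok = np.abs(mu[:, iL]) > guard
    n_guarded = int((~ok).sum())
    if n_guarded > 0.01 * len(ok):
        warnings.warn(
            f"{n_guarded}/{len(ok)} draws guarded for small likelihood coefficient",
            RuntimeWarning,
            stacklevel=2,
        )
    pop_rows, part_rows = [], []
    for term in TERMS[1:]:
        if term in fit.terms:
            it = fit.term_index(term)
            ratio = mu[ok, it] / mu[ok, iL]
            pop_rows.append((term, ratio.mean(), ratio.std()))
            bl = beta[ok][:, :, iL]
            with np.errstate(divide="ignore", invalid="ignore"):
                pr = np.where(np.abs(bl) > guard, beta[ok][:, :, it] / bl, np.nan)
            for j, pid in enumerate(fit.participants):
                part_rows.append(
                    (pid, term, np.nanmean(pr[:, j]), np.nanstd(pr[:, j]))
                )
        else:
            pop_rows.append((term, np.nan, np.nan))
    population = pd.DataFrame(pop_rows, columns=["term", "mean", "sd"])
    participant = pd.DataFrame(
        part_rows, columns=["participant_id", "term", "mean", "sd"]
    )
    return {"population": population, "participant": participant, "n_guarded": n_guarded}


def compare_waic(fit_a: HierarchicalFit, fit_b: HierarchicalFit) -> pd.DataFrame:
    """WAIC comparison of two fits of the *same* data (paired standard error)."""
    if fit_a.n_rows != fit_b.n_rows or fit_a.design_hash != fit_b.design_hash:
        raise ValueError("fits were not computed on identical data")
    pa, pb = fit_a.waic["pointwise"], fit_b.waic["pointwise"]
    d = pa - pb
    d_se = float(np.sqrt(len(d) * np.var(d)))
    return pd.DataFrame(
        {
            "model": ["fit_a", "fit_b"],
            "waic": [fit_a.waic["waic"], fit_b.waic["waic"]],
            "se": [fit_a.waic["se"], fit_b.waic["se"]],
            "elpd": [fit_a.waic["elpd"], fit_b.waic["elpd"]],
            "elpd_diff": [0.0, float(-d.sum())],
            "diff_se": [0.0, d_se],
        }
    )


def accuracy_sensitivity_corr(
    fit: HierarchicalFit,
    accuracies: Mapping[str, float],
    *,
    guard: float = 1e-3,
    max_draws: int = 500,
    force: bool = False,
) -> pd.DataFrame:
    """Spearman correlation between accuracy and |relative sensitivity - 1|.

    Computed per posterior draw across participants (participant-level
    relative sensitivities), summarized as mean +/- sd; refuses cohorts of
    fewer than 5 participants.
    """
    _check_converged(fit, force)
    if len(fit.participants) < 5:
        raise ValueError("need at least 5 participants for a rank correlation")
    acc = np.array([accuracies[p] for p in fit.participants], dtype=float)
    iL = fit.term_index("likelihood")
    beta = fit.flat(fit.beta)
    if beta.shape[0] > max_draws:
        step = beta.shape[0] // max_draws
        beta = beta[::step][:max_draws]
    rows = []
    for term in TERMS[1:]:
        if term not in fit.terms:
            rows.append((term, np.nan, np.nan))
            continue
        it = fit.term_index(term)
        rhos = []
        for s in range(beta.shape[0]):
            bl = beta[s, :, iL]
            if np.any(np.abs(bl) <= guard):
                continue
            dev = np.abs(beta[s, :, it] / bl - 1.0)
            rho = spearmanr(acc, dev).statistic
            if np.isfinite(rho):
                rhos.append(rho)
        rhos = np.asarray(rhos)
        rows.append((term, rhos.mean(), rhos.std()))
    return pd.DataFrame(rows, columns=["term", "rho_mean", "rho_sd"])
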