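"""Bayesian estimation backbone: Gibbs sampling, convergence, DIC, intervals.

All hierarchical models in this package are conditionally conjugate Gaussian
models, so posterior sampling is done with blocked Gibbs updates rather than a
general-purpose sampler.  Half-Cauchy priors on scale parameters are handled
through their inverse-gamma scale-mixture representation (a half-Cauchy(A)
prior on a standard deviation sigma is equivalent to sigma^2 | a ~ IG(1/2, 1/a)
with a ~ IG(1/2, 1/A^2)), which keeps every full conditional in closed form.

Three ingredients are exposed to the rest of the package:

* :class:`HierarchicalLinearModel` -- Gaussian linear regression with an
  optional group level at which the intercept and every slope receive
  independent Normal deviations (random intercept + random slopes).
* :class:`CrossedRandomInterceptsModel` -- Gaussian intercept-only model with
  several crossed random-intercept factors (used for variance decomposition
  of observer ratings with a shared rater pool).
* :func:`run_mcmc`, :func:`gelman_rubin`, :func:`dic`,
  :func:`credible_interval` -- the sampling/diagnostic contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Protocol

import numpy as np

__all__ = [
    "McmcConfig",
    "MCMC_PRESETS",
    "PosteriorSamples",
    "ConvergenceReport",
    "DicResult",
    "GibbsModel",
    "HierarchicalLinearModel",
    "CrossedRandomInterceptsModel",
    "run_mcmc",
    "gelman_rubin",
    "dic",
    "credible_interval",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings.

    Parameters
    ----------
    n_chains:
        Number of independent chains with distinct seeded starting values.
    iterations:
        Total Gibbs iterations per chain, including burn-in.
    burn_in:
        Iterations discarded from the start of each chain.
    thinning:
        Keep every ``thinning``-th post-burn-in draw.
    seed:
        Root seed; chain seeds are spawned from it deterministically.
    rhat_threshold:
        Potential-scale-reduction threshold used by convergence checks.
    """

    n_chains: int = 3
    iterations: int = 4000
    burn_in: int = 2000
    thinning: int = 1
    seed: int = 0
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    def with_seed(self, seed: int) -> "McmcConfig":
        return replace(self, seed=int(seed))


#: Named presets.  ``desk`` is sized for interactive use; ``paper`` mirrors the
#: original WinBUGS schedule (90k retained iterations after 60k burn-in with a
#: thinning rate of 30, three chains).
MCMC_PRESETS: dict[str, McmcConfig] = {
    "desk": McmcConfig(n_chains=3, iterations=4000, burn_in=2000, thinning=1),
    "paper": McmcConfig(n_chains=3, iterations=150_000, burn_in=60_000, thinning=30),
}


def resolve_mcmc(config: "McmcConfig | str | None", seed: int | None = None) -> McmcConfig:
    """Turn a preset name, config object or None into an :class:`McmcConfig`."""
    if config is None:
        config = MCMC_PRESETS["desk"]
    elif isinstance(config, str):
        try:
            config = MCMC_PRESETS[config]
        except KeyError:
            raise ValueError(
                f"unknown MCMC preset {config!r}; choose from {sorted(MCMC_PRESETS)}"
            ) from None
    if seed is not None:
        config = config.with_seed(seed)
    return config


# --------------------------------------------------------------------------
# sample container
# --------------------------------------------------------------------------


@dataclass
class PosteriorSamples:
    """Post-burn-in, thinned draws keyed by parameter name.

    Each array has shape ``(n_chains, n_draws, *parameter_shape)``.
    """

    draws: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        counts = {v.shape[:2] for v in self.draws.values()}
        if len(counts) > 1:
            raise ValueError("all parameters must share (n_chains, n_draws)")

    @property
    def names(self) -> list[str]:
        return list(self.draws)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated: shape ``(n_chains * n_draws, *shape)``."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def posterior_mean(self, name: str) -> np.ndarray | float:
        m = self.pooled(name).mean(axis=0)
        return float(m) if m.ndim == 0 else m

    def point_estimates(self) -> dict[str, np.ndarray | float]:
        return {name: self.posterior_mean(name) for name in self.draws}


# --------------------------------------------------------------------------
# model protocol
# --------------------------------------------------------------------------


class GibbsModel(Protocol):
    """Contract a model must satisfy to be sampled by :func:`run_mcmc`."""

    def init_state(self, rng: np.random.Generator) -> dict: ...

    def step(self, state: dict, rng: np.random.Generator) -> dict: ...

    def collect(self, state: dict) -> dict[str, np.ndarray | float]: ...

    def log_likelihood(self, point: dict) -> float: ...


def run_mcmc(model: GibbsModel, config: McmcConfig | str | None = None) -> PosteriorSamples:
    """Run seeded Gibbs chains and return post-burn-in, thinned draws.

    Deterministic given ``config.seed``: chain c uses the c-th child of the
    root seed sequence, so adding chains never perturbs existing ones.
    """
    config = resolve_mcmc(config)
    child_seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    kept_per_chain = (config.iterations - config.burn_in + config.thinning - 1) // config.thinning

    store: dict[str, np.ndarray] | None = None
    for chain, seq in enumerate(child_seeds):
        rng = np.random.default_rng(seq)
        state = model.init_state(rng)
        kept = 0
        for it in range(config.iterations):
            state = model.step(state, rng)
            if it < config.burn_in or (it - config.burn_in) % config.thinning:
                continue
            sample = model.collect(state)
            if store is None:
                store = {
                    name: np.empty(
                        (config.n_chains, kept_per_chain, *np.shape(value)), dtype=float
                    )
                    for name, value in sample.items()
                }
            for name, value in sample.items():
                store[name][chain, kept] = value
            kept += 1
    assert store is not None
    return PosteriorSamples(store)


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------


@dataclass
class ConvergenceReport:
    """Split-chain potential scale reduction (Gelman-Rubin R-hat)."""

    rhat: dict[str, np.ndarray]
    threshold: float
    degenerate: list[str] = field(default_factory=list)

    @property
    def max_rhat(self) -> float:
        vals = [np.nanmax(v) for v in self.rhat.values() if v.size]
        return float(max(vals)) if vals else float("nan")

    @property
    def passed(self) -> bool:
        return bool(np.isfinite(self.max_rhat) and self.max_rhat < self.threshold)


def _split_rhat(arr: np.ndarray) -> np.ndarray:
    """Classic split-chain R-hat for draws of shape (chains, draws, *shape)."""
    n_chains, n_draws = arr.shape[:2]
    half = n_draws // 2
    if half < 2:
        raise ValueError("need at least 4 draws per chain for split R-hat")
    seqs = np.concatenate([arr[:, :half], arr[:, half : 2 * half]], axis=0)
    m, n = seqs.shape[:2]
    chain_means = seqs.mean(axis=1)
    w = seqs.var(axis=1, ddof=1).mean(axis=0)
    b_over_n = chain_means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * w + b_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / w)
    # constant sequences: 0/0 -> declare degenerate via NaN
    rhat = np.where(w <= 0, np.nan, rhat)
    return np.atleast_1d(rhat)


def gelman_rubin(
    samples: PosteriorSamples,
    rhat_threshold: float = 1.1,
    skip: tuple[str, ...] = ("deviance",),
) -> ConvergenceReport:
    """Per-parameter split-chain potential scale reduction statistic.

    Parameters whose draws are constant in every half-chain are flagged as
    degenerate (their R-hat is undefined) rather than failing the check.
    """
    if samples.n_chains < 2:
        raise ValueError("Gelman-Rubin diagnostic requires at least 2 chains")
    rhat: dict[str, np.ndarray] = {}
    degenerate: list[str] = []
    for name in samples.names:
        if name in skip:
            continue
        r = _split_rhat(samples.draws[name])
        if np.isnan(r).any():
            degenerate.append(name)
            r = r[np.isfinite(r)] if np.isfinite(r).any() else r
        rhat[name] = r
    return ConvergenceReport(rhat=rhat, threshold=rhat_threshold, degenerate=degenerate)


@dataclass(frozen=True)
class DicResult:
    """Deviance information criterion: DIC = mean deviance + p_D."""

    dic: float
    p_eff: float
    mean_deviance: float

    def __float__(self) -> float:
        return self.dic


def dic(samples: PosteriorSamples, model: GibbsModel) -> DicResult:
    """Spiegelhalter DIC from tracked deviance draws.

    ``p_D`` (effective number of parameters) is the mean posterior deviance
    minus the deviance at the posterior-mean parameter values.
    """
    if "deviance" not in samples.draws:
        raise ValueError("samples must track a 'deviance' parameter")
    dev = samples.pooled("deviance")
    if not np.all(np.isfinite(dev)):
        raise FloatingPointError("non-finite deviance draws encountered")
    mean_dev = float(dev.mean())
    point = samples.point_estimates()
    d_hat = -2.0 * model.log_likelihood(point)
    p_eff = mean_dev - d_hat
    return DicResult(dic=mean_dev + p_eff, p_eff=p_eff, mean_deviance=mean_dev)


def credible_interval(
    samples: PosteriorSamples, name: str, level: float = 0.95
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Equal-tailed posterior interval at the given level."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    pooled = samples.pooled(name)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(pooled, alpha, axis=0)
    hi = np.quantile(pooled, 1.0 - alpha, axis=0)
    if lo.ndim == 0:
        return float(lo), float(hi)
    return lo, hi


# --------------------------------------------------------------------------
# inverse-gamma helpers (half-Cauchy via scale mixture)
# --------------------------------------------------------------------------


def _rinvgamma(rng: np.random.Generator, shape: float, rate) -> np.ndarray | float:
    """Draw from InverseGamma(shape, rate) with density ~ x^-(a+1) e^(-rate/x)."""
    return np.asarray(rate) / rng.gamma(shape, 1.0, size=np.shape(rate) or None)


_VAR_FLOOR = 1e-12


# --------------------------------------------------------------------------
# hierarchical linear model (random intercept + random slopes)
# --------------------------------------------------------------------------


class HierarchicalLinearModel:
    """Gaussian linear model with optional per-group coefficient deviations.

    The observation model is

        y_i = x_i' (beta + b_{g(i)}) + e_i,     e_i ~ N(0, sigma^2)

    where ``g(i)`` indexes the grouping level (physicians).  With
    ``random_effects=True`` every coefficient (intercept and all slopes)
    receives an independent Normal deviation per group,
    ``b_{g,j} ~ N(0, tau_j^2)``; with ``random_effects=False`` the deviations
    are fixed at zero, giving an ordinary Bayesian regression.  Groups with
    few observations are shrunk toward the population coefficients (partial
    pooling) automatically by the Normal group-level prior.

    Priors: beta_j ~ N(0, coef_prior_sd^2); sigma and every tau_j ~
    half-Cauchy(scale_prior) through the inverse-gamma mixture.
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        groups: np.ndarray | None = None,
        random_effects: bool = False,
        coef_prior_sd: float = 100.0,
        scale_prior: float = 5.0,
    ) -> None:
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be (n, p) aligned with y")
        self.n, self.p = self.X.shape
        self.random_effects = bool(random_effects)
        self.coef_prior_sd = float(coef_prior_sd)
        self.scale_prior = float(scale_prior)

        if groups is None:
            groups = np.zeros(self.n, dtype=int)
        self.groups = np.asarray(groups)
        codes, inverse = np.unique(self.groups, return_inverse=True)
        self.group_labels = codes
        self._g = inverse
        self.n_groups = len(codes)
        if self.random_effects and self.n_groups < 2:
            raise ValueError("random effects require at least 2 groups")

        # sufficient statistics, global and per group
        self._XtX = self.X.T @ self.X
        self._Xty = self.X.T @ self.y
        self._XtX_g = np.zeros((self.n_groups, self.p, self.p))
        self._Xty_g = np.zeros((self.n_groups, self.p))
        for g in range(self.n_groups):
            Xg = self.X[self._g == g]
            yg = self.y[self._g == g]
            self._XtX_g[g] = Xg.T @ Xg
            self._Xty_g[g] = Xg.T @ yg

    # -- state ---------------------------------------------------------

    def init_state(self, rng: np.random.Generator) -> dict:
        ridge = self._XtX + 1e-6 * np.eye(self.p)
        beta_ls = np.linalg.solve(ridge, self._Xty)
        resid = self.y - self.X @ beta_ls
        s2 = max(float(resid @ resid) / max(self.n - self.p, 1), 1e-6)
        # overdispersed starting values per chain
        beta = beta_ls + rng.normal(0.0, np.sqrt(s2), self.p)
        state = {
            "beta": beta,
            "b": np.zeros((self.n_groups, self.p)),
            "sigma2": s2 * float(np.exp(rng.uniform(-1.0, 1.0))),
            "a_sigma": 1.0,
            "tau2": np.full(self.p, s2 * 0.1) * np.exp(rng.uniform(-2.0, 0.0, self.p)),
            "a_tau": np.ones(self.p),
        }
        return state

    # -- Gibbs sweep ---------------------------------------------------

    def step(self, state: dict, rng: np.random.Generator) -> dict:
        beta = state["beta"]
        b = state["b"]
        sigma2 = state["sigma2"]
        tau2 = state["tau2"]
        A2 = self.scale_prior**2

        # beta | b, sigma2  (uses only sufficient statistics)
        if self.random_effects:
            Xt_Zb = np.einsum("gij,gj->i", self._XtX_g, b)
        else:
            Xt_Zb = 0.0
        prec = self._XtX / sigma2 + np.eye(self.p) / self.coef_prior_sd**2
        rhs = (self._Xty - Xt_Zb) / sigma2
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, rhs)
        beta = mean + np.linalg.solve(L.T, rng.standard_normal(self.p))

        if self.random_effects:
            # b_g | beta, tau2, sigma2 -- batched over groups
            prec_g = self._XtX_g / sigma2 + np.diag(1.0 / np.maximum(tau2, _VAR_FLOOR))
            rhs_g = (self._Xty_g - self._XtX_g @ beta) / sigma2
            Lg = np.linalg.cholesky(prec_g)
            mean_g = np.linalg.solve(prec_g, rhs_g[..., None])[..., 0]
            z = rng.standard_normal((self.n_groups, self.p))
            b = mean_g + np.linalg.solve(np.transpose(Lg, (0, 2, 1)), z[..., None])[..., 0]

            # tau2_j | b  (half-Cauchy via IG mixture)
            ss = (b**2).sum(axis=0)
            tau2 = np.maximum(
                _rinvgamma(rng, 0.5 * (self.n_groups + 1), 1.0 / state["a_tau"] + 0.5 * ss),
                _VAR_FLOOR,
            )
            a_tau = _rinvgamma(rng, 1.0, 1.0 / A2 + 1.0 / tau2)
        else:
            a_tau = state["a_tau"]

        # sigma2 | beta, b
        fitted = self.X @ beta
        if self.random_effects:
            fitted = fitted + np.einsum("ij,ij->i", self.X, b[self._g])
        ssr = float(np.sum((self.y - fitted) ** 2))
        sigma2 = float(
            max(_rinvgamma(rng, 0.5 * (self.n + 1), 1.0 / state["a_sigma"] + 0.5 * ssr), _VAR_FLOOR)
        )
        a_sigma = float(_rinvgamma(rng, 1.0, 1.0 / A2 + 1.0 / sigma2))

        deviance = self.n * np.log(2.0 * np.pi * sigma2) + ssr / sigma2
        return {
            "beta": beta,
            "b": b,
            "sigma2": sigma2,
            "a_sigma": a_sigma,
            "tau2": tau2,
            "a_tau": a_tau,
            "deviance": deviance,
        }

    def collect(self, state: dict) -> dict[str, np.ndarray | float]:
        out: dict[str, np.ndarray | float] = {
            "beta": state["beta"],
            "sigma2": state["sigma2"],
            "deviance": state["deviance"],
        }
        if self.random_effects:
            out["b"] = state["b"]
            out["tau2"] = state["tau2"]
        return out

    def log_likelihood(self, point: dict) -> float:
        beta = np.asarray(point["beta"])
        sigma2 = float(point["sigma2"])
        fitted = self.X @ beta
        if self.random_effects:
            b = np.asarray(point["b"])
            fitted = fitted + np.einsum("ij,ij->i", self.X, b[self._g])
        ssr = float(np.sum((self.y - fitted) ** 2))
        return -0.5 * (self.n * np.log(2.0 * np.pi * sigma2) + ssr / sigma2)


# --------------------------------------------------------------------------
# crossed random intercepts (variance decomposition / inter-rater model)
# --------------------------------------------------------------------------


class CrossedRandomInterceptsModel:
    """Intercept-only Gaussian model with crossed random-intercept factors.

    y_i = mu + sum_f u_f[level_f(i)] + e_i, with u_f ~ N(0, tau_f^2) i.i.d.
    within each factor.  Used to decompose observer-rating variance into
    physician, consultation-within-physician and rater components, where the
    rater factor is crossed with physicians (a shared rater pool).
    """

    def __init__(
        self,
        y: np.ndarray,
        factors: dict[str, np.ndarray],
        mean_prior_sd: float = 100.0,
        scale_prior: float = 5.0,
    ) -> None:
        self.y = np.asarray(y, dtype=float)
        self.n = len(self.y)
        if not factors:
            raise ValueError("at least one factor is required")
        self.factor_names = list(factors)
        self._codes: dict[str, np.ndarray] = {}
        self._levels: dict[str, int] = {}
        self._counts: dict[str, np.ndarray] = {}
        for name, codes in factors.items():
            _, inv = np.unique(np.asarray(codes), return_inverse=True)
            self._codes[name] = inv
            self._levels[name] = int(inv.max()) + 1
            self._counts[name] = np.bincount(inv).astype(float)
        self.mean_prior_sd = float(mean_prior_sd)
        self.scale_prior = float(scale_prior)

    def init_state(self, rng: np.random.Generator) -> dict:
        s2 = max(float(np.var(self.y)), 1e-6)
        return {
            "mu": float(self.y.mean() + rng.normal(0, np.sqrt(s2))),
            "u": {
                name: np.zeros(self._levels[name], dtype=float) for name in self.factor_names
            },
            "tau2": {
                name: s2 * 0.2 * float(np.exp(rng.uniform(-2.0, 0.0)))
                for name in self.factor_names
            },
            "a_tau": {name: 1.0 for name in self.factor_names},
            "sigma2": s2 * float(np.exp(rng.uniform(-1.0, 1.0))),
            "a_sigma": 1.0,
        }

    def _linear_pred(self, mu: float, u: dict[str, np.ndarray]) -> np.ndarray:
        pred = np.full(self.n, mu)
        for name in self.factor_names:
            pred = pred + u[name][self._codes[name]]
        return pred

    def step(self, state: dict, rng: np.random.Generator) -> dict:
        u = {k: v.copy() for k, v in state["u"].items()}
        tau2 = dict(state["tau2"])
        a_tau = dict(state["a_tau"])
        sigma2 = state["sigma2"]
        A2 = self.scale_prior**2

        # mu | rest
        offset = self._linear_pred(0.0, u)
        prec = self.n / sigma2 + 1.0 / self.mean_prior_sd**2
        mean = np.sum(self.y - offset) / sigma2 / prec
        mu = float(rng.normal(mean, 1.0 / np.sqrt(prec)))

        # each factor's intercepts, then its variance
        for name in self.factor_names:
            codes = self._codes[name]
            others = self._linear_pred(mu, {**u, name: np.zeros_like(u[name])})
            resid_sum = np.bincount(codes, weights=self.y - others, minlength=self._levels[name])
            prec_l = self._counts[name] / sigma2 + 1.0 / max(tau2[name], _VAR_FLOOR)
            mean_l = resid_sum / sigma2 / prec_l
            u[name] = mean_l + rng.standard_normal(self._levels[name]) / np.sqrt(prec_l)

            ss = float(np.sum(u[name] ** 2))
            tau2[name] = float(
                max(
                    _rinvgamma(rng, 0.5 * (self._levels[name] + 1), 1.0 / a_tau[name] + 0.5 * ss),
                    _VAR_FLOOR,
                )
            )
            a_tau[name] = float(_rinvgamma(rng, 1.0, 1.0 / A2 + 1.0 / tau2[name]))

        ssr = float(np.sum((self.y - self._linear_pred(mu, u)) ** 2))
        sigma2 = float(
            max(_rinvgamma(rng, 0.5 * (self.n + 1), 1.0 / state["a_sigma"] + 0.5 * ssr), _VAR_FLOOR)
        )
        a_sigma = float(_rinvgamma(rng, 1.0, 1.0 / A2 + 1.0 / sigma2))

        deviance = self.n * np.log(2.0 * np.pi * sigma2) + ssr / sigma2
        return {
            "mu": mu,
            "u": u,
            "tau2": tau2,
            "a_tau": a_tau,
            "sigma2": sigma2,
            "a_sigma": a_sigma,
            "deviance": deviance,
        }

    def collect(self, state: dict) -> dict[str, np.ndarray | float]:
        out: dict[str, np.ndarray | float] = {
            "mu": state["mu"],
            "sigma2": state["sigma2"],
            "deviance": state["deviance"],
        }
        for name in self.factor_names:
            out[f"var_{name}"] = state["tau2"][name]
            out[f"u_{name}"] = state["u"][name]
        return out

    def log_likelihood(self, point: dict) -> float:
        u = {name: np.asarray(point[f"u_{name}"]) for name in self.factor_names}
        pred = self._linear_pred(float(point["mu"]), u)
        sigma2 = float(point["sigma2"])
        ssr = float(np.sum((self.y - pred) ** 2))
        return -0.5 * (self.n * np.log(2.0 * np.pi * sigma2) + ssr / sigma2)
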