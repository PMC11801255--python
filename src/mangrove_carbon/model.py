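"""Bayesian nonlinear logistic model of carbon-stock buildup ratios.

The buildup ratio R of a planted stand (planted stock over mean intact
stock) is modelled as a logistic function of stand age with a free
asymptote::

    R(age) = Rmax / (1 + exp(-beta0 - beta1 * ln(age)))

so that ln R is normal around the curve::

    ln R ~ Normal( ln(Rmax) - ln(1 + exp(-beta0 - beta1 * ln age)), sigma )

Rmax is the asymptotic planted-to-intact ratio (it may exceed 1: some
planted stands overshoot intact stocks), beta0 locates the curve (the log
odds at age 1 year), beta1 is its slope per unit ln(age), and sigma is the
residual SD of the log ratio.  Priors are weakly informative normals on the
unconstrained scale — ln Rmax ~ N(0, 2.5), beta0 ~ N(0, 5),
beta1 ~ N(0, 2.5) — and the Jeffreys (flat) prior on ln sigma, realized as
a wide uniform for the sampler.

Sampling uses an affine-invariant ensemble MCMC in the unconstrained
parameterization (ln Rmax, beta0, beta1, ln sigma); walkers are grouped
into pseudo-chains for split-Rhat / effective-sample-size diagnostics.

The statsmodels-style entry points are :class:`BuildupModel` (data + prior
+ sampler config; ``fit()`` runs MCMC) and :class:`BuildupResults`
(posterior draws, diagnostics, ``summary()``, derived quantities).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy import stats

from .pairing import RatioObservation, StratumSpec

_LOG_2PI = math.log(2.0 * math.pi)


class ConvergenceError(RuntimeError):
    """MCMC diagnostics failed the gate; carries the per-parameter table."""

    def __init__(self, message: str, diagnostics: pd.DataFrame):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class PriorSpec:
    """Prior scales for the unconstrained parameters.

    Normal(0, sd) on ln Rmax, beta0, beta1; flat on ln sigma within
    ``log_sigma_bounds`` (a proper stand-in for the improper Jeffreys
    prior, wide enough that the posterior is insensitive to the bounds).
    """

    log_rmax_sd: float = 2.5
    beta0_sd: float = 5.0
    beta1_sd: float = 2.5
    log_sigma_bounds: tuple[float, float] = (-10.0, 10.0)

    def __post_init__(self) -> None:
        if min(self.log_rmax_sd, self.beta0_sd, self.beta1_sd) <= 0:
            raise ValueError("prior sds must be > 0")
        if not self.log_sigma_bounds[0] < self.log_sigma_bounds[1]:
            raise ValueError("log_sigma_bounds must be increasing")


@dataclass(frozen=True)
class ParameterDraw:
    """One draw (or point value) of the curve parameters."""

    rmax: float
    beta0: float
    beta1: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.rmax > 0:
            raise ValueError("rmax must be > 0")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class FitConfig:
    """Sampler configuration; all randomness flows from ``seed``."""

    chains: int = 4
    walkers_per_chain: int = 8
    warmup: int = 2000
    samples: int = 8000
    seed: int = 0
    age_floor_yr: float = 0.25  # ages below this are floored before ln()
    rhat_max: float = 1.01
    ess_min: float = 100.0
    check_convergence: bool = True

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need >= 2 chains for split-Rhat")
        for name in ("walkers_per_chain", "warmup", "samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.age_floor_yr > 0:
            raise ValueError("age_floor_yr must be > 0")

    @property
    def n_walkers(self) -> int:
        return self.chains * self.walkers_per_chain


@dataclass
class PosteriorSamples:
    """Posterior draws for one stratum with chain labels and diagnostics."""

    stratum: StratumSpec
    rmax: np.ndarray  # flat, length n_draws
    beta0: np.ndarray
    beta1: np.ndarray
    sigma: np.ndarray
    chain: np.ndarray  # chain label per draw
    iteration: np.ndarray  # within-chain iteration per draw
    diagnostics: pd.DataFrame  # index parameter, columns rhat / ess
    seed: int = 0

    def __post_init__(self) -> None:
        arrays = (self.rmax, self.beta0, self.beta1, self.sigma, self.chain, self.iteration)
        n = len(self.rmax)
        if any(len(a) != n for a in arrays):
            raise ValueError("draw arrays must share a length")
        if len(np.unique(self.chain)) < 2:
            raise ValueError("need draws from >= 2 chains")
        for name in ("rmax", "beta0", "beta1", "sigma"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite draws in {name}")

    def __len__(self) -> int:
        return len(self.rmax)

    def draws(self) -> list[ParameterDraw]:
        return [
            ParameterDraw(r, b0, b1, s)
            for r, b0, b1, s in zip(self.rmax, self.beta0, self.beta1, self.sigma)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.stratum.label,
                "chain": self.chain,
                "iteration": self.iteration,
                "log_rmax": np.log(self.rmax),
                "beta0": self.beta0,
                "beta1": self.beta1,
                "log_sigma": np.log(self.sigma),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, seed: int = 0) -> "PosteriorSamples":
        labels = df["stratum"].unique()
        if len(labels) != 1:
            raise ValueError("frame must hold a single stratum")
        diag = pd.DataFrame(
            {"rhat": np.nan, "ess": np.nan},
            index=["log_rmax", "beta0", "beta1", "log_sigma"],
        )
        return cls(
            stratum=StratumSpec.from_label(labels[0]),
            rmax=np.exp(df["log_rmax"].to_numpy(float)),
            beta0=df["beta0"].to_numpy(float),
            beta1=df["beta1"].to_numpy(float),
            sigma=np.exp(df["log_sigma"].to_numpy(float)),
            chain=df["chain"].to_numpy(int),
            iteration=df["iteration"].to_numpy(int),
            diagnostics=diag,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# Curve and densities


def _log1pexp(x: np.ndarray | float) -> np.ndarray | float:
    """ln(1 + e^x), overflow-safe (→ x for large x, e^x for very negative x)."""
    return np.logaddexp(0.0, x)


def curve_ratio(theta: ParameterDraw, age_yr: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the logistic buildup curve R(age) = Rmax·expit(beta0+beta1·ln age).

    At age 0 the analytic limit applies: 0 for beta1 > 0 (curve starts from
    nothing), Rmax·expit(beta0) for beta1 = 0 (flat curve), Rmax for
    beta1 < 0.
    """
    age = np.asarray(age_yr, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be >= 0")
    with np.errstate(divide="ignore"):
        log_age = np.log(age)
    # -inf * 0 at age 0 with beta1 == 0 would be nan; the limit is expit(beta0)
    if theta.beta1 == 0.0:
        eta = np.full_like(age, theta.beta0)
    else:
        eta = theta.beta0 + theta.beta1 * log_age
    out = theta.rmax * np.exp(-_log1pexp(-eta))
    return float(out) if np.isscalar(age_yr) else out


def _mu(
    log_rmax: np.ndarray, beta0: np.ndarray, beta1: np.ndarray, log_age: np.ndarray
) -> np.ndarray:
    """Model mean of ln R; broadcasts parameters against observations."""
    return log_rmax - _log1pexp(-(beta0 + beta1 * log_age))


def effective_age(age_yr: np.ndarray | float, floor_yr: float) -> np.ndarray | float:
    return np.maximum(age_yr, floor_yr)


def log_likelihood(
    theta: ParameterDraw, obs: RatioObservation, age_floor_yr: float = 0.25
) -> float:
    """Normal log-density of ln(obs.ratio) under the curve at the stand's age."""
    if not np.isfinite([theta.rmax, theta.beta0, theta.beta1, theta.sigma]).all():
        raise ValueError("non-finite parameters")
    log_age = math.log(effective_age(obs.age_yr, age_floor_yr))
    mu = math.log(theta.rmax) - float(_log1pexp(-(theta.beta0 + theta.beta1 * log_age)))
    z = (math.log(obs.ratio) - mu) / theta.sigma
    return -0.5 * z * z - math.log(theta.sigma) - 0.5 * _LOG_2PI


def log_prior(theta: ParameterDraw, prior: PriorSpec | None = None) -> float:
    """Joint log prior density (up to the flat ln-sigma constant)."""
    prior = prior or PriorSpec()
    if theta.rmax <= 0 or theta.sigma <= 0:
        return -math.inf
    lo, hi = prior.log_sigma_bounds
    if not lo <= math.log(theta.sigma) <= hi:
        return -math.inf
    lp = 0.0
    for value, sd in (
        (math.log(theta.rmax), prior.log_rmax_sd),
        (theta.beta0, prior.beta0_sd),
        (theta.beta1, prior.beta1_sd),
    ):
        lp += -0.5 * (value / sd) ** 2 - math.log(sd) - 0.5 * _LOG_2PI
    return lp


def prior_interval_mass(
    sd: float, lo: float, hi: float, scale: str = "identity"
) -> float:
    """Prior probability a zero-mean Normal(0, sd) puts on [lo, hi].

    ``scale='exp'`` interprets the bounds on the exponentiated variable
    (e.g. Rmax bounds for the ln-Rmax prior); a non-positive lower bound
    then contributes its full left tail.
    """
    if not sd > 0:
        raise ValueError("sd must be > 0")
    if not lo < hi:
        raise ValueError("need lo < hi")
    if scale == "exp":
        lo = math.log(lo) if lo > 0 else -math.inf
        hi = math.log(hi) if hi > 0 else -math.inf
    elif scale != "identity":
        raise ValueError("scale must be 'identity' or 'exp'")
    return float(stats.norm.cdf(hi / sd) - stats.norm.cdf(lo / sd))


# ---------------------------------------------------------------------------
# Posterior sampling


def _make_log_prob(
    log_r: np.ndarray, log_age: np.ndarray, prior: PriorSpec, pivot: float
):
    """Vectorized log posterior in the sampling parameterization.

    The sampler works in x = (phi, beta0, beta1, ln sigma) where phi is the
    curve's log level at the pivot log-age: phi = ln Rmax - ln(1 +
    exp(-(beta0 + beta1*pivot))).  When the curve saturates over the
    observed age range, ln Rmax and beta0 are individually only
    prior-identified and form a long curved ridge; phi is the
    data-identified combination, so this transform (unit Jacobian)
    decorrelates the posterior and lets the ensemble sampler mix.  Priors
    are evaluated on the natural parameters.
    """
    lo, hi = prior.log_sigma_bounds

    def log_prob(x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        phi, beta0, beta1, log_sigma = x.T
        log_rmax = phi + _log1pexp(-(beta0 + beta1 * pivot))
        with np.errstate(over="ignore", invalid="ignore"):
            lp = np.where(
                (log_sigma >= lo) & (log_sigma <= hi),
                -0.5 * (
                    (log_rmax / prior.log_rmax_sd) ** 2
                    + (beta0 / prior.beta0_sd) ** 2
                    + (beta1 / prior.beta1_sd) ** 2
                ),
                -np.inf,
            )
            if log_r.size:
                mu = _mu(
                    log_rmax[:, None], beta0[:, None], beta1[:, None], log_age[None, :]
                )
                sigma = np.exp(log_sigma)[:, None]
                z = (log_r[None, :] - mu) / sigma
                lp = lp + np.sum(-0.5 * z * z - np.log(sigma), axis=1)
        return np.where(np.isfinite(lp), lp, -np.inf)

    return log_prob


def _to_natural(chain: np.ndarray, pivot: float) -> np.ndarray:
    """Map sampled (phi, b0, b1, ln sigma) draws to (ln Rmax, b0, b1, ln sigma)."""
    nat = chain.copy()
    nat[..., 0] = chain[..., 0] + np.asarray(
        _log1pexp(-(chain[..., 1] + chain[..., 2] * pivot))
    )
    return nat


def _diagnostics(chains: np.ndarray, names: Sequence[str]) -> pd.DataFrame:
    """Split-Rhat and bulk ESS per parameter from (chain, draw, dim) draws."""
    rows = {}
    for k, name in enumerate(names):
        da = az.convert_to_dataset(chains[:, :, k])
        rows[name] = {
            "rhat": float(az.rhat(da)["x"].values),
            "ess": float(az.ess(da)["x"].values),
        }
    return pd.DataFrame(rows).T[["rhat", "ess"]]


_PARAM_NAMES = ("log_rmax", "beta0", "beta1", "log_sigma")


def _initial_positions(
    log_prob,
    rng: np.random.RandomState,
    n_walkers: int,
    log_r: np.ndarray,
) -> np.ndarray:
    """Walker starting positions in the sampling parameterization.

    With data: a ball around the posterior mode (found by quasi-Newton
    ascent from a few seeded starts) scaled by the Laplace approximation,
    so tight posteriors burn in quickly.  Without data the prior itself is
    the target and walkers start spread over its scales.
    """
    if not log_r.size:
        # prior is the target: overdisperse walkers across its full scales,
        # including the wide flat ln-sigma band
        return np.column_stack(
            [
                rng.normal(0.0, 2.5, n_walkers),  # phi
                rng.normal(0.0, 5.0, n_walkers),
                rng.normal(0.0, 2.5, n_walkers),
                rng.uniform(-9.5, 9.5, n_walkers),
            ]
        )
    from scipy import optimize

    neg = lambda x: -float(log_prob(x[None, :])[0])
    phi0 = float(np.mean(log_r))
    ls0 = float(np.log(max(np.std(log_r), 1e-3)))
    best = None
    for b0, b1 in ((0.0, 0.5), (-2.0, 1.0), (2.0, 0.2)):
        res = optimize.minimize(
            neg,
            np.array([phi0, b0, b1, ls0]),
            method="L-BFGS-B",
            bounds=[(-12.0, 12.0), (-15.0, 15.0), (-8.0, 8.0), (-9.5, 9.5)],
        )
        if best is None or res.fun < best.fun:
            best = res
    scales = np.full(4, 0.05)
    try:
        hess_inv = best.hess_inv.todense() if hasattr(best.hess_inv, "todense") else best.hess_inv
        diag = np.clip(np.diag(np.asarray(hess_inv)), 1e-8, 4.0)
        scales = np.sqrt(diag)
    except Exception:
        pass
    return best.x[None, :] + rng.normal(0.0, 1.0, (n_walkers, 4)) * scales[None, :]


def fit_posterior(
    obs: Sequence[RatioObservation],
    prior: PriorSpec | None = None,
    cfg: FitConfig | None = None,
    stratum: StratumSpec | None = None,
) -> PosteriorSamples:
    """Sample the posterior for one stratum's observations by ensemble MCMC.

    With no observations the posterior equals the prior (useful for prior
    checks).  Raises :class:`ConvergenceError` when any split-Rhat exceeds
    ``cfg.rhat_max`` or any ESS falls below ``cfg.ess_min``; the error
    carries the diagnostics table.  Runs are reproducible given
    ``cfg.seed``.
    """
    prior = prior or PriorSpec()
    cfg = cfg or FitConfig()
    obs = list(obs)
    if stratum is None:
        strata = {o.stratum for o in obs}
        if len(strata) > 1:
            raise ValueError("observations span several strata; fit one at a time")
        stratum = strata.pop() if strata else StratumSpec("agb", "all")

    log_r = np.array([math.log(o.ratio) for o in obs])
    log_age = np.log(effective_age(np.array([o.age_yr for o in obs]), cfg.age_floor_yr))
    pivot = float(log_age.mean()) if log_age.size else 0.0
    log_prob = _make_log_prob(log_r, log_age, prior, pivot)

    rng = np.random.RandomState(cfg.seed % (2**31))
    nw = cfg.n_walkers
    p0 = _initial_positions(log_prob, rng, nw, log_r)
    sampler = emcee.EnsembleSampler(nw, 4, log_prob, vectorize=True)
    sampler.random_state = rng.get_state()
    sampler.run_mcmc(p0, cfg.warmup + cfg.samples, progress=False)
    # natural parameterization for storage and diagnostics
    chain = _to_natural(sampler.get_chain(discard=cfg.warmup), pivot)

    # each walker is one diagnostic chain; labels group walkers into
    # cfg.chains pseudo-chains for storage
    walker_chains = np.moveaxis(chain, 0, 1)  # (walkers, samples, 4)
    diag = _diagnostics(walker_chains, _PARAM_NAMES)

    flat = chain.reshape(-1, 4)  # iteration-major: all walkers per step
    n_steps = chain.shape[0]
    walker_ids = np.tile(np.arange(nw), n_steps)
    iteration = np.repeat(np.arange(n_steps), nw)
    samples = PosteriorSamples(
        stratum=stratum,
        rmax=np.exp(flat[:, 0]),
        beta0=flat[:, 1],
        beta1=flat[:, 2],
        sigma=np.exp(flat[:, 3]),
        chain=walker_ids // cfg.walkers_per_chain,
        iteration=iteration,
        diagnostics=diag,
        seed=cfg.seed,
    )
    if cfg.check_convergence:
        bad = diag[(diag["rhat"] > cfg.rhat_max) | (diag["ess"] < cfg.ess_min)]
        if len(bad):
            raise ConvergenceError(
                f"MCMC did not converge for {stratum.label}: "
                + ", ".join(
                    f"{p} rhat={r.rhat:.3f} ess={r.ess:.0f}" for p, r in bad.iterrows()
                ),
                diag,
            )
    return samples


# ---------------------------------------------------------------------------
# Derived quantities


def age_at_ratio(theta: ParameterDraw, target_r: float) -> float:
    """Invert the curve: the age at which R(age) = target_r.

    Returns ``inf`` when target_r >= Rmax (the curve never reaches it).
    A flat curve (beta1 = 0) has no age solution.
    """
    if not target_r > 0:
        raise ValueError("target_r must be > 0")
    if theta.beta1 == 0.0:
        raise ValueError("beta1 = 0: flat curve, age undefined")
    if target_r >= theta.rmax:
        return math.inf
    return math.exp(
        (math.log(target_r / (theta.rmax - target_r)) - theta.beta0) / theta.beta1
    )


def summarize_curve(
    samples: PosteriorSamples, ages: Sequence[float]
) -> pd.DataFrame:
    """Posterior mean and equal-tailed 95% interval of R(age) at each age."""
    ages = np.asarray(ages, dtype=float)
    curves = _curve_matrix(samples, ages)
    return pd.DataFrame(
        {
            "age_yr": ages,
            "mean": curves.mean(axis=0),
            "q2.5": np.quantile(curves, 0.025, axis=0),
            "q97.5": np.quantile(curves, 0.975, axis=0),
        }
    )


def _curve_matrix(samples: PosteriorSamples, ages: np.ndarray) -> np.ndarray:
    """R(age) for every draw x age, with the age-0 limit rule applied."""
    ages = np.asarray(ages, dtype=float)
    with np.errstate(divide="ignore"):
        log_age = np.log(ages)
    b1 = samples.beta1[:, None]
    with np.errstate(invalid="ignore"):
        eta = samples.beta0[:, None] + b1 * log_age[None, :]
    # age 0: eta is ±inf depending on sign(beta1); beta1 == 0 gives nan -> beta0
    zero = ages == 0.0
    if np.any(zero):
        flat = samples.beta1 == 0.0
        if np.any(flat):
            eta[np.ix_(flat, zero)] = samples.beta0[flat, None]
    return samples.rmax[:, None] * np.exp(-_log1pexp(-eta))


def slope_probability(samples: PosteriorSamples) -> dict[str, float]:
    """Posterior probabilities for the curve slope by draw counting.

    Returns the one-sided tail probability ``min(P(beta1<=0), P(beta1>=0))``
    (small values mean the slope is clearly signed) together with
    ``P(beta1 > 0)``.
    """
    if len(samples) < 100:
        raise ValueError("need >= 100 draws")
    b1 = samples.beta1
    p_le = float(np.mean(b1 <= 0.0))
    p_ge = float(np.mean(b1 >= 0.0))
    return {"tail": min(p_le, p_ge), "p_positive": float(np.mean(b1 > 0.0))}


def bayes_r2(samples: PosteriorSamples, obs: Sequence[RatioObservation],
             age_floor_yr: float = 0.25) -> float:
    """Bayesian R^2: draw-averaged Var(fitted ln R) / (Var(fit) + Var(residual))."""
    obs = list(obs)
    if len(obs) < 2:
        raise ValueError("need >= 2 observations")
    log_r = np.array([math.log(o.ratio) for o in obs])
    log_age = np.log(effective_age(np.array([o.age_yr for o in obs]), age_floor_yr))
    mu = _mu(
        np.log(samples.rmax)[:, None],
        samples.beta0[:, None],
        samples.beta1[:, None],
        log_age[None, :],
    )
    var_fit = mu.var(axis=1)
    var_res = (log_r[None, :] - mu).var(axis=1)
    total = var_fit + var_res
    if np.all(total == 0.0):
        raise ValueError("zero total variance; R^2 undefined")
    return float(np.mean(var_fit / np.where(total == 0.0, np.nan, total)))


# ---------------------------------------------------------------------------
# statsmodels-style surface


class BuildupModel:
    """Logistic buildup-ratio model for one stratum of ratio observations.

    Parameters
    ----------
    obs:
        Ratio observations (one stratum; see ``pairing``).
    prior:
        Prior scales; defaults to the weakly informative set.
    stratum:
        Optional explicit stratum (required when ``obs`` is empty).

    ``fit()`` runs the ensemble sampler and returns :class:`BuildupResults`.
    """

    def __init__(
        self,
        obs: Sequence[RatioObservation],
        prior: PriorSpec | None = None,
        stratum: StratumSpec | None = None,
    ):
        self.obs = list(obs)
        self.prior = prior or PriorSpec()
        self.stratum = stratum
        if self.stratum is None:
            strata = {o.stratum for o in self.obs}
            if len(strata) != 1:
                raise ValueError("pass stratum= when obs is empty or mixed")
            self.stratum = strata.pop()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        compartment: str,
        composition_group: str = "all",
        prior: PriorSpec | None = None,
    ) -> "BuildupModel":
        """Build from a ratios table (``pairing.observations_to_frame`` schema).

        ``composition_group='all'`` pools every composition in the
        compartment; otherwise rows are filtered to the requested group.
        """
        from .pairing import observations_from_frame

        sub = df[df["compartment"] == compartment]
        if composition_group != "all":
            sub = sub[sub["composition_group"] == composition_group]
        obs = observations_from_frame(sub)
        spec = StratumSpec(compartment, composition_group)
        if composition_group == "all":
            obs = [
                RatioObservation(
                    planted_id=o.planted_id,
                    compartment=o.compartment,
                    ratio=o.ratio,
                    age_yr=o.age_yr,
                    reference_ids=o.reference_ids,
                    reference_distance_km=o.reference_distance_km,
                    match_mode=o.match_mode,
                    stratum=spec,
                    study_id=o.study_id,
                )
                for o in obs
            ]
        return cls(obs, prior=prior, stratum=spec)

    def loglike(self, theta: ParameterDraw, age_floor_yr: float = 0.25) -> float:
        return sum(log_likelihood(theta, o, age_floor_yr) for o in self.obs)

    def fit(self, cfg: FitConfig | None = None, **kwargs) -> "BuildupResults":
        cfg = cfg or FitConfig(**kwargs)
        samples = fit_posterior(self.obs, self.prior, cfg, stratum=self.stratum)
        return BuildupResults(self, samples, cfg)


class BuildupResults:
    """Posterior results for a fitted :class:`BuildupModel`."""

    def __init__(self, model: BuildupModel, samples: PosteriorSamples, cfg: FitConfig):
        self.model = model
        self.samples = samples
        self.config = cfg

    # -- summaries -----------------------------------------------------

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd, 95% interval and diagnostics per parameter."""
        values = {
            "rmax": self.samples.rmax,
            "beta0": self.samples.beta0,
            "beta1": self.samples.beta1,
            "sigma": self.samples.sigma,
        }
        rows = []
        diag_names = dict(zip(("rmax", "beta0", "beta1", "sigma"), _PARAM_NAMES))
        for name, arr in values.items():
            d = self.samples.diagnostics.loc[diag_names[name]]
            rows.append(
                {
                    "parameter": name,
                    "mean": float(arr.mean()),
                    "sd": float(arr.std(ddof=1)),
                    "q2.5": float(np.quantile(arr, 0.025)),
                    "q97.5": float(np.quantile(arr, 0.975)),
                    "rhat": float(d["rhat"]),
                    "ess": float(d["ess"]),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def curve(self, ages: Sequence[float]) -> pd.DataFrame:
        return summarize_curve(self.samples, ages)

    def slope_probability(self) -> dict[str, float]:
        return slope_probability(self.samples)

    def bayes_r2(self) -> float:
        return bayes_r2(self.samples, self.model.obs, self.config.age_floor_yr)

    def age_at(self, target_r: float) -> pd.Series:
        """Posterior distribution summary of the age reaching ``target_r``.

        Draws whose asymptote never reaches the target contribute ``inf``;
        quantiles then propagate that honestly.
        """
        ages = np.array([age_at_ratio(t, target_r) for t in self.samples.draws()])
        finite = np.isfinite(ages)
        return pd.Series(
            {
                "median": float(np.median(ages)),
                "q2.5": float(np.quantile(ages, 0.025)),
                "q97.5": float(np.quantile(ages, 0.975)),
                "p_unreachable": float(1.0 - finite.mean()),
            }
        )

    # -- prediction ----------------------------------------------------

    def predict_stocks(self, intact, ages: Sequence[float], seed: int | None = None):
        from .prediction import predict_stocks

        return predict_stocks(self.samples, intact, ages, seed=seed)

    def net_gain(self, intact, t_end: float = 40.0, seed: int | None = None):
        from .prediction import net_gain

        return net_gain(self.samples, intact, t_end, seed=seed)
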