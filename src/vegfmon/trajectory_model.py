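"""Bayesian hierarchical piecewise-linear inflection-point model.

A biomarker trajectory under anti-angiogenic treatment is modeled as two
linear segments joined at a patient-specific inflection time::

    C(t) = alpha + S(t_inf - t) * beta * t
                 + S(t - t_inf) * (beta * t_inf + gamma * (t - t_inf)) + eps

where ``alpha`` is the pre-treatment quantity, ``beta`` the slope before the
inflection, ``gamma`` the slope after it, ``S`` the strict indicator
(1 if x > 0 else 0), and ``eps`` technical noise proportional to the
biomarker quantity (``sd = sigma_eps * |C(t)|``).  The inflection is
interpreted as the earliest sign of progression in the biomarker's tissue
compartment.

The population level mirrors the generative structure of
:mod:`vegfmon.synthetic_cohort`: log-normal baselines, Bernoulli-mixture
slope components expressed as relative rates per 365 days::

    log(alpha) ~ N(mu_a, sig_a^2)
    beta  = alpha * (b1 + s1 * E1 * b2) / 365,  b1 ~ N(mu_b1, sig_b1^2),
            log(b2) ~ N(mu_b2, sig_b2^2),       E1 ~ Bernoulli(p1)
    gamma = alpha * (g1 + s2 * E2 * g2) / 365   (analogous, p2)
    t_inf ~ U(21, PFS - 21)

with normal hyperpriors on every location and scale hyperparameter (scales
truncated to (0, inf)) and uniform hyperpriors on p1, p2.  Posteriors are
drawn by an adaptive Metropolis-within-Gibbs sampler: vectorised random-walk
updates per patient-level parameter block (inflection proposals reflected
into their support), exact full-conditional flips for the Bernoulli
indicators, conjugate draws for location hyperparameters, truncated-Beta
inverse-CDF draws for p1/p2 and random-walk updates for the scale
hyperparameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_cohort import CohortDataset, SLOPE_TIME_SCALE

__all__ = [
    "PiecewiseParams",
    "PriorSpec",
    "MCMCConfig",
    "PosteriorDraws",
    "ConvergenceReport",
    "TIE2_PRIOR",
    "indicator",
    "piecewise_eval",
    "log_likelihood",
    "run_mcmc",
    "gelman_rubin",
    "impute_pseudo_trial",
    "pseudo_trial",
]

HYPER_NAMES = (
    "mu_alpha", "sigma_alpha",
    "mu_beta1", "sigma_beta1", "mu_beta2", "sigma_beta2", "p1",
    "mu_gamma1", "sigma_gamma1", "mu_gamma2", "sigma_gamma2", "p2",
    "sigma_eps",
)
PATIENT_PARAM_NAMES = ("alpha", "beta", "gamma", "t_inflection", "e1", "e2")

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Types


@dataclass(frozen=True)
class PiecewiseParams:
    """Per-patient trajectory parameters (slopes in units/day)."""

    alpha: float
    beta: float
    gamma: float
    t_inflection: float


@dataclass(frozen=True)
class PriorSpec:
    """Hyperpriors for the population level.

    Each ``(loc, var)`` pair is a normal hyperprior N(loc, var) — the second
    entry is a *variance*, matching the convention of the model's prior
    block.  Scale hyperparameters are truncated to (0, inf).  ``p1_bounds``
    and ``p2_bounds`` are uniform supports for the mixture probabilities.
    ``slope2_sign``/``postslope2_sign`` fix whether the positive log-normal
    mixture component steepens the decline (-1) or the rise (+1).
    """

    mu_alpha: tuple[float, float] = (4.3, 1.0)
    sigma_alpha: tuple[float, float] = (0.6, 1.0)
    mu_beta1: tuple[float, float] = (-2.0, 1.0)
    sigma_beta1: tuple[float, float] = (1.0, 1.0)
    mu_beta2: tuple[float, float] = (1.5, 1.0)
    sigma_beta2: tuple[float, float] = (1.0, 1.0)
    p1_bounds: tuple[float, float] = (0.2, 0.7)
    mu_gamma1: tuple[float, float] = (0.0, 1.0)
    sigma_gamma1: tuple[float, float] = (2.0, 1.0)
    mu_gamma2: tuple[float, float] = (1.0, 1.0)
    sigma_gamma2: tuple[float, float] = (1.0, 1.0)
    p2_bounds: tuple[float, float] = (0.2, 0.7)
    sigma_eps: tuple[float, float] = (0.15, 10.0)
    slope2_sign: float = -1.0
    postslope2_sign: float = 1.0

    def validate(self) -> None:
        for name in ("sigma_alpha", "sigma_beta1", "sigma_beta2",
                     "sigma_gamma1", "sigma_gamma2", "sigma_eps",
                     "mu_alpha", "mu_beta1", "mu_beta2", "mu_gamma1", "mu_gamma2"):
            if getattr(self, name)[1] <= 0:
                raise ValueError(f"hyperprior variance for {name} must be > 0")
        for name in ("p1_bounds", "p2_bounds"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(f"{name} must satisfy 0 <= lo < hi <= 1")


#: Hyperpriors used when the vascular marker Tie2 is modeled.
TIE2_PRIOR = PriorSpec()


@dataclass(frozen=True)
class MCMCConfig:
    """Chain protocol.

    Defaults are scaled for desk-size synthetic problems (2,000 burn-in +
    5,000 retained draws over three chains); trial-scale runs (50,000
    burn-in, 100,000 sampling) are available through the same fields.
    """

    n_chains: int = 3
    burn_in_iters: int = 2000
    sample_iters: int = 5000
    seed: int = 0
    adaptation: bool = True
    thin: int = 1

    def validate(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2")
        if self.burn_in_iters < 1 or self.sample_iters < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorDraws:
    """Per-parameter, per-chain MCMC draws for one biomarker model.

    ``hyper[name]`` has shape (n_chains, n_draws); ``patient[name]`` has
    shape (n_chains, n_draws, n_patients) for the derived per-patient
    parameters (alpha, beta, gamma, t_inflection, e1, e2).
    """

    biomarker: str
    patient_ids: list[str]
    pfs_days: np.ndarray
    hyper: dict[str, np.ndarray]
    patient: dict[str, np.ndarray]
    seed: int
    config: MCMCConfig
    prior: PriorSpec

    @property
    def n_chains(self) -> int:
        return next(iter(self.hyper.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.hyper.values())).shape[1]

    def hyper_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """Equal-tailed posterior credible interval pooled over chains."""
        x = self.hyper[name].ravel()
        a = (1.0 - level) / 2.0
        return float(np.quantile(x, a)), float(np.quantile(x, 1.0 - a))

    def patient_median(self, name: str) -> pd.Series:
        med = np.median(self.patient[name].reshape(-1, len(self.patient_ids)), axis=0)
        return pd.Series(med, index=self.patient_ids, name=name)

    def patient_params_at(self, chain: int, draw: int,
                          patient_index: int) -> PiecewiseParams:
        p = self.patient
        return PiecewiseParams(
            alpha=float(p["alpha"][chain, draw, patient_index]),
            beta=float(p["beta"][chain, draw, patient_index]),
            gamma=float(p["gamma"][chain, draw, patient_index]),
            t_inflection=float(p["t_inflection"][chain, draw, patient_index]),
        )

    def to_csv(self, path) -> None:
        """Export hyperparameter draws as long CSV (chain, iteration, parameter, value)."""
        rows = []
        for name, arr in self.hyper.items():
            for c in range(arr.shape[0]):
                rows.append(pd.DataFrame({
                    "chain": c,
                    "iteration": np.arange(arr.shape[1]),
                    "parameter": name,
                    "value": arr[c],
                }))
        pd.concat(rows, ignore_index=True).to_csv(Path(path), index=False)


@dataclass
class ConvergenceReport:
    """Gelman-Rubin potential scale reduction factors and effective sizes."""

    rhat: dict[str, float]
    ess: dict[str, float]
    cutoff: float
    converged: bool
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rhat": {k: (None if not np.isfinite(v) else float(v))
                     for k, v in self.rhat.items()},
            "ess": {k: (None if not np.isfinite(v) else float(v))
                    for k, v in self.ess.items()},
            "cutoff": self.cutoff,
            "converged": self.converged,
            "undefined": list(self.undefined),
        }


# ---------------------------------------------------------------------------
# Model primitives


def indicator(x):
    """Strict indicator S(x): 1 where x > 0, else 0."""
    if np.isscalar(x):
        return 1 if x > 0 else 0
    return (np.asarray(x) > 0).astype(int)


def piecewise_eval(params: PiecewiseParams, t, *, literal_indicators: bool = False):
    """Noiseless piecewise-linear trajectory value at time(s) ``t``.

    By default the trajectory is continuous at the inflection (left-limit
    convention: ``alpha + beta * t_inf`` at ``t = t_inf``).  With
    ``literal_indicators=True`` the strict indicators are applied verbatim,
    which zeroes both slope terms exactly at the inflection (a removable
    discontinuity of the literal parameterisation).
    """
    t_arr = np.asarray(t, dtype=float)
    a, b, g, tf = params.alpha, params.beta, params.gamma, params.t_inflection
    if literal_indicators:
        out = (a
               + indicator(tf - t_arr) * b * t_arr
               + indicator(t_arr - tf) * (b * tf + g * (t_arr - tf)))
    else:
        out = np.where(t_arr < tf, a + b * t_arr, a + b * tf + g * (t_arr - tf))
    if np.isscalar(t):
        return float(out)
    return out


def log_likelihood(params: Mapping[str, PiecewiseParams], sigma_eps: float,
                   observations: pd.DataFrame) -> float:
    """Gaussian log-likelihood with quantity-proportional noise.

    ``observations`` is a long-format measurement table (columns
    ``patient_id``, ``time_days``, ``value``); each point contributes a
    normal log-density with mean ``piecewise_eval`` and standard deviation
    ``sigma_eps * |mean|``.  Missing visits simply contribute nothing.
    """
    if sigma_eps <= 0:
        raise ValueError("sigma_eps must be > 0")
    if observations.empty:
        raise ValueError("observations must be non-empty")
    total = 0.0
    for pid, grp in observations.groupby("patient_id", sort=False):
        p = params[pid]
        t = np.maximum(grp["time_days"].to_numpy(float), 0.0)
        y = grp["value"].to_numpy(float)
        mean = piecewise_eval(p, t)
        if np.any(mean == 0.0):
            raise ValueError(
                f"degenerate noise scale: predicted mean is 0 for patient {pid}"
            )
        sd = sigma_eps * np.abs(mean)
        total += float(np.sum(-0.5 * ((y - mean) / sd) ** 2 - np.log(sd)
                              - 0.5 * _LOG2PI))
    return total


# ---------------------------------------------------------------------------
# Sampler internals


class _ModelData:
    """Padded per-patient observation arrays for vectorised likelihoods."""

    def __init__(self, dataset: CohortDataset, biomarker: str):
        meas = dataset.measurements
        sub = meas[meas["biomarker"] == biomarker]
        if sub.empty:
            raise ValueError(f"no measurements for biomarker {biomarker!r}")
        surv = dataset.survival.set_index("patient_id")
        ids = sorted(sub["patient_id"].unique())
        too_few = []
        t_list, y_list, pfs_list = [], [], []
        for pid in ids:
            grp = sub[sub["patient_id"] == pid]
            # Pre-treatment replicates measure the baseline quantity alpha:
            # map them to t = 0 on the model's time axis.
            t = np.maximum(grp["time_days"].to_numpy(float), 0.0)
            y = grp["value"].to_numpy(float)
            if len(t) < 3:
                too_few.append(pid)
            pfs = float(surv.loc[pid, "pfs_days"])
            if pfs < 42.0:
                raise ValueError(
                    f"patient {pid} has pfs_days={pfs:.1f} < 42; "
                    "inflection support would be empty"
                )
            t_list.append(t)
            y_list.append(y)
            pfs_list.append(pfs)
        if too_few:
            raise ValueError(
                "every modeled patient needs >=3 observations; too few for: "
                + ", ".join(too_few)
            )
        self.patient_ids = ids
        self.n = len(ids)
        m = max(len(t) for t in t_list)
        self.T = np.zeros((self.n, m))
        self.Y = np.zeros((self.n, m))
        self.mask = np.zeros((self.n, m), dtype=bool)
        for i, (t, y) in enumerate(zip(t_list, y_list)):
            self.T[i, :len(t)] = t
            self.Y[i, :len(y)] = y
            self.mask[i, :len(t)] = True
        self.pfs = np.asarray(pfs_list)
        self.tf_lo = np.full(self.n, 21.0)
        self.tf_hi = self.pfs - 21.0


class _State:
    """One chain's parameter state."""

    __slots__ = ("la", "b1", "lb2", "e1", "g1", "lg2", "e2", "tf", "hyper")

    def __init__(self, la, b1, lb2, e1, g1, lg2, e2, tf, hyper):
        self.la, self.b1, self.lb2, self.e1 = la, b1, lb2, e1
        self.g1, self.lg2, self.e2, self.tf = g1, lg2, e2, tf
        self.hyper = hyper  # dict name -> float


def _patient_loglik(data: _ModelData, la, b1, lb2, e1, g1, lg2, e2, tf,
                    sigma_eps, s1, s2) -> np.ndarray:
    """Vector of per-patient log-likelihoods (length n)."""
    alpha = np.exp(la)
    beta = alpha * (b1 + s1 * e1 * np.exp(lb2)) / SLOPE_TIME_SCALE
    gamma = alpha * (g1 + s2 * e2 * np.exp(lg2)) / SLOPE_TIME_SCALE
    tf_c = tf[:, None]
    mean = np.where(data.T < tf_c,
                    alpha[:, None] + beta[:, None] * data.T,
                    alpha[:, None] + beta[:, None] * tf_c
                    + gamma[:, None] * (data.T - tf_c))
    absmean = np.abs(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        sd = sigma_eps * absmean
        ll = -0.5 * ((data.Y - mean) / sd) ** 2 - np.log(sd) - 0.5 * _LOG2PI
    ll = np.where(data.mask & (absmean > 0), ll, np.where(data.mask, -np.inf, 0.0))
    return ll.sum(axis=1)


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Reflect proposals into [lo, hi] (handles multiple bounces)."""
    width = hi - lo
    y = np.mod(x - lo, 2.0 * width)
    y = np.where(y > width, 2.0 * width - y, y)
    return lo + y


def _norm_logpdf(x, loc, var):
    return -0.5 * (x - loc) ** 2 / var - 0.5 * math.log(var) - 0.5 * _LOG2PI


def _init_state(data: _ModelData, prior: PriorSpec, rng: np.random.Generator,
                chain: int) -> _State:
    """Over-dispersed initialisation anchored at crude data estimates.

    Per patient, the relative decline rate to the observed minimum and the
    relative rebound rate after it seed the slope components, and the time
    of the minimum seeds the inflection; each chain adds its own jitter so
    chains start over-dispersed.
    """
    s1, s2 = prior.slope2_sign, prior.postslope2_sign
    jitter = 0.25 * (chain + 1)
    n = data.n
    first = np.empty(n)
    rel_pre = np.empty(n)
    rel_post = np.empty(n)
    t_min = np.empty(n)
    for i in range(n):
        t = data.T[i, data.mask[i]]
        y = data.Y[i, data.mask[i]]
        order = np.argsort(t)
        t, y = t[order], y[order]
        a0 = max(y[0], 1e-6)
        first[i] = a0
        k = int(np.argmin(y))
        t_min[i] = t[k]
        rel_pre[i] = ((y[k] - a0) / max(t[k], 1.0)) / a0 * SLOPE_TIME_SCALE
        if k < len(t) - 1 and t[-1] > t[k]:
            rel_post[i] = ((y[-1] - y[k]) / (t[-1] - t[k])) / a0 * SLOPE_TIME_SCALE
        else:
            rel_post[i] = 0.3
    la = np.log(first) + rng.normal(0.0, 0.1 + 0.05 * chain, n)
    # Split patients at the median decline rate: the steeper half seeds the
    # second mixture component.
    e1 = (rel_pre < np.median(rel_pre)).astype(float)
    depth = np.maximum(np.abs(rel_pre) / 2.0, 0.05)
    lb2 = np.log(depth) + rng.normal(0, jitter, n)
    b1 = rel_pre - s1 * e1 * depth + rng.normal(0, 0.1 + jitter / 4, n)
    e2 = (rel_post > np.median(rel_post)).astype(float)
    depth2 = np.maximum(np.abs(rel_post) / 2.0, 0.05)
    lg2 = np.log(depth2) + rng.normal(0, jitter, n)
    g1 = rel_post - s2 * e2 * depth2 + rng.normal(0, 0.1 + jitter / 4, n)
    tf = _reflect(t_min + rng.normal(0, 10 * (chain + 1), n),
                  data.tf_lo, data.tf_hi)
    hyper = {
        "mu_alpha": float(la.mean()) + rng.normal(0, 0.2),
        "sigma_alpha": float(la.std()) + abs(rng.normal(0, 0.1)) + 0.05,
        "mu_beta1": float(b1.mean()) + rng.normal(0, 0.3),
        "sigma_beta1": float(b1.std()) + abs(rng.normal(0, 0.15)) + 0.05,
        "mu_beta2": float(lb2.mean()) + rng.normal(0, 0.3),
        "sigma_beta2": float(lb2.std()) + abs(rng.normal(0, 0.15)) + 0.05,
        "p1": rng.uniform(*prior.p1_bounds),
        "mu_gamma1": float(g1.mean()) + rng.normal(0, 0.3),
        "sigma_gamma1": float(g1.std()) + abs(rng.normal(0, 0.15)) + 0.05,
        "mu_gamma2": float(lg2.mean()) + rng.normal(0, 0.3),
        "sigma_gamma2": float(lg2.std()) + abs(rng.normal(0, 0.15)) + 0.05,
        "p2": rng.uniform(*prior.p2_bounds),
        "sigma_eps": abs(prior.sigma_eps[0] + rng.normal(0, 0.03)) + 0.02,
    }
    return _State(la, b1, lb2, e1, g1, lg2, e2, tf, hyper)


_BLOCKS = ("la", "b1", "lb2", "g1", "lg2", "tf")
_BLOCK_PRIOR = {
    "la": ("mu_alpha", "sigma_alpha"),
    "b1": ("mu_beta1", "sigma_beta1"),
    "lb2": ("mu_beta2", "sigma_beta2"),
    "g1": ("mu_gamma1", "sigma_gamma1"),
    "lg2": ("mu_gamma2", "sigma_gamma2"),
}


def _run_chain(data: _ModelData, prior: PriorSpec, config: MCMCConfig,
               rng: np.random.Generator, chain: int):
    s1, s2 = prior.slope2_sign, prior.postslope2_sign
    st = _init_state(data, prior, rng, chain)

    def loglik(state: _State, **over) -> np.ndarray:
        kw = dict(la=state.la, b1=state.b1, lb2=state.lb2, e1=state.e1,
                  g1=state.g1, lg2=state.lg2, e2=state.e2, tf=state.tf,
                  sigma_eps=state.hyper["sigma_eps"])
        kw.update(over)
        return _patient_loglik(data, s1=s1, s2=s2, **kw)

    ll_cur = loglik(st)
    if not np.all(np.isfinite(ll_cur)):
        bad = data.patient_ids[int(np.argmin(np.isfinite(ll_cur)))]
        raise RuntimeError(
            f"non-finite posterior at initialization for patient {bad}"
        )

    steps = {"la": 0.05, "b1": 0.3, "lb2": 0.3, "g1": 0.3, "lg2": 0.3,
             "tf": 0.1}  # tf step is a fraction of each patient's support
    hyper_steps = {name: 0.1 for name in
                   ("sigma_alpha", "sigma_beta1", "sigma_beta2",
                    "sigma_gamma1", "sigma_gamma2")}
    hyper_steps["sigma_eps"] = 0.03
    acc = {k: [0, 0] for k in list(steps) + list(hyper_steps)}

    n_draws = config.sample_iters // config.thin
    out_hyper = {name: np.empty(n_draws) for name in HYPER_NAMES}
    out_patient = {name: np.empty((n_draws, data.n)) for name in PATIENT_PARAM_NAMES}
    k_out = 0

    total_iters = config.burn_in_iters + config.sample_iters
    for it in range(total_iters):
        burn = it < config.burn_in_iters

        # --- patient-level random-walk blocks
        for name in _BLOCKS:
            cur = getattr(st, name)
            if name == "tf":
                width = data.tf_hi - data.tf_lo
                prop = cur + steps["tf"] * width * rng.standard_normal(data.n)
                prop = _reflect(prop, data.tf_lo, data.tf_hi)
                dprior = 0.0  # uniform support, reflection keeps it
            else:
                prop = cur + steps[name] * rng.standard_normal(data.n)
                mu_n, sig_n = _BLOCK_PRIOR[name]
                mu, sig = st.hyper[mu_n], st.hyper[sig_n]
                dprior = (_norm_logpdf(prop, mu, sig ** 2)
                          - _norm_logpdf(cur, mu, sig ** 2))
            ll_prop = loglik(st, **{name: prop})
            log_r = ll_prop - ll_cur + dprior
            accept = np.log(rng.random(data.n)) < log_r
            cur[accept] = prop[accept]
            ll_cur = np.where(accept, ll_prop, ll_cur)
            acc[name][0] += int(accept.sum())
            acc[name][1] += data.n

        # --- Bernoulli indicator flips (exact full conditionals)
        for e_name, p_name in (("e1", "p1"), ("e2", "p2")):
            p = st.hyper[p_name]
            ll0 = loglik(st, **{e_name: np.zeros(data.n)})
            ll1 = loglik(st, **{e_name: np.ones(data.n)})
            logit = (ll1 - ll0) + math.log(p) - math.log1p(-p)
            prob1 = 1.0 / (1.0 + np.exp(-np.clip(logit, -700, 700)))
            new_e = (rng.random(data.n) < prob1).astype(float)
            setattr(st, e_name, new_e)
            ll_cur = np.where(new_e == 1.0, ll1, ll0)

        # --- label-mixing sweeps (likelihood-free, so repeated cheaply):
        # (a) exact Gibbs refresh of inactive mixture latents — when E = 0
        # the log-normal component does not enter the likelihood, so its
        # full conditional is its population prior; (b) compensated label
        # flips — flip an indicator while shifting the normal component to
        # preserve the total slope, leaving the likelihood unchanged, so
        # acceptance depends only on the priors.  Together these let
        # patients travel between mixture labels without a likelihood
        # barrier, resolving the label non-identifiability.
        for _ in range(3):
            for e_name, l_name in (("e1", "lb2"), ("e2", "lg2")):
                e = getattr(st, e_name)
                inactive = e == 0.0
                if np.any(inactive):
                    mu_n, sig_n = _BLOCK_PRIOR[l_name]
                    lat = getattr(st, l_name)
                    lat[inactive] = (st.hyper[mu_n] + st.hyper[sig_n]
                                     * rng.standard_normal(int(inactive.sum())))
            for e_name, c_name, l_name, p_name, sign in (
                    ("e1", "b1", "lb2", "p1", s1), ("e2", "g1", "lg2", "p2", s2)):
                e = getattr(st, e_name)
                c = getattr(st, c_name)
                comp = np.exp(getattr(st, l_name))
                e_new = 1.0 - e
                c_new = c - sign * (e_new - e) * comp
                mu_n, sig_n = _BLOCK_PRIOR[c_name]
                mu, sig = st.hyper[mu_n], st.hyper[sig_n]
                p = st.hyper[p_name]
                log_r = (_norm_logpdf(c_new, mu, sig ** 2)
                         - _norm_logpdf(c, mu, sig ** 2)
                         + (e_new - e) * (math.log(p) - math.log1p(-p)))
                accept = np.log(rng.random(data.n)) < log_r
                c[accept] = c_new[accept]
                setattr(st, e_name, np.where(accept, e_new, e))

        # --- hyperparameters
        _update_locations(st, prior, rng)
        _update_scales(st, prior, rng, hyper_steps, acc)
        _update_mixture_probs(st, prior, rng)
        ll_cur = _update_sigma_eps(st, prior, rng, hyper_steps, acc, loglik, ll_cur)

        # --- burn-in adaptation toward 20-50% acceptance
        if burn and config.adaptation and (it + 1) % 50 == 0:
            for k in acc:
                n_acc, n_tot = acc[k]
                if n_tot == 0:
                    continue
                rate = n_acc / n_tot
                factor = math.exp(0.5 * (rate - 0.35))
                if k in steps:
                    steps[k] = float(np.clip(steps[k] * factor, 1e-4, 10.0))
                else:
                    hyper_steps[k] = float(np.clip(hyper_steps[k] * factor,
                                                   1e-4, 10.0))
                acc[k] = [0, 0]

        # --- record retained draws
        if not burn and (it - config.burn_in_iters) % config.thin == 0:
            for name in HYPER_NAMES:
                out_hyper[name][k_out] = st.hyper[name]
            alpha = np.exp(st.la)
            beta = alpha * (st.b1 + s1 * st.e1 * np.exp(st.lb2)) / SLOPE_TIME_SCALE
            gamma = alpha * (st.g1 + s2 * st.e2 * np.exp(st.lg2)) / SLOPE_TIME_SCALE
            out_patient["alpha"][k_out] = alpha
            out_patient["beta"][k_out] = beta
            out_patient["gamma"][k_out] = gamma
            out_patient["t_inflection"][k_out] = st.tf
            out_patient["e1"][k_out] = st.e1
            out_patient["e2"][k_out] = st.e2
            k_out += 1

    return out_hyper, out_patient


def _update_locations(st: _State, prior: PriorSpec, rng) -> None:
    """Conjugate normal-normal draws for the location hyperparameters."""
    pairs = (("mu_alpha", "sigma_alpha", st.la, prior.mu_alpha),
             ("mu_beta1", "sigma_beta1", st.b1, prior.mu_beta1),
             ("mu_beta2", "sigma_beta2", st.lb2, prior.mu_beta2),
             ("mu_gamma1", "sigma_gamma1", st.g1, prior.mu_gamma1),
             ("mu_gamma2", "sigma_gamma2", st.lg2, prior.mu_gamma2))
    for mu_name, sig_name, x, (loc0, var0) in pairs:
        sig2 = st.hyper[sig_name] ** 2
        n = len(x)
        prec = 1.0 / var0 + n / sig2
        mean = (loc0 / var0 + x.sum() / sig2) / prec
        st.hyper[mu_name] = mean + math.sqrt(1.0 / prec) * rng.standard_normal()


def _update_scales(st: _State, prior: PriorSpec, rng, hyper_steps, acc) -> None:
    """Random-walk updates for patient-level scale hyperparameters
    (normal hyperpriors truncated to positive values)."""
    pairs = (("sigma_alpha", st.la, st.hyper["mu_alpha"], prior.sigma_alpha),
             ("sigma_beta1", st.b1, st.hyper["mu_beta1"], prior.sigma_beta1),
             ("sigma_beta2", st.lb2, st.hyper["mu_beta2"], prior.sigma_beta2),
             ("sigma_gamma1", st.g1, st.hyper["mu_gamma1"], prior.sigma_gamma1),
             ("sigma_gamma2", st.lg2, st.hyper["mu_gamma2"], prior.sigma_gamma2))
    for name, x, mu, (loc0, var0) in pairs:
        cur = st.hyper[name]
        prop = abs(cur + hyper_steps[name] * rng.standard_normal())
        if prop <= 0:
            continue
        ss = float(np.sum((x - mu) ** 2))
        n = len(x)

        def logpost(s):
            return (-n * math.log(s) - ss / (2.0 * s * s)
                    + _norm_logpdf(s, loc0, var0))

        if math.log(rng.random() + 1e-300) < logpost(prop) - logpost(cur):
            st.hyper[name] = prop
            acc[name][0] += 1
        acc[name][1] += 1


def _update_mixture_probs(st: _State, prior: PriorSpec, rng) -> None:
    """Exact truncated-Beta inverse-CDF draws for p1 and p2."""
    for e, p_name, bounds in ((st.e1, "p1", prior.p1_bounds),
                              (st.e2, "p2", prior.p2_bounds)):
        s = float(e.sum())
        n = len(e)
        dist = stats.beta(s + 1.0, n - s + 1.0)
        lo, hi = dist.cdf(bounds[0]), dist.cdf(bounds[1])
        u = rng.uniform(lo, hi)
        st.hyper[p_name] = float(np.clip(dist.ppf(u), bounds[0] + 1e-9,
                                         bounds[1] - 1e-9))


def _update_sigma_eps(st: _State, prior: PriorSpec, rng, hyper_steps, acc,
                      loglik, ll_cur):
    cur = st.hyper["sigma_eps"]
    prop = abs(cur + hyper_steps["sigma_eps"] * rng.standard_normal())
    if prop <= 0:
        return ll_cur
    loc0, var0 = prior.sigma_eps
    ll_prop = loglik(st, sigma_eps=prop)
    log_r = (ll_prop.sum() - ll_cur.sum()
             + _norm_logpdf(prop, loc0, var0) - _norm_logpdf(cur, loc0, var0))
    acc["sigma_eps"][1] += 1
    if math.log(rng.random() + 1e-300) < log_r:
        st.hyper["sigma_eps"] = prop
        acc["sigma_eps"][0] += 1
        return ll_prop
    return ll_cur


def run_mcmc(dataset: CohortDataset, biomarker: str,
             prior: PriorSpec = TIE2_PRIOR,
             config: MCMCConfig = MCMCConfig()) -> PosteriorDraws:
    """Fit the hierarchical piecewise model to one biomarker's trajectories.

    Runs ``config.n_chains`` independent, over-dispersed adaptive
    Metropolis-within-Gibbs chains and returns every retained draw.  Fully
    deterministic under ``config.seed``.
    """
    prior.validate()
    config.validate()
    data = _ModelData(dataset, biomarker)
    child_seqs = np.random.SeedSequence(config.seed).spawn(config.n_chains)

    hyper_all = {name: [] for name in HYPER_NAMES}
    patient_all = {name: [] for name in PATIENT_PARAM_NAMES}
    for c, seq in enumerate(child_seqs):
        rng = np.random.default_rng(seq)
        out_hyper, out_patient = _run_chain(data, prior, config, rng, c)
        for name in HYPER_NAMES:
            hyper_all[name].append(out_hyper[name])
        for name in PATIENT_PARAM_NAMES:
            patient_all[name].append(out_patient[name])

    return PosteriorDraws(
        biomarker=biomarker,
        patient_ids=data.patient_ids,
        pfs_days=data.pfs,
        hyper={k: np.stack(v) for k, v in hyper_all.items()},
        patient={k: np.stack(v) for k, v in patient_all.items()},
        seed=config.seed,
        config=config,
        prior=prior,
    )


# ---------------------------------------------------------------------------
# Convergence diagnostics


def _rhat(chains: np.ndarray) -> float:
    """Classic Gelman-Rubin potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws).  Returns NaN when the
    within-chain variance is zero (constant parameter).
    """
    m, n = chains.shape
    means = chains.mean(axis=1)
    w = float(chains.var(axis=1, ddof=1).mean())
    if w == 0.0 or not np.isfinite(w):
        return float("nan")
    b_over_n = float(means.var(ddof=1))
    var_hat = (n - 1) / n * w + b_over_n * (1.0 + 1.0 / m)
    # The pooled-variance estimate can fall marginally below the
    # within-chain variance by sampling noise; the reported factor is >= 1
    # by definition.
    return max(math.sqrt(max(var_hat / w, 0.0)), 1.0)


def gelman_rubin(draws, cutoff: float = 1.1,
                 params: Sequence[str] | None = None) -> ConvergenceReport:
    """Potential scale reduction factors over the monitored parameters.

    ``draws`` may be a :class:`PosteriorDraws` (hyperparameters are
    monitored) or a mapping of parameter name to a (n_chains, n_draws)
    array.  A parameter with zero within-chain variance is reported as
    undefined rather than crashing.
    """
    import arviz as az

    if isinstance(draws, PosteriorDraws):
        arrays = dict(draws.hyper)
    else:
        arrays = {k: np.asarray(v, dtype=float) for k, v in draws.items()}
    if params is not None:
        arrays = {k: arrays[k] for k in params}
    for name, arr in arrays.items():
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 10:
            raise ValueError(
                f"{name}: need >=2 chains with >=10 retained draws each"
            )
    rhat, ess, undefined = {}, {}, []
    for name, arr in arrays.items():
        r = _rhat(arr)
        rhat[name] = r
        if math.isnan(r):
            undefined.append(name)
            ess[name] = float("nan")
        else:
            ess[name] = float(az.ess(arr))
    defined = [v for v in rhat.values() if np.isfinite(v)]
    converged = bool(defined) and all(v < cutoff for v in defined) and not undefined
    return ConvergenceReport(rhat=rhat, ess=ess, cutoff=cutoff,
                             converged=converged, undefined=undefined)


# ---------------------------------------------------------------------------
# Posterior predictive pseudo-trials


def monthly_grid(pfs_days: float, rng: np.random.Generator,
                 interval: float = 30.0, jitter: float = 5.0) -> np.ndarray:
    """Monthly collection times (interval +/- jitter days), capped at PFS."""
    k = int(pfs_days // interval)
    times = interval * np.arange(1, k + 1)
    if k:
        times = times + rng.uniform(-jitter, jitter, size=k)
    return np.minimum(np.maximum(times, 0.0), pfs_days)


def impute_pseudo_trial(draws: PosteriorDraws, patient_id: str,
                        grid: Sequence[float] | None = None,
                        seed: int = 0, *, include_noise: bool = True) -> pd.DataFrame:
    """Posterior-predictive biomarker values for one patient.

    For each grid time an independent posterior parameter vector is drawn
    and a predictive value emitted (including the proportional noise term
    unless ``include_noise=False``).  The default grid is monthly with
    uniform +/-5-day jitter up to the patient's PFS.  This interpolates the
    patient's own trajectory; no new patients are invented.
    """
    if patient_id not in draws.patient_ids:
        raise KeyError(f"patient {patient_id!r} not present in draws")
    idx = draws.patient_ids.index(patient_id)
    pfs = float(draws.pfs_days[idx])
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = monthly_grid(pfs, rng)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid > pfs):
        raise ValueError(f"grid time beyond PFS ({pfs:.1f} d) for {patient_id}")

    n_total = draws.n_chains * draws.n_draws
    alpha = draws.patient["alpha"][:, :, idx].ravel()
    beta = draws.patient["beta"][:, :, idx].ravel()
    gamma = draws.patient["gamma"][:, :, idx].ravel()
    tf = draws.patient["t_inflection"][:, :, idx].ravel()
    sig = draws.hyper["sigma_eps"].ravel()

    pick = rng.integers(0, n_total, size=len(grid))
    a, b, g, t0, s = alpha[pick], beta[pick], gamma[pick], tf[pick], sig[pick]
    mean = np.where(grid < t0, a + b * grid, a + b * t0 + g * (grid - t0))
    if include_noise:
        mean = mean + np.abs(mean) * s * rng.standard_normal(len(grid))
    return pd.DataFrame({
        "patient_id": patient_id,
        "biomarker": draws.biomarker,
        "time_days": grid,
        "value": mean,
        "replicate": 0,
    })


def pseudo_trial(draws: PosteriorDraws, seed: int = 0, *,
                 include_noise: bool = True) -> pd.DataFrame:
    """One monthly-schedule pseudo-trial over every patient in ``draws``."""
    rng = np.random.default_rng(seed)
    frames = []
    for pid in draws.patient_ids:
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        frames.append(impute_pseudo_trial(draws, pid, None, sub_seed,
                                          include_noise=include_noise))
    return pd.concat(frames, ignore_index=True)
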