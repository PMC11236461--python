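"""Data-augmented multi-species occupancy model (MSOM).

The incidence matrix of detected species is augmented with twice as many
all-zero pseudo-species rows; a latent community-membership indicator per
slot, patch-level occupancy with an area covariate, and a per-visit
detection probability are estimated by a bespoke MCMC sampler
(full-conditional Gibbs updates for the discrete latents, adaptive
random-walk Metropolis for the continuous parameters).

Model, for augmented slot m and patch p with V visits:

    omega_m ~ Bernoulli(Omega)
    z_pm    ~ Bernoulli(omega_m * psi_pm)
    y_pm    ~ Binomial(V, z_pm * vartheta_m)
    logit psi_pm    = delta0_m + delta1_m * x_p
    logit vartheta_m = lambda0_m

with a joint bivariate-normal prior on the intercept pair
(delta0_m, lambda0_m) and community-level hyperpriors: Beta(1, 1) on the
intercept hyper-means expressed on the probability scale, Normal(0, 1) on
the slope hyper-mean, Uniform(0, 5) on the hyper-SDs, Uniform(-1, 1) on the
intercept correlation, and Beta(a, 1) with small a (a scale-prior
approximation) on Omega.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln, logit

__all__ = [
    "AugmentedIncidence",
    "MsomConfig",
    "MsomParams",
    "PosteriorDraws",
    "PUBLISHED_MCMC",
    "DESK_MCMC",
    "augment",
    "log_likelihood",
    "fit_msom",
    "gelman_rubin",
    "rhat_table",
    "derive_richness",
    "derive_sorensen",
    "simulate_msom_data",
]

_EPS = 1e-300

HYPER_NAMES = (
    "mu_delta0",
    "mu_lambda0",
    "mu_delta1",
    "sd_delta0",
    "sd_lambda0",
    "sd_delta1",
    "rho",
    "Omega",
)


@dataclass(frozen=True)
class AugmentedIncidence:
    """Slot x patch incidence counts: observed species rows, then all-zero rows."""

    Y_aug: np.ndarray  # M x P integer counts in [0, V]
    S_obs_total: int
    V: int

    @property
    def M(self) -> int:
        return self.Y_aug.shape[0]

    @property
    def n_patches(self) -> int:
        return self.Y_aug.shape[1]


def augment(Y_detected: np.ndarray, V: int, factor: int = 2) -> AugmentedIncidence:
    """Append ``factor`` x (number of detected species) all-zero rows.

    ``Y_detected`` is species x patches counts of detection visits for the
    species actually observed. Default factor 2 gives M = 3 * S_obs.
    """
    Y = np.asarray(Y_detected, dtype=np.int64)
    if Y.ndim != 2 or Y.shape[0] < 1:
        raise ValueError("need an incidence matrix with at least one detected species")
    if np.any((Y.sum(axis=1)) == 0):
        raise ValueError("Y_detected must contain only species with >=1 detection")
    if np.any(Y > V) or np.any(Y < 0):
        raise ValueError("incidence counts must lie in [0, V]")
    s_obs = Y.shape[0]
    zeros = np.zeros((factor * s_obs, Y.shape[1]), dtype=np.int64)
    return AugmentedIncidence(
        Y_aug=np.vstack([Y, zeros]), S_obs_total=s_obs, V=int(V)
    )


@dataclass(frozen=True)
class MsomConfig:
    """MCMC settings and prior constants."""

    chains: int = 4
    iterations: int = 50_000
    burn_in: int = 10_000
    thin: int = 20
    covariate: str = "log_std"  # "log_std" | "log" | "raw"
    omega_prior_a: float = 0.001
    sd_prior_upper: float = 5.0
    adapt_interval: int = 50
    target_accept: float = 0.44
    rhat_threshold: float = 1.05

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin

    @property
    def retained_total(self) -> int:
        return self.chains * self.retained_per_chain


PUBLISHED_MCMC = MsomConfig()
DESK_MCMC = MsomConfig(chains=2, iterations=6_000, burn_in=2_000, thin=10)


@dataclass
class MsomParams:
    """One full latent state of the model (used by :func:`log_likelihood`)."""

    omega: np.ndarray  # M
    z: np.ndarray  # M x P
    delta0: np.ndarray  # M
    delta1: np.ndarray  # M
    lambda0: np.ndarray  # M
    Omega: float


def _covariate(areas: np.ndarray, mode: str) -> np.ndarray:
    areas = np.asarray(areas, dtype=float)
    if mode == "raw":
        return areas
    x = np.log(areas)
    if mode == "log":
        return x
    if mode == "log_std":
        sd = x.std(ddof=0)
        return (x - x.mean()) / (sd if sd > 0 else 1.0)
    raise ValueError(f"unknown covariate mode {mode!r}")


def log_likelihood(
    params: MsomParams, data: AugmentedIncidence, areas: np.ndarray,
    covariate: str = "log_std",
) -> float:
    """Joint log-density of data and discrete latents given the parameters.

    Returns -inf for impossible states (a detection at a slot/patch whose
    occupancy indicator is 0, or a detection for a slot with omega = 0).
    """
    x = _covariate(areas, covariate)
    y = data.Y_aug
    V = data.V
    omega = np.asarray(params.omega, dtype=float)
    z = np.asarray(params.z, dtype=float)
    if np.any((y > 0) & (z == 0)):
        return -np.inf
    psi = expit(params.delta0[:, None] + params.delta1[:, None] * x[None, :])
    theta = expit(params.lambda0)[:, None]

    ll = np.sum(
        omega * np.log(max(params.Omega, _EPS))
        + (1 - omega) * np.log(max(1 - params.Omega, _EPS))
    )
    occ_p = omega[:, None] * psi
    ll += np.sum(z * np.log(np.maximum(occ_p, _EPS)))
    ll += np.sum((1 - z) * np.log(np.maximum(1 - occ_p, _EPS)))
    if not np.isfinite(ll):
        return -np.inf
    # detection: only z = 1 cells involve theta; z = 0 forces y = 0 (checked)
    logcomb = gammaln(V + 1) - gammaln(y + 1) - gammaln(V - y + 1)
    det = logcomb + y * np.log(np.maximum(theta, _EPS)) + (V - y) * np.log(
        np.maximum(1 - theta, _EPS)
    )
    ll += float(np.sum(z * det))
    return float(ll)


@dataclass
class PosteriorDraws:
    """Retained draws, scalar traces, and bookkeeping from one MSOM fit."""

    z: np.ndarray  # n_draws x M x P (uint8)
    traces: dict  # name -> chains x retained_per_chain
    config: MsomConfig
    S_obs_total: int
    accept_rates: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.z.shape[0]

    def rhat(self) -> dict:
        return {name: gelman_rubin(tr) for name, tr in self.traces.items()}

    @property
    def converged(self) -> bool:
        return all(r < self.config.rhat_threshold for r in self.rhat().values())


def _bvn_logpdf(a, b, mu_a, mu_b, sd_a, sd_b, rho):
    """Element-wise bivariate normal log-density."""
    za = (a - mu_a) / sd_a
    zb = (b - mu_b) / sd_b
    om = 1.0 - rho**2
    return (
        -np.log(2 * np.pi * sd_a * sd_b * np.sqrt(om))
        - (za**2 - 2 * rho * za * zb + zb**2) / (2 * om)
    )


def _log1m_exp_pow(theta: np.ndarray, V: int) -> np.ndarray:
    """log((1 - theta)^V), stable for theta near 1."""
    return V * np.log1p(-np.clip(theta, None, 1 - 1e-15))


class _Sampler:
    """One-chain Gibbs/Metropolis sampler, vectorized over augmented slots."""

    def __init__(self, data: AugmentedIncidence, x: np.ndarray,
                 config: MsomConfig, rng: np.random.Generator):
        self.y = data.Y_aug
        self.V = data.V
        self.M, self.P = self.y.shape
        self.x = x
        self.cfg = config
        self.rng = rng
        self.detected = self.y.sum(axis=1) > 0  # slots with any detection
        self.y1 = self.y.astype(float)
        self.logcomb = (
            gammaln(self.V + 1) - gammaln(self.y + 1) - gammaln(self.V - self.y + 1)
        )
        self._init_state()
        # adaptive proposal scales: vectors per slot, scalars per hyper
        self.step_d0 = np.full(self.M, 0.5)
        self.step_d1 = np.full(self.M, 0.5)
        self.step_l0 = np.full(self.M, 0.5)
        self.step_hyper = {n: 0.3 for n in HYPER_NAMES if n != "Omega"}
        self._acc = {k: np.zeros(self.M) for k in ("d0", "d1", "l0")}
        self._acc_h = {n: 0.0 for n in self.step_hyper}
        self._batch = 0

    def _init_state(self):
        rng = self.rng
        self.Omega = rng.uniform(0.3, 0.9)
        self.mu_delta0 = logit(rng.uniform(0.3, 0.7))
        self.mu_lambda0 = logit(rng.uniform(0.3, 0.7))
        self.mu_delta1 = rng.normal(0, 0.25)
        self.sd_delta0 = rng.uniform(0.5, 1.5)
        self.sd_lambda0 = rng.uniform(0.5, 1.5)
        self.sd_delta1 = rng.uniform(0.5, 1.5)
        self.rho = rng.uniform(-0.3, 0.3)
        self.delta0 = rng.normal(self.mu_delta0, self.sd_delta0, self.M)
        self.delta1 = rng.normal(self.mu_delta1, self.sd_delta1, self.M)
        self.lambda0 = rng.normal(self.mu_lambda0, self.sd_lambda0, self.M)
        self.omega = np.where(
            self.detected, 1, (rng.random(self.M) < self.Omega).astype(int)
        )
        self.z = np.where(
            self.y > 0,
            1,
            (rng.random((self.M, self.P)) < 0.5).astype(int)
            * self.omega[:, None],
        )

    # -- Gibbs updates for discrete latents -------------------------------

    def _psi(self):
        return expit(self.delta0[:, None] + self.delta1[:, None] * self.x[None, :])

    def _update_omega_z(self):
        psi = self._psi()
        theta = expit(self.lambda0)
        logq = _log1m_exp_pow(theta, self.V)[:, None]  # log (1-theta)^V, per slot
        # P(all-zero detection history at patch | occupied) = (1-theta)^V
        log_zero_given_pres = np.logaddexp(
            np.log(np.maximum(psi, _EPS)) + logq,
            np.log(np.maximum(1 - psi, _EPS)),
        )  # marginal over z of a zero history
        und = ~self.detected
        if np.any(und):
            log_num = np.log(max(self.Omega, _EPS)) + log_zero_given_pres[und].sum(
                axis=1
            )
            log_den = np.logaddexp(log_num, np.log(max(1 - self.Omega, _EPS)))
            p1 = np.exp(log_num - log_den)
            self.omega[und] = (self.rng.random(und.sum()) < p1).astype(int)
        self.omega[self.detected] = 1

        # z | omega, params: detections force z = 1
        with np.errstate(divide="ignore"):
            num = psi * np.exp(logq)
            pz = num / (num + (1 - psi))
        draw = (self.rng.random((self.M, self.P)) < pz).astype(int)
        self.z = np.where(self.y > 0, 1, draw * self.omega[:, None])

    def _update_Omega(self):
        a = self.cfg.omega_prior_a + self.omega.sum()
        b = 1.0 + self.M - self.omega.sum()
        self.Omega = self.rng.beta(a, b)

    # -- Metropolis updates for continuous parameters ---------------------

    def _occ_loglik(self, delta0, delta1):
        """Occupancy log-likelihood per slot (only omega = 1 slots count)."""
        psi = expit(delta0[:, None] + delta1[:, None] * self.x[None, :])
        ll = self.z * np.log(np.maximum(psi, _EPS)) + (1 - self.z) * np.log(
            np.maximum(1 - psi, _EPS)
        )
        return np.where(self.omega == 1, ll.sum(axis=1), 0.0)

    def _det_loglik(self, lambda0):
        """Detection log-likelihood per slot over z = 1 cells."""
        theta = expit(lambda0)
        s1 = (self.z * self.y1).sum(axis=1)
        s0 = (self.z * (self.V - self.y1)).sum(axis=1)
        return s1 * np.log(np.maximum(theta, _EPS)) + s0 * np.log(
            np.maximum(1 - theta, _EPS)
        )

    def _intercept_prior(self, delta0, lambda0):
        return _bvn_logpdf(
            delta0, lambda0, self.mu_delta0, self.mu_lambda0,
            self.sd_delta0, self.sd_lambda0, self.rho,
        )

    def _slope_prior(self, delta1):
        return -0.5 * ((delta1 - self.mu_delta1) / self.sd_delta1) ** 2 - np.log(
            self.sd_delta1
        )

    def _update_species_params(self):
        rng = self.rng
        active = self.omega == 1
        # slots outside the community carry no likelihood: refresh from prior
        idle = ~active
        if np.any(idle):
            n = int(idle.sum())
            e0 = rng.normal(size=n)
            e1 = rng.normal(size=n)
            d0 = self.mu_delta0 + self.sd_delta0 * e0
            l0 = (
                self.mu_lambda0
                + self.sd_lambda0 * (self.rho * e0 + np.sqrt(1 - self.rho**2) * e1)
            )
            self.delta0[idle] = d0
            self.lambda0[idle] = l0
            self.delta1[idle] = rng.normal(self.mu_delta1, self.sd_delta1, n)

        # delta0
        prop = self.delta0 + self.step_d0 * rng.normal(size=self.M)
        cur = self._occ_loglik(self.delta0, self.delta1) + self._intercept_prior(
            self.delta0, self.lambda0
        )
        new = self._occ_loglik(prop, self.delta1) + self._intercept_prior(
            prop, self.lambda0
        )
        acc = (np.log(rng.random(self.M)) < new - cur) & active
        self.delta0 = np.where(acc, prop, self.delta0)
        self._acc["d0"] += acc

        # delta1
        prop = self.delta1 + self.step_d1 * rng.normal(size=self.M)
        cur = self._occ_loglik(self.delta0, self.delta1) + self._slope_prior(self.delta1)
        new = self._occ_loglik(self.delta0, prop) + self._slope_prior(prop)
        acc = (np.log(rng.random(self.M)) < new - cur) & active
        self.delta1 = np.where(acc, prop, self.delta1)
        self._acc["d1"] += acc

        # lambda0
        prop = self.lambda0 + self.step_l0 * rng.normal(size=self.M)
        cur = self._det_loglik(self.lambda0) + self._intercept_prior(
            self.delta0, self.lambda0
        )
        new = self._det_loglik(prop) + self._intercept_prior(self.delta0, prop)
        acc = (np.log(rng.random(self.M)) < new - cur) & active
        self.lambda0 = np.where(acc, prop, self.lambda0)
        self._acc["l0"] += acc

    def _hyper_logpost(self, name, value):
        h = {n: getattr(self, n) for n in self.step_hyper}
        h[name] = value
        if not (0 < h["sd_delta0"] < self.cfg.sd_prior_upper):
            return -np.inf
        if not (0 < h["sd_lambda0"] < self.cfg.sd_prior_upper):
            return -np.inf
        if not (0 < h["sd_delta1"] < self.cfg.sd_prior_upper):
            return -np.inf
        if not (-1 < h["rho"] < 1):
            return -np.inf
        lp = float(
            np.sum(
                _bvn_logpdf(
                    self.delta0, self.lambda0, h["mu_delta0"], h["mu_lambda0"],
                    h["sd_delta0"], h["sd_lambda0"], h["rho"],
                )
            )
        )
        lp += float(
            np.sum(
                -0.5 * ((self.delta1 - h["mu_delta1"]) / h["sd_delta1"]) ** 2
                - np.log(h["sd_delta1"])
            )
        )
        # Beta(1,1) prior on expit(mu) == standard-logistic prior on mu
        for mu in (h["mu_delta0"], h["mu_lambda0"]):
            lp += mu - 2 * np.log1p(np.exp(mu)) if mu < 30 else -mu
        lp += -0.5 * h["mu_delta1"] ** 2
        return lp

    def _update_hypers(self):
        rng = self.rng
        for name in self.step_hyper:
            cur_val = getattr(self, name)
            prop = cur_val + self.step_hyper[name] * rng.normal()
            cur = self._hyper_logpost(name, cur_val)
            new = self._hyper_logpost(name, prop)
            if np.log(rng.random()) < new - cur:
                setattr(self, name, prop)
                self._acc_h[name] += 1.0

    def _adapt(self):
        """Robbins-Monro-style step-size adaptation toward the target rate."""
        self._batch += 1
        gamma = min(0.25, 1.0 / np.sqrt(self._batch))
        k = self.cfg.adapt_interval
        for key, step in (("d0", self.step_d0), ("d1", self.step_d1),
                          ("l0", self.step_l0)):
            rate = self._acc[key] / k
            step *= np.exp(gamma * (rate - self.cfg.target_accept))
            self._acc[key][:] = 0.0
        for name in self.step_hyper:
            rate = self._acc_h[name] / k
            self.step_hyper[name] *= np.exp(gamma * (rate - self.cfg.target_accept))
            self._acc_h[name] = 0.0

    def run(self):
        cfg = self.cfg
        n_keep = cfg.retained_per_chain
        z_draws = np.empty((n_keep, self.M, self.P), dtype=np.uint8)
        traces = {n: np.empty(n_keep) for n in HYPER_NAMES}
        kept = 0
        for it in range(cfg.iterations):
            self._update_omega_z()
            self._update_Omega()
            self._update_species_params()
            self._update_hypers()
            if it < cfg.burn_in:
                if (it + 1) % cfg.adapt_interval == 0:
                    self._adapt()
                continue
            if (it - cfg.burn_in) % cfg.thin == cfg.thin - 1 and kept < n_keep:
                z_draws[kept] = self.z.astype(np.uint8)
                for n in HYPER_NAMES:
                    traces[n][kept] = getattr(self, n)
                kept += 1
        return z_draws[:kept], {n: t[:kept] for n, t in traces.items()}


def fit_msom(
    data: AugmentedIncidence,
    areas: np.ndarray,
    config: MsomConfig = PUBLISHED_MCMC,
    rng: np.random.Generator | int | None = None,
) -> PosteriorDraws:
    """Fit the MSOM by MCMC and return retained draws.

    Chains run sequentially from independent substreams of ``rng``. Retained
    draw count is chains x (iterations - burn_in) / thin.
    """
    root = np.random.default_rng(rng)
    x = _covariate(areas, config.covariate)
    z_all, trace_all = [], []
    for _ in range(config.chains):
        chain_rng = np.random.default_rng(root.integers(2**63))
        sampler = _Sampler(data, x, config, chain_rng)
        z, traces = sampler.run()
        z_all.append(z)
        trace_all.append(traces)
    traces = {
        n: np.stack([t[n] for t in trace_all]) for n in HYPER_NAMES
    }
    return PosteriorDraws(
        z=np.concatenate(z_all),
        traces=traces,
        config=config,
        S_obs_total=data.S_obs_total,
    )


def gelman_rubin(traces: np.ndarray) -> float:
    """Potential scale reduction factor over a chains x draws array."""
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 2:
        raise ValueError("need >= 2 chains")
    m, n = traces.shape
    if n < 2:
        raise ValueError("need >= 2 draws per chain")
    chain_means = traces.mean(axis=1)
    W = traces.var(axis=1, ddof=1).mean()
    B = n * chain_means.var(ddof=1)
    var_hat = (n - 1) / n * W + B / n
    if W == 0:
        return 1.0 if B == 0 else np.inf
    return float(np.sqrt(var_hat / W))


def rhat_table(draws: PosteriorDraws) -> dict:
    """R-hat per monitored hyperparameter."""
    return draws.rhat()


def derive_richness(draws: PosteriorDraws) -> np.ndarray:
    """Posterior-mean per-patch richness, S_p = sum_m z_pm per draw."""
    return draws.z.sum(axis=1).mean(axis=0)


def derive_sorensen(draws: PosteriorDraws) -> np.ndarray:
    """Posterior-mean pairwise Sorensen similarity matrix.

    Per draw, Sor(a, b) = 2 |z_a & z_b| / (|z_a| + |z_b|); draws where both
    patches are empty are excluded from the mean for that pair. Pairs empty
    in every draw come back NaN. Diagonal is the posterior mean of 1 over
    draws where the patch is nonempty.
    """
    n_draws, _, P = draws.z.shape
    total = np.zeros((P, P))
    count = np.zeros((P, P))
    for d in range(n_draws):
        z = draws.z[d].astype(np.int64)
        shared = z.T @ z
        rich = z.sum(axis=0)
        denom = rich[:, None] + rich[None, :]
        valid = denom > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.where(valid, 2.0 * shared / np.maximum(denom, 1), 0.0)
        total += np.where(valid, sim, 0.0)
        count += valid
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return out


def simulate_msom_data(
    n_patches: int,
    n_species: int,
    V: int,
    areas: np.ndarray | None = None,
    mu_psi: float = 0.5,
    mu_theta: float = 0.5,
    sd_delta0: float = 1.0,
    sd_lambda0: float = 1.0,
    mu_delta1: float = 0.5,
    sd_delta1: float = 0.5,
    rho: float = 0.0,
    covariate: str = "log_std",
    rng: np.random.Generator | int | None = None,
):
    """Simulate incidence data from the model's own generative process.

    All ``n_species`` species are community members (omega = 1). Returns
    ``(Y, areas, truth)`` where Y is species x patches incidence counts
    (including possibly undetected species) and ``truth`` holds the
    hyperparameters and the realized occupancy matrix.
    """
    rng = np.random.default_rng(rng)
    if areas is None:
        areas = np.exp(rng.uniform(np.log(25), np.log(20_000), n_patches))
    x = _covariate(areas, covariate)
    e0 = rng.normal(size=n_species)
    e1 = rng.normal(size=n_species)
    delta0 = logit(mu_psi) + sd_delta0 * e0
    lambda0 = logit(mu_theta) + sd_lambda0 * (rho * e0 + np.sqrt(1 - rho**2) * e1)
    delta1 = rng.normal(mu_delta1, sd_delta1, n_species)
    psi = expit(delta0[:, None] + delta1[:, None] * x[None, :])
    z = (rng.random((n_species, n_patches)) < psi).astype(int)
    theta = expit(lambda0)
    Y = rng.binomial(V, z * theta[:, None])
    truth = {
        "mu_delta0": float(logit(mu_psi)),
        "mu_lambda0": float(logit(mu_theta)),
        "mu_delta1": float(mu_delta1),
        "delta0": delta0,
        "delta1": delta1,
        "lambda0": lambda0,
        "z": z,
        "areas": np.asarray(areas, dtype=float),
    }
    return Y, np.asarray(areas, dtype=float), truth
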