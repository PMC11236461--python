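"""Factorial simulation experiment and estimator-performance criteria.

Crosses detection hyperparameters (mu, sigma), area-response strength
(alpha_max), and visit count (V); simulates replicate communities and
replicate sampling runs per community; estimates the six community
parameters by observed counts, asymptotic (Chao) estimators, and optionally
the MSOM; and aggregates bias, accuracy, and precision per parameter x
method x scenario.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import chao, msom, sampling, trends
from .community import CommunityConfig, Community, simulate_community

__all__ = [
    "ExperimentConfig",
    "FULL_PROFILE",
    "DESK_PROFILE",
    "bias",
    "accuracy",
    "precision",
    "enumerate_combinations",
    "scheduled_counts",
    "sample_community",
    "estimate_dataset",
    "evaluate_landscape",
    "run_experiment",
]

logger = logging.getLogger(__name__)

PARAMETERS = ("richness", "c_value", "z_value", "sorensen", "gamma0", "gamma1")
METHODS = ("observed", "chao", "msom")


@dataclass(frozen=True)
class ExperimentConfig:
    """Factorial design of the simulation experiment."""

    mu_grid: tuple = (0.005, 0.05, 0.2)
    sigma_grid: tuple = (0.25, 1.0, 3.0)
    alpha_max_grid: tuple = (4.0, 8.0, 12.0)
    v_grid: tuple = (3, 6, 12)
    communities_per_combo: int = 35
    sampling_reps_per_community: int = 10
    master_seed: int = 0
    methods: tuple = ("observed", "chao")
    community: CommunityConfig = field(default_factory=CommunityConfig)
    msom_config: msom.MsomConfig = field(default_factory=lambda: msom.DESK_MCMC)
    perfect_detection: bool = False  # control scenario: theta = 1, pi = 1

    @property
    def n_combinations(self) -> int:
        return (
            len(self.mu_grid)
            * len(self.sigma_grid)
            * len(self.alpha_max_grid)
            * len(self.v_grid)
        )

    @property
    def n_communities(self) -> int:
        return self.n_combinations * self.communities_per_combo

    @property
    def n_datasets(self) -> int:
        return self.n_communities * self.sampling_reps_per_community


FULL_PROFILE = ExperimentConfig()
DESK_PROFILE = ExperimentConfig(
    mu_grid=(0.2,),
    sigma_grid=(1.0,),
    alpha_max_grid=(8.0,),
    v_grid=(6,),
    communities_per_combo=2,
    sampling_reps_per_community=3,
)


# -- performance criteria --------------------------------------------------


def bias(estimates, truth, scale_by_truth: bool = False) -> float:
    """Mean signed error; optionally divided by the (scalar) true value."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size < 1:
        raise ValueError("need at least one estimate")
    err = np.nanmean(estimates - truth)
    if scale_by_truth:
        if truth == 0:
            return float("nan")
        err /= truth
    return float(err)


def accuracy(estimates, truth, scale_by_truth: bool = False) -> float:
    """Negative mean absolute error; optionally divided by the true value."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size < 1:
        raise ValueError("need at least one estimate")
    err = -np.nanmean(np.abs(estimates - truth))
    if scale_by_truth:
        if truth == 0:
            return float("nan")
        err /= truth
    return float(err)


def precision(estimates) -> float:
    """Negative coefficient of variation (sample SD / |mean|) of the estimates."""
    estimates = np.asarray(estimates, dtype=float)
    estimates = estimates[np.isfinite(estimates)]
    if estimates.size < 2:
        raise ValueError("need at least two estimates")
    mean = estimates.mean()
    if mean == 0:
        return float("nan")
    return float(-estimates.std(ddof=1) / abs(mean))


# -- experiment plumbing ---------------------------------------------------


def enumerate_combinations(config: ExperimentConfig):
    """All (mu, sigma, alpha_max, V) cells of the factorial design."""
    return list(
        itertools.product(
            config.mu_grid, config.sigma_grid, config.alpha_max_grid, config.v_grid
        )
    )


def scheduled_counts(config: ExperimentConfig) -> dict:
    """Design arithmetic: combinations, communities, and datasets scheduled."""
    combos = enumerate_combinations(config)
    n_comm = len(combos) * config.communities_per_combo
    return {
        "combinations": len(combos),
        "communities": n_comm,
        "datasets": n_comm * config.sampling_reps_per_community,
    }


def sample_community(
    community: Community,
    mu: float,
    sigma: float,
    V: int,
    rng: np.random.Generator | int | None = None,
    perfect_detection: bool = False,
) -> tuple[sampling.DetectionScenario, sampling.SamplingDesign, sampling.SurveyData]:
    """One full sampling run of a community under a detection scenario."""
    rng = np.random.default_rng(rng)
    n_species = community.metacommunity.n_species
    if perfect_detection:
        theta = np.ones(n_species)
        design = sampling.SamplingDesign(
            transects=np.ones(community.landscape.n_patches, dtype=np.int64),
            pi_p=np.ones(community.landscape.n_patches),
        )
    else:
        theta = sampling.draw_detection_probs(n_species, mu, sigma, rng)
        design = sampling.sampling_design(community.landscape.patch_areas)
    scenario = sampling.DetectionScenario(
        mu=mu, sigma=sigma, theta=theta,
        scenario_id=sampling.scenario_label(mu, sigma),
    )
    n_avail = sampling.available_counts(community.abundance, design.pi_p)
    data = sampling.survey(n_avail, theta, V, rng)
    return scenario, design, data


def true_parameters(community: Community) -> dict:
    """The six community parameters from the true abundance matrix."""
    richness = trends.richness_from_matrix(community.abundance)
    sim = trends.sorensen_pairwise(community.occurrence)
    return trends.community_parameters(
        richness, sim, community.landscape.patch_areas
    )


def estimate_dataset(
    data: sampling.SurveyData,
    areas: np.ndarray,
    methods=("observed", "chao"),
    msom_config: msom.MsomConfig = msom.DESK_MCMC,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Estimate all six parameters from one sampled dataset, per method.

    Returns {method: parameter dict}; a method whose trend fits fail maps to
    an ``"error"`` entry instead.
    """
    out = {}
    pooled = data.pooled
    for method in methods:
        try:
            if method == "observed":
                richness = sampling.observed_richness(data)
                sim = trends.sorensen_pairwise(pooled)
            elif method == "chao":
                richness = chao.batch_chao1(pooled)
                sim = chao.chao_sorensen_matrix(pooled)
            elif method == "msom":
                detected = pooled.sum(axis=0) > 0
                Y = data.Y[:, detected].T  # species x patches incidence
                aug = msom.augment(Y, data.V)
                draws = msom.fit_msom(aug, areas, msom_config, rng)
                richness = msom.derive_richness(draws)
                sim = msom.derive_sorensen(draws)
            else:
                raise ValueError(f"unknown method {method!r}")
            out[method] = trends.community_parameters(richness, sim, areas)
        except (trends.FitError, ValueError) as exc:
            logger.warning("%s estimation failed: %s", method, exc)
            out[method] = {"error": str(exc)}
    return out


def _upper_pairs(matrix: np.ndarray) -> np.ndarray:
    i, j = np.triu_indices(matrix.shape[0], k=1)
    return matrix[i, j]


def evaluate_landscape(truth: dict, estimates: list[dict]) -> list[dict]:
    """Bias/accuracy/precision per parameter x method over one landscape's
    sampling replicates.

    Vector parameters (per-patch richness, pairwise similarity) are scored
    per element across replicates and then averaged over elements; richness
    criteria are scaled by the true richness.
    """
    records = []
    methods = sorted({m for est in estimates for m in est})
    for method in methods:
        reps = [est[method] for est in estimates if "error" not in est.get(method, {"error": 1})]
        n_fail = sum(1 for est in estimates if "error" in est.get(method, {"error": 1}))
        if not reps:
            continue
        # scalar trend coefficients
        for par in ("c_value", "z_value", "gamma0", "gamma1"):
            vals = np.array([r[par] for r in reps], dtype=float)
            rec = {
                "parameter": par,
                "method": method,
                "bias": bias(vals, truth[par]),
                "accuracy": accuracy(vals, truth[par]),
                "precision": precision(vals) if vals.size >= 2 else np.nan,
                "n_replicates": len(reps),
                "n_failures": n_fail,
            }
            records.append(rec)
        # per-patch richness, scaled by true richness
        rich = np.stack([r["richness"] for r in reps])  # reps x patches
        tr = truth["richness"]
        b = np.nanmean([bias(rich[:, p], tr[p], True) for p in range(tr.size)])
        a = np.nanmean([accuracy(rich[:, p], tr[p], True) for p in range(tr.size)])
        if rich.shape[0] >= 2:
            with np.errstate(invalid="ignore"):
                pr = np.nanmean(
                    [_safe_precision(rich[:, p]) for p in range(tr.size)]
                )
        else:
            pr = np.nan
        records.append(
            {
                "parameter": "richness", "method": method, "bias": float(b),
                "accuracy": float(a), "precision": float(pr),
                "n_replicates": len(reps), "n_failures": n_fail,
            }
        )
        # pairwise similarity
        sims = np.stack([_upper_pairs(r["sorensen"]) for r in reps])
        tsim = _upper_pairs(truth["sorensen"])
        ok = np.isfinite(tsim)
        b = np.nanmean([bias(sims[:, k], tsim[k]) for k in np.where(ok)[0]])
        a = np.nanmean([accuracy(sims[:, k], tsim[k]) for k in np.where(ok)[0]])
        if sims.shape[0] >= 2:
            pr = np.nanmean([_safe_precision(sims[:, k]) for k in np.where(ok)[0]])
        else:
            pr = np.nan
        records.append(
            {
                "parameter": "sorensen", "method": method, "bias": float(b),
                "accuracy": float(a), "precision": float(pr),
                "n_replicates": len(reps), "n_failures": n_fail,
            }
        )
    return records


def _safe_precision(vals) -> float:
    try:
        return precision(vals)
    except ValueError:
        return float("nan")


def run_experiment(config: ExperimentConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the factorial experiment.

    Returns ``(performance, raw)``: per-scenario performance criteria
    (averaged over landscapes) and the per-landscape raw criteria table.
    Fully deterministic given ``config.master_seed`` (hierarchical seeding:
    master -> per-landscape -> per-sampling-replicate).
    """
    master = np.random.SeedSequence(config.master_seed)
    combos = enumerate_combinations(config)
    raw_rows = []
    t0 = time.time()
    for ci, (mu, sigma, alpha_max, V) in enumerate(combos):
        combo_seed = master.spawn(1)[0]
        scenario_id = sampling.scenario_label(mu, sigma)
        for li in range(config.communities_per_combo):
            land_seed, samp_seed = combo_seed.spawn(2)
            comm_cfg = replace(config.community, alpha_max=alpha_max)
            community = simulate_community(
                comm_cfg, np.random.default_rng(land_seed)
            )
            try:
                truth = true_parameters(community)
            except trends.FitError as exc:
                logger.warning("true-parameter fit failed, skipping landscape: %s", exc)
                continue
            estimates = []
            for ri in range(config.sampling_reps_per_community):
                rep_seed = samp_seed.spawn(1)[0]
                rng = np.random.default_rng(rep_seed)
                _, _, data = sample_community(
                    community, mu, sigma, V, rng,
                    perfect_detection=config.perfect_detection,
                )
                estimates.append(
                    estimate_dataset(
                        data, community.landscape.patch_areas,
                        methods=config.methods,
                        msom_config=config.msom_config, rng=rng,
                    )
                )
            for rec in evaluate_landscape(truth, estimates):
                rec.update(
                    mu=mu, sigma=sigma, alpha_max=alpha_max, V=V,
                    scenario=scenario_id, landscape=li, combination=ci,
                )
                raw_rows.append(rec)
        logger.info(
            "combination %d/%d done (%.1fs elapsed)",
            ci + 1, len(combos), time.time() - t0,
        )
    raw = pd.DataFrame(raw_rows)
    if raw.empty:
        return raw, raw
    keys = ["mu", "sigma", "alpha_max", "V", "scenario", "parameter", "method"]
    performance = (
        raw.groupby(keys, dropna=False)
        .agg(
            bias=("bias", "mean"),
            accuracy=("accuracy", "mean"),
            precision=("precision", "mean"),
            n_replicates=("n_replicates", "sum"),
            n_failures=("n_failures", "sum"),
            n_landscapes=("landscape", "count"),
        )
        .reset_index()
    )
    return performance, raw
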