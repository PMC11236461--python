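"""Imperfect-detection sampling of simulated communities.

Per-species detection probabilities are drawn on the logit scale from a
community-level hyperparameter distribution; each patch is surveyed along a
set of fixed-footprint transects covering a proportion of its area, and
repeat visits record binomially thinned counts of the available individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "TRANSECT_AREA_HA",
    "DetectionScenario",
    "SamplingDesign",
    "SurveyData",
    "SCENARIO_GRID",
    "scenario_from_id",
    "draw_detection_probs",
    "transect_schedule",
    "sampling_design",
    "available_counts",
    "survey",
    "observed_richness",
]

#: Area surveyed by a single 500 m transect (Ha).
TRANSECT_AREA_HA = 5.93

#: Scenario grid: id -> (mean detection probability mu, logit-scale SD sigma).
SCENARIO_GRID: dict[str, tuple[float, float]] = {
    "S1": (0.005, 0.25),
    "S2": (0.005, 1.0),
    "S3": (0.005, 3.0),
    "S4": (0.05, 0.25),
    "S5": (0.05, 1.0),
    "S6": (0.05, 3.0),
    "S7": (0.2, 0.25),
    "S8": (0.2, 1.0),
    "S9": (0.2, 3.0),
}


@dataclass(frozen=True)
class DetectionScenario:
    """Detection hyperparameters and the realized per-species probabilities."""

    mu: float
    sigma: float
    theta: np.ndarray
    scenario_id: str | None = None


@dataclass(frozen=True)
class SamplingDesign:
    """Transect counts and sampled proportions per patch."""

    transects: np.ndarray  # integer count per patch
    pi_p: np.ndarray  # sampled proportion of each patch, in (0, 1]
    transect_area: float = TRANSECT_AREA_HA


@dataclass(frozen=True)
class SurveyData:
    """Counts from V repeat visits and derived summaries.

    X is patches x species x visits; ``pooled`` sums over visits (individuals
    may be recounted across visits); ``Y`` counts visits with at least one
    detection.
    """

    X: np.ndarray
    V: int

    @property
    def pooled(self) -> np.ndarray:
        return self.X.sum(axis=2)

    @property
    def Y(self) -> np.ndarray:
        return (self.X > 0).sum(axis=2)


def scenario_label(mu: float, sigma: float) -> str | None:
    for sid, (m, s) in SCENARIO_GRID.items():
        if np.isclose(m, mu) and np.isclose(s, sigma):
            return sid
    return None


def scenario_from_id(scenario_id: str) -> tuple[float, float]:
    return SCENARIO_GRID[scenario_id]


def draw_detection_probs(
    n_species: int,
    mu: float,
    sigma: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw per-species detection probabilities, logit(theta) ~ N(logit(mu), sigma)."""
    if not 0 < mu < 1:
        raise ValueError("mu must be in (0, 1)")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = np.random.default_rng(rng)
    return expit(rng.normal(logit(mu), sigma, size=n_species))


def transect_schedule(
    area: float,
    scale: float = 1.0,
    exponent: float = 0.75,
    transect_area: float = TRANSECT_AREA_HA,
    lookup: dict[float, int] | None = None,
) -> tuple[int, float]:
    """Number of transects and sampled proportion for one patch.

    Default schedule: ``max(1, round(scale * (area/25)**exponent))`` transects,
    so sampled area grows with patch size while the sampled *proportion*
    pi_p = transects * transect_area / area shrinks (exponent < 1). A lookup
    table mapping area -> transect count overrides the power law exactly.
    """
    if area <= 0:
        raise ValueError("area must be positive")
    if lookup is not None and area in lookup:
        transects = int(lookup[area])
    else:
        transects = max(1, int(round(scale * (area / 25.0) ** exponent)))
    pi_p = min(1.0, transects * transect_area / area)
    return transects, pi_p


def sampling_design(
    patch_areas: np.ndarray,
    scale: float = 1.0,
    exponent: float = 0.75,
    transect_area: float = TRANSECT_AREA_HA,
    lookup: dict[float, int] | None = None,
) -> SamplingDesign:
    """Vector form of :func:`transect_schedule` over a landscape."""
    pairs = [
        transect_schedule(a, scale, exponent, transect_area, lookup)
        for a in np.asarray(patch_areas, dtype=float)
    ]
    transects = np.array([t for t, _ in pairs], dtype=np.int64)
    pi_p = np.array([p for _, p in pairs], dtype=float)
    return SamplingDesign(transects=transects, pi_p=pi_p, transect_area=transect_area)


def available_counts(N: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Individuals available for sampling: n[p,i] = round(N[p,i] * pi_p).

    Rounding is half-up (away from zero), so species whose in-transect
    expectation falls below 0.5 become unavailable entirely — the sampling
    design's extra source of detection failure.
    """
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0) or np.any(pi > 1):
        raise ValueError("sampled proportions must lie in (0, 1]")
    scaled = np.asarray(N, dtype=float) * pi[:, None]
    return np.floor(scaled + 0.5).astype(np.int64)


def survey(
    n: np.ndarray,
    theta: np.ndarray,
    V: int,
    rng: np.random.Generator | None = None,
) -> SurveyData:
    """Simulate V repeat visits: X[p,i,v] ~ Binomial(n[p,i], theta_i)."""
    if V < 1:
        raise ValueError("V must be >= 1")
    rng = np.random.default_rng(rng)
    n = np.asarray(n, dtype=np.int64)
    theta = np.asarray(theta, dtype=float)
    X = rng.binomial(n[:, :, None], theta[None, :, None], size=n.shape + (V,))
    return SurveyData(X=X, V=V)


def observed_richness(data: SurveyData) -> np.ndarray:
    """Per-patch count of species detected on at least one visit."""
    return (data.pooled > 0).sum(axis=1)
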