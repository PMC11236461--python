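"""Community parameters: richness, SAR coefficients, pairwise Sorensen
similarity, and logit-link models of area effects on similarity.

All six parameters can be computed from any occurrence or abundance source —
true abundances, observed counts, or estimator output — so true values and
estimates flow through identical code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import DomainWarning, PerfectSeparationError

__all__ = [
    "SarFit",
    "BetaGlmFit",
    "FitError",
    "richness_from_matrix",
    "sorensen_pairwise",
    "fit_sar",
    "fit_beta_glm",
    "pairwise_area_predictor",
    "community_parameters",
]


class FitError(RuntimeError):
    """Raised when a trend model cannot be fitted (too few points, separation)."""


@dataclass(frozen=True)
class SarFit:
    """ln-ln (power model) species-area relationship coefficients."""

    c_value: float
    z_value: float
    n_patches_used: int


@dataclass(frozen=True)
class BetaGlmFit:
    """Logit-link GLM of pairwise similarity on ln(|area difference| + 1)."""

    gamma0: float
    gamma1: float
    n_pairs: int


def richness_from_matrix(N: np.ndarray) -> np.ndarray:
    """Species per patch: count of positive entries in each row."""
    return (np.asarray(N) > 0).sum(axis=1)


def sorensen_pairwise(occurrence: np.ndarray) -> np.ndarray:
    """Pairwise Sorensen similarity 2|A&B| / (|A|+|B|) over all patch pairs.

    ``occurrence`` is a patches x species boolean (or count) matrix. The
    diagonal is 1 for nonempty patches; entries where both patches are empty
    are NaN.
    """
    occ = (np.asarray(occurrence) > 0).astype(np.int64)
    shared = occ @ occ.T
    rich = occ.sum(axis=1)
    denom = rich[:, None] + rich[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, 2.0 * shared / denom, np.nan)
    return sim


def fit_sar(richness: np.ndarray, areas: np.ndarray) -> SarFit:
    """OLS fit of ln(S) on ln(Area), dropping zero-richness patches."""
    richness = np.asarray(richness, dtype=float)
    areas = np.asarray(areas, dtype=float)
    mask = richness > 0
    n_used = int(mask.sum())
    if n_used < 3:
        raise FitError(f"only {n_used} patches with positive richness")
    if n_used < richness.size:
        warnings.warn(
            f"dropping {richness.size - n_used} zero-richness patch(es) from SAR",
            RuntimeWarning,
            stacklevel=2,
        )
    x = np.log(areas[mask])
    y = np.log(richness[mask])
    X = np.column_stack([np.ones(n_used), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return SarFit(c_value=float(coef[0]), z_value=float(coef[1]), n_patches_used=n_used)


def pairwise_area_predictor(areas: np.ndarray) -> np.ndarray:
    """ln(|Area_a - Area_b| + 1) for every unordered patch pair (a < b)."""
    areas = np.asarray(areas, dtype=float)
    i, j = np.triu_indices(areas.size, k=1)
    return np.log(np.abs(areas[i] - areas[j]) + 1.0)


def fit_beta_glm(similarity: np.ndarray, areas: np.ndarray) -> BetaGlmFit:
    """Quasi-binomial logit-link GLM of pairwise similarity on area difference.

    The response is the continuous similarity in [0, 1] for each unordered
    patch pair; the predictor is ln(|area difference| + 1). Pairs with
    undefined (NaN) similarity are excluded. Coefficients are maximum
    quasi-likelihood (IRLS) estimates.
    """
    similarity = np.asarray(similarity, dtype=float)
    areas = np.asarray(areas, dtype=float)
    i, j = np.triu_indices(areas.size, k=1)
    y = similarity[i, j]
    x = np.log(np.abs(areas[i] - areas[j]) + 1.0)
    ok = np.isfinite(y)
    y, x = y[ok], x[ok]
    n_pairs = int(ok.sum())
    if n_pairs < 3:
        raise FitError(f"only {n_pairs} pairs with defined similarity")
    if np.all(y == y[0]) and y[0] in (0.0, 1.0):
        raise FitError("all similarities are 0 or 1: logit fit is degenerate")
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        # statsmodels objects to non-integer binomial responses; the
        # quasi-likelihood point estimates are exactly what we want
        warnings.simplefilter("ignore", DomainWarning)
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError) as exc:
            raise FitError(f"GLM fit failed: {exc}") from exc
    return BetaGlmFit(
        gamma0=float(res.params[0]), gamma1=float(res.params[1]), n_pairs=n_pairs
    )


def community_parameters(
    richness: np.ndarray,
    similarity: np.ndarray,
    areas: np.ndarray,
) -> dict:
    """All six community parameters from richness + similarity inputs.

    Returns a dict with per-patch richness, the SAR (c, z), the pairwise
    similarity matrix, and the beta-GLM (gamma0, gamma1). Trend-model
    failures propagate as :class:`FitError`.
    """
    sar = fit_sar(richness, areas)
    glm = fit_beta_glm(similarity, areas)
    return {
        "richness": np.asarray(richness, dtype=float),
        "c_value": sar.c_value,
        "z_value": sar.z_value,
        "sorensen": similarity,
        "gamma0": glm.gamma0,
        "gamma1": glm.gamma1,
    }
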