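"""Asymptotic, abundance-based richness and similarity estimators (q = 0).

Implements the bias-corrected Chao1 richness estimator and the two-assemblage
Hill-number decomposition that converts asymptotic gamma and alpha richness
into a Sorensen-type similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AbundanceVector", "chao1_richness", "chao_sorensen", "batch_chao1"]


@dataclass(frozen=True)
class AbundanceVector:
    """Per-species counts for one assemblage plus rare-species frequencies."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def s_obs(self) -> int:
        return int((self.counts > 0).sum())

    @property
    def f1(self) -> int:
        return int((self.counts == 1).sum())

    @property
    def f2(self) -> int:
        return int((self.counts == 2).sum())


def chao1_richness(v: AbundanceVector | np.ndarray) -> float:
    """Bias-corrected Chao1 asymptotic richness estimate.

    With singletons f1 and doubletons f2 out of n individuals:
    S_obs + ((n-1)/n) * f1^2 / (2 f2) when f2 > 0, else the f2 = 0
    correction S_obs + ((n-1)/n) * f1 (f1 - 1) / 2. Degenerates to S_obs
    when n <= 1 and to 0 for an empty assemblage.
    """
    if not isinstance(v, AbundanceVector):
        v = AbundanceVector(np.asarray(v))
    if v.n == 0:
        return 0.0
    if v.n <= 1:
        return float(v.s_obs)
    factor = (v.n - 1) / v.n
    if v.f2 > 0:
        return v.s_obs + factor * v.f1**2 / (2 * v.f2)
    return v.s_obs + factor * v.f1 * (v.f1 - 1) / 2


def chao_sorensen(
    a: AbundanceVector | np.ndarray, b: AbundanceVector | np.ndarray
) -> float:
    """Asymptotic Sorensen similarity between two assemblages.

    gamma-hat is the Chao1 estimate of the pooled assemblage; alpha-hat is
    half the Chao1 estimate of the joint vector in which each (species,
    assemblage) combination is a distinct entity; beta-hat = gamma/alpha is
    clamped to [1, 2] and similarity = 2 - beta-hat. Returns NaN when both
    assemblages are empty.
    """
    if not isinstance(a, AbundanceVector):
        a = AbundanceVector(np.asarray(a))
    if not isinstance(b, AbundanceVector):
        b = AbundanceVector(np.asarray(b))
    if a.counts.shape != b.counts.shape:
        raise ValueError("assemblages must share one species list")
    if a.n == 0 and b.n == 0:
        return float("nan")
    gamma = chao1_richness(AbundanceVector(a.counts + b.counts))
    joint = AbundanceVector(np.concatenate([a.counts, b.counts]))
    alpha = chao1_richness(joint) / 2.0
    if alpha == 0:
        return float("nan")
    beta = min(2.0, max(1.0, gamma / alpha))
    return 2.0 - beta


def batch_chao1(pooled: np.ndarray) -> np.ndarray:
    """Chao1 richness for every row of a patches x species count matrix."""
    return np.array([chao1_richness(row) for row in np.asarray(pooled)])


def chao_sorensen_matrix(pooled: np.ndarray) -> np.ndarray:
    """Pairwise asymptotic Sorensen similarity over all patch pairs.

    Diagonal is 1 for nonempty patches, NaN where a pair is undefined.
    """
    pooled = np.asarray(pooled)
    P = pooled.shape[0]
    out = np.full((P, P), np.nan)
    vecs = [AbundanceVector(pooled[p]) for p in range(P)]
    for p in range(P):
        if vecs[p].n > 0:
            out[p, p] = 1.0
        for q in range(p + 1, P):
            s = chao_sorensen(vecs[p], vecs[q])
            out[p, q] = out[q, p] = s
    return out
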