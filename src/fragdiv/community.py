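"""Fragmented-landscape community simulator.

Generates one landscape community in four steps: patch areas from a
four-parameter beta distribution (with the smallest and largest patches
pinned), a log-normal metacommunity abundance distribution, per-species
area-response coefficients, and a capacity-constrained assignment of
individuals (in groups) to patches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

try:  # optional acceleration for the group-assignment loop
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is present in CI images
    _HAVE_NUMBA = False

__all__ = [
    "Beta4Params",
    "Landscape",
    "Metacommunity",
    "AreaResponses",
    "CommunityConfig",
    "Community",
    "draw_patch_areas",
    "simulate_metacommunity",
    "draw_area_responses",
    "assignment_probs",
    "assign_individuals",
    "simulate_community",
]

DEFAULT_DENSITY = 500.0  # individuals per Ha; also the abundance inflation factor


@dataclass(frozen=True)
class Beta4Params:
    """Four-parameter beta distribution: Beta(alpha, beta) rescaled to [min, max]."""

    alpha: float
    beta: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("shape parameters must be positive")
        if not self.max > self.min:
            raise ValueError("max must exceed min")


#: Default patch-area distribution: negative power-law-like frequency of areas.
DEFAULT_AREA_PARAMS = Beta4Params(alpha=1.0, beta=4.0, min=25.0, max=20_000.0)

#: Default area-response distribution bounds (second shape parameter is fixed).
DEFAULT_RESPONSE_BOUNDS = (0.0, 5.0)


@dataclass(frozen=True)
class Landscape:
    """Patch areas (Ha) and their carrying capacities (individuals)."""

    patch_areas: np.ndarray
    density: float = DEFAULT_DENSITY

    def __post_init__(self) -> None:
        object.__setattr__(self, "patch_areas", np.asarray(self.patch_areas, dtype=float))
        if np.any(self.patch_areas <= 0):
            raise ValueError("patch areas must be positive")

    @property
    def n_patches(self) -> int:
        return self.patch_areas.size

    @property
    def total_area(self) -> float:
        return float(self.patch_areas.sum())

    @property
    def capacities(self) -> np.ndarray:
        """Carrying capacity per patch, K_p = round(density * Area_p)."""
        return np.rint(self.density * self.patch_areas).astype(np.int64)


@dataclass(frozen=True)
class Metacommunity:
    """Landscape-level per-species abundances."""

    abundances: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "abundances", np.asarray(self.abundances, dtype=np.int64)
        )
        if np.any(self.abundances < 0):
            raise ValueError("abundances must be nonnegative")

    @property
    def n_species(self) -> int:
        return self.abundances.size

    @property
    def total_individuals(self) -> int:
        return int(self.abundances.sum())


@dataclass(frozen=True)
class AreaResponses:
    """Per-species area-response coefficients and their generating shapes."""

    beta_area: np.ndarray
    alpha_i: np.ndarray
    sign_flipped: np.ndarray  # indices of species whose response was negated


def draw_patch_areas(
    n_patches: int,
    params: Beta4Params = DEFAULT_AREA_PARAMS,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw patch areas with the smallest and largest patches pre-assigned.

    The first patch takes ``params.min`` and the last ``params.max`` exactly;
    the remaining ``n_patches - 2`` areas are drawn from the four-parameter
    beta distribution. The returned vector is sorted ascending.
    """
    if n_patches < 2:
        raise ValueError("need at least 2 patches (the pre-assigned endpoints)")
    rng = np.random.default_rng(rng)
    free = rng.beta(params.alpha, params.beta, size=n_patches - 2)
    areas = np.concatenate(
        [[params.min, params.max], params.min + (params.max - params.min) * free]
    )
    return np.sort(areas)


def _lognormal_relative_abundances(
    n_species: int,
    meanlog: float,
    sdlog: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Relative abundances from a log-normal SAD (shape is all that matters)."""
    if sdlog < 0:
        raise ValueError("sdlog must be nonnegative")
    draws = np.exp(rng.normal(meanlog, sdlog, size=n_species))
    return draws / draws.sum()


def _largest_remainder_allocation(rel: np.ndarray, total: int) -> np.ndarray:
    """Allocate ``total`` integer units proportionally with a floor of 1 each."""
    n = rel.size
    if total < n:
        raise ValueError("cannot allocate at least one individual per species")
    # floor of 1 guaranteed by allocating the remainder over (total - n)
    spare = total - n
    raw = rel * spare
    base = np.floor(raw).astype(np.int64)
    short = spare - int(base.sum())
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base + 1


def simulate_metacommunity(
    n_species: int,
    total_area: float,
    sad_meanlog: float = float(np.log(650.0)),
    sad_sdlog: float = 3.0,
    inflation: int = 500,
    rng: np.random.Generator | None = None,
) -> Metacommunity:
    """Simulate a landscape metacommunity.

    Draws a log-normal species abundance distribution, allocates
    ``round(total_area)`` individuals to species proportionally (every species
    receives at least one), then multiplies abundances by ``inflation`` so
    the minimum landscape-level population is ``inflation`` individuals and
    overall density is ``inflation`` individuals per Ha.

    The log-normal is parameterized on the log scale (location ``sad_meanlog``,
    scale ``sad_sdlog``); only its shape influences the result because the
    draws are rescaled to the fixed individual total.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if total_area <= 0:
        raise ValueError("total_area must be positive")
    total = int(round(total_area))
    if total < n_species:
        raise ValueError(
            f"round(total_area)={total} < n_species={n_species}: "
            "cannot guarantee one individual per species"
        )
    rng = np.random.default_rng(rng)
    rel = _lognormal_relative_abundances(n_species, sad_meanlog, sad_sdlog, rng)
    counts = _largest_remainder_allocation(rel, total)
    return Metacommunity(abundances=counts * inflation)


def draw_area_responses(
    metacommunity: Metacommunity,
    alpha_max: float,
    beta_shape: float = 5.0,
    bounds: tuple[float, float] = DEFAULT_RESPONSE_BOUNDS,
    neg_fraction: float = 1.0 / 8.0,
    ramp: str = "inverse",
    rng: np.random.Generator | None = None,
) -> AreaResponses:
    """Draw per-species area-response coefficients.

    The first shape parameter ``alpha_i`` spans ``[0.1, alpha_max]`` in
    inverse proportion to abundance: the most abundant species gets 0.1
    (weak, near-zero responses concentrate there) and the rarest gets
    ``alpha_max``. With ``ramp="inverse"`` (default) alpha_i is 1/abundance
    rescaled linearly onto the range, so only genuinely rare species acquire
    strong responses; ``ramp="rank"`` instead spaces alpha_i evenly over the
    decreasing-abundance ranks, which produces markedly steeper
    species-area slopes. Responses are ``lo + (hi-lo) *
    Beta(alpha_i, beta_shape)`` draws; a uniformly random subset of
    ``round(S * neg_fraction)`` species has its response negated.
    """
    if alpha_max <= 0.1:
        raise ValueError("alpha_max must exceed 0.1")
    rng = np.random.default_rng(rng)
    S = metacommunity.n_species
    lo, hi = bounds
    if ramp == "inverse":
        inv = 1.0 / metacommunity.abundances
        if S == 1 or inv.max() == inv.min():
            alpha_i = np.full(S, 0.1)
        else:
            alpha_i = 0.1 + (alpha_max - 0.1) * (inv - inv.min()) / (
                inv.max() - inv.min()
            )
    elif ramp == "rank":
        # decreasing-abundance rank; ties broken by species index (stable sort)
        order = np.argsort(-metacommunity.abundances, kind="stable")
        alpha_i = np.empty(S)
        alpha_i[order] = np.linspace(0.1, alpha_max, S)
    else:
        raise ValueError(f"unknown ramp mode {ramp!r}")
    beta_area = lo + (hi - lo) * rng.beta(alpha_i, beta_shape)
    n_neg = int(round(S * neg_fraction))
    flipped = rng.choice(S, size=n_neg, replace=False)
    beta_area[flipped] *= -1.0
    return AreaResponses(beta_area=beta_area, alpha_i=alpha_i, sign_flipped=flipped)


def assignment_probs(patch_areas: np.ndarray, beta_i: float) -> np.ndarray:
    """Per-patch assignment probabilities, phi_p = Area_p^beta_i / sum."""
    areas = np.asarray(patch_areas, dtype=float)
    if np.any(areas <= 0):
        raise ValueError("patch areas must be positive")
    logw = beta_i * np.log(areas)
    w = np.exp(logw - logw.max())  # stable for |beta_i| up to 5 over 3 decades
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        raise RuntimeError("assignment weights have empty support")
    return w / total


def _assign_groups_py(species_order, group_sizes, phi, caps, uniforms):
    """Sequential capacity-constrained group assignment (reference path).

    Deterministic given ``uniforms`` (one uniform per group), so the numba
    and pure-python paths produce identical output.
    """
    n_patches, _ = phi.shape
    N = np.zeros((n_patches, phi.shape[1]), dtype=np.int64)
    filled = np.zeros(n_patches, dtype=np.int64)
    overflow = 0
    for g in range(species_order.size):
        s = species_order[g]
        size = group_sizes[g]
        total = 0.0
        for p in range(n_patches):
            if filled[p] < caps[p]:
                total += phi[p, s]
        if total > 0.0:
            u = uniforms[g] * total
            acc = 0.0
            chosen = n_patches - 1
            for p in range(n_patches):
                if filled[p] < caps[p]:
                    acc += phi[p, s]
                    if u <= acc:
                        chosen = p
                        break
        else:
            # no non-full patch (or zero weight support): fall back to the
            # unrestricted assignment probabilities
            overflow += 1
            u = uniforms[g]
            acc = 0.0
            chosen = n_patches - 1
            for p in range(n_patches):
                acc += phi[p, s]
                if u <= acc:
                    chosen = p
                    break
        N[chosen, s] += size
        filled[chosen] += size
    return N, overflow


if _HAVE_NUMBA:
    _assign_groups = njit(cache=True)(_assign_groups_py)
else:  # pragma: no cover
    _assign_groups = _assign_groups_py


def assign_individuals(
    metacommunity: Metacommunity,
    landscape: Landscape,
    responses: AreaResponses,
    group_size: int = 100,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Assign individuals to patches in groups, respecting carrying capacities.

    Individuals of each species are split into groups of ``group_size`` (the
    final group may be smaller). All (species, group) units are shuffled
    globally, then placed one at a time by weighted sampling with the
    species' assignment probabilities restricted to non-full patches. A patch
    is full once its assigned total reaches ``round(K_p)``; a group placed
    into an almost-full patch may overshoot by at most ``group_size - 1``.

    Returns the patch x species abundance matrix ``N``. Column sums equal the
    metacommunity abundances exactly.
    """
    rng = np.random.default_rng(rng)
    caps = landscape.capacities
    abundances = metacommunity.abundances
    if abundances.sum() > caps.sum() + group_size * landscape.n_patches:
        raise ValueError("total individuals exceed total landscape capacity")

    n_groups_per_species = -(-abundances // group_size)  # ceil division
    species_order = np.repeat(
        np.arange(metacommunity.n_species), n_groups_per_species
    )
    group_sizes = np.full(species_order.size, group_size, dtype=np.int64)
    # final group of each species holds the remainder
    last_idx = np.cumsum(n_groups_per_species) - 1
    remainders = abundances - (n_groups_per_species - 1) * group_size
    group_sizes[last_idx[n_groups_per_species > 0]] = remainders[
        n_groups_per_species > 0
    ]

    perm = rng.permutation(species_order.size)
    species_order = species_order[perm]
    group_sizes = group_sizes[perm]
    uniforms = rng.random(species_order.size)

    phi = np.empty((landscape.n_patches, metacommunity.n_species))
    for s in range(metacommunity.n_species):
        phi[:, s] = assignment_probs(landscape.patch_areas, responses.beta_area[s])

    N, overflow = _assign_groups(species_order, group_sizes, phi, caps, uniforms)
    if overflow:
        warnings.warn(
            f"{overflow} group(s) assigned after all patches reached capacity",
            RuntimeWarning,
            stacklevel=2,
        )
    return N


@dataclass(frozen=True)
class CommunityConfig:
    """All knobs of the community simulator, with published defaults."""

    n_patches: int = 25
    n_species: int = 200
    area_params: Beta4Params = DEFAULT_AREA_PARAMS
    density: float = DEFAULT_DENSITY
    inflation: int = 500
    sad_meanlog: float = float(np.log(650.0))
    sad_sdlog: float = 3.0
    alpha_max: float = 8.0
    response_beta_shape: float = 5.0
    response_bounds: tuple[float, float] = DEFAULT_RESPONSE_BOUNDS
    neg_fraction: float = 1.0 / 8.0
    response_ramp: str = "inverse"
    group_size: int = 100


@dataclass(frozen=True)
class Community:
    """One simulated landscape community and its generating pieces."""

    landscape: Landscape
    metacommunity: Metacommunity
    responses: AreaResponses
    abundance: np.ndarray  # patches x species
    config: CommunityConfig = field(default_factory=CommunityConfig)
    seed: int | None = None

    @property
    def occurrence(self) -> np.ndarray:
        """Boolean patches x species true-occurrence matrix."""
        return self.abundance > 0


def simulate_community(
    config: CommunityConfig = CommunityConfig(),
    rng: np.random.Generator | int | None = None,
) -> Community:
    """Run the full community simulation pipeline under one RNG stream."""
    seed = rng if isinstance(rng, int) else None
    rng = np.random.default_rng(rng)
    areas = draw_patch_areas(config.n_patches, config.area_params, rng)
    landscape = Landscape(patch_areas=areas, density=config.density)
    meta = simulate_metacommunity(
        config.n_species,
        landscape.total_area,
        sad_meanlog=config.sad_meanlog,
        sad_sdlog=config.sad_sdlog,
        inflation=config.inflation,
        rng=rng,
    )
    responses = draw_area_responses(
        meta,
        alpha_max=config.alpha_max,
        beta_shape=config.response_beta_shape,
        bounds=config.response_bounds,
        neg_fraction=config.neg_fraction,
        ramp=config.response_ramp,
        rng=rng,
    )
    N = assign_individuals(
        meta, landscape, responses, group_size=config.group_size, rng=rng
    )
    return Community(
        landscape=landscape,
        metacommunity=meta,
        responses=responses,
        abundance=N,
        config=config,
        seed=seed,
    )
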