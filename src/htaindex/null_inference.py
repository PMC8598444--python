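"""Permutation null model and normal-approximation p-values for HTA.

The null model is a uniformly random rearrangement of the *observed*
trait-combination labels over the *observed* occupied positions: label
frequencies and the occupancy mask are both preserved exactly. Permuting
whole combinations (rather than individual traits) keeps the sample's
molecular composition intact — a tissue expressing one combination stays a
tissue expressing that one combination under every permutation.

Because the occupancy mask is fixed, the regions and their weights
w_r = n_r / n are identical across permutations; only the per-region HTI
varies. Writing HTA = sum_r w_r * X_r with X_r the region HTI, the null
distribution of HTA is approximately normal by the Lyapunov central limit
theorem for independent, non-identically distributed summands:

    z = (HTA - sum_r w_r mu_r) / sqrt(sum_r w_r^2 sigma_r^2)

where mu_r, sigma_r are the null moments of X_r, estimated from repeated
permutations (default 1000) or — for small equal-occupancy regions — computed
exactly by enumeration. The lower tail of z tests homogeneity, the upper tail
heterogeneity, and the overall significance doubles the smaller one-sided
p-value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import norm

from .core_stats import GridPartition, HTAResult, partition_grid
from .errors import CapacityError, InferenceError, InputError
from .trait_calling import TraitCombinationMatrix

#: Below this number of retained regions the normal approximation is dubious.
MIN_REGIONS_FOR_CLT = 30

#: Enumeration guard for the exact path: (2^t)^cells configurations.
MAX_EXACT_CONFIGURATIONS = 10**7


def permute_combinations(
    matrix: TraitCombinationMatrix, seed: int | np.random.Generator | None = None
) -> TraitCombinationMatrix:
    """Uniformly shuffle the non-empty labels over the occupied positions.

    The multiset of labels and the empty-position mask are preserved exactly;
    each arrangement of the labels is equally likely.
    """
    occ = matrix.occupied
    if not occ.any():
        raise InputError("matrix contains no occupied entries to permute")
    rng = np.random.default_rng(seed)
    labels = matrix.labels.copy()
    labels[occ] = rng.permutation(labels[occ])
    return TraitCombinationMatrix(labels=labels, decoding=dict(matrix.decoding), C=matrix.C)


@dataclass
class NullMoments:
    """Per-region null mean and sd of the region HTI, plus fixed weights."""

    mu_r: np.ndarray
    sigma_r: np.ndarray
    weights: np.ndarray
    n_permutations: int
    seed: int | None
    method: str

    @property
    def R(self) -> int:
        return len(self.mu_r)


def _null_hti_samples(
    partition: GridPartition,
    labels_flat: np.ndarray,
    region_of_entry: np.ndarray,
    n_permutations: int,
    seed: int | None,
) -> np.ndarray:
    """(n_permutations, R) region HTIs under the permutation null.

    Permutation ``i`` uses an independent stream spawned from ``(seed, i)`` so
    results are reproducible regardless of chunking or parallel evaluation.
    """
    R, C = partition.R, partition.C
    n = labels_flat.size
    base = np.random.SeedSequence(seed)
    children = base.spawn(n_permutations)
    logC = math.log(C) if C > 1 else 1.0
    inv_n_r = 1.0 / partition.n_r
    out = np.empty((n_permutations, R))
    offset = region_of_entry * C - 1  # maps label L at entry e to bin reg*C + L-1
    for i, child in enumerate(children):
        perm = np.random.default_rng(child).permutation(n)
        counts = np.bincount(offset + labels_flat[perm], minlength=R * C).reshape(R, C)
        if C > 1:
            p = counts * inv_n_r[:, None]
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(p > 0, -p * np.log(p), 0.0)
            out[i] = terms.sum(axis=1) / logC
        else:
            out[i] = 0.0
    return out


def estimate_null_moments(
    matrix: TraitCombinationMatrix,
    region_size: int | tuple[int, ...],
    n_permutations: int = 1000,
    seed: int | None = None,
) -> NullMoments:
    """Estimate mu_r, sigma_r by repeated label permutation.

    The occupancy mask — hence the partition and the weights — is held fixed;
    for each permutation the HTI of every retained region is recomputed, and
    per-region sample moments are taken across permutations (population-form
    standard deviation). Deterministic given ``seed``.
    """
    if n_permutations < 1:
        raise InputError("n_permutations must be positive")
    partition = partition_grid(matrix, region_size)
    if partition.R < 2:
        raise InferenceError(
            "need at least 2 non-empty regions to form a null distribution"
        )
    occ = matrix.occupied
    labels_flat = matrix.labels[occ]
    region_of_entry = partition.cell_region[occ]
    samples = _null_hti_samples(
        partition, labels_flat, region_of_entry, n_permutations, seed
    )
    mu = samples.mean(axis=0)
    sigma = samples.std(axis=0)  # population form; negligible vs sample at 1000
    return NullMoments(
        mu_r=mu,
        sigma_r=sigma,
        weights=partition.weights,
        n_permutations=n_permutations,
        seed=seed,
        method="permutation",
    )


@dataclass
class ExactNullSpec:
    """Cell-level model for exact enumeration of a region's null HTI moments.

    Each cell of a region of shape ``region_shape`` independently takes one of
    2^t states — every subset of the t traits, including the empty one — with
    equal probability (each trait present with probability 1/2 independently).
    Empty cells are excluded from the counts, C = 2^t - 1 is the log base, and
    the moments are conditioned on the region containing at least one
    non-empty cell.
    """

    region_shape: tuple[int, ...]
    n_traits: int


def _compositions(total: int, parts: int):
    """All ordered non-negative integer compositions of ``total`` into ``parts``."""
    for dividers in combinations(range(total + parts - 1), parts - 1):
        prev = -1
        comp = []
        for d in dividers:
            comp.append(d - prev - 1)
            prev = d
        comp.append(total + parts - 2 - prev)
        yield tuple(comp)


def exact_region_moments(spec: ExactNullSpec) -> tuple[float, float]:
    """Exact null mean and sd of a region's HTI by exhaustive enumeration.

    Enumerates all (2^t)^cells cell-state configurations of one region (via
    their state-count vectors, weighted by exact multinomial probabilities)
    and returns the mean and population sd of the base-(2^t - 1) HTI,
    conditioned on at least one non-empty cell.
    """
    cells = int(np.prod(spec.region_shape))
    if cells < 1 or spec.n_traits < 1:
        raise InputError("region must have >= 1 cell and >= 1 trait")
    states = 2**spec.n_traits
    if states**cells > MAX_EXACT_CONFIGURATIONS:
        raise CapacityError(
            f"{states}^{cells} configurations exceed the exact-path guard "
            f"({MAX_EXACT_CONFIGURATIONS:.0e}); use the permutation estimator"
        )
    C = states - 1
    if C == 1:
        return 0.0, 0.0  # a single combination: HTI is identically 0

    log_states = math.log(states)
    lgamma = math.lgamma
    log_fact_cells = lgamma(cells + 1)
    m1 = m2 = total_p = 0.0
    for counts in _compositions(cells, states):
        k_empty = counts[0]
        if k_empty == cells:
            continue  # empty region: discarded
        occ_counts = counts[1:]
        logw = (
            log_fact_cells
            - sum(lgamma(k + 1) for k in counts)
            - cells * log_states
        )
        w = math.exp(logw)
        n_r = cells - k_empty
        h = 0.0
        if n_r > 1:
            for k in occ_counts:
                if 0 < k < n_r:
                    p = k / n_r
                    h -= p * math.log(p)
            h /= math.log(C)
        total_p += w
        m1 += w * h
        m2 += w * h * h
    m1 /= total_p
    m2 /= total_p
    return m1, math.sqrt(max(m2 - m1 * m1, 0.0))


def exact_null_moments(
    matrix: TraitCombinationMatrix,
    region_size: int | tuple[int, ...],
    n_traits: int,
) -> NullMoments:
    """Equal-moment :class:`NullMoments` from the exact per-region enumeration.

    Applies the :class:`ExactNullSpec` cell model uniformly to every retained
    region of the partition. Appropriate when regions are equal-occupancy
    blocks (fully occupied matrices); the permutation estimator is the general
    path for ragged occupancy.
    """
    partition = partition_grid(matrix, region_size)
    mu, sigma = exact_region_moments(
        ExactNullSpec(region_shape=partition.region_size, n_traits=n_traits)
    )
    R = partition.R
    return NullMoments(
        mu_r=np.full(R, mu),
        sigma_r=np.full(R, sigma),
        weights=partition.weights,
        n_permutations=0,
        seed=None,
        method="exact",
    )


@dataclass
class PValuePair:
    """One-sided p-values for homogeneity / heterogeneity plus the overall test.

    ``p_homogeneity`` is the lower-tail normal probability of the standardized
    HTA (small HTA = combinations segregated); ``p_heterogeneity`` is its
    complement. ``p_overall`` doubles the smaller one-sided value, capped at 1.
    """

    p_homogeneity: float
    p_heterogeneity: float
    p_overall: float
    z: float


def hta_p_values(result: HTAResult, moments: NullMoments) -> PValuePair:
    """Standardize HTA against its permutation-null moments and return p-values.

    z = (HTA - sum_r w_r mu_r) / sqrt(sum_r w_r^2 sigma_r^2). A warning is
    emitted when fewer than :data:`MIN_REGIONS_FOR_CLT` regions back the
    normal approximation.
    """
    if moments.R != result.R:
        raise InferenceError(
            f"moments cover {moments.R} regions but the statistic has {result.R}"
        )
    w = moments.weights
    null_mean = float(w @ moments.mu_r)
    null_var = float((w**2) @ (moments.sigma_r**2))
    if null_var <= 0:
        raise InferenceError(
            "null variance is zero (e.g. a single observed combination); "
            "the standardized statistic is degenerate"
        )
    if result.R < MIN_REGIONS_FOR_CLT:
        warnings.warn(
            f"only {result.R} regions; the normal approximation may be poor",
            stacklevel=2,
        )
    z = (result.hta - null_mean) / math.sqrt(null_var)
    p_hom = float(norm.cdf(z))
    p_het = float(norm.sf(z))
    return PValuePair(
        p_homogeneity=p_hom,
        p_heterogeneity=p_het,
        p_overall=min(2.0 * min(p_hom, p_het), 1.0),
        z=float(z),
    )


def empirical_p_values(
    result: HTAResult,
    matrix: TraitCombinationMatrix,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> PValuePair:
    """Rank-based permutation p-values — a debug cross-check, not the primary path.

    Recomputes HTA under ``n_permutations`` label permutations and returns
    add-one rank p-values; z is reported as NaN since no standardization is
    involved.
    """
    partition = result.partition
    occ = matrix.occupied
    samples = _null_hti_samples(
        partition, matrix.labels[occ], partition.cell_region[occ], n_permutations, seed
    )
    null_hta = samples @ partition.weights
    p_hom = float((1 + (null_hta <= result.hta).sum()) / (n_permutations + 1))
    p_het = float((1 + (null_hta >= result.hta).sum()) / (n_permutations + 1))
    return PValuePair(
        p_homogeneity=p_hom,
        p_heterogeneity=p_het,
        p_overall=min(2.0 * min(p_hom, p_het), 1.0),
        z=float("nan"),
    )
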