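"""HTI / HTA statistics over grid partitions of a trait-combination matrix.

HTI (HeTerogeneity Index) is the base-C Shannon entropy of the proportions of
trait combinations among occupied positions:

    HTI = -sum_c p_c * log_C(p_c)

with C the number of combinations in play, so HTI lies in [0, 1]: 0 when one
combination dominates, 1 when all C combinations are equally frequent.

HTA (HeTerogeneity Average) partitions the position lattice into axis-aligned
regions of a chosen size, computes HTI within each region, and averages the
per-region values weighted by the regions' occupied-entry counts:

    HTA = sum_r (n_r / n) * HTI(region r)

Regions in which every position is empty are discarded. Low HTA means the
combinations are spatially segregated (locally homogeneous); high HTA means
they are mixed within regions (locally heterogeneous). On a fully occupied
matrix HTA decreases monotonically under grid refinement, mirroring the
conditioning inequality H(Y|X) <= H(Y).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import entropy as _shannon

from .errors import InputError
from .trait_calling import TraitCombinationMatrix


def _normalize_region_size(
    region_size: int | tuple[int, ...], shape: tuple[int, ...]
) -> tuple[int, ...]:
    """Broadcast a scalar region size to all axes; clamp oversized extents."""
    if np.isscalar(region_size):
        sizes = (int(region_size),) * len(shape)
    else:
        sizes = tuple(int(s) for s in region_size)
    if len(sizes) != len(shape):
        raise InputError(
            f"region size {sizes} does not match matrix dimensionality {len(shape)}"
        )
    if any(s <= 0 for s in sizes):
        raise InputError(f"region size must be positive on every axis; got {sizes}")
    clamped = []
    for s, extent in zip(sizes, shape):
        if s > extent:
            warnings.warn(
                f"region extent {s} exceeds matrix extent {extent}; "
                "clamping to a single region on that axis",
                stacklevel=3,
            )
            s = extent
        clamped.append(s)
    return tuple(clamped)


@dataclass
class GridPartition:
    """Axis-aligned tiling of a label matrix, with per-region occupancy counts.

    Regions are blocks of extent ``region_size`` anchored at index 0 on every
    axis; trailing blocks are smaller when the extents do not divide the matrix
    shape. Regions whose every position is empty are discarded. ``bounds[r]``
    gives half-open ``(start, stop)`` index ranges per axis for retained region
    ``r``; ``cell_region`` maps every lattice position to its retained-region
    index (or -1 inside a discarded region).
    """

    region_size: tuple[int, ...]
    bounds: list[tuple[tuple[int, int], ...]]
    n_r: np.ndarray
    n_rc: np.ndarray
    n: int
    C: int
    cell_region: np.ndarray

    @property
    def R(self) -> int:
        return len(self.bounds)

    @property
    def weights(self) -> np.ndarray:
        """Fraction of all occupied entries falling in each region (sums to 1)."""
        return self.n_r / self.n

    @property
    def n_single_entry_regions(self) -> int:
        """Regions with exactly one occupied entry (HTI pinned to 0)."""
        return int((self.n_r == 1).sum())


def partition_grid(
    matrix: TraitCombinationMatrix, region_size: int | tuple[int, ...]
) -> GridPartition:
    """Tile the matrix into regions and tabulate combination counts per region."""
    shape = matrix.shape
    sizes = _normalize_region_size(region_size, shape)

    block_index = [np.arange(extent) // s for extent, s in zip(shape, sizes)]
    n_blocks = [int(b[-1]) + 1 for b in block_index]
    grids = np.meshgrid(*block_index, indexing="ij")
    full_region = np.ravel_multi_index([g for g in grids], dims=n_blocks)

    occ = matrix.occupied
    n = int(occ.sum())
    if n == 0:
        raise InputError("matrix contains no occupied entries")
    C = matrix.C

    n_total_regions = int(np.prod(n_blocks))
    flat = full_region[occ] * C + (matrix.labels[occ] - 1)
    n_rc_full = np.bincount(flat, minlength=n_total_regions * C).reshape(
        n_total_regions, C
    )
    n_r_full = n_rc_full.sum(axis=1)
    keep = n_r_full > 0

    remap = np.full(n_total_regions, -1, dtype=np.int64)
    remap[keep] = np.arange(int(keep.sum()))
    cell_region = remap[full_region]

    bounds = []
    for flat_id in np.nonzero(keep)[0]:
        multi = np.unravel_index(int(flat_id), n_blocks)
        bounds.append(
            tuple(
                (int(b * s), int(min((b + 1) * s, extent)))
                for b, s, extent in zip(multi, sizes, shape)
            )
        )

    return GridPartition(
        region_size=sizes,
        bounds=bounds,
        n_r=n_r_full[keep],
        n_rc=n_rc_full[keep],
        n=n,
        C=C,
        cell_region=cell_region,
    )


def hti(counts: np.ndarray, C: int) -> float:
    """Base-C Shannon entropy of combination proportions.

    ``counts`` are non-negative per-combination occupancy counts; proportions
    are taken over their total. Returns 0 when only one combination occurs,
    when the region holds a single entry, or when C = 1.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.size == 0 or (counts < 0).any():
        raise InputError("counts must be a non-empty array of non-negative numbers")
    total = counts.sum()
    if total <= 0:
        raise InputError("counts are all zero; HTI is undefined")
    n_pos = int((counts > 0).sum())
    if int(C) < n_pos:
        raise InputError(f"C={C} is smaller than the {n_pos} combinations with positive count")
    if C <= 1 or n_pos == 1 or total == 1:
        return 0.0
    return float(_shannon(counts[counts > 0], base=C))


def hti_per_region(partition: GridPartition) -> np.ndarray:
    """Vectorized HTI over the retained regions of a partition."""
    if partition.C <= 1:
        return np.zeros(partition.R)
    p = partition.n_rc / partition.n_r[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return terms.sum(axis=1) / np.log(partition.C)


@dataclass
class HTAResult:
    """HTA statistic together with the per-region detail needed for inference."""

    hta: float
    region_size: tuple[int, ...]
    R: int
    weights: np.ndarray
    hti_per_region: np.ndarray
    C: int
    partition: GridPartition

    def to_dict(self) -> dict:
        return {
            "hta": self.hta,
            "region_size": list(self.region_size),
            "R": self.R,
            "C": self.C,
            "weights": self.weights.tolist(),
            "hti_per_region": self.hti_per_region.tolist(),
        }


def hta(
    matrix: TraitCombinationMatrix, region_size: int | tuple[int, ...]
) -> HTAResult:
    """Occupancy-weighted mean of per-region HTIs for one grid size."""
    partition = partition_grid(matrix, region_size)
    htis = hti_per_region(partition)
    weights = partition.weights
    value = float(weights @ htis)
    return HTAResult(
        hta=value,
        region_size=partition.region_size,
        R=partition.R,
        weights=weights,
        hti_per_region=htis,
        C=partition.C,
        partition=partition,
    )


@dataclass
class RegionReport:
    """Ranked trait-combination frequencies within one region."""

    region_id: int
    bounds: tuple[tuple[int, int], ...]
    entries: list[tuple[tuple[str, ...], int, float]]


def region_report(
    partition: GridPartition,
    decoding: dict[int, tuple[str, ...]],
    region_id: int,
) -> RegionReport:
    """Decode and rank the combinations in a retained region.

    Entries are ``(trait subset, count, fraction of the region's occupied
    entries)``, sorted by descending fraction (ties broken by label order).
    """
    if not (0 <= int(region_id) < partition.R):
        raise InputError(
            f"unknown region id {region_id}; valid ids are 0..{partition.R - 1}"
        )
    region_id = int(region_id)
    counts = partition.n_rc[region_id]
    n_r = int(partition.n_r[region_id])
    order = sorted(
        (int(lab) for lab in np.nonzero(counts)[0] + 1),
        key=lambda lab: (-counts[lab - 1], lab),
    )
    entries = [
        (decoding.get(lab, (f"label_{lab}",)), int(counts[lab - 1]), counts[lab - 1] / n_r)
        for lab in order
    ]
    return RegionReport(
        region_id=region_id, bounds=partition.bounds[region_id], entries=entries
    )
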