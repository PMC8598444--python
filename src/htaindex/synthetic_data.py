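"""Synthetic trait-combination maps with known heterogeneity structure.

These generators produce the canonical test-bed constructions for the HTA
statistic:

* :func:`random_uniform_map` — every position draws each trait independently
  (default presence probability 0.5), i.e. a draw from the global null of
  spatially unstructured trait combinations.
* :func:`region_homogeneous_map` — each grid region is filled with a single
  combination (combinations cycled across regions), the extreme of local
  homogeneity: HTA = 0 at the construction region size.
* :func:`region_heterogeneous_map` — every region contains all combinations
  in exactly equal counts, the extreme of local heterogeneity: HTA = 1 at the
  construction region size.
* :func:`layered_z_map` — a 3D volume whose z-layers each carry one
  combination, so regions confined to a layer are pure (HTA = 0) while
  regions spanning the layers are perfectly balanced (HTA = 1).
* :func:`from_permuted` — a null replicate of an existing map via label
  permutation.

All generators are deterministic given their seed. Mutually exclusive
single-trait combinations are used for the region-structured constructions so
that exact within-region balance is achievable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core_stats import _normalize_region_size
from .errors import InputError
from .null_inference import permute_combinations
from .trait_calling import (
    BinaryTraitTensor,
    TraitCombinationMatrix,
    encode_combinations,
)

_GENERATORS = (
    "random_uniform",
    "region_homogeneous",
    "region_heterogeneous",
    "layered_z",
    "from_permuted",
)


@dataclass
class MapSpec:
    """Declarative description of a synthetic map (serializable to JSON)."""

    shape: tuple[int, ...]
    generator: str = "random_uniform"
    n_traits: int = 2
    region_size: Optional[tuple[int, ...]] = None
    n_combinations: Optional[int] = None
    p_present: float = 0.5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) not in (2, 3) or any(s <= 0 for s in self.shape):
            raise InputError(f"shape must be 2D or 3D with positive extents; got {self.shape}")
        if self.generator not in _GENERATORS:
            raise InputError(f"unknown generator {self.generator!r}; choose from {_GENERATORS}")
        if not 0 < self.p_present < 1:
            raise InputError("p_present must lie strictly in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "generator": self.generator,
            "n_traits": self.n_traits,
            "region_size": list(self.region_size) if self.region_size else None,
            "n_combinations": self.n_combinations,
            "p_present": self.p_present,
            "seed": self.seed,
        }


def _exclusive_trait_decoding(k: int) -> dict[int, tuple[str, ...]]:
    """k mutually exclusive single-trait combinations labelled 1..k."""
    return {i: (f"T{i}",) for i in range(1, k + 1)}


def random_uniform_map(
    shape: tuple[int, ...],
    n_traits: int = 2,
    p_present: float = 0.5,
    seed: int | None = None,
    c_mode: str = "observed",
) -> TraitCombinationMatrix:
    """Spatially unstructured map: each trait present i.i.d. per position.

    Positions where no trait fires become empty, so the expected occupied
    fraction is 1 - (1 - p_present)^n_traits.
    """
    rng = np.random.default_rng(seed)
    presence = rng.random((n_traits, *shape)) < p_present
    tensor = BinaryTraitTensor(
        presence=presence,
        occupied=np.ones(shape, dtype=bool),
        trait_names=[f"T{i}" for i in range(1, n_traits + 1)],
    )
    return encode_combinations(tensor, c_mode=c_mode)


def region_homogeneous_map(
    shape: tuple[int, ...],
    region_size: int | tuple[int, ...],
    n_combinations: int = 2,
) -> TraitCombinationMatrix:
    """Each grid region filled with one combination; combinations cycled.

    Requires the region size to divide the shape exactly so every region is
    pure by construction.
    """
    sizes = _normalize_region_size(region_size, shape)
    if any(extent % s for extent, s in zip(shape, sizes)):
        raise InputError(
            f"region size {sizes} must divide shape {shape} for the exact construction"
        )
    if n_combinations < 1:
        raise InputError("need at least one combination")
    n_blocks = [extent // s for extent, s in zip(shape, sizes)]
    block_labels = (
        np.arange(int(np.prod(n_blocks))).reshape(n_blocks) % n_combinations + 1
    )
    labels = block_labels
    for axis, s in enumerate(sizes):
        labels = np.repeat(labels, s, axis=axis)
    return TraitCombinationMatrix(
        labels=labels,
        decoding=_exclusive_trait_decoding(n_combinations),
        C=n_combinations,
    )


def region_heterogeneous_map(
    shape: tuple[int, ...],
    region_size: int | tuple[int, ...],
    n_combinations: int = 2,
) -> TraitCombinationMatrix:
    """Every region holds all combinations in exactly equal counts.

    Labels are cycled row-major within each region, which yields exact balance
    whenever the region cell count is divisible by ``n_combinations``.
    """
    sizes = _normalize_region_size(region_size, shape)
    if any(extent % s for extent, s in zip(shape, sizes)):
        raise InputError(
            f"region size {sizes} must divide shape {shape} for the exact construction"
        )
    cells = int(np.prod(sizes))
    if n_combinations < 1 or cells % n_combinations:
        raise InputError(
            f"region cell count {cells} must be divisible by C={n_combinations}"
        )
    block = (np.arange(cells) % n_combinations + 1).reshape(sizes)
    tiles = [extent // s for extent, s in zip(shape, sizes)]
    labels = np.tile(block, tiles)
    return TraitCombinationMatrix(
        labels=labels,
        decoding=_exclusive_trait_decoding(n_combinations),
        C=n_combinations,
    )


def layered_z_map(
    shape: tuple[int, int, int], n_combinations: int | None = None
) -> TraitCombinationMatrix:
    """3D volume with z-layer k filled entirely by combination k."""
    if len(shape) != 3:
        raise InputError("layered_z_map requires a 3D shape")
    n_layers = shape[2]
    if n_combinations is None:
        n_combinations = n_layers
    if n_layers > n_combinations:
        raise InputError(
            f"{n_layers} layers need {n_layers} combinations; only {n_combinations} requested"
        )
    labels = np.zeros(shape, dtype=np.int64)
    for k in range(n_layers):
        labels[:, :, k] = k + 1
    return TraitCombinationMatrix(
        labels=labels,
        decoding=_exclusive_trait_decoding(n_combinations),
        C=n_combinations,
    )


def from_permuted(
    matrix: TraitCombinationMatrix, seed: int | None = None
) -> TraitCombinationMatrix:
    """Null replicate: the same labels uniformly rearranged over occupied cells."""
    return permute_combinations(matrix, seed)


def generate(spec: MapSpec, source: TraitCombinationMatrix | None = None) -> TraitCombinationMatrix:
    """Dispatch a :class:`MapSpec` to its generator."""
    if spec.generator == "random_uniform":
        return random_uniform_map(
            spec.shape, n_traits=spec.n_traits, p_present=spec.p_present, seed=spec.seed
        )
    if spec.generator == "region_homogeneous":
        if spec.region_size is None:
            raise InputError("region_homogeneous requires region_size")
        return region_homogeneous_map(
            spec.shape, spec.region_size, n_combinations=spec.n_combinations or 2
        )
    if spec.generator == "region_heterogeneous":
        if spec.region_size is None:
            raise InputError("region_heterogeneous requires region_size")
        return region_heterogeneous_map(
            spec.shape, spec.region_size, n_combinations=spec.n_combinations or 2
        )
    if spec.generator == "layered_z":
        return layered_z_map(spec.shape, n_combinations=spec.n_combinations)
    if spec.generator == "from_permuted":
        if source is None:
            raise InputError("from_permuted requires a source matrix")
        return from_permuted(source, seed=spec.seed)
    raise InputError(f"unknown generator {spec.generator!r}")
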