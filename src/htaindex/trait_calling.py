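"""Trait calling: from numeric spot-level measurements to trait-combination labels.

A *trait* is any per-position numeric measurement (a gene's expression at a
barcoded spot, a voxel intensity in one imaging sequence, ...). Trait calling
proceeds in two steps:

1. :func:`binarize_median` thresholds each trait at its own median across all
   measured spots, producing a binary presence tensor on a dense integer grid.
2. :func:`encode_combinations` collapses the per-trait indicators at each
   position into a single categorical label identifying the exact *subset* of
   traits present there. Positions with no measured spot, or with no trait
   above threshold, carry the reserved empty label.

:func:`resize_nearest` harmonizes label maps of different extents via
nearest-neighbour resampling, which by construction never invents labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

#: Reserved label for "no spot measured here" and "no trait above threshold".
NONE_LABEL = 0

#: Largest trait count for which ``c_mode="full"`` will materialize the
#: complete subset decoding (2^t - 1 entries).
_MAX_FULL_TRAITS = 16


@dataclass
class SpotTable:
    """Long-format table of measured spots.

    Parameters
    ----------
    coordinates
        Integer grid indices, shape ``(n_spots, d)`` with ``d`` in {2, 3}.
        Coordinates are unitless lattice positions; they need not start at 0.
    values
        One numeric value per trait per spot, shape ``(n_spots, n_traits)``.
    trait_names
        Ordered trait identifiers, one per column of ``values``.
    """

    coordinates: np.ndarray
    values: np.ndarray
    trait_names: list[str]

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] not in (2, 3):
            raise InputError(
                "coordinates must have shape (n_spots, d) with d in {2, 3}; "
                f"got {self.coordinates.shape}"
            )
        if self.values.ndim != 2 or self.values.shape[0] != self.coordinates.shape[0]:
            raise InputError("values must have one row per spot")
        if self.values.shape[1] == 0 or len(self.trait_names) != self.values.shape[1]:
            raise InputError("need at least one trait column, with matching names")
        uniq = np.unique(self.coordinates, axis=0)
        if uniq.shape[0] != self.coordinates.shape[0]:
            raise InputError("duplicate spot coordinates present")

    @property
    def n_spots(self) -> int:
        return self.coordinates.shape[0]

    @property
    def ndim(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class BinaryTraitTensor:
    """Per-position, per-trait 0/1 presence on a dense grid.

    ``presence`` has shape ``(n_traits, *shape)``; it is meaningful only where
    ``occupied`` is True. ``occupied`` distinguishes "measured but no trait
    present" from "no spot measured at this lattice position".
    """

    presence: np.ndarray
    occupied: np.ndarray
    trait_names: list[str]

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        self.occupied = np.asarray(self.occupied, dtype=bool)
        if self.presence.shape[1:] != self.occupied.shape:
            raise InputError("presence and occupied grids disagree on shape")
        if self.presence.shape[0] != len(self.trait_names):
            raise InputError("one presence plane per trait is required")
        # presence is defined only on occupied positions
        self.presence &= self.occupied

    @property
    def shape(self) -> tuple[int, ...]:
        return self.occupied.shape

    @property
    def n_traits(self) -> int:
        return self.presence.shape[0]


@dataclass
class TraitCombinationMatrix:
    """Dense d-dimensional grid of trait-combination labels.

    ``labels`` holds integers in ``{1..C}`` for occupied positions manifesting
    at least one trait, and :data:`NONE_LABEL` (0) elsewhere. ``decoding``
    maps each label to the tuple of trait names it denotes; under
    ``c_mode="observed"`` only labels actually present are decoded, under
    ``c_mode="full"`` every non-empty subset of the trait set has a label.
    """

    labels: np.ndarray
    decoding: dict[int, tuple[str, ...]]
    C: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.C < 1:
            raise InputError("C must be >= 1")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() > self.C):
            raise InputError("labels must lie in {0..C} (0 = empty)")
        for lab, subset in self.decoding.items():
            if lab != NONE_LABEL and len(subset) == 0:
                raise InputError(f"label {lab} decodes to an empty trait subset")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def occupied(self) -> np.ndarray:
        """Boolean mask of positions carrying a non-empty combination."""
        return self.labels != NONE_LABEL

    @property
    def n_occupied(self) -> int:
        return int(self.occupied.sum())

    def observed_labels(self) -> np.ndarray:
        """Sorted distinct non-empty labels present in the matrix."""
        u = np.unique(self.labels)
        return u[u != NONE_LABEL]


def binarize_median(
    table: SpotTable, thresholds: dict[str, float] | None = None
) -> BinaryTraitTensor:
    """Threshold each trait at its median; mark presence strictly above it.

    The grid is the minimal axis-aligned bounding box of the spot coordinates
    (origin at the per-axis minimum). A spot's trait is *present* iff its value
    is strictly greater than the trait's median over all spots, so ties at the
    median are called absent. Pass ``thresholds`` to override the median for
    selected traits with a fixed cut-off (same strict-above rule).
    """
    thresholds = thresholds or {}
    origin = table.coordinates.min(axis=0)
    shape = tuple((table.coordinates.max(axis=0) - origin + 1).tolist())
    idx = tuple((table.coordinates - origin).T)

    occupied = np.zeros(shape, dtype=bool)
    occupied[idx] = True

    presence = np.zeros((len(table.trait_names), *shape), dtype=bool)
    for j, name in enumerate(table.trait_names):
        col = table.values[:, j]
        finite = np.isfinite(col)
        if not finite.any():
            raise InputError(f"trait column {name!r} has no finite values")
        cut = thresholds.get(name, float(np.median(col[finite])))
        above = finite & (col > cut)
        presence[j][idx] = above
    return BinaryTraitTensor(presence=presence, occupied=occupied, trait_names=list(table.trait_names))


def encode_combinations(
    tensor: BinaryTraitTensor, c_mode: str = "observed"
) -> TraitCombinationMatrix:
    """Collapse per-trait presence into a single combination label per position.

    Parameters
    ----------
    tensor
        Binary trait tensor from :func:`binarize_median` (or built directly).
    c_mode
        ``"observed"``: C counts the distinct non-empty combinations actually
        present, with compact labels 1..C (ordered by trait-subset bitmask).
        ``"full"``: C = 2^t - 1 for t traits, and each subset keeps its bitmask
        label whether or not it occurs.
    """
    t = tensor.n_traits
    if t == 0:
        raise InputError("at least one trait is required")
    if c_mode not in ("observed", "full"):
        raise InputError(f"unknown c_mode {c_mode!r}")

    bitmask = np.zeros(tensor.shape, dtype=np.int64)
    for j in range(t):
        bitmask |= tensor.presence[j].astype(np.int64) << j
    bitmask[~tensor.occupied] = 0

    def subset(mask: int) -> tuple[str, ...]:
        return tuple(n for j, n in enumerate(tensor.trait_names) if mask >> j & 1)

    if c_mode == "full":
        if t > _MAX_FULL_TRAITS:
            raise InputError(
                f"c_mode='full' materializes 2^{t}-1 labels; limit is t <= {_MAX_FULL_TRAITS}"
            )
        C = 2**t - 1
        decoding = {m: subset(m) for m in range(1, 2**t)}
        return TraitCombinationMatrix(labels=bitmask, decoding=decoding, C=C)

    present = np.unique(bitmask)
    present = present[present != 0]
    C = int(present.size)
    relabel = np.zeros(int(bitmask.max()) + 1, dtype=np.int64)
    relabel[present] = np.arange(1, C + 1)
    decoding = {int(relabel[m]): subset(int(m)) for m in present}
    return TraitCombinationMatrix(labels=relabel[bitmask], decoding=decoding, C=max(C, 1))


def resize_nearest(
    matrix: TraitCombinationMatrix, target_shape: tuple[int, ...]
) -> TraitCombinationMatrix:
    """Resample a label map to new extents by nearest-neighbour lookup.

    Uses the standard pixel-centre scale mapping: output index ``i`` on an axis
    of length ``m`` reads source index ``floor((i + 0.5) * n / m)`` (clipped),
    so integer upscaling replicates blocks and no new labels are created.
    """
    target_shape = tuple(int(s) for s in target_shape)
    if len(target_shape) != matrix.labels.ndim:
        raise InputError("target dimensionality must match the matrix")
    if any(s <= 0 for s in target_shape):
        raise InputError(f"target extents must be positive; got {target_shape}")
    axes = []
    for n_in, n_out in zip(matrix.shape, target_shape):
        src = np.floor((np.arange(n_out) + 0.5) * n_in / n_out).astype(np.int64)
        axes.append(np.minimum(src, n_in - 1))
    out = matrix.labels[np.ix_(*axes)]
    return TraitCombinationMatrix(labels=out, decoding=dict(matrix.decoding), C=matrix.C)


def all_subsets(trait_names: list[str]) -> list[tuple[str, ...]]:
    """All non-empty subsets of a trait list, in bitmask order."""
    out = []
    for m in range(1, 2 ** len(trait_names)):
        out.append(tuple(n for j, n in enumerate(trait_names) if m >> j & 1))
    return out
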