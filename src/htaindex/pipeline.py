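"""End-to-end orchestration: input -> trait calling -> HTA -> inference -> files.

:func:`run_compute` is the engine behind the ``hta compute`` command. It
accepts either a spot table (thresholded at the per-trait median, or at fixed
cut-offs) or a pre-encoded label matrix, evaluates HTA and its permutation
null at one or more region sizes, and writes a deterministic JSON result
bundle plus optional region reports and renderings.

Each region size draws its own permutations (the region structure changes the
null), from a stream seeded by ``(seed, size index)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .core_stats import hta, region_report
from .errors import InputError
from .io import read_label_matrix, read_spot_table, write_json, write_label_matrix
from .null_inference import (
    estimate_null_moments,
    exact_null_moments,
    hta_p_values,
)
from .trait_calling import TraitCombinationMatrix, binarize_median, encode_combinations

logger = logging.getLogger("htaindex")


@dataclass
class RunConfig:
    """Resolved parameters of one analysis run."""

    input_path: Path
    out_prefix: Path
    input_kind: str = "spots"  # spots | labels
    dialect: Optional[str] = None
    traits: Optional[list[str]] = None
    threshold: str = "median"  # median | fixed:<value> | binarized
    c_mode: str = "observed"
    region_sizes: Sequence[int | tuple[int, ...]] = (8,)
    n_permutations: int = 1000
    seed: Optional[int] = None
    exact_null: bool = False
    report_regions: list[int] = field(default_factory=list)
    render: bool = False
    sentinel: str = ""

    def __post_init__(self) -> None:
        self.input_path = Path(self.input_path)
        self.out_prefix = Path(self.out_prefix)
        if not self.region_sizes:
            raise InputError("at least one region size is required")
        if not self.exact_null and self.n_permutations < 100:
            raise InputError(
                "the permutation path needs n_permutations >= 100 for stable moments"
            )
        if self.input_kind not in ("spots", "labels"):
            raise InputError(f"unknown input kind {self.input_kind!r}")


def _load_matrix(config: RunConfig) -> tuple[TraitCombinationMatrix, int]:
    """Read the input and return (label matrix, trait count)."""
    if config.input_kind == "labels":
        sidecar = config.input_path.with_suffix(config.input_path.suffix + ".json")
        matrix = read_label_matrix(
            config.input_path,
            sidecar=sidecar if sidecar.exists() else None,
            sentinel=config.sentinel,
        )
        n_traits = max((len(s) for s in matrix.decoding.values()), default=1)
        return matrix, n_traits

    table = read_spot_table(config.input_path, dialect=config.dialect)
    if config.traits:
        missing = [t for t in config.traits if t not in table.trait_names]
        if missing:
            raise InputError(f"traits not found in input: {missing}")
        cols = [table.trait_names.index(t) for t in config.traits]
        table = type(table)(
            coordinates=table.coordinates,
            values=table.values[:, cols],
            trait_names=list(config.traits),
        )
    if config.threshold == "median":
        tensor = binarize_median(table)
    elif config.threshold.startswith("fixed:"):
        cut = float(config.threshold.split(":", 1)[1])
        tensor = binarize_median(table, thresholds={t: cut for t in table.trait_names})
    elif config.threshold == "binarized":
        tensor = binarize_median(table, thresholds={t: 0.5 for t in table.trait_names})
    else:
        raise InputError(f"unknown threshold mode {config.threshold!r}")
    matrix = encode_combinations(tensor, c_mode=config.c_mode)
    return matrix, len(table.trait_names)


def run_compute(config: RunConfig) -> dict:
    """Execute the full analysis described by ``config``; return the result dict.

    Writes ``<prefix>.result.json`` and ``<prefix>.labels.tsv`` (with its
    ``.json`` decoding sidecar); optionally ``<prefix>.size<k>.report.tsv``
    and ``<prefix>.size<k>.map.png`` per region size.
    """
    matrix, n_traits = _load_matrix(config)
    logger.info(
        "input %s: shape=%s C=%d occupied=%d seed=%s",
        config.input_path,
        matrix.shape,
        matrix.C,
        matrix.n_occupied,
        config.seed,
    )

    config.out_prefix.parent.mkdir(parents=True, exist_ok=True)
    write_label_matrix(
        matrix,
        Path(str(config.out_prefix) + ".labels.tsv"),
        sidecar=Path(str(config.out_prefix) + ".labels.tsv.json"),
        sentinel=config.sentinel,
    )

    results: dict = {
        "version": __version__,
        "input": str(config.input_path),
        "n_traits": n_traits,
        "C": matrix.C,
        "c_mode": config.c_mode,
        "shape": list(matrix.shape),
        "n_occupied": matrix.n_occupied,
        "seed": config.seed,
        "by_region_size": [],
    }

    for k, size in enumerate(config.region_sizes):
        res = hta(matrix, size)
        size_seed = None if config.seed is None else int(config.seed) * 10_000 + k
        if config.exact_null:
            moments = exact_null_moments(matrix, size, n_traits=n_traits)
        else:
            moments = estimate_null_moments(
                matrix, size, n_permutations=config.n_permutations, seed=size_seed
            )
        pvals = hta_p_values(res, moments)
        entry = {
            "region_size": list(res.region_size),
            "hta": res.hta,
            "R": res.R,
            "C": res.C,
            "method": moments.method,
            "n_permutations": moments.n_permutations,
            "seed": size_seed,
            "mu_null": float(moments.weights @ moments.mu_r),
            "sigma_null": float(
                np.sqrt((moments.weights**2) @ (moments.sigma_r**2))
            ),
            "z": pvals.z,
            "p_homogeneity": pvals.p_homogeneity,
            "p_heterogeneity": pvals.p_heterogeneity,
            "p_overall": pvals.p_overall,
            "n_single_entry_regions": res.partition.n_single_entry_regions,
        }
        logger.info(
            "region_size=%s HTA=%.4f R=%d z=%.3f p_hom=%.3g p_het=%.3g",
            res.region_size,
            res.hta,
            res.R,
            pvals.z,
            pvals.p_homogeneity,
            pvals.p_heterogeneity,
        )

        if config.report_regions:
            report_path = Path(f"{config.out_prefix}.size{k}.report.tsv")
            with open(report_path, "w") as fh:
                fh.write("region_id\tbounds\tcombination\tcount\tfraction\n")
                for rid in config.report_regions:
                    rep = region_report(res.partition, matrix.decoding, rid)
                    for subset, count, frac in rep.entries:
                        fh.write(
                            f"{rep.region_id}\t{rep.bounds}\t{'+'.join(subset)}"
                            f"\t{count}\t{frac:.6f}\n"
                        )
            entry["report"] = str(report_path)

        if config.render:
            from .plotting import render_heterogeneity_map

            png = Path(f"{config.out_prefix}.size{k}.map.png")
            render_heterogeneity_map(matrix, res.partition, png)
            entry["map"] = str(png)

        results["by_region_size"].append(entry)

    write_json(results, Path(str(config.out_prefix) + ".result.json"))
    return results
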