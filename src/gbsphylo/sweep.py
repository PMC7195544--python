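"""Threshold sweeps: SNP-count curves and downstream topology stability.

Each filter threshold is swept over a grid while the rest of the
configuration is held fixed; the surviving SNP count (and optionally an
NJ tree plus its RF distance to the tree at the base setting) is
recorded per grid point.  This reproduces, on any matrix, the count-vs-
threshold curves used to pick the operating point of each filter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .filters import FilterConfig, apply_filters
from .genotype import GenotypeMatrix

SWEEPABLE = {
    "site_missing": "max_site_missing",
    "maf": "min_maf",
    "het": "min_het",
    "linkage": "min_link_dist",
    "depth_floor": "depth_value",
    "depth_ceiling": "depth_value",
}

# the explored ranges used as sweep defaults
DEFAULT_GRIDS = {
    "maf": [0.01, 0.02, 0.03, 0.04, 0.05, 0.06],
    "site_missing": [round(0.1 * k, 1) for k in range(1, 10)],
    "linkage": [0, 64, 128, 256],
}


@dataclass
class SweepResult:
    """SNP-count (and optional stability) curve for one rule."""

    rule: str
    grid: list
    snp_counts: list
    trees: list | None = None
    stability: list | None = None  # RF distance to the base-setting tree

    def to_frame(self) -> pd.DataFrame:
        data = {"threshold": self.grid, "snp_count": self.snp_counts}
        if self.stability is not None:
            data["rf_to_base"] = self.stability
        return pd.DataFrame(data)


def _config_for(rule: str, base: FilterConfig, value) -> FilterConfig:
    if rule == "depth_floor":
        return replace(base, depth_mode="floor_value", depth_value=value)
    if rule == "depth_ceiling":
        return replace(base, depth_mode="ceiling_value", depth_value=value)
    return replace(base, **{SWEEPABLE[rule]: value})


def sweep_filter(
    matrix: GenotypeMatrix,
    rule: str,
    grid: Sequence | None = None,
    base_config: FilterConfig = FilterConfig(),
    build_trees: bool = False,
    seed: int | None = None,
) -> SweepResult:
    """Sweep one rule's threshold over ``grid``, base config fixed.

    When ``build_trees`` is set, an NJ tree is built at every grid point
    and at the base setting, and the RF distance of each grid tree to
    the base tree is recorded as the stability curve.  The input matrix
    is never mutated.
    """
    from .phylo import nj_tree, pdistance_matrix, rf_distance

    if rule not in SWEEPABLE:
        raise ValueError(
            f"unknown sweep rule {rule!r}; choose from {sorted(SWEEPABLE)}"
        )
    if grid is None:
        grid = DEFAULT_GRIDS.get(rule)
    if grid is None or len(grid) == 0:
        raise ValueError("empty sweep grid")
    grid = list(grid)
    counts, trees, stability = [], [], []
    base_tree = None
    if build_trees:
        base_matrix, _ = apply_filters(matrix, base_config)
        base_tree = nj_tree(pdistance_matrix(base_matrix))
    for value in grid:
        filtered, _ = apply_filters(matrix, _config_for(rule, base_config, value))
        counts.append(filtered.n_sites)
        if build_trees:
            t = nj_tree(pdistance_matrix(filtered))
            trees.append(t)
            stability.append(rf_distance(t, base_tree).rf)
    return SweepResult(
        rule=rule,
        grid=grid,
        snp_counts=counts,
        trees=trees if build_trees else None,
        stability=stability if build_trees else None,
    )


@dataclass
class DepthSweepResult:
    """Floor and ceiling depth sweeps around a centre (usually the mean)."""

    thresholds: list
    floor_counts: list
    ceiling_counts: list
    plateau_floor: float | None
    plateau_ceiling: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "floor_snp_count": self.floor_counts,
                "ceiling_snp_count": self.ceiling_counts,
            }
        )


def _plateau(thresholds: Sequence[float], counts: Sequence[int]) -> float | None:
    """First threshold where the count change falls below 1%."""
    for prev_t, prev_c, t, c in zip(
        thresholds, counts, thresholds[1:], counts[1:]
    ):
        if abs(c - prev_c) <= 0.01 * max(prev_c, 1):
            return t
    return None


def depth_simulation(
    matrix: GenotypeMatrix,
    span: int = 3,
    base_config: FilterConfig | None = None,
) -> DepthSweepResult:
    """Probe how depth cutoffs around the mean change the SNP count.

    Sweeps a depth floor and a depth ceiling over the integer offsets
    [-span, +span] around the dataset mean call depth and reports the
    surviving SNP count in each direction, flagging the plateau point
    (first threshold where the count change drops below 1%).
    """
    if span < 0:
        raise ValueError("span must be >= 0")
    if base_config is None:
        base_config = FilterConfig(
            max_site_missing=None,
            max_sample_missing=None,
            min_maf=None,
            min_het=None,
            depth_mode="floor_mean",  # placeholder; overridden per point
            min_link_dist=None,
            drop_invariant=False,
        )
    mean = matrix.mean_depth()
    thresholds = [mean + k for k in range(-span, span + 1)]
    floor_counts, ceiling_counts = [], []
    for thr in thresholds:
        f, _ = apply_filters(
            matrix, _config_for("depth_floor", base_config, thr)
        )
        floor_counts.append(f.n_sites)
        c, _ = apply_filters(
            matrix, _config_for("depth_ceiling", base_config, thr)
        )
        ceiling_counts.append(c.n_sites)
    return DepthSweepResult(
        thresholds=thresholds,
        floor_counts=floor_counts,
        ceiling_counts=ceiling_counts,
        plateau_floor=_plateau(thresholds, floor_counts),
        plateau_ceiling=_plateau(thresholds, ceiling_counts),
    )
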