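"""Composable SNP-matrix filters with an order-logged report.

Boundary semantics, fixed and unit-tested per rule:

* sample / site missingness — keep iff missing fraction <= threshold
  for sites, strictly > removes for samples (">90% missing" discards);
* MAF and heterozygosity — keep iff value >= minimum (and <= optional
  maximum for het);
* depth floor / ceiling — a call strictly below the floor (or strictly
  above the ceiling) is set to missing; the floor may be the dataset
  mean call depth (real-valued, not rounded);
* linkage pruning — greedy left-to-right per contig: a site is removed
  when its distance to the last retained site is strictly below the
  minimum (default 128 bp, twice the 64-bp tag length).

Filters never mutate their input and are idempotent; ``apply_filters``
chains them in an explicit, logged order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_ORDER = (
    "sample_missing",
    "depth",
    "site_missing",
    "maf",
    "het",
    "invariant",
    "linkage",
)


@dataclass(frozen=True)
class FilterConfig:
    """Threshold settings for the filter chain.

    ``None`` disables the corresponding rule.  Defaults reproduce the
    composite setting missing < 50%, MAF >= 0.02, het >= 0.01, depth
    floor at the dataset mean, 128-bp linkage pruning, invariant-site
    removal.
    """

    max_site_missing: float | None = 0.50
    max_sample_missing: float | None = 0.90
    min_maf: float | None = 0.02
    min_het: float | None = 0.01
    max_het: float | None = None
    depth_mode: str = "floor_mean"  # floor_mean | floor_value | ceiling_value | none
    depth_value: float | None = None
    min_link_dist: int | None = 128
    drop_invariant: bool = True

    def __post_init__(self):
        for name in ("max_site_missing", "max_sample_missing", "min_maf",
                     "min_het", "max_het"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_link_dist is not None and self.min_link_dist < 0:
            raise ValueError("min_link_dist must be >= 0")
        if self.depth_mode not in {"floor_mean", "floor_value",
                                   "ceiling_value", "none"}:
            raise ValueError(f"unknown depth_mode {self.depth_mode!r}")
        if self.depth_mode in {"floor_value", "ceiling_value"} and (
            self.depth_value is None
        ):
            raise ValueError(f"depth_mode={self.depth_mode} needs depth_value")

    def enabled_rules(self) -> list[str]:
        rules = []
        if self.max_sample_missing is not None:
            rules.append("sample_missing")
        if self.depth_mode != "none":
            rules.append("depth")
        if self.max_site_missing is not None:
            rules.append("site_missing")
        if self.min_maf is not None:
            rules.append("maf")
        if self.min_het is not None or self.max_het is not None:
            rules.append("het")
        if self.drop_invariant:
            rules.append("invariant")
        if self.min_link_dist is not None:
            rules.append("linkage")
        return rules


IDENTITY_CONFIG = FilterConfig(
    max_site_missing=None,
    max_sample_missing=None,
    min_maf=None,
    min_het=None,
    max_het=None,
    depth_mode="none",
    min_link_dist=None,
    drop_invariant=False,
)


@dataclass
class FilterReport:
    """Ordered log of what each rule removed."""

    rows: list = field(default_factory=list)

    def add(self, rule: str, sites_before: int, sites_removed: int,
            samples_removed: int, threshold) -> None:
        self.rows.append(
            {
                "rule": rule,
                "sites_before": sites_before,
                "sites_removed": sites_removed,
                "samples_removed": samples_removed,
                "threshold": threshold,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["rule", "sites_before", "sites_removed",
                     "samples_removed", "threshold"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------
# individual rules
# ---------------------------------------------------------------------

def filter_sample_missing(
    matrix: GenotypeMatrix, max_sample_missing: float = 0.90
) -> GenotypeMatrix:
    """Drop samples with missing-call fraction strictly above threshold."""
    frac = matrix.sample_missing_frac()
    keep = frac <= max_sample_missing
    if not keep.any():
        raise ValueError("no samples survive the sample-missingness filter")
    if keep.all():
        return matrix.copy()
    return matrix.take_samples(keep)


def filter_site_missing(
    matrix: GenotypeMatrix, max_site_missing: float = 0.50
) -> GenotypeMatrix:
    """Keep sites whose missing fraction is <= threshold."""
    return matrix.take_sites(matrix.site_missing_frac() <= max_site_missing)


def filter_maf(matrix: GenotypeMatrix, min_maf: float = 0.02) -> GenotypeMatrix:
    """Keep sites with minor allele frequency >= ``min_maf``.

    Allele counts come from non-missing diploid calls (dosage 0/1/2).
    Monomorphic sites (MAF 0) fall whenever ``min_maf`` > 0; sites with
    zero non-missing calls are removed as well.
    """
    maf = matrix.maf()
    with np.errstate(invalid="ignore"):
        keep = maf >= min_maf
    keep &= ~np.isnan(maf)
    return matrix.take_sites(keep)


def filter_het(
    matrix: GenotypeMatrix,
    min_het: float | None = 0.01,
    max_het: float | None = None,
) -> GenotypeMatrix:
    """Keep sites whose observed heterozygosity lies in [min_het, max_het]."""
    h = matrix.het_rate()
    keep = ~np.isnan(h)
    if min_het is not None:
        with np.errstate(invalid="ignore"):
            keep &= h >= min_het
    if max_het is not None:
        with np.errstate(invalid="ignore"):
            keep &= h <= max_het
    return matrix.take_sites(keep)


def depth_threshold(matrix: GenotypeMatrix, depth_mode: str,
                    depth_value: float | None) -> float:
    if depth_mode == "floor_mean":
        return matrix.mean_depth()
    return float(depth_value)


def filter_depth(
    matrix: GenotypeMatrix,
    depth_mode: str = "floor_mean",
    depth_value: float | None = None,
) -> GenotypeMatrix:
    """Mask calls outside the depth threshold, then drop emptied sites.

    floor modes set calls with depth strictly below the threshold to
    missing; ceiling_value sets calls strictly above it to missing.
    The caller composes any re-application of missingness filters
    explicitly — nothing is implicit here.
    """
    if depth_mode == "none":
        raise ValueError("filter_depth called with depth_mode='none'")
    thr = depth_threshold(matrix, depth_mode, depth_value)
    out = matrix.copy()
    called = out.genotypes != MISSING
    if depth_mode in ("floor_mean", "floor_value"):
        mask = called & (out.depths < thr)
    else:  # ceiling_value
        mask = called & (out.depths > thr)
    out.genotypes[mask] = MISSING
    out.gq[mask] = np.nan
    emptied = (out.genotypes != MISSING).sum(axis=0) > 0
    return out.take_sites(emptied)


def drop_invariant(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Remove sites where all non-missing calls are one homozygote.

    An all-heterozygous site is polymorphic (both alleles present) and
    is kept.
    """
    return matrix.take_sites(~matrix.invariant_mask())


def prune_linked(
    matrix: GenotypeMatrix, min_link_dist: int = 128
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Greedy physical-distance thinning of positioned sites.

    Per contig, sites are scanned in position order and a site is
    removed when its distance to the last *retained* site is strictly
    below ``min_link_dist``.  Position ties prefer the site with fewer
    missing calls, then the lower site id.  Unpositioned sites (de novo
    tag pairs) pass through untouched with a warning.

    Returns the pruned matrix and a report listing each removed site
    and the retained neighbour that blocked it.
    """
    positioned = matrix.sites["positioned"].to_numpy(dtype=bool)
    if not positioned.all() and positioned.any():
        warnings.warn(
            f"{(~positioned).sum()} unpositioned site(s) pass through "
            "linkage pruning untouched",
            stacklevel=2,
        )
    elif not positioned.any() and matrix.n_sites:
        warnings.warn(
            "no positioned sites: linkage pruning is a no-op",
            stacklevel=2,
        )
    n_missing = (matrix.genotypes == MISSING).sum(axis=0)
    drop: list[int] = []
    removed_rows = []
    sub = matrix.sites.loc[positioned]
    for contig, group in sub.groupby("contig", sort=False):
        order = sorted(
            group.index,
            key=lambda i: (
                matrix.sites.at[i, "pos0"],
                n_missing[i],
                matrix.sites.at[i, "id"],
            ),
        )
        last_pos = None
        last_id = None
        for i in order:
            pos = matrix.sites.at[i, "pos0"]
            if last_pos is not None and abs(pos - last_pos) < min_link_dist:
                drop.append(i)
                removed_rows.append(
                    {
                        "removed_id": matrix.sites.at[i, "id"],
                        "contig": contig,
                        "pos0": pos,
                        "blocking_id": last_id,
                        "blocking_pos0": last_pos,
                        "distance": abs(pos - last_pos),
                    }
                )
            else:
                last_pos = pos
                last_id = matrix.sites.at[i, "id"]
    keep = np.ones(matrix.n_sites, dtype=bool)
    keep[drop] = False
    report = pd.DataFrame(
        removed_rows,
        columns=["removed_id", "contig", "pos0", "blocking_id",
                 "blocking_pos0", "distance"],
    )
    return matrix.take_sites(keep), report


# ---------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------

def apply_filters(
    matrix: GenotypeMatrix,
    config: FilterConfig = FilterConfig(),
    order: Sequence[str] | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the enabled rules in the given (or default) order.

    ``order`` must be a permutation of the enabled rules; each step is
    logged with sites before/removed, samples removed and the threshold
    actually used (the resolved mean for ``floor_mean``).
    """
    enabled = config.enabled_rules()
    if order is None:
        order = [r for r in DEFAULT_ORDER if r in enabled]
    else:
        unknown = set(order) - set(DEFAULT_ORDER)
        if unknown:
            raise ValueError(f"unknown filter rule(s): {sorted(unknown)}")
        if sorted(order) != sorted(enabled):
            raise ValueError(
                f"order {list(order)} is not a permutation of enabled "
                f"rules {enabled}"
            )
    report = FilterReport()
    current = matrix
    for rule in order:
        before_sites = current.n_sites
        before_samples = current.n_samples
        threshold: object
        if rule == "sample_missing":
            current = filter_sample_missing(current, config.max_sample_missing)
            threshold = config.max_sample_missing
        elif rule == "depth":
            threshold = depth_threshold(
                current, config.depth_mode, config.depth_value
            )
            current = filter_depth(
                current, config.depth_mode, config.depth_value
            )
            threshold = f"{config.depth_mode}:{threshold:g}"
        elif rule == "site_missing":
            current = filter_site_missing(current, config.max_site_missing)
            threshold = config.max_site_missing
        elif rule == "maf":
            current = filter_maf(current, config.min_maf)
            threshold = config.min_maf
        elif rule == "het":
            current = filter_het(current, config.min_het, config.max_het)
            threshold = (config.min_het, config.max_het)
        elif rule == "invariant":
            current = drop_invariant(current)
            threshold = None
        elif rule == "linkage":
            current, _ = prune_linked(current, config.min_link_dist)
            threshold = config.min_link_dist
        else:  # pragma: no cover
            raise ValueError(f"unknown rule {rule!r}")
        report.add(
            rule,
            before_sites,
            before_sites - current.n_sites,
            before_samples - current.n_samples,
            threshold,
        )
        logger.info(
            "filter %-14s threshold=%-18s sites %d -> %d, samples %d -> %d",
            rule, threshold, before_sites, current.n_sites,
            before_samples, current.n_samples,
        )
    return current, report
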