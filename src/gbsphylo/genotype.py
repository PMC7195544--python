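"""Diploid genotype calling and the SNP matrix container.

Calls are made from per-sample counts of reads supporting each of the two
alleles at a candidate site, under a symmetric-error binomial likelihood:

    L(AA) = C(d, b) * e^b * (1-e)^a
    L(BB) = C(d, b) * e^a * (1-e)^b
    L(AB) = C(d, b) * 0.5^d

with a, b the two allele depths, d = a + b and e the per-read error rate.
The genotype is the argmax; genotype quality (GQ) is the Phred-scaled gap
between the best and second-best likelihood, capped at 99.  Ties are broken
toward the heterozygote, then toward the reference homozygote, with GQ 0.

Genotypes are dosage-coded: 0 = homozygous reference/major allele, 1 =
heterozygous, 2 = homozygous alternate/minor allele, ``MISSING`` (-1) when
no call can be made (depth below ``min_depth``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

MISSING: int = -1
GQ_CAP: float = 99.0

_LOG10 = math.log(10.0)

SITE_COLUMNS = ["id", "contig", "pos0", "ref", "alt", "source", "positioned"]


class SiteCall(NamedTuple):
    """One diploid call: dosage genotype, read depth and Phred GQ."""

    genotype: int
    depth: int
    gq: float


def _log10_likelihoods(
    depth_a: np.ndarray, depth_b: np.ndarray, error_rate: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """log10 likelihoods of (hom-A, het, hom-B) for allele depth arrays."""
    a = np.asarray(depth_a, dtype=float)
    b = np.asarray(depth_b, dtype=float)
    d = a + b
    log10_comb = (gammaln(d + 1) - gammaln(a + 1) - gammaln(b + 1)) / _LOG10
    le = math.log10(error_rate)
    l1e = math.log10(1.0 - error_rate)
    l_aa = log10_comb + b * le + a * l1e
    l_bb = log10_comb + a * le + b * l1e
    l_ab = log10_comb + d * math.log10(0.5)
    return l_aa, l_ab, l_bb


def call_genotypes(
    depth_a,
    depth_b,
    error_rate: float = 0.01,
    min_depth: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised genotype calling.

    Parameters
    ----------
    depth_a, depth_b
        Arrays of per-call read counts supporting the reference (A) and
        alternate (B) allele.  Any shape; broadcast together.
    error_rate
        Per-read probability that a read shows the wrong allele
        (0 < error_rate < 0.5).
    min_depth
        Calls with total depth below this are set to ``MISSING``.

    Returns
    -------
    genotypes : int8 array (0/1/2 or MISSING)
    gq : float array, Phred-scaled gap best vs. second-best, capped at 99;
         NaN where the call is missing.
    """
    if not 0.0 < error_rate < 0.5:
        raise ValueError(f"error_rate must be in (0, 0.5), got {error_rate}")
    a = np.asarray(depth_a)
    b = np.asarray(depth_b)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("allele depths must be non-negative")
    a, b = np.broadcast_arrays(a, b)
    l_aa, l_ab, l_bb = _log10_likelihoods(a, b, error_rate)
    # order (het, hom-ref, hom-alt) so that np.argmax's first-wins rule
    # implements the tie-break: het, then genotype 0.
    stacked = np.stack([l_ab, l_aa, l_bb])
    order = np.argmax(stacked, axis=0)
    genotypes = np.array([1, 0, 2], dtype=np.int8)[order]
    top2 = np.sort(stacked, axis=0)[-2:]
    gq = np.minimum(10.0 * (top2[1] - top2[0]), GQ_CAP)
    missing = (a + b) < min_depth
    genotypes = np.where(missing, np.int8(MISSING), genotypes)
    gq = np.where(missing, np.nan, gq)
    return genotypes.astype(np.int8), gq


def call_genotype(
    depth_a: int,
    depth_b: int,
    error_rate: float = 0.01,
    min_depth: int = 1,
) -> SiteCall:
    """Call a single site from its two allele depths (scalar front end)."""
    g, q = call_genotypes(
        np.array([depth_a]), np.array([depth_b]), error_rate, min_depth
    )
    gq = float(q[0])
    return SiteCall(int(g[0]), int(depth_a) + int(depth_b), gq)


def _empty_sites() -> pd.DataFrame:
    return pd.DataFrame(columns=SITE_COLUMNS)


@dataclass
class GenotypeMatrix:
    """Samples x sites table of diploid calls with depth and GQ.

    Attributes
    ----------
    samples
        Ordered sample identifiers (rows).
    sites
        One row per site, columns ``id, contig, pos0, ref, alt, source,
        positioned``.  ``pos0`` is 0-based; writers convert to 1-based.
        ``positioned`` marks sites with genuine genomic coordinates
        (reference-mapped); de novo tag-pair sites are unpositioned.
    genotypes, depths, gq
        (n_samples, n_sites) arrays: int8 dosage codes (MISSING = -1),
        int32 total read depth, float GQ (NaN where missing).
    """

    samples: list[str]
    sites: pd.DataFrame
    genotypes: np.ndarray
    depths: np.ndarray
    gq: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.sites = self.sites.reset_index(drop=True)
        shape = (len(self.samples), len(self.sites))
        for name in ("genotypes", "depths", "gq"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {shape}"
                )
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.depths = np.asarray(self.depths, dtype=np.int32)
        self.gq = np.asarray(self.gq, dtype=float)
        ids = self.sites["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate site id: {dup!r}")

    # -- shape ---------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.samples),
            self.sites.copy(),
            self.genotypes.copy(),
            self.depths.copy(),
            self.gq.copy(),
        )

    # -- subsetting ----------------------------------------------------
    def take_sites(self, index) -> "GenotypeMatrix":
        """New matrix restricted to the given site index/bool mask."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            list(self.samples),
            self.sites.iloc[index].reset_index(drop=True),
            self.genotypes[:, index].copy(),
            self.depths[:, index].copy(),
            self.gq[:, index].copy(),
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            [self.samples[i] for i in index],
            self.sites.copy(),
            self.genotypes[index, :].copy(),
            self.depths[index, :].copy(),
            self.gq[index, :].copy(),
        )

    def select_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return self.take_samples([pos[n] for n in names])

    # -- per-site / per-sample statistics -----------------------------
    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def site_missing_frac(self) -> np.ndarray:
        return self.missing_mask().mean(axis=0)

    def sample_missing_frac(self) -> np.ndarray:
        return self.missing_mask().mean(axis=1)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per site over non-missing diploid calls.

        Sites with zero non-missing calls get NaN.
        """
        g = self.genotypes
        ok = g != MISSING
        n_ok = ok.sum(axis=0)
        alt = np.where(ok, g, 0).sum(axis=0)  # alt-allele dosage sum
        with np.errstate(invalid="ignore", divide="ignore"):
            p_alt = alt / (2.0 * n_ok)
            out = np.minimum(p_alt, 1.0 - p_alt)
        out = np.where(n_ok == 0, np.nan, out)
        return out

    def het_rate(self) -> np.ndarray:
        """Observed heterozygosity per site (het / non-missing); NaN if none."""
        g = self.genotypes
        ok = g != MISSING
        n_ok = ok.sum(axis=0)
        het = (g == 1).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = het / n_ok
        return np.where(n_ok == 0, np.nan, out)

    def mean_depth(self) -> float:
        """Mean read depth over non-missing calls (real-valued)."""
        ok = ~self.missing_mask()
        if not ok.any():
            return float("nan")
        return float(self.depths[ok].mean())

    def invariant_mask(self) -> np.ndarray:
        """True for sites where all non-missing calls are one homozygote."""
        g = self.genotypes
        ok = g != MISSING
        n_ok = ok.sum(axis=0)
        all0 = np.where(ok, g == 0, True).all(axis=0)
        all2 = np.where(ok, g == 2, True).all(axis=0)
        return (all0 | all2) | (n_ok == 0)

    # -- comparison ----------------------------------------------------
    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and list(self.sites["id"]) == list(other.sites["id"])
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.depths, other.depths)
            and np.allclose(self.gq, other.gq, equal_nan=True)
        )


def build_matrix(
    candidates,
    samples: Sequence[str] | None = None,
    *,
    reference: Mapping[str, str] | None = None,
    error_rate: float = 0.01,
    min_depth: int = 1,
) -> GenotypeMatrix:
    """Assemble a :class:`GenotypeMatrix` from candidate SNPs.

    ``candidates`` is either a collection of de novo tag pairs, in which
    case per-sample allele depths are the two tag count vectors, or a
    collection of reference placements together with ``reference=``, in
    which case allele depths are the per-sample counts of placed tags
    carrying each base at every candidate site.
    """
    if reference is not None:
        return matrix_from_placements(
            candidates,
            reference,
            samples,
            error_rate=error_rate,
            min_depth=min_depth,
        )
    return matrix_from_pairs(
        candidates, samples, error_rate=error_rate, min_depth=min_depth
    )


def _sample_universe(counts_iter: Iterable[Mapping[str, int]]) -> list[str]:
    seen: set[str] = set()
    for counts in counts_iter:
        seen.update(counts)
    return sorted(seen)


def matrix_from_pairs(
    pairs,
    samples: Sequence[str] | None = None,
    *,
    error_rate: float = 0.01,
    min_depth: int = 1,
) -> GenotypeMatrix:
    """Genotype matrix from de novo tag pairs.

    Each pair becomes one site on a synthetic per-pair contig
    (``pair00001`` ...) at tag-centre position (0-based 32 for 64-bp
    tags, written as 33 in VCF).  The reference allele of the site is the
    major tag's allele (``allele_a``).
    """
    pairs = sorted(pairs, key=lambda p: p.key)
    if samples is None:
        samples = _sample_universe(
            c for p in pairs for c in (p.tag_a.counts, p.tag_b.counts)
        )
    samples = list(samples)
    n_s, n_p = len(samples), len(pairs)
    depth_a = np.zeros((n_s, n_p), dtype=np.int32)
    depth_b = np.zeros((n_s, n_p), dtype=np.int32)
    rows = []
    for j, p in enumerate(pairs):
        tag_len = len(p.tag_a.sequence)
        rows.append(
            {
                "id": f"pair{j + 1:05d}",
                "contig": f"pair{j + 1:05d}",
                "pos0": tag_len // 2,
                "ref": p.allele_a,
                "alt": p.allele_b,
                "source": "denovo",
                "positioned": False,
            }
        )
        for i, s in enumerate(samples):
            depth_a[i, j] = p.tag_a.counts.get(s, 0)
            depth_b[i, j] = p.tag_b.counts.get(s, 0)
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS) if rows else _empty_sites()
    genotypes, gq = call_genotypes(depth_a, depth_b, error_rate, min_depth)
    return GenotypeMatrix(samples, sites, genotypes, depth_a + depth_b, gq)


def matrix_from_placements(
    placements,
    reference: Mapping[str, str],
    samples: Sequence[str] | None = None,
    *,
    error_rate: float = 0.01,
    min_depth: int = 1,
) -> GenotypeMatrix:
    """Genotype matrix from reference-mapped tags.

    Runs the pileup (see :func:`gbsphylo.tags.placements_to_sites`) and,
    at each biallelic candidate site, accumulates per-sample depths of
    the reference and alternate base from the count vectors of the tags
    covering the site.
    """
    from .tags import placements_to_sites

    sites_df, _stats, pileup = placements_to_sites(
        placements, reference, return_pileup=True
    )
    if samples is None:
        samples = _sample_universe(p.tag.counts for p in placements)
    samples = list(samples)
    s_index = {s: i for i, s in enumerate(samples)}
    n_s, n_sites = len(samples), len(sites_df)
    depth_a = np.zeros((n_s, n_sites), dtype=np.int32)
    depth_b = np.zeros((n_s, n_sites), dtype=np.int32)
    rows = []
    for j, rec in enumerate(sites_df.itertuples(index=False)):
        rows.append(
            {
                "id": f"{rec.contig}:{rec.pos0 + 1}",
                "contig": rec.contig,
                "pos0": rec.pos0,
                "ref": rec.ref,
                "alt": rec.alt,
                "source": "reference",
                "positioned": True,
            }
        )
        for base, counts in pileup[(rec.contig, rec.pos0)].items():
            if base == rec.ref:
                target = depth_a
            elif base == rec.alt:
                target = depth_b
            else:  # pragma: no cover - excluded by biallelic site contract
                continue
            for sample, c in counts.items():
                target[s_index[sample], j] += c
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS) if rows else _empty_sites()
    genotypes, gq = call_genotypes(depth_a, depth_b, error_rate, min_depth)
    return GenotypeMatrix(samples, sites, genotypes, depth_a + depth_b, gq)


def align_matrices(
    a: GenotypeMatrix,
    b: GenotypeMatrix,
    site_map: Mapping[str, str],
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Restrict two matrices to mapped shared sites with harmonised alleles.

    ``site_map`` maps site ids of ``a`` to site ids of ``b``.  Shared
    samples are intersected (order of ``a`` kept).  Where the two
    matrices label the same site with swapped alleles, the genotypes of
    ``b`` are flipped (0 <-> 2) so dosage codes are directly comparable.
    """
    shared_samples = [s for s in a.samples if s in set(b.samples)]
    a = a.select_samples(shared_samples)
    b = b.select_samples(shared_samples)
    b_index = {sid: j for j, sid in enumerate(b.sites["id"])}
    a_keep, b_keep, flip = [], [], []
    for i, sid in enumerate(a.sites["id"]):
        tgt = site_map.get(sid)
        if tgt is None or tgt not in b_index:
            continue
        j = b_index[tgt]
        ra, aa = a.sites.at[i, "ref"], a.sites.at[i, "alt"]
        rb, ab = b.sites.at[j, "ref"], b.sites.at[j, "alt"]
        if (ra, aa) == (rb, ab):
            flip.append(False)
        elif (ra, aa) == (ab, rb):
            flip.append(True)
        else:
            continue  # allele labels irreconcilable; not a shared site
        a_keep.append(i)
        b_keep.append(j)
    a2 = a.take_sites(np.array(a_keep, dtype=int))
    b2 = b.take_sites(np.array(b_keep, dtype=int))
    flip_arr = np.array(flip, dtype=bool)
    if flip_arr.any():
        g = b2.genotypes
        cols = np.flatnonzero(flip_arr)
        sub = g[:, cols]
        swapped = np.where(sub == 0, np.int8(2), np.where(sub == 2, np.int8(0), sub))
        g[:, cols] = swapped
        b2.sites.loc[cols, ["ref", "alt"]] = b2.sites.loc[
            cols, ["alt", "ref"]
        ].to_numpy()
    return a2, b2
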