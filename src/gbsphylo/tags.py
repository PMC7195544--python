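"""Raw reads -> candidate SNPs, by both GBS discovery routes.

De novo route: barcoded reads are demultiplexed, trimmed to fixed-length
tags (64 bp by default), identical reads collapsed into tags with
per-sample counts, and tags differing at exactly one base paired into
candidate biallelic SNPs, followed by a network error filter.

Reference route: tags are placed on a reference genome by ungapped
search on both strands; only tags with a unique best placement are kept,
and a pileup over placements yields candidate sites where tags disagree
with the reference or each other.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .io import BarcodeKey, ReadRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Tag:
    """A distinct fixed-length sequence with per-sample read counts."""

    __slots__ = ("sequence", "counts", "total")

    def __init__(self, sequence: str, counts: Mapping[str, int]):
        self.sequence = sequence
        self.counts = {s: int(c) for s, c in counts.items() if c > 0}
        self.total = sum(self.counts.values())
        if self.total < 1:
            raise ValueError(f"tag {sequence!r} has no reads")

    def __eq__(self, other) -> bool:
        return isinstance(other, Tag) and self.sequence == other.sequence

    def __hash__(self) -> int:
        return hash(self.sequence)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tag({self.sequence!r}, total={self.total})"


class TagPair:
    """Two tags at Hamming distance 1 — a candidate biallelic SNP.

    ``tag_a`` is the major tag (higher total read count; ties broken by
    lexicographically smaller sequence), so ``allele_a`` plays the role
    of the provisional reference/major allele downstream.
    """

    __slots__ = ("tag_a", "tag_b", "snp_offset", "allele_a", "allele_b")

    def __init__(self, tag_a: Tag, tag_b: Tag):
        if len(tag_a.sequence) != len(tag_b.sequence):
            raise ValueError("tags in a pair must have equal length")
        diffs = [
            i
            for i, (x, y) in enumerate(zip(tag_a.sequence, tag_b.sequence))
            if x != y
        ]
        if len(diffs) != 1:
            raise ValueError(
                f"tags differ at {len(diffs)} positions, expected exactly 1"
            )
        if (tag_b.total, tag_a.sequence) > (tag_a.total, tag_b.sequence):
            tag_a, tag_b = tag_b, tag_a
        self.tag_a = tag_a
        self.tag_b = tag_b
        self.snp_offset = diffs[0]
        self.allele_a = tag_a.sequence[self.snp_offset]
        self.allele_b = tag_b.sequence[self.snp_offset]

    @property
    def key(self) -> tuple[str, str]:
        """Order-independent identity of the pair."""
        return tuple(sorted((self.tag_a.sequence, self.tag_b.sequence)))

    def __eq__(self, other) -> bool:
        return isinstance(other, TagPair) and self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"TagPair(offset={self.snp_offset}, "
            f"{self.allele_a}/{self.allele_b}, "
            f"totals=({self.tag_a.total},{self.tag_b.total}))"
        )


@dataclass(frozen=True)
class TagPlacement:
    """Unique best ungapped placement of a tag on the reference."""

    tag: Tag
    contig: str
    start: int  # 0-based
    strand: str  # '+' or '-'
    mismatches: tuple[tuple[int, str, str], ...]  # (ref offset, ref, tag base)

    def oriented_sequence(self) -> str:
        """Tag sequence expressed on the reference (+) strand."""
        s = self.tag.sequence
        return s if self.strand == "+" else revcomp(s)


# ---------------------------------------------------------------------
# demultiplexing / collapsing / pairing
# ---------------------------------------------------------------------

def demultiplex_and_trim(
    reads: Iterable[ReadRecord],
    key: BarcodeKey,
    tag_length: int = 64,
) -> tuple[dict[str, list[str]], Counter]:
    """Assign reads to samples by barcode prefix and trim to tags.

    The longest barcode matching the read prefix wins.  The
    ``tag_length`` bases after the barcode are kept; reads with no
    matching barcode, an N in the kept window, or too few bases are
    discarded and counted by reason.
    """
    if tag_length < 1:
        raise ValueError("tag_length must be >= 1")
    if not key.entries:
        raise ValueError("empty barcode key")
    by_len = sorted({len(b) for _, b in key.entries}, reverse=True)
    lookup = {b: s for s, b in key.entries}
    per_sample: dict[str, list[str]] = {s: [] for s, _ in key.entries}
    counters: Counter = Counter()
    for read in reads:
        seq = read.sequence
        sample = None
        for L in by_len:  # longest barcode match wins
            sample = lookup.get(seq[:L])
            if sample is not None:
                bc_len = L
                break
        if sample is None:
            counters["no_barcode"] += 1
            continue
        window = seq[bc_len : bc_len + tag_length]
        if len(window) < tag_length:
            counters["too_short"] += 1
            continue
        if "N" in window:
            counters["ambiguous_base"] += 1
            continue
        per_sample[sample].append(window)
        counters["assigned"] += 1
    return per_sample, counters


def collapse_tags(per_sample: Mapping[str, Sequence[str]]) -> list[Tag]:
    """Collapse identical sequences into tags with per-sample counts.

    Returns tags sorted by sequence (canonical order, so downstream
    results are independent of input order).  Read counts are conserved:
    sum of tag totals equals the number of input sequences.
    """
    lengths = {
        len(s) for seqs in per_sample.values() for s in seqs
    }
    if len(lengths) > 1:
        raise ValueError(f"mixed sequence lengths: {sorted(lengths)}")
    counts: dict[str, Counter] = defaultdict(Counter)
    for sample, seqs in per_sample.items():
        for s in seqs:
            counts[s][sample] += 1
    return [Tag(seq, counts[seq]) for seq in sorted(counts)]


def pair_tags(tags: Iterable[Tag]) -> list[TagPair]:
    """All unordered tag pairs at Hamming distance exactly 1.

    Neighbourhood hashing: two equal-length tags differ at exactly one
    position iff they collide in exactly one of the L "mask position i"
    buckets, so each qualifying pair is produced exactly once.
    """
    tags = sorted(set(tags), key=lambda t: t.sequence)
    if not tags:
        return []
    lengths = {len(t.sequence) for t in tags}
    if len(lengths) > 1:
        raise ValueError(f"mixed tag lengths: {sorted(lengths)}")
    (L,) = lengths
    pairs: list[TagPair] = []
    for i in range(L):
        buckets: dict[str, list[Tag]] = defaultdict(list)
        for t in tags:
            buckets[t.sequence[:i] + t.sequence[i + 1 :]].append(t)
        for group in buckets.values():
            if len(group) < 2:
                continue
            for x in range(len(group)):
                for y in range(x + 1, len(group)):
                    pairs.append(TagPair(group[x], group[y]))
    pairs.sort(key=lambda p: p.key)
    return pairs


def network_error_filter(
    pairs: Iterable[TagPair],
    etr: float = 0.03,
    allow_complex: bool = False,
) -> tuple[list[TagPair], dict[str, int]]:
    """Drop putative sequencing-error pairs and tangled tag networks.

    Rule 1 (error-tolerance rate): a pair is dropped when the rarer
    tag's share of the pair's reads, min(a, b) / (a + b), is below
    ``etr`` — the rare tag looks like a sequencing error of the common
    one.  Rule 2 (reciprocal networks): unless ``allow_complex``, any
    tag participating in more than one surviving pair has all its pairs
    dropped, so only clean 1-to-1 tag networks remain.
    """
    if not 0.0 <= etr < 0.5:
        raise ValueError("etr must be in [0, 0.5)")
    pairs = list(pairs)
    stats = {"input": len(pairs), "dropped_etr": 0, "dropped_complex": 0}
    survivors = []
    for p in pairs:
        lo = min(p.tag_a.total, p.tag_b.total)
        if lo / (p.tag_a.total + p.tag_b.total) < etr:
            stats["dropped_etr"] += 1
        else:
            survivors.append(p)
    if not allow_complex:
        degree: Counter = Counter()
        for p in survivors:
            degree[p.tag_a.sequence] += 1
            degree[p.tag_b.sequence] += 1
        kept = [
            p
            for p in survivors
            if degree[p.tag_a.sequence] == 1 and degree[p.tag_b.sequence] == 1
        ]
        stats["dropped_complex"] = len(survivors) - len(kept)
        survivors = kept
    stats["kept"] = len(survivors)
    return survivors, stats


# ---------------------------------------------------------------------
# reference mapping
# ---------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class _SeedIndex:
    """Pigeonhole seed index over a reference for ungapped tag search.

    A tag placed with <= k mismatches must match the reference exactly
    in at least one of k+1 non-overlapping chunks, so exact hits of each
    chunk anchor the candidate placements to verify.
    """

    def __init__(self, reference: Mapping[str, str], tag_length: int, k: int):
        self.tag_length = tag_length
        bounds = np.linspace(0, tag_length, k + 2).astype(int)
        self.chunks = [
            (int(bounds[i]), int(bounds[i + 1])) for i in range(k + 1)
        ]
        self.encoded = {c: _encode(s) for c, s in reference.items()}
        # one dict per chunk length: substring -> [(contig, pos), ...]
        self.index: dict[int, dict[str, list[tuple[str, int]]]] = {}
        for clen in {b - a for a, b in self.chunks}:
            d: dict[str, list[tuple[str, int]]] = defaultdict(list)
            for contig, seq in reference.items():
                for p in range(len(seq) - clen + 1):
                    d[seq[p : p + clen]].append((contig, p))
            self.index[clen] = d

    def candidates(self, seq: str) -> set[tuple[str, int]]:
        out: set[tuple[str, int]] = set()
        for a, b in self.chunks:
            hits = self.index[b - a].get(seq[a:b])
            if not hits:
                continue
            for contig, p in hits:
                start = p - a
                if start >= 0 and start + self.tag_length <= len(
                    self.encoded[contig]
                ):
                    out.add((contig, start))
        return out


def map_tags(
    tags: Iterable[Tag],
    reference: Mapping[str, str],
    max_mismatch: int = 3,
) -> tuple[list[TagPlacement], dict[str, float]]:
    """Place tags on the reference by ungapped search on both strands.

    A tag is kept iff it has exactly one placement achieving its minimum
    mismatch count (<= ``max_mismatch``); ties at the minimum make it a
    multimapper, which is discarded.  Returns the unique placements and
    the fractions of input tags kept / unaligned / multimapped (summing
    to 1).
    """
    tags = sorted(set(tags), key=lambda t: t.sequence)
    if not reference or not any(reference.values()):
        raise ValueError("reference is empty")
    if not tags:
        return [], {"kept_frac": 0.0, "unaligned_frac": 0.0,
                    "multimapped_frac": 0.0}
    lengths = {len(t.sequence) for t in tags}
    if len(lengths) > 1:
        raise ValueError(f"mixed tag lengths: {sorted(lengths)}")
    (L,) = lengths
    index = _SeedIndex(reference, L, max_mismatch)
    placements: list[TagPlacement] = []
    n_unaligned = n_multi = 0
    for tag in tags:
        hits: list[tuple[int, str, int, str, np.ndarray]] = []
        for strand, seq in (("+", tag.sequence), ("-", revcomp(tag.sequence))):
            enc = _encode(seq)
            for contig, start in sorted(index.candidates(seq)):
                window = index.encoded[contig][start : start + L]
                diff = window != enc
                nm = int(diff.sum())
                if nm <= max_mismatch:
                    hits.append((nm, contig, start, strand, diff))
        if not hits:
            n_unaligned += 1
            continue
        best = min(h[0] for h in hits)
        best_hits = [h for h in hits if h[0] == best]
        if len(best_hits) > 1:
            n_multi += 1
            continue
        nm, contig, start, strand, diff = best_hits[0]
        oriented = tag.sequence if strand == "+" else revcomp(tag.sequence)
        mm = tuple(
            (int(o), chr(index.encoded[contig][start + o]), oriented[o])
            for o in np.flatnonzero(diff)
        )
        placements.append(TagPlacement(tag, contig, start, strand, mm))
    n = len(tags)
    stats = {
        "kept_frac": len(placements) / n,
        "unaligned_frac": n_unaligned / n,
        "multimapped_frac": n_multi / n,
    }
    return placements, stats


def placements_to_sites(
    placements: Sequence[TagPlacement],
    reference: Mapping[str, str],
    return_pileup: bool = False,
):
    """Candidate biallelic SNP sites from a pileup of placed tags.

    Every reference position covered by at least one placed tag where
    the observed bases (tag bases plus the reference base) form exactly
    two alleles yields a site; positions showing more than two alleles
    are discarded and counted.

    Returns ``(sites, stats)`` — sites as a DataFrame with columns
    contig, pos0, ref, alt — or ``(sites, stats, pileup)`` when
    ``return_pileup`` is set, where pileup maps (contig, pos0) to
    {base: {sample: depth}}.
    """
    import pandas as pd

    pileup: dict[tuple[str, int], dict[str, Counter]] = defaultdict(
        lambda: defaultdict(Counter)
    )
    for pl in placements:
        oriented = pl.oriented_sequence()
        for off, base in enumerate(oriented):
            cell = pileup[(pl.contig, pl.start + off)][base]
            for sample, c in pl.tag.counts.items():
                cell[sample] += c
    rows = []
    n_triallelic = 0
    for (contig, pos0) in sorted(pileup):
        ref_base = reference[contig][pos0]
        observed = set(pileup[(contig, pos0)]) | {ref_base}
        if len(observed) == 1:
            continue
        if len(observed) > 2:
            n_triallelic += 1
            continue
        (alt,) = observed - {ref_base}
        rows.append(
            {"contig": contig, "pos0": pos0, "ref": ref_base, "alt": alt}
        )
    sites = pd.DataFrame(rows, columns=["contig", "pos0", "ref", "alt"])
    stats = {"n_sites": len(sites), "n_multiallelic_discarded": n_triallelic}
    if return_pileup:
        return sites, stats, pileup
    return sites, stats


def anchor_pairs(
    pairs: Sequence[TagPair],
    reference: Mapping[str, str],
    max_mismatch: int = 3,
) -> "pd.DataFrame":
    """Genomic coordinates for de novo tag pairs, via the major tag.

    Maps each pair's major tag onto the reference; uniquely placed pairs
    get the genomic contig and SNP position (strand-aware) plus both
    alleles expressed on the reference strand.  Pairs whose tag cannot
    be placed uniquely are omitted.  Used to apply position-based rules
    (e.g. linkage pruning) and cross-route comparisons to de novo sites.
    """
    import pandas as pd

    by_seq = {}
    for j, p in enumerate(pairs):
        by_seq[p.tag_a.sequence] = (j, p)
    placements, _ = map_tags(
        [p.tag_a for _, p in by_seq.values()], reference, max_mismatch
    )
    rows = []
    for pl in placements:
        j, pair = by_seq[pl.tag.sequence]
        L = len(pl.tag.sequence)
        if pl.strand == "+":
            pos0 = pl.start + pair.snp_offset
            a_a, a_b = pair.allele_a, pair.allele_b
        else:
            pos0 = pl.start + (L - 1 - pair.snp_offset)
            a_a, a_b = revcomp(pair.allele_a), revcomp(pair.allele_b)
        rows.append(
            {
                "pair_index": j,
                "contig": pl.contig,
                "pos0": pos0,
                "allele_a": a_a,
                "allele_b": a_b,
            }
        )
    return pd.DataFrame(
        rows, columns=["pair_index", "contig", "pos0", "allele_a", "allele_b"]
    ).sort_values("pair_index", ignore_index=True)


# ---------------------------------------------------------------------
# tag dump TSV
# ---------------------------------------------------------------------

def write_tags_tsv(tags: Iterable[Tag], path) -> None:
    """Dump tags as TSV: sequence <TAB> sample=count,sample=count,..."""
    with open(path, "w") as fh:
        fh.write("sequence\tcounts\n")
        for t in sorted(tags, key=lambda t: t.sequence):
            counts = ",".join(
                f"{s}={c}" for s, c in sorted(t.counts.items())
            )
            fh.write(f"{t.sequence}\t{counts}\n")


def read_tags_tsv(path) -> list[Tag]:
    tags = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sequence"):
            raise ValueError(f"{path}: missing tag TSV header")
        for line in fh:
            seq, counts_s = line.rstrip("\n").split("\t")
            counts = {}
            for item in counts_s.split(","):
                s, c = item.rsplit("=", 1)
                counts[s] = int(c)
            tags.append(Tag(seq, counts))
    return tags
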