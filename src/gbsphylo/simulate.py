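"""Synthetic GBS datasets with known truth.

The generator emulates the data regime the toolkit is built for:
barcoded single-end reads carrying 64-bp restriction-site tags, sampled
from a known species tree, with negative-binomial per-sample depth
variation around a GBS-like mean (~7x), optional sequencing error and
locus dropout.  Every dataset comes with its truth table — the species
and sample trees, the complete error-free genotype matrix, locus
coordinates and the reference sequence — so each pipeline stage can be
checked against ground truth without any download.

Genotypes are species-fixed by default (no incomplete lineage sorting):
each locus carries exactly one biallelic SNP placed on a tree branch
with probability proportional to branch length, and every sample of a
derived species is homozygous for the derived allele.  This makes tree
recovery exact and testable; ``het_rate`` adds optional within-species
polymorphism by turning calls heterozygous at random.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .genotype import SITE_COLUMNS, GenotypeMatrix
from .io import BarcodeKey, ReadRecord, write_barcode_key, write_fasta, write_fastq
from .phylo import Tree

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic GBS dataset.

    Defaults follow the regime the toolkit targets: 64-bp tags, mean
    depth 7 with overdispersion, species-fixed biallelic loci spaced
    200 bp apart so linkage pruning is exercisable.
    """

    n_species: int = 8
    n_samples_per_species: int = 3
    tree: str = "random_yule"  # or a newick string
    n_loci: int = 500
    tag_length: int = 64
    mean_depth: float = 7.0
    depth_dispersion: float = 1.5
    error_rate: float = 0.0
    missing_rate: float = 0.0
    het_rate: float = 0.0
    locus_gap: int = 200
    loci_per_contig: int = 50
    barcode_length: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.tag_length < 2:
            raise ValueError("tag_length must be >= 2")
        for name in ("error_rate", "missing_rate", "het_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("mean_depth and depth_dispersion must be > 0")
        if self.locus_gap < 0:
            raise ValueError("locus_gap must be >= 0")


@dataclass
class TruthTable:
    """Ground truth accompanying a simulated dataset."""

    species_tree: Tree
    sample_tree: Tree
    genotypes: GenotypeMatrix  # complete, error-free; depths are the drawn depths
    loci: pd.DataFrame
    reference: dict
    linked_removed_expected: list = field(default_factory=list)


@dataclass
class SimResult:
    """A simulated dataset: reads + key + truth + provenance."""

    config: SimulationConfig
    key: BarcodeKey
    reads: list
    truth: TruthTable
    edges: list  # (length, frozenset of derived species); mutation targets

    def write_outputs(self, outdir) -> dict:
        """Write FASTQ, barcode key, reference FASTA, truth VCF + newick."""
        from .io import write_vcf

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fastq": outdir / "reads.fastq",
            "key": outdir / "barcodes.tsv",
            "reference": outdir / "reference.fasta",
            "truth_vcf": outdir / "truth.vcf",
            "truth_tree": outdir / "truth_species.nwk",
            "truth_sample_tree": outdir / "truth_samples.nwk",
        }
        write_fastq(self.reads, paths["fastq"])
        write_barcode_key(self.key, paths["key"])
        write_fasta(self.truth.reference, paths["reference"])
        write_vcf(self.truth.genotypes, paths["truth_vcf"])
        paths["truth_tree"].write_text(self.truth.species_tree.to_newick() + "\n")
        paths["truth_sample_tree"].write_text(
            self.truth.sample_tree.to_newick() + "\n"
        )
        return paths


# ---------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------

def _species_tree(config: SimulationConfig, pyrng: random.Random) -> dendropy.Tree:
    if config.tree == "random_yule":
        from dendropy.model import birthdeath

        dtree = birthdeath.birth_death_tree(
            birth_rate=1.0,
            death_rate=0.0,
            num_extant_tips=config.n_species,
            rng=pyrng,
        )
        # the process stops at the n-th speciation, leaving the newest
        # tips with zero-length branches; extend all tips by the waiting
        # time to the next (uncommitted) speciation so every species is
        # genetically distinct.
        extra = pyrng.expovariate(config.n_species * 1.0)
        for i, leaf in enumerate(dtree.leaf_node_iter(), 1):
            leaf.taxon.label = f"sp{i:02d}"
            leaf.edge.length = (leaf.edge.length or 0.0) + extra
    else:
        dtree = dendropy.Tree.get(
            data=config.tree,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        n = len(dtree.leaf_nodes())
        if n != config.n_species:
            raise ValueError(
                f"tree has {n} leaves but n_species={config.n_species}"
            )
    return dtree


def _mutation_edges(dtree: dendropy.Tree) -> list:
    """(length, derived species set) per edge below the seed node."""
    all_species = frozenset(
        lf.taxon.label for lf in dtree.leaf_node_iter()
    )
    edges = []
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            continue
        derived = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if not derived or derived == all_species:
            continue
        length = node.edge.length if node.edge.length else 0.0
        edges.append((float(length), derived))
    return edges


def _sample_tree_newick(dtree: dendropy.Tree, k: int) -> str:
    clone = dtree.clone(depth=1)
    for leaf in list(clone.leaf_node_iter()):
        label = leaf.taxon.label
        if k == 1:
            leaf.taxon.label = f"{label}_1"
            continue
        leaf.taxon = None
        for i in range(1, k + 1):
            child = leaf.new_child(edge_length=0.0)
            child.taxon = clone.taxon_namespace.new_taxon(f"{label}_{i}")
    clone.is_rooted = False
    return clone.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def _draw_barcodes(n: int, length: int, rng: np.random.Generator) -> list:
    seen: set[str] = set()
    out = []
    while len(out) < n:
        bc = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _make_loci(
    config: SimulationConfig,
    edges: list,
    rng: np.random.Generator,
    n_loci: int,
    contig_namer,
    spacing: int | None = None,
    start_index: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Lay out loci windows on fresh contigs and assign SNPs to edges.

    ``spacing=None`` places ``loci_per_contig`` windows per contig
    separated by ``locus_gap``; an integer spacing places exactly two
    windows per contig whose SNPs are ``spacing`` bp apart (linked-pair
    injection).
    """
    L = config.tag_length
    weights = np.array([e[0] for e in edges], dtype=float)
    if weights.sum() <= 0:
        weights = np.ones(len(edges))
    weights = weights / weights.sum()
    rows = []
    reference: dict[str, str] = {}
    if spacing is None:
        per_contig = config.loci_per_contig
        stride = L + config.locus_gap
        contig_seq: list[str] = []
        contig_name = None
        for k in range(n_loci):
            slot = k % per_contig
            if slot == 0:
                if contig_name is not None:
                    reference[contig_name] = "".join(contig_seq)
                contig_name = contig_namer(k // per_contig)
                contig_seq = []
            window = _random_seq(L, rng)
            gap = _random_seq(config.locus_gap, rng)
            contig_seq.extend([window, gap])
            rows.append(
                _locus_row(
                    config, edges, weights, rng, start_index + k,
                    contig_name, slot * stride, window,
                )
            )
        if contig_name is not None:
            reference[contig_name] = "".join(contig_seq)
    else:
        if spacing < L:
            raise ValueError(
                f"spacing {spacing} < tag_length {L}: windows would overlap"
            )
        if spacing >= config.locus_gap + L:
            raise ValueError(
                f"spacing {spacing} >= locus gap + tag length "
                f"({config.locus_gap + L}): pair would be no closer than "
                "background loci"
            )
        n_pairs = n_loci // 2
        for p in range(n_pairs):
            contig_name = contig_namer(p)
            offset = int(rng.integers(0, L))
            w1 = _random_seq(L, rng)
            w2 = _random_seq(L, rng)
            pad = _random_seq(spacing - L, rng)
            reference[contig_name] = w1 + pad + w2
            rows.append(
                _locus_row(
                    config, edges, weights, rng,
                    start_index + 2 * p, contig_name, 0, w1,
                    snp_offset=offset,
                )
            )
            rows.append(
                _locus_row(
                    config, edges, weights, rng,
                    start_index + 2 * p + 1, contig_name, spacing, w2,
                    snp_offset=offset,
                )
            )
    loci = pd.DataFrame(rows)
    return loci, reference


def _locus_row(
    config, edges, weights, rng, index, contig, window_start, window,
    snp_offset: int | None = None,
):
    L = config.tag_length
    if snp_offset is None:
        snp_offset = int(rng.integers(0, L))
    edge_id = int(rng.choice(len(edges), p=weights))
    ref_base = window[snp_offset]
    others = [b for b in "ACGT" if b != ref_base]
    alt_base = others[int(rng.integers(0, 3))]
    seq_alt = window[:snp_offset] + alt_base + window[snp_offset + 1 :]
    return {
        "locus": f"locus{index + 1:05d}",
        "contig": contig,
        "window_start0": window_start,
        "snp_offset": snp_offset,
        "pos0": window_start + snp_offset,
        "ref": ref_base,
        "alt": alt_base,
        "seq_ref": window,
        "seq_alt": seq_alt,
        "edge_id": edge_id,
    }


def _true_genotypes(
    loci: pd.DataFrame,
    edges: list,
    samples: list,
    species_of: dict,
    het_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n_s, n_l = len(samples), len(loci)
    g = np.zeros((n_s, n_l), dtype=np.int8)
    for j, edge_id in enumerate(loci["edge_id"]):
        derived = edges[edge_id][1]
        for i, s in enumerate(samples):
            if species_of[s] in derived:
                g[i, j] = 2
    if het_rate > 0:
        flip = rng.random((n_s, n_l)) < het_rate
        g[flip] = 1
    return g


def _emit_reads(
    config: SimulationConfig,
    loci: pd.DataFrame,
    genotypes: np.ndarray,
    depths: np.ndarray,
    samples: list,
    barcode_of: dict,
    rng: np.random.Generator,
    read_prefix: str = "r",
) -> list:
    L = config.tag_length
    seq_ref = [np.frombuffer(s.encode(), dtype=np.uint8) for s in loci["seq_ref"]]
    seq_alt = [np.frombuffer(s.encode(), dtype=np.uint8) for s in loci["seq_alt"]]
    reads = []
    counter = 0
    for i, sample in enumerate(samples):
        bc = barcode_of[sample]
        qual = tuple([40] * (len(bc) + L))
        for j in range(len(loci)):
            d = int(depths[i, j])
            if d == 0:
                continue
            g = genotypes[i, j]
            if g == 0:
                mat = np.repeat(seq_ref[j][None, :], d, axis=0)
            elif g == 2:
                mat = np.repeat(seq_alt[j][None, :], d, axis=0)
            else:
                mat = np.repeat(seq_ref[j][None, :], d, axis=0)
                alt_rows = rng.random(d) < 0.5
                mat[alt_rows] = seq_alt[j]
            if config.error_rate > 0:
                err = rng.random((d, L)) < config.error_rate
                if err.any():
                    idx = _BASE_INDEX[mat[err]]
                    shift = rng.integers(1, 4, size=idx.shape)
                    mat[err] = _BASES[(idx + shift) % 4]
            for row in mat:
                reads.append(
                    ReadRecord(
                        f"{read_prefix}{counter:07d}",
                        bc + row.tobytes().decode("ascii"),
                        qual,
                    )
                )
                counter += 1
    return reads


def _truth_matrix(
    samples: list, loci: pd.DataFrame, genotypes: np.ndarray,
    depths: np.ndarray,
) -> GenotypeMatrix:
    sites = pd.DataFrame(
        {
            "id": [f"{c}:{p + 1}" for c, p in zip(loci["contig"], loci["pos0"])],
            "contig": loci["contig"],
            "pos0": loci["pos0"],
            "ref": loci["ref"],
            "alt": loci["alt"],
            "source": "reference",
            "positioned": True,
        },
        columns=SITE_COLUMNS,
    )
    gq = np.full(genotypes.shape, 99.0)
    return GenotypeMatrix(samples, sites, genotypes, depths, gq)


def _draw_depths(config, shape, rng):
    k = config.depth_dispersion
    m = config.mean_depth
    depths = rng.negative_binomial(k, k / (k + m), size=shape).astype(np.int32)
    if config.missing_rate > 0:
        depths[rng.random(shape) < config.missing_rate] = 0
    return depths


# ---------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------

def simulate(config: SimulationConfig) -> SimResult:
    """Generate a fully seeded synthetic GBS dataset with truth.

    Pipeline: species tree (drawn or given) -> reference of spaced tag
    windows -> one biallelic SNP per locus on a branch chosen with
    probability proportional to branch length -> species-fixed diploid
    genotypes (plus optional het polymorphism) -> negative-binomial
    depths with dropout -> barcoded error-injected reads.
    """
    rng = np.random.default_rng(config.seed)
    pyrng = random.Random(int(rng.integers(2**31)))
    dtree = _species_tree(config, pyrng)
    edges = _mutation_edges(dtree)
    species = sorted(lf.taxon.label for lf in dtree.leaf_node_iter())
    samples = [
        f"{sp}_{i}"
        for sp in species
        for i in range(1, config.n_samples_per_species + 1)
    ]
    species_of = {s: s.rsplit("_", 1)[0] for s in samples}
    barcodes = _draw_barcodes(len(samples), config.barcode_length, rng)
    key = BarcodeKey.from_pairs(zip(samples, barcodes))
    barcode_of = dict(key.entries)

    loci, reference = _make_loci(
        config, edges, rng, config.n_loci,
        contig_namer=lambda c: f"contig{c + 1:03d}",
    )
    genotypes = _true_genotypes(
        loci, edges, samples, species_of, config.het_rate, rng
    )
    depths = _draw_depths(config, genotypes.shape, rng)
    reads = _emit_reads(
        config, loci, genotypes, depths, samples, barcode_of, rng
    )

    dtree.is_rooted = False
    species_tree = Tree.from_newick(
        dtree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()
    )
    sample_tree = Tree.from_newick(
        _sample_tree_newick(dtree, config.n_samples_per_species)
    )
    truth = TruthTable(
        species_tree=species_tree,
        sample_tree=sample_tree,
        genotypes=_truth_matrix(samples, loci, genotypes, depths),
        loci=loci,
        reference=reference,
    )
    return SimResult(config, key, reads, truth, edges)


def inject_linked_pairs(
    sim: SimResult,
    n_pairs: int,
    spacing_bp: int,
    seed: int | None = None,
) -> SimResult:
    """Add pairs of SNP loci ``spacing_bp`` apart on fresh shared contigs.

    The returned dataset's truth table records, per pair, the site that
    a correct distance pruning (greedy, keep-first) must remove — the
    downstream site of each pair.  The input dataset is not modified.
    """
    if n_pairs == 0:
        return sim
    config = sim.config
    rng = np.random.default_rng(
        config.seed + 7919 if seed is None else seed
    )
    loci, reference = _make_loci(
        config, sim.edges, rng, 2 * n_pairs,
        contig_namer=lambda p: f"linked{p + 1:03d}",
        spacing=spacing_bp,
        start_index=len(sim.truth.loci),
    )
    samples = sim.truth.genotypes.samples
    species_of = {s: s.rsplit("_", 1)[0] for s in samples}
    genotypes = _true_genotypes(
        loci, sim.edges, samples, species_of, config.het_rate, rng
    )
    depths = _draw_depths(config, genotypes.shape, rng)
    barcode_of = dict(sim.key.entries)
    extra_reads = _emit_reads(
        config, loci, genotypes, depths, samples, barcode_of, rng,
        read_prefix="x",
    )
    extra_matrix = _truth_matrix(samples, loci, genotypes, depths)
    base = sim.truth.genotypes
    combined = GenotypeMatrix(
        samples,
        pd.concat([base.sites, extra_matrix.sites], ignore_index=True),
        np.hstack([base.genotypes, extra_matrix.genotypes]),
        np.hstack([base.depths, extra_matrix.depths]),
        np.hstack([base.gq, extra_matrix.gq]),
    )
    # greedy keep-first pruning retains the upstream site of each pair
    removed = [
        extra_matrix.sites.at[j, "id"]
        for j in range(1, len(loci), 2)
    ]
    truth = TruthTable(
        species_tree=sim.truth.species_tree,
        sample_tree=sim.truth.sample_tree,
        genotypes=combined,
        loci=pd.concat([sim.truth.loci, loci], ignore_index=True),
        reference={**sim.truth.reference, **reference},
        linked_removed_expected=list(sim.truth.linked_removed_expected)
        + removed,
    )
    return SimResult(
        config, sim.key, list(sim.reads) + extra_reads, truth, sim.edges
    )
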