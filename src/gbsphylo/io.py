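"""On-disk formats: FASTQ, barcode keys, VCF 4.2, alignment exports, Newick.

Internal coordinates are 0-based half-open everywhere; VCF and Newick
are emitted with their standard 1-based / format-native conventions.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .genotype import MISSING, SITE_COLUMNS, GenotypeMatrix

logger = logging.getLogger(__name__)

_VALID_BARCODE = set("ACGT")

# IUPAC ambiguity codes for heterozygous diploid calls
IUPAC = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}


class FastqParseError(ValueError):
    """Malformed FASTQ input, reporting the offending record index."""


class NewickParseError(ValueError):
    pass


# ---------------------------------------------------------------------
# barcode key
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class BarcodeKey:
    """Sample -> barcode demultiplexing key.

    Barcodes are non-empty strings over {A,C,G,T} and mutually
    prefix-free (no barcode is a prefix of another), so the longest-
    prefix match during demultiplexing is unambiguous.
    """

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self):
        samples = [s for s, _ in self.entries]
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample ids in barcode key")
        for sample, bc in self.entries:
            if not bc or set(bc) - _VALID_BARCODE:
                raise ValueError(
                    f"invalid barcode {bc!r} for sample {sample!r}"
                )
        barcodes = sorted(bc for _, bc in self.entries)
        for x, y in zip(barcodes, barcodes[1:]):
            if y.startswith(x):
                raise ValueError(
                    f"barcode {x!r} is a prefix of {y!r}: key not prefix-free"
                )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "BarcodeKey":
        return cls(tuple((str(s), str(b)) for s, b in pairs))

    @property
    def samples(self) -> list[str]:
        return [s for s, _ in self.entries]


def read_barcode_key(path) -> BarcodeKey:
    """Read a tab-separated sample_id<TAB>barcode key."""
    pairs = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{ln}: expected 2 tab-separated fields"
                )
            pairs.append((fields[0], fields[1]))
    return BarcodeKey.from_pairs(pairs)


def write_barcode_key(key: BarcodeKey, path) -> None:
    with open(path, "w") as fh:
        for sample, bc in key.entries:
            fh.write(f"{sample}\t{bc}\n")


# ---------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: id, sequence, per-base Phred quality scores."""

    read_id: str
    sequence: str
    quality: tuple[int, ...]

    def __post_init__(self):
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.read_id!r}: sequence/quality length mismatch"
            )


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream records from a (possibly gzipped) Phred+33 FASTQ file."""
    with _open_text(path) as fh:
        record_index = 0
        while True:
            header = fh.readline()
            if not header:
                break
            lines = [header.rstrip("\n")]
            for _ in range(3):
                line = fh.readline()
                if not line:
                    raise FastqParseError(
                        f"{path}: record {record_index}: truncated record "
                        "(line count not a multiple of 4)"
                    )
                lines.append(line.rstrip("\n"))
            head, seq, plus, qual = lines
            if not head.startswith("@") or not plus.startswith("+"):
                raise FastqParseError(
                    f"{path}: record {record_index}: malformed header lines"
                )
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"{path}: record {record_index}: sequence length "
                    f"{len(seq)} != quality length {len(qual)}"
                )
            yield ReadRecord(
                head[1:].split()[0],
                seq,
                tuple(ord(c) - 33 for c in qual),
            )
            record_index += 1


def write_fastq(records: Iterable[ReadRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        for r in records:
            qual = "".join(chr(q + 33) for q in r.quality)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------
# FASTA (references)
# ---------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Reference FASTA as an ordered contig -> sequence dict."""
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(contigs: dict[str, str], path, width: int = 80) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in contigs.items()
    ]
    seqio_write(records, str(path), "fasta")


# ---------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------

_VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    "##source=gbsphylo",
    '##INFO=<ID=SRC,Number=1,Type=String,Description='
    '"Site provenance: denovo or reference">',
    '##INFO=<ID=UNPOS,Number=0,Type=Flag,Description='
    '"Site has no genomic position (synthetic per-pair contig)">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=GQ,Number=1,Type=Float,Description="Genotype quality">',
]

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write the matrix as VCF 4.2 with GT:DP:GQ per call.

    Sites are emitted sorted by (contig, position); if the input order
    differs, the writer sorts and logs.  De novo sites appear on their
    synthetic per-pair contigs at the tag-centre position.
    """
    sites = matrix.sites
    order = sites.sort_values(
        ["contig", "pos0"], kind="stable"
    ).index.to_numpy()
    if not np.array_equal(order, np.arange(len(sites))):
        logger.info("write_vcf: sites were not position-sorted; sorting")
    with open(path, "w") as fh:
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        for contig in dict.fromkeys(sites["contig"].iloc[order]):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for j in order:
            rec = sites.iloc[j]
            info = f"SRC={rec['source']}"
            if not rec["positioned"]:
                info += ";UNPOS"
            calls = []
            for i in range(matrix.n_samples):
                g = int(matrix.genotypes[i, j])
                dp = int(matrix.depths[i, j])
                gq = matrix.gq[i, j]
                gq_s = "." if np.isnan(gq) else format(float(gq), ".6g")
                calls.append(f"{_GT_STRINGS[g]}:{dp}:{gq_s}")
            fh.write(
                f"{rec['contig']}\t{rec['pos0'] + 1}\t{rec['id']}\t"
                f"{rec['ref']}\t{rec['alt']}\t.\tPASS\t{info}\tGT:DP:GQ\t"
                + "\t".join(calls)
                + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are loaded; others are skipped with a
    warning and counted in the log.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows = []
    genos, depths, gqs = [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        g = np.asarray(var.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        try:
            dp_raw = var.format("DP")
        except KeyError:
            dp_raw = None
        dp = (
            np.zeros(len(samples), dtype=np.int32)
            if dp_raw is None
            else dp_raw.reshape(-1).astype(np.int64)
        )
        dp = np.where(dp < 0, 0, dp).astype(np.int32)
        try:
            gq_raw = var.format("GQ")
        except KeyError:
            gq_raw = None
        if gq_raw is None:
            gq = np.full(len(samples), np.nan)
        else:
            gq = gq_raw.reshape(-1).astype(float)
        gq = np.where(g == MISSING, np.nan, gq)
        info_src = var.INFO.get("SRC") or "reference"
        unpos = var.INFO.get("UNPOS") is not None
        rows.append(
            {
                "id": var.ID or f"{var.CHROM}:{var.POS}",
                "contig": var.CHROM,
                "pos0": var.POS - 1,
                "ref": var.REF,
                "alt": var.ALT[0],
                "source": info_src,
                "positioned": not unpos and info_src == "reference",
            }
        )
        genos.append(g)
        depths.append(dp)
        gqs.append(gq)
    if n_skipped:
        warnings.warn(
            f"{path}: skipped {n_skipped} non-biallelic record(s)",
            stacklevel=2,
        )
        logger.warning("read_vcf: skipped %d non-biallelic records", n_skipped)
    sites = (
        pd.DataFrame(rows, columns=SITE_COLUMNS)
        if rows
        else pd.DataFrame(columns=SITE_COLUMNS)
    )
    n_sites = len(rows)
    shape = (len(samples), n_sites)
    return GenotypeMatrix(
        samples,
        sites,
        np.array(genos, dtype=np.int8).T.reshape(shape),
        np.array(depths, dtype=np.int32).T.reshape(shape),
        np.array(gqs, dtype=float).T.reshape(shape),
    )


# ---------------------------------------------------------------------
# alignment export (supermatrix for external tree engines)
# ---------------------------------------------------------------------

def _matrix_to_sequences(
    matrix: GenotypeMatrix, missing_char: str
) -> dict[str, str]:
    if matrix.n_sites == 0 or matrix.n_samples == 0:
        raise ValueError("cannot export an empty matrix")
    refs = matrix.sites["ref"].to_numpy()
    alts = matrix.sites["alt"].to_numpy()
    het = np.array(
        [IUPAC[frozenset((r, a))] for r, a in zip(refs, alts)]
    )
    lut = np.stack([refs, het, alts, np.full(len(refs), missing_char)])
    out = {}
    for i, sample in enumerate(matrix.samples):
        g = matrix.genotypes[i].copy()
        g[g == MISSING] = 3
        seq = "".join(lut[g, np.arange(len(refs))])
        if set(seq) == {missing_char}:
            warnings.warn(
                f"sample {sample!r} is entirely missing in the export",
                stacklevel=3,
            )
        out[sample] = seq
    return out


def export_alignment(matrix: GenotypeMatrix, path, fmt: str = "phylip") -> None:
    """Export the concatenated SNP supermatrix for external tree tools.

    One sequence per sample; heterozygotes become IUPAC ambiguity codes;
    missing calls become ``?`` (phylip/nexus) or ``N`` (fasta).
    """
    fmt = fmt.lower()
    if fmt not in {"phylip", "nexus", "fasta"}:
        raise ValueError(f"unknown alignment format {fmt!r}")
    missing_char = "N" if fmt == "fasta" else "?"
    seqs = _matrix_to_sequences(matrix, missing_char)
    n, m = len(seqs), matrix.n_sites
    with open(path, "w") as fh:
        if fmt == "phylip":
            fh.write(f"{n} {m}\n")
            for name, seq in seqs.items():
                fh.write(f"{name}  {seq}\n")
        elif fmt == "fasta":
            for name, seq in seqs.items():
                fh.write(f">{name}\n{seq}\n")
        else:  # nexus
            fh.write("#NEXUS\n\nBEGIN TAXA;\n")
            fh.write(f"    DIMENSIONS NTAX={n};\n    TAXLABELS\n")
            for name in seqs:
                fh.write(f"        {name}\n")
            fh.write("    ;\nEND;\n\nBEGIN CHARACTERS;\n")
            fh.write(f"    DIMENSIONS NCHAR={m};\n")
            fh.write(
                "    FORMAT DATATYPE=DNA MISSING=? GAP=-;\n    MATRIX\n"
            )
            for name, seq in seqs.items():
                fh.write(f"        {name}  {seq}\n")
            fh.write("    ;\nEND;\n")


# ---------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------

def _check_parens(text: str, name: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"{name}: unbalanced ')' at character {offset}"
                )
    if depth != 0:
        raise NewickParseError(
            f"{name}: {depth} unclosed '(' at end of input "
            f"(character {len(text)})"
        )


def read_newick(path) -> "Tree":
    """Read a Newick tree (branch lengths, internal support labels)."""
    from .phylo import Tree

    text = Path(path).read_text().strip()
    _check_parens(text, str(path))
    return Tree.from_newick(text)


def write_newick(tree: "Tree", path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
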