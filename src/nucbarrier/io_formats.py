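"""Readers and writers for the formats the pipeline touches.

All internal coordinates are 0-based, half-open.  Conversion to and from
the 1-based conventions of SAM, GFF3 and WIG happens here and only here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "AlignedRead",
    "GeneModel",
    "Genome",
    "read_alignments",
    "write_bed",
    "read_gene_models",
    "write_gene_models",
    "read_genome_table",
    "write_genome_table",
    "write_wig",
    "read_wig",
    "read_table",
    "write_table",
    "read_config",
]


class AlignedRead(NamedTuple):
    """One mapped single-end read.

    ``start`` is the 0-based leftmost coordinate regardless of strand;
    ``length`` is the aligned length in bp.
    """

    chrom: str
    start: int
    length: int
    strand: str

    @property
    def end(self) -> int:
        """0-based exclusive right coordinate."""
        return self.start + self.length

    @property
    def five_prime(self) -> int:
        """0-based coordinate of the 5' base (rightmost base for - reads)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class GeneModel:
    """A gene with its transcription start site and optional CRE site.

    ``cre_site`` is the midpoint of the cyclic-AMP response element (the
    Atf1 binding motif) in the promoter, when annotated.  ``atf1_dependent``
    marks genes whose regulation depends on the Atf1 barrier.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    cre_site: int | None = None
    atf1_dependent: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def direction(self) -> int:
        """+1 for plus-strand genes, -1 for minus-strand genes."""
        return 1 if self.strand == "+" else -1


@dataclass
class Genome:
    """Ordered map of sequence name to length in bp."""

    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, n in self.lengths.items():
            if n <= 0:
                raise ValueError(f"chromosome {name}: length must be > 0")

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    def __getitem__(self, name: str) -> int:
        return self.lengths[name]

    def __iter__(self):
        return iter(self.lengths)

    def items(self):
        return self.lengths.items()


# ---------------------------------------------------------------------------
# alignments

_SAM_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
# CIGAR ops consuming the query sequence; their sum is the read length
_QUERY_OPS = {"M", "I", "S", "=", "X"}


def _sam_read_length(cigar: str, seq: str) -> int:
    if seq not in ("*", ""):
        return len(seq)
    if cigar in ("*", ""):
        raise ValueError("neither SEQ nor CIGAR available to infer read length")
    return sum(int(n) for n, op in _SAM_CIGAR_RE.findall(cigar) if op in _QUERY_OPS)


def read_alignments(path: str | Path, format: str = "bed") -> tuple[list[AlignedRead], int]:
    """Read single-end alignments from BED6 or a minimal SAM file.

    Returns ``(reads, total_mapped)`` where ``total_mapped`` equals the
    number of mapped records emitted (unmapped SAM records are skipped and
    not counted).
    """
    path = Path(path)
    if format not in ("bed", "sam"):
        raise ValueError(f"unknown alignment format {format!r} (expected 'bed' or 'sam')")
    reads: list[AlignedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if format == "sam":
                if line.startswith("@"):
                    continue
                fields = line.split("\t")
                if len(fields) < 10:
                    raise ValueError(f"{path}:{lineno}: malformed SAM record ({len(fields)} fields)")
                try:
                    flag = int(fields[1])
                    pos = int(fields[3])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed SAM record: {exc}") from None
                if flag & 0x4:  # unmapped
                    continue
                length = _sam_read_length(fields[5], fields[9])
                strand = "-" if flag & 0x10 else "+"
                reads.append(AlignedRead(fields[2], pos - 1, length, strand))
            else:
                fields = line.split("\t")
                if len(fields) < 6:
                    raise ValueError(f"{path}:{lineno}: BED6 requires 6 columns, got {len(fields)}")
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed BED line: {exc}") from None
                strand = fields[5]
                if strand not in ("+", "-"):
                    raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
                if end <= start:
                    raise ValueError(f"{path}:{lineno}: end must exceed start")
                reads.append(AlignedRead(fields[0], start, end - start, strand))
    return reads, len(reads)


def write_bed(reads: Iterable[AlignedRead], path: str | Path) -> None:
    """Write reads as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tread{i}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# gene models (GFF3)

def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3.

    The TSS is the feature start for + genes and the feature end for -
    genes, converted to 0-based.  An optional ``cre_site`` attribute
    (1-based coordinate) marks the CRE midpoint; ``atf1_dependent`` is a
    truthy flag attribute.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: GFF3 requires 9 columns, got {len(fields)}")
            if fields[2] != "gene":
                continue
            chrom, start1, end1, strand = fields[0], int(fields[3]), int(fields[4]), fields[6]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: gene feature lacks a strand")
            attrs = _parse_gff_attributes(fields[8])
            gene_id = attrs.get("ID", f"gene{lineno}")
            tss = start1 - 1 if strand == "+" else end1 - 1
            cre = int(attrs["cre_site"]) - 1 if "cre_site" in attrs else None
            dep = attrs.get("atf1_dependent", "false").lower() in ("1", "true", "yes")
            genes.append(GeneModel(gene_id, chrom, strand, tss, cre, dep))
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path, gene_length: int = 2000) -> None:
    """Write gene models as GFF3 gene features.

    ``gene_length`` sets the feature span used for TSS round-tripping; the
    TSS end of the feature is exact, the far end is nominal.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            if g.strand == "+":
                start1, end1 = g.tss + 1, g.tss + gene_length
            else:
                start1, end1 = max(1, g.tss + 1 - gene_length + 1), g.tss + 1
            attrs = [f"ID={g.gene_id}"]
            if g.cre_site is not None:
                attrs.append(f"cre_site={g.cre_site + 1}")
            attrs.append(f"atf1_dependent={'true' if g.atf1_dependent else 'false'}")
            fh.write(
                f"{g.chrom}\tnucbarrier\tgene\t{start1}\t{end1}\t.\t{g.strand}\t.\t{';'.join(attrs)}\n"
            )


# ---------------------------------------------------------------------------
# genome table (TSV: chrom, length)

def read_genome_table(path: str | Path) -> Genome:
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "length"} <= set(df.columns):
        raise ValueError(f"{path}: genome table requires 'chrom' and 'length' columns")
    return Genome(dict(zip(df["chrom"].astype(str), df["length"].astype(int))))


def write_genome_table(genome: Genome, path: str | Path) -> None:
    pd.DataFrame(
        {"chrom": list(genome.lengths), "length": list(genome.lengths.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# WIG (fixedStep, step=1, span=1)

def write_wig(track, path: str | Path) -> None:
    """Export a coverage track as fixedStep WIG.

    WIG coordinates are 1-based: internal position 0 is written with
    ``start=1``.  Values are rendered with 6 significant digits, so a WIG
    round trip reproduces values to within 1e-6 relative.
    """
    from .coverage import CoverageTrack  # local import to avoid cycle

    if not isinstance(track, CoverageTrack):
        raise TypeError("write_wig expects a CoverageTrack")
    with open(path, "w") as fh:
        for chrom, values in track.data.items():
            if values.size == 0:
                continue
            fh.write(f"fixedStep chrom={chrom} start=1 step=1 span=1\n")
            np.savetxt(fh, values, fmt="%.6g")


def read_wig(path: str | Path, total_mapped: int = 0, state: str = "rpm"):
    """Read a fixedStep WIG file back into a CoverageTrack.

    Leading positions before the declared ``start`` are zero-filled so the
    track remains dense from coordinate 0.
    """
    from .coverage import CoverageTrack

    data: dict[str, np.ndarray] = {}
    chrom = None
    start = 1
    buf: list[float] = []

    def flush() -> None:
        if chrom is None:
            return
        arr = np.zeros(start - 1 + len(buf))
        arr[start - 1:] = buf
        data[chrom] = arr

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            if line.startswith("fixedStep"):
                flush()
                kv = dict(item.split("=") for item in line.split()[1:])
                chrom = kv["chrom"]
                start = int(kv.get("start", 1))
                if int(kv.get("step", 1)) != 1:
                    raise ValueError(f"{path}:{lineno}: only step=1 fixedStep is supported")
                buf = []
            elif line.startswith("variableStep"):
                raise ValueError(f"{path}:{lineno}: variableStep WIG is not supported")
            else:
                if chrom is None:
                    raise ValueError(f"{path}:{lineno}: data line before fixedStep header")
                buf.append(float(line))
    flush()
    return CoverageTrack(data=data, state=state, total_mapped=total_mapped)


# ---------------------------------------------------------------------------
# generic TSV tables and flat config files

def read_table(path: str | Path, required: Iterable[str] = ()) -> pd.DataFrame:
    """Read a TSV table with a header row, checking required columns."""
    df = pd.read_csv(path, sep="\t")
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` config file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out
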