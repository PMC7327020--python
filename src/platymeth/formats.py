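"""Readers and writers for the on-disk artifacts of the pipeline.

All internal coordinates are 0-based half-open.  GFF3 is emitted/consumed in
its native 1-based closed convention, BED in 0-based half-open, and the
cytosine report (Bismark CX dialect) carries 1-based positions.  Gzip is
supported transparently for tabular formats when the path ends in ``.gz``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CONTEXTS = ("CG", "CHG", "CHH")

CX_COLUMNS = ["chrom", "pos", "strand", "count_m", "count_u", "context", "trinucleotide"]


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


@dataclass(frozen=True)
class CxRecord:
    """One strand-specific cytosine with methylated/unmethylated read counts."""

    chrom: str
    pos: int  # 1-based, as in the CX report
    strand: str
    count_m: int
    count_u: int
    context: str
    trinucleotide: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"position must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise FormatError(f"strand must be + or -, got {self.strand!r}")
        if self.count_m < 0 or self.count_u < 0:
            raise FormatError("read counts must be non-negative")
        if self.context not in CONTEXTS:
            raise FormatError(f"unknown context {self.context!r}")

    @property
    def coverage(self) -> int:
        return self.count_m + self.count_u


@dataclass(frozen=True)
class GeneModel:
    """A stranded single-exon gene with 0-based half-open body coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    family: str = "other"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise FormatError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start

    def body_interval(self) -> tuple[int, int]:
        return self.start, self.end

    def upstream_interval(self, flank: int) -> tuple[int, int]:
        """Genomic interval of the 5' flank (left of start for +, right of end for -)."""
        if self.strand == "+":
            return max(0, self.start - flank), self.start
        return self.end, self.end + flank

    def downstream_interval(self, flank: int) -> tuple[int, int]:
        if self.strand == "+":
            return self.end, self.end + flank
        return max(0, self.start - flank), self.start

    def region_interval(self, region: str, flank: int = 2000) -> tuple[int, int]:
        if region in ("body", "coding"):
            return self.body_interval()
        if region == "upstream":
            return self.upstream_interval(flank)
        if region == "downstream":
            return self.downstream_interval(flank)
        raise ValueError(f"unknown region {region!r}")


# ---------------------------------------------------------------------------
# cytosine (CX) reports
# ---------------------------------------------------------------------------


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def iter_cx_records(path: str | Path) -> Iterator[CxRecord]:
    """Stream a CX report as validated :class:`CxRecord` objects.

    Raises :class:`FormatError` naming the offending line number on any
    malformed line.
    """
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise FormatError(f"line {lineno}: expected 7 tab-separated fields, got {len(fields)}")
            chrom, pos, strand, m, u, context, tri = fields
            try:
                pos_i, m_i, u_i = int(pos), int(m), int(u)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer field ({exc})") from None
            try:
                yield CxRecord(chrom, pos_i, strand, m_i, u_i, context, tri)
            except FormatError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None


def read_cx_report(path: str | Path) -> pd.DataFrame:
    """Read a CX report into a validated DataFrame (columns ``CX_COLUMNS``)."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            names=CX_COLUMNS,
            header=None,
            dtype={
                "chrom": str,
                "strand": str,
                "context": str,
                "trinucleotide": str,
            },
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: {exc}") from None
    if df.empty:
        return pd.DataFrame(columns=CX_COLUMNS)
    for col in ("pos", "count_m", "count_u"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            raise FormatError(f"line {bad.idxmax() + 1}: non-integer {col!r} field")
        df[col] = numeric.astype(int)
    for col, allowed in (("strand", {"+", "-"}), ("context", set(CONTEXTS))):
        bad = ~df[col].isin(allowed)
        if bad.any():
            raise FormatError(f"line {bad.idxmax() + 1}: invalid {col!r} value {df[col][bad.idxmax()]!r}")
    if (df["pos"] < 1).any():
        raise FormatError(f"line {(df['pos'] < 1).idxmax() + 1}: position must be >= 1")
    if (df[["count_m", "count_u"]] < 0).any().any():
        bad = ((df["count_m"] < 0) | (df["count_u"] < 0)).idxmax()
        raise FormatError(f"line {bad + 1}: negative read count")
    return df


def write_cx_report(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=CX_COLUMNS)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{name: upper-case sequence}`` (order preserved)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 ``gene`` features (1-based closed coordinates)."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};family={g.family}"
            fh.write(
                "\t".join(
                    [g.chrom, "platymeth", "gene", str(g.start + 1), str(g.end), ".", g.strand, ".", attrs]
                )
                + "\n"
            )


def read_gff3(path: str | Path, chrom_sizes: Mapping[str, int] | None = None) -> list[GeneModel]:
    """Read ``gene`` features from GFF3 in file order.

    ``chrom_sizes``, when given, enables validation that no feature extends
    beyond its chromosome.
    """
    genes: list[GeneModel] = []
    for feat in gffutils.DataIterator(str(path)):
        if feat.featuretype != "gene":
            continue
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        family = feat.attributes.get("family", ["other"])[0]
        start0, end0 = feat.start - 1, feat.end  # 1-based closed -> 0-based half-open
        if chrom_sizes is not None:
            size = chrom_sizes.get(feat.seqid)
            if size is None:
                raise FormatError(f"{gene_id}: unknown chromosome {feat.seqid!r}")
            if end0 > size:
                raise FormatError(f"{gene_id}: end {end0} beyond chromosome length {size}")
        genes.append(GeneModel(gene_id, feat.seqid, start0, end0, feat.strand, family))
    return genes


# ---------------------------------------------------------------------------
# family map, matrices, BED
# ---------------------------------------------------------------------------


def write_family_map(genes: Iterable[GeneModel], path: str | Path) -> None:
    df = pd.DataFrame({"gene_id": [g.gene_id for g in genes], "family": [g.family for g in genes]})
    df.to_csv(path, sep="\t", index=False)


def read_family_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene_id", "family"]:
        raise FormatError(f"{path}: expected columns gene_id, family")
    return dict(zip(df["gene_id"], df["family"]))


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_dmc_bed(dmcs: pd.DataFrame, path: str | Path) -> None:
    """Write DMCs as single-base BED intervals (0-based half-open).

    name = direction (hyper/hypo), score = \\|delta\\| rounded to integer.
    """
    out = pd.DataFrame(
        {
            "chrom": dmcs["chrom"],
            "start": dmcs["pos0"],
            "end": dmcs["pos0"] + 1,
            "name": dmcs["direction"],
            "score": dmcs["delta"].abs().round().astype(int),
            "strand": dmcs["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_dmc_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "name", "score", "strand"]
    )
    if not (df["end"] == df["start"] + 1).all():
        raise FormatError(f"{path}: DMC BED intervals must be single-base")
    return df
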