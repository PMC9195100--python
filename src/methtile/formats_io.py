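"""Shared data model, coordinate conventions and file formats.

All coordinates held in memory are 0-based half-open on the Watson strand.
Emitted GFF3 and CGmap files use the 1-based conventions of those formats;
BED output is 0-based half-open.

Per-cytosine methylation tables use the 8-column CGmap dialect::

    chrom  nucleotide  pos(1-based)  context  dinucleotide  level  meth_reads  total_reads

where ``nucleotide`` is the Watson-strand base (C for plus-strand cytosines,
G for minus-strand ones), ``context`` is one of CG/CHG/CHH and ``level`` is
the fraction of reads supporting methylation at the site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("methtile")

CONTEXTS = ("CG", "CHG", "CHH")

#: column order of the per-site table inside a MethylomeTable
SITE_COLUMNS = (
    "chrom",
    "pos",
    "strand",
    "context",
    "dinuc",
    "meth_reads",
    "total_reads",
    "level",
)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# core records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CytosineSite:
    """A single reference cytosine with its observed read support."""

    chrom: str
    pos: int  # 0-based Watson-strand coordinate
    strand: str  # '+' or '-'
    context: str  # CG / CHG / CHH
    meth_reads: int
    total_reads: int
    dinuc: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"bad strand {self.strand!r}")
        if self.context not in CONTEXTS:
            raise FormatError(f"unknown context {self.context!r}")
        if not (0 <= self.meth_reads <= self.total_reads):
            raise FormatError(
                f"meth_reads {self.meth_reads} > total_reads {self.total_reads} "
                f"at {self.chrom}:{self.pos}"
            )

    @property
    def level(self) -> float:
        return self.meth_reads / self.total_reads if self.total_reads else float("nan")


@dataclass
class MethylomeTable:
    """All assayed cytosines of one sample plus sample metadata.

    ``sites`` is a DataFrame with :data:`SITE_COLUMNS`, sorted by
    (chrom, pos, strand) with no duplicate site keys.
    """

    sample_id: str
    sites: pd.DataFrame
    condition: str = "other"  # control / stress / other
    genotype: str = "other"  # sensitive / tolerant / other
    tissue: str = "other"  # root / shoot / other
    nonconversion_rate: float | None = None

    def __post_init__(self) -> None:
        df = self.sites
        missing = [c for c in SITE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"site table missing columns {missing}")
        df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
        if df.duplicated(["chrom", "pos", "strand"]).any():
            raise FormatError("duplicate (chrom, pos, strand) in site table")
        self.sites = df

    def __len__(self) -> int:
        return len(self.sites)

    def assayed(self, min_depth: int = 1) -> pd.DataFrame:
        """Sites with at least ``min_depth`` total reads."""
        return self.sites[self.sites["total_reads"] >= min_depth]

    def restrict(self, chrom: str) -> "MethylomeTable":
        sub = self.sites[self.sites["chrom"] == chrom].reset_index(drop=True)
        return MethylomeTable(
            sample_id=self.sample_id,
            sites=sub,
            condition=self.condition,
            genotype=self.genotype,
            tissue=self.tissue,
            nonconversion_rate=self.nonconversion_rate,
        )


@dataclass
class GeneModel:
    """One gene (longest transcript) with exon structure.

    ``exons`` are half-open genomic intervals ordered 5'->3' in the
    direction of transcription; ``utr5``/``utr3`` are optional lists of
    half-open intervals (a UTR may span an intron).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int  # leftmost genomic coordinate, 0-based
    end: int  # rightmost genomic coordinate, half-open
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not self.exons:
            self.exons = [(self.start, self.end)]
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise FormatError(
                    f"exon [{s},{e}) outside gene span of {self.gene_id}"
                )
        ordered = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 < e1:
                raise FormatError(f"overlapping exons in {self.gene_id}")
        # keep transcription order
        self.exons = ordered if self.strand == "+" else ordered[::-1]

    @property
    def tss(self) -> int:
        """Transcription start, 0-based (rightmost base for minus strand)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Transcription end, 0-based."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Half-open intron intervals, 5'->3' in transcription direction."""
        ordered = sorted(self.exons)
        gaps = [(e1, s2) for (_, e1), (s2, _) in zip(ordered, ordered[1:])]
        return gaps if self.strand == "+" else gaps[::-1]

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a genome as {chrom: uppercase sequence}."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True, read_long_names=False)
    genome = {name: str(fa[name][:]).upper() for name in fa.keys()}
    fa.close()
    log.info("read %d sequences from %s", len(genome), path)
    return genome


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene models from GFF3, keeping the longest transcript per gene.

    GFF3 1-based inclusive intervals are converted to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        transcripts = list(db.children(gene, featuretype="mRNA"))
        if transcripts:
            tx = max(transcripts, key=lambda t: t.end - t.start)
            exon_parent = tx
        else:
            exon_parent = gene
        exons = [
            (f.start - 1, f.end)
            for f in db.children(exon_parent, featuretype="exon", order_by="start")
        ]
        utr5 = [
            (f.start - 1, f.end)
            for f in db.children(exon_parent, featuretype="five_prime_UTR", order_by="start")
        ]
        utr3 = [
            (f.start - 1, f.end)
            for f in db.children(exon_parent, featuretype="three_prime_UTR", order_by="start")
        ]
        gstart, gend = gene.start - 1, gene.end
        for s, e in exons:
            if s < gstart or e > gend:
                raise FormatError(
                    f"exon [{s},{e}) outside gene span of {gene.id} [{gstart},{gend})"
                )
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                start=gstart,
                end=gend,
                exons=exons or [(gstart, gend)],
                utr5=utr5,
                utr3=utr3,
            )
        )
    log.info("read %d gene models from %s", len(genes), path)
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path, source: str = "methtile") -> None:
    """Write gene models as GFF3 (1-based inclusive intervals)."""

    def row(chrom, typ, s, e, strand, attrs):
        return f"{chrom}\t{source}\t{typ}\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}\n"

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(row(g.chrom, "gene", g.start, g.end, g.strand, f"ID={g.gene_id}"))
            mrna = f"{g.gene_id}.1"
            fh.write(
                row(g.chrom, "mRNA", g.start, g.end, g.strand, f"ID={mrna};Parent={g.gene_id}")
            )
            for i, (s, e) in enumerate(sorted(g.exons), 1):
                fh.write(row(g.chrom, "exon", s, e, g.strand, f"ID={mrna}.exon{i};Parent={mrna}"))
            for i, (s, e) in enumerate(g.utr5, 1):
                fh.write(
                    row(g.chrom, "five_prime_UTR", s, e, g.strand, f"ID={mrna}.utr5.{i};Parent={mrna}")
                )
            for i, (s, e) in enumerate(g.utr3, 1):
                fh.write(
                    row(g.chrom, "three_prime_UTR", s, e, g.strand, f"ID={mrna}.utr3.{i};Parent={mrna}")
                )


# ---------------------------------------------------------------------------
# CGmap-style per-cytosine tables
# ---------------------------------------------------------------------------

_CGMAP_COLS = ["chrom", "nuc", "pos1", "context", "dinuc", "level", "meth_reads", "total_reads"]


def read_cgmap(path: str | Path, sample_id: str | None = None, **meta) -> MethylomeTable:
    """Read an 8-column CGmap-style TSV into a :class:`MethylomeTable`.

    File positions are 1-based and converted to 0-based; strand is inferred
    from the Watson-strand nucleotide (C -> '+', G -> '-'). Sites with zero
    total reads are dropped (count logged). Malformed rows raise
    :class:`FormatError` with 1-based line numbers.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            names=_CGMAP_COLS,
            comment="#",
            dtype={
                "chrom": str,
                "nuc": str,
                "context": str,
                "dinuc": str,
            },
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse as 8-column TSV: {exc}") from exc
    if df.shape[1] != 8:
        raise FormatError(f"{path}: expected 8 tab-separated columns")

    lineno = df.index.to_numpy() + 1

    def bad_lines(mask: np.ndarray, why: str) -> None:
        if mask.any():
            lines = ", ".join(str(x) for x in lineno[mask][:10])
            raise FormatError(f"{path}: {why} at line(s) {lines}")

    bad_lines(~df["nuc"].isin(["C", "G"]).to_numpy(), "nucleotide not C/G")
    bad_lines(~df["context"].isin(CONTEXTS).to_numpy(), "unknown context token")
    for col in ("pos1", "meth_reads", "total_reads"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad_lines(vals.isna().to_numpy(), f"non-numeric {col}")
        df[col] = vals.astype(int)
    bad_lines((df["pos1"] < 1).to_numpy(), "position < 1")
    bad_lines((df["meth_reads"] < 0).to_numpy(), "negative meth_reads")
    bad_lines(
        (df["meth_reads"] > df["total_reads"]).to_numpy(),
        "meth_reads > total_reads",
    )

    n_zero = int((df["total_reads"] == 0).sum())
    if n_zero:
        log.info("%s: dropped %d sites with zero total reads", path, n_zero)
        df = df[df["total_reads"] > 0]

    sites = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "pos": df["pos1"].to_numpy() - 1,
            "strand": np.where(df["nuc"].to_numpy() == "C", "+", "-"),
            "context": df["context"].to_numpy(),
            "dinuc": df["dinuc"].to_numpy(),
            "meth_reads": df["meth_reads"].to_numpy(),
            "total_reads": df["total_reads"].to_numpy(),
        }
    )
    sites["level"] = sites["meth_reads"] / sites["total_reads"]
    log.info("%s: read %d cytosine sites", path, len(sites))
    if sample_id is None:
        sample_id = Path(path).stem
    return MethylomeTable(sample_id=sample_id, sites=sites, **meta)


def write_cgmap(table: MethylomeTable, path: str | Path) -> None:
    """Write a MethylomeTable as 8-column CGmap-style TSV (1-based positions)."""
    df = table.sites
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "nuc": np.where(df["strand"] == "+", "C", "G"),
            "pos1": df["pos"] + 1,
            "context": df["context"],
            "dinuc": df["dinuc"],
            "level": (df["meth_reads"] / df["total_reads"]).map(lambda x: format(x, ".6g")),
            "meth_reads": df["meth_reads"],
            "total_reads": df["total_reads"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# BED / TSV output
# ---------------------------------------------------------------------------


def bed_score(q: float) -> int:
    """BED score column from a q-value: min(1000, round(-10*log10(q)))."""
    if q <= 0:
        return 1000
    return int(min(1000, round(-10.0 * np.log10(q))))


def write_dmr_bed(dmrs: pd.DataFrame, path: str | Path) -> None:
    """Write DMR calls as BED6 (0-based half-open, name=context:direction)."""
    with open(path, "w") as fh:
        fh.write("# methtile DMR calls: chrom start end context:direction score strand\n")
        if len(dmrs) == 0:
            return
        for row in dmrs.sort_values(["chrom", "start", "context"]).itertuples():
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.context}:{row.direction}\t"
                f"{bed_score(row.q_value)}\t.\n"
            )


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV dump used for all tabular outputs."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# expression matrix / design
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> pd.DataFrame:
    """FPKM matrix: first column gene_id, one column per sample."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise FormatError(f"{path}: first column must be 'gene_id'")
    return df.set_index("gene_id")


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.rename_axis("gene_id").reset_index().to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_design(path: str | Path) -> pd.DataFrame:
    """Design table mapping sample -> condition (and replicate)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "condition"):
        if col not in df.columns:
            raise FormatError(f"{path}: design table needs a '{col}' column")
    return df
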