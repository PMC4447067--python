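"""Readers and writers for the genomic file formats the pipeline touches.

All in-memory coordinates are 1-based and inclusive at both ends — the
convention shared by GFF3 and by the published peak tables this package
ships.  BED and bedGraph use 0-based half-open coordinates on disk; the
conversion happens in this module and nowhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "ParseError",
    "GenomicInterval",
    "GeneFeature",
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "write_gff3",
    "read_intervals",
    "write_intervals",
    "write_bedgraph",
    "write_peaks",
    "read_peaks",
]

FASTA_ALPHABET = frozenset("ACGTN")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, fully-closed genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of + - . , got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int, tolerance: int = 0) -> bool:
        return self.start - tolerance <= pos <= self.end + tolerance

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


# how far upstream of a gene's interval an annotated TSS may legitimately sit
TSS_UPSTREAM_SLACK = 1000

GENE_KINDS = ("ORF", "ncRNA", "tRNA", "pseudogene")


@dataclass(frozen=True)
class GeneFeature:
    """A strand-aware gene-level feature with optional known TSS positions."""

    interval: GenomicInterval
    gene_id: str
    kind: str = "ORF"
    tss: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.kind not in GENE_KINDS:
            raise ValueError(f"gene {self.gene_id}: unknown kind {self.kind!r}")
        lo, hi = self.interval.start, self.interval.end
        if self.interval.strand == "+":
            lo -= TSS_UPSTREAM_SLACK
        else:
            hi += TSS_UPSTREAM_SLACK
        for t in self.tss:
            if not lo <= t <= hi:
                raise ValueError(
                    f"gene {self.gene_id}: TSS {t} outside interval "
                    f"extended {TSS_UPSTREAM_SLACK} bp upstream"
                )

    @property
    def tx_start(self) -> int:
        """Genomic position where transcription of this gene begins (5' end)."""
        return self.interval.start if self.interval.strand == "+" else self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {id: uppercase sequence}.

    The record id is the first whitespace-delimited token of the header.
    Sequences are restricted to A/C/G/T/N (case-insensitive); violations
    raise :class:`ParseError` naming the offending line.
    """
    records: dict[str, str] = {}
    current: Optional[str] = None
    chunks: list[str] = []

    def _flush() -> None:
        if current is not None:
            records[current] = "".join(chunks)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:].strip()
                if not header:
                    raise ParseError(f"{path}: line {lineno}: empty FASTA header")
                _flush()
                current = header.split()[0]
                chunks = []
            else:
                if current is None:
                    raise ParseError(
                        f"{path}: line {lineno}: sequence before any header"
                    )
                seq = line.upper()
                bad = set(seq) - FASTA_ALPHABET
                if bad:
                    raise ParseError(
                        f"{path}: line {lineno}: illegal character(s) "
                        f"{''.join(sorted(bad))!r} in sequence"
                    )
                chunks.append(seq)
    _flush()
    return records


def write_fasta(records: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_annotation(path) -> list[GeneFeature]:
    """Read gene-level features from a GFF3 file, sorted by (chrom, start).

    Recognised feature types are gene, ncRNA, tRNA and pseudogene; every
    feature must carry an ``ID`` attribute.  Coordinates are kept 1-based
    inclusive, as in GFF3.  An optional ``tss`` attribute (comma-separated
    integers) records experimentally known transcription start sites.
    """
    import gffutils

    kind_map = {"gene": "ORF", "ncRNA": "ncRNA", "tRNA": "tRNA", "pseudogene": "pseudogene"}
    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", keep_order=True, merge_strategy="create_unique"
        )
    except Exception as exc:  # gffutils raises a mix of its own + sqlite errors
        raise ParseError(f"{path}: not parseable as GFF3: {exc}") from exc

    genes: list[GeneFeature] = []
    for feat in db.all_features():
        if feat.featuretype not in kind_map:
            continue
        if "ID" not in feat.attributes:
            raise ParseError(f"{path}: feature at {feat.seqid}:{feat.start} lacks ID")
        if feat.end < feat.start:
            raise ParseError(
                f"{path}: feature {feat.attributes['ID'][0]}: end < start"
            )
        tss: tuple[int, ...] = ()
        if "tss" in feat.attributes:
            try:
                tss = tuple(
                    int(x) for v in feat.attributes["tss"] for x in str(v).split(",") if x
                )
            except ValueError as exc:
                raise ParseError(
                    f"{path}: feature {feat.attributes['ID'][0]}: bad tss attribute"
                ) from exc
        try:
            genes.append(
                GeneFeature(
                    interval=GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand),
                    gene_id=feat.attributes["ID"][0],
                    kind=kind_map[feat.featuretype],
                    tss=tss,
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start))
    return genes


def write_gff3(genes: Iterable[GeneFeature], path, header_lines: Sequence[str] = ()) -> None:
    type_map = {"ORF": "gene", "ncRNA": "ncRNA", "tRNA": "tRNA", "pseudogene": "pseudogene"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in header_lines:
            fh.write(f"# {line}\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.tss:
                attrs += ";tss=" + ",".join(str(t) for t in g.tss)
            fh.write(
                "\t".join(
                    [
                        g.interval.chrom,
                        "sigchip",
                        type_map[g.kind],
                        str(g.interval.start),
                        str(g.interval.end),
                        ".",
                        g.interval.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_intervals(path, format: str = "BED") -> list[tuple[GenomicInterval, Optional[float]]]:
    """Read BED or bedGraph intervals, converting to 1-based inclusive.

    A BED start ``s``, end ``e`` (0-based half-open) becomes start ``s+1``,
    end ``e``.  bedGraph values (and BED score columns, when present) are
    attached as the second tuple element; otherwise the score is None.
    BED strand (column 6) is carried onto the interval.
    """
    fmt = format.lower()
    if fmt not in ("bed", "bedgraph"):
        raise ValueError(f"unknown interval format {format!r}")
    out: list[tuple[GenomicInterval, Optional[float]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                s, e = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if s < 0 or e < 0:
                raise ParseError(f"{path}: line {lineno}: negative coordinate")
            if e <= s:
                raise ParseError(
                    f"{path}: line {lineno}: empty or inverted interval ({s}, {e})"
                )
            score: Optional[float] = None
            strand = "."
            if fmt == "bedgraph":
                if len(fields) < 4:
                    raise ParseError(f"{path}: line {lineno}: bedGraph needs 4 columns")
                try:
                    score = float(fields[3])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}: line {lineno}: non-numeric bedGraph value"
                    ) from exc
                if math.isnan(score):
                    raise ParseError(f"{path}: line {lineno}: NaN bedGraph value")
            else:
                if len(fields) >= 5 and fields[4] not in (".", ""):
                    try:
                        score = float(fields[4])
                    except ValueError as exc:
                        raise ParseError(
                            f"{path}: line {lineno}: non-numeric BED score"
                        ) from exc
                if len(fields) >= 6 and fields[5] in ("+", "-"):
                    strand = fields[5]
            out.append((GenomicInterval(chrom, s + 1, e, strand), score))
    return out


def write_intervals(
    items: Iterable[tuple[GenomicInterval, Optional[float]]],
    path,
    header_lines: Sequence[str] = (),
) -> None:
    """Write intervals as BED6 (internal 1-based inclusive -> BED convention)."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for i, (iv, score) in enumerate(items):
            sc = "." if score is None else f"{score:g}"
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\tiv{i}\t{sc}\t{iv.strand}\n"
            )


def write_bedgraph(depth, chrom: str, path, header_lines: Sequence[str] = ()) -> None:
    """Write a per-base depth vector as run-length-compressed bedGraph."""
    import numpy as np

    depth = np.asarray(depth)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        if depth.size == 0:
            return
        change = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [depth.size]))
        for s, e in zip(starts, ends):
            fh.write(f"{chrom}\t{s}\t{e}\t{depth[s]:g}\n")


def write_peaks(peaks, path, header_lines: Sequence[str] = ()) -> None:
    """Write called peaks as BED6+3 (p-value, enrichment, summit columns).

    Internal 1-based inclusive coordinates are converted back to the BED
    convention; :func:`read_peaks` inverts this exactly.
    """
    with open(path, "w") as fh:
        fh.write("# BED6+3: chrom start end name score strand p_value enrichment summit\n")
        for line in header_lines:
            fh.write(f"# {line}\n")
        for i, pk in enumerate(peaks):
            iv = pk.interval
            score = 0 if pk.p_value <= 0 else min(1000, int(round(-10 * math.log10(pk.p_value))))
            if pk.p_value == 0:
                score = 1000
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\tpeak_{i + 1}\t{score}\t"
                f"{iv.strand}\t{pk.p_value:.6g}\t{pk.enrichment:.6g}\t{pk.summit}\n"
            )


def read_peaks(path) -> "list":
    """Read a file written by :func:`write_peaks` back into Peak objects."""
    from .peaks import Peak

    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "name", "score", "strand", "p_value", "enrichment", "summit"],
        )
    except pd.errors.EmptyDataError:
        return []
    peaks = []
    for row in df.itertuples(index=False):
        peaks.append(
            Peak(
                interval=GenomicInterval(str(row.chrom), int(row.start) + 1, int(row.end), str(row.strand)),
                p_value=float(row.p_value),
                enrichment=float(row.enrichment),
                summit=int(row.summit),
            )
        )
    return peaks
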