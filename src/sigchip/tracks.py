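"""Fragment sets and per-base coverage tracks.

Fragments are stored as vectors of 1-based start positions, lengths and
strands on a single (optionally circular) replicon.  A fragment whose end
runs past the sequence end wraps around the origin when the replicon is
circular, mirroring a bacterial chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .formats_io import GenomicInterval

__all__ = ["FragmentSet", "CoverageTrack", "coverage_from_fragments"]


@dataclass
class FragmentSet:
    """Aligned sonication fragments for one sequencing library."""

    chrom: str
    genome_length: int
    start: np.ndarray  # 1-based start positions, int64
    length: np.ndarray  # fragment lengths, int64
    strand: np.ndarray  # '+' or '-' per fragment
    circular: bool = True

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=np.int64)
        self.length = np.asarray(self.length, dtype=np.int64)
        self.strand = np.asarray(self.strand)
        if not (len(self.start) == len(self.length) == len(self.strand)):
            raise ValueError("start/length/strand must have equal lengths")
        if self.n_fragments and (self.start.min() < 1 or self.start.max() > self.genome_length):
            raise ValueError("fragment starts must lie in [1, genome_length]")
        if self.n_fragments and self.length.min() < 1:
            raise ValueError("fragment lengths must be positive")
        if not self.circular and self.n_fragments:
            if (self.start + self.length - 1).max() > self.genome_length:
                raise ValueError("fragment runs past the end of a linear sequence")

    @property
    def n_fragments(self) -> int:
        return len(self.start)

    @property
    def end(self) -> np.ndarray:
        """Inclusive end positions; may exceed genome_length for wrapped fragments."""
        return self.start + self.length - 1

    def five_prime(self) -> np.ndarray:
        """1-based genomic position of each fragment's 5' end (strand-aware)."""
        pos = np.where(self.strand == "+", self.start, self.end)
        return (pos - 1) % self.genome_length + 1

    def intervals(self) -> list[GenomicInterval]:
        """Fragments as (possibly origin-clipped) 1-based intervals."""
        out = []
        L = self.genome_length
        for s, ln, st in zip(self.start, self.length, self.strand):
            e = s + ln - 1
            if e <= L:
                out.append(GenomicInterval(self.chrom, int(s), int(e), str(st)))
            else:  # wrapped: emit the two arcs
                out.append(GenomicInterval(self.chrom, int(s), L, str(st)))
                out.append(GenomicInterval(self.chrom, 1, int(e - L), str(st)))
        return out


@dataclass
class CoverageTrack:
    """Per-base depth for one library, plus the library size behind it."""

    chrom: str
    depth: np.ndarray
    n_fragments: int

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.float64)

    @property
    def genome_length(self) -> int:
        return self.depth.size

    @property
    def total_mass(self) -> float:
        return float(self.depth.sum())

    @property
    def mean_fragment_length(self) -> float:
        if self.n_fragments == 0:
            raise ValueError("empty track has no mean fragment length")
        return self.total_mass / self.n_fragments

    def mean_depth(self, interval: GenomicInterval) -> float:
        if interval.end > self.genome_length:
            raise ValueError("interval outside track")
        return float(self.depth[interval.start - 1 : interval.end].mean())


def coverage_from_fragments(
    fragments: FragmentSet, genome_length: Optional[int] = None
) -> CoverageTrack:
    """Per-base depth where each fragment adds 1 to every base it covers.

    Total mass equals the sum of fragment widths (wrapped fragments included).
    """
    L = genome_length if genome_length is not None else fragments.genome_length
    if fragments.n_fragments and fragments.end.max() > L and not fragments.circular:
        raise ValueError("fragments extend past a linear sequence end")
    diff = np.zeros(L + 1, dtype=np.int64)
    s = fragments.start - 1  # 0-based
    e = fragments.start + fragments.length - 1  # 0-based exclusive end
    inside = e <= L
    np.add.at(diff, s[inside], 1)
    np.add.at(diff, e[inside], -1)
    if not inside.all():
        sw, ew = s[~inside], e[~inside]
        np.add.at(diff, sw, 1)
        diff[L] -= len(sw)
        wrap_len = ew - L
        diff[0] += len(ew)
        np.add.at(diff, wrap_len, -1)
    depth = np.cumsum(diff[:L])
    return CoverageTrack(chrom=fragments.chrom, depth=depth, n_fragments=fragments.n_fragments)
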