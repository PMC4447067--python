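"""Genomic-context classification and promoter attribution of peaks.

A called peak is attributed to the gene(s) whose promoter it plausibly
covers, using the rules of the source study: the direction of
transcription of the neighbouring genes, the distance from the peak to
the nearest gene starts, and — when annotated — the presence of an
experimentally determined TSS inside the peak.  Peaks between divergently
transcribed genes that cannot be resolved are attributed to both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .formats_io import GeneFeature, GenomicInterval

__all__ = [
    "AttributionParams",
    "GeneCall",
    "PeakAnnotation",
    "classify_peak",
    "summarize_annotations",
    "join_prior_evidence",
    "CONTEXTS",
]

CONTEXTS = (
    "promoter_unequivocal",
    "promoter_divergent",
    "promoter_internal",  # single-gene promoter lying within another ORF
    "intragenic",
    "excluded_multiORF",
    "ambiguous",  # same-strand exact distance tie; never guessed
)

PROMOTER_CONTEXTS = ("promoter_unequivocal", "promoter_divergent", "promoter_internal")
SINGLE_GENE_CONTEXTS = ("promoter_unequivocal", "promoter_internal")


@dataclass(frozen=True)
class AttributionParams:
    max_upstream_distance: int = 500  # peak edge to gene start
    big_peak_length: int = 1000  # wider peaks kept only with a unique candidate
    multi_orf_limit: int = 5  # peaks containing this many ORFs are excluded
    tss_tolerance: int = 1  # a printed TSS may abut the peak by one base

    def __post_init__(self) -> None:
        if min(self.max_upstream_distance, self.big_peak_length, self.multi_orf_limit) <= 0:
            raise ValueError("attribution parameters must be positive")


@dataclass(frozen=True)
class GeneCall:
    gene_id: str
    strand: str
    distance: int  # peak edge to gene transcription start, bp (0 if inside)
    tss_contained: bool


@dataclass(frozen=True)
class PeakAnnotation:
    interval: GenomicInterval
    context: str
    genes: tuple[GeneCall, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        n = len(self.genes)
        if self.context in SINGLE_GENE_CONTEXTS and n != 1:
            raise ValueError(f"{self.context} requires exactly 1 gene, got {n}")
        if self.context == "promoter_divergent":
            if n != 2 or {g.strand for g in self.genes} != {"+", "-"}:
                raise ValueError("promoter_divergent requires 2 genes on opposite strands")
        if self.context in ("intragenic", "excluded_multiORF") and n != 0:
            raise ValueError(f"{self.context} must carry no attributed genes")


def _as_interval(peak) -> GenomicInterval:
    if isinstance(peak, GenomicInterval):
        return peak
    return peak.interval


def _candidate(
    peak: GenomicInterval, gene: GeneFeature, params: AttributionParams
) -> "GeneCall | None":
    """A gene is a candidate when its transcription is directed away from
    the peak and starts within the attribution distance, or when one of its
    annotated TSSs lies inside the peak."""
    tss_contained = any(peak.contains(t, params.tss_tolerance) for t in gene.tss)
    ts = gene.tx_start
    if gene.strand == "+":
        directed_away = ts >= peak.start
        distance = max(0, ts - peak.end)
    else:
        directed_away = ts <= peak.end
        distance = max(0, peak.start - ts)
    if (directed_away and distance <= params.max_upstream_distance) or tss_contained:
        return GeneCall(gene.gene_id, gene.strand, distance, tss_contained)
    return None


def classify_peak(
    peak,
    annotation: Sequence[GeneFeature],
    params: AttributionParams = AttributionParams(),
) -> PeakAnnotation:
    """Classify one peak's genomic context and attribute it to gene(s).

    Decision cascade: (1) a peak fully containing ``multi_orf_limit`` or
    more genes is excluded; (2) candidate genes are collected by
    distance/direction and TSS containment; (3) an over-length peak
    (> ``big_peak_length``) is kept only with a unique candidate; (4) one
    candidate gives ``promoter_unequivocal`` (``promoter_internal`` when
    the peak lies inside another ORF); (5) two opposite-strand candidates
    resolve to one gene only by unique TSS containment, else
    ``promoter_divergent``; (6) no candidate gives ``intragenic``.
    """
    iv = _as_interval(peak)
    on_chrom = [g for g in annotation if g.interval.chrom == iv.chrom]
    if not on_chrom:
        raise ValueError(f"peak on unannotated sequence {iv.chrom!r}")

    contained = [
        g for g in on_chrom if iv.start <= g.interval.start and g.interval.end <= iv.end
    ]
    if len(contained) >= params.multi_orf_limit:
        return PeakAnnotation(iv, "excluded_multiORF")

    by_gene: dict[str, GeneCall] = {}
    candidate_features: dict[str, GeneFeature] = {}
    for g in on_chrom:
        call = _candidate(iv, g, params)
        if call is not None:
            by_gene[g.gene_id] = call
            candidate_features[g.gene_id] = g
    candidates = sorted(by_gene.values(), key=lambda c: (c.distance, c.gene_id))

    if iv.width > params.big_peak_length and len(candidates) != 1:
        return PeakAnnotation(iv, "excluded_multiORF")

    def _inside_other_orf(call: GeneCall) -> bool:
        return any(
            g.gene_id != call.gene_id
            and g.kind == "ORF"
            and g.interval.start <= iv.start
            and iv.end <= g.interval.end
            for g in on_chrom
        )

    if not candidates:
        return PeakAnnotation(iv, "intragenic")

    if len(candidates) == 1:
        call = candidates[0]
        ctx = "promoter_internal" if _inside_other_orf(call) else "promoter_unequivocal"
        return PeakAnnotation(iv, ctx, (call,))

    # several candidates: a uniquely TSS-supported gene wins outright
    with_tss = [c for c in candidates if c.tss_contained]
    if len(with_tss) == 1:
        call = with_tss[0]
        ctx = "promoter_internal" if _inside_other_orf(call) else "promoter_unequivocal"
        return PeakAnnotation(iv, ctx, (call,))

    pool = with_tss if with_tss else candidates
    if len(pool) == 2 and {c.strand for c in pool} == {"+", "-"}:
        return PeakAnnotation(iv, "promoter_divergent", tuple(pool))

    # same-strand (or >2-way) competition: nearer gene start wins, exact tie
    # is reported as ambiguous rather than guessed
    pool = sorted(pool, key=lambda c: (c.distance, c.gene_id))
    if len(pool) > 1 and pool[0].distance == pool[1].distance:
        return PeakAnnotation(iv, "ambiguous", tuple(pool))
    call = pool[0]
    ctx = "promoter_internal" if _inside_other_orf(call) else "promoter_unequivocal"
    return PeakAnnotation(iv, ctx, (call,))


def summarize_annotations(
    annotations: Sequence[PeakAnnotation], total_called: int
) -> dict[str, int]:
    """Accounting report over a set of annotated peaks.

    ``total_called`` is the full number of peaks called in the experiment;
    annotations may cover only the promoter-attributable subset, in which
    case the remainder is reported as intragenic-or-excluded.
    """
    n_unequivocal = sum(1 for a in annotations if a.context in SINGLE_GENE_CONTEXTS)
    n_internal = sum(1 for a in annotations if a.context == "promoter_internal")
    n_divergent = sum(1 for a in annotations if a.context == "promoter_divergent")
    n_promoter = n_unequivocal + n_divergent
    if total_called < n_promoter:
        raise ValueError("total_called smaller than the number of promoter peaks")
    n_nonpromoter = total_called - n_promoter
    pct = round(100 * n_nonpromoter / total_called) if total_called else 0
    return {
        "n_promoter": n_promoter,
        "n_unequivocal": n_unequivocal,
        "n_divergent": n_divergent,
        "n_internal": n_internal,
        "n_intergenic": n_promoter - n_internal,
        "n_intragenic_or_excluded": n_nonpromoter,
        "pct_nonpromoter": pct,
        "total_called": total_called,
    }


def join_prior_evidence(
    annotations: Sequence[PeakAnnotation], evidence_flags: Mapping[str, bool]
) -> tuple[int, int]:
    """Count attributed genes with prior sigma-S-dependence evidence.

    Returns ``(n_unequivocal_flagged, n_total_flagged)``: flagged genes
    among single-gene attributions, and flagged genes among all attributed
    genes (both members of a flagged divergent pair count).
    """
    n_single = 0
    n_total = 0
    for ann in annotations:
        if ann.context not in PROMOTER_CONTEXTS:
            continue
        for call in ann.genes:
            if call.gene_id not in evidence_flags:
                raise ValueError(f"no evidence flag for gene {call.gene_id!r}")
            if evidence_flags[call.gene_id]:
                n_total += 1
                if ann.context in SINGLE_GENE_CONTEXTS:
                    n_single += 1
    return n_single, n_total
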