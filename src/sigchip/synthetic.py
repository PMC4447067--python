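"""Synthetic ChIP-seq experiments with planted RNA-polymerase binding sites.

Generates a toy circular genome with annotated genes, plants holoenzyme
binding sites in intergenic promoter regions (writing a -20..+1 promoter
sequence of either the sigma-S or the sigma-70 class into the genome), and
simulates paired IP / Input sonication-fragment libraries:

* Input fragments start uniformly over the genome with lengths uniform on
  the sonication range (default 100-400 bp).
* The IP library is a mixture: background fragments as in the Input, plus,
  for each planted site, fragments constrained to contain the site's
  binding footprint.  The per-site share is chosen so that expected IP
  coverage across the footprint is ``enrichment_fold`` times the local IP
  background, while the library still totals exactly ``depth`` fragments.

Every quantity is reproducible from ``SimulationParams.seed`` alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .formats_io import GeneFeature, GenomicInterval
from .tracks import CoverageTrack, FragmentSet, coverage_from_fragments

__all__ = [
    "SimulationParams",
    "PlantedSite",
    "SimulationTruth",
    "generate_genome",
    "simulate_libraries",
    "coverage_from_fragments",
    "sample_promoter_window",
    "promoter_profile",
    "dps_like_params",
    "reference_intervals",
    "site_interval",
    "reverse_complement",
    "CHROM",
    "BASES",
    "SIGMA_S",
    "SIGMA_70",
]

CHROM = "synchrom"
BASES = np.array(list("ACGT"))
SIGMA_S = "sigmaS"
SIGMA_70 = "sigma70"

# window coordinates: index 0..19 = promoter positions -20..-1, index 20 = +1
WINDOW_LEN = 21

_SLOT_MIN = 800  # minimal per-gene slot, leaves room for ORF + promoter


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one synthetic ChIP-seq experiment."""

    genome_length: int = 200_000
    n_genes: int = 40
    n_sites: int = 10
    enrichment_fold: float = 10.0
    fragment_size_range: tuple[int, int] = (100, 400)
    depth: int = 100_000
    seed: int = 0
    promoter_class_mix: float = 0.5  # fraction of sites given sigma-S promoters
    divergent_fraction: float = 0.2  # fraction of sites in a divergent layout
    footprint: int = 50  # bp of DNA protected by the bound polymerase
    circular: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.fragment_size_range
        if lo < 50 or hi <= lo:
            raise ValueError("fragment_size_range must satisfy min >= 50, max > min")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")
        if self.footprint >= lo:
            raise ValueError("footprint must be smaller than the shortest fragment")
        if not 0 <= self.promoter_class_mix <= 1:
            raise ValueError("promoter_class_mix must be in [0, 1]")
        if self.n_sites > self.n_genes:
            raise ValueError("cannot plant more sites than genes")
        if self.n_genes * _SLOT_MIN > self.genome_length:
            raise ValueError(
                f"{self.n_genes} genes need at least {self.n_genes * _SLOT_MIN} bp"
            )


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted holoenzyme binding site."""

    position: int  # 1-based binding-site (footprint) center
    promoter_class: str  # SIGMA_S or SIGMA_70
    promoter_sequence: str  # strand-oriented 21-mer covering -20..+1
    enrichment_fold: float
    tss: int  # genomic position of the designated +1
    strand: str
    gene_ids: tuple[str, ...]  # expected attribution (1 gene, or 2 if divergent)
    layout: str  # 'unequivocal' or 'divergent'


@dataclass(frozen=True)
class SimulationTruth:
    params: SimulationParams
    sites: tuple[PlantedSite, ...] = field(default_factory=tuple)


def promoter_profile(promoter_class: str) -> np.ndarray:
    """Per-position base probabilities (21 x ACGT) used to draw promoters.

    The sigma-S class fixes the selectivity determinants (C at -13/-12,
    C at -8, T at -6) and favors an A/T-rich discriminator; the sigma-70
    class fixes the canonical -12T of TATAAT and favors a G/C-rich
    discriminator.
    """
    U = [0.25, 0.25, 0.25, 0.25]  # A C G T
    if promoter_class == SIGMA_S:
        disc = [0.425, 0.075, 0.075, 0.425]
        rows = (
            [U, U, U]  # -20..-18
            + [[0.05, 0.05, 0.05, 0.85]]  # -17 T
            + [U]  # -16
            + [[0.05, 0.05, 0.05, 0.85]]  # -15 T
            + [[0.05, 0.05, 0.85, 0.05]]  # -14 G
            + [[0.0, 1.0, 0.0, 0.0]]  # -13 C (determinant)
            + [[0.0, 1.0, 0.0, 0.0]]  # -12 C (determinant)
            + [[0.85, 0.05, 0.05, 0.05]] * 3  # -11..-9 A
            + [[0.0, 1.0, 0.0, 0.0]]  # -8 C (determinant)
            + [[0.05, 0.05, 0.05, 0.85]]  # -7 T
            + [[0.0, 0.0, 0.0, 1.0]]  # -6 T (determinant)
            + [disc] * 5  # -5..-1 discriminator
            + [[0.5, 0.1, 0.3, 0.1]]  # +1 purine-biased
        )
    elif promoter_class == SIGMA_70:
        disc = [0.1, 0.4, 0.4, 0.1]
        rows = (
            [U, U, U, U, U, U, U]  # -20..-14
            + [[0.15, 0.15, 0.15, 0.55]]  # -13 mostly T
            + [[0.0, 0.0, 0.0, 1.0]]  # -12 T (canonical)
            + [[0.85, 0.05, 0.05, 0.05]]  # -11 A
            + [[0.05, 0.05, 0.05, 0.85]]  # -10 T
            + [[0.85, 0.05, 0.05, 0.05]]  # -9 A
            + [[0.85, 0.05, 0.05, 0.05]]  # -8 A
            + [[0.05, 0.05, 0.05, 0.85]]  # -7 T
            + [[0.2, 0.3, 0.3, 0.2]]  # -6
            + [disc] * 5  # -5..-1 discriminator
            + [[0.5, 0.1, 0.3, 0.1]]  # +1
        )
    else:
        raise ValueError(f"unknown promoter class {promoter_class!r}")
    return np.array(rows, dtype=float)


def _at_fraction(window: str, lo: int, hi: int) -> float:
    seg = window[lo:hi]
    return sum(c in "AT" for c in seg) / len(seg)


def sample_promoter_window(promoter_class: str, rng: np.random.Generator) -> str:
    """Draw one 21-mer promoter window; class invariants are enforced.

    sigma-S windows always carry -13C/-12C/-8C/-6T and a discriminator
    (-6..-1) with A/T fraction >= 2/3; sigma-70 windows carry -12T and a
    discriminator A/T fraction <= 1/2.  The discriminator is redrawn on the
    rare draws that miss the class bound.
    """
    profile = promoter_profile(promoter_class)
    for _ in range(200):
        idx = np.array([rng.choice(4, p=row) for row in profile])
        window = "".join(BASES[idx])
        at = _at_fraction(window, 14, 20)  # positions -6..-1
        if promoter_class == SIGMA_S and at >= 2 / 3:
            return window
        if promoter_class == SIGMA_70 and at <= 0.5:
            return window
    raise RuntimeError("failed to satisfy promoter class invariant")  # pragma: no cover


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def generate_genome(
    params: SimulationParams,
) -> tuple[str, list[GeneFeature], SimulationTruth]:
    """Build a random genome, gene annotation and planted binding sites.

    Genes occupy evenly spaced slots on alternating random strands.  Each
    planted site sits in the intergenic region upstream of its gene
    (unequivocal layout) or between two divergently transcribed genes
    (divergent layout), with the class-specific promoter 21-mer written
    into the genome at -20..+1 of the designated TSS.  The binding-site
    center is placed 15 bp upstream of the TSS, roughly the middle of the
    region an initiation-poised polymerase occupies.
    """
    rng = np.random.default_rng([params.seed, 0])
    L = params.genome_length
    seq = rng.choice(BASES, size=L)  # uniform background composition

    slot = L // params.n_genes
    site_slots = set(
        rng.choice(params.n_genes, size=params.n_sites, replace=False).tolist()
    )
    n_divergent = int(round(params.divergent_fraction * params.n_sites))
    divergent_slots = set(list(sorted(site_slots))[:n_divergent]) if n_divergent else set()

    genes: list[GeneFeature] = []
    sites: list[PlantedSite] = []
    gene_no = 0

    def _plant(window: str, tss: int, strand: str) -> None:
        # window index 20 is the +1 base; indices 0..19 are -20..-1
        if strand == "+":
            seq[tss - 21 : tss] = list(window)
        else:
            seq[tss - 1 : tss + 20] = list(reverse_complement(window))

    for i in range(params.n_genes):
        s0 = i * slot + 1
        if i in site_slots:
            cls = SIGMA_S if rng.random() < params.promoter_class_mix else SIGMA_70
            fold = params.enrichment_fold
            window = sample_promoter_window(cls, rng)
            if i in divergent_slots:
                g_minus = GeneFeature(
                    GenomicInterval(CHROM, s0, s0 + 299, "-"),
                    gene_id=f"gene{gene_no:04d}",
                )
                # the planted TSS is deliberately NOT annotated: the layout
                # must stay unresolvable, like the published divergent pairs
                g_plus = GeneFeature(
                    GenomicInterval(CHROM, s0 + 499, s0 + 798, "+"),
                    gene_id=f"gene{gene_no + 1:04d}",
                )
                gene_no += 2
                tss, strand = s0 + 439, "+"
                center = tss - 15
                genes.extend([g_minus, g_plus])
                gene_ids: tuple[str, ...] = (g_minus.gene_id, g_plus.gene_id)
                layout = "divergent"
            else:
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "+":
                    iv = GenomicInterval(CHROM, s0 + 199, s0 + 798, "+")
                    tss = s0 + 139
                    center = tss - 15
                else:
                    iv = GenomicInterval(CHROM, s0, s0 + 599, "-")
                    tss = s0 + 659
                    center = tss + 15
                g = GeneFeature(iv, gene_id=f"gene{gene_no:04d}", tss=(tss,))
                gene_no += 1
                genes.append(g)
                gene_ids = (g.gene_id,)
                layout = "unequivocal"
            _plant(window, tss, strand)
            sites.append(
                PlantedSite(
                    position=center,
                    promoter_class=cls,
                    promoter_sequence=window,
                    enrichment_fold=fold,
                    tss=tss,
                    strand=strand,
                    gene_ids=gene_ids,
                    layout=layout,
                )
            )
        else:
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneFeature(
                    GenomicInterval(CHROM, s0 + 99, s0 + 698, strand),
                    gene_id=f"gene{gene_no:04d}",
                )
            )
            gene_no += 1

    truth = SimulationTruth(params=params, sites=tuple(sites))
    return "".join(seq), genes, truth


def simulate_libraries(
    genome, sites: Sequence[PlantedSite], params: SimulationParams
) -> tuple[FragmentSet, FragmentSet]:
    """Simulate the IP and Input fragment libraries for one experiment.

    ``genome`` may be the sequence string or its length.  Both libraries
    contain exactly ``params.depth`` fragments; the IP library allocates
    fragments between uniform background and per-site components so that
    expected footprint coverage is ``enrichment_fold`` x local background.
    """
    L = len(genome) if not isinstance(genome, (int, np.integer)) else int(genome)
    if params.depth <= 0:
        raise ValueError("depth must be positive")
    for s in sites:
        if not 1 <= s.position <= L:
            raise ValueError(f"site at {s.position} outside genome of length {L}")
    rng = np.random.default_rng([params.seed, 1])
    lo, hi = params.fragment_size_range
    mean_len = (lo + hi) / 2
    N = params.depth

    def _background(n: int, r: np.random.Generator) -> tuple[np.ndarray, ...]:
        starts = r.integers(1, L + 1, size=n)
        lengths = r.integers(lo, hi + 1, size=n)
        strands = np.where(r.random(n) < 0.5, "+", "-")
        return starts, lengths, strands

    # Input: pure sonication background
    in_start, in_len, in_strand = _background(N, rng)
    input_lib = FragmentSet(CHROM, L, in_start, in_len, in_strand, circular=params.circular)

    # IP: solve the background share so that each site's expected extra
    # fragment count is (fold - 1) x expected background per-base coverage.
    folds = np.array([s.enrichment_fold for s in sites], dtype=float)
    excess = (folds - 1.0).sum() * mean_len / L
    n_bg_expected = N / (1.0 + excess)
    site_weights = (folds - 1.0) * n_bg_expected * mean_len / L
    probs = np.concatenate(([n_bg_expected], site_weights))
    probs /= probs.sum()
    counts = rng.multinomial(N, probs)

    ip_start, ip_len, ip_strand = _background(int(counts[0]), rng)
    parts_s, parts_l, parts_t = [ip_start], [ip_len], [ip_strand]
    half = params.footprint // 2
    for site, n_k in zip(sites, counts[1:]):
        n_k = int(n_k)
        if n_k == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=n_k)
        # fragment [s, s+len-1] must contain the footprint [c-half, c+half-1]
        foot_hi = site.position + half - 1
        starts = foot_hi - lengths + 1 + rng.integers(
            0, lengths - params.footprint + 1
        )
        starts = (starts - 1) % L + 1
        strands = np.where(rng.random(n_k) < 0.5, "+", "-")
        parts_s.append(starts)
        parts_l.append(lengths)
        parts_t.append(strands)
    ip_lib = FragmentSet(
        CHROM,
        L,
        np.concatenate(parts_s),
        np.concatenate(parts_l),
        np.concatenate(parts_t),
        circular=params.circular,
    )
    return ip_lib, input_lib


def dps_like_params(seed: int, depth: int = 50_000) -> SimulationParams:
    """One strongly enriched promoter site on a 200 kb genome.

    Emulates the single-locus quality-control comparison of a known
    sigma-S-dependent promoter against unenriched coding-sequence
    references: one planted site at 10-fold enrichment, unequivocal layout.
    """
    return SimulationParams(
        genome_length=200_000,
        n_genes=40,
        n_sites=1,
        enrichment_fold=10.0,
        depth=depth,
        seed=seed,
        promoter_class_mix=1.0,
        divergent_fraction=0.0,
    )


def reference_intervals(
    genes: Sequence[GeneFeature],
    truth: SimulationTruth,
    n: int = 2,
    width: int = 300,
) -> list[GenomicInterval]:
    """Background reference loci: interior windows of unenriched gene bodies."""
    planted = {gid for s in truth.sites for gid in s.gene_ids}
    refs = []
    for g in genes:
        if g.gene_id in planted or g.interval.width < width + 2:
            continue
        mid = (g.interval.start + g.interval.end) // 2
        refs.append(
            GenomicInterval(g.interval.chrom, mid - width // 2, mid + width // 2 - 1)
        )
        if len(refs) == n:
            break
    if len(refs) < n:
        raise ValueError("not enough unenriched genes for reference intervals")
    return refs


def site_interval(site: PlantedSite, footprint: int = 50) -> GenomicInterval:
    """The planted site's binding footprint as a genomic interval."""
    half = footprint // 2
    return GenomicInterval(CHROM, site.position - half, site.position + half - 1)
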