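"""Promoter -10 region alignment, consensus derivation and sigma-S scoring.

Promoters are represented as 21-mers covering positions -20..+1 relative
to the TSS, aligned so the first base of the -10 hexamer sits at -12 (the
hexamer occupies -12..-7).  The IUPAC consensus is reported for -17..-6.
The sigma-S selectivity determinants scored here are the C residues at
-13, -12 and -8, the T at -6, and the A/T richness of the discriminator
(-6..-1, the segment between the -10 element and the transcription
start); an optional feature measures similarity of a supplied -35 region
to the sigma-70 consensus TTGACA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PromoterRecord",
    "ConsensusModel",
    "SigmaSFeatures",
    "pos_index",
    "extract_promoter_window",
    "build_consensus",
    "score_sigmaS_features",
    "classify_promoter",
    "calibrate_threshold",
    "WINDOW_LEN",
    "POSITIONS",
]

WINDOW_LEN = 21
# window positions, 5' to 3': -20..-1 then +1 (there is no position 0)
POSITIONS = tuple(range(-20, 0)) + (1,)
ALPHABET = "ACGT"

MINUS10_START, MINUS10_END = -12, -7  # the -10 hexamer
CONSENSUS_START, CONSENSUS_END = -17, -6  # reported consensus region (12 nt)
DISCRIMINATOR_START, DISCRIMINATOR_END = -6, -1

SIGMA70_MINUS35 = "TTGACA"

_IUPAC_PAIRS = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def pos_index(position: int) -> int:
    """Array index of a promoter position (-20..-1, +1) within the window."""
    if -20 <= position <= -1:
        return position + 20
    if position == 1:
        return 20
    raise ValueError(f"no window position {position}")


@dataclass(frozen=True)
class PromoterRecord:
    gene_id: str
    tss: int  # 1-based genomic position of +1
    strand: str
    window: str  # strand-oriented 21-mer, window[-1] is the +1 base
    dependence_label: str = "unknown"  # sigmaS_dependent / sigmaS_independent / unknown

    def __post_init__(self) -> None:
        if len(self.window) != WINDOW_LEN:
            raise ValueError(f"{self.gene_id}: window must be {WINDOW_LEN} nt")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")


def extract_promoter_window(genome: str, tss: int, strand: str, circular: bool = False) -> str:
    """The strand-oriented -20..+1 window around a TSS.

    On the minus strand the reverse complement is taken, so the returned
    window always reads 5'->3' with its last base at the TSS.
    """
    L = len(genome)
    if strand == "+":
        lo, hi = tss - 21, tss  # 0-based slice bounds
    elif strand == "-":
        lo, hi = tss - 1, tss + 20
    else:
        raise ValueError("strand must be + or -")
    if circular:
        window = "".join(genome[i % L] for i in range(lo, hi))
    else:
        if lo < 0 or hi > L:
            raise ValueError(f"window around TSS {tss} outside linear sequence")
        window = genome[lo:hi]
    window = window.upper()
    if strand == "-":
        window = window.translate(_COMPLEMENT)[::-1]
    return window


@dataclass(frozen=True)
class ConsensusModel:
    """Position frequencies over -20..+1 and the -17..-6 IUPAC consensus."""

    frequencies: np.ndarray  # (21, 4) over ACGT, each row sums to 1
    iupac_consensus: str  # 12 letters, positions -17..-6
    n_records: int
    single_letter_threshold: float = 0.75
    pair_threshold: float = 0.85

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.frequencies, index=list(POSITIONS), columns=list(ALPHABET))


def _iupac_letter(freqs: np.ndarray, single_thr: float, pair_thr: float) -> str:
    order = np.lexsort((list(ALPHABET), -freqs))  # by freq desc, base alphabetical
    b1, b2 = order[0], order[1]
    if freqs[b1] >= single_thr:
        return ALPHABET[b1]
    if freqs[b1] + freqs[b2] >= pair_thr:
        pair = frozenset((ALPHABET[b1], ALPHABET[b2]))
        return _IUPAC_PAIRS[pair]
    return "N"


def consensus_from_frequencies(
    frequencies: np.ndarray,
    single_letter_threshold: float = 0.75,
    pair_threshold: float = 0.85,
) -> str:
    """Apply the IUPAC consensus rule to a (21, 4) frequency table."""
    lo, hi = pos_index(CONSENSUS_START), pos_index(CONSENSUS_END)
    return "".join(
        _iupac_letter(frequencies[i], single_letter_threshold, pair_threshold)
        for i in range(lo, hi + 1)
    )


def build_consensus(
    records: Iterable,
    single_letter_threshold: float = 0.75,
    pair_threshold: float = 0.85,
) -> ConsensusModel:
    """Position frequency table and IUPAC consensus from aligned promoters.

    ``records`` may be :class:`PromoterRecord` objects or plain window
    strings.  Per position, the consensus letter is the single base when
    its frequency reaches ``single_letter_threshold``, else the two-base
    degenerate code when the top two reach ``pair_threshold``, else N.
    """
    windows = [r.window if hasattr(r, "window") else str(r) for r in records]
    if len(windows) < 2:
        raise ValueError("need at least 2 promoter records")
    lengths = {len(w) for w in windows}
    if lengths != {WINDOW_LEN}:
        raise ValueError(f"all windows must be {WINDOW_LEN} nt, got lengths {sorted(lengths)}")
    counts = np.zeros((WINDOW_LEN, 4))
    base_idx = {b: i for i, b in enumerate(ALPHABET)}
    for w in windows:
        for i, ch in enumerate(w.upper()):
            if ch not in base_idx:
                raise ValueError(f"non-ACGT base {ch!r} in window {w}")
            counts[i, base_idx[ch]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    consensus = consensus_from_frequencies(freqs, single_letter_threshold, pair_threshold)
    return ConsensusModel(
        frequencies=freqs,
        iupac_consensus=consensus,
        n_records=len(windows),
        single_letter_threshold=single_letter_threshold,
        pair_threshold=pair_threshold,
    )


@dataclass(frozen=True)
class SigmaSFeatures:
    has_m13C: bool
    has_m12C: bool
    has_m8C: bool
    has_m6T: bool
    discriminator_at_fraction: float
    composite_score: float
    minus35_sigma70_match: Optional[float] = None  # 1 - editdist/6 to TTGACA
    undefined_positions: tuple[int, ...] = ()

    @property
    def defined(self) -> bool:
        return not self.undefined_positions


DEFAULT_WEIGHTS = {"m13C": 1.0, "m12C": 1.0, "m8C": 1.0, "m6T": 1.0, "discriminator": 2.0}


def _edit_distance(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def score_sigmaS_features(
    window: str,
    minus35: Optional[str] = None,
    weights: Optional[dict] = None,
) -> SigmaSFeatures:
    """Read the sigma-S selectivity determinants off one promoter window.

    The composite score is a weighted sum of the four determinant booleans
    plus the discriminator A/T fraction.  A non-ACGT base at any scored
    position flags the feature set as undefined (score NaN) rather than
    guessing.
    """
    if len(window) != WINDOW_LEN:
        raise ValueError(f"window must be {WINDOW_LEN} nt")
    w = dict(DEFAULT_WEIGHTS, **(weights or {}))
    win = window.upper()
    scored = [-13, -12, -8, -6] + list(range(DISCRIMINATOR_START, DISCRIMINATOR_END + 1))
    undefined = tuple(p for p in scored if win[pos_index(p)] not in ALPHABET)

    disc = [win[pos_index(p)] for p in range(DISCRIMINATOR_START, DISCRIMINATOR_END + 1)]
    at_fraction = sum(c in "AT" for c in disc) / len(disc)
    has = {
        "m13C": win[pos_index(-13)] == "C",
        "m12C": win[pos_index(-12)] == "C",
        "m8C": win[pos_index(-8)] == "C",
        "m6T": win[pos_index(-6)] == "T",
    }
    if undefined:
        score = float("nan")
    else:
        score = sum(w[k] * has[k] for k in has) + w["discriminator"] * at_fraction
    match = None
    if minus35 is not None:
        match = 1.0 - _edit_distance(minus35.upper(), SIGMA70_MINUS35) / len(SIGMA70_MINUS35)
    return SigmaSFeatures(
        has_m13C=has["m13C"],
        has_m12C=has["m12C"],
        has_m8C=has["m8C"],
        has_m6T=has["m6T"],
        discriminator_at_fraction=at_fraction,
        composite_score=score,
        minus35_sigma70_match=match,
        undefined_positions=undefined,
    )


def calibrate_threshold(scores_sigmaS: Sequence[float], scores_sigma70: Sequence[float]) -> float:
    """Midpoint of the two class mean composite scores."""
    return (float(np.mean(scores_sigmaS)) + float(np.mean(scores_sigma70))) / 2.0


def classify_promoter(features: SigmaSFeatures, threshold: float) -> str:
    """'sigmaS' when the composite score reaches the threshold, else 'sigma70'."""
    if not features.defined:
        raise ValueError(
            f"features undefined at positions {features.undefined_positions}"
        )
    return "sigmaS" if features.composite_score >= threshold else "sigma70"
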